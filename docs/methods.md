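# Methods

`perturbmap` analyses multiplexed in vivo perturbation experiments read out by
probe-based spatial transcriptomics.  A pool of perturbation plasmids, each
tagged with an array of 50-nt capture barcodes, induces hundreds of coexisting
tumour nodules in one tissue; the package converts spot-level barcode counts
into per-nodule genotypes, tests the genotype population for selection and
epistasis, links genotypes to phenotypes with regularised GLMs, and analyses
validation cohorts in which single perturbations are left out of the pool.

## Genotype model

Barcode counts `D[s, b]` at spot `s` are negative binomial with mean

    lambda[s, b] = mu_s * (sum_r A[s, r] sum_g G[r, g] B[g, b]) * kappa_b + xi_b

and overdispersion `phi_b`.  `A` assigns spots to annotated regions, `B` links
the 8 plasmids to their 38 barcodes, `kappa_b` is a barcode expression rate,
`xi_b` an additive background, and `mu_s` a per-spot sensitivity that also
absorbs tumour-purity dilution.  The integration load `G[r, g]` is the
expectation of a categorical variable `F[r, g, o]` over `o = 0..6` copies
(seven states; at most six copies of one plasmid per clone) with a uniform
Dirichlet prior.  Priors: `phi ~ Gamma(1000, 0.03)` (pushes the likelihood
toward Poisson unless the data demand overdispersion), `mu ~ Gamma(3, 0.3)`,
`kappa, xi ~ Exponential(1)`.  Annotated normal-tissue regions are clamped to
a presence of 1e-3 — near absence, but not zero, for numerical stability.
Presence of plasmid `g` in region `r` is `P[r, g] = 1 - E[F[r, g, 0]]`.

### Inference

No probabilistic-programming backend is used: the package ships a compact
stochastic variational inference engine (`perturbmap.svi`).  Guides are
log-normal for the positive scalars and Dirichlet for each `F[r, g, .]`.
The ELBO is estimated as analytic KL/entropy terms plus a Monte-Carlo
likelihood term with pathwise gradients: log-normals are reparameterised as
`exp(loc + scale * eps)`; Dirichlet gradients use implicit reparameterisation
of the underlying Gamma variates, with the CDF derivative obtained by central
finite differences of the regularised incomplete gamma function (step
`1e-5 * max(alpha, 0.01)`).  Optimisation uses Adam at learning rate 0.01
with 3 Monte-Carlo samples per step for 10,000 steps, monitoring the ELBO
(no early stopping).  Special functions of `y + phi_b` are evaluated once per
distinct count value per barcode, which makes a 2,000-spot fit take minutes
on one CPU core.  Dirichlet concentrations are floored at 1e-6; all
computations are double precision.

Numerical choices worth knowing:

* The Dirichlet guide is initialised absence-biased (concentration 3 on the
  zero-copy state, 0.3 elsewhere).  Real signal pulls the guide off this
  start within a few hundred steps; on weak data it keeps early dynamics out
  of degenerate corners.
* The likelihood has a ridge: for a barcode with no signal anywhere,
  `kappa_b -> 0` explains the data exactly as well as absence of
  integrations.  The factorised (mean-field) guide cannot represent this
  ridge, so on data where a barcode is entirely blank its rate collapses and
  the corresponding copy-number posteriors revert to their prior (presence
  6/7).  This is a property of the variational family, not of the model; the
  exact posterior, marginalising `kappa`, favours absence.  Operationally
  such barcodes never reach the model: the preprocessing step flags barcodes
  whose pooled log1p expression per 1e4 counts falls below 0.05, mirroring
  how blank barcodes are excluded in practice.  Fits should therefore be run
  after `flag_low_signal_barcodes`, and presence calls for flagged barcodes'
  plasmids interpreted with care.

## Genotype statistics

Representative genotypes are sampled from the fitted posterior (first `F`
from its Dirichlet posterior, then Bernoulli presence; 5,000 draws by
default) and aggregated across nodules into the `2^8 = 256` genotype states.
The enrichment null holds marginal plasmid frequencies and the expected
number of integrations fixed and draws genotypes independently; `p(O > E)`
compares paired observed/null occurrence counts per state with half-weight
on ties, so identical distributions sit at 0.5 exactly.  The observed
marginal-frequency rescaling prescribed for the null (divide by the summed
frequencies, multiply by the expected integration count) is the identity
unless the expected-integration target is overridden — the override knob is
exposed (`expected_integrations`), and the default reproduces the observed
marginals.

Pairwise epistasis is parameterised by the saturated softmax model of the
2x2 co-occurrence table, in which the interaction coefficient `theta_11`
equals the log odds ratio `log(p11 p00 / p10 p01)`.  Odds ratios are
summarised per posterior draw (median and central 95% interval over draws;
a +0.5 continuity addition is applied, and flagged, when any cell is empty).
The interaction test fits the independence model (`theta_11 = 0`, which
factorises into the observed margins), simulates full 2x2 tables at the
observed nodule count, and compares the deviation of the double-positive
proportion from independence between observed and simulated tables
(two-tailed mid-P).  Re-estimating the margins in every simulated table is
what keeps the test calibrated; comparing raw double-positive proportions
against a fixed-margin binomial is conservative because the observed
statistic and the null share margin-estimation noise.

## Genotype-to-phenotype GLMs

Binary nodule phenotypes follow `Y ~ Bernoulli(sigmoid(X w + z_k))` with the
batch effect `z_k` inside the link — the printed form with the batch effect
added outside the sigmoid can leave the unit interval, so the inside-link
form is used deliberately.  Spot-level expression follows
`Y ~ Poisson(mu_s exp(X w + z_k))` with the spot sensitivity as a
multiplicative offset.  Weights carry Laplace priors centred at zero: scale
1 for the intercept, 0.1 for perturbation weights in the binary model, and a
strongly regularising 1e-3 in the expression model; batch effects are
Laplace(0, 1).  Mean-field Gaussian guides are optimised with the same SVI
engine (2,000 steps, learning rate 0.01, 3 samples).  When a genotype
posterior is supplied, `X = 1 - F[., ., 0]` and `mu` are redrawn from it at
each gradient step, propagating genotype uncertainty into the coefficients;
a fixed-X fast path exists for testing.  Intervals are mean +/- 3 posterior
standard deviations; transcriptome-wide runs select genes whose any
perturbation interval excludes zero (a documented default — the selection
rule behind published gene lists is not uniquely determined) and cluster the
selected genes by average-linkage hierarchical clustering of coefficient
vectors under correlation distance.

## Phenotype pipeline

Counts are filtered (genes with < 10 or > 1e6 raw counts on any slide are
dropped, barcodes excluded), scaled to 1e4 per spot, and log1p-transformed.
Highly variable genes are selected per slide with the Seurat-style
binned-dispersion statistic (via scanpy) and intersected across slides.
Expression is aggregated per nodule as the mean (tumour-intrinsic readouts)
or the 95th percentile (microenvironment readouts), rescaled per gene by
`(x - q25) / (q99 - q25)` over all nodules of all slides (linear-interpolation
quantiles, not clipped; genes with `q99 == q25` are flagged degenerate), and
phenotypes are called when the core-marker average strictly exceeds 0.5.
The shipped marker sets are deliberately partial seed lists (e.g. Krt19/Cldn7
for cholangiocarcinoma-like, Sds/Sdsl portal-like, Cyp2e1/Oat central-like,
Col1a1/Col3a1 fibroblast); users supply full signature CSVs.  Coexpression
graphs come from an L1-penalised Gaussian graphical model on the gene-gene
correlation matrix (penalty 0.3) with edges kept only when the absolute
pairwise Pearson correlation is at least 0.25, then isolated genes dropped.
Heatmap ordering uses average-linkage clustering of 1 - Spearman
correlation, with plasmid presence annotations sharpened as `p^10`.

## Leave-one-out count model

Tumour counts per section are `y ~ Poisson(exp(beta_g + alpha_a))` with
`beta_g ~ N(0, sigma_beta)`, `sigma_beta ~ HalfCauchy(1.0)`,
`alpha_a ~ N(0, sigma_alpha)`, `sigma_alpha ~ HalfCauchy(0.05)` (animal
effects deliberately more regularised than group effects).  The posterior is
sampled with an affine-invariant ensemble sampler (emcee) using
differential-evolution moves, a non-centred parameterisation, and two
independent ensembles of >= 2*dim+2 walkers; 1,000 warm-up steps are
discarded and 3,000 draws retained.  Convergence is reported as split-chain
R-hat computed across the two independent ensembles (walkers within one
ensemble interact, so they are pooled rather than treated as chains); values
above 1.05 trigger a warning.  Directional contrasts are posterior tail
probabilities of `beta` differences.  Group summaries report both the mean
and the median of the posterior rate.  The accompanying nonparametric
analysis is a two-sided Kruskal-Wallis omnibus test followed by Dunn's
post-hoc z tests computed from tie-corrected ranks with Holm-Bonferroni
adjustment; Dunn's test is implemented directly from the rank formulas.

## Synthetic data

The generator emulates the statistical structure the inference assumes, not
tissue realism: spots on a 100-um grid; circular nodules covering about half
the array; one normal region annotated by the same distance rule the
preprocessing uses (>= 300 um from any tumour spot); genotypes drawn
independently per nodule with presence probability 0.6 per plasmid and a
truncated-geometric copy number on 1..6 (decay 0.5) given presence;
`mu ~ Gamma(3, 0.3)`, `kappa ~ Exponential(scale 5)` (bright barcodes),
`xi ~ Exponential(scale 0.05)` (faint background),
`phi ~ Gamma(1000, 0.03)`; counts negative binomial around the same rate
equation the model fits.  Fifty unstructured filler genes at rate
`25 * mu_s` give spots realistic totals so the 5,000-UMI filter behaves as
on real data.  Phenotype genes follow the Poisson GLM above with supplied
weights; leave-one-out tables follow the hierarchical count model.  One seed
drives a simulation, with sub-streams spawned per component.

What passing tests on these simulations do *not* show: robustness to
segmentation errors in nodule annotation, spatial autocorrelation of
sensitivity, doublet-like nodule overlap, platform chemistry differences, or
marker-set misspecification — none of which the generator models.

## Problem sizes used in the checks

The acceptance script and test suite run the full model at 2,000 spots, 50
nodules, 8 plasmids x 24 barcodes and 10,000 variational steps — the scale
at which a single fit remains a few minutes on one core — and scale
repetition counts (e.g. 20 GLM repetitions, 200 interaction-test
repetitions at 500 simulations each) so the whole suite completes in well
under half an hour.
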