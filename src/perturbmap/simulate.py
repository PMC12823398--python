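"""Ground-truthed synthetic tissue generator.

Generates Visium-like datasets with the exact statistical structure the
inference modules assume, so every stage of the pipeline can be exercised and
validated against a known truth:

* spots on a regular grid (100 um pitch), partitioned into circular tumour
  nodules, a distant normal-tissue region and unassigned spots;
* per-nodule plasmid genotypes: presence is Bernoulli per plasmid, and present
  plasmids carry 1..max_copies integrated copies (truncated geometric);
* barcode counts are negative binomial around the same mean law the genotype
  model fits (spot sensitivity x copies x barcode rate + background);
* phenotype genes follow the Poisson GLM of the genotype-to-phenotype module;
* leave-one-out tumour counts follow the hierarchical Poisson model
  (group effect + normal animal effect on the log scale).

One seed governs a simulation; component sub-streams are spawned
deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SimulationConfig
from .data import BarcodeDesign, CountMatrix, NoduleMap, SpotTable
from .errors import ConfigurationError
from .genotype import expected_rate
from .preprocess import annotate_normal_spots

__all__ = [
    "SimulationTruth",
    "simulate_tissue",
    "simulate_phenotype_genes",
    "simulate_loo_counts",
]


@dataclass
class SimulationTruth:
    """Generative ground truth underlying a synthetic tissue."""

    copies: np.ndarray  # (n_nodules, n_plasmids) integer copies 0..max
    presence: np.ndarray  # copies > 0
    mu: np.ndarray  # per-spot sensitivity
    kappa: np.ndarray  # per-barcode rate
    xi: np.ndarray  # per-barcode background
    phi: np.ndarray  # per-barcode overdispersion
    region_ids: list  # nodule region ids, ordering of `copies`
    lam: np.ndarray  # (spots, barcodes) expected barcode counts

    def __post_init__(self) -> None:
        for name in ("mu", "kappa", "xi", "phi"):
            if np.any(getattr(self, name) < 0):
                raise ConfigurationError(f"truth field {name} must be >= 0")


def _truncated_geometric(rng, p_decay: float, max_copies: int, size) -> np.ndarray:
    """Copies on {1..max_copies}: P(c) proportional to p_decay**(c-1)."""
    support = np.arange(1, max_copies + 1)
    pmf = p_decay ** (support - 1.0)
    pmf /= pmf.sum()
    return rng.choice(support, size=size, p=pmf)


def simulate_tissue(
    n_spots: int | None = None,
    n_nodules: int | None = None,
    design: BarcodeDesign | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
    sample_id: str = "sim0",
) -> tuple[CountMatrix, SpotTable, NoduleMap, SimulationTruth]:
    """Generate one synthetic sample.

    Returns barcode counts (plus unstructured filler genes when configured),
    the spot table, the nodule map (with a distance-annotated normal region)
    and the generative truth.
    """
    config = config or SimulationConfig()
    n_spots = config.n_spots if n_spots is None else n_spots
    n_nodules = config.n_nodules if n_nodules is None else n_nodules
    if n_spots < 1 or n_nodules < 1:
        raise ConfigurationError("n_spots and n_nodules must be positive")
    design = design or _default_design()
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(6)]
    rng_geo, rng_gt, rng_rates, rng_counts, rng_filler, _ = rngs

    # -- spot grid
    side = int(np.ceil(np.sqrt(n_spots)))
    rows, cols = np.divmod(np.arange(n_spots), side)
    x = cols * config.spot_spacing_um
    y = rows * config.spot_spacing_um
    spot_ids = np.array([f"{sample_id}_s{i}" for i in range(n_spots)])

    # -- circular nodules covering ~tumour_fraction of the tissue
    centers = np.column_stack([
        rng_geo.uniform(x.min(), x.max(), n_nodules),
        rng_geo.uniform(y.min(), y.max(), n_nodules),
    ])
    area = (x.max() - x.min() + config.spot_spacing_um) * \
           (y.max() - y.min() + config.spot_spacing_um)
    radius = np.sqrt(config.tumour_fraction * area / (np.pi * n_nodules))
    coords = np.column_stack([x, y])
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    nearest = d2.argmin(axis=1)
    in_disc = d2[np.arange(n_spots), nearest] <= radius ** 2
    region_ids = [f"{sample_id}_nod{j}" for j in range(n_nodules)]
    map_rows = [
        {"spot_id": spot_ids[i], "region_id": region_ids[nearest[i]],
         "region_class": "nodule"}
        for i in np.flatnonzero(in_disc)
    ]
    nodule_map = NoduleMap(pd.DataFrame(
        map_rows, columns=["spot_id", "region_id", "region_class"]))

    # -- genotypes
    G_n = design.n_plasmids
    p = np.broadcast_to(np.asarray(config.presence_prob, dtype=float), (G_n,))
    presence = rng_gt.random((n_nodules, G_n)) < p[None, :]
    copies = np.where(
        presence,
        _truncated_geometric(rng_gt, config.copy_decay, 6, (n_nodules, G_n)),
        0,
    )

    # -- rates and counts
    B_n = design.n_barcodes
    mu = rng_rates.gamma(config.mu_shape, 1.0 / config.mu_rate, n_spots)
    kappa = rng_rates.exponential(config.kappa_scale, B_n)
    xi = rng_rates.exponential(config.xi_scale, B_n)
    phi = rng_rates.gamma(config.phi_shape, 1.0 / config.phi_rate, B_n)

    A = nodule_map.membership_matrix(spot_ids, region_ids)
    lam = expected_rate(mu, A, copies.astype(float), design.matrix(), kappa, xi)
    with np.errstate(divide="ignore", invalid="ignore"):
        nb_p = np.where(phi[None, :] + lam > 0, phi[None, :] / (phi[None, :] + lam), 1.0)
    counts = rng_counts.negative_binomial(np.broadcast_to(phi, lam.shape), nb_p)

    features = pd.DataFrame({
        "feature_id": design.barcodes, "feature_kind": "barcode"})
    matrix = counts
    if config.n_filler_genes > 0:
        filler_rate = config.filler_gene_rate * mu[:, None]
        filler = rng_filler.poisson(
            np.broadcast_to(filler_rate, (n_spots, config.n_filler_genes)))
        matrix = np.hstack([counts, filler])
        features = pd.concat([
            features,
            pd.DataFrame({
                "feature_id": [f"gene{i}" for i in range(config.n_filler_genes)],
                "feature_kind": "gene",
            }),
        ], ignore_index=True)

    count_matrix = CountMatrix(sp.csr_matrix(matrix), features, spot_ids)
    spots = SpotTable(pd.DataFrame({
        "spot_id": spot_ids, "x": x, "y": y,
        "sample_id": sample_id, "platform": "manual",
        "row": rows, "col": cols,
        "total_umi": count_matrix.row_sums().astype(int),
    }))
    nodule_map = annotate_normal_spots(spots, nodule_map, min_distance=300.0)

    truth = SimulationTruth(
        copies=copies, presence=presence, mu=mu, kappa=kappa, xi=xi, phi=phi,
        region_ids=region_ids, lam=lam,
    )
    return count_matrix, spots, nodule_map, truth


def _default_design() -> BarcodeDesign:
    from .barcodes import default_design

    return default_design()


def spot_presence_design(
    truth: SimulationTruth, nodule_map: NoduleMap, spot_ids: np.ndarray
) -> np.ndarray:
    """Spot-level explanatory matrix X[s, g]: the nodule's presence indicator
    propagated to its member spots (0 outside nodules)."""
    A = nodule_map.membership_matrix(spot_ids, truth.region_ids)
    return A @ truth.presence.astype(float)


def simulate_phenotype_genes(
    truth: SimulationTruth,
    nodule_map: NoduleMap,
    spot_ids: np.ndarray,
    weights: np.ndarray,
    batch_effects: np.ndarray | float = 0.0,
    batch_labels: np.ndarray | None = None,
    mu: np.ndarray | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Poisson phenotype genes: Y[s, m] ~ Poisson(mu_s * exp(X[s,:] @ w[:,m] + z_k)).

    ``weights`` is (n_plasmids, n_genes); ``batch_effects`` is a scalar or a
    per-batch vector indexed by ``batch_labels``.  ``mu`` defaults to the
    tissue truth's spot sensitivity.
    """
    rng = np.random.default_rng(seed)
    X = spot_presence_design(truth, nodule_map, spot_ids)
    mu = truth.mu if mu is None else np.asarray(mu, dtype=float)
    z = np.asarray(batch_effects, dtype=float)
    if z.ndim == 0:
        z_per_spot = np.full(len(spot_ids), float(z))
    else:
        if batch_labels is None:
            raise ConfigurationError("batch_labels required with per-batch effects")
        z_per_spot = z[np.asarray(batch_labels)]
    rate = mu[:, None] * np.exp(X @ weights + z_per_spot[:, None])
    if not np.all(np.isfinite(rate)):
        raise ConfigurationError("non-finite Poisson rates")
    counts = rng.poisson(rate)
    n_genes = weights.shape[1]
    features = pd.DataFrame({
        "feature_id": [f"pheno{i}" for i in range(n_genes)],
        "feature_kind": "gene",
    })
    return CountMatrix(sp.csr_matrix(counts), features, np.asarray(spot_ids))


def simulate_loo_counts(
    beta_by_group: dict[str, float],
    sigma_alpha: float,
    n_animals: int,
    n_sections: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Tumour-count table for a leave-one-out style cohort.

    Each group gets ``n_animals`` animals with effects alpha ~ N(0, sigma_alpha)
    and ``n_sections`` sections per animal; counts are Poisson(exp(beta_g + alpha_a)).
    Returns a table with columns group, animal, section, count.
    """
    if sigma_alpha < 0:
        raise ConfigurationError("sigma_alpha must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, beta in beta_by_group.items():
        for a in range(n_animals):
            alpha = rng.normal(0.0, sigma_alpha) if sigma_alpha > 0 else 0.0
            rate = np.exp(beta + alpha)
            for s in range(n_sections):
                rows.append({
                    "group": group,
                    "animal": f"{group}_a{a}",
                    "section": s,
                    "count": int(rng.poisson(rate)),
                })
    return pd.DataFrame(rows)
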