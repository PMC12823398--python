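"""Population statistics over posterior genotype draws.

Works on binary draw arrays of shape (n_draws, n_nodules, n_plasmids) as
produced by :func:`perturbmap.genotype.sample_genotypes`:

* powerset aggregation of nodules into the 2^n genotype states, with
  per-state medians and credible intervals over draws;
* the integration-order distribution with a Binomial(n, 1/2) reference;
* per-plasmid marginal frequencies;
* a marginal-preserving independence null over genotype states, and the
  enrichment probability p(O > E) per state;
* pairwise co-occurrence odds ratios -- in the saturated softmax model of the
  2x2 co-occurrence table the interaction coefficient theta_11 equals log OR --
  and a simulation-based two-tailed interaction test with the independence
  (theta_11 = 0) fit as the null;
* replicate concordance of presence probabilities across paired sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "InteractionResult",
    "powerset_aggregate",
    "order_distribution",
    "marginal_frequencies",
    "null_expected_distribution",
    "p_observed_gt_expected",
    "pairwise_or",
    "interaction_test",
    "replicate_concordance",
]


def _check_draws(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws)
    if draws.ndim != 3:
        raise ValueError("draws must have shape (n_draws, n_nodules, n_plasmids)")
    if not np.isin(draws, (0, 1)).all():
        raise ValueError("draws must be binary")
    if draws.shape[2] > 16:
        raise ValueError("more than 16 plasmids: genotype table too large")
    return draws.astype(np.uint8)


def _state_counts(draws: np.ndarray) -> np.ndarray:
    """(n_draws, 2^n) occurrence counts of each genotype state per draw."""
    n_draws, n_nodules, n_plasmids = draws.shape
    weights = (1 << np.arange(n_plasmids)).astype(np.int64)
    states = draws.astype(np.int64) @ weights
    n_states = 1 << n_plasmids
    counts = np.zeros((n_draws, n_states), dtype=np.int64)
    for d in range(n_draws):
        counts[d] = np.bincount(states[d], minlength=n_states)
    return counts


def state_labels(n_plasmids: int, plasmid_names=None) -> list[str]:
    """Bitmask labels for the 2^n genotype states ('' for the empty genotype)."""
    names = plasmid_names or [f"p{g}" for g in range(n_plasmids)]
    return [
        "+".join(names[g] for g in range(n_plasmids) if (s >> g) & 1)
        for s in range(1 << n_plasmids)
    ]


def powerset_aggregate(draws: np.ndarray, ci: float = 0.95) -> pd.DataFrame:
    """Per-genotype occurrence distribution over draws.

    Returns a table with one row per state (bitmask order): median and central
    credible interval of the nodule count carrying that exact genotype.
    """
    draws = _check_draws(draws)
    counts = _state_counts(draws)
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    return pd.DataFrame({
        "state": np.arange(counts.shape[1]),
        "median": np.median(counts, axis=0),
        "lo": np.quantile(counts, lo, axis=0),
        "hi": np.quantile(counts, hi, axis=0),
        "mean": counts.mean(axis=0),
    })


def order_distribution(draws: np.ndarray, ci: float = 0.95) -> pd.DataFrame:
    """Distribution of the integration order (number of plasmids per nodule).

    Frequencies sum to one within each draw; the table also carries the
    Binomial(n, 1/2) reference pmf of an unbiased random integration rate.
    """
    draws = _check_draws(draws)
    n_draws, n_nodules, n = draws.shape
    orders = draws.sum(axis=2)
    freq = np.stack([
        np.bincount(orders[d], minlength=n + 1) / n_nodules
        for d in range(n_draws)
    ])
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    return pd.DataFrame({
        "order": np.arange(n + 1),
        "mean": freq.mean(axis=0),
        "lo": np.quantile(freq, lo, axis=0),
        "hi": np.quantile(freq, hi, axis=0),
        "binomial_reference": sps.binom.pmf(np.arange(n + 1), n, 0.5),
    })


def marginal_frequencies(
    draws: np.ndarray, plasmid_names=None, ci: float = 0.95
) -> pd.DataFrame:
    """Per-plasmid presence frequency (mean over nodules), summarised over
    draws and reported in descending order of the mean."""
    draws = _check_draws(draws)
    per_draw = draws.mean(axis=1)  # (n_draws, n_plasmids)
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    names = plasmid_names or [f"p{g}" for g in range(draws.shape[2])]
    out = pd.DataFrame({
        "plasmid": names,
        "mean": per_draw.mean(axis=0),
        "lo": np.quantile(per_draw, lo, axis=0),
        "hi": np.quantile(per_draw, hi, axis=0),
    })
    return out.sort_values("mean", ascending=False).reset_index(drop=True)


def null_expected_distribution(
    draws: np.ndarray,
    n_nodules: int | None = None,
    n_sim: int = 5000,
    seed: int = 0,
    expected_integrations: float | None = None,
) -> np.ndarray:
    """Simulated per-genotype occurrence counts under the independence null.

    The null holds marginal plasmid frequencies and the expected number of
    integrations fixed: observed marginal frequencies are divided by their sum
    and multiplied by the expected integration count (by default that sum
    itself, so the rescaling is the identity unless
    ``expected_integrations`` overrides it), then nodule genotypes are drawn
    as independent Bernoullis and aggregated into the 2^n states.

    Returns an (n_sim, 2^n) count array.
    """
    draws = _check_draws(draws)
    rng = np.random.default_rng(seed)
    n_nodules = n_nodules or draws.shape[1]
    n = draws.shape[2]
    marginals = draws.mean(axis=(0, 1))
    total = marginals.sum()
    target = total if expected_integrations is None else expected_integrations
    p = marginals / total * target if total > 0 else marginals
    if np.any(p > 1):
        warnings.warn("rescaled null probabilities exceed 1; clipping")
        p = np.minimum(p, 1.0)
    sims = (rng.random((n_sim, n_nodules, n)) < p[None, None, :]).astype(np.uint8)
    return _state_counts(sims)


def p_observed_gt_expected(
    observed_counts: np.ndarray, null_counts: np.ndarray, seed: int = 0
) -> np.ndarray:
    """p(O > E) per genotype state, with half-weight on ties.

    ``observed_counts`` and ``null_counts`` are (draws, states) count arrays,
    paired in order (both sides are exchangeable draws); when sizes differ the
    longer side is subsampled with ``seed``.  Identical distributions give 0.5
    by the tie rule, and p(O>E) computed both ways partitions unity:
    p(O>E) + p(E>O) = 1 for a fixed pairing.
    """
    obs = np.asarray(observed_counts)
    null = np.asarray(null_counts)
    rng = np.random.default_rng(seed)
    n = min(obs.shape[0], null.shape[0])
    o = obs if obs.shape[0] == n else obs[rng.permutation(obs.shape[0])[:n]]
    e = null if null.shape[0] == n else null[rng.permutation(null.shape[0])[:n]]
    return ((o > e).mean(axis=0) + 0.5 * (o == e).mean(axis=0))


def _tables_per_draw(draws: np.ndarray, ia: int, ib: int) -> np.ndarray:
    """(n_draws, 4) co-occurrence counts [n00, n01, n10, n11] over nodules."""
    a = draws[:, :, ia].astype(np.int64)
    b = draws[:, :, ib].astype(np.int64)
    idx = 2 * a + b
    n_draws = draws.shape[0]
    tables = np.zeros((n_draws, 4), dtype=np.int64)
    for d in range(n_draws):
        tables[d] = np.bincount(idx[d], minlength=4)
    return tables


@dataclass
class InteractionResult:
    """Pairwise co-occurrence summary for one plasmid pair.

    ``p_ij`` are mean co-occurrence probabilities (i = first plasmid,
    j = second); ``theta_11`` is the softmax interaction coefficient, equal to
    log OR; ``or_median``/CI summarise the per-draw odds ratios;
    ``p_value`` (two-tailed, simulation) is filled by
    :func:`interaction_test`.
    """

    plasmid_a: str
    plasmid_b: str
    p_00: float
    p_01: float
    p_10: float
    p_11: float
    or_median: float
    or_lo: float
    or_hi: float
    theta_01: float
    theta_10: float
    theta_11: float
    n_draws: int
    continuity_corrected: bool
    p_value: float | None = None

    @property
    def odds_ratio(self) -> float:
        return self.or_median


def pairwise_or(
    draws: np.ndarray, plasmid_a: int, plasmid_b: int,
    plasmid_names=None, ci: float = 0.95,
) -> InteractionResult:
    """Co-occurrence odds ratio OR = p11*p00 / (p10*p01) = exp(theta_11).

    Per draw, the 2x2 table over nodules yields one OR; the summary is the
    median and central credible interval over draws.  Draws with an empty cell
    receive a +0.5 continuity addition to all cells and the result is flagged.
    A degenerate column (plasmid constant in every draw) yields NaN.
    """
    draws = _check_draws(draws)
    names = plasmid_names or [f"p{g}" for g in range(draws.shape[2])]
    tables = _tables_per_draw(draws, plasmid_a, plasmid_b).astype(float)
    n_nodules = draws.shape[1]

    col_a = draws[:, :, plasmid_a]
    col_b = draws[:, :, plasmid_b]
    degenerate = (
        col_a.mean() in (0.0, 1.0) or col_b.mean() in (0.0, 1.0)
    )
    zero_cells = (tables == 0).any()
    work = tables + 0.5 if zero_cells else tables
    with np.errstate(divide="ignore", invalid="ignore"):
        ors = (work[:, 3] * work[:, 0]) / (work[:, 2] * work[:, 1])
    probs = tables.mean(axis=0) / n_nodules
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    if degenerate:
        or_med = or_lo = or_hi = t01 = t10 = t11 = np.nan
    else:
        or_med = float(np.median(ors))
        or_lo = float(np.quantile(ors, lo))
        or_hi = float(np.quantile(ors, hi))
        work_mean = work.mean(axis=0)
        t10 = float(np.log(work_mean[2] / work_mean[0]))
        t01 = float(np.log(work_mean[1] / work_mean[0]))
        t11 = float(np.log(or_med))
    return InteractionResult(
        plasmid_a=names[plasmid_a], plasmid_b=names[plasmid_b],
        p_00=probs[0], p_01=probs[1], p_10=probs[2], p_11=probs[3],
        or_median=or_med, or_lo=or_lo, or_hi=or_hi,
        theta_01=t01, theta_10=t10, theta_11=t11,
        n_draws=draws.shape[0], continuity_corrected=bool(zero_cells),
    )


def interaction_test(
    draws: np.ndarray, plasmid_a: int, plasmid_b: int,
    n_sim: int = 5000, seed: int = 0, plasmid_names=None,
) -> InteractionResult:
    """Two-tailed simulation test of the pairwise interaction.

    The null fits the softmax model with the interaction fixed at zero
    (OR = 1), whose maximum likelihood solution factorises into the observed
    margins.  ``n_sim`` full 2x2 tables are simulated from that null at the
    observed nodule count, and the deviation of the double-positive
    proportion from independence (p11 minus the product of the table's own
    margins) is compared two-tailed between the observed and simulated
    tables; re-estimating the margins per simulated table keeps the test
    calibrated.  The returned :class:`InteractionResult` carries the mid-P
    two-tailed ``p_value``.
    """
    draws = _check_draws(draws)
    rng = np.random.default_rng(seed)
    result = pairwise_or(draws, plasmid_a, plasmid_b, plasmid_names=plasmid_names)
    n_nodules = draws.shape[1]
    if np.isnan(result.or_median):
        result.p_value = np.nan
        return result
    m_a = result.p_10 + result.p_11
    m_b = result.p_01 + result.p_11
    null_cells = np.array([
        (1 - m_a) * (1 - m_b), (1 - m_a) * m_b, m_a * (1 - m_b), m_a * m_b])
    sims = rng.multinomial(n_nodules, null_cells, size=n_sim) / n_nodules
    sim_ma = sims[:, 2] + sims[:, 3]
    sim_mb = sims[:, 1] + sims[:, 3]
    t_sim = sims[:, 3] - sim_ma * sim_mb
    t_obs = result.p_11 - m_a * m_b
    gt = (t_sim > t_obs).mean()
    lt = (t_sim < t_obs).mean()
    eq = (t_sim == t_obs).mean()
    p = 2.0 * min(gt + 0.5 * eq, lt + 0.5 * eq)
    result.p_value = float(min(p, 1.0))
    return result


def replicate_concordance(
    P_a: np.ndarray, P_b: np.ndarray, nodule_pairing: np.ndarray | None = None,
    plasmid_names=None,
) -> pd.DataFrame:
    """Per-plasmid Pearson correlation of presence probabilities across
    paired nodules of two replicate sections.

    ``nodule_pairing`` maps rows of ``P_a`` to rows of ``P_b`` (default:
    identity).  Fewer than 3 pairs yields a missing value.
    """
    P_a = np.asarray(P_a, dtype=float)
    P_b = np.asarray(P_b, dtype=float)
    if nodule_pairing is None:
        pairing = np.arange(min(P_a.shape[0], P_b.shape[0]))
        a_idx = pairing
        b_idx = pairing
    else:
        pairing = np.asarray(nodule_pairing)
        a_idx, b_idx = pairing[:, 0], pairing[:, 1]
    names = plasmid_names or [f"p{g}" for g in range(P_a.shape[1])]
    rows = []
    for g, name in enumerate(names):
        x, y = P_a[a_idx, g], P_b[b_idx, g]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"plasmid": name, "pearson_r": r, "n_pairs": int(x.size)})
    return pd.DataFrame(rows)
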