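"""Docking-score screening statistics.

Compares per-compound docking scores between two target groups (e.g.
DEL-enriched vs DEL-neutral): global Z-score standardization, the
enrichment factor EF(c) at score cutoffs, Monte Carlo resampling of EF
curves, per-target top-fraction extraction, and a one-sided Mann–Whitney U
test with a rank-biserial/normal-approximation effect size.

Docking scores are in kcal/mol; more negative means better predicted
binding, so "hits at cutoff c" are scores <= c.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Default EF cutoff grid: -10 to -8 kcal/mol in 0.25 steps.
DEFAULT_CUTOFFS = tuple(np.arange(-10.0, -8.0 + 1e-9, 0.25))


@dataclass
class EFCurve:
    """Monte Carlo enrichment-factor curve (mean ± SD per cutoff)."""

    cutoffs: np.ndarray
    ef_mean: np.ndarray  # nan where undefined
    ef_sd: np.ndarray
    n_iterations: int
    sample_size: int
    metadata: dict = field(default_factory=dict)


def zscores(scores, ddof: int = 0) -> np.ndarray:
    """Global Z-score transform: (S_i − μ_all) / σ_all.

    Uses the mean and standard deviation over *all* rows (population SD by
    default; ``ddof=1`` for the sample convention).
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    sd = s.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance: Z-scores undefined")
    return (s - s.mean()) / sd


def enrichment_factor(pos_scores, neg_scores, cutoff: float) -> float:
    """EF(c) = (N_pos(c)/N_pos_total) / (N_neg(c)/N_neg_total).

    N(c) counts scores <= c.  Returns NaN when no negative-pool score
    reaches the cutoff (0/0 or x/0 is undefined, never infinity).
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score pools must be non-empty")
    n_neg = np.count_nonzero(neg <= cutoff)
    if n_neg == 0:
        return float("nan")
    frac_pos = np.count_nonzero(pos <= cutoff) / pos.size
    frac_neg = n_neg / neg.size
    return float(frac_pos / frac_neg)


def monte_carlo_ef(pos_scores, neg_scores, cutoffs=DEFAULT_CUTOFFS,
                   sample_size: int = 200, iterations: int = 1000,
                   seed: int = 0) -> EFCurve:
    """Monte Carlo estimate of the EF curve.

    Per iteration, ``sample_size`` scores are drawn without replacement
    from each pool and EF is computed at every cutoff; the returned curve
    is the mean ± SD over iterations (NaN-aware: undefined iterations are
    excluded per cutoff).
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if sample_size > pos.size or sample_size > neg.size:
        raise ValueError(f"sample_size={sample_size} exceeds a pool size")
    cutoffs = np.asarray(cutoffs, dtype=np.float64)
    rng = np.random.default_rng(seed)
    efs = np.full((iterations, cutoffs.size), np.nan)
    for it in range(iterations):
        ps = rng.choice(pos, size=sample_size, replace=False)
        ns = rng.choice(neg, size=sample_size, replace=False)
        for j, c in enumerate(cutoffs):
            efs[it, j] = enrichment_factor(ps, ns, c)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # cutoffs below every sampled score yield all-NaN columns by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(efs, axis=0)
        sd = np.nanstd(efs, axis=0)
    return EFCurve(cutoffs=cutoffs, ef_mean=mean, ef_sd=sd,
                   n_iterations=iterations, sample_size=sample_size,
                   metadata={"sampling": "per-group without replacement"})


def top_fraction(scores, fraction: float = 0.01, compound_ids=None):
    """The ceil(fraction·n) most negative scores of one target.

    Boundary ties are broken by compound id (deterministic).  Returns the
    selected indices into ``scores``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        logger.info("top_fraction: empty target skipped")
        return np.array([], dtype=int)
    k = math.ceil(fraction * s.size)
    ids = list(compound_ids) if compound_ids is not None else [str(i) for i in range(s.size)]
    order = sorted(range(s.size), key=lambda i: (s[i], ids[i]))
    return np.asarray(order[:k], dtype=int)


def top_fraction_per_target(df, fraction: float = 0.01):
    """Apply :func:`top_fraction` per target of a docking-score table.

    ``df`` is a pandas DataFrame with columns compound_id, target_id,
    score.  Returns the concatenated sub-table of selected rows.
    """
    import pandas as pd

    parts = []
    for _, sub in df.groupby("target_id", sort=True):
        idx = top_fraction(sub["score"].to_numpy(), fraction,
                           compound_ids=sub["compound_id"].tolist())
        parts.append(sub.iloc[idx])
    return pd.concat(parts, ignore_index=True) if parts else df.iloc[0:0]


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_value: float
    effect_r: float
    z: float
    method: str


def mann_whitney_one_sided(x, y, exact_threshold: int = 20) -> MannWhitneyResult:
    """One-sided Mann–Whitney U test of x stochastically smaller than y.

    U is the rank-sum statistic of x (midranks for ties).  For small
    untied samples (combined n at most ``exact_threshold``) the p-value is
    exact; otherwise the normal approximation with tie-corrected variance
    and continuity correction is used.  The effect size is
    r = z / sqrt(n_x + n_y), signed (negative when x tends to be smaller).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    Ux = ranks[:nx].sum() - nx * (nx + 1) / 2.0

    has_ties = np.unique(combined).size < n
    mu = nx * ny / 2.0
    # tie-corrected variance of U
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return MannWhitneyResult(U=float(Ux), p_value=1.0, effect_r=0.0, z=0.0,
                                 method="degenerate")
    z = (Ux - mu + 0.5) / math.sqrt(sigma2)  # continuity-corrected, lower tail

    if n <= exact_threshold and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="less", method="exact")
        p = float(res.pvalue)
        method = "exact"
    else:
        p = float(stats.norm.cdf(z))
        method = "normal-approximation"
    return MannWhitneyResult(U=float(Ux), p_value=p, effect_r=float(z / math.sqrt(n)),
                             z=float(z), method=method)
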