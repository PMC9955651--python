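"""Nonparametric repeated-measures statistics and parameter tuning.

The analysis pipeline for a within-subject paced-breathing protocol:
Friedman rank tests (tie-corrected) with Kendall's W as effect size,
Conover all-pairs post-hoc tests with Bonferroni adjustment, consistency
intraclass correlation across segment durations, Mann-Whitney effect
sizes, per-participant direction counts between trial pairs, robust
descriptors (MAD-based coefficient of variation, Theil-Sen slope),
divide-by-maximum standardisation with top-slicing, and the
grid-sweeping parameter tuner with its sign-ratio tie-break.

Conventions follow strict repeated-measures practice: Friedman
significance at p < 0.001, post-hoc adjusted p <= 0.001, Bonferroni
rather than FDR control.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sst

__all__ = [
    "FriedmanResult",
    "PosthocResult",
    "TuningReport",
    "friedman_kendall",
    "conover_posthoc",
    "icc_consistency",
    "mannwhitney_es",
    "direction_counts",
    "robust_descriptors",
    "standardize_topslice",
    "tune_parameter",
    "spearman_rho",
]


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float
    kendall_w: float
    n_blocks: int
    k_treatments: int


@dataclass(frozen=True)
class PosthocResult:
    pairs: tuple
    statistic: np.ndarray       # Conover t per pair (absolute)
    p_adjusted: np.ndarray      # Bonferroni
    standardized: np.ndarray    # S / max S over the compared set
    df: int


@dataclass(frozen=True)
class TuningReport:
    selections: Mapping[str, object]    # strategy -> chosen parameter
    sign_ratios: Mapping[str, float]    # strategy -> ups/downs ratio
    consensus: object                   # parameter or "ambiguous"


def _ranks(data: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sst.rankdata, 1, data)


def friedman_kendall(data) -> FriedmanResult:
    """Friedman rank test with tie correction, plus Kendall's W.

    ``data`` is blocks x treatments (participants x trials).  Within
    each block midranks are assigned; the tie-corrected statistic is
    chi2 = (k-1) * sum_j (R_j - N(k+1)/2)^2 / (A - N k (k+1)^2 / 4)
    with A the sum of squared ranks, reducing to the textbook
    12/(Nk(k+1)) sum R_j^2 - 3N(k+1) without ties.  W = chi2 / (N(k-1)).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be blocks x treatments")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    r = _ranks(data)
    rj = r.sum(axis=0)
    a = float(np.sum(r ** 2))
    denom = a - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:
        chi2 = 0.0  # every block fully tied
    else:
        chi2 = (k - 1) * float(np.sum((rj - n * (k + 1) / 2.0) ** 2)) / denom
    df = k - 1
    p = float(sst.chi2.sf(chi2, df))
    w = chi2 / (n * (k - 1))
    return FriedmanResult(chi2=float(chi2), df=df, p=p, kendall_w=float(w),
                          n_blocks=n, k_treatments=k)


def conover_posthoc(data, pairs: Sequence[tuple[int, int]] | None = None,
                    labels: Sequence[str] | None = None) -> PosthocResult:
    """Conover all-pairs post-hoc test after Friedman.

    For treatments j, l the statistic is
    t = |R_j - R_l| / sqrt(2 N (A - B) / ((N-1)(k-1))),
    with A the sum of squared within-block ranks and B = sum R_j^2 / N,
    referred to Student's t on (N-1)(k-1) degrees of freedom.  p-values
    are Bonferroni-adjusted over the tested pairs; the statistics are
    also returned standardised by their maximum.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k < 3:
        raise ValueError("need at least 3 treatments")
    r = _ranks(data)
    rj = r.sum(axis=0)
    a = float(np.sum(r ** 2))
    b = float(np.sum(rj ** 2)) / n
    df = (n - 1) * (k - 1)
    se = np.sqrt(2.0 * n * max(a - b, 0.0) / df)
    if pairs is None:
        pairs = list(itertools.combinations(range(k), 2))
    diffs = np.array([abs(rj[j] - rj[l]) for j, l in pairs])
    if se > 0:
        stat = diffs / se
        standardized = stat / stat.max() if stat.max() > 0 else \
            np.full_like(stat, np.nan)
    else:
        # perfectly concordant rankings: zero within-treatment rank
        # variance; the statistic diverges but rank-sum differences
        # still order the pairs
        stat = np.where(diffs > 0, np.inf, 0.0)
        standardized = diffs / diffs.max() if diffs.max() > 0 else \
            np.full_like(diffs, np.nan)
    p = 2.0 * sst.t.sf(stat, df)
    p_adj = np.minimum(p * len(pairs), 1.0)
    if labels is not None:
        pair_labels = tuple((labels[j], labels[l]) for j, l in pairs)
    else:
        pair_labels = tuple(pairs)
    return PosthocResult(pairs=pair_labels, statistic=stat, p_adjusted=p_adj,
                         standardized=standardized, df=df)


def icc_consistency(data) -> float:
    """ICC(3,1): two-way mixed, consistency form.

    ``data`` is targets x raters (participants x segment durations).
    ICC = (MSR - MSE) / (MSR + (k-1) MSE) from the two-way ANOVA
    decomposition; column offsets do not affect it.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 columns")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr + (k - 1) * mse == 0:
        raise ValueError("degenerate data: no variance anywhere")
    return float((msr - mse) / (msr + (k - 1) * mse))


def mannwhitney_es(a, b):
    """Mann-Whitney U with normal-approximation Z and effect size |Z|/sqrt(N).

    Midranks with tie correction, no continuity correction.  Returns
    (U, Z, ES) where U counts pairs won by ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    ranks = sst.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return float(u), 0.0, 0.0
    z = (u - mu) / np.sqrt(var)
    return float(u), float(z), float(abs(z) / np.sqrt(n))


def direction_counts(before, after, threshold: float = 0.795):
    """Count per-participant increases/decreases between paired trials.

    Returns (ups, downs, zeros, proportion, consistent): ``proportion``
    is ups/n, and the change is called consistent when the proportion
    exceeds ``threshold`` or falls below 1 - threshold (at n = 44 that
    is 35 or more increases, or 9 or fewer).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    diff = after - before
    ups = int(np.sum(diff > 0))
    downs = int(np.sum(diff < 0))
    zeros = int(np.sum(diff == 0))
    n = diff.size
    proportion = ups / n
    consistent = proportion > threshold or proportion < 1.0 - threshold
    if ups == 0 and downs == 0:
        consistent = False  # degenerate: nothing moved
    return ups, downs, zeros, proportion, consistent


def robust_descriptors(x):
    """Robust coefficient of variation and Theil-Sen slope.

    RoCV = 1.4826 MAD / |median|; RoSlope is the median of pairwise
    slopes of the sample against its index.  Returns (RoCV, RoSlope).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    med = float(np.median(x))
    if med == 0:
        raise ValueError("median is zero; RoCV undefined")
    mad = sst.median_abs_deviation(x, scale=1.0)
    rocv = 1.4826 * float(mad) / abs(med)
    if np.ptp(x) == 0:
        return rocv, 0.0
    slope = sst.theilslopes(x, np.arange(x.size)).slope
    return rocv, float(slope)


def standardize_topslice(values: Mapping[str, float], threshold: float = 0.8):
    """Divide each value by the maximum and retain those >= threshold.

    Returns (standardized dict, retained key set).  The maximal entry is
    always retained.
    """
    if not values:
        raise ValueError("empty value set")
    vmax = max(values.values())
    if vmax <= 0:
        raise ValueError("all values non-positive")
    standardized = {k: v / vmax for k, v in values.items()}
    retained = {k for k, v in standardized.items() if v >= threshold}
    return standardized, retained


def spearman_rho(a, b) -> float:
    """Spearman's rho: Pearson correlation of midranks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input")
    return float(np.corrcoef(sst.rankdata(a), sst.rankdata(b))[0, 1])


def _sign_ratio(diffs: np.ndarray) -> float:
    ups = int(np.sum(diffs > 0))
    downs = int(np.sum(diffs < 0))
    if downs == 0:
        return np.inf if ups > 0 else 1.0
    return ups / downs


def tune_parameter(grid_a: Mapping[object, Sequence[float]],
                   grid_b: Mapping[object, Sequence[float]]) -> TuningReport:
    """Choose a measure parameter from per-participant grids of two trials.

    ``grid_a[param]`` / ``grid_b[param]`` hold the measure values of
    every participant in trials A and B at that parameter setting.
    Strategies:

    * s2 - largest pooled robust CV across both trials;
    * s3 - largest |median(A) - median(B)|;
    * s4 - largest median |paired difference|;
    * s5 - parameter winning the most per-participant maximal
      |difference| counts.

    The consensus is the modal selection; unresolved ties go to the
    strategy whose increase/decrease sign ratio is farthest from 1.0,
    and remain "ambiguous" if that also ties.
    """
    params = list(grid_a)
    if list(grid_b) != params:
        raise ValueError("grids must share the parameter set")
    if len(params) < 2:
        raise ValueError("need a grid of at least 2 parameters")
    a = {p: np.asarray(grid_a[p], dtype=float) for p in params}
    b = {p: np.asarray(grid_b[p], dtype=float) for p in params}
    n = a[params[0]].size
    for p in params:
        if a[p].size != n or b[p].size != n:
            raise ValueError("incomplete grid")

    def rocv_pooled(p):
        pooled = np.concatenate([a[p], b[p]])
        med = np.median(pooled)
        if med == 0:
            return 0.0
        return 1.4826 * sst.median_abs_deviation(pooled, scale=1.0) / abs(med)

    s2 = max(params, key=rocv_pooled)
    s3 = max(params, key=lambda p: abs(np.median(a[p]) - np.median(b[p])))
    s4 = max(params, key=lambda p: np.median(np.abs(b[p] - a[p])))
    # s5: for each participant, which parameter shows their largest |diff|
    diff_matrix = np.column_stack([np.abs(b[p] - a[p]) for p in params])
    winners = np.argmax(diff_matrix, axis=1)
    counts = np.bincount(winners, minlength=len(params))
    s5 = params[int(np.argmax(counts))]

    selections = {"s2": s2, "s3": s3, "s4": s4, "s5": s5}
    ratios = {s: _sign_ratio(b[p] - a[p]) for s, p in selections.items()}

    chosen = list(selections.values())
    best_count = max(chosen.count(c) for c in chosen)
    modal = [c for c in dict.fromkeys(chosen) if chosen.count(c) == best_count]
    if len(modal) == 1:
        consensus = modal[0]
    else:
        # prefer the strategy whose sign ratio is farthest from 1.0
        def distance(s):
            r = ratios[s]
            return abs(np.log(r)) if np.isfinite(r) and r > 0 else np.inf
        contenders = [s for s in selections if selections[s] in modal]
        dists = {s: distance(s) for s in contenders}
        dmax = max(dists.values())
        winners_s = [s for s in contenders if dists[s] == dmax]
        winning_params = {selections[s] for s in winners_s}
        consensus = (winning_params.pop() if len(winning_params) == 1
                     else "ambiguous")
    return TuningReport(selections=selections, sign_ratios=ratios,
                        consensus=consensus)
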