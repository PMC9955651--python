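"""Ordinal-pattern machinery and the permutation-entropy measure family.

A window of m values taken at lag tau is mapped to the permutation that
sorts it ascending (ties broken by original position, unless diverted
to explicit tie patterns).  The distribution of patterns over all
windows supports Shannon, Renyi, Tsallis and min entropies, amplitude-
and edge-weighted variants, a composite index with tie patterns (CPEI),
the Jensen-Shannon statistical complexity, and multiscale versions via
coarse graining.

All normalised outputs lie in [0, 1]: 0 for a monotone ramp (a single
pattern), 1 for the uniform pattern distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "OrdinalDistribution",
    "ordinal_patterns",
    "entropy_functional",
    "aape",
    "edge_pe",
    "permutation_entropy",
    "cpei",
    "pjsc",
    "coarse_grain",
    "multiscale_pe",
]

_MAX_ORDER = 7


def _pattern_table(m: int) -> dict[tuple[int, ...], int]:
    """Lexicographic index of each permutation of range(m)."""
    return {p: i for i, p in enumerate(itertools.permutations(range(m)))}


@dataclass(frozen=True)
class OrdinalDistribution:
    """Ordinal-pattern counts for order m, lag tau.

    ``counts`` has m! slots in lexicographic pattern order, plus one
    trailing tie slot when ``tie_policy == "tie-patterns"``.
    """

    m: int
    tau: int
    counts: np.ndarray
    tie_policy: str = "rank-by-order"

    @property
    def n_windows(self) -> int:
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        n = self.n_windows
        if n == 0:
            raise ValueError("empty distribution")
        return self.counts / n

    def merge(self, other: "OrdinalDistribution") -> "OrdinalDistribution":
        if (self.m, self.tie_policy) != (other.m, other.tie_policy):
            raise ValueError("incompatible distributions")
        return OrdinalDistribution(self.m, self.tau,
                                   self.counts + other.counts,
                                   self.tie_policy)


def _windows(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_win = x.size - (m - 1) * tau
    idx = np.arange(m) * tau + np.arange(n_win)[:, None]
    return x[idx]


def ordinal_patterns(x: Sequence[float], m: int = 3, tau: int = 1,
                     tie_policy: str = "rank-by-order",
                     tie_threshold: float = 0.0) -> OrdinalDistribution:
    """Count the ordinal pattern of every length-m, lag-tau window.

    With ``rank-by-order`` ties are broken by original position (stable
    argsort).  With ``tie-patterns`` any window containing a pair of
    consecutive values closer than ``tie_threshold`` in magnitude is
    diverted to a single extra tie slot.
    """
    x = np.asarray(x, dtype=float)
    if m > _MAX_ORDER:
        raise ValueError(f"order m > {_MAX_ORDER} not supported")
    if m < 2 or tau < 1:
        raise ValueError("need m >= 2 and tau >= 1")
    if x.size < (m - 1) * tau + 1:
        raise ValueError("series too short for the requested window")
    if tie_policy not in ("rank-by-order", "tie-patterns"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    win = _windows(x, m, tau)
    table = _pattern_table(m)
    perms = np.argsort(win, axis=1, kind="stable")
    n_slots = math.factorial(m) + (1 if tie_policy == "tie-patterns" else 0)
    counts = np.zeros(n_slots, dtype=np.int64)
    if tie_policy == "tie-patterns":
        tied = np.any(np.abs(np.diff(win, axis=1)) <= tie_threshold, axis=1)
    else:
        tied = np.zeros(win.shape[0], dtype=bool)
    for row, is_tied in zip(perms, tied):
        if is_tied:
            counts[-1] += 1
        else:
            counts[table[tuple(row)]] += 1
    return OrdinalDistribution(m=m, tau=tau, counts=counts,
                               tie_policy=tie_policy)


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def entropy_functional(dist: OrdinalDistribution, family: str = "shannon",
                       alpha: float = 2.0, q: float = 2.0,
                       normalize: bool = True) -> float:
    """Entropy of an ordinal distribution.

    Families: ``shannon`` (-sum p ln p), ``renyi`` (order alpha),
    ``tsallis`` (index q), ``min`` (-ln max p).  Normalisation divides
    by the value attained by the uniform distribution over the
    available slots.
    """
    p = dist.p
    n_slots = p.size
    if family == "shannon":
        h = _shannon(p)
        h_max = np.log(n_slots)
    elif family == "renyi":
        if alpha == 1.0:
            raise ValueError("alpha must differ from 1")
        h = float(np.log(np.sum(p ** alpha)) / (1.0 - alpha))
        h_max = np.log(n_slots)
    elif family == "tsallis":
        if q == 1.0:
            raise ValueError("q must differ from 1")
        h = float((1.0 - np.sum(p ** q)) / (q - 1.0))
        h_max = (1.0 - n_slots ** (1.0 - q)) / (q - 1.0)
    elif family == "min":
        h = float(-np.log(np.max(p)))
        h_max = np.log(n_slots)
    else:
        raise ValueError(f"unknown entropy family {family!r}")
    return h / h_max if normalize else h


def permutation_entropy(x: Sequence[float], m: int = 3, tau: int = 1,
                        family: str = "shannon", **kw) -> float:
    """Normalised permutation entropy of a series (convenience wrapper)."""
    return entropy_functional(ordinal_patterns(x, m, tau), family=family, **kw)


def _weighted_pe(win: np.ndarray, weights: np.ndarray, m: int) -> float:
    table = _pattern_table(m)
    perms = np.argsort(win, axis=1, kind="stable")
    probs = np.zeros(math.factorial(m))
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    for row, w in zip(perms, weights):
        probs[table[tuple(row)]] += w
    probs /= total
    return _shannon(probs) / np.log(math.factorial(m))


def aape(x: Sequence[float], m: int = 3, tau: int = 1,
         a: float = 0.5) -> float:
    """Amplitude-aware permutation entropy.

    Each window contributes weight A * mean|values| + (1-A) *
    mean|successive differences| (amplitudes in units of the series
    scale) instead of a unit count; with equal weights this reduces to
    plain normalised PE.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("A must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    scale = float(np.std(x))
    z = x / scale if scale > 0 else x
    win = _windows(z, m, tau)
    w = (a * np.mean(np.abs(win), axis=1)
         + (1 - a) * np.mean(np.abs(np.diff(win, axis=1)), axis=1))
    return _weighted_pe(win, w, m)


def edge_pe(x: Sequence[float], m: int = 3, tau: int = 1) -> float:
    """Edge permutation entropy: windows weighted by the total magnitude
    of their successive differences (their 'edges')."""
    x = np.asarray(x, dtype=float)
    win = _windows(x, m, tau)
    w = np.sum(np.abs(np.diff(win, axis=1)), axis=1)
    if np.all(w == 0):
        raise ValueError("constant series has no edges")
    return _weighted_pe(win, w, m)


def cpei(x: Sequence[float], tie_threshold: float = 0.0) -> float:
    """Composite permutation entropy index.

    Order-3 ordinal distributions at lags 1 and 2, with near-equal
    consecutive samples (|difference| <= tie_threshold) diverted to a
    tie pattern, are pooled by summing counts; CPEI is the Shannon
    entropy of the pooled distribution normalised by ln(7) (six genuine
    patterns plus the tie slot).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    d1 = ordinal_patterns(x, m=3, tau=1, tie_policy="tie-patterns",
                          tie_threshold=tie_threshold)
    d2 = ordinal_patterns(x, m=3, tau=2, tie_policy="tie-patterns",
                          tie_threshold=tie_threshold)
    pooled = d1.merge(d2)
    return entropy_functional(pooled, "shannon", normalize=True)


def pjsc(dist: OrdinalDistribution) -> float:
    """Jensen-Shannon statistical complexity C = Q_J * H_S.

    H_S is the normalised Shannon entropy; Q_J is the Jensen-Shannon
    divergence between the pattern distribution and the uniform one,
    divided by its analytic maximum (attained by a single-pattern
    distribution).  C vanishes both for a single pattern and for the
    uniform distribution.
    """
    p = dist.p
    n = p.size
    u = np.full(n, 1.0 / n)
    h_p = _shannon(p)
    h_s = h_p / np.log(n)
    mid = 0.5 * (p + u)
    jsd = _shannon(mid) - 0.5 * (h_p + _shannon(u))
    # max of JSD(p, u) over p: a point mass
    q_max = -0.5 * ((n + 1.0) / n * np.log(n + 1.0)
                    - 2.0 * np.log(2.0 * n) + np.log(n))
    return float(jsd / q_max * h_s)


def coarse_grain(x: Sequence[float], s: int) -> np.ndarray:
    """Non-overlapping means of s consecutive samples (multiscale step)."""
    if s < 1:
        raise ValueError("scale must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < 2 * s:
        raise ValueError("series too short for this scale")
    n = (x.size // s) * s
    return x[:n].reshape(-1, s).mean(axis=1)


def multiscale_pe(x: Sequence[float], m: int = 3, tau: int = 1,
                  scales: Sequence[int] = (1, 2, 3, 4, 5),
                  variant: str = "mPE") -> dict[int, float]:
    """Multiscale permutation entropy, one value per scale.

    ``mPE``: PE of the coarse-grained series; ``ImPE``: ordinal
    distributions averaged over all s coarse-graining offsets before one
    entropy (refined/improved variant); ``mPM_E``: min-entropy of the
    coarse-grained series.
    """
    x = np.asarray(x, dtype=float)
    if variant not in ("mPE", "ImPE", "mPM_E"):
        raise ValueError(f"unknown multiscale variant {variant!r}")
    out: dict[int, float] = {}
    for s in scales:
        if x.size < 2 * s * ((m - 1) * tau + 1):
            raise ValueError(f"series too short at scale {s}")
        if variant == "ImPE":
            merged = None
            for off in range(s):
                cg = coarse_grain(x[off:], s)
                d = ordinal_patterns(cg, m, tau)
                merged = d if merged is None else merged.merge(d)
            out[s] = entropy_functional(merged, "shannon")
        else:
            cg = coarse_grain(x, s)
            fam = "min" if variant == "mPM_E" else "shannon"
            out[s] = entropy_functional(ordinal_patterns(cg, m, tau), fam)
    return out
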