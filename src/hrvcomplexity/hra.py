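"""Lagged Poincaré descriptors and heart-rate asymmetry indices.

The lag-m Poincaré plot scatters each interval x_i against x_{i+m}.
SD1/SD2 are the standard deviations transverse to and along the line of
identity (LI, the diagonal x_{i+m} = x_i).  Heart-rate asymmetry splits
the scatter into decelerations ("up", above the LI: the RR interval
lengthens) and accelerations ("down", below), and quantifies their
unequal contribution to short- and long-term variability.

Naming note: "up" here always means above the LI (decelerations),
matching the SD1up/SDNNup convention; parts of the literature write the
same quantities as SD1a/SD1d.  The up/down second moments are taken
about zero (transverse) and about the centroid (longitudinal), the
convention under which the variance-conservation identities
SD1up^2 + SD1down^2 = SD1_0^2 and SDNNup^2 + SDNNdown^2 = SDNN^2 hold
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .sigio import EventSeries

__all__ = [
    "PoincareSummary",
    "AsymmetrySummary",
    "lagged_poincare",
    "asymmetry_decomposition",
    "classical_indices",
    "karmakar_indices",
    "asymmetric_spread_index",
    "ccm",
    "poincare_points",
]

_SQRT2 = np.sqrt(2.0)


def _as_intervals(x) -> np.ndarray:
    if isinstance(x, EventSeries):
        return np.asarray(x.intervals, dtype=float)
    return np.asarray(x, dtype=float)


def poincare_points(x, m: int = 1):
    """Return the lag-m Poincaré coordinates (x_i, x_{i+m})."""
    v = _as_intervals(x)
    if m < 1:
        raise ValueError("lag must be >= 1")
    if v.size <= m:
        raise ValueError("series shorter than lag")
    return v[:-m], v[m:]


@dataclass(frozen=True)
class PoincareSummary:
    m: int
    sd1: float
    sd2: float
    sdnn: float
    ratio: float       # SD2/SD1
    r: float           # Pearson correlation of (x_i, x_{i+m})
    n_points: int


@dataclass(frozen=True)
class AsymmetrySummary:
    d: np.ndarray          # signed transverse distances (ms / sqrt 2)
    n_above: int
    n_below: int
    n_on: int
    sd1_up: float
    sd1_down: float
    sd2_up: float
    sd2_down: float
    sdnn_up: float
    sdnn_down: float
    c1a: float
    c1d: float
    c2a: float
    c2d: float
    sd1_total: float       # second moment about zero
    sd2_total: float
    sdnn_total: float


def lagged_poincare(x, m: int = 1) -> PoincareSummary:
    """SD1/SD2/SDNN and correlation of the lag-m Poincaré plot.

    SD1 = sample sd of (x_{i+m} - x_i)/sqrt(2), SD2 = sample sd of
    (x_{i+m} + x_i)/sqrt(2) (both with denominator n-1); the identity
    SDNN^2 = (SD1^2 + SD2^2)/2 defines SDNN.
    """
    a, b = poincare_points(x, m)
    if a.size < 3:
        raise ValueError("need more than m + 2 intervals")
    diff = (b - a) / _SQRT2
    summ = (b + a) / _SQRT2
    sd1 = float(np.std(diff, ddof=1))
    sd2 = float(np.std(summ, ddof=1))
    sdnn = float(np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = np.nan  # undefined for a constant coordinate
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    ratio = sd2 / sd1 if sd1 > 0 else np.inf
    return PoincareSummary(m=m, sd1=sd1, sd2=sd2, sdnn=sdnn, ratio=ratio,
                           r=r, n_points=int(a.size))


def asymmetry_decomposition(x, m: int = 1) -> AsymmetrySummary:
    """Split Poincaré variability into deceleration/acceleration parts.

    Transverse distances d_i = (x_{i+m} - x_i)/sqrt(2) are pooled about
    zero: SD1up^2 = (1/n) sum_{above} d_i^2 and likewise below, so
    SD1up^2 + SD1down^2 equals the second moment SD1_0^2.  Longitudinal
    deviations are taken about their mean, with on-LI points giving half
    weight to each side; SDNNup = sqrt((SD1up^2 + SD2up^2)/2).
    C1a/C1d (C2a/C2d) are the corresponding variance fractions.
    """
    a, b = poincare_points(x, m)
    if a.size < 2:
        raise ValueError("need at least 3 intervals")
    d = (b - a) / _SQRT2
    above = d > 0
    below = d < 0
    on = ~above & ~below
    n = d.size
    if not above.any() and not below.any():
        raise ValueError("all points on the line of identity; "
                         "asymmetry undefined")
    sd1_up2 = float(np.sum(d[above] ** 2) / n)
    sd1_down2 = float(np.sum(d[below] ** 2) / n)
    sd1_tot2 = float(np.sum(d ** 2) / n)

    e = (b + a) / _SQRT2
    dev2 = (e - e.mean()) ** 2
    sd2_up2 = float((np.sum(dev2[above]) + 0.5 * np.sum(dev2[on])) / n)
    sd2_down2 = float((np.sum(dev2[below]) + 0.5 * np.sum(dev2[on])) / n)
    sd2_tot2 = float(np.sum(dev2) / n)

    sdnn_up2 = (sd1_up2 + sd2_up2) / 2.0
    sdnn_down2 = (sd1_down2 + sd2_down2) / 2.0
    sdnn_tot2 = (sd1_tot2 + sd2_tot2) / 2.0

    def frac(part, total):
        return part / total if total > 0 else np.nan

    return AsymmetrySummary(
        d=d,
        n_above=int(above.sum()), n_below=int(below.sum()), n_on=int(on.sum()),
        sd1_up=np.sqrt(sd1_up2), sd1_down=np.sqrt(sd1_down2),
        sd2_up=np.sqrt(sd2_up2), sd2_down=np.sqrt(sd2_down2),
        sdnn_up=np.sqrt(sdnn_up2), sdnn_down=np.sqrt(sdnn_down2),
        c1a=frac(sd1_up2, sd1_tot2), c1d=frac(sd1_down2, sd1_tot2),
        c2a=frac(sd2_up2, sd2_tot2), c2d=frac(sd2_down2, sd2_tot2),
        sd1_total=np.sqrt(sd1_tot2), sd2_total=np.sqrt(sd2_tot2),
        sdnn_total=np.sqrt(sdnn_tot2),
    )


def classical_indices(x):
    """Ehlers' (EI), Guzik's (GI) and Porta's (PI) asymmetry indices.

    With successive differences D_i = x_{i+1} - x_i:
    EI = sum D^3 / (sum D^2)^(3/2) (a skewness-like, linear measure);
    GI = 100 * (transverse power of decelerations) / (off-LI power);
    PI = 100 * (number of accelerations) / (off-LI count).
    Returns (EI, GI, PI).
    """
    a, b = poincare_points(x, 1)
    if a.size < 2:
        raise ValueError("need at least 3 intervals")
    delta = b - a
    ss = float(np.sum(delta ** 2))
    if ss == 0:
        raise ValueError("all successive differences are zero")
    ei = float(np.sum(delta ** 3) / ss ** 1.5)
    d2 = (delta / _SQRT2) ** 2
    off = delta != 0
    if not off.any():
        raise ValueError("no off-LI points")
    gi = 100.0 * float(np.sum(d2[delta > 0]) / np.sum(d2[off]))
    pi = 100.0 * float(np.count_nonzero(delta < 0) / np.count_nonzero(off))
    return ei, gi, pi


def karmakar_indices(x):
    """Slope index (SI) and Area index (AI).

    Each Poincaré point subtends an angle theta_i between its position
    vector and the LI; SI is the percentage of total |theta| from
    deceleration points.  AI weights each point by the circular-sector
    area 0.5 r_i^2 |theta_i|.  Returns (SI, AI).
    """
    a, b = poincare_points(x, 1)
    if a.size < 3:
        raise ValueError("need at least 4 intervals")
    theta = np.arctan2(b, a) - np.pi / 4.0
    off = theta != 0
    if not off.any():
        raise ValueError("all points on the line of identity")
    above = theta > 0
    abs_t = np.abs(theta)
    si = 100.0 * float(np.sum(abs_t[above]) / np.sum(abs_t[off]))
    r2 = a ** 2 + b ** 2
    area = 0.5 * r2 * abs_t
    ai = 100.0 * float(np.sum(area[above]) / np.sum(area[off]))
    return si, ai


def asymmetric_spread_index(x) -> float:
    """ASI: deceleration share of the transverse root-mean-square spread.

    ASI = 100 * s_above / (s_above + s_below) with s the RMS of the
    |transverse distances| of each point set; 50 for mirror-symmetric
    clouds, and ASI(x) + ASI(reversed x) = 100 when no point lies on
    the LI.
    """
    a, b = poincare_points(x, 1)
    if a.size < 3:
        raise ValueError("need at least 4 intervals")
    d = (b - a) / _SQRT2
    up = d[d > 0]
    down = d[d < 0]
    if up.size == 0 or down.size == 0:
        raise ValueError("need off-LI points on both sides")
    s_up = float(np.sqrt(np.mean(up ** 2)))
    s_down = float(np.sqrt(np.mean(down ** 2)))
    return 100.0 * s_up / (s_up + s_down)


def ccm(x, m: int = 1) -> float:
    """Complex Correlation Measure of the lag-m Poincaré plot.

    Mean absolute area of the triangles through consecutive plot points,
    normalised by pi * SD1 * SD2: temporal structure that SD1/SD2 alone
    cannot see.  Undefined (nan) when SD1 * SD2 = 0.
    """
    a, b = poincare_points(x, m)
    if a.size < 4:
        raise ValueError("need at least m + 4 intervals")
    summary = lagged_poincare(x, m)
    if summary.sd1 * summary.sd2 == 0:
        return np.nan
    x0, y0 = a[:-2], b[:-2]
    x1, y1 = a[1:-1], b[1:-1]
    x2, y2 = a[2:], b[2:]
    # shoelace triangle area
    area = 0.5 * np.abs(x0 * (y1 - y2) + x1 * (y2 - y0) + x2 * (y0 - y1))
    n_pts = a.size
    return float(np.sum(area) /
                 (np.pi * summary.sd1 * summary.sd2 * (n_pts - 2)))
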