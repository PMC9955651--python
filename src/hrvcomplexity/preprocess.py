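"""Data-modification toolbox for interval series and waveforms.

Detrending, deduplication of up-sampled waveforms, shape-preserving
tachogram resampling, segmentation (nested prefixes or five equal
segments), finegrid interpolation for short records, coloured-noise
addition, amplitude normalisation/binarisation, the reverse-arrangement
stationarity test, and breath-interval extraction from a respiration
waveform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .sigio import EventSeries, UniformSignal

__all__ = [
    "SegmentationPlan",
    "detrend",
    "deduplicate",
    "resample_uniform",
    "segment",
    "finegrid_interpolate",
    "add_noise",
    "transform_amplitude",
    "reverse_arrangement_test",
    "extract_breath_intervals",
    "BreathIntervals",
]


@dataclass(frozen=True)
class SegmentationPlan:
    """Either nested prefixes of given durations (minutes, ascending) or
    five equal contiguous segments."""

    mode: Literal["nested", "equal_fifths"]
    durations: Sequence[float] | None = None

    def __post_init__(self):
        if self.mode == "nested":
            if not self.durations:
                raise ValueError("nested mode requires durations (minutes)")
            d = list(self.durations)
            if sorted(d) != d:
                raise ValueError("nested durations must be ascending")
        elif self.mode != "equal_fifths":
            raise ValueError(f"unknown segmentation mode {self.mode!r}")


def detrend(x: UniformSignal, method: str = "linear") -> UniformSignal:
    """Remove the least-squares linear trend or the mean."""
    if method not in ("linear", "constant"):
        raise ValueError(f"unknown detrend method {method!r}")
    values = sps.detrend(x.values, type=method)
    return UniformSignal(values=values, fs=x.fs, t0=x.t0)


def deduplicate(x: Sequence[float]) -> np.ndarray:
    """Collapse runs of consecutive equal values to a single value.

    Up-sampled 32 Hz waveforms exported at 256 Hz repeat each sample
    eight times; this undoes that.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x
    keep = np.concatenate(([True], x[1:] != x[:-1]))
    return x[keep]


def resample_uniform(x: EventSeries, fs: float) -> UniformSignal:
    """Interpolate the tachogram onto a uniform grid.

    Interval values are anchored at their event times and interpolated
    with a monotone (shape-preserving) piecewise-cubic interpolant, so
    the output never overshoots the input range.
    """
    if len(x) < 4:
        raise ValueError("need at least 4 events to resample")
    if fs <= 0:
        raise ValueError("fs must be positive")
    interp = PchipInterpolator(x.times, x.intervals)
    t = np.arange(x.times[0], x.times[-1] + 0.5 / fs, 1.0 / fs)
    t = t[t <= x.times[-1] + 1e-12]
    return UniformSignal(values=interp(t), fs=fs, t0=float(t[0]))


def _segment_signal(x: UniformSignal, plan: SegmentationPlan):
    n = len(x)
    if plan.mode == "nested":
        out = []
        for minutes in plan.durations:
            ns = int(round(minutes * 60 * x.fs))
            if ns > n:
                raise ValueError(
                    f"recording ({n / x.fs:.1f} s) shorter than requested "
                    f"{minutes} min segment")
            out.append(UniformSignal(values=x.values[:ns], fs=x.fs, t0=x.t0))
        return out
    bounds = np.linspace(0, n, 6).round().astype(int)
    return [UniformSignal(values=x.values[a:b], fs=x.fs, t0=x.t0 + a / x.fs)
            for a, b in zip(bounds[:-1], bounds[1:])]


def _segment_events(x: EventSeries, plan: SegmentationPlan):
    t0 = x.times[0] - x.intervals[0] * x.unit_scale
    total = x.times[-1] - t0

    def take(lo: float, hi: float) -> EventSeries:
        # half-open [lo, hi): keep events with time < hi
        mask = (x.times >= lo) & (x.times < hi)
        if mask.sum() < 1:
            raise ValueError("segment contains no events")
        return EventSeries(times=x.times[mask], intervals=x.intervals[mask],
                           kind=x.kind, strict=x.strict)

    if plan.mode == "nested":
        out = []
        for minutes in plan.durations:
            if minutes * 60 > total + 1e-9:
                raise ValueError(f"recording shorter than {minutes} min")
            out.append(take(t0 - 1e-12, t0 + minutes * 60))
        return out
    edges = t0 + np.linspace(0, total, 6)
    edges[-1] += 1e-9  # include the final event
    return [take(a, b) for a, b in zip(edges[:-1], edges[1:])]


def segment(x, plan: SegmentationPlan):
    """Split a recording per the plan.

    Nested mode returns prefixes of 1..k minutes all sharing the start
    point; equal_fifths returns five contiguous length-balanced segments
    (half-open boundaries for event series).
    """
    if isinstance(x, UniformSignal):
        return _segment_signal(x, plan)
    if isinstance(x, EventSeries):
        return _segment_events(x, plan)
    raise TypeError("segment expects UniformSignal or EventSeries")


def finegrid_interpolate(x: Sequence[float], method: str = "linear",
                         n_points: int = 1) -> np.ndarray:
    """Insert ``n_points`` interpolated values between every adjacent pair.

    Output length is N + (N-1)*n_points.  ``linear`` inserts equally
    spaced values on the chord; ``nearest`` copies the nearer endpoint
    (midpoint ties go to the left endpoint).
    """
    if n_points not in (1, 2, 3):
        raise ValueError("n_points must be 1, 2 or 3")
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown finegrid method {method!r}")
    step = n_points + 1
    out = np.empty(x.size + (x.size - 1) * n_points, dtype=float)
    out[::step] = x
    frac = np.arange(1, step) / step
    for j, f in enumerate(frac, start=1):
        if method == "linear":
            vals = x[:-1] + f * (x[1:] - x[:-1])
        else:
            vals = x[:-1] if f <= 0.5 else x[1:]
        out[j::step] = vals
    return out


_NOISE_BETA = {"white": 0.0, "pink": -1.0, "brown": -2.0, "blue": 1.0}


def coloured_noise(n: int, colour: str, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ f**beta."""
    beta = _NOISE_BETA[colour]
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (beta / 2.0)
    spec = spec * shaping
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    if sd == 0:
        raise ValueError("degenerate noise realisation")
    return out / sd


def add_noise(x: UniformSignal, colour: str, snr_db: float,
              seed: int) -> UniformSignal:
    """Add spectrally shaped noise at the requested signal-to-noise ratio.

    ``snr_db = inf`` is the no-noise sentinel.  The noise is scaled so
    10*log10(var(x)/var(noise)) equals ``snr_db``.
    """
    if colour not in _NOISE_BETA:
        raise ValueError(f"unknown noise colour {colour!r}")
    if np.isinf(snr_db) and snr_db > 0:
        return x
    var_x = float(np.var(x.values))
    if var_x <= 0:
        raise ValueError("zero-variance input with finite snr_db")
    rng = np.random.default_rng(seed)
    noise = coloured_noise(len(x), colour, rng)
    target_var = var_x / 10.0 ** (snr_db / 10.0)
    noise *= np.sqrt(target_var)
    return UniformSignal(values=x.values + noise, fs=x.fs, t0=x.t0)


def transform_amplitude(x: Sequence[float], method: str) -> np.ndarray:
    """Amplitude normalisations and binarisations.

    zscore / minmax / robust rescale the series; binarize_a thresholds at
    the mean; binarize_b is the sign of successive differences (length
    N-1); binarize_c flags successive differences larger in magnitude
    than their standard deviation.
    """
    x = np.asarray(x, dtype=float)
    if method == "zscore":
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0:
            raise ValueError("constant input for zscore")
        return (x - x.mean()) / sd
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("degenerate range for minmax")
        return (x - lo) / (hi - lo)
    if method == "robust":
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            raise ValueError("zero spread for robust scaling")
        return (x - med) / (1.4826 * mad)
    if method == "binarize_a":
        return (x > x.mean()).astype(float)
    if method == "binarize_b":
        return np.sign(np.diff(x))
    if method == "binarize_c":
        d = np.abs(np.diff(x))
        return (d > d.std(ddof=1 if d.size > 1 else 0)).astype(float)
    raise ValueError(f"unknown transform {method!r}")


def reverse_arrangement_test(x: Sequence[float], alpha: float = 0.05):
    """Reverse-arrangement test for (trend) non-stationarity.

    A counts pairs (i, j), i < j, with x_i > x_j.  Under exchangeability
    A has mean N(N-1)/4 and variance N(2N+5)(N-1)/72; the verdict is
    "nonstationary" when |z| exceeds the two-sided normal quantile.
    Returns (verdict, A, z).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    a = int(np.sum(x[:, None] > x[None, :], where=np.triu(
        np.ones((n, n), dtype=bool), k=1)))
    mean_a = n * (n - 1) / 4.0
    var_a = n * (2 * n + 5) * (n - 1) / 72.0
    z = (a - mean_a) / np.sqrt(var_a)
    crit = norm.ppf(1 - alpha / 2.0)
    verdict = "nonstationary" if abs(z) > crit else "stationary"
    return verdict, a, float(z)


@dataclass(frozen=True)
class BreathIntervals:
    """Breath interval triple plus the outbreath(n)/inbreath(n+1) ratio."""

    inbreath: EventSeries    # trough(n) -> peak(n+1)
    outbreath: EventSeries   # peak(n) -> trough(n)
    peak_to_peak: EventSeries
    ratio: np.ndarray


def _smooth(values: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    w = max(1, int(round(window_s * fs)))
    kernel = np.ones(w) / w
    pad = np.pad(values, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def extract_breath_intervals(rsp: UniformSignal,
                             min_cycle_s: float = 2.0) -> BreathIntervals:
    """Locate breathing peaks/troughs and derive interval series.

    The waveform is smoothed with a 1-s moving average; extrema are
    found by prominence with a minimum peak distance of ``min_cycle_s``
    (breathing is assumed slower than 30 cycles/min).  Intervals:
    IN(n) = trough(n) to peak(n+1), OUT(n) = peak(n) to trough(n),
    PP(n) = peak(n) to peak(n+1), ratio(n) = OUT(n)/IN(n+1).
    """
    y = _smooth(rsp.values, rsp.fs)
    prom = 0.25 * float(np.std(y))
    dist = max(1, int(round(min_cycle_s * rsp.fs)))
    peaks, _ = sps.find_peaks(y, prominence=prom, distance=dist)
    troughs, _ = sps.find_peaks(-y, prominence=prom, distance=dist)
    # smoothing skews asymmetric extrema; refine on the raw waveform
    half = max(1, int(round(0.75 * rsp.fs)))

    def refine(idx: np.ndarray, sign: float) -> np.ndarray:
        out = []
        for i in idx:
            lo, hi = max(0, i - half), min(rsp.values.size, i + half + 1)
            out.append(lo + int(np.argmax(sign * rsp.values[lo:hi])))
        return np.asarray(out, dtype=int)

    peaks = refine(peaks, +1.0)
    troughs = refine(troughs, -1.0)
    if peaks.size < 3 or troughs.size < 2:
        raise ValueError("no detectable breathing cycles")
    t = rsp.times
    tp, tt = t[peaks], t[troughs]

    # OUT(n): each peak to the first following trough
    out_list, out_times = [], []
    for pk in tp:
        nxt = tt[tt > pk]
        if nxt.size:
            out_list.append(nxt[0] - pk)
            out_times.append(nxt[0])
    # IN(n): each trough to the first following peak
    in_list, in_times = [], []
    for tr in tt:
        nxt = tp[tp > tr]
        if nxt.size:
            in_list.append(nxt[0] - tr)
            in_times.append(nxt[0])
    pp = np.diff(tp)

    inb = EventSeries(times=np.asarray(in_times), intervals=np.asarray(in_list),
                      kind="IN", strict=False)
    outb = EventSeries(times=np.asarray(out_times),
                       intervals=np.asarray(out_list), kind="OUT", strict=False)
    ppb = EventSeries(times=tp[1:], intervals=pp, kind="PP", strict=False)

    # ratio(n) = OUT(n) / IN(n+1): pair each outbreath with the inbreath
    # that starts at its ending trough.
    ratios = []
    for end_time, out_dur in zip(outb.times, outb.intervals):
        j = np.searchsorted(inb.times, end_time, side="right")
        if j < len(inb):
            ratios.append(out_dur / inb.intervals[j])
    return BreathIntervals(inbreath=inb, outbreath=outb, peak_to_peak=ppb,
                           ratio=np.asarray(ratios))
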