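"""Frequency-domain HRV and the resonance-breathing assessment (RBA).

The tachogram (RR intervals in ms on a uniform grid) is analysed with
Welch-averaged periodograms, Burg autoregressive spectra, or the
Lomb-Scargle periodogram for unevenly sampled data.  Band metrics use
the conventional LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) bands; slow
paced breathing at 5-7 breaths/min (0.083-0.117 Hz) lands inside LF by
design.

The RBA scorecard gathers, per trial: LF absolute band power (LFBP),
peak LF power (PLFP), LF in normalised units, the mean within-breath
heart-rate excursion (HRMaxMin), and the HR-respiration phase.  The
resonance breathing rate (RBR) is the paced trial with the highest LF
spectral peak; exact ties go to the slower rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .sigio import EventSeries, UniformSignal

__all__ = [
    "SpectralSummary",
    "BandMetrics",
    "RBAScorecard",
    "TrialScore",
    "psd_estimate",
    "lomb_psd",
    "band_metrics",
    "hr_max_min",
    "resp_hr_phase",
    "select_rbr",
    "LF_BAND",
    "HF_BAND",
    "PACED_TRIALS",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
PACED_TRIALS = ("5", "5.5", "6", "6.5", "7")


@dataclass(frozen=True)
class SpectralSummary:
    freqs: np.ndarray       # Hz
    psd: np.ndarray         # ms^2/Hz (one-sided)
    method: str
    enbw: float             # equivalent noise bandwidth of one bin, Hz

    def total_power(self) -> float:
        return float(np.trapezoid(self.psd, self.freqs))


@dataclass(frozen=True)
class BandMetrics:
    power: float        # ms^2, trapezoidal integral over the band
    peak_freq: float    # Hz
    peak_power: float   # ms^2, density at peak x resolution bandwidth
    nu: float           # percent of LF+HF power


def psd_estimate(x: UniformSignal, method: str = "welch",
                 segment_s: float = 150.0, overlap: float = 0.5,
                 order: int = 16) -> SpectralSummary:
    """One-sided PSD of a uniformly sampled (detrended) signal.

    ``welch``: averaged Hann-tapered modified periodograms with
    ``segment_s``-second segments and fractional ``overlap``.
    ``burg``: autoregressive spectrum of the given order from the Burg
    reflection-coefficient recursion.
    """
    v = x.values - x.values.mean()
    if method == "welch":
        nper = min(len(v), int(round(segment_s * x.fs)))
        # 4x zero-padding keeps off-bin peaks from scalloping losses
        f, p = sps.welch(v, fs=x.fs, nperseg=nper, nfft=4 * nper,
                         noverlap=int(nper * overlap), window="hann",
                         detrend="constant")
        win = sps.get_window("hann", nper)
        enbw = x.fs * np.sum(win ** 2) / np.sum(win) ** 2
        return SpectralSummary(freqs=f, psd=p, method="welch", enbw=enbw)
    if method == "burg":
        if order >= len(v):
            raise ValueError("Burg order must be below the series length")
        from statsmodels.regression.linear_model import burg as sm_burg
        ar, sigma2 = sm_burg(v, order=order, demean=True)
        nfreq = 1024
        f = np.linspace(0.0, x.fs / 2.0, nfreq)
        z = np.exp(-2j * np.pi * np.outer(f / x.fs, np.arange(1, order + 1)))
        denom = np.abs(1.0 - z @ ar) ** 2
        p = 2.0 * sigma2 / x.fs / denom
        return SpectralSummary(freqs=f, psd=p, method="burg",
                               enbw=float(f[1] - f[0]))
    raise ValueError(f"unknown PSD method {method!r}")


def lomb_psd(t: Sequence[float], x: Sequence[float],
             oversample: int = 4) -> SpectralSummary:
    """Lomb-Scargle periodogram of an unevenly sampled series.

    Frequencies run from one cycle per record up to the mean Nyquist
    rate; power is rescaled so that the integral of the density equals
    the series variance (a Parseval-style calibration that leaves peak
    locations untouched).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 20:
        raise ValueError("need at least 20 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    span = t[-1] - t[0]
    mean_dt = span / (t.size - 1)
    f_max = 0.5 / mean_dt
    df = 1.0 / (oversample * span)
    freqs = np.arange(df, f_max + df / 2, df)
    xc = x - x.mean()
    var = float(np.var(xc))
    pgram = sps.lombscargle(t, xc, 2 * np.pi * freqs)
    if var > 0 and np.trapezoid(pgram, freqs) > 0:
        pgram = pgram * var / np.trapezoid(pgram, freqs)
    return SpectralSummary(freqs=freqs, psd=pgram, method="lomb", enbw=df)


def band_metrics(summary: SpectralSummary, band: tuple[float, float],
                 lf: tuple[float, float] = LF_BAND,
                 hf: tuple[float, float] = HF_BAND) -> BandMetrics:
    """Band power, spectral peak and normalised units for one band."""
    f, p = summary.freqs, summary.psd
    if band[0] < f[0] - 1e-12 or band[1] > f[-1] + 1e-12:
        raise ValueError("band outside the resolved frequency range")

    def integral(lo, hi):
        mask = (f >= lo) & (f <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(p[mask], f[mask]))

    mask = (f >= band[0]) & (f <= band[1])
    power = integral(*band)
    sub_f, sub_p = f[mask], p[mask]
    i_peak = int(np.argmax(sub_p))
    peak_freq = float(sub_f[i_peak])
    peak_power = float(sub_p[i_peak] * summary.enbw)
    denom = integral(*lf) + integral(*hf)
    nu = 100.0 * power / denom if denom > 0 else np.nan
    return BandMetrics(power=power, peak_freq=peak_freq,
                       peak_power=peak_power, nu=nu)


def hr_max_min(rri: EventSeries, cycle_bounds: Sequence[float]) -> float:
    """Mean within-breath heart-rate excursion, in beats per minute.

    ``cycle_bounds`` are successive breath-cycle boundary times in
    seconds; within each cycle HR = 60000/RRi, and the per-cycle
    max-minus-min values are averaged.
    """
    bounds = np.asarray(cycle_bounds, dtype=float)
    if bounds.size < 4:
        raise ValueError("need at least 3 full breathing cycles")
    hr = 60000.0 / rri.intervals
    t = rri.times
    diffs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mask = (t >= lo) & (t < hi)
        if mask.sum() >= 2:
            seg = hr[mask]
            diffs.append(float(seg.max() - seg.min()))
    if not diffs:
        raise ValueError("no cycle contained enough beats")
    return float(np.mean(diffs))


def resp_hr_phase(hr: UniformSignal, rsp: UniformSignal, f_b: float) -> float:
    """Phase of heart rate relative to respiration at the breathing
    frequency, in degrees in (-180, 180]; positive when HR lags."""
    if hr.fs != rsp.fs:
        raise ValueError("signals must share a sampling rate")
    n = min(len(hr), len(rsp))
    if n / hr.fs < 5.0 / f_b:
        raise ValueError("need at least 5 breathing cycles")
    nper = min(n, int(round(hr.fs * 4.0 / f_b)))
    f, pxy = sps.csd(hr.values[:n], rsp.values[:n], fs=hr.fs, nperseg=nper)
    if f_b > f[-1]:
        raise ValueError("breathing frequency unresolved")
    i = int(np.argmin(np.abs(f - f_b)))
    deg = float(np.degrees(np.angle(pxy[i])))
    if deg <= -180.0:
        deg += 360.0
    return deg


@dataclass(frozen=True)
class TrialScore:
    """RBA measures for one trial."""

    lfbp: float
    plfp: float
    lf_nu: float
    hr_max_min: float | None = None
    phase_deg: float | None = None
    comfort: float | None = None


@dataclass
class RBAScorecard:
    """Per-trial RBA measures plus the selected resonance breathing rate."""

    trials: Mapping[str, TrialScore]
    selected_rbr: str | None = None
    selection_rule: str = "plfp"
    tie_notes: list = field(default_factory=list)


def select_rbr(scorecard: RBAScorecard, include_self: bool = False) -> str:
    """Pick the trial with the highest LF spectral peak (PLFP).

    Only the externally paced trials compete by default;
    ``include_self`` admits the self-paced trial (some individuals peak
    higher there).  Exact PLFP ties resolve to the slower rate.  The
    scorecard is updated in place and the label returned.
    """
    candidates = [t for t in scorecard.trials if t in PACED_TRIALS]
    if include_self and "Self" in scorecard.trials:
        candidates.append("Self")
    if not candidates:
        raise ValueError("no paced trials in scorecard")
    missing = [t for t in candidates if not np.isfinite(
        scorecard.trials[t].plfp)]
    if missing:
        raise ValueError(f"PLFP missing for trials {missing}")

    def sort_key(label: str):
        # higher PLFP first; ties -> slower rate (lower BrPM; Self last)
        rate = float(label) if label != "Self" else np.inf
        return (-scorecard.trials[label].plfp, rate)

    best = sorted(candidates, key=sort_key)[0]
    scorecard.selected_rbr = best
    return best


def score_trial(rri: EventSeries, rsp: UniformSignal | None = None,
                fs_resample: float = 4.0, method: str = "welch") -> TrialScore:
    """Compute the spectral RBA measures for one trial.

    The tachogram is resampled (shape-preserving) at ``fs_resample``,
    detrended, and its PSD summarised over the LF band.  When a paired
    respiration waveform is supplied, HRMaxMin and the HR-respiration
    phase are evaluated at the dominant breathing frequency.
    """
    from .preprocess import detrend, extract_breath_intervals, resample_uniform

    tach = detrend(resample_uniform(rri, fs_resample), "linear")
    summary = psd_estimate(tach, method=method)
    lf = band_metrics(summary, LF_BAND)
    hrmm = None
    phase = None
    if rsp is not None:
        breaths = extract_breath_intervals(rsp)
        peaks = breaths.peak_to_peak
        bounds = np.concatenate((
            [peaks.times[0] - peaks.intervals[0]], peaks.times))
        hrmm = hr_max_min(rri, bounds)
        f_b = 1.0 / float(np.mean(peaks.intervals))
        rsp_grid = np.interp(tach.times, rsp.times, rsp.values)
        hr_sig = UniformSignal(60000.0 / tach.values, fs=tach.fs, t0=tach.t0)
        rsp_sig = UniformSignal(rsp_grid, fs=tach.fs, t0=tach.t0)
        phase = resp_hr_phase(hr_sig, rsp_sig, f_b)
    return TrialScore(lfbp=lf.power, plfp=lf.peak_power, lf_nu=lf.nu,
                      hr_max_min=hrmm, phase_deg=phase)
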