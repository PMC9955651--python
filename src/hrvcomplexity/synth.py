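"""Synthetic calibration signals and a paced-breathing physiological cohort.

Two kinds of generators:

* Calibration signals of known fractal dimension — fractional Brownian
  motion (graph dimension 2 - H) via circulant-embedding synthesis of
  fractional Gaussian noise, and random-phase Weierstrass functions of
  prescribed graph dimension D.

* A cohort of virtual participants performing the paced-breathing
  protocol: Baseline, self-paced, and five externally paced trials at
  7, 6.5, 6, 5.5 and 5 breaths/min, each 315 s.  Respiratory sinus
  arrhythmia is modelled with a second-order resonance transfer
  function peaking at a per-subject resonance frequency f0 near 0.1 Hz:
  breathing at the rate closest to f0 produces the largest heart-rate
  oscillation, which is what the resonance-breathing assessment is
  designed to recover.  Beat times follow an integrate-and-fire rule on
  the instantaneous RR duration; 1/f (pink) noise models intrinsic HRV.

Defaults are chosen to be physiologically plausible for seated adults:
mean RR 900 ms, RSA gain 20 ms with resonance quality Q = 3 (so the
within-breath heart-rate excursion at resonance is on the order of
10-20 bpm), pink-noise sd 15 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import coloured_noise
from .sigio import EventSeries, UniformSignal

__all__ = [
    "CohortSpec",
    "gen_fbm",
    "gen_fgn",
    "gen_weierstrass",
    "gen_pacer",
    "gen_rri_trial",
    "gen_eda",
    "gen_cohort",
    "TRIAL_RATES",
]

#: Externally paced trial rates, breaths per minute.
TRIAL_RATES = (5.0, 5.5, 6.0, 6.5, 7.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for the synthetic cohort."""

    n_subjects: int = 44
    rates: Sequence[float] = TRIAL_RATES
    f0_choices: Sequence[float] | None = None   # Hz; default: rates/60
    q: float = 3.0              # resonance quality factor
    #: RSA amplitude scale G (ms): at resonance the sinusoidal RR swing is
    #: G*q.  Calibrated so the within-breath HR excursion at resonance sits
    #: at the centre (~15 bpm) of the 10-20 bpm range typical of slow
    #: breathing at resonance.
    rsa_gain_ms: float = 30.0
    mean_rr_ms: float = 900.0
    noise_sd_ms: float = 15.0   # 1/f noise sd
    duration_s: float = 315.0   # "5 min 15 s"
    eda_trend_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 600 <= self.mean_rr_ms <= 1200:
            raise ValueError("mean RR outside 600-1200 ms")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be positive")
        choices = self.f0_choices or [r / 60.0 for r in self.rates]
        if any(not 0.06 <= f <= 0.14 for f in choices):
            raise ValueError("f0 must lie in [0.06, 0.14] Hz")
        object.__setattr__(self, "f0_choices", tuple(choices))


# ---------------------------------------------------------------------------
# Calibration signals

def gen_fgn(n: int, h: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding (Davies-Harte)."""
    if not 0.0 < h < 1.0:
        raise ValueError("H must lie in (0, 1)")
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k - 1) ** (2 * h) - 2 * k ** (2 * h)
                   + (k + 1) ** (2 * h))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    eig = np.maximum(eig, 0.0)  # clip tiny negative rounding noise
    m = row.size
    z = (rng.standard_normal(eig.size)
         + 1j * rng.standard_normal(eig.size))
    z[0] = z[0].real * np.sqrt(2)
    if m % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2)
    spec = z * np.sqrt(eig * m / 2.0)
    out = np.fft.irfft(spec, n=m) / np.sqrt(m)
    return out[:n]


def gen_fbm(n: int, h: float, seed: int) -> np.ndarray:
    """Fractional Brownian motion: cumulative sum of fGn increments.

    The graph has fractal dimension 2 - H; increment variance over span
    s scales as s**(2H).
    """
    if n < 2 ** 8:
        raise ValueError("need n >= 256")
    rng = np.random.default_rng(seed)
    return np.cumsum(gen_fgn(n, h, rng))


def gen_weierstrass(n: int, d: float, gamma: float = 1.3,
                    k_terms: int | None = None, seed: int = 0) -> np.ndarray:
    """Random-phase Weierstrass function with graph dimension ``d``.

    W(t) = sum_k gamma**((d-2) k) cos(2 pi gamma**k t + phi_k) on
    t in [0, 1).  Frequencies above the sampling Nyquist contribute
    nothing resolvable, so ``k_terms`` defaults to the largest k with
    gamma**k <= n/2 (at least 20).
    """
    if not 1.0 < d < 2.0:
        raise ValueError("D must lie in (1, 2)")
    if gamma <= 1.0:
        raise ValueError("gamma must exceed 1")
    if k_terms is None:
        k_terms = max(20, int(np.floor(np.log(n / 2.0) / np.log(gamma))))
    if k_terms < 20:
        raise ValueError("need at least 20 frequency terms")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / n
    w = np.zeros(n)
    for k in range(k_terms + 1):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        w += gamma ** ((d - 2.0) * k) * np.cos(
            2.0 * np.pi * gamma ** k * t + phi)
    return w


# ---------------------------------------------------------------------------
# Physiological cohort

def gen_pacer(rate: float, in_fraction: float = 0.4,
              duration_s: float = 315.0, fs: float = 32.0) -> UniformSignal:
    """On-screen breathing pacer waveform.

    Each cycle of period 60/rate s is a rising half-cosine over
    ``in_fraction`` of the cycle (inhalation) followed by a falling
    half-cosine (exhalation), continuous at the joins with no pause.
    The default 0.4 realises the 40/60 inhalation/exhalation ratio.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not 0.0 < in_fraction < 1.0:
        raise ValueError("in_fraction must lie in (0, 1)")
    period = 60.0 / rate
    t_in = in_fraction * period
    t = np.arange(int(round(duration_s * fs))) / fs
    phase = np.mod(t, period)
    rising = phase < t_in
    vals = np.empty_like(t)
    vals[rising] = -np.cos(np.pi * phase[rising] / t_in)
    vals[~rising] = np.cos(np.pi * (phase[~rising] - t_in) / (period - t_in))
    return UniformSignal(values=vals, fs=fs, t0=0.0)


def _rsa_amplitude(f_b: float, f0: float, g: float, q: float) -> float:
    """Second-order resonance transfer: peaks near f0 with quality q."""
    ratio = f_b / f0
    return g / np.sqrt((1.0 - ratio ** 2) ** 2 + (ratio / q) ** 2)


def gen_rri_trial(spec: CohortSpec, subject: int, rate,
                  f0: float | None = None):
    """One trial for one subject: (EventSeries of RRi, respiration signal).

    ``rate`` is a paced BrPM value, "baseline" (normal breathing,
    12-16 BrPM) or "self" (slow breathing jittered around 6 BrPM).  The
    instantaneous RR signal is mean RR + RSA sinusoid at the breathing
    frequency (resonance-scaled amplitude) + pink noise; beats fire at
    t_{n+1} = t_n + RR(t_n)/1000.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, subject, _rate_tag(rate)]))
    if f0 is None:
        f0 = float(rng.choice(spec.f0_choices))
    if rate == "baseline":
        f_b = rng.uniform(12.0, 16.0) / 60.0
    elif rate == "self":
        f_b = (6.0 + rng.normal(0.0, 0.3)) / 60.0
    else:
        f_b = float(rate) / 60.0
    amp = _rsa_amplitude(f_b, f0, spec.rsa_gain_ms, spec.q)
    phi = rng.uniform(0.0, 2.0 * np.pi)

    fs_mod = 8.0
    t_grid = np.arange(int(spec.duration_s * fs_mod) + 1) / fs_mod
    if spec.noise_sd_ms > 0:
        noise = coloured_noise(t_grid.size, "pink", rng) * spec.noise_sd_ms
    else:
        noise = np.zeros(t_grid.size)
    rr_of_t = (spec.mean_rr_ms
               + amp * np.sin(2.0 * np.pi * f_b * t_grid + phi) + noise)

    beats = []
    t = 0.0
    while True:
        rr = float(np.interp(t, t_grid, rr_of_t))
        rr = max(rr, 300.0)  # physiological floor
        t += rr / 1000.0
        if t > spec.duration_s:
            break
        beats.append((t, rr))
    times = np.array([b[0] for b in beats])
    intervals = np.array([b[1] for b in beats])
    rri = EventSeries(times=times, intervals=intervals, kind="RRi")

    # paired respiration: pacer shape with mild cycle jitter
    jitter = 0.08 if rate == "baseline" else 0.02
    rsp = gen_pacer(f_b * 60.0, duration_s=spec.duration_s)
    jig = 1.0 + jitter * np.sin(2.0 * np.pi * 0.01 * rsp.times
                                + rng.uniform(0, 2 * np.pi))
    rsp = UniformSignal(values=rsp.values * jig, fs=rsp.fs, t0=0.0)
    return rri, rsp


def _rate_tag(rate) -> int:
    if rate == "baseline":
        return 900
    if rate == "self":
        return 901
    return int(round(float(rate) * 10))


def gen_eda(duration_s: float, trend_rate: float = 0.05,
            scr_rate: float = 0.02, seed: int = 0,
            fs: float = 32.0, noise_sd: float = 0.005) -> UniformSignal:
    """Electrodermal activity: decaying tonic level, sparse phasic
    responses (bi-exponential kernels, Poisson arrivals) and white noise.

    ``trend_rate`` is the tonic decay rate (1/min); sitting quietly the
    tonic level drifts down, so the robust slope of the output is
    negative.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    tonic = 2.0 + 3.0 * np.exp(-trend_rate * t / 60.0)
    phasic = np.zeros(n)
    n_events = rng.poisson(scr_rate * duration_s)
    for _ in range(n_events):
        onset = rng.uniform(0.0, duration_s)
        tau_rise, tau_decay = 0.75, 2.0
        mask = t >= onset
        dt = t[mask] - onset
        kernel = np.exp(-dt / tau_decay) - np.exp(-dt / tau_rise)
        phasic[mask] += 0.3 * rng.uniform(0.5, 1.5) * kernel
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    return UniformSignal(values=tonic + phasic + noise, fs=fs, t0=0.0)


@dataclass
class SubjectRecord:
    subject: int
    f0: float
    trials: dict = field(default_factory=dict)  # label -> (rri, rsp)


def gen_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort: per subject, Baseline + Self + the five
    paced trials, with a per-subject resonance frequency drawn from
    ``spec.f0_choices``."""
    master = np.random.default_rng(np.random.SeedSequence([spec.seed, 777]))
    records = []
    for s in range(spec.n_subjects):
        f0 = float(master.choice(spec.f0_choices))
        rec = SubjectRecord(subject=s, f0=f0)
        rec.trials["Baseline"] = gen_rri_trial(spec, s, "baseline", f0=f0)
        rec.trials["Self"] = gen_rri_trial(spec, s, "self", f0=f0)
        for rate in spec.rates:
            label = f"{rate:g}"
            rec.trials[label] = gen_rri_trial(spec, s, rate, f0=f0)
        records.append(rec)
    return records
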