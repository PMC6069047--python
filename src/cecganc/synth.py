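"""Synthetic four-channel capacitive-ECG records with known ground truth.

The generator produces a clean PQRST waveform (Gaussian bumps per wave),
structured motion noise (baseline wander, noise bursts, impulses), and four
sensor channels built from a linear coupling model:

    sigL  = +s/2              + hL  * n + vL
    sigR  = -s/2              + hR  * n + vR
    sigaL = +(1-lam) * s/2    + haL * n + vaL
    sigaR = -(1-lam) * s/2    + haR * n + vaR

where ``s`` is the clean ECG, ``n`` the motion noise, ``hX`` short distinct
FIR coupling paths, ``vX`` independent sensor noise and ``lam`` the
``leakage_coeff``.  The outer difference recovers ``s`` plus differential
noise; each reference (outer minus inner) carries motion information plus a
residual ``lam * s / 2`` of the clean ECG — the imperfect-correlation
condition that makes plain ANC eat QRS power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import signal as sps

from .preprocess import MultichannelRecord

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_clean_ecg",
    "generate_motion_noise",
    "generate_record",
    "preset_params",
    "PRESETS",
    "WAVE_OFFSETS_S",
    "WAVE_POLARITY",
]

#: Wave-center offsets relative to the R peak, seconds.
WAVE_OFFSETS_S = {"P": -0.22, "Q": -0.035, "R": 0.0, "S": 0.035, "T": 0.30}

#: Deflection sign per wave (amplitudes are stored as magnitudes).
WAVE_POLARITY = {"P": 1.0, "Q": -1.0, "R": 1.0, "S": -1.0, "T": 1.0}

_WANDER_MAX_HZ = 0.8
_BURST_LP_HZ = 20.0


def _default_amplitudes() -> dict:
    # P and T deliberately small: capacitive sensors barely pick them up.
    return {"P": 0.05, "Q": 0.1, "R": 1.0, "S": 0.15, "T": 0.1}


def _default_widths() -> dict:
    return {"P": 0.04, "Q": 0.01, "R": 0.012, "S": 0.012, "T": 0.07}


@dataclass
class SynthParams:
    """Everything needed to generate one synthetic record deterministically."""

    duration_s: float = 60.0
    fs: float = 200.0
    heart_rate_bpm: float = 60.0
    rr_jitter: float = 0.03
    wave_amplitudes: dict = field(default_factory=_default_amplitudes)
    wave_widths: dict = field(default_factory=_default_widths)
    baseline_wander_amp: float = 0.0
    burst_noise_amp: float = 0.0
    burst_rate: float = 0.0
    impulse_amp: float = 0.0
    impulse_rate: float = 0.0
    leakage_coeff: float = 0.1
    sensor_noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 20 < self.heart_rate_bpm < 240:
            raise ValueError("heart_rate_bpm must be in (20, 240)")
        if not 0 <= self.leakage_coeff < 1:
            raise ValueError("leakage_coeff must be in [0, 1)")
        for name, amp in self.wave_amplitudes.items():
            if amp < 0:
                raise ValueError(f"wave amplitude {name} must be >= 0")
        for val, name in (
            (self.baseline_wander_amp, "baseline_wander_amp"),
            (self.burst_noise_amp, "burst_noise_amp"),
            (self.burst_rate, "burst_rate"),
            (self.impulse_amp, "impulse_amp"),
            (self.impulse_rate, "impulse_rate"),
            (self.sensor_noise_std, "sensor_noise_std"),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class GroundTruth:
    """Known truth accompanying a synthetic record."""

    true_r_peaks: np.ndarray
    clean_ecg: np.ndarray
    motion_noise: np.ndarray

    def __post_init__(self) -> None:
        self.true_r_peaks = np.asarray(self.true_r_peaks, dtype=int)
        if len(self.true_r_peaks) > 1 and np.any(np.diff(self.true_r_peaks) <= 0):
            raise ValueError("true_r_peaks must be strictly increasing")
        n = len(self.clean_ecg)
        if len(self.true_r_peaks) and (
            self.true_r_peaks[0] < 0 or self.true_r_peaks[-1] >= n
        ):
            raise ValueError("true_r_peaks out of range")


def generate_clean_ecg(params: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Clean PQRST waveform as a sum of per-beat Gaussian bumps.

    RR intervals are drawn around the mean heart rate with fractional
    standard deviation ``rr_jitter``.  Returns ``(samples, r_peaks)`` where
    ``r_peaks`` are the exact sample indices of the R-wave maxima.
    """
    fs = params.fs
    n = params.n_samples
    rng = np.random.default_rng(params.seed)
    rr_mean = 60.0 / params.heart_rate_bpm

    # schedule R times; first beat offset leaves room for the P wave
    t = 0.35 * rr_mean + 0.15
    # leave room for the S and T waves so the final beat is not truncated
    last_valid = n - int(round(0.3 * fs))
    r_idx: list[int] = []
    while True:
        idx = int(round(t * fs))
        if idx >= last_valid:
            break
        r_idx.append(idx)
        rr = rr_mean * max(0.3, 1.0 + params.rr_jitter * rng.standard_normal())
        t += rr
    r_peaks = np.asarray(r_idx, dtype=int)

    sig = np.zeros(n)
    times = np.arange(n) / fs
    for idx in r_peaks:
        t_r = idx / fs
        lo = max(0, int((t_r - 0.6) * fs))
        hi = min(n, int((t_r + 0.7) * fs) + 1)
        seg_t = times[lo:hi]
        for wave, off in WAVE_OFFSETS_S.items():
            amp = params.wave_amplitudes.get(wave, 0.0)
            if amp == 0.0:
                continue
            width = params.wave_widths.get(wave, 0.02)
            sig[lo:hi] += (
                WAVE_POLARITY[wave]
                * amp
                * np.exp(-0.5 * ((seg_t - (t_r + off)) / width) ** 2)
            )
    return sig, r_peaks


def generate_motion_noise(params: SynthParams, n_samples: int) -> np.ndarray:
    """Structured motion noise: baseline wander + bursts + impulses.

    Wander is a sum of random-phase sinusoids below 0.8 Hz normalized to RMS
    ``baseline_wander_amp``; bursts are Poisson-scheduled Hann-windowed
    segments of low-pass-filtered white noise with RMS ``burst_noise_amp``;
    impulses are Poisson-scheduled single-sample spikes of
    ``+-impulse_amp``.  Deterministic given ``params.seed``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    fs = params.fs
    rng = np.random.default_rng(params.seed)
    out = np.zeros(n_samples)
    times = np.arange(n_samples) / fs
    duration = n_samples / fs

    if params.baseline_wander_amp > 0:
        k = 6
        freqs = rng.uniform(0.05, _WANDER_MAX_HZ, k)
        phases = rng.uniform(0, 2 * np.pi, k)
        amps = rng.uniform(0.5, 1.0, k)
        wander = np.zeros(n_samples)
        for f, ph, a in zip(freqs, phases, amps):
            wander += a * np.sin(2 * np.pi * f * times + ph)
        rms = np.sqrt(np.mean(wander**2))
        if rms > 0:
            out += params.baseline_wander_amp * wander / rms

    if params.burst_noise_amp > 0 and params.burst_rate > 0:
        n_bursts = rng.poisson(params.burst_rate * duration / 60.0)
        sos = sps.butter(4, _BURST_LP_HZ, btype="low", fs=fs, output="sos")
        for _ in range(n_bursts):
            b_dur = rng.uniform(0.5, 2.0)
            b_len = max(8, int(round(b_dur * fs)))
            start = int(rng.uniform(0, max(1, n_samples - b_len)))
            white = rng.standard_normal(b_len)
            shaped = sps.sosfilt(sos, white) * np.hanning(b_len)
            rms = np.sqrt(np.mean(shaped**2))
            if rms > 0:
                shaped = shaped / rms * params.burst_noise_amp
            stop = min(n_samples, start + b_len)
            out[start:stop] += shaped[: stop - start]

    if params.impulse_amp > 0 and params.impulse_rate > 0:
        n_imp = rng.poisson(params.impulse_rate * duration / 60.0)
        if n_imp > 0:
            pos = rng.integers(0, n_samples, n_imp)
            signs = rng.choice([-1.0, 1.0], n_imp)
            out[pos] += signs * params.impulse_amp

    return out


#: Per-channel noise-coupling gain ranges.  The outer pair is deliberately
#: imbalanced (different contact quality) so differential noise survives in
#: the measured ECG, and the inner pair couples more weakly so each
#: outer-minus-inner reference keeps a strong motion component.  With i.i.d.
#: gains the mismatches can vanish by chance and the record degenerates to
#: either a noise-free ECG or a dead reference.
_GAIN_RANGES = {
    "L": (1.05, 1.25),
    "R": (0.75, 0.95),
    "aL": (0.45, 0.60),
    "aR": (0.45, 0.60),
}


def _coupling_fir(rng: np.random.Generator, channel: str) -> np.ndarray:
    """Length-5 smoothing FIR, unit DC gain, times a per-channel gain."""
    h = rng.uniform(0.2, 1.0, 5)
    h = h / h.sum()
    lo, hi = _GAIN_RANGES[channel]
    return rng.uniform(lo, hi) * h


#: Knot spacing (s) and relative depth of the slow coupling-gain drift.
_GAIN_DRIFT_KNOT_S = 1.5
_GAIN_DRIFT_DEPTH = 0.3


def _gain_drift(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Slowly varying multiplicative envelope for a noise-coupling path.

    Body-sensor coupling drifts as posture shifts, so the noise transfer is
    nonstationary on a seconds timescale.  Linear interpolation between
    random knots a couple of seconds apart is enough to make a
    small-step-size canceller lag while a fast one tracks.
    """
    knot_step = max(1, int(round(_GAIN_DRIFT_KNOT_S * fs)))
    n_knots = n // knot_step + 2
    knots = 1.0 + _GAIN_DRIFT_DEPTH * rng.uniform(-1.0, 1.0, n_knots)
    x = np.arange(n) / knot_step
    return np.interp(x, np.arange(n_knots), knots)


def generate_record(params: SynthParams) -> tuple[MultichannelRecord, GroundTruth]:
    """Build the four sensor channels from the linear coupling model.

    Sub-generators use seeds derived from ``params.seed`` so the record is
    fully determined by its parameters.  With all noise sources off,
    ``sigL - sigR`` equals the clean ECG exactly and each reference carries
    ``leakage_coeff * s / 2``.
    """
    n = params.n_samples
    s, r_peaks = generate_clean_ecg(params)
    noise = generate_motion_noise(replace(params, seed=params.seed + 1), n)
    rng = np.random.default_rng(params.seed + 2)

    h = {name: _coupling_fir(rng, name) for name in ("L", "R", "aL", "aR")}
    coupled = {
        name: sps.lfilter(h[name], 1.0, noise) * _gain_drift(rng, n, params.fs)
        for name in h
    }

    def sensor_noise() -> np.ndarray:
        if params.sensor_noise_std > 0:
            return rng.normal(0.0, params.sensor_noise_std, n)
        return np.zeros(n)

    lam = params.leakage_coeff
    sigL = 0.5 * s + coupled["L"] + sensor_noise()
    sigR = -0.5 * s + coupled["R"] + sensor_noise()
    sigaL = (1.0 - lam) * 0.5 * s + coupled["aL"] + sensor_noise()
    sigaR = -(1.0 - lam) * 0.5 * s + coupled["aR"] + sensor_noise()

    record = MultichannelRecord(
        fs=params.fs,
        sigL=sigL,
        sigR=sigR,
        sigaL=sigaL,
        sigaR=sigaR,
        ecg_contact=s,
        meta={"seed": params.seed, "params": asdict(params)},
    )
    truth = GroundTruth(true_r_peaks=r_peaks, clean_ecg=s, motion_noise=noise)
    return record, truth


#: Noise presets.  ``clean`` has no motion noise at all; ``moderate``
#: resembles continuous driving vibration plus occasional disturbances;
#: ``abnormal`` is dominated by large bursts and impulses that no canceller
#: is expected to remove.
PRESETS: dict[str, dict] = {
    # With no motion noise a leaky reference would contain nothing but the
    # ECG itself, so the ideal preset also zeroes the leakage.
    "clean": dict(
        baseline_wander_amp=0.0,
        burst_noise_amp=0.0,
        burst_rate=0.0,
        impulse_amp=0.0,
        impulse_rate=0.0,
        sensor_noise_std=0.0,
        leakage_coeff=0.0,
    ),
    # quasi-continuous vibration plus wander, no impulsive events: the
    # regime where adaptive cancellation is expected to help
    "moderate": dict(
        baseline_wander_amp=0.3,
        burst_noise_amp=0.35,
        burst_rate=400.0,
        impulse_amp=0.0,
        impulse_rate=0.0,
        sensor_noise_std=0.02,
        leakage_coeff=0.2,
    ),
    "abnormal": dict(
        baseline_wander_amp=1.0,
        burst_noise_amp=6.0,
        burst_rate=30.0,
        impulse_amp=8.0,
        impulse_rate=30.0,
        sensor_noise_std=0.02,
        leakage_coeff=0.2,
    ),
}


def preset_params(
    preset: str,
    duration_s: float = 60.0,
    seed: int = 0,
    heart_rate_bpm: float = 60.0,
    **overrides,
) -> SynthParams:
    """SynthParams for a named noise preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return SynthParams(
        duration_s=duration_s,
        seed=seed,
        heart_rate_bpm=heart_rate_bpm,
        **kwargs,
    )
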