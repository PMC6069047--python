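"""Evaluation indices: peak matching, Se, P+, Avg, SNR estimate, and PIR."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rpeak import PeakSet

__all__ = [
    "MatchResult",
    "MetricsReport",
    "match_peaks",
    "sensitivity",
    "positive_predictivity",
    "avg",
    "snr_hat",
    "qrs_power_mask",
    "qrs_power_ratio",
    "pir",
    "evaluate_peaks",
]

#: Width of the search window centered on each true R peak, seconds.
MATCH_WINDOW_S = 0.080


@dataclass
class MatchResult:
    """Outcome of matching detected peaks against true peaks."""

    tp: int
    fn: int
    fp: int
    matched_pairs: list = field(default_factory=list)


@dataclass
class MetricsReport:
    """Detection-quality summary for one signal."""

    se: float
    p_plus: float
    avg: float
    snr_hat: float
    tp: int
    fn: int
    fp: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def match_peaks(
    true_peaks: PeakSet, detected: PeakSet, window_s: float = MATCH_WINDOW_S
) -> MatchResult:
    """Greedy one-to-one matching inside a window centered on each true peak.

    A detected peak within ``window_s / 2`` of a true peak (closed interval,
    half-window rounded to the nearest sample) is a true positive; each peak
    can participate in at most one match.  Matching proceeds in time order,
    which for equal-width windows attains the optimum number of matches.
    """
    if true_peaks.fs != detected.fs:
        raise ValueError("peak sets must share a sampling rate")
    half = int(round(window_s / 2 * true_peaks.fs))
    t = true_peaks.indices
    d = detected.indices
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < len(t) and j < len(d):
        if d[j] < t[i] - half:
            j += 1
        elif d[j] <= t[i] + half:
            pairs.append((int(t[i]), int(d[j])))
            i += 1
            j += 1
        else:
            i += 1
    tp = len(pairs)
    return MatchResult(
        tp=tp, fn=len(t) - tp, fp=len(d) - tp, matched_pairs=pairs
    )


def sensitivity(m: MatchResult) -> float:
    """Se = TP / (TP + FN) * 100."""
    if m.tp + m.fn == 0:
        raise ValueError("sensitivity undefined: no true peaks")
    return 100.0 * m.tp / (m.tp + m.fn)


def positive_predictivity(m: MatchResult) -> float:
    """P+ = TP / (TP + FP) * 100."""
    if m.tp + m.fp == 0:
        raise ValueError("positive predictivity undefined: no detections")
    return 100.0 * m.tp / (m.tp + m.fp)


def avg(se: float, p_plus: float) -> float:
    """Mean of sensitivity and positive predictivity."""
    return 0.5 * (se + p_plus)


def qrs_power_mask(
    n_samples: int, peaks: PeakSet, fs: float, window_s: float = 0.100
) -> np.ndarray:
    """Boolean mask of the union of windows centered on the given peaks."""
    half = int(round(window_s / 2 * fs))
    mask = np.zeros(n_samples, dtype=bool)
    for p in peaks.indices:
        mask[max(0, p - half) : min(n_samples, p + half + 1)] = True
    return mask


def snr_hat(
    signal: np.ndarray,
    r_peaks: PeakSet,
    fs: float,
    qrs_window_s: float = 0.100,
) -> float:
    """Power in 100-ms windows around R peaks over power everywhere else.

    Returns ``inf`` when the outside-window power is zero while the inside
    power is not.
    """
    signal = np.asarray(signal, dtype=float)
    if len(r_peaks) == 0:
        raise ValueError("snr_hat requires at least one peak")
    mask = qrs_power_mask(len(signal), r_peaks, fs, qrs_window_s)
    ps = float(np.mean(signal[mask] ** 2))
    outside = signal[~mask]
    pn = float(np.mean(outside**2)) if len(outside) else 0.0
    if pn == 0.0:
        return math.inf if ps > 0 else 0.0
    return ps / pn


def qrs_power_ratio(
    filtered: np.ndarray,
    reference: np.ndarray,
    peaks: PeakSet,
    fs: float,
    window_s: float = 0.100,
) -> float:
    """QRS-power conservation: window power of ``filtered`` over ``reference``.

    Values near 1 mean the QRS complexes survived filtering; values well
    below 1 mean the canceller ate them.
    """
    mask = qrs_power_mask(len(filtered), peaks, fs, window_s)
    num = float(np.mean(np.asarray(filtered, dtype=float)[mask] ** 2))
    den = float(np.mean(np.asarray(reference, dtype=float)[mask] ** 2))
    if den == 0.0:
        raise ValueError("reference has zero power in QRS windows")
    return num / den


def pir(davg_proposed: float, davg_apa: float) -> float:
    """Performance increase ratio: quotient of the two Avg improvements."""
    if davg_apa == 0:
        raise ValueError("pir undefined: denominator d_Avg is zero")
    return davg_proposed / davg_apa


def evaluate_peaks(
    true_peaks: PeakSet,
    detected: PeakSet,
    signal: np.ndarray | None = None,
    snr_peaks: PeakSet | None = None,
    window_s: float = MATCH_WINDOW_S,
) -> MetricsReport:
    """Full report: match, Se, P+, Avg, and (if a signal is given) SNR.

    ``snr_peaks`` selects which peak set centers the SNR windows; it
    defaults to the true peaks when available.
    """
    m = match_peaks(true_peaks, detected, window_s)
    se = sensitivity(m)
    pp = positive_predictivity(m) if (m.tp + m.fp) > 0 else 0.0
    snr = float("nan")
    if signal is not None:
        peaks_for_snr = snr_peaks if snr_peaks is not None else true_peaks
        if len(peaks_for_snr):
            snr = snr_hat(signal, peaks_for_snr, peaks_for_snr.fs)
    return MetricsReport(
        se=se, p_plus=pp, avg=avg(se, pp), snr_hat=snr, tp=m.tp, fn=m.fn, fp=m.fp
    )
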