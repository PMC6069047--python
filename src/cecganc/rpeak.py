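"""R-peak detection via the classic derivative/square/integrate chain.

Stage chain: band-pass for QRS emphasis, five-point derivative, squaring,
moving-window integration, then adaptive signal/noise thresholding with a
refractory period and optional search-back.  Detected locations are refined
to the local maximum of the band-passed signal near each integration peak.
All thresholds are derived from the data, so detection is invariant to
positive rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["DetectorConfig", "PeakSet", "pan_tompkins", "merge_peaks"]


@dataclass
class DetectorConfig:
    """Stage parameters of the detector (classic defaults)."""

    band: tuple = (5.0, 15.0)
    mwi_width_s: float = 0.150
    refractory_s: float = 0.200
    search_back: bool = True
    #: threshold running-average coefficient for accepted peaks
    peak_memory: float = 0.125
    #: search-back triggers when the gap exceeds this multiple of the mean RR
    searchback_rr_factor: float = 1.66

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.mwi_width_s <= 0 or self.refractory_s <= 0:
            raise ValueError("widths must be positive")


@dataclass
class PeakSet:
    """Ordered R-peak sample indices at a given sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    def times(self) -> np.ndarray:
        return self.indices / self.fs


def _stages(signal: np.ndarray, fs: float, cfg: DetectorConfig):
    low, high = cfg.band
    high = min(high, 0.95 * fs / 2)
    sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, signal)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    squared = deriv**2
    w = max(1, int(round(cfg.mwi_width_s * fs)))
    mwi = np.convolve(squared, np.ones(w) / w, mode="same")
    return bp, mwi


def pan_tompkins(
    signal: np.ndarray, fs: float, cfg: DetectorConfig | None = None
) -> PeakSet:
    """Detect R peaks in a single-channel ECG.

    Requires at least two seconds of samples.  Returns a :class:`PeakSet`
    whose consecutive peaks are separated by at least the refractory period.
    """
    cfg = cfg or DetectorConfig()
    signal = np.asarray(signal, dtype=float)
    fs = float(fs)
    if len(signal) < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    if not np.any(signal):
        return PeakSet(np.array([], dtype=int), fs)

    bp, mwi = _stages(signal, fs, cfg)
    refr = max(1, int(round(cfg.refractory_s * fs)))
    cands, _ = sps.find_peaks(mwi, distance=refr)
    if len(cands) == 0:
        return PeakSet(np.array([], dtype=int), fs)

    # robust global initialization: a first-seconds max is hijacked by any
    # startup artifact, so seed the running thresholds from quantiles instead
    spki = 0.25 * float(np.quantile(mwi, 0.98))
    npki = float(np.median(mwi))
    pm = cfg.peak_memory

    accepted: list[int] = []
    rr_intervals: list[float] = []
    noise_since_last: list[int] = []

    def accept(c: int, searchback: bool) -> None:
        nonlocal spki
        if searchback:
            spki = 0.25 * mwi[c] + 0.75 * spki
        else:
            spki = pm * mwi[c] + (1 - pm) * spki
        if accepted:
            rr_intervals.append(c - accepted[-1])
            if len(rr_intervals) > 8:
                rr_intervals.pop(0)
        accepted.append(c)
        noise_since_last.clear()

    for c in cands:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] > thr:
            accept(int(c), searchback=False)
            continue
        npki = pm * mwi[c] + (1 - pm) * npki
        noise_since_last.append(int(c))
        if cfg.search_back and accepted and rr_intervals:
            rr_avg = float(np.mean(rr_intervals))
            if c - accepted[-1] > cfg.searchback_rr_factor * rr_avg:
                gap = [g for g in noise_since_last if g - accepted[-1] >= refr]
                if gap:
                    best = max(gap, key=lambda g: mwi[g])
                    if mwi[best] > 0.5 * thr:
                        accept(best, searchback=True)

    if not accepted:
        return PeakSet(np.array([], dtype=int), fs)

    # refine each integration peak to the band-passed local maximum
    half = max(1, int(round(0.050 * fs)))
    refined = []
    for c in sorted(accepted):
        lo = max(0, c - half)
        hi = min(len(bp), c + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))

    # enforce the refractory period after refinement, keeping the stronger peak
    refined.sort()
    kept: list[int] = []
    for r in refined:
        if kept and r - kept[-1] < refr:
            if bp[r] > bp[kept[-1]]:
                kept[-1] = r
        else:
            kept.append(r)

    return PeakSet(np.asarray(kept, dtype=int), fs)


def merge_peaks(a: PeakSet, b: PeakSet, tol_s: float = 0.080) -> PeakSet:
    """Union of two peak sets with near-duplicates collapsed to the earlier.

    Any two peaks closer than ``tol_s`` are treated as one detection (used
    to deduplicate peaks found in overlapping processing windows).
    """
    if a.fs != b.fs:
        raise ValueError("peak sets must share a sampling rate")
    merged = np.union1d(a.indices, b.indices)
    tol = tol_s * a.fs
    kept: list[int] = []
    for idx in merged:
        if kept and idx - kept[-1] < tol:
            continue
        kept.append(int(idx))
    return PeakSet(np.asarray(kept, dtype=int), a.fs)
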