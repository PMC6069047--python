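"""The full active-noise-cancellation loop over a record.

For each sample ``i`` the stacked reference vector is formed, the filter
output ``y(i) = w^T n_i'`` subtracted from the measured ECG
(``e(i) = d(i) - y(i)`` is the denoised stream), and one weight update of
the configured algorithm applied.  The adaptive filter runs as one
continuous stream; the 6-s/2-s-overlap windows are used only for the
postprocessing sanity rules, which may substitute the raw ECG for a window
whose filtered version looks abnormal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import filters, rpeak
from .filters import Branch, FilterConfig, UpdateTrace
from .preprocess import reference_vector

__all__ = ["ANCConfig", "ANCResult", "iter_windows", "postprocess", "run_anc"]


@dataclass
class ANCConfig:
    """Loop-level configuration wrapping a :class:`FilterConfig`."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    window_s: float = 6.0
    overlap_s: float = 2.0
    postprocess: bool = False
    pp_rr_ratio_bounds: tuple = (0.5, 2.0)
    pp_power_ratio_max: float = 4.0

    def __post_init__(self) -> None:
        if not self.window_s > self.overlap_s >= 0:
            raise ValueError("need window_s > overlap_s >= 0")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["filter"] = self.filter.to_dict()
        d["pp_rr_ratio_bounds"] = list(self.pp_rr_ratio_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ANCConfig":
        d = dict(d)
        if isinstance(d.get("filter"), dict):
            d["filter"] = FilterConfig.from_dict(d["filter"])
        if "pp_rr_ratio_bounds" in d:
            d["pp_rr_ratio_bounds"] = tuple(d["pp_rr_ratio_bounds"])
        return cls(**d)


@dataclass
class ANCResult:
    """Denoised stream plus per-iteration diagnostics."""

    filtered: np.ndarray
    traces: list
    windows_reverted: list = field(default_factory=list)

    def branch_counts(self) -> dict:
        counts: dict = {b.value: 0 for b in Branch}
        for t in self.traces:
            counts[t.branch.value] += 1
        return counts


def iter_windows(
    n_samples: int, fs: float, window_s: float = 6.0, overlap_s: float = 2.0
) -> list[tuple[int, int]]:
    """Half-open sample ranges of overlapping processing windows.

    Hop is ``window_s - overlap_s``; a final partial window is included so
    the ranges always cover ``[0, n_samples)``.
    """
    win = int(round(window_s * fs))
    hop = int(round((window_s - overlap_s) * fs))
    if hop <= 0:
        raise ValueError("window must be longer than overlap")
    if n_samples <= win:
        return [(0, n_samples)]
    out = []
    start = 0
    while True:
        end = start + win
        if end >= n_samples:
            out.append((start, n_samples))
            break
        out.append((start, end))
        start += hop
    return out


def postprocess(
    filtered_window: np.ndarray,
    raw_window: np.ndarray,
    detected_peaks: rpeak.PeakSet,
    cfg: ANCConfig,
) -> tuple[np.ndarray, bool]:
    """Sanity rules over one window; revert to the raw ECG when abnormal.

    Rule 1: for every run of three consecutive detected peaks the ratio of
    the two RR intervals must stay inside ``pp_rr_ratio_bounds``.  Rule 2:
    the filtered/raw power ratio must not exceed ``pp_power_ratio_max`` and
    the filtered window must not be silent while the raw one is not.
    Returns the window to use plus a flag saying whether it was reverted.
    """
    if len(filtered_window) != len(raw_window):
        raise ValueError("windows must have equal length")
    abnormal = False

    idx = detected_peaks.indices
    if len(idx) >= 3:
        rr = np.diff(idx).astype(float)
        lo, hi = cfg.pp_rr_ratio_bounds
        ratios = rr[1:] / rr[:-1]
        if np.any((ratios < lo) | (ratios > hi)):
            abnormal = True

    p_f = float(np.mean(np.asarray(filtered_window, dtype=float) ** 2))
    p_r = float(np.mean(np.asarray(raw_window, dtype=float) ** 2))
    if p_r > 0 and (p_f == 0.0 or p_f / p_r > cfg.pp_power_ratio_max):
        abnormal = True

    if abnormal:
        return np.array(raw_window, dtype=float, copy=True), True
    return np.asarray(filtered_window, dtype=float), False


def _apply_postprocess(
    filtered: np.ndarray, raw: np.ndarray, fs: float, cfg: ANCConfig
) -> tuple[np.ndarray, list[int]]:
    out = filtered.copy()
    reverted: list[int] = []
    min_len = int(2 * fs)  # detector needs two seconds of context
    for widx, (a, b) in enumerate(
        iter_windows(len(filtered), fs, cfg.window_s, cfg.overlap_s)
    ):
        fwin = filtered[a:b]
        rwin = raw[a:b]
        if len(fwin) >= min_len:
            peaks = rpeak.pan_tompkins(fwin, fs)
        else:
            peaks = rpeak.PeakSet(np.array([], dtype=int), fs)
        chosen, flag = postprocess(fwin, rwin, peaks, cfg)
        if flag:
            out[a:b] = chosen
            reverted.append(widx)
    return out, reverted


def run_anc(
    ecg_m: np.ndarray,
    r_left: np.ndarray,
    r_right: np.ndarray,
    cfg: ANCConfig | FilterConfig | None = None,
    fs: float = 200.0,
    collect_traces: bool = True,
) -> ANCResult:
    """Stream the whole record through the adaptive canceller.

    The output has the same length and alignment as the input; filter state
    persists across the full record (windows are never refiltered).  When
    ``cfg.postprocess`` is on, the configured windows are checked afterwards
    and abnormal ones replaced by the raw measured ECG; ``fs`` is only used
    for that windowing and for peak detection inside it.
    """
    if cfg is None:
        cfg = ANCConfig()
    elif isinstance(cfg, FilterConfig):
        cfg = ANCConfig(filter=cfg)
    d = np.asarray(ecg_m, dtype=float)
    r_left = np.asarray(r_left, dtype=float)
    r_right = np.asarray(r_right, dtype=float)
    if not len(d) == len(r_left) == len(r_right):
        raise ValueError("ecg_m, r_left, r_right must have equal length")

    fcfg = cfg.filter
    L, P = fcfg.L, fcfg.P
    state = filters.init_state(fcfg)
    n = len(d)
    out = np.empty(n)
    traces: list[UpdateTrace] = []

    U = np.zeros((2 * L, P))
    d_vec = np.zeros(P)
    for i in range(n):
        nv = reference_vector(r_left, r_right, i, L)
        if P > 1:
            U[:, 1:] = U[:, :-1].copy()
            d_vec[1:] = d_vec[:-1].copy()
        U[:, 0] = nv
        d_vec[0] = d[i]
        out[i] = d[i] - state.w @ nv
        state, trace = filters.dispatch_step(state, U, d_vec, fcfg)
        if collect_traces:
            traces.append(trace)

    reverted: list[int] = []
    if cfg.postprocess:
        out, reverted = _apply_postprocess(out, d, fs, cfg)

    return ANCResult(filtered=out, traces=traces, windows_reverted=reverted)
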