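"""Adaptive-filter updates: APA, APSA, RVSS-APA, and the switched algorithm.

All updates operate on a weight vector of length ``2L`` (``L`` taps per
reference channel) against a matrix ``U`` whose ``P`` columns are the most
recent stacked reference vectors (newest first) and a desired vector
``d_vec`` of the matching measured-ECG samples.

The switched ("proposed") algorithm runs the affine projection algorithm
(APA) while its would-be update is small, and falls back to a tiny
affine-projection-sign (APSA) step whenever the APA update norm crosses an
adaptive threshold.  Large, sudden errors — the QRS complex seen through an
imperfect reference, or genuine impulsive noise — therefore barely move the
weights, which conserves QRS power while motion noise keeps being removed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Algorithm",
    "Branch",
    "FilterConfig",
    "FilterState",
    "UpdateTrace",
    "SingularUpdateError",
    "init_state",
    "assemble_history",
    "apa_step",
    "apsa_step",
    "rvss_step",
    "proposed_step",
    "dispatch_step",
]


class Algorithm(str, Enum):
    """Selectable weight-update rules."""

    APA = "apa"
    APSA = "apsa"
    RVSS = "rvss"
    PROPOSED = "proposed"


class Branch(str, Enum):
    """Which update actually fired at an iteration."""

    APA = "APA"
    APSA = "APSA"
    SKIPPED = "SKIPPED"


class SingularUpdateError(np.linalg.LinAlgError):
    """Raised when the P-by-P projection system is singular and unregularized."""


@dataclass
class FilterConfig:
    """All adaptive-filter parameters.

    ``L`` is the tap count per reference channel (weight length ``2L``),
    ``P`` the projection order.  ``mu`` is the plain-APA step size; ``mu1``,
    ``gamma``, ``beta`` parameterize the switched algorithm (APA step,
    APSA step scale, and threshold scale).  ``alpha`` is the memory factor
    of the threshold recursion, ``delta0`` its initial value, and
    ``eps_reg`` a Tikhonov term added before inverting ``U^T U``.

    ``eps_reg`` matters beyond start-up: during reference-power lulls an
    unregularized projection lets the weights run far along weakly excited
    directions and the output blows up when reference power returns.
    ``delta0`` should start above the operating update quantity — the
    threshold recursion relaxes downward on the APA branch but is frozen on
    the sign branch, so a too-small start traps the filter in tiny sign
    updates.
    """

    L: int = 8
    P: int = 4
    mu: float = 0.05
    mu1: float = 0.4
    gamma: float = 0.01
    beta: float = 3.5
    alpha: float = 0.995
    delta0: float = 0.5
    eps_reg: float = 0.2
    algorithm: Algorithm = Algorithm.PROPOSED

    def __post_init__(self) -> None:
        self.algorithm = Algorithm(self.algorithm)
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if not 0 < self.mu <= 1:
            raise ValueError("mu must be in (0, 1]")
        if not 0 < self.mu1 <= 1:
            raise ValueError("mu1 must be in (0, 1]")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.delta0 <= 0:
            raise ValueError("delta0 must be positive")
        if self.eps_reg < 0:
            raise ValueError("eps_reg must be non-negative")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["algorithm"] = self.algorithm.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)


@dataclass
class FilterState:
    """Evolving filter state: weights, threshold, and input history."""

    w: np.ndarray
    delta: float
    history: deque = field(default_factory=deque)  # (ref_vector, d) pairs, newest left
    iteration: int = 0


@dataclass
class UpdateTrace:
    """Per-iteration diagnostics.

    ``apa_update_norm`` is the norm of the APA update quantity evaluated at
    this iteration (for plain APSA it is the norm of the applied update);
    ``step_norm`` is the norm of the weight change actually applied.
    """

    branch: Branch
    apa_update_norm: float
    delta_after: float
    error: float
    step_norm: float


def init_state(cfg: FilterConfig) -> FilterState:
    """Zero weights, delta at ``delta0``, empty history."""
    return FilterState(
        w=np.zeros(2 * cfg.L),
        delta=float(cfg.delta0),
        history=deque(maxlen=cfg.P),
        iteration=0,
    )


def push_history(state: FilterState, ref_vec: np.ndarray, d: float) -> None:
    """Record the newest reference vector / desired sample pair."""
    state.history.appendleft((np.asarray(ref_vec, dtype=float), float(d)))


def assemble_history(state: FilterState, cfg: FilterConfig) -> tuple[np.ndarray, np.ndarray]:
    """Build ``(U, d_vec)`` from the stored history.

    Columns are newest-first; missing columns during the first ``P - 1``
    iterations are zero-padded (``eps_reg`` keeps the projection system
    invertible in that regime).
    """
    U = np.zeros((2 * cfg.L, cfg.P))
    d_vec = np.zeros(cfg.P)
    for k, (vec, d) in enumerate(state.history):
        U[:, k] = vec
        d_vec[k] = d
    return U, d_vec


def _solve_projection(U: np.ndarray, e: np.ndarray, eps_reg: float) -> np.ndarray:
    """Return ``(U^T U + eps_reg I)^{-1} e``."""
    P = U.shape[1]
    G = U.T @ U
    if eps_reg > 0:
        G = G + eps_reg * np.eye(P)
    try:
        return np.linalg.solve(G, e)
    except np.linalg.LinAlgError as exc:
        raise SingularUpdateError(
            "U^T U is singular; set eps_reg > 0 to regularize the projection"
        ) from exc


def apa_step(
    state: FilterState,
    U: np.ndarray,
    d_vec: np.ndarray,
    mu: float,
    eps_reg: float = 1e-6,
) -> tuple[FilterState, UpdateTrace]:
    """Affine projection update with step size ``mu``.

    Computes the a-priori error vector ``e = d_vec - U^T w`` and applies
    ``w <- w + mu * U (U^T U + eps_reg I)^{-1} e``.
    """
    e = d_vec - U.T @ state.w
    dw = mu * (U @ _solve_projection(U, e, eps_reg))
    state.w = state.w + dw
    state.iteration += 1
    nrm = float(np.linalg.norm(dw))
    trace = UpdateTrace(
        branch=Branch.APA,
        apa_update_norm=nrm,
        delta_after=state.delta,
        error=float(e[0]),
        step_norm=nrm,
    )
    return state, trace


def apsa_step(
    state: FilterState,
    U: np.ndarray,
    e_vec: np.ndarray,
    step: float,
) -> tuple[FilterState, UpdateTrace]:
    """Affine projection sign update with fixed update norm ``step``.

    ``w <- w + step * U sgn(e) / sqrt(sgn(e)^T U^T U sgn(e))``.  The applied
    weight change always has Euclidean norm exactly ``step``; if the
    direction degenerates (``U sgn(e) = 0``) the update is skipped.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    sg = np.sign(e_vec)
    direction = U @ sg
    denom = float(np.linalg.norm(direction))
    if denom == 0.0:
        state.iteration += 1
        trace = UpdateTrace(
            branch=Branch.SKIPPED,
            apa_update_norm=0.0,
            delta_after=state.delta,
            error=float(e_vec[0]),
            step_norm=0.0,
        )
        return state, trace
    dw = step * direction / denom
    state.w = state.w + dw
    state.iteration += 1
    trace = UpdateTrace(
        branch=Branch.APSA,
        apa_update_norm=float(np.linalg.norm(dw)),
        delta_after=state.delta,
        error=float(e_vec[0]),
        step_norm=float(np.linalg.norm(dw)),
    )
    return state, trace


def rvss_step(
    state: FilterState,
    U: np.ndarray,
    d_vec: np.ndarray,
    cfg: FilterConfig,
) -> tuple[FilterState, UpdateTrace]:
    """Reference RVSS-APA update.

    Applies a unit-step APA update when its norm stays below the current
    threshold ``delta``, otherwise an APSA update of norm ``delta``.  The
    threshold then relaxes via
    ``delta <- alpha*delta + (1-alpha)*min(|e|/||n||, delta)`` where ``n``
    is the newest reference vector.
    """
    e = d_vec - U.T @ state.w
    cand = U @ _solve_projection(U, e, cfg.eps_reg)
    cand_norm = float(np.linalg.norm(cand))
    delta_prev = state.delta
    if cand_norm < delta_prev:
        state.w = state.w + cand
        state.iteration += 1
        branch = Branch.APA
        step_norm = cand_norm
    else:
        state, trace = apsa_step(state, U, e, delta_prev)
        branch = trace.branch
        step_norm = trace.step_norm
    n_cur = U[:, 0]
    n_norm = float(np.linalg.norm(n_cur))
    term = min(abs(float(e[0])) / n_norm, delta_prev) if n_norm > 0 else delta_prev
    state.delta = cfg.alpha * delta_prev + (1.0 - cfg.alpha) * term
    trace = UpdateTrace(
        branch=branch,
        apa_update_norm=cand_norm,
        delta_after=state.delta,
        error=float(e[0]),
        step_norm=step_norm,
    )
    return state, trace


def proposed_step(
    state: FilterState,
    U: np.ndarray,
    d_vec: np.ndarray,
    cfg: FilterConfig,
) -> tuple[FilterState, UpdateTrace]:
    """Switched APA/APSA update with the update-quantity-tracking threshold.

    Let ``q = ||mu1 * U (U^T U)^{-1} e||``.  If ``q < beta*delta`` the APA
    update (step ``mu1``) is applied and the threshold tracks the update
    quantity, ``delta <- alpha*delta + (1-alpha)*q``; otherwise an APSA
    update of norm ``gamma*delta`` is applied and ``delta`` is left
    unchanged.
    """
    e = d_vec - U.T @ state.w
    cand = cfg.mu1 * (U @ _solve_projection(U, e, cfg.eps_reg))
    q = float(np.linalg.norm(cand))
    delta_prev = state.delta
    if q < cfg.beta * delta_prev:
        state.w = state.w + cand
        state.iteration += 1
        state.delta = cfg.alpha * delta_prev + (1.0 - cfg.alpha) * q
        branch = Branch.APA
        step_norm = q
    else:
        state, trace = apsa_step(state, U, e, cfg.gamma * delta_prev)
        branch = trace.branch
        step_norm = trace.step_norm
        # threshold frozen on the sign branch
    trace = UpdateTrace(
        branch=branch,
        apa_update_norm=q,
        delta_after=state.delta,
        error=float(e[0]),
        step_norm=step_norm,
    )
    return state, trace


def dispatch_step(
    state: FilterState,
    U: np.ndarray,
    d_vec: np.ndarray,
    cfg: FilterConfig,
) -> tuple[FilterState, UpdateTrace]:
    """Run one update of the configured algorithm."""
    alg = cfg.algorithm
    if alg is Algorithm.APA:
        return apa_step(state, U, d_vec, cfg.mu, cfg.eps_reg)
    if alg is Algorithm.APSA:
        e = d_vec - U.T @ state.w
        return apsa_step(state, U, e, cfg.mu)
    if alg is Algorithm.RVSS:
        return rvss_step(state, U, d_vec, cfg)
    if alg is Algorithm.PROPOSED:
        return proposed_step(state, U, d_vec, cfg)
    raise ValueError(f"unknown algorithm {alg!r}")
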