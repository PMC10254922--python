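"""Mechanistic and phenomenological models of probe transport across a vesicle membrane.

A cationic SHG-active dye added to a vesicle suspension passes through four
populations: free in solution, adsorbed upright on the outer leaflet,
flipped/embedded within the outer leaflet, and translocated to the inner
leaflet.  Because SHG is coherent, the three surface populations contribute
to the scattered field with orientation-dependent signs: the inner-leaflet
population is anti-phased with the outer one and the two contributions
partly cancel.  The observable field therefore rises rapidly on adsorption
and then decays bi-phasically as the probe flips (fast) and translocates
(slow).

Two model layers are provided:

* a linear four-state rate-equation chain solved in closed form
  (:func:`solve_linear_chain`) plus a coherent field read-out
  (:func:`field_from_trajectory`) — the generative mechanism;
* the bi-exponential decay ``A0 + B1 exp(-(t-t0)/tau1) + B2 exp(-(t-t0)/tau2)``
  used for fitting measured traces (:func:`biexp_field`), with the slow
  constant ``tau2`` interpreted as the reciprocal transport rate and its
  temperature dependence following an Arrhenius law
  (:func:`rate_at_temperature`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "GAS_CONSTANT",
    "KineticParams",
    "StateTrajectory",
    "BiExpParams",
    "ArrheniusLaw",
    "solve_linear_chain",
    "field_from_trajectory",
    "biexp_field",
    "rate_at_temperature",
]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Relative eigenvalue gap below which the closed form switches to the
#: matrix-exponential limiting form.
_DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and coherent-field weights of the four-state chain.

    Rates are in 1/s: ``k_ads`` (solution -> upright on the outer leaflet),
    ``k_flip`` (upright -> flipped/embedded), ``k_trans`` (flipped -> inner
    leaflet) and ``k_back`` (inner -> flipped reverse step, may be zero).
    ``n_total`` is the total adsorbable probe population in arbitrary units.
    ``w_up``, ``w_flip``, ``w_in`` are the orientation weights with which the
    three surface states enter the coherent field sum; ``w_up`` is fixed at
    +1 by convention and ``w_in`` must be negative (anti-phased inner leaflet).
    """

    k_ads: float
    k_flip: float
    k_trans: float
    k_back: float = 0.0
    n_total: float = 1.0
    w_up: float = 1.0
    w_flip: float = -0.6
    w_in: float = -1.0

    def __post_init__(self) -> None:
        for name in ("k_ads", "k_flip", "k_trans", "k_back"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")
        if self.w_up != 1.0:
            raise ValueError("w_up is fixed at +1 by convention")
        if self.w_in >= 0:
            raise ValueError("w_in must be < 0 (inner leaflet is anti-phased)")
        if not -1.0 <= self.w_flip <= 1.0:
            raise ValueError("w_flip must lie in [-1, 1]")


@dataclass(frozen=True)
class StateTrajectory:
    """Populations of the four states on a common time grid."""

    time: np.ndarray
    n_solution: np.ndarray
    n_up: np.ndarray
    n_flip: np.ndarray
    n_in: np.ndarray
    n_total: float = field(default=1.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be a strictly increasing 1-d grid")
        for name in ("n_solution", "n_up", "n_flip", "n_in"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match the time grid shape")

    @property
    def total(self) -> np.ndarray:
        return self.n_solution + self.n_up + self.n_flip + self.n_in


@dataclass(frozen=True)
class BiExpParams:
    """Parameters of the bi-exponential field decay.

    ``A0`` is the long-time plateau, ``B1``/``tau1`` the fast component
    (flip-embedding), ``B2``/``tau2`` the slow component (cross-membrane
    transport), ``t0`` the decay origin (the post-addition field maximum).
    ``tau1 < tau2`` is enforced.
    """

    A0: float
    B1: float
    tau1: float
    B2: float
    tau2: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        if not self.tau1 < self.tau2:
            raise ValueError(f"tau1 ({self.tau1}) must be < tau2 ({self.tau2})")
        if self.A0 < 0:
            raise ValueError("A0 must be >= 0")


@dataclass(frozen=True)
class ArrheniusLaw:
    """Arrhenius temperature law ``ln k = lnA - Ea/(R T)``.

    ``Ea`` is in kJ/mol, ``lnA`` is the natural log of the pre-exponential
    factor (A in 1/s).  The gas constant is fixed at 8.314 J mol^-1 K^-1.
    """

    Ea: float
    lnA: float

    @classmethod
    def from_rate_at(cls, Ea: float, T_ref: float, k_ref: float) -> "ArrheniusLaw":
        """Build a law with activation energy ``Ea`` pinned to ``k(T_ref) = k_ref``."""
        if T_ref <= 0 or k_ref <= 0:
            raise ValueError("reference temperature and rate must be positive")
        lnA = float(np.log(k_ref) + Ea * 1000.0 / (GAS_CONSTANT * T_ref))
        return cls(Ea=Ea, lnA=lnA)


def rate_at_temperature(law: ArrheniusLaw, T: float | np.ndarray) -> float | np.ndarray:
    """Rate constant ``k(T) = exp(lnA - Ea*1000/(R*T))`` in 1/s, for T in kelvin."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    k = np.exp(law.lnA - law.Ea * 1000.0 / (GAS_CONSTANT * T))
    return float(k) if k.ndim == 0 else k


def _rate_matrix(p: KineticParams) -> np.ndarray:
    # state order: solution, upright, flipped, inner
    return np.array(
        [
            [-p.k_ads, 0.0, 0.0, 0.0],
            [p.k_ads, -p.k_flip, 0.0, 0.0],
            [0.0, p.k_flip, -p.k_trans, p.k_back],
            [0.0, 0.0, p.k_trans, -p.k_back],
        ]
    )


def solve_linear_chain(
    params: KineticParams,
    times: np.ndarray,
    initial: np.ndarray | None = None,
) -> StateTrajectory:
    """Closed-form solution of the four-state rate equations.

    The system ``dn/dt = M n`` is solved by eigendecomposition of the rate
    matrix ``M``:  ``n(t) = V exp(L t) V^-1 n(0)``.  When two eigenvalues
    coincide within a relative gap of 1e-12 the eigenbasis is ill-conditioned
    and the solver falls back to evaluating the matrix exponential
    ``expm(M t)`` at every grid point, which handles the degenerate limit
    exactly.

    Parameters
    ----------
    params : rate constants (weights unused here).
    times : strictly increasing time grid, seconds.
    initial : populations ``(n_solution, n_up, n_flip, n_in)`` at ``times[0]``;
        defaults to all mass in solution (``n_total, 0, 0, 0``).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing 1-d grid")
    if initial is None:
        n0 = np.array([params.n_total, 0.0, 0.0, 0.0])
    else:
        n0 = np.asarray(initial, dtype=float)
        if n0.shape != (4,):
            raise ValueError("initial must hold the four state populations")
        if np.any(n0 < 0):
            raise ValueError("initial populations must be >= 0")

    M = _rate_matrix(params)
    # measure time relative to the grid origin so initial conditions apply at t[0]
    dt = t - t[0]

    evals, V = np.linalg.eig(M)
    scale = max(np.max(np.abs(evals)), 1e-300)
    gaps = np.abs(evals[:, None] - evals[None, :])
    np.fill_diagonal(gaps, np.inf)
    degenerate = np.min(gaps) < _DEGENERACY_RTOL * scale

    if degenerate:
        states = np.empty((t.size, 4))
        for i, d in enumerate(dt):
            states[i] = expm(M * d) @ n0
    else:
        c = np.linalg.solve(V, n0.astype(complex))
        # n(t) = V @ (c * exp(lambda * t)); real by construction (real M, real n0)
        states = np.real(np.exp(np.outer(dt, evals)) * c @ V.T)

    states = np.clip(states, 0.0, None)
    total = float(np.sum(n0))
    return StateTrajectory(
        time=t,
        n_solution=states[:, 0],
        n_up=states[:, 1],
        n_flip=states[:, 2],
        n_in=states[:, 3],
        n_total=total,
    )


def field_from_trajectory(
    traj: StateTrajectory,
    weights: tuple[float, float, float] = (1.0, -0.6, -1.0),
    scale: float = 1.0,
) -> np.ndarray:
    """Coherent SHG field of a surface-state trajectory.

    ``E(t) = scale * max(0, w_up*n_up + w_flip*n_flip + w_in*n_in)``.  The
    zero clamp is the declared convention for full cancellation: the
    anti-phased inner-leaflet contribution may at most null the field, never
    drive it through zero into a rectified rebound.
    """
    w_up, w_flip, w_in = weights
    if w_up != 1.0 or w_in >= 0 or not -1.0 <= w_flip <= 1.0:
        raise ValueError("weights must satisfy w_up=+1, w_in<0, -1<=w_flip<=1")
    coherent = w_up * traj.n_up + w_flip * traj.n_flip + w_in * traj.n_in
    return scale * np.clip(coherent, 0.0, None)


def biexp_field(params: BiExpParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the bi-exponential decay model on a time grid with ``t >= t0``."""
    t = np.asarray(times, dtype=float)
    if np.any(t < params.t0):
        raise ValueError("decay model undefined before t0")
    dt = t - params.t0
    return (
        params.A0
        + params.B1 * np.exp(-dt / params.tau1)
        + params.B2 * np.exp(-dt / params.tau2)
    )
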