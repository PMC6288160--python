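"""Within-cycle dynamics of a single patch.

One patch is a well-mixed co-culture of the AmpR strain (density ``N1``,
cells/ul), the ChlR strain (``N2``), ampicillin (``A1``, ug/ml) and
chloramphenicol (``A2``, ug/ml).  Over a growth cycle of ``T_cycle`` hours

.. math::

    dN_1/dt &= \\gamma_1(A_2)\\,N_1\\,(1 - (N_1+N_2)/K) \\\\
    dN_2/dt &= \\gamma_2(A_1)\\,N_2\\,(1 - (N_1+N_2)/K) \\\\
    dA_1/dt &= -V_{max} A_1/(K_m + A_1)\\; N_1(t{=}0) \\\\
    dA_2/dt &= -c_2 A_2 N_2

with concentration-dependent growth rates that vanish during the lag
phase.  The ampicillin equation is driven by the *initial* AmpR density of
the cycle (enzyme carried over from the previous day), which is the source
of the inoculum effect that makes the daily map oscillate.

This module is the readable SciPy implementation and the carrier of the
domain types; the daily protocol loop in :mod:`crossprotect.protocol` uses
the numerically equivalent compiled kernels from
:mod:`crossprotect._kernels` (the test suite checks agreement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import ATOL, RTOL
from .params import ModelParams

__all__ = [
    "PatchState",
    "CycleTrajectory",
    "growth_rate_ampR",
    "growth_rate_chlR",
    "cycle_derivatives",
    "integrate_growth_cycle",
    "logistic_with_lag",
]


@dataclass(frozen=True)
class PatchState:
    """Instantaneous state of one patch: densities (cells/ul) and
    antibiotic concentrations (ug/ml)."""

    N1: float
    N2: float
    A1: float
    A2: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"patch state must be finite, got {arr}")
        if np.any(arr < 0):
            raise ValueError(f"patch state must be non-negative, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.N1, self.N2, self.A1, self.A2], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "PatchState":
        return cls(float(y[0]), float(y[1]), float(y[2]), float(y[3]))

    @property
    def total_density(self) -> float:
        return self.N1 + self.N2


@dataclass(frozen=True)
class CycleTrajectory:
    """Solution of one growth cycle on a time grid.

    ``states[0]`` equals the initial state and ``N1_initial`` records the
    frozen AmpR density that drives ampicillin degradation all cycle.
    """

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 4)
    N1_initial: float

    @property
    def final_state(self) -> PatchState:
        return PatchState.from_array(self.states[-1])


def _check_time(t: float, params: ModelParams) -> None:
    if not 0.0 <= t <= params.T_cycle:
        raise ValueError(
            f"time {t} h outside the growth cycle [0, {params.T_cycle}] h"
        )


def growth_rate_ampR(A2: float, t: float, params: ModelParams) -> float:
    """AmpR growth rate under chloramphenicol (1/h).

    Chloramphenicol is bacteriostatic: the rate decays hyperbolically from
    ``gamma1R`` toward zero with half-inhibition at ``I12`` but never turns
    negative.  Identically zero during the lag phase.
    """
    if A2 < 0:
        raise ValueError(f"chloramphenicol concentration must be >= 0, got {A2}")
    _check_time(t, params)
    if t < params.t_lag:
        return 0.0
    return params.gamma1R / (1.0 + A2 / params.I12)


def growth_rate_chlR(A1: float, t: float, params: ModelParams) -> float:
    """ChlR growth rate under ampicillin (1/h).

    Ampicillin is bactericidal: the rate interpolates from ``gamma2R`` at
    zero concentration down to ``-gamma2D`` at saturating concentration,
    crossing (gamma2R - gamma2D)/2 at ``I21``.  Zero during the lag phase.
    """
    if A1 < 0:
        raise ValueError(f"ampicillin concentration must be >= 0, got {A1}")
    _check_time(t, params)
    if t < params.t_lag:
        return 0.0
    return -params.gamma2D + (params.gamma2R + params.gamma2D) / (1.0 + A1 / params.I21)


def cycle_derivatives(
    state: PatchState, t: float, N1_initial: float, params: ModelParams
) -> np.ndarray:
    """Time derivatives (dN1, dN2, dA1, dA2) at time ``t`` within a cycle."""
    if N1_initial < 0:
        raise ValueError("N1_initial must be >= 0")
    y = state.as_array()
    g1 = growth_rate_ampR(state.A2, t, params)
    g2 = growth_rate_chlR(state.A1, t, params)
    cap = 1.0 - (state.N1 + state.N2) / params.K
    return np.array(
        [
            g1 * state.N1 * cap,
            g2 * state.N2 * cap,
            -params.Vmax * state.A1 / (params.Km + state.A1) * N1_initial,
            -params.c2 * state.A2 * state.N2,
        ]
    )


def integrate_growth_cycle(
    initial: PatchState,
    params: ModelParams,
    n_grid: int = 241,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> CycleTrajectory:
    """Integrate one growth cycle with a stiffness-switching solver.

    The cycle is split at ``t_lag`` so the solver never steps across the
    growth-rate discontinuity.  Components driven below zero by truncation
    error are clamped to zero in the returned trajectory.

    Raises
    ------
    RuntimeError
        If the solver reports failure; the message carries the solver
        diagnostics.
    """
    n1_init = initial.N1
    y0 = initial.as_array()
    t_lag = min(params.t_lag, params.T_cycle)
    times = np.unique(
        np.concatenate(
            [np.linspace(0.0, params.T_cycle, n_grid), [t_lag]]
        )
    )

    def rhs(t, y, growth_on):
        if growth_on:
            g1 = params.gamma1R / (1.0 + y[3] / params.I12)
            g2 = -params.gamma2D + (params.gamma2R + params.gamma2D) / (
                1.0 + y[2] / params.I21
            )
            cap = 1.0 - (y[0] + y[1]) / params.K
            dn1 = g1 * y[0] * cap
            dn2 = g2 * y[1] * cap
        else:
            dn1 = dn2 = 0.0
        return [
            dn1,
            dn2,
            -params.Vmax * y[2] / (params.Km + y[2]) * n1_init,
            -params.c2 * y[3] * y[1],
        ]

    segments = []
    if t_lag > 0:
        segments.append((0.0, t_lag, False))
    if params.T_cycle > t_lag:
        segments.append((t_lag, params.T_cycle, True))

    states = np.empty((len(times), 4))
    states[0] = y0
    y = y0
    for (t0, t1, growth_on) in segments:
        mask = (times > t0) & (times <= t1)
        t_eval = times[mask]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method="LSODA",
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol,
            atol=atol,
            args=(growth_on,),
        )
        if not sol.success:
            raise RuntimeError(
                f"growth-cycle integration failed on [{t0}, {t1}] h: "
                f"{sol.message}"
            )
        if len(t_eval):
            states[mask] = sol.y.T
            y = sol.y[:, -1]
    np.clip(states, 0.0, None, out=states)
    return CycleTrajectory(times=times, states=states, N1_initial=n1_init)


def logistic_with_lag(
    N0: float, t: float, growth_rate: float, K: float, t_lag: float
) -> float:
    """Closed-form single-strain logistic solution with a lag phase.

    ``N(t) = K N0 / (N0 + (K - N0) exp(-r (t - t_lag)))`` for ``t >= t_lag``
    and ``N0`` before; used as an analytic oracle for the integrator.
    """
    if t <= t_lag:
        return N0
    e = np.exp(-growth_rate * (t - t_lag))
    return K * N0 / (N0 + (K - N0) * e)
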