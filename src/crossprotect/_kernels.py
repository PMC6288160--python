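"""Numba-compiled inner loops for the daily growth-migration-dilution map.

The within-cycle dynamics are a four-variable ODE (two cell densities, two
antibiotic concentrations) integrated over each 24 h growth period with an
adaptive Dormand-Prince 5(4) stepper.  The cycle is split at the lag time
so the integrator never steps across the growth-rate discontinuity.  The
slow-path reference integration lives in :mod:`crossprotect.model` (SciPy);
the two are cross-checked in the test suite.

State layout everywhere: ``y = (N1, N2, A1, A2)``.
Packed parameter layout: ``(gamma1R, gamma2R, gamma2D, I12, I21, K, Vmax,
Km, c2, t_lag, T_cycle)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: default integrator tolerances; multi-decade density swings need tight
#: control for reproducible bifurcation structure.
RTOL = 1e-8
ATOL = 1e-10


def pack_params(model) -> np.ndarray:
    return np.array(
        [
            model.gamma1R,
            model.gamma2R,
            model.gamma2D,
            model.I12,
            model.I21,
            model.K,
            model.Vmax,
            model.Km,
            model.c2,
            model.t_lag,
            model.T_cycle,
        ],
        dtype=np.float64,
    )


@njit(cache=False)
def _rhs(y, p, n1_initial, growth_on):
    g1R, g2R, g2D, I12, I21, K, Vmax, Km, c2 = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8],
    )
    N1, N2, A1, A2 = y[0], y[1], y[2], y[3]
    d = np.empty(4)
    if growth_on:
        g1 = g1R / (1.0 + A2 / I12)
        g2 = -g2D + (g2R + g2D) / (1.0 + A1 / I21)
        cap = 1.0 - (N1 + N2) / K
        d[0] = g1 * N1 * cap
        d[1] = g2 * N2 * cap
    else:
        d[0] = 0.0
        d[1] = 0.0
    d[2] = -Vmax * A1 / (Km + A1) * n1_initial
    d[3] = -c2 * A2 * N2
    return d


@njit(cache=False)
def _dp45_segment(y, p, t0, t1, n1_initial, growth_on, rtol, atol):
    """Adaptive Dormand-Prince 5(4) from t0 to t1; returns the end state."""
    t = t0
    h = min(0.01, t1 - t0)
    k1 = _rhs(y, p, n1_initial, growth_on)
    while t < t1:
        if h > t1 - t:
            h = t1 - t
        k2 = _rhs(y + h * (k1 / 5.0), p, n1_initial, growth_on)
        k3 = _rhs(y + h * (3.0 * k1 / 40.0 + 9.0 * k2 / 40.0), p, n1_initial, growth_on)
        k4 = _rhs(
            y + h * (44.0 * k1 / 45.0 - 56.0 * k2 / 15.0 + 32.0 * k3 / 9.0),
            p, n1_initial, growth_on,
        )
        k5 = _rhs(
            y + h * (
                19372.0 * k1 / 6561.0
                - 25360.0 * k2 / 2187.0
                + 64448.0 * k3 / 6561.0
                - 212.0 * k4 / 729.0
            ),
            p, n1_initial, growth_on,
        )
        k6 = _rhs(
            y + h * (
                9017.0 * k1 / 3168.0
                - 355.0 * k2 / 33.0
                + 46732.0 * k3 / 5247.0
                + 49.0 * k4 / 176.0
                - 5103.0 * k5 / 18656.0
            ),
            p, n1_initial, growth_on,
        )
        ynew = y + h * (
            35.0 * k1 / 384.0
            + 500.0 * k3 / 1113.0
            + 125.0 * k4 / 192.0
            - 2187.0 * k5 / 6784.0
            + 11.0 * k6 / 84.0
        )
        k7 = _rhs(ynew, p, n1_initial, growth_on)
        # embedded 4th-order error estimate
        e0 = h * (
            (35.0 / 384.0 - 5179.0 / 57600.0) * k1[0]
            + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3[0]
            + (125.0 / 192.0 - 393.0 / 640.0) * k4[0]
            + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5[0]
            + (11.0 / 84.0 - 187.0 / 2100.0) * k6[0]
            - k7[0] / 40.0
        )
        e1 = h * (
            (35.0 / 384.0 - 5179.0 / 57600.0) * k1[1]
            + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3[1]
            + (125.0 / 192.0 - 393.0 / 640.0) * k4[1]
            + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5[1]
            + (11.0 / 84.0 - 187.0 / 2100.0) * k6[1]
            - k7[1] / 40.0
        )
        e2 = h * (
            (35.0 / 384.0 - 5179.0 / 57600.0) * k1[2]
            + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3[2]
            + (125.0 / 192.0 - 393.0 / 640.0) * k4[2]
            + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5[2]
            + (11.0 / 84.0 - 187.0 / 2100.0) * k6[2]
            - k7[2] / 40.0
        )
        e3 = h * (
            (35.0 / 384.0 - 5179.0 / 57600.0) * k1[3]
            + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3[3]
            + (125.0 / 192.0 - 393.0 / 640.0) * k4[3]
            + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5[3]
            + (11.0 / 84.0 - 187.0 / 2100.0) * k6[3]
            - k7[3] / 40.0
        )
        err = 0.0
        sc = atol + rtol * max(abs(y[0]), abs(ynew[0]))
        err += (e0 / sc) ** 2
        sc = atol + rtol * max(abs(y[1]), abs(ynew[1]))
        err += (e1 / sc) ** 2
        sc = atol + rtol * max(abs(y[2]), abs(ynew[2]))
        err += (e2 / sc) ** 2
        sc = atol + rtol * max(abs(y[3]), abs(ynew[3]))
        err += (e3 / sc) ** 2
        err = np.sqrt(err / 4.0)
        if err <= 1.0:
            t += h
            y = ynew
            k1 = k7
        if err > 1e-10:
            fac = 0.9 * err ** -0.2
        else:
            fac = 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
    return y


@njit(cache=False)
def integrate_cycle(y0, p, rtol, atol):
    """One full growth cycle; returns the end-of-cycle state.

    The ampicillin-degradation driver is frozen at the initial AmpR
    density.  Any component driven below zero by integration error is
    clamped to zero at cycle end.
    """
    n1_initial = y0[0]
    t_lag = p[9]
    T = p[10]
    y = y0.copy()
    if t_lag > 0.0:
        y = _dp45_segment(y, p, 0.0, min(t_lag, T), n1_initial, False, rtol, atol)
    if T > t_lag:
        y = _dp45_segment(y, p, t_lag, T, n1_initial, True, rtol, atol)
    for i in range(4):
        if y[i] < 0.0:
            y[i] = 0.0
    return y


@njit(cache=False)
def run_pair_kernel(
    yA0, yB0, p, m, D, A1_fresh, A2_fresh, carryover, threshold,
    n_days, noise, rtol, atol,
):
    """Daily grow -> record -> migrate -> dilute loop for two patches.

    ``noise`` has shape (n_days, 4) holding the multiplicative factors
    (f_AB, f_BA, f_A, f_B): the first two perturb the transferred fraction
    of the A->B and B->A migration events, the last two the dilution factor
    of each patch.  All ones gives the deterministic protocol.

    Returns (ends, starts, extinction_day) where ``ends[d]`` /
    ``starts[d]`` are the concatenated (A, B) states at the end of growth /
    start of day ``d+1``, and extinction_day is 0 if the pair is still
    alive after n_days, else the 1-based day on which every subpopulation
    fell below the extinction threshold.
    """
    ends = np.zeros((n_days, 8))
    starts = np.zeros((n_days, 8))
    sA = yA0.copy()
    sB = yB0.copy()
    ext_day = 0
    for d in range(n_days):
        starts[d, :4] = sA
        starts[d, 4:] = sB
        eA = integrate_cycle(sA, p, rtol, atol)
        eB = integrate_cycle(sB, p, rtol, atol)
        ends[d, :4] = eA
        ends[d, 4:] = eB
        # migration: fraction m of each whole culture (cells and medium)
        # swaps into the partner, both transfers computed from
        # pre-migration states so pairwise totals are conserved.
        fAB = min(m * noise[d, 0], 1.0)
        fBA = min(m * noise[d, 1], 1.0)
        mA = np.empty(4)
        mB = np.empty(4)
        for i in range(4):
            mA[i] = eA[i] - fAB * eA[i] + fBA * eB[i]
            mB[i] = eB[i] - fBA * eB[i] + fAB * eA[i]
        # dilution into fresh medium + antibiotics
        dA = D * noise[d, 2]
        dB = D * noise[d, 3]
        for i in range(4):
            sA[i] = mA[i] / dA
            sB[i] = mB[i] / dB
        for i in range(2):
            if sA[i] < threshold:
                sA[i] = 0.0
            if sB[i] < threshold:
                sB[i] = 0.0
        if carryover:
            sA[2] += A1_fresh
            sA[3] += A2_fresh
            sB[2] += A1_fresh
            sB[3] += A2_fresh
        else:
            sA[2] = A1_fresh
            sA[3] = A2_fresh
            sB[2] = A1_fresh
            sB[3] = A2_fresh
        if sA[0] + sA[1] + sB[0] + sB[1] == 0.0:
            ext_day = d + 1
            break
    return ends, starts, ext_day
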