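"""Monte-Carlo survival analysis in harsh conditions.

In the harsh environment (10 ug/ml ampicillin, 16 ug/ml chloramphenicol)
an isolated pair of patches goes extinct deterministically; protocol
noise and migration can stretch survival.  The ensemble machinery here
draws initial condition pairs distributed around the three phases of the
benign period-3 oscillation (the two patches always start in *different*
phases), simulates the noisy protocol to a horizon, and summarizes the
survival-time distribution P(tau) and the survival probability at a
threshold day with its standard error of proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import PatchState
from .params import ModelParams, ProtocolParams, benign_protocol
from .protocol import PairSeries, run_pair_simulation

__all__ = [
    "SurvivalEnsembleResult",
    "benign_phase_states",
    "sample_initial_condition_pairs",
    "survival_time",
    "survival_curve",
    "scan_survival_vs_m",
    "fit_exponential_tail",
]


@dataclass
class SurvivalEnsembleResult:
    """Survival summary of one ensemble at a fixed migration rate."""

    m: float
    n_runs: int
    survival_times: np.ndarray
    horizon: int
    threshold: int
    #: P(tau) for tau = 0 .. horizon (fraction of runs surviving >= tau)
    survival_curve: np.ndarray
    p_survive_at_threshold: float
    standard_error: float
    seeds: Optional[np.ndarray] = None

    def to_long_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                m=self.m,
                tau=np.arange(self.horizon + 1),
                P=self.survival_curve,
            )
        )


def benign_phase_states(
    model: ModelParams,
    protocol: Optional[ProtocolParams] = None,
    n_days: int = 400,
    initial_total: float = 1000.0,
    initial_fraction: float = 0.5,
) -> list[PatchState]:
    """The three phase states of the benign period-3 oscillation.

    Converges a single isolated patch under the (deterministic, benign)
    protocol and returns the start-of-day states of the last three cycles:
    post-dilution densities with fresh antibiotics, i.e. valid initial
    conditions for subsequent runs.  Raises if the benign run has not
    settled into a period-3 cycle.
    """
    from .dynamics import detect_period  # local import to avoid cycle

    proto = (protocol or benign_protocol()).replace(m=0.0, noise_cv=0.0)
    n1 = initial_total * initial_fraction
    init = PatchState(n1, initial_total - n1, proto.A1_fresh, proto.A2_fresh)
    series = run_pair_simulation(init, init, model, proto, n_days)
    if series.extinction_day is not None:
        raise RuntimeError(
            "benign reference run went extinct; cannot extract phase states"
        )
    x = series.log_ratio("A")
    period = detect_period(x)
    if period != 3:
        raise RuntimeError(
            f"benign reference run is not period-3 (detected {period}); "
            "check the model parameters before sampling survival ensembles"
        )
    starts = series.start_states
    # start_states[d] begins day d+1; the states beginning the last three
    # days are the three oscillation phases.
    phases = []
    for d in range(n_days - 3, n_days):
        phases.append(PatchState.from_array(starts[d, :4]))
    return phases


def sample_initial_condition_pairs(
    attractor_states: Sequence[PatchState],
    n: int,
    jitter_cv: float = 0.1,
    rng_seed: Optional[int] = None,
    A1_fresh: float = 10.0,
    A2_fresh: float = 16.0,
) -> list[tuple[PatchState, PatchState]]:
    """Draw ``n`` initial pairs around the three oscillation phases.

    Each pair assigns the two patches *different* phase indices, uniformly
    over the six ordered unequal pairs (for ``jitter_cv == 0`` and
    ``n == 6`` each ordered pair appears exactly once).  Densities get
    multiplicative lognormal jitter with CV ``jitter_cv``; antibiotics are
    set to the fresh harsh concentrations.
    """
    if len(attractor_states) != 3:
        raise ValueError(
            "need exactly 3 attractor phase states; run the benign "
            "converger (benign_phase_states) first"
        )
    if n == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    ordered = [(i, j) for i in range(3) for j in range(3) if i != j]
    sigma = np.sqrt(np.log1p(jitter_cv ** 2)) if jitter_cv > 0 else 0.0
    pairs = []
    for k in range(n):
        iA, iB = ordered[k % 6]
        out = []
        for idx in (iA, iB):
            s = attractor_states[idx]
            if sigma > 0:
                f1, f2 = rng.lognormal(-0.5 * sigma ** 2, sigma, size=2)
            else:
                f1 = f2 = 1.0
            out.append(PatchState(s.N1 * f1, s.N2 * f2, A1_fresh, A2_fresh))
        pairs.append((out[0], out[1]))
    return pairs


def survival_time(series: PairSeries, horizon: int) -> int:
    """Survival time tau: the last day the system was alive.

    ``extinction_day - 1`` when the pair went globally extinct, else the
    horizon (right-censored).
    """
    if series.extinction_day is not None:
        return series.extinction_day - 1
    return horizon


def survival_curve(
    survival_times: Sequence[int],
    horizon: int,
    threshold: int,
    m: float = float("nan"),
    seeds: Optional[np.ndarray] = None,
) -> SurvivalEnsembleResult:
    """Empirical survival curve P(tau) and threshold-day probability.

    ``P(tau)`` is the fraction of runs with survival time >= tau, so
    ``P(0) = 1`` and P is non-increasing; the standard error of the
    threshold probability is ``sqrt(p (1-p) / n)``.
    """
    taus = np.asarray(survival_times, dtype=int)
    if len(taus) == 0:
        raise ValueError("empty ensemble")
    if np.any(taus > horizon):
        raise ValueError("survival times exceed the stated horizon")
    grid = np.arange(horizon + 1)
    curve = np.array([(taus >= t).mean() for t in grid])
    p = float(curve[threshold])
    se = float(np.sqrt(p * (1.0 - p) / len(taus)))
    return SurvivalEnsembleResult(
        m=m,
        n_runs=len(taus),
        survival_times=taus,
        horizon=horizon,
        threshold=threshold,
        survival_curve=curve,
        p_survive_at_threshold=p,
        standard_error=se,
        seeds=seeds,
    )


def scan_survival_vs_m(
    m_grid: Sequence[float],
    model: ModelParams,
    protocol_template: ProtocolParams,
    attractor_states: Sequence[PatchState],
    n_runs: int = 300,
    horizon: int = 10,
    threshold: int = 10,
    jitter_cv: float = 0.1,
    rng_seed: int = 0,
) -> list[SurvivalEnsembleResult]:
    """Noisy survival ensembles across migration rates.

    Per ``m``: draws ``n_runs`` fresh initial pairs around the benign
    phases, runs the noisy harsh protocol to the horizon and records the
    survival summary.  Child seeds are spawned deterministically from
    ``rng_seed`` so any individual run can be reproduced.
    """
    results = []
    mg = np.asarray(m_grid, dtype=float)
    root = np.random.SeedSequence(rng_seed)
    for m, child in zip(mg, root.spawn(len(mg))):
        proto = protocol_template.replace(m=float(m))
        pair_seed, noise_seed = child.spawn(2)
        pairs = sample_initial_condition_pairs(
            attractor_states,
            n_runs,
            jitter_cv=jitter_cv,
            rng_seed=pair_seed.generate_state(1)[0] % (2 ** 31),
            A1_fresh=proto.A1_fresh,
            A2_fresh=proto.A2_fresh,
        )
        run_seeds = noise_seed.generate_state(n_runs) % (2 ** 31)
        taus = np.empty(n_runs, dtype=int)
        for i, ((a, b), s) in enumerate(zip(pairs, run_seeds)):
            series = run_pair_simulation(
                a, b, model, proto, n_days=horizon, rng_seed=int(s)
            )
            taus[i] = survival_time(series, horizon)
        results.append(
            survival_curve(
                taus, horizon, min(threshold, horizon), m=float(m),
                seeds=run_seeds,
            )
        )
    return results


def fit_exponential_tail(
    curve: Sequence[float],
    fit_range: tuple[int, int],
) -> float:
    """Decay timescale (days) of an exponentially decaying survival curve.

    Least-squares slope of log P(tau) over ``fit_range`` (inclusive);
    returns ``inf`` for a flat curve.  Zero values truncate the range with
    a warning.
    """
    P = np.asarray(curve, dtype=float)
    lo, hi = fit_range
    taus = np.arange(lo, hi + 1)
    if hi >= len(P):
        raise ValueError("fit range exceeds curve length")
    vals = P[taus]
    if np.any(vals <= 0):
        keep = vals > 0
        if keep.sum() < 2:
            raise ValueError("fewer than two positive values in fit range")
        warnings.warn("zero survival values truncate the exponential fit range")
        taus, vals = taus[keep], vals[keep]
    slope = np.polyfit(taus, np.log(vals), 1)[0]
    if slope >= 0:
        return float("inf")
    return float(-1.0 / slope)
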