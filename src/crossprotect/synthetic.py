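"""Synthetic fixtures and measurement emulation.

Two jobs: (1) generate daily log-ratio series with known period,
amplitude and noise so every analyzer can be tested without running the
ODE pipeline; (2) emulate the daily measurements of the experimental
protocol — an optical-density proxy for total density and a
flow-cytometry-style count model for the strain fraction — so analysis
code can be exercised on data with realistic measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .protocol import PairSeries

__all__ = [
    "MeasurementRecord",
    "generate_periodic_fixture",
    "emulate_measurements",
]

#: OD-to-density calibration constant (arbitrary units per cells/ul);
#: measurements divide out to a proxy so only relative noise matters.
OD_CALIBRATION = 1e-5


@dataclass(frozen=True)
class MeasurementRecord:
    """One day of emulated measurements for one patch."""

    day: int
    od600_proxy: float
    fraction_ampR: float  # NaN on extinct days
    counts_total: int


def generate_periodic_fixture(
    period: int,
    n_days: int,
    amplitude_decades: float = 4.0,
    noise_sd: float = 0.0,
    rng_seed: Optional[int] = None,
) -> np.ndarray:
    """Daily log10-ratio series repeating ``period`` distinct levels.

    The noiseless levels are evenly spaced over ``amplitude_decades``
    (a single level for period 1), mimicking ratio oscillations spanning
    several orders of magnitude; additive Gaussian noise of standard
    deviation ``noise_sd`` (log10 units) is applied on top.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    if period > n_days:
        raise ValueError(f"period {period} exceeds series length {n_days}")
    if amplitude_decades <= 0:
        raise ValueError("amplitude_decades must be > 0")
    if period == 1:
        levels = np.array([0.0])
    else:
        levels = np.linspace(
            -amplitude_decades / 2.0, amplitude_decades / 2.0, period
        )
        # visit order mixes high and low days so the cycle is not a ramp
        order = np.argsort(np.tile([0, 2, 1], period)[:period], kind="stable")
        levels = levels[order]
    series = np.tile(levels, n_days // period + 1)[:n_days].astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        series = series + rng.normal(0.0, noise_sd, size=n_days)
    return series


def emulate_measurements(
    series: PairSeries,
    od_noise_cv: float = 0.02,
    counts_total: int = 10_000,
    rng_seed: Optional[int] = None,
    patch: str = "A",
) -> list[MeasurementRecord]:
    """Emulate daily OD and cytometry measurements of one patch.

    The OD proxy is the total density times a calibration constant with
    multiplicative lognormal noise (CV ``od_noise_cv``); the AmpR fraction
    is drawn from a binomial count model with ``counts_total`` events and
    success probability N1/(N1+N2).  Extinct days give a zero OD baseline
    and an undefined (NaN) fraction.
    """
    if series.n_days == 0:
        raise ValueError("empty series")
    rng = np.random.default_rng(rng_seed)
    sigma = np.sqrt(np.log1p(od_noise_cv ** 2)) if od_noise_cv > 0 else 0.0
    out = []
    for rec in series.records:
        s = rec.end_state_A if patch == "A" else rec.end_state_B
        total = s.total_density
        if total <= 0:
            out.append(
                MeasurementRecord(rec.day, 0.0, float("nan"), counts_total)
            )
            continue
        od = total * OD_CALIBRATION
        if sigma > 0:
            od *= rng.lognormal(-0.5 * sigma ** 2, sigma)
        frac_true = s.N1 / total
        counts = rng.binomial(counts_total, frac_true)
        out.append(
            MeasurementRecord(rec.day, od, counts / counts_total, counts_total)
        )
    return out
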