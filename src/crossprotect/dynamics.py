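"""Dynamical characterization of end-of-cycle ratio series.

The serial-dilution protocol turns the continuous within-day dynamics into
a discrete daily map, so oscillations are characterized by their integer
period: the number of dilution cycles after which the end-of-cycle state
repeats.  All analysis operates on ``log10(N1/N2)`` because the strain
ratio swings over several orders of magnitude, making an additive
tolerance in log space the natural metric.  Default tolerance: 0.1
decades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PatchState
from .params import ModelParams, ProtocolParams
from .protocol import run_pair_simulation

__all__ = [
    "IRREGULAR",
    "BifurcationResult",
    "asymptotic_value_set",
    "detect_period",
    "find_peaks_daily",
    "classify_synchronization",
    "detect_antisynchrony",
    "bifurcation_scan",
]

#: sentinel period for series that repeat at no period up to n_last // 2
IRREGULAR = 0

DEFAULT_TOL = 0.1  # log10 units
DEFAULT_N_LAST = 50


def _trailing_finite(series: Sequence[float], n_last: int) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if len(x) < n_last:
        raise ValueError(f"series length {len(x)} < n_last {n_last}")
    tail = x[-n_last:]
    if not np.all(np.isfinite(tail)):
        warnings.warn(
            "non-finite ratio values (extinct denominator) excluded from "
            "the analysis window",
            stacklevel=3,
        )
        tail = tail[np.isfinite(tail)]
    return tail


def asymptotic_value_set(
    series: Sequence[float],
    n_last: int = DEFAULT_N_LAST,
    tol: float = DEFAULT_TOL,
) -> np.ndarray:
    """Cluster the last ``n_last`` values into the set of values the
    series visits asymptotically.

    Single-linkage in one dimension: after sorting, a gap larger than
    ``tol`` starts a new cluster, so two values share a cluster iff they
    are connected by steps of at most ``tol``.  Returns the sorted cluster
    means.
    """
    tail = np.sort(_trailing_finite(series, n_last))
    if len(tail) == 0:
        return np.array([])
    breaks = np.where(np.diff(tail) > tol)[0]
    clusters = np.split(tail, breaks + 1)
    return np.array([c.mean() for c in clusters])


def detect_period(
    series: Sequence[float],
    n_last: int = DEFAULT_N_LAST,
    tol: float = DEFAULT_TOL,
) -> int:
    """Smallest period ``p`` with ``|x[t] - x[t-p]| <= tol`` throughout the
    trailing window, or :data:`IRREGULAR` (0) if none exists with
    ``p <= n_last // 2``.

    A constant series has period 1.  Windows containing non-finite values
    (extinct denominator) are irregular by definition.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < n_last:
        raise ValueError(f"series length {len(x)} < n_last {n_last}")
    tail = x[-n_last:]
    if not np.all(np.isfinite(tail)):
        return IRREGULAR
    for p in range(1, n_last // 2 + 1):
        if np.max(np.abs(tail[p:] - tail[:-p])) <= tol:
            return p
    return IRREGULAR


def find_peaks_daily(series: Sequence[float], window: int = 3) -> np.ndarray:
    """Indices of local maxima of a daily series.

    A peak is the maximum of a centered ``window``-day neighbourhood;
    plateau ties break toward the earliest day.  Endpoints cannot be
    peaks.
    """
    x = np.asarray(series, dtype=float)
    half = window // 2
    peaks = []
    for i in range(half, len(x) - half):
        seg = x[i - half : i + half + 1]
        if not np.all(np.isfinite(seg)):
            continue
        # maximum of its neighbourhood with a strict rise from the left:
        # later points of a plateau fail the strict test, so ties break
        # toward the earliest day.
        if x[i] == np.max(seg) and x[i] > x[i - 1]:
            peaks.append(i)
    return np.array(peaks, dtype=int)


def classify_synchronization(
    seriesA: Sequence[float],
    seriesB: Sequence[float],
    window_fraction: float = 0.4,
    cycles_required: int = 2,
) -> str:
    """Label two ratio series ``"synchronized"``, ``"asynchronous"`` or
    ``"undetermined"``.

    Following the experimental criterion, the two patches are synchronized
    when the peaks of their oscillations fall on the same days throughout
    the trailing ``window_fraction`` of the series, with at least
    ``cycles_required`` oscillation cycles available in that window.
    """
    a = np.asarray(seriesA, dtype=float)
    b = np.asarray(seriesB, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    start = int(np.floor(len(a) * (1.0 - window_fraction)))
    pa = find_peaks_daily(a[start:])
    pb = find_peaks_daily(b[start:])
    if len(pa) < cycles_required or len(pb) < cycles_required:
        return "undetermined"
    if set(pa) == set(pb):
        return "synchronized"
    return "asynchronous"


def detect_antisynchrony(
    seriesA: Sequence[float],
    seriesB: Sequence[float],
    n_last: int = DEFAULT_N_LAST,
    tol: float = DEFAULT_TOL,
) -> bool:
    """True iff both series oscillate with period 2 in the trailing window
    and their peaks interleave (A high on B's low days)."""
    pA = detect_period(seriesA, n_last=n_last, tol=tol)
    pB = detect_period(seriesB, n_last=n_last, tol=tol)
    if pA != 2 or pB != 2:
        return False
    a = np.asarray(seriesA, dtype=float)[-n_last:]
    b = np.asarray(seriesB, dtype=float)[-n_last:]
    # phase of the 2-cycle: does the even-index subsequence sit above the
    # odd one?  Antisynchronous iff the two series disagree.
    phaseA = a[0::2].mean() > a[1::2].mean()
    phaseB = b[0::2].mean() > b[1::2].mean()
    return phaseA != phaseB


@dataclass
class BifurcationResult:
    """Asymptotic ratio values, periods and synchronization labels on a
    migration-rate grid (patch A by convention)."""

    m_grid: np.ndarray
    value_sets: list[np.ndarray]
    periods: list[int]
    sync_labels: list[str]
    extinct: list[bool] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame with one row per (m, asymptotic value), ready for
        scatter plotting."""
        rows = []
        for m, values, period, label, ext in zip(
            self.m_grid, self.value_sets, self.periods, self.sync_labels,
            self.extinct if self.extinct else [False] * len(self.m_grid),
        ):
            if ext or len(values) == 0:
                rows.append(
                    dict(m=m, value=np.nan, period=period, sync_label=label)
                )
                continue
            for v in values:
                rows.append(dict(m=m, value=v, period=period, sync_label=label))
        return pd.DataFrame(rows)


def bifurcation_scan(
    m_grid: Sequence[float],
    model: ModelParams,
    protocol_template: ProtocolParams,
    initialA: PatchState,
    initialB: PatchState,
    n_days: int = 1000,
    n_last: int = DEFAULT_N_LAST,
    tol: float = DEFAULT_TOL,
) -> BifurcationResult:
    """Deterministic bifurcation scan over migration rates.

    For each ``m``, runs the pair for ``n_days`` dilution cycles from the
    given out-of-phase initial states and records the asymptotic value set
    of patch A's log ratio, the detected period and the synchronization
    label.  Requires a noise-free protocol template; per-``m`` extinctions
    are flagged and the scan continues.
    """
    if protocol_template.noise_cv != 0:
        raise ValueError("bifurcation_scan requires a deterministic protocol")
    if n_days < 2 * n_last:
        raise ValueError("n_days must be at least 2 * n_last")
    m_grid = np.asarray(m_grid, dtype=float)
    if np.any(np.diff(m_grid) <= 0):
        raise ValueError("m_grid must be strictly increasing")
    values, periods, labels, extinct = [], [], [], []
    for m in m_grid:
        proto = protocol_template.replace(m=float(m))
        series = run_pair_simulation(
            initialA, initialB, model, proto, n_days=n_days
        )
        if series.extinction_day is not None or series.n_days < n_days:
            values.append(np.array([]))
            periods.append(IRREGULAR)
            labels.append("extinct")
            extinct.append(True)
            continue
        xA = series.log_ratio("A")
        xB = series.log_ratio("B")
        if not np.all(np.isfinite(xA[-n_last:])):
            values.append(np.array([]))
            periods.append(IRREGULAR)
            labels.append("extinct")
            extinct.append(True)
            continue
        values.append(asymptotic_value_set(xA, n_last=n_last, tol=tol))
        periods.append(detect_period(xA, n_last=n_last, tol=tol))
        labels.append(classify_synchronization(xA, xB))
        extinct.append(False)
    return BifurcationResult(
        m_grid=m_grid,
        value_sets=values,
        periods=periods,
        sync_labels=labels,
        extinct=extinct,
    )
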