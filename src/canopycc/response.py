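"""Treatment response ratios, coefficients of variation, growth-stage means.

The response ratio RR = ln(B_s / B_ns) compares an index under a reduced-
irrigation condition (B_s) against the fully irrigated control (B_ns); RR > 0
means an increase under the comparison condition.  The growing season splits
into three stages: early (Apr 1 - May 31), middle (Jun 1 - Jul 31), late
(Aug 1 - Sep 30).
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .indices import ColorTimeSeries

logger = logging.getLogger(__name__)

OUT_OF_SEASON = "out_of_season"


@dataclass(frozen=True)
class GrowthStage:
    """A stage of the growing season bounded by inclusive month-day limits."""

    id: str
    start: tuple[int, int]
    end: tuple[int, int]

    def contains(self, date: _dt.date) -> bool:
        return self.start <= (date.month, date.day) <= self.end


DEFAULT_STAGES: tuple[GrowthStage, ...] = (
    GrowthStage("early", (4, 1), (5, 31)),
    GrowthStage("middle", (6, 1), (7, 31)),
    GrowthStage("late", (8, 1), (9, 30)),
)


@dataclass
class ResponseRatioSeries:
    """Ordered (doy, rr) pairs for one treatment-vs-control comparison."""

    key: tuple
    index_name: str
    doy: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.doy.shape != self.rr.shape:
            raise ValueError("doy and rr must align")

    def __len__(self) -> int:
        return len(self.doy)


def response_ratio(b_s: float, b_ns: float) -> float:
    """Natural log of the treatment/control index ratio."""
    if b_s <= 0 or b_ns <= 0:
        raise ValueError(f"response ratio needs positive inputs, got ({b_s}, {b_ns})")
    return math.log(b_s / b_ns)


def response_ratio_series(
    treatment_ts: ColorTimeSeries, control_ts: ColorTimeSeries
) -> ResponseRatioSeries:
    """Pointwise RR at exactly matching DOY values; unmatched dates dropped."""
    if treatment_ts.index_name != control_ts.index_name:
        raise ValueError(
            f"index mismatch: {treatment_ts.index_name!r} vs {control_ts.index_name!r}"
        )
    common, ti, ci = np.intersect1d(treatment_ts.doy, control_ts.doy, return_indices=True)
    if common.size == 0:
        raise ValueError("treatment and control series share no dates")
    dropped = (len(treatment_ts) - common.size) + (len(control_ts) - common.size)
    if dropped:
        logger.info("response_ratio_series: dropped %d unmatched dates", dropped)
    rr = np.array(
        [
            response_ratio(tv, cv)
            for tv, cv in zip(treatment_ts.values[ti], control_ts.values[ci])
        ]
    )
    return ResponseRatioSeries(
        key=treatment_ts.key, index_name=treatment_ts.index_name, doy=common, rr=rr
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation over the mean, in percent."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def assign_stage(
    date: _dt.date, stages: Sequence[GrowthStage] = DEFAULT_STAGES
) -> str:
    """Stage id containing ``date``, or ``"out_of_season"``."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    for stage in stages:
        if stage.contains(date):
            return stage.id
    return OUT_OF_SEASON


def _doy_stage(doy: int, year: int, stages: Sequence[GrowthStage]) -> str:
    date = _dt.date(year, 1, 1) + _dt.timedelta(days=int(doy) - 1)
    return assign_stage(date, stages)


def stage_mean(
    series: ColorTimeSeries | ResponseRatioSeries,
    stages: Sequence[GrowthStage] = DEFAULT_STAGES,
    *,
    year: int | None = None,
) -> dict[str, float]:
    """Unweighted mean of series values per growth stage.

    Stages with no data map to NaN.  DOY-to-date conversion needs the
    calendar year; when not given it is taken from the series key if a
    4-digit year element is present, else a non-leap year is assumed.
    """
    values = series.rr if isinstance(series, ResponseRatioSeries) else series.values
    if len(values) == 0:
        raise ValueError("empty series")
    if year is None:
        year = next(
            (k for k in series.key if isinstance(k, (int, np.integer)) and 1900 < k < 2200),
            2022,
        )
    labels = np.array([_doy_stage(d, int(year), stages) for d in series.doy])
    out: dict[str, float] = {}
    for stage in stages:
        sel = labels == stage.id
        out[stage.id] = float(np.mean(values[sel])) if sel.any() else float("nan")
    return out
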