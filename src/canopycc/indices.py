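"""Chromatic coordinates over vegetation masks and plot-level time series.

The per-image index is the chromatic coordinate of the *masked mean* digital
numbers (ratio of means): G_CC = G_DN / (R_DN + G_DN + B_DN), likewise R_CC
and B_CC, and Y_CC = (G_CC + R_CC) / 2.  A mean-of-per-pixel-ratios variant
is available for sensitivity checks; the two agree exactly on uniform
regions.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import HSVThresholds, VegetationMask, segment_vegetation, vegetation_fraction

INDEX_NAMES = ("g_cc", "r_cc", "b_cc", "y_cc")


class EmptyMaskError(ValueError):
    """Raised when an operation requires at least one vegetation pixel."""


@dataclass(frozen=True)
class DNTriplet:
    """Mean digital numbers over a mask, one value per channel in [0, 255]."""

    r_dn: float
    g_dn: float
    b_dn: float

    def __post_init__(self) -> None:
        for name, v in (("r_dn", self.r_dn), ("g_dn", self.g_dn), ("b_dn", self.b_dn)):
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")


@dataclass(frozen=True)
class ChromaticCoordinates:
    """Normalized color fractions; g_cc + r_cc + b_cc = 1, y_cc = (g+r)/2."""

    g_cc: float
    r_cc: float
    b_cc: float
    y_cc: float

    def __post_init__(self) -> None:
        if abs(self.g_cc + self.r_cc + self.b_cc - 1.0) > 1e-9:
            raise ValueError("chromatic coordinates must sum to 1")
        if abs(self.y_cc - (self.g_cc + self.r_cc) / 2.0) > 1e-12:
            raise ValueError("y_cc must equal (g_cc + r_cc)/2")

    def __getitem__(self, name: str) -> float:
        if name not in INDEX_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class ObservationRecord:
    """One plot x date measurement joining color indices and covariates."""

    plot_id: str
    species: str
    treatment: str
    replicate: int
    date: _dt.date
    cc: ChromaticCoordinates
    vegetation_fraction: float
    period: str | None = None
    swc_percent: float | None = None
    spad: float | None = None
    sla: float | None = None

    @property
    def doy(self) -> int:
        return self.date.timetuple().tm_yday


@dataclass
class ColorTimeSeries:
    """Ordered (doy, value) pairs of one index for one grouping key."""

    key: tuple
    index_name: str
    doy: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.doy.shape != self.values.shape:
            raise ValueError("doy and values must align")
        if np.any(np.diff(self.doy) <= 0):
            raise ValueError("doy must be strictly increasing")

    def __len__(self) -> int:
        return len(self.doy)


def masked_mean_dn(image: np.ndarray, mask: VegetationMask) -> DNTriplet:
    """Arithmetic mean of each channel over the masked pixels."""
    if mask.n_vegetation == 0:
        raise EmptyMaskError("no vegetation pixels under the mask")
    pixels = np.asarray(image, dtype=float)[mask.grid]
    r, g, b = pixels.mean(axis=0)
    return DNTriplet(r_dn=float(r), g_dn=float(g), b_dn=float(b))


def chromatic_coordinates(dn: DNTriplet) -> ChromaticCoordinates:
    """Normalize mean DNs to chromatic coordinates."""
    total = dn.r_dn + dn.g_dn + dn.b_dn
    if total <= 0:
        raise ValueError("cannot normalize: R+G+B is zero")
    g = dn.g_dn / total
    r = dn.r_dn / total
    b = dn.b_dn / total
    return ChromaticCoordinates(g_cc=g, r_cc=r, b_cc=b, y_cc=(g + r) / 2.0)


def _mean_of_ratios(image: np.ndarray, mask: VegetationMask) -> ChromaticCoordinates:
    pixels = np.asarray(image, dtype=float)[mask.grid]
    totals = pixels.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("cannot normalize: some masked pixels have R+G+B = 0")
    cc = pixels / totals[:, None]
    r, g, b = cc.mean(axis=0)
    # renormalize away accumulated rounding so the sum-to-1 invariant is exact
    s = r + g + b
    r, g, b = r / s, g / s, b / s
    return ChromaticCoordinates(g_cc=g, r_cc=r, b_cc=b, y_cc=(g + r) / 2.0)


def extract_index_record(
    image: np.ndarray,
    thr: HSVThresholds,
    metadata: Mapping,
    *,
    aggregation: Literal["ratio_of_means", "mean_of_ratios"] = "ratio_of_means",
    min_vegetation_fraction: float = 0.0,
) -> ObservationRecord:
    """Segment, average DNs over the mask, and normalize — in that order."""
    mask = segment_vegetation(image, thr)
    frac = vegetation_fraction(mask)
    context = f"plot={metadata.get('plot_id')!r} date={metadata.get('date')!r}"
    if mask.n_vegetation == 0:
        raise EmptyMaskError(f"no vegetation pixels ({context})")
    if frac < min_vegetation_fraction:
        import warnings

        warnings.warn(
            f"vegetation fraction {frac:.3f} below {min_vegetation_fraction} ({context})",
            stacklevel=2,
        )
    if aggregation == "ratio_of_means":
        cc = chromatic_coordinates(masked_mean_dn(image, mask))
    elif aggregation == "mean_of_ratios":
        cc = _mean_of_ratios(image, mask)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    date = metadata["date"]
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return ObservationRecord(
        plot_id=str(metadata["plot_id"]),
        species=str(metadata["species"]),
        treatment=str(metadata["treatment"]),
        replicate=int(metadata.get("replicate", 0)),
        period=metadata.get("period"),
        date=date,
        cc=cc,
        vegetation_fraction=frac,
        swc_percent=metadata.get("swc_percent"),
        spad=metadata.get("spad"),
        sla=metadata.get("sla"),
    )


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Tabulate records with one column per index and covariate."""
    rows = []
    for rec in records:
        rows.append(
            {
                "plot_id": rec.plot_id,
                "species": rec.species,
                "treatment": rec.treatment,
                "period": rec.period,
                "replicate": rec.replicate,
                "date": rec.date.isoformat(),
                "doy": rec.doy,
                "year": rec.date.year,
                "g_cc": rec.cc.g_cc,
                "r_cc": rec.cc.r_cc,
                "b_cc": rec.cc.b_cc,
                "y_cc": rec.cc.y_cc,
                "vegetation_fraction": rec.vegetation_fraction,
                "swc_percent": rec.swc_percent,
                "spad": rec.spad,
                "sla": rec.sla,
            }
        )
    return pd.DataFrame(rows)


def assemble_series(
    records: Sequence[ObservationRecord] | pd.DataFrame,
    index_name: str,
    aggregation_level: Literal["plot", "treatment"] = "treatment",
    *,
    extra_keys: Sequence[str] = (),
) -> list[ColorTimeSeries]:
    """Group records into doy-ordered series of one index.

    At ``treatment`` level, replicate values sharing a date are averaged
    (unweighted).  Keys always include the calendar year, so multi-year
    inputs produce separate series.  Duplicate (plot, date) rows are
    rejected.
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}")
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to assemble")
    if frame.duplicated(subset=["plot_id", "date"]).any():
        dupes = frame[frame.duplicated(subset=["plot_id", "date"], keep=False)]
        raise ValueError(f"duplicate (plot, date) observations:\n{dupes[['plot_id', 'date']]}")
    if "year" not in frame.columns:
        frame = frame.assign(year=pd.to_datetime(frame["date"]).dt.year)

    base_keys = ["species", "treatment", "year", *extra_keys]
    if aggregation_level == "plot":
        group_keys = base_keys + ["replicate"]
    elif aggregation_level == "treatment":
        group_keys = base_keys
    else:
        raise ValueError(f"unknown aggregation level {aggregation_level!r}")

    out: list[ColorTimeSeries] = []
    for key, grp in frame.groupby(group_keys, sort=True):
        per_doy = grp.groupby("doy", sort=True)[index_name].mean()
        out.append(
            ColorTimeSeries(
                key=tuple(key),
                index_name=index_name,
                doy=per_doy.index.to_numpy(),
                values=per_doy.to_numpy(),
            )
        )
    return out
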