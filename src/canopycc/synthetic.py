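"""Synthetic factorial irrigation-experiment datasets.

Generates canopy RGB scenes, ground-truth vegetation masks and SWC / SPAD /
SLA tables with the statistical structure the downstream analysis assumes:

* a seasonal double-logistic trajectory of each species' dominant chromatic
  coordinate, peaking mid-season;
* a multiplicative drought coupling — the dominant index is scaled by
  ``1 - sensitivity * stress`` where stress in [0, 1] derives from the
  simulated soil water content (0 at/above a well-watered SWC, 1 at/below a
  severe-drought SWC);
* treatment regimes for SWC as AR(1) series around treatment means
  (full > deficit > rainfed > drought), with Poisson rain pulses under the
  rainfed regime, active only during each plot's assigned treatment period;
* leaf colors constructed in HSV so that the rendered canopy's chromatic
  coordinates hit the seasonal target exactly: a per-species hue schedule
  maps the target index to foliage hue (green -> yellow-brown under stress,
  purple-red -> brown/green), and saturation is solved by root finding.

A chromatic constraint worth noting: any pixel kept by a hue window in which
one channel dominates has that channel's chromatic coordinate above 1/3, so
stressed colors are floored (per-archetype ``index_floor``) to stay
segmentable under the default rule; stress scenarios that need the full
imposed reduction lower the floor and widen the hue window instead.
"""

from __future__ import annotations

import colorsys
import datetime as _dt
import functools
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy.optimize import brentq
from scipy.special import expit

from .design import ExperimentDesign, PlotUnit, build_design
from .indices import ChromaticCoordinates
from .response import DEFAULT_STAGES
from .segmentation import VegetationMask

_BACKGROUND_COLORS: dict[str, tuple[float, float, float]] = {
    # dark soil: hue 30 deg < 50 fails the hue test
    "soil": (120.0, 80.0, 40.0),
    # bright equipment: V ~ 0.99 >= 0.95 fails the value test
    "bright": (250.0, 250.0, 252.0),
    # achromatic cover: S ~ 0.016 <= 0.1 fails the saturation test
    "gray": (126.0, 127.0, 128.0),
}


@dataclass(frozen=True)
class SpeciesArchetype:
    """Color phenology and drought response of one shrub archetype.

    The seasonal trajectory of the dominant chromatic coordinate is a
    double logistic in day-of-year rising to ``peak`` and declining back
    toward ``baseline``; drought multiplies it by ``1 - swc_sensitivity *
    stress`` and the result is clamped at ``index_floor``.  ``hue_schedule``
    maps the target index to foliage hue (degrees, may exceed 360 so red
    schedules interpolate smoothly across the 0-deg wrap).
    """

    id: str
    dominant_index: str
    base_hue: float
    baseline: float
    peak: float
    spring_midpoint: float
    spring_rate: float
    autumn_midpoint: float
    autumn_rate: float
    swc_sensitivity: float
    index_floor: float
    hue_schedule: tuple[tuple[float, float], ...]
    hue_sd: float = 1.5
    leaf_value: float = 0.50
    hue_window: tuple[float, float] | None = None
    spad_range: tuple[float, float] = (15.0, 90.0)
    sla_range: tuple[float, float] = (15.0, 90.0)

    def __post_init__(self) -> None:
        if self.peak < self.baseline:
            raise ValueError("peak must be >= baseline (amplitude >= 0)")
        if self.spring_midpoint >= self.autumn_midpoint:
            raise ValueError("spring midpoint must precede autumn midpoint")
        if self.swc_sensitivity < 0:
            raise ValueError("swc_sensitivity must be >= 0")
        if self.dominant_index not in ("g_cc", "r_cc", "y_cc"):
            raise ValueError(f"unknown dominant index {self.dominant_index!r}")

    def _shape(self, doy) -> np.ndarray:
        d = np.asarray(doy, dtype=float)
        return expit(self.spring_rate * (d - self.spring_midpoint)) * expit(
            -self.autumn_rate * (d - self.autumn_midpoint)
        )

    @functools.cached_property
    def amplitude(self) -> float:
        """Amplitude scaled so the unstressed seasonal maximum equals ``peak``."""
        return (self.peak - self.baseline) / float(self._shape(np.arange(1, 367)).max())

    def seasonal_value(self, doy) -> np.ndarray:
        """Unstressed dominant-index value at a day of year."""
        return self.baseline + self.amplitude * self._shape(doy)


def default_archetypes() -> dict[str, SpeciesArchetype]:
    """The three shrub archetypes: evergreen green, golden yellow, purple red."""
    return {
        "euonymus": SpeciesArchetype(
            id="euonymus",
            dominant_index="g_cc",
            base_hue=95.0,
            baseline=0.336,
            peak=0.414,
            spring_midpoint=100.0,
            spring_rate=0.07,
            autumn_midpoint=250.0,
            autumn_rate=0.05,
            swc_sensitivity=0.40,
            index_floor=0.350,
            hue_schedule=(
                (0.18, 0.0), (0.24, 10.0), (0.30, 25.0), (0.335, 45.0),
                (0.345, 50.0), (0.36, 58.0), (0.40, 78.0), (0.45, 95.0),
                (0.60, 100.0),
            ),
            leaf_value=0.50,
            spad_range=(38.0, 102.7),
            sla_range=(13.0, 125.5),
        ),
        "ligustrum": SpeciesArchetype(
            id="ligustrum",
            dominant_index="y_cc",
            base_hue=62.0,
            baseline=0.372,
            peak=0.417,
            spring_midpoint=100.0,
            spring_rate=0.07,
            autumn_midpoint=250.0,
            autumn_rate=0.05,
            swc_sensitivity=0.10,
            index_floor=0.355,
            hue_schedule=((0.34, 58.0), (0.40, 62.0), (0.55, 64.0)),
            leaf_value=0.55,
            spad_range=(15.0, 71.7),
            sla_range=(15.0, 95.0),
        ),
        "berberis": SpeciesArchetype(
            id="berberis",
            dominant_index="r_cc",
            base_hue=345.0,
            baseline=0.347,
            peak=0.419,
            spring_midpoint=100.0,
            spring_rate=0.07,
            autumn_midpoint=250.0,
            autumn_rate=0.05,
            swc_sensitivity=0.35,
            index_floor=0.360,
            # unwrapped hues: 520 -> 160 (faded green), 420 -> 60, 385 -> 25
            # (brown), down to deep red 340 when fully pigmented
            hue_schedule=(
                (0.20, 520.0), (0.30, 490.0), (0.345, 420.0), (0.36, 385.0),
                (0.40, 355.0), (0.50, 340.0),
            ),
            leaf_value=0.45,
            hue_window=(300.0, 40.0),
            spad_range=(10.6, 77.4),
            sla_range=(17.0, 60.18),
        ),
    }


@dataclass(frozen=True)
class SWCRegime:
    """Stationary AR(1) soil-water-content regime for one treatment."""

    mean: float
    sd: float
    ar1: float = 0.6
    rain_pulse_rate: float = 0.0  # expected pulses per sampling step
    rain_pulse_mean: float = 0.0  # mean pulse amplitude, SWC %

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 100.0:
            raise ValueError("SWC mean must lie in (0, 100)")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")


def default_regimes() -> dict[str, SWCRegime]:
    return {
        "full": SWCRegime(mean=65.0, sd=4.0),
        "deficit": SWCRegime(mean=40.0, sd=4.0),
        "rainfed": SWCRegime(mean=32.0, sd=6.0, rain_pulse_rate=0.25, rain_pulse_mean=10.0),
        "drought": SWCRegime(mean=18.0, sd=3.0),
    }


@dataclass
class SimulationConfig:
    """Everything the generator needs besides per-call seeds."""

    design: ExperimentDesign
    archetypes: Mapping[str, SpeciesArchetype] = field(default_factory=default_archetypes)
    swc_regimes: Mapping[str, SWCRegime] = field(default_factory=default_regimes)
    image_size: tuple[int, int] = (48, 48)
    background_fraction: float = 0.35
    pixel_noise_sd: float = 3.0  # DN units
    illumination_jitter: float = 0.04  # fractional brightness sd
    photo_interval_days: int = 10
    season_start: tuple[int, int] = (4, 1)
    season_end: tuple[int, int] = (9, 30)
    stress_swc_high: float = 60.0  # stress = 0 at/above this SWC
    stress_swc_low: float = 20.0  # stress = 1 at/below this SWC
    background_classes: tuple[str, ...] = ("soil", "bright")
    baseline_treatment: str = "full"
    trait_noise_frac: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image dimensions must be >= 16")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        if not 0.0 <= self.illumination_jitter <= 1.0:
            raise ValueError("illumination_jitter must lie in [0, 1]")
        if self.stress_swc_low >= self.stress_swc_high:
            raise ValueError("stress_swc_low must be < stress_swc_high")
        for name in self.background_classes:
            if name not in _BACKGROUND_COLORS:
                raise ValueError(f"unknown background class {name!r}")

    @property
    def year(self) -> int:
        try:
            return int(self.design.year_label)
        except ValueError:
            return 2022


@dataclass(frozen=True)
class LeafColorParams:
    """Mean leaf color of one scene, solved to hit a target dominant index."""

    hue_mean: float
    hue_sd: float
    sat_mean: float
    val_mean: float
    dominant_index: str
    target_index: float
    rgb_unit: tuple[float, float, float]  # continuous unit RGB of the mean leaf


@dataclass(frozen=True)
class GroundTruth:
    """What the renderer actually drew, for validating the pipeline."""

    true_mask: VegetationMask
    true_mean_indices: ChromaticCoordinates
    stress_level: float
    no_vegetation: bool = False


def subseed(master: int, *parts) -> np.random.SeedSequence:
    """Stable child seed from a master seed and hashable identifiers."""
    entropy = [int(master) & 0x7FFFFFFF] + [
        zlib.crc32(str(p).encode("utf8")) for p in parts
    ]
    return np.random.SeedSequence(entropy)


def _dominant_proportion(hue_deg: float, sat: float, dominant: str) -> float:
    r, g, b = colorsys.hsv_to_rgb((hue_deg % 360.0) / 360.0, sat, 1.0)
    tot = r + g + b
    if dominant == "g_cc":
        return g / tot
    if dominant == "r_cc":
        return r / tot
    return (g + r) / (2.0 * tot)


def _solve_saturation(hue_deg: float, target: float, dominant: str) -> float:
    """Saturation at which the leaf hue yields the target dominant proportion."""
    lo, hi = 1e-9, 0.985
    f = lambda s: _dominant_proportion(hue_deg, s, dominant) - target
    flo, fhi = f(lo), f(hi)
    if abs(flo) < 1e-12:
        return lo
    if flo * fhi > 0:
        raise ValueError(
            f"target {dominant}={target:.3f} unreachable at hue {hue_deg:.1f} deg"
        )
    return float(brentq(f, lo, hi, xtol=1e-13))


def seasonal_color_params(
    arch: SpeciesArchetype, doy: int, stress: float
) -> LeafColorParams:
    """Leaf color for a day of year under a stress level in [0, 1]."""
    if not 1 <= doy <= 366:
        raise ValueError("doy must lie in [1, 366]")
    if not 0.0 <= stress <= 1.0:
        raise ValueError("stress must lie in [0, 1]")
    target = float(arch.seasonal_value(doy)) * (1.0 - arch.swc_sensitivity * stress)
    target = max(target, arch.index_floor)
    ts = np.array([t for t, _ in arch.hue_schedule])
    hues = np.array([h for _, h in arch.hue_schedule])
    hue = float(np.interp(target, ts, hues)) % 360.0
    try:
        sat = _solve_saturation(hue, target, arch.dominant_index)
    except ValueError:
        # near the 1/3 feasibility boundary a scheduled hue can miss the
        # target by a hair; nudge the hue minimally to the feasible side
        for delta in np.arange(0.5, 20.5, 0.5):
            for candidate in (hue - delta, hue + delta):
                try:
                    sat = _solve_saturation(candidate % 360.0, target, arch.dominant_index)
                    hue = candidate % 360.0
                    break
                except ValueError:
                    continue
            else:
                continue
            break
        else:
            raise
    rgb = colorsys.hsv_to_rgb(hue / 360.0, sat, arch.leaf_value)
    return LeafColorParams(
        hue_mean=hue,
        hue_sd=arch.hue_sd,
        sat_mean=sat,
        val_mean=arch.leaf_value,
        dominant_index=arch.dominant_index,
        target_index=target,
        rgb_unit=rgb,
    )


def _true_indices(rgb_unit: Sequence[float]) -> ChromaticCoordinates:
    r, g, b = rgb_unit
    tot = r + g + b
    g, r, b = g / tot, r / tot, b / tot
    return ChromaticCoordinates(g_cc=g, r_cc=r, b_cc=b, y_cc=(g + r) / 2.0)


def render_canopy(
    params: LeafColorParams,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    *,
    stress_level: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Draw one canopy scene and its ground truth.

    Vegetation pixels carry the leaf color with per-pixel hue jitter,
    multiplicative illumination jitter, and additive DN noise; background
    pixels come from soil / bright-equipment / gray color models, all of
    which fail the default segmentation rule at zero noise.
    """
    rng = np.random.default_rng(seed)
    h, w = config.image_size
    veg = rng.random((h, w)) >= config.background_fraction

    # vegetation colors
    if params.hue_sd > 0:
        hue = rng.normal(params.hue_mean, params.hue_sd, (h, w))
    else:
        hue = np.full((h, w), params.hue_mean)
    hsv = np.stack(
        [
            (hue % 360.0) / 360.0,
            np.full((h, w), params.sat_mean),
            np.full((h, w), params.val_mean),
        ],
        axis=-1,
    )
    img = hsv_to_rgb(hsv) * 255.0

    # background colors
    classes = config.background_classes
    pick = rng.integers(0, len(classes), (h, w))
    bg = np.zeros((h, w, 3))
    for i, name in enumerate(classes):
        bg[pick == i] = _BACKGROUND_COLORS[name]
    img = np.where(veg[..., None], img, bg)

    if config.illumination_jitter > 0:
        m = np.clip(rng.normal(1.0, config.illumination_jitter, (h, w)), 0.6, 1.4)
        img = img * m[..., None]
    if config.pixel_noise_sd > 0:
        img = img + rng.normal(0.0, config.pixel_noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        true_mask=VegetationMask(grid=veg, n_vegetation=int(veg.sum())),
        true_mean_indices=_true_indices(params.rgb_unit),
        stress_level=float(stress_level),
        no_vegetation=not bool(veg.any()),
    )
    return img, truth


def stress_from_swc(swc, config: SimulationConfig) -> np.ndarray:
    """Piecewise-linear stress: 0 at well-watered SWC, 1 at drought SWC."""
    swc = np.asarray(swc, dtype=float)
    hi, lo = config.stress_swc_high, config.stress_swc_low
    return np.clip((hi - swc) / (hi - lo), 0.0, 1.0)


_STAGE_BY_ID = {s.id: s for s in DEFAULT_STAGES}


def _treatment_active(plot: PlotUnit, date: _dt.date) -> bool:
    stage = _STAGE_BY_ID.get(plot.period)
    return True if stage is None else stage.contains(date)


def photo_dates(config: SimulationConfig, year: int | None = None) -> list[_dt.date]:
    """Photo acquisition calendar at the configured cadence."""
    year = config.year if year is None else year
    d = _dt.date(year, *config.season_start)
    end = _dt.date(year, *config.season_end)
    out = []
    while d <= end:
        out.append(d)
        d += _dt.timedelta(days=config.photo_interval_days)
    return out


def simulate_swc(
    plot: PlotUnit,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    dates: Sequence[_dt.date] | None = None,
) -> pd.Series:
    """AR(1) soil-water-content series at the photo dates.

    The plot's treatment regime applies while the date falls inside the
    plot's treatment period; outside it the baseline (well-watered) regime
    applies.  Rainfed regimes add Poisson-count exponential rain pulses.
    """
    if plot.treatment not in config.swc_regimes:
        raise KeyError(f"no SWC regime configured for treatment {plot.treatment!r}")
    rng = np.random.default_rng(seed)
    dates = photo_dates(config) if dates is None else list(dates)
    base = config.swc_regimes.get(config.baseline_treatment)
    if base is None:
        base = SWCRegime(mean=65.0, sd=4.0)
    own = config.swc_regimes[plot.treatment]

    values = []
    prev_dev = None
    prev_sd = None
    for d in dates:
        reg = own if _treatment_active(plot, d) else base
        if prev_dev is None:
            dev = rng.normal(0.0, 1.0) * reg.sd
        else:
            innov = rng.normal(0.0, 1.0) * reg.sd * np.sqrt(1.0 - reg.ar1**2)
            dev = reg.ar1 * (prev_dev / prev_sd if prev_sd > 0 else 0.0) * reg.sd + innov
        x = reg.mean + dev
        if reg.rain_pulse_rate > 0:
            n_pulses = rng.poisson(reg.rain_pulse_rate)
            if n_pulses:
                x += rng.exponential(reg.rain_pulse_mean, n_pulses).sum()
        values.append(float(np.clip(x, 0.5, 99.5)))
        prev_dev, prev_sd = dev, reg.sd
    return pd.Series(values, index=pd.Index(dates, name="date"), name="swc_percent")


def simulate_traits(
    plot: PlotUnit,
    stress: float,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[float, float]:
    """(SPAD, SLA) draw: both decline linearly in stress within species bounds."""
    if not 0.0 <= stress <= 1.0:
        raise ValueError("stress must lie in [0, 1]")
    arch = config.archetypes[plot.species]
    rng = np.random.default_rng(seed)
    out = []
    for lo, hi in (arch.spad_range, arch.sla_range):
        center = hi - (hi - lo) * stress
        noise = rng.normal(0.0, config.trait_noise_frac * (hi - lo)) if config.trait_noise_frac > 0 else 0.0
        out.append(float(np.clip(center + noise, lo, hi)))
    return out[0], out[1]


@dataclass
class DatasetBundle:
    """In-memory dataset: images, ground truth and the three tables."""

    config: SimulationConfig
    metadata: pd.DataFrame
    swc: pd.DataFrame
    traits: pd.DataFrame
    images: dict[tuple[str, str], np.ndarray]
    ground_truth: dict[tuple[str, str], GroundTruth]

    def write(self, out_dir: str | Path) -> Path:
        """Write images and CSVs; returns the output directory."""
        from PIL import Image

        out = Path(out_dir)
        try:
            (out / "images").mkdir(parents=True, exist_ok=True)
            (out / "masks").mkdir(parents=True, exist_ok=True)
            for (pid, date), img in self.images.items():
                Image.fromarray(img).save(out / "images" / f"{pid}_{date}.png")
                mask = self.ground_truth[(pid, date)].true_mask.grid
                Image.fromarray((mask * np.uint8(255))).save(
                    out / "masks" / f"{pid}_{date}.png"
                )
            self.metadata.to_csv(out / "metadata.csv", index=False)
            self.swc.to_csv(out / "swc.csv", index=False)
            self.traits.to_csv(out / "traits.csv", index=False)
            truth_rows = [
                {
                    "plot_id": pid,
                    "date": date,
                    "stress": gt.stress_level,
                    "true_g_cc": gt.true_mean_indices.g_cc,
                    "true_r_cc": gt.true_mean_indices.r_cc,
                    "true_b_cc": gt.true_mean_indices.b_cc,
                    "true_y_cc": gt.true_mean_indices.y_cc,
                    "n_vegetation": gt.true_mask.n_vegetation,
                }
                for (pid, date), gt in self.ground_truth.items()
            ]
            pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
        except OSError as exc:
            raise OSError(f"failed writing dataset under {out}: {exc}") from exc
        return out


def generate_dataset(config: SimulationConfig) -> DatasetBundle:
    """One image per plot per photo date, plus SWC / trait / metadata tables."""
    master = config.seed
    dates = photo_dates(config)
    meta_rows, swc_rows, trait_rows = [], [], []
    images: dict[tuple[str, str], np.ndarray] = {}
    truths: dict[tuple[str, str], GroundTruth] = {}

    for plot in config.design.plots:
        if plot.species not in config.archetypes:
            raise KeyError(f"no archetype configured for species {plot.species!r}")
        arch = config.archetypes[plot.species]
        swc_series = simulate_swc(plot, config, subseed(master, plot.plot_id, "swc"), dates)
        for d in dates:
            iso = d.isoformat()
            swc_val = float(swc_series.loc[d])
            stress = float(stress_from_swc(swc_val, config))
            params = seasonal_color_params(arch, d.timetuple().tm_yday, stress)
            img, gt = render_canopy(
                params, config, subseed(master, plot.plot_id, iso, "img"),
                stress_level=stress,
            )
            spad, sla = simulate_traits(
                plot, stress, config, subseed(master, plot.plot_id, iso, "trait")
            )
            images[(plot.plot_id, iso)] = img
            truths[(plot.plot_id, iso)] = gt
            meta_rows.append(
                {
                    "plot_id": plot.plot_id,
                    "species": plot.species,
                    "treatment": plot.treatment,
                    "period": plot.period,
                    "replicate": plot.replicate,
                    "date": iso,
                    "image_path": f"images/{plot.plot_id}_{iso}.png",
                }
            )
            swc_rows.append({"plot_id": plot.plot_id, "date": iso, "swc_percent": swc_val})
            trait_rows.append({"plot_id": plot.plot_id, "date": iso, "spad": spad, "sla": sla})

    return DatasetBundle(
        config=config,
        metadata=pd.DataFrame(meta_rows),
        swc=pd.DataFrame(swc_rows),
        traits=pd.DataFrame(trait_rows),
        images=images,
        ground_truth=truths,
    )


def default_config(year_label: str = "2022", **overrides) -> SimulationConfig:
    """Convenience constructor: standard design plus keyword overrides."""
    design = overrides.pop("design", None) or build_design(year_label)
    return SimulationConfig(design=design, **overrides)
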