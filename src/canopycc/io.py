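"""Readers/writers, pipeline configuration and the end-to-end pipeline.

``run_pipeline`` composes the stages in protocol order: (optional) synthetic
generation -> HSV segmentation -> chromatic-coordinate extraction ->
response ratios vs the control treatment -> coefficient-of-variation and
ANOVA summaries -> SWC threshold estimation, writing one CSV/JSON artifact
per stage plus a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import build_design
from .indices import (
    EmptyMaskError,
    assemble_series,
    extract_index_record,
    records_to_frame,
)
from .inference import anova_table
from .response import (
    assign_stage,
    coefficient_of_variation,
    response_ratio_series,
)
from .segmentation import DEFAULT_THRESHOLDS, HSVThresholds
from .synthetic import DatasetBundle, SimulationConfig, default_archetypes, generate_dataset
from .thresholds import bootstrap_threshold_ci

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


def read_image(path: str | Path, *, flatten_alpha: bool = False) -> np.ndarray:
    """Load an 8-bit RGB image as an HxWx3 uint8 array.

    Grayscale and 16-bit inputs are rejected with explicit messages; RGBA is
    rejected unless ``flatten_alpha`` composites it over white.
    """
    from PIL import Image, UnidentifiedImageError

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        img = Image.open(path)
        img.load()
    except UnidentifiedImageError as exc:
        raise ValueError(f"cannot decode image {path}: {exc}") from exc
    if img.mode in ("I", "I;16", "I;16B", "F"):
        raise ValueError(f"unsupported bit depth ({img.mode}) in {path}: expected 8-bit RGB")
    if img.mode == "RGBA":
        if not flatten_alpha:
            raise ValueError(f"{path} has an alpha channel; pass flatten_alpha=True")
        bg = Image.new("RGB", img.size, (255, 255, 255))
        bg.paste(img, mask=img.split()[3])
        img = bg
    if img.mode != "RGB":
        n_channels = len(img.getbands())
        raise ValueError(
            f"{path} has {n_channels} channel(s) (mode {img.mode}); expected 3-channel RGB"
        )
    return np.asarray(img, dtype=np.uint8)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    from PIL import Image

    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255))).save(path)


def _parse_thresholds(value) -> HSVThresholds:
    if value is None:
        return DEFAULT_THRESHOLDS
    if isinstance(value, HSVThresholds):
        return value
    if isinstance(value, str):
        parts = [float(v) for v in value.split(",")]
        return HSVThresholds(*parts)
    if isinstance(value, Mapping):
        return HSVThresholds(**value)
    return HSVThresholds(*[float(v) for v in value])


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run (synthetic or on-disk inputs)."""

    out_dir: str | Path = "canopycc_run"
    # synthetic mode: either a standard year label or custom factors
    simulate: dict | None = None
    # on-disk mode
    images_dir: str | Path | None = None
    metadata: str | Path | None = None
    swc: str | Path | None = None
    traits: str | Path | None = None
    thresholds: HSVThresholds = DEFAULT_THRESHOLDS
    species_thresholds: dict[str, HSVThresholds] = field(default_factory=dict)
    dominant_index: dict[str, str] = field(default_factory=dict)
    control_treatment: str = "full"
    criterion_fraction: float = 0.95
    n_boot: int = 200
    seed: int = 0
    write_images: bool = True
    min_vegetation_fraction: float = 0.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["thresholds"] = _parse_thresholds(raw.get("thresholds"))
        raw["species_thresholds"] = {
            k: _parse_thresholds(v) for k, v in (raw.get("species_thresholds") or {}).items()
        }
        return cls(**raw)


@dataclass
class RunManifest:
    """Machine-readable run summary, emitted exactly once per run."""

    version: str
    config: dict
    row_counts: dict[str, int]
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def _simulation_config(config: PipelineConfig) -> SimulationConfig:
    spec = dict(config.simulate or {"year_label": "2022"})
    year_label = spec.pop("year_label", "2022")
    design_kwargs = {
        k: spec.pop(k)
        for k in ("species", "treatments", "periods", "replicates")
        if k in spec
    }
    design = build_design(year_label, **design_kwargs)
    spec.setdefault("seed", config.seed)
    if "image_size" in spec:
        spec["image_size"] = tuple(spec["image_size"])
    return SimulationConfig(design=design, **spec)


def _species_thresholds(config: PipelineConfig, archetypes) -> dict[str, HSVThresholds]:
    """Per-species windows: explicit config first, then archetype overrides."""
    out = dict(config.species_thresholds)
    base = config.thresholds
    for sp, arch in archetypes.items():
        if sp not in out and arch.hue_window is not None:
            out[sp] = HSVThresholds(
                hue_min=arch.hue_window[0],
                hue_max=arch.hue_window[1],
                sat_min=base.sat_min,
                val_max=base.val_max,
            )
    return out


def _stage(name: str):
    """Decorator-free stage context: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def extract_indices_frame(
    metadata: pd.DataFrame,
    get_image,
    thresholds: HSVThresholds,
    species_thresholds: Mapping[str, HSVThresholds] | None = None,
    swc: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    *,
    min_vegetation_fraction: float = 0.0,
) -> pd.DataFrame:
    """Segment and extract one record per metadata row.

    ``get_image(row)`` must return the HxWx3 array for that row.  SWC and
    trait tables are joined on (plot_id, date) before extraction so records
    carry their covariates.
    """
    species_thresholds = species_thresholds or {}
    meta = metadata.copy()
    for extra in (swc, traits):
        if extra is not None:
            meta = meta.merge(extra, on=["plot_id", "date"], how="left")
    records = []
    for row in meta.to_dict("records"):
        thr = species_thresholds.get(row["species"], thresholds)
        try:
            records.append(
                extract_index_record(
                    get_image(row), thr, row,
                    min_vegetation_fraction=min_vegetation_fraction,
                )
            )
        except EmptyMaskError as exc:
            raise EmptyMaskError(
                f"{exc} [plot={row.get('plot_id')}, date={row.get('date')}]"
            ) from exc
    return records_to_frame(records)


def _dominant_map(config: PipelineConfig, species: list[str], archetypes) -> dict[str, str]:
    out = {}
    for sp in species:
        if sp in config.dominant_index:
            out[sp] = config.dominant_index[sp]
        elif sp in archetypes:
            out[sp] = archetypes[sp].dominant_index
        else:
            out[sp] = "g_cc"
    return out


def _plot_stage_table(indices: pd.DataFrame, dominant: Mapping[str, str]) -> pd.DataFrame:
    """Per-plot means of the species' dominant index (and SWC) within the
    plot's own treatment period; the unit of analysis for ANOVA/thresholds."""
    frame = indices.copy()
    frame["stage"] = [assign_stage(d) for d in frame["date"]]
    frame = frame[frame["stage"] == frame["period"]]
    rows = []
    for (pid,), grp in frame.groupby(["plot_id"]):
        sp = grp["species"].iloc[0]
        idx = dominant[sp]
        rows.append(
            {
                "plot_id": pid,
                "species": sp,
                "season": grp["period"].iloc[0],
                "treatment": grp["treatment"].iloc[0],
                "replicate": grp["replicate"].iloc[0],
                "value": grp[idx].mean(),
                "swc_percent": grp["swc_percent"].mean()
                if "swc_percent" in grp
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and write the declared artifacts under ``out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    row_counts: dict[str, int] = {}

    bundle: DatasetBundle | None = None
    archetypes = default_archetypes()
    with _stage("simulate"):
        if config.simulate is not None or config.images_dir is None:
            sim_config = _simulation_config(config)
            archetypes = dict(sim_config.archetypes)
            bundle = generate_dataset(sim_config)
            if config.write_images:
                bundle.write(out / "data")
            metadata = bundle.metadata
            swc, traits = bundle.swc, bundle.traits
        else:
            metadata = pd.read_csv(config.metadata, dtype={"date": str})
            swc = pd.read_csv(config.swc, dtype={"date": str}) if config.swc else None
            traits = pd.read_csv(config.traits, dtype={"date": str}) if config.traits else None

    # configuration validation before any computation
    if config.control_treatment not in set(metadata["treatment"]):
        raise PipelineError(
            f"control treatment {config.control_treatment!r} absent from metadata"
        )

    species_thr = _species_thresholds(config, archetypes)

    with _stage("index"):
        if bundle is not None:
            get_image = lambda row: bundle.images[(row["plot_id"], row["date"])]
        else:
            images_dir = Path(config.images_dir)
            get_image = lambda row: read_image(images_dir / row["image_path"])
        indices = extract_indices_frame(
            metadata, get_image, config.thresholds, species_thr, swc, traits,
            min_vegetation_fraction=config.min_vegetation_fraction,
        )
        indices.to_csv(out / "indices.csv", index=False)
        row_counts["indices"] = len(indices)
        low = (indices["vegetation_fraction"] < max(config.min_vegetation_fraction, 0.05)).sum()
        if low:
            warnings_log.append(f"{low} records with low vegetation fraction")

    dominant = _dominant_map(config, sorted(indices["species"].unique()), archetypes)

    with _stage("response_ratio"):
        rr_rows = []
        for sp, grp in indices.groupby("species"):
            idx = dominant[sp]
            series = assemble_series(grp, idx, "treatment", extra_keys=("period",))
            controls = {
                (s.key[0], s.key[2], s.key[3]): s
                for s in series
                if s.key[1] == config.control_treatment
            }
            for s in series:
                if s.key[1] == config.control_treatment:
                    continue
                control = controls.get((s.key[0], s.key[2], s.key[3]))
                if control is None:
                    warnings_log.append(f"no control series for {s.key}")
                    continue
                rr = response_ratio_series(s, control)
                for d, v in zip(rr.doy, rr.rr):
                    rr_rows.append(
                        {
                            "species": sp,
                            "treatment": s.key[1],
                            "year": s.key[2],
                            "period": s.key[3],
                            "index_name": idx,
                            "doy": int(d),
                            "rr": v,
                        }
                    )
        rr_frame = pd.DataFrame(rr_rows)
        rr_frame.to_csv(out / "rr.csv", index=False)
        row_counts["rr"] = len(rr_frame)

    with _stage("cv"):
        cv_rows = []
        for sp, grp in indices.groupby("species"):
            idx = dominant[sp]
            for s in assemble_series(grp, idx, "treatment"):
                cv_rows.append(
                    {
                        "species": sp,
                        "treatment": s.key[1],
                        "year": s.key[2],
                        "index_name": idx,
                        "cv_percent": coefficient_of_variation(s.values),
                    }
                )
        cv_frame = pd.DataFrame(cv_rows)
        cv_frame.to_csv(out / "cv.csv", index=False)
        row_counts["cv"] = len(cv_frame)

    with _stage("anova"):
        plot_table = _plot_stage_table(indices, dominant)
        row_counts["plot_stage_means"] = len(plot_table)
        factors = [
            f for f in ("species", "season", "treatment") if plot_table[f].nunique() > 1
        ]
        try:
            if not factors:
                raise ValueError("no factor with two or more levels")
            table = anova_table(plot_table, factors=factors)
            table.frame.assign(error_df=table.error_df, error_ms=table.error_ms).to_csv(
                out / "anova.csv"
            )
        except ValueError as exc:
            warnings_log.append(f"anova skipped: {exc}")

    with _stage("threshold"):
        results = {}
        for sp, grp in plot_table.groupby("species"):
            if grp["swc_percent"].isna().any() or len(grp) < 8:
                warnings_log.append(f"threshold skipped for {sp}: insufficient SWC data")
                continue
            control_level = grp.loc[
                grp["treatment"] == config.control_treatment, "value"
            ].mean()
            criterion = config.criterion_fraction * control_level
            try:
                est = bootstrap_threshold_ci(
                    grp["swc_percent"].to_numpy(),
                    grp["value"].to_numpy(),
                    criterion,
                    n_boot=config.n_boot,
                    seed=config.seed,
                )
            except ValueError as exc:
                warnings_log.append(f"threshold skipped for {sp}: {exc}")
                continue
            if not est.achievable:
                warnings_log.append(f"criterion unachievable for {sp}")
            results[sp] = {
                "index_name": dominant[sp],
                "criterion": est.criterion,
                "swc_star": est.swc_star,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_boot": est.n_boot,
                "achievable": est.achievable,
                "reliable": est.reliable,
                "fit_family": est.fit_family,
            }
        (out / "thresholds.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        row_counts["thresholds"] = len(results)

    manifest = RunManifest(
        version=__version__,
        config={
            k: str(v)
            for k, v in dataclasses.asdict(config).items()
        },
        row_counts=row_counts,
        warnings=warnings_log,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
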