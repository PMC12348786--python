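"""Simulation studies run on top of the pipeline.

These functions wire the synthetic generator through segmentation, index
extraction and response analysis to measure how well the pipeline recovers
effects it imposed: drought effect-size recovery via response ratios, ANOVA
type-I error calibration and power, and SWC-threshold recovery.  They back
the statistical-calibration tests and the acceptance script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .design import build_design
from .indices import assemble_series, extract_index_record, records_to_frame
from .inference import anova_table
from .response import response_ratio_series, stage_mean
from .segmentation import HSVThresholds
from .synthetic import (
    SimulationConfig,
    default_archetypes,
    generate_dataset,
    subseed,
)
from .thresholds import bootstrap_threshold_ci, fit_index_response, invert_criterion, logistic4

#: wrapped hue window covering green, yellow, brown and red foliage
#: (everything but the blue-cyan 180-300 deg band) for stress scenarios in
#: which heavily stressed leaves brown below the default 50-deg hue bound
WIDE_THRESHOLDS = HSVThresholds(hue_min=300.0, hue_max=180.0, sat_min=0.1, val_max=0.985)


def drought_reduction_scenario(
    seed: int,
    species: str = "euonymus",
    sensitivity: float | None = None,
    *,
    replicates: int = 3,
    image_size: tuple[int, int] = (24, 24),
    pixel_noise_sd: float = 3.0,
) -> float:
    """Recover an imposed late-season multiplicative drought reduction.

    Builds a late-period drought-vs-full design for one archetype whose
    stressed colors are *not* floored (index_floor lowered to 0.15), renders
    the season, extracts indices through the segmentation pipeline with the
    wide hue window, and returns the reduction implied by the late-stage
    mean response ratio, ``1 - exp(mean RR)``, as a fraction.
    """
    arch = default_archetypes()[species]
    if sensitivity is not None:
        arch = replace(arch, swc_sensitivity=sensitivity)
    arch = replace(arch, index_floor=0.15)
    design = build_design(
        "stress-scenario",
        species=(species,),
        treatments=("full", "drought"),
        periods=("late",),
        replicates=replicates,
    )
    config = SimulationConfig(
        design=design,
        archetypes={species: arch},
        image_size=image_size,
        pixel_noise_sd=pixel_noise_sd,
        season_start=(8, 1),
        season_end=(9, 30),
        background_classes=("bright", "gray"),
        seed=seed,
    )
    bundle = generate_dataset(config)
    records = [
        extract_index_record(
            bundle.images[(row.plot_id, row.date)], WIDE_THRESHOLDS, row._asdict()
        )
        for row in bundle.metadata.itertuples(index=False)
    ]
    series = assemble_series(records_to_frame(records), arch.dominant_index, "treatment")
    by_treatment = {s.key[1]: s for s in series}
    rr = response_ratio_series(by_treatment["drought"], by_treatment["full"])
    late_rr = stage_mean(rr, year=config.year)["late"]
    return float(1.0 - np.exp(late_rr))


def simulate_index_table(
    rng: np.random.Generator,
    *,
    treatment_effects: dict[str, float] | None = None,
    noise_sd: float = 0.03,
    replicates: int = 3,
) -> pd.DataFrame:
    """Balanced long table of index values with additive factor effects.

    Species, season and replicate carry small fixed effects; the treatment
    effect defaults to zero (the null).  One row per species x season x
    treatment x replicate cell of the four-treatment design.
    """
    species = ("euonymus", "ligustrum", "berberis")
    seasons = ("early", "middle", "late")
    treatments = ("full", "deficit", "rainfed", "drought")
    sp_eff = dict(zip(species, (0.010, 0.0, -0.010)))
    se_eff = dict(zip(seasons, (-0.020, 0.020, 0.0)))
    rep_eff = {r: e for r, e in zip(range(1, replicates + 1), (0.005, 0.0, -0.005))}
    tr_eff = treatment_effects or {t: 0.0 for t in treatments}
    rows = []
    for sp in species:
        for se in seasons:
            for tr in treatments:
                for rep in range(1, replicates + 1):
                    mu = (
                        0.40
                        + sp_eff[sp]
                        + se_eff[se]
                        + tr_eff.get(tr, 0.0)
                        + rep_eff.get(rep, 0.0)
                    )
                    rows.append(
                        {
                            "species": sp,
                            "season": se,
                            "treatment": tr,
                            "replicate": rep,
                            "value": mu + rng.normal(0.0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


def anova_rejection_rate(
    n_sims: int,
    seed: int,
    *,
    drought_effect: float = 0.0,
    alpha: float = 0.05,
    noise_sd: float = 0.03,
) -> float:
    """Fraction of simulated tables whose treatment F-test rejects at alpha."""
    rng = np.random.default_rng(subseed(seed, "anova", drought_effect))
    effects = {"drought": -drought_effect}
    hits = 0
    for _ in range(n_sims):
        table = simulate_index_table(rng, treatment_effects=effects, noise_sd=noise_sd)
        result = anova_table(table)
        if result.frame.loc["treatment", "p"] < alpha:
            hits += 1
    return hits / n_sims


TRUE_LOGISTIC = {"lower": 0.2, "upper": 0.9, "mid": 40.0, "rate": 0.15}


def simulate_swc_response(
    rng: np.random.Generator, n_plots: int = 24, noise_sd: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Per-plot (SWC, index) pairs from the reference logistic response."""
    swc = rng.uniform(10.0, 80.0, n_plots)
    index = logistic4(swc, **TRUE_LOGISTIC) + rng.normal(0.0, noise_sd, n_plots)
    return swc, index


def threshold_recovery(
    n_sims: int, seed: int, *, noise_sd: float = 0.02, n_plots: int = 24
) -> np.ndarray:
    """Criterion-crossing SWC estimates over repeated noisy simulations.

    The criterion is the true curve's value at SWC = 40, so the true
    threshold is exactly 40; returns the array of estimates.
    """
    criterion = float(logistic4(40.0, **TRUE_LOGISTIC))
    rng = np.random.default_rng(subseed(seed, "threshold"))
    estimates = []
    for _ in range(n_sims):
        swc, index = simulate_swc_response(rng, n_plots=n_plots, noise_sd=noise_sd)
        fit = fit_index_response(swc, index)
        star, ok = invert_criterion(fit, criterion)
        if ok:
            estimates.append(star)
    return np.asarray(estimates)


def zero_noise_threshold_ci(seed: int, n_plots: int = 24):
    """Bootstrap threshold estimate on noiseless logistic data (truth = 40)."""
    rng = np.random.default_rng(subseed(seed, "threshold-zero"))
    swc = rng.uniform(10.0, 80.0, n_plots)
    index = logistic4(swc, **TRUE_LOGISTIC)
    criterion = float(logistic4(40.0, **TRUE_LOGISTIC))
    return bootstrap_threshold_ci(swc, index, criterion, n_boot=200, seed=seed)
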