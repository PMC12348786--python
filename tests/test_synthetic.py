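import dataclasses
import datetime as dt

import numpy as np
import pytest

from canopycc import (
    SimulationConfig,
    SWCRegime,
    build_design,
    chromatic_coordinates,
    default_archetypes,
    generate_dataset,
    masked_mean_dn,
    photo_dates,
    render_canopy,
    seasonal_color_params,
    segment_vegetation,
    simulate_swc,
    simulate_traits,
    stress_from_swc,
)
from canopycc.design import PlotUnit
from canopycc.experiments import WIDE_THRESHOLDS
from canopycc.inference import linear_r2


def always_plot(treatment="drought"):
    # period name outside the stage calendar -> treatment active on every date
    return PlotUnit("p1", "euonymus", treatment, "always", 1)


DATES = [dt.date(2022, 8, 1) + dt.timedelta(days=10 * i) for i in range(6)]


def config_with(regimes, design=None, **kw):
    design = design or build_design(
        "t", species=("euonymus",), treatments=tuple(regimes), periods=("always",), replicates=1
    )
    return SimulationConfig(design=design, swc_regimes=regimes, **kw)


def test_swc_zero_noise_is_constant_at_regime_mean():
    cfg = config_with({"drought": SWCRegime(mean=20.0, sd=0.0)})
    series = simulate_swc(always_plot(), cfg, seed=0, dates=DATES)
    assert np.allclose(series.to_numpy(), 20.0)


def test_swc_regime_ordering_in_expectation():
    cfg = config_with(
        {"full": SWCRegime(mean=65.0, sd=4.0), "drought": SWCRegime(mean=20.0, sd=3.0)}
    )
    full = np.concatenate(
        [
            simulate_swc(always_plot("full"), cfg, seed=s, dates=DATES).to_numpy()
            for s in range(50)
        ]
    )
    drought = np.concatenate(
        [
            simulate_swc(always_plot(), cfg, seed=s + 100, dates=DATES).to_numpy()
            for s in range(50)
        ]
    )
    assert full.mean() > drought.mean()


def test_swc_deterministic_and_missing_regime():
    cfg = config_with({"drought": SWCRegime(mean=20.0, sd=3.0)})
    a = simulate_swc(always_plot(), cfg, seed=5, dates=DATES)
    b = simulate_swc(always_plot(), cfg, seed=5, dates=DATES)
    assert a.equals(b)
    with pytest.raises(KeyError, match="regime"):
        simulate_swc(always_plot("rainfed"), cfg, seed=0, dates=DATES)


def test_swc_rain_pulses_raise_rainfed_mean():
    base = SWCRegime(mean=30.0, sd=2.0)
    pulsed = SWCRegime(mean=30.0, sd=2.0, rain_pulse_rate=1.0, rain_pulse_mean=10.0)
    cfg = config_with({"rainfed": pulsed, "dry": base})
    wet = np.concatenate(
        [
            simulate_swc(always_plot("rainfed"), cfg, seed=s, dates=DATES).to_numpy()
            for s in range(30)
        ]
    )
    dry = np.concatenate(
        [
            simulate_swc(always_plot("dry"), cfg, seed=s, dates=DATES).to_numpy()
            for s in range(30)
        ]
    )
    assert wet.mean() > dry.mean() + 5.0


def test_stress_mapping_is_piecewise_linear():
    cfg = config_with({"drought": SWCRegime(mean=20.0, sd=0.0)})
    assert stress_from_swc(70.0, cfg) == 0.0
    assert stress_from_swc(10.0, cfg) == 1.0
    assert stress_from_swc(40.0, cfg) == pytest.approx(0.5)


def test_seasonal_target_peaks_midseason(green_archetype):
    p_peak = seasonal_color_params(green_archetype, 165, 0.0)
    assert p_peak.target_index == pytest.approx(green_archetype.peak, abs=1e-3)
    p_edge = seasonal_color_params(green_archetype, 91, 0.0)
    assert p_peak.target_index > p_edge.target_index


def test_stress_coupling_is_multiplicative(green_archetype):
    arch = dataclasses.replace(green_archetype, swc_sensitivity=0.4, index_floor=0.0)
    unstressed = seasonal_color_params(arch, 165, 0.0).target_index
    full_stress = seasonal_color_params(arch, 165, 1.0).target_index
    half_stress = seasonal_color_params(arch, 165, 0.5).target_index
    assert full_stress == pytest.approx(0.6 * unstressed, rel=1e-9)
    assert half_stress == pytest.approx(0.8 * unstressed, rel=1e-9)


def test_index_floor_clamps_target(green_archetype):
    arch = dataclasses.replace(green_archetype, swc_sensitivity=0.9, index_floor=0.35)
    assert seasonal_color_params(arch, 165, 1.0).target_index == 0.35


def test_seasonal_params_validation(green_archetype):
    with pytest.raises(ValueError):
        seasonal_color_params(green_archetype, 0, 0.0)
    with pytest.raises(ValueError):
        seasonal_color_params(green_archetype, 100, 1.5)


@pytest.mark.parametrize("species", ["euonymus", "ligustrum", "berberis"])
def test_leaf_color_hits_target_index(species):
    """The solved leaf color's dominant chromatic coordinate equals the target."""
    arch = default_archetypes()[species]
    for stress in (0.0, 0.5, 1.0):
        p = seasonal_color_params(arch, 180, stress)
        r, g, b = p.rgb_unit
        tot = r + g + b
        value = {"g_cc": g / tot, "r_cc": r / tot, "y_cc": (g + r) / (2 * tot)}[
            arch.dominant_index
        ]
        assert value == pytest.approx(p.target_index, abs=1e-9)


def test_render_degenerate_all_vegetation(quiet_green_archetype, noise_free_config):
    cfg = dataclasses.replace(noise_free_config, background_fraction=0.0)
    p = seasonal_color_params(quiet_green_archetype, 180, 0.0)
    img, gt = render_canopy(p, cfg, seed=3)
    assert gt.true_mask.n_vegetation == img.shape[0] * img.shape[1]
    assert len(np.unique(img.reshape(-1, 3), axis=0)) == 1  # uniform scene


def test_render_all_background_flagged(quiet_green_archetype, noise_free_config):
    cfg = dataclasses.replace(noise_free_config, background_fraction=1.0)
    p = seasonal_color_params(quiet_green_archetype, 180, 0.0)
    _, gt = render_canopy(p, cfg, seed=3)
    assert gt.no_vegetation and gt.true_mask.n_vegetation == 0


def test_render_deterministic(quiet_green_archetype, noise_free_config):
    p = seasonal_color_params(quiet_green_archetype, 180, 0.3)
    img1, _ = render_canopy(p, noise_free_config, seed=11)
    img2, _ = render_canopy(p, noise_free_config, seed=11)
    np.testing.assert_array_equal(img1, img2)


def test_noise_free_scene_matches_ground_truth_exactly(
    quiet_green_archetype, noise_free_config
):
    """At zero noise the segmentation mask equals the rendered truth and the
    extracted coordinates match the target within 8-bit quantization."""
    for stress in (0.0, 0.4):
        p = seasonal_color_params(quiet_green_archetype, 180, stress)
        img, gt = render_canopy(p, noise_free_config, seed=7, stress_level=stress)
        mask = segment_vegetation(img)
        np.testing.assert_array_equal(mask.grid, gt.true_mask.grid)
        cc = chromatic_coordinates(masked_mean_dn(img, gt.true_mask))
        assert cc.g_cc == pytest.approx(gt.true_mean_indices.g_cc, abs=1 / 255)
        assert cc.r_cc == pytest.approx(gt.true_mean_indices.r_cc, abs=1 / 255)


def test_soil_pixels_fail_hue_test(quiet_green_archetype, noise_free_config):
    cfg = dataclasses.replace(
        noise_free_config, background_classes=("soil",), background_fraction=0.5
    )
    p = seasonal_color_params(quiet_green_archetype, 180, 0.0)
    img, gt = render_canopy(p, cfg, seed=2)
    soil_pixels = img[~gt.true_mask.grid]
    assert (soil_pixels == np.array([120, 80, 40])).all()
    mask = segment_vegetation(img)
    assert not mask.grid[~gt.true_mask.grid].any()


def test_traits_monotone_and_bounded():
    arches = default_archetypes()
    cfg = SimulationConfig(
        design=build_design("2022"), trait_noise_frac=0.0, archetypes=arches
    )
    for sp, arch in arches.items():
        plot = PlotUnit("p", sp, "drought", "late", 1)
        spad0, sla0 = simulate_traits(plot, 0.0, cfg, seed=0)
        spad1, sla1 = simulate_traits(plot, 1.0, cfg, seed=0)
        assert spad0 > spad1 and sla0 > sla1
        # fully stressed, noise-free SLA sits at the species drought floor
        assert 12.13 <= sla1 <= 17.45
    noisy = dataclasses.replace(cfg, trait_noise_frac=0.05)
    plot = PlotUnit("p", "euonymus", "drought", "late", 1)
    lo, hi = arches["euonymus"].spad_range
    draws = [simulate_traits(plot, 0.5, noisy, seed=s)[0] for s in range(300)]
    assert all(lo <= d <= hi for d in draws)


def test_photo_calendar_2022_has_19_dates():
    cfg = SimulationConfig(design=build_design("2022"))
    dates = photo_dates(cfg)
    assert len(dates) == 19
    assert dates[0] == dt.date(2022, 4, 1) and dates[-1] <= dt.date(2022, 9, 30)


def test_dataset_rows_equal_plots_times_dates(noise_free_config):
    bundle = generate_dataset(noise_free_config)
    n_dates = len(photo_dates(noise_free_config))
    n_plots = noise_free_config.design.n_plots
    assert len(bundle.metadata) == n_plots * n_dates
    assert len(bundle.images) == n_plots * n_dates
    assert set(bundle.swc.columns) == {"plot_id", "date", "swc_percent"}


def test_dataset_reproducible_for_fixed_seed(noise_free_config):
    a = generate_dataset(noise_free_config)
    b = generate_dataset(noise_free_config)
    assert a.metadata.to_csv(index=False) == b.metadata.to_csv(index=False)
    assert a.swc.to_csv(index=False) == b.swc.to_csv(index=False)
    key = next(iter(a.images))
    np.testing.assert_array_equal(a.images[key], b.images[key])


def test_imposed_stress_coupling_is_recoverable():
    """Regressing the pipeline-extracted dominant index on the generator's
    target recovers slope 1 within 5% at default noise."""
    from canopycc.indices import extract_index_record

    arch = dataclasses.replace(
        default_archetypes()["euonymus"], swc_sensitivity=0.3, index_floor=0.15
    )
    design = build_design(
        "t", species=("euonymus",), treatments=("full", "drought"),
        periods=("late",), replicates=4,
    )
    cfg = SimulationConfig(
        design=design, archetypes={"euonymus": arch}, image_size=(24, 24),
        season_start=(8, 1), season_end=(9, 30),
        background_classes=("bright", "gray"), seed=42,
    )
    bundle = generate_dataset(cfg)
    targets, extracted = [], []
    for row in bundle.metadata.itertuples(index=False):
        rec = extract_index_record(
            bundle.images[(row.plot_id, row.date)], WIDE_THRESHOLDS, row._asdict()
        )
        gt = bundle.ground_truth[(row.plot_id, row.date)]
        targets.append(gt.true_mean_indices.g_cc)
        extracted.append(rec.cc.g_cc)
    fit = linear_r2(np.array(targets), np.array(extracted))
    assert fit.slope == pytest.approx(1.0, abs=0.05)
    assert fit.r2 > 0.95
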