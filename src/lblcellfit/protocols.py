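"""Condition-level reference protocols.

Each function runs one complete generate -> analyze chain at the study's
standard settings and returns the condition-level statistic a benchmark
or report would quote: single-cell and population lag means, expression
and size ratios, viability percentages, and electrokinetic parameter
recovery.  Both the test suite and the reproduction script call these,
so the numbers they quote always come from the same code path.
"""

from __future__ import annotations

import numpy as np

from .electrophoresis import (
    SoftParticleParams,
    fit_soft_particle,
    smoluchowski_zeta,
    zeta_to_mobility,
)
from .growth_kinetics import GrowthCurve, estimate_lag, normalize_plate_signals
from .imaging import ImagingConfig, binarize, biomass_series, per_cell_measurements
from .pipeline import viability_fraction
from .presets import ZETA_PRESETS
from .synthetic_data import (
    default_ionic_strength_grid,
    simulate_colony_stack,
    simulate_mobility_series,
    simulate_plate,
    simulate_plate_growth,
)

LAG_SETTINGS = dict(min_points=3, r2_drop=0.01)


def single_cell_lag_min(preset: str, seeds=(1, 2, 3), n_cells0: int = 15) -> list[float]:
    """Per-seed two-line lag estimates (min) from rendered colony movies.

    Full pipeline: agent simulation -> rendering -> Otsu binarization ->
    8-connected particle areas -> two-segment regression on the biomass
    series.
    """
    cfg = ImagingConfig()
    lams = []
    for seed in seeds:
        stack, _ = simulate_colony_stack(preset, n_cells0=n_cells0, seed=seed)
        biomass = biomass_series(stack, channel="gfp", cfg=cfg)
        curve = GrowthCurve(
            time=biomass["time_min"].to_numpy(),
            signal=biomass["total_area_um2"].to_numpy(),
            time_unit="min",
            signal_unit="um2",
        )
        lams.append(estimate_lag(curve, **LAG_SETTINGS).lambda_lag)
    return lams


def population_lag_h(preset: str, seed: int = 7, n_replicates: int = 3) -> list[float]:
    """Per-well lag estimates (h) from blank-corrected plate OD curves."""
    table, _ = simulate_plate(
        presets=(preset,), n_replicates=n_replicates, n_blank=3, seed=seed
    )
    norm = normalize_plate_signals(table, control_condition=preset)
    lams = []
    for rep in range(n_replicates):
        sub = norm[
            (norm["condition"] == preset) & (norm["replicate"] == rep)
        ].sort_values("time_h")
        curve = GrowthCurve(
            time=sub["time_h"].to_numpy(), signal=sub["od_norm"].to_numpy()
        )
        lams.append(estimate_lag(curve, **LAG_SETTINGS).lambda_lag)
    return lams


def peak_normalized_fluorescence(
    condition: str, noise: bool = False, seed: int = 0
) -> float:
    """Max over time of control-normalized fluorescence for a condition."""
    import dataclasses

    from .presets import PLATE_PRESETS

    if noise:
        presets = ["control", condition]
    else:
        presets = [
            dataclasses.replace(PLATE_PRESETS[n], noise_sd=0.0)
            for n in ("control", condition)
        ]
    table, _ = simulate_plate(presets=presets, n_replicates=3, seed=seed)
    norm = normalize_plate_signals(table)
    sub = norm[norm["condition"] == condition]
    return float(sub.groupby("time_h")["fluor_norm"].mean().max())


def stalled_phenotype_ratios(seed: int = 11, n_cells0: int = 15) -> dict[str, float]:
    """Entrapped-vs-control GFP intensity and length ratios.

    The stalled condition is measured on its final frame (phenotype fully
    relaxed); the control on a frame at the end of its lag, while cells
    are still optically separable single rods.  GFP levels are constant
    over time in the generator, so the intensity ratio does not depend
    on the control frame choice.
    """
    stack_s, _ = simulate_colony_stack("stalled8", n_cells0=n_cells0, seed=seed)
    stack_c, _ = simulate_colony_stack(
        "control", n_cells0=n_cells0, duration=60.0, seed=seed
    )

    def measure(stack):
        img = stack.frame("gfp", stack.n_frames - 1)
        return per_cell_measurements(
            binarize(img), {"gfp": img}, pixel_size=stack.pixel_size
        )

    stalled = measure(stack_s)
    control = measure(stack_c)
    return {
        "intensity_ratio": float(
            stalled["mean_gfp"].mean() / control["mean_gfp"].mean()
        ),
        "length_ratio": float(
            stalled["length_um"].mean() / control["length_um"].mean()
        ),
    }


def viable_growth_percent(seed: int = 13, n_cells0: int = 110) -> float:
    """Percent of founding cells whose measured area grows over the movie.

    All-viable encapsulated condition (4 layers, nothing stalled); growth
    means the matched particle area rises by more than 10% between the
    first and last frames.
    """
    stack, truth = simulate_colony_stack("layers4", n_cells0=n_cells0, seed=seed)
    return 100.0 * viability_fraction(stack, truth, growth_threshold=0.10)


def mobility_recovery(
    noise_fraction: float = 0.0,
    n_seeds: int = 1,
    truth: SoftParticleParams | None = None,
    seed0: int = 0,
) -> dict[str, float]:
    """Relative errors of (ZN, 1/lambda) recovered from ISDEM series."""
    truth = truth or SoftParticleParams(zn_molar=-0.05, softness_nm=2.0)
    base, _ = simulate_mobility_series(truth, noise_sd=0.0)
    sd = noise_fraction * float(np.abs(base.mobility).max())
    zn_err, soft_err = [], []
    for k in range(n_seeds):
        series, _ = simulate_mobility_series(truth, noise_sd=sd, seed=seed0 + k)
        fit = fit_soft_particle(series)
        zn_err.append(abs(fit.params.zn_molar - truth.zn_molar) / abs(truth.zn_molar))
        soft_err.append(
            abs(fit.params.softness_nm - truth.softness_nm) / truth.softness_nm
        )
    return {
        "zn_relative_error_median": float(np.median(zn_err)),
        "softness_relative_error_median": float(np.median(soft_err)),
    }


def coated_cell_zeta_roundtrip_mv(preset: str = "pei_coated") -> float:
    """Zeta potential (mV) from the Smoluchowski round trip.

    The generator synthesizes the mobility a coated cell with the
    preset's stated zeta potential would show at the lowest ionic
    strength of the measurement grid; the conversion maps it back.
    """
    zeta_true_v = ZETA_PRESETS[preset].zeta_mv * 1e-3
    ionic_min = float(default_ionic_strength_grid()[0])  # measurement point
    mobility = zeta_to_mobility(zeta_true_v)
    # mobility is ionic-strength independent under Smoluchowski; the grid
    # point documents where the synthetic measurement is taken
    assert ionic_min > 0
    return float(smoluchowski_zeta(mobility)) * 1e3
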