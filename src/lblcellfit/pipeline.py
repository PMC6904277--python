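"""End-to-end orchestration: generate -> analyze -> compare, reproducibly.

A single `AnalysisConfig` (YAML/JSON-loadable) names the presets, seeds
and estimator settings for a run; `run_endtoend` executes the stages and
writes a `RunReport` (JSON plus CSV tables) whose stochastic content is
byte-identical for a fixed config.  Every report carries the SHA-256
hash of its canonical config so numbers are traceable to settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import (
    ImagingConfig,
    binarize,
    biomass_series,
    colony_shape_descriptor,
    compare_groups,
    per_cell_measurements,
)
from .growth_kinetics import (
    GrowthCurve,
    LagEstimationError,
    compare_conditions,
    curves_from_plate,
    estimate_lag,
    fit_logistic,
    normalize_plate_signals,
    peak_fluorescence_ratio,
)
from .electrophoresis import fit_soft_particle
from .presets import COLONY_PRESETS, PLATE_PRESETS, RenderConfig
from .synthetic_data import (
    simulate_colony_stack,
    simulate_mobility_series,
    simulate_plate,
)
from .synthetic_data.mobility import DEFAULT_TRUE_PARAMS

logger = logging.getLogger("lblcellfit")


class PipelineStageError(RuntimeError):
    """Wraps a failure with the stage name and offending inputs."""

    def __init__(self, stage: str, detail: str, cause: Exception | None = None):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")
        self.__cause__ = cause


@dataclass
class AnalysisConfig:
    """Settings for one reproducible run."""

    seed: int = 1
    out_dir: str = "runs/demo"
    colony_presets: tuple[str, ...] = ("control", "layers8")
    colony_replicates: int = 2
    n_cells0: int = 12
    dt_min: float = 5.0
    duration_min: float | None = None
    plate_presets: tuple[str, ...] = (
        "control", "bilayers1", "bilayers2", "bilayers3", "bilayers4",
    )
    plate_replicates: int = 3
    n_blank: int = 3
    run_mobility: bool = True
    mobility_noise_sd: float = 0.0
    binarize_method: str = "otsu"
    min_area_px: int = 5
    lag_min_points: int = 3
    lag_r2_drop: float = 0.01
    lag_scale: str = "log"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        self.colony_presets = tuple(self.colony_presets)
        self.plate_presets = tuple(self.plate_presets)
        unknown = [p for p in self.colony_presets if p not in COLONY_PRESETS]
        unknown += [p for p in self.plate_presets if p not in PLATE_PRESETS]
        if unknown:
            raise ValueError(f"unknown presets: {unknown}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All condition-level results of a run plus provenance."""

    config: dict
    config_hash: str
    versions: dict
    plate: dict = field(default_factory=dict)
    colony: dict = field(default_factory=dict)
    mobility: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "config": self.config,
                "config_hash": self.config_hash,
                "versions": self.versions,
                "plate": self.plate,
                "colony": self.colony,
                "mobility": self.mobility,
                "morphometry": self.morphometry,
            },
            indent=indent,
            sort_keys=True,
            default=_json_default,
        )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            logger.info("stage %s: %.2f s", stage, dt)
            return False

    return _Timer()


def analyze_plate_stage(config: AnalysisConfig) -> tuple[dict, pd.DataFrame]:
    table, truths = simulate_plate(
        presets=config.plate_presets,
        n_replicates=config.plate_replicates,
        n_blank=config.n_blank,
        seed=config.seed,
    )
    norm = normalize_plate_signals(table)
    rows = []
    for curve in curves_from_plate(norm):
        try:
            lag = estimate_lag(
                curve,
                min_points=config.lag_min_points,
                r2_drop=config.lag_r2_drop,
                scale=config.lag_scale,
            )
            lam = lag.lambda_lag
        except LagEstimationError:
            lam = float("nan")
        fit = fit_logistic(curve)
        rows.append(
            {
                "condition": curve.condition,
                "replicate": curve.replicate,
                "lambda_lag_h": lam,
                **{f"{k}": v for k, v in fit.as_dict().items()},
            }
        )
    params = pd.DataFrame(rows)
    summary, tests = compare_conditions(params)
    fluor = {
        cond: peak_fluorescence_ratio(table, cond)
        for cond in config.plate_presets
        if cond != "control"
    }
    result = {
        "lag_mean_h": params.groupby("condition")["lambda_lag_h"].mean().to_dict(),
        "lag_sd_h": params.groupby("condition")["lambda_lag_h"].std().to_dict(),
        "peak_fluor_ratio": fluor,
        "t_tests": tests.to_dict(orient="records"),
        "truth_lag_h": {k: v.lag_h for k, v in truths.items()},
    }
    return result, params


def analyze_colony_stage(config: AnalysisConfig) -> tuple[dict, pd.DataFrame]:
    imcfg = ImagingConfig(
        method=config.binarize_method, min_area_px=config.min_area_px
    )
    rows = []
    shapes = {}
    for preset in config.colony_presets:
        for rep in range(config.colony_replicates):
            seed = config.seed + rep
            stack, truth = simulate_colony_stack(
                preset,
                n_cells0=config.n_cells0,
                duration=config.duration_min,
                dt=config.dt_min,
                seed=seed,
            )
            biomass = biomass_series(stack, channel="gfp", cfg=imcfg)
            curve = GrowthCurve(
                time=biomass["time_min"].to_numpy(),
                signal=biomass["total_area_um2"].to_numpy(),
                time_unit="min",
                signal_unit="um2",
                condition=preset,
                replicate=rep,
            )
            try:
                lag = estimate_lag(
                    curve,
                    min_points=config.lag_min_points,
                    r2_drop=config.lag_r2_drop,
                    scale=config.lag_scale,
                )
                lam = lag.lambda_lag
            except LagEstimationError:
                lam = float("nan")
            last = binarize(
                stack.frame("gfp", stack.n_frames - 1), config.binarize_method
            )
            rows.append(
                {
                    "condition": preset,
                    "replicate": rep,
                    "seed": seed,
                    "lambda_lag_min": lam,
                    "lag_true_min": truth.lag_true_min,
                    "final_biomass_um2": float(
                        biomass["total_area_um2"].iloc[-1]
                    ),
                    "n_divisions": truth.n_divisions,
                    "shape_descriptor": colony_shape_descriptor(last),
                }
            )
        shapes[preset] = float(
            np.mean([r["shape_descriptor"] for r in rows if r["condition"] == preset])
        )
    params = pd.DataFrame(rows)
    result = {
        "lag_mean_min": params.groupby("condition")["lambda_lag_min"].mean().to_dict(),
        "lag_sd_min": params.groupby("condition")["lambda_lag_min"].std().to_dict(),
        "lag_true_min": params.groupby("condition")["lag_true_min"].first().to_dict(),
        "shape_descriptor": shapes,
    }
    return result, params


def analyze_morphometry_stage(config: AnalysisConfig) -> dict:
    """Entrapped (stalled) vs control single-cell size and expression."""
    stack_s, _ = simulate_colony_stack(
        "stalled8", n_cells0=config.n_cells0, seed=config.seed
    )
    stack_c, _ = simulate_colony_stack(
        "control",
        n_cells0=config.n_cells0,
        duration=60.0,
        seed=config.seed,
    )

    def measure(stack, frame):
        img = stack.frame("gfp", frame)
        mask = binarize(img, config.binarize_method)
        return per_cell_measurements(
            mask, {"gfp": img}, pixel_size=stack.pixel_size,
            min_area_px=config.min_area_px,
        )

    stalled = measure(stack_s, stack_s.n_frames - 1)
    control = measure(stack_c, stack_c.n_frames - 1)
    comp = compare_groups(
        stalled, control,
        columns=("length_um", "width_um", "mean_gfp"),
        labels=("stalled", "control"),
    )
    return {
        "intensity_ratio": float(
            stalled["mean_gfp"].mean() / control["mean_gfp"].mean()
        ),
        "length_ratio": float(
            stalled["length_um"].mean() / control["length_um"].mean()
        ),
        "width_ratio": float(
            stalled["width_um"].mean() / control["width_um"].mean()
        ),
        "tests": comp.to_dict(orient="records"),
    }


def viability_fraction(
    stack,
    truth,
    growth_threshold: float = 0.10,
    method: str = "otsu",
) -> float:
    """Fraction of founding cells whose measured area grows over the movie.

    Each founding cell is matched to the segmented particle under its
    centroid in the first frame and to the particle under one of its
    descendants' centroids in the last frame; it counts as growing when
    the particle area rises by more than `growth_threshold` (fractional).
    This is the imaging-based viability readout: a cell that never
    elongates or divides keeps a constant footprint.
    """
    from collections import defaultdict

    from skimage import measure as skmeasure

    px = stack.pixel_size
    tab = truth.table
    last_f = int(tab["frame"].max())

    def labelled(frame):
        mask = binarize(stack.frame("gfp", frame), method).mask
        lbl = skmeasure.label(mask, connectivity=2)
        return lbl, np.bincount(lbl.ravel())

    lbl0, areas0 = labelled(0)
    lbl1, areas1 = labelled(last_f)
    h, w = lbl0.shape

    def particle_area(lbl, areas, x, y):
        i = min(max(int(y / px), 0), h - 1)
        j = min(max(int(x / px), 0), w - 1)
        lab = lbl[i, j]
        return float(areas[lab]) * px * px if lab else 0.0

    first = tab[tab["frame"] == 0].set_index("cell_id")
    last = tab[tab["frame"] == last_f]
    parent = dict(zip(tab["cell_id"], tab["parent"]))

    def lineage_root(cid):
        while parent.get(cid, -1) != -1:
            cid = parent[cid]
        return cid

    descendants = defaultdict(list)
    for cid in last["cell_id"].unique():
        descendants[lineage_root(cid)].append(cid)

    growing = 0
    total = 0
    for cid in truth.initial_ids:
        total += 1
        a0 = particle_area(
            lbl0, areas0, first.loc[cid, "x_um"], first.loc[cid, "y_um"]
        )
        kids = descendants.get(cid, [])
        if not kids or a0 == 0.0:
            continue
        # a lineage may straddle particles (or partly leave the field):
        # take the largest particle any descendant centroid falls in
        sub = last[last["cell_id"].isin(kids)]
        a1 = max(
            particle_area(lbl1, areas1, row["x_um"], row["y_um"])
            for _, row in sub.iterrows()
        )
        if a1 > (1.0 + growth_threshold) * a0:
            growing += 1
    return growing / total if total else float("nan")


def analyze_mobility_stage(config: AnalysisConfig) -> dict:
    series, truth = simulate_mobility_series(
        DEFAULT_TRUE_PARAMS, noise_sd=config.mobility_noise_sd, seed=config.seed
    )
    fit = fit_soft_particle(series)
    return {
        "zn_molar": fit.params.zn_molar,
        "softness_nm": fit.params.softness_nm,
        "zn_true": truth.params.zn_molar,
        "softness_true_nm": truth.params.softness_nm,
        "stderr_zn": fit.stderr_zn,
        "stderr_softness_nm": fit.stderr_softness,
        "rss": fit.rss,
    }


def run_endtoend(config: AnalysisConfig, write: bool = True) -> RunReport:
    """Execute the configured stages and (optionally) write the report."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    report = RunReport(
        config=config.to_dict(),
        config_hash=config.config_hash,
        versions={
            "lblcellfit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )
    out = Path(config.out_dir)

    stages = []
    if config.plate_presets:
        stages.append(("plate", analyze_plate_stage))
    if config.colony_presets:
        stages.append(("colony", analyze_colony_stage))
        stages.append(("morphometry", lambda c: (analyze_morphometry_stage(c), None)))
    if config.run_mobility:
        stages.append(("mobility", lambda c: (analyze_mobility_stage(c), None)))

    for name, fn in stages:
        with _timed(name):
            try:
                result, params = fn(config)
            except Exception as exc:  # surface the stage context
                raise PipelineStageError(name, str(exc), exc) from exc
        setattr(report, name, result)
        if write and params is not None:
            out.mkdir(parents=True, exist_ok=True)
            params.to_csv(out / f"{name}_params.csv", index=False)

    if write:
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
    return report
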