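"""Synthetic plate-reader growth and fluorescence curves.

The well signal follows a delayed logistic: optical density stays at the
inoculum level N0 (on top of the medium blank) for `lag_true` hours and
then rises logistically to the carrying capacity K at intrinsic rate r.
Fluorescence is proportional to blank-corrected OD through a fixed gain,
scaled by the condition's expression factor relative to the control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..constants import FLUOR_GAIN_RFU_PER_OD
from ..presets import PlatePreset, PLATE_PRESETS


@dataclass(frozen=True)
class PlateGroundTruth:
    """True parameters behind a set of simulated wells."""

    preset: PlatePreset
    lag_h: float
    r_per_h: float
    K_od: float
    N0_od: float
    fluor_factor: float
    fluor_gain: float
    seed: int


def delayed_logistic(t, K, N0, r, lag):
    """Logistic OD trajectory with a hard lag delay (blank-free)."""
    t = np.asarray(t, dtype=float)
    a = (K - N0) / N0
    return K / (1.0 + a * np.exp(-r * np.maximum(0.0, t - lag)))


def logistic_tmid(K, N0, r, lag=0.0):
    """Closed-form time at which the curve reaches K/2."""
    return lag + np.log((K - N0) / N0) / r


def simulate_plate_growth(
    preset: PlatePreset | str,
    n_replicates: int = 3,
    t_grid=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlateGroundTruth]:
    """Simulate replicate wells for one condition.

    Returns a tidy table (time_h, od, fluorescence, condition, replicate)
    and the ground truth.  The default grid is 0-16 h in 20-min steps,
    i.e. 49 rows per replicate.
    """
    if isinstance(preset, str):
        preset = PLATE_PRESETS[preset]
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if t_grid is None:
        t_grid = default_time_grid_h()
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    rng = np.random.default_rng(seed)
    clean = delayed_logistic(t, preset.K_true, preset.N0_true, preset.r_true, preset.lag_true)
    gain = FLUOR_GAIN_RFU_PER_OD
    rows = []
    for rep in range(n_replicates):
        od = preset.blank_od + clean + rng.normal(0.0, preset.noise_sd, t.size)
        fluor = (
            preset.fluor_factor * gain * clean
            + rng.normal(0.0, gain * preset.noise_sd, t.size)
        )
        rows.append(
            pd.DataFrame(
                {
                    "time_h": t,
                    "od": od,
                    "fluorescence": fluor,
                    "condition": preset.name,
                    "replicate": rep,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = PlateGroundTruth(
        preset=preset,
        lag_h=preset.lag_true,
        r_per_h=preset.r_true,
        K_od=preset.K_true,
        N0_od=preset.N0_true,
        fluor_factor=preset.fluor_factor,
        fluor_gain=gain,
        seed=seed,
    )
    return table, truth


def simulate_plate(
    presets=("control", "bilayers1", "bilayers2", "bilayers3", "bilayers4"),
    n_replicates: int = 3,
    n_blank: int = 3,
    t_grid=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, PlateGroundTruth]]:
    """Simulate a whole plate: several conditions plus sterile blank wells.

    Blank wells carry the medium OD (with the control preset's noise) and
    zero-mean fluorescence noise; their condition label is ``blank``.
    """
    if t_grid is None:
        t_grid = default_time_grid_h()
    t = np.asarray(t_grid, dtype=float)
    tables = []
    truths: dict[str, PlateGroundTruth] = {}
    for i, name in enumerate(presets):
        tab, truth = simulate_plate_growth(
            name, n_replicates=n_replicates, t_grid=t, seed=seed + i
        )
        tables.append(tab)
        truths[truth.preset.name] = truth

    ref = PLATE_PRESETS[presets[0]] if isinstance(presets[0], str) else presets[0]
    rng = np.random.default_rng(seed + len(list(presets)))
    gain = FLUOR_GAIN_RFU_PER_OD
    for rep in range(n_blank):
        tables.append(
            pd.DataFrame(
                {
                    "time_h": t,
                    "od": ref.blank_od + rng.normal(0.0, ref.noise_sd, t.size),
                    "fluorescence": rng.normal(0.0, gain * ref.noise_sd, t.size),
                    "condition": "blank",
                    "replicate": rep,
                }
            )
        )
    return pd.concat(tables, ignore_index=True), truths


def default_time_grid_h() -> np.ndarray:
    """16 h of incubation read every 20 min: 49 time points."""
    return np.arange(0.0, 16.0 + 1e-9, 1.0 / 3.0)
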