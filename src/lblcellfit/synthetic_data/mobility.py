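"""Synthetic ionic-strength-dependent electrophoretic mobility (ISDEM) series.

Mobilities follow the soft-particle forward model on the measurement
grid of the electrophoresis protocol: NaCl ionic strengths from
0.00062 M to 0.11 M in 12 steps, with additive Gaussian measurement
noise.  Conductivity standards for the instrument calibration line can
be generated alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..electrophoresis import MobilitySeries, SoftParticleParams, ohshima_mobility

# molar conductivity of dilute aqueous NaCl at 25 C, mS/cm per mol/L
NACL_CONDUCTIVITY_MS_CM_PER_M = 126.4

DEFAULT_TRUE_PARAMS = SoftParticleParams(zn_molar=-0.05, softness_nm=2.0)


@dataclass(frozen=True)
class MobilityGroundTruth:
    params: SoftParticleParams
    noise_sd: float
    seed: int


def default_ionic_strength_grid() -> np.ndarray:
    """The protocol's 12-point linear NaCl gradient, 0.00062-0.11 M."""
    return np.linspace(0.00062, 0.11, 12)


def simulate_mobility_series(
    params_true: SoftParticleParams = DEFAULT_TRUE_PARAMS,
    grid=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[MobilitySeries, MobilityGroundTruth]:
    """Forward-model mobilities on `grid` plus Gaussian noise (SI units)."""
    I = default_ionic_strength_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(I <= 0):
        raise ValueError("ionic strengths must be positive")
    rng = np.random.default_rng(seed)
    mu = ohshima_mobility(params_true, I)
    mu = mu + rng.normal(0.0, noise_sd, I.size)
    series = MobilitySeries(
        ionic_strength_m=I,
        mobility=mu,
        temperature_k=params_true.temperature_k,
        conductivity_ms_cm=I * NACL_CONDUCTIVITY_MS_CM_PER_M,
    )
    return series, MobilityGroundTruth(params=params_true, noise_sd=noise_sd, seed=seed)


def simulate_conductivity_standards(
    concentrations_m=None,
    rel_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """NaCl standards table (concentration_m, conductivity_ms_cm)."""
    if concentrations_m is None:
        concentrations_m = np.geomspace(0.0005, 0.15, 8)
    c = np.asarray(concentrations_m, dtype=float)
    rng = np.random.default_rng(seed)
    cond = c * NACL_CONDUCTIVITY_MS_CM_PER_M
    cond = cond * (1.0 + rng.normal(0.0, rel_noise, c.size))
    return pd.DataFrame({"concentration_m": c, "conductivity_ms_cm": cond})
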