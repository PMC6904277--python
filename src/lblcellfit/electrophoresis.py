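"""Soft-particle electrokinetics: forward model, inversion, calibration.

A bacterial cell is modelled as a hard core coated with an ion- and
water-permeable polymer layer carrying a uniform volume charge density
rho_fix = z e N (the layer's charge groups) and a hydrodynamic softness
1/lambda_soft, the characteristic depth to which electro-osmotic flow
penetrates the layer.  For such a particle the electrophoretic mobility
in a symmetric z:z electrolyte is

    mu = (eps_r eps_0 / eta) * (psi_0/kappa_m + psi_DON/lambda_soft)
                             / (1/kappa_m + 1/lambda_soft)
         + rho_fix / (eta lambda_soft^2)

where psi_DON and psi_0 are the Donnan and layer-surface potentials and
kappa_m is the Debye parameter inside the charged layer.  The charge
density is parameterized as ZN, the signed molar concentration of
elementary charges in the layer (mol/L), which keeps fitted magnitudes
O(0.01-0.1) and converts to C/m^3 via Faraday's constant.

Fitting ZN and 1/lambda_soft from an ionic-strength-dependent mobility
series (ISDEM) is a small nonlinear least-squares problem; the objective
has shallow valleys in the softness direction, so the fit is multi-start
over a log-spaced grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    DEFAULT_RELATIVE_PERMITTIVITY,
    DEFAULT_TEMPERATURE_K,
    DEFAULT_VALENCE,
    DEFAULT_VISCOSITY_PA_S,
    ELEMENTARY_CHARGE,
    FARADAY,
    VACUUM_PERMITTIVITY,
)

# documented search range for the multi-start grid
ZN_RANGE_M = (0.001, 0.5)
SOFTNESS_RANGE_NM = (0.1, 10.0)


@dataclass(frozen=True)
class SoftParticleParams:
    """Surface-layer parameters of the soft-particle model.

    zn_molar: signed volume charge density of the layer, mol/L of
        elementary charges (negative for a bacterial surface).
    softness_nm: 1/lambda_soft in nm.
    """

    zn_molar: float
    softness_nm: float
    temperature_k: float = DEFAULT_TEMPERATURE_K
    relative_permittivity: float = DEFAULT_RELATIVE_PERMITTIVITY
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S
    valence: int = DEFAULT_VALENCE

    def __post_init__(self) -> None:
        if self.softness_nm <= 0:
            raise ValueError("softness must be positive")
        if self.relative_permittivity <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("medium constants must be positive")


@dataclass
class MobilitySeries:
    """Ionic-strength-dependent mobility measurements (SI mobility units)."""

    ionic_strength_m: np.ndarray  # mol/L
    mobility: np.ndarray  # m^2 V^-1 s^-1, signed
    temperature_k: float = DEFAULT_TEMPERATURE_K
    conductivity_ms_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ionic_strength_m = np.asarray(self.ionic_strength_m, dtype=float)
        self.mobility = np.asarray(self.mobility, dtype=float)
        if self.ionic_strength_m.shape != self.mobility.shape:
            raise ValueError("ionic strength and mobility must align")
        if np.any(self.ionic_strength_m <= 0):
            raise ValueError("ionic strengths must be positive")


@dataclass
class ConductivityCalibration:
    """Linear map from conductivity (mS/cm) to NaCl concentration (mol/L)."""

    slope: float  # mol/L per mS/cm
    intercept: float  # mol/L
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def debye_parameter(
    ionic_strength_m,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    relative_permittivity: float = DEFAULT_RELATIVE_PERMITTIVITY,
    valence: int = DEFAULT_VALENCE,
):
    """Debye-Hueckel parameter kappa (1/m) for a z:z electrolyte."""
    I = np.asarray(ionic_strength_m, dtype=float)
    if np.any(I <= 0):
        raise ValueError("ionic strength must be positive")
    num = 2.0 * ELEMENTARY_CHARGE**2 * AVOGADRO * (1000.0 * I) * valence**2
    den = relative_permittivity * VACUUM_PERMITTIVITY * BOLTZMANN * temperature_k
    return np.sqrt(num / den)


def donnan_and_surface_potential(
    zn_molar,
    ionic_strength_m,
    valence: int = DEFAULT_VALENCE,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    relative_permittivity: float = DEFAULT_RELATIVE_PERMITTIVITY,
):
    """Donnan potential, layer-surface potential (V) and kappa_m (1/m).

    With x = ZN / (2 z c) (c the bulk electrolyte molarity, c = I/z^2):

        psi_DON = (kT / z e) asinh(x)
        psi_0   = psi_DON + (kT / z e) (1 - sqrt(x^2 + 1)) / x
        kappa_m = kappa (1 + x^2)^(1/4)

    The uncharged limit x -> 0 gives (0, 0, kappa).
    """
    I = np.asarray(ionic_strength_m, dtype=float)
    zn = np.asarray(zn_molar, dtype=float)
    kt_over_ze = BOLTZMANN * temperature_k / (valence * ELEMENTARY_CHARGE)
    c = I / valence**2
    x = zn / (2.0 * valence * c)
    psi_don = kt_over_ze * np.arcsinh(x)
    # (1 - sqrt(x^2+1))/x -> 0 as x -> 0; expand where x is tiny
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(
            np.abs(x) > 1e-8,
            (1.0 - np.sqrt(x**2 + 1.0)) / np.where(x == 0.0, 1.0, x),
            -x / 2.0,
        )
    psi_0 = psi_don + kt_over_ze * corr
    kappa = debye_parameter(I, temperature_k, relative_permittivity, valence)
    kappa_m = kappa * (1.0 + x**2) ** 0.25
    return psi_don, psi_0, kappa_m


def ohshima_mobility(
    params: SoftParticleParams,
    ionic_strength_m,
    temperature_k: float | None = None,
):
    """Forward soft-particle mobility (m^2 V^-1 s^-1) at given ionic strength."""
    T = params.temperature_k if temperature_k is None else temperature_k
    psi_don, psi_0, kappa_m = donnan_and_surface_potential(
        params.zn_molar,
        ionic_strength_m,
        valence=params.valence,
        temperature_k=T,
        relative_permittivity=params.relative_permittivity,
    )
    lam = 1.0 / (params.softness_nm * 1e-9)  # lambda_soft, 1/m
    eps = params.relative_permittivity * VACUUM_PERMITTIVITY
    rho_fix = FARADAY * 1000.0 * params.zn_molar  # C/m^3
    membrane = (eps / params.viscosity_pa_s) * (
        (psi_0 / kappa_m + psi_don / lam) / (1.0 / kappa_m + 1.0 / lam)
    )
    polymer = rho_fix / (params.viscosity_pa_s * lam**2)
    return membrane + polymer


@dataclass
class SoftParticleFit:
    """Result of fitting (ZN, 1/lambda_soft) to an ISDEM series."""

    params: SoftParticleParams
    residuals: np.ndarray
    rss: float
    stderr_zn: float
    stderr_softness: float
    n_starts: int
    boundary_warning: bool = False
    predicted: np.ndarray = field(default_factory=lambda: np.empty(0))


def fit_soft_particle(
    series: MobilitySeries,
    init_grid: tuple[np.ndarray, np.ndarray] | None = None,
    n_grid: int = 5,
) -> SoftParticleFit:
    """Least-squares inversion of the soft-particle model.

    Multi-start over a log-spaced (|ZN|, softness) grid, with the sign of
    ZN taken from the sign of the measured mobilities; best start wins.
    Standard errors come from the Gauss-Newton curvature at the optimum.
    """
    I = series.ionic_strength_m
    mu = series.mobility
    if I.size < 4:
        raise ValueError("need at least 4 mobility points")
    if np.log10(I.max() / I.min()) < 1.0:
        raise ValueError("ionic strengths must span at least one decade")

    if init_grid is None:
        zn_grid = np.geomspace(*ZN_RANGE_M, n_grid)
        soft_grid = np.geomspace(*SOFTNESS_RANGE_NM, n_grid)
    else:
        zn_grid, soft_grid = (np.asarray(g, dtype=float) for g in init_grid)
    sign = -1.0 if np.mean(mu) < 0 else 1.0

    def resid(theta):
        zn, log_soft = theta
        # clip softness to a physically sensible window so LM line searches
        # cannot overflow exp()
        p = SoftParticleParams(
            zn_molar=zn,
            softness_nm=float(np.exp(np.clip(log_soft, -12.0, 12.0))),
            temperature_k=series.temperature_k,
        )
        return ohshima_mobility(p, I) - mu

    best = None
    for zn0 in zn_grid:
        for s0 in soft_grid:
            try:
                sol = optimize.least_squares(
                    resid,
                    x0=[sign * zn0, np.log(s0)],
                    method="lm",
                    xtol=1e-14,
                    ftol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("soft-particle fit failed to converge from any start")

    zn_hat = float(best.x[0])
    soft_hat = float(np.exp(best.x[1]))
    params = SoftParticleParams(
        zn_molar=zn_hat, softness_nm=soft_hat, temperature_k=series.temperature_k
    )
    res = resid(best.x)
    dof = max(I.size - 2, 1)
    s2 = float(res @ res) / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_zn = float(np.sqrt(cov[0, 0]))
        se_soft = float(np.sqrt(cov[1, 1]) * soft_hat)  # delta method for exp
    except np.linalg.LinAlgError:
        se_zn = se_soft = float("nan")
    boundary = not (
        SOFTNESS_RANGE_NM[0] * 1.001 < soft_hat < SOFTNESS_RANGE_NM[1] * 0.999
    )
    if boundary:
        warnings.warn(
            "fitted softness sits at the edge of the search grid", RuntimeWarning
        )
    return SoftParticleFit(
        params=params,
        residuals=res,
        rss=float(res @ res),
        stderr_zn=se_zn,
        stderr_softness=se_soft,
        n_starts=zn_grid.size * soft_grid.size,
        boundary_warning=boundary,
        predicted=mu + res,
    )


def fit_conductivity_calibration(standards: pd.DataFrame) -> ConductivityCalibration:
    """OLS line mapping conductivity (mS/cm) to NaCl molarity.

    `standards` needs columns ``conductivity_ms_cm`` and ``concentration_m``.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    x = standards["conductivity_ms_cm"].to_numpy(dtype=float)
    y = standards["concentration_m"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float(((y - pred) ** 2).sum()) / sst
    return ConductivityCalibration(slope=float(slope), intercept=float(intercept), r_squared=r2)


def conductivity_to_ionic_strength(
    conductivity_ms_cm,
    calibration: ConductivityCalibration,
    floor_m: float = 1e-6,
):
    """Apply the standard curve; negative ionic strengths clip to a floor."""
    c = calibration.slope * np.asarray(conductivity_ms_cm, dtype=float) + calibration.intercept
    if np.any(c <= 0):
        warnings.warn(
            "calibrated ionic strength non-positive; clipping to floor", RuntimeWarning
        )
    return np.clip(c, floor_m, None)


def smoluchowski_zeta(
    mobility,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    relative_permittivity: float = DEFAULT_RELATIVE_PERMITTIVITY,
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
):
    """Smoluchowski conversion mobility -> zeta potential (V)."""
    eps = relative_permittivity * VACUUM_PERMITTIVITY
    return np.asarray(mobility, dtype=float) * viscosity_pa_s / eps


def zeta_to_mobility(
    zeta_v,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    relative_permittivity: float = DEFAULT_RELATIVE_PERMITTIVITY,
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
):
    """Inverse Smoluchowski relation: zeta potential (V) -> mobility."""
    eps = relative_permittivity * VACUUM_PERMITTIVITY
    return np.asarray(zeta_v, dtype=float) * eps / viscosity_pa_s
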