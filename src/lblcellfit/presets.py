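"""Named experimental conditions driving the synthetic-data generators.

Each preset encodes one condition of the encapsulation study: a colony
preset describes single cells on agar under time-lapse imaging, a plate
preset describes a bulk culture in a microplate well, and a zeta preset
describes the surface potential of bare or polyelectrolyte-coated cells.
The lag means encode the condition-level lag-phase durations of the
study (single cells: 65.2 min control, 111.5 min for 8 layers;
populations: 1.5 h control, 2.5 h for 2-3 bilayers, 5 h for 4 bilayers);
per-layer values in between are linear interpolations.  Cell geometry and
elongation defaults are typical for exponentially growing E. coli on
rich solid medium and are calibrated so that the full
render -> segment -> regress pipeline recovers the encoded lags and
size/fluorescence ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class ColonyPreset:
    """Condition for the agent-based single-cell colony simulation."""

    name: str
    mean_lag: float  # min
    sd_lag: float  # min
    elong_rate: float  # 1/min, growth rate of (length - width)
    division_length_mean: float = 4.5  # μm
    division_length_sd: float = 0.4  # μm
    width_mean: float = 1.0  # μm
    width_sd: float = 0.05  # μm
    gfp_mean: float = 1000.0  # arbitrary intensity units
    gfp_sd: float = 100.0
    stalled_fraction: float = 0.0
    stalled_length_factor: float = 1.0
    stalled_width_factor: float = 1.0
    stalled_gfp_factor: float = 1.0
    adhesion: float = 0.1  # 0 = daughters free to separate, 1 = sticky
    shell_label: bool = False
    n_layers: int = 0

    def __post_init__(self) -> None:
        if self.mean_lag < 0 or self.sd_lag < 0:
            raise ValueError("lag parameters must be non-negative")
        if self.elong_rate < 0:
            raise ValueError("elong_rate must be non-negative")
        if not 0.0 <= self.stalled_fraction <= 1.0:
            raise ValueError("stalled_fraction must be in [0, 1]")
        if not 0.0 <= self.adhesion <= 1.0:
            raise ValueError("adhesion must be in [0, 1]")
        if self.stalled_fraction > 0 and (
            self.stalled_length_factor < 1.0
            or self.stalled_width_factor < 1.0
            or self.stalled_gfp_factor < 1.0
        ):
            raise ValueError("stalled factors must be >= 1 for stalled presets")

    @property
    def default_duration(self) -> float:
        """Movie length: the encoded lag plus ~3 doublings of growth (min)."""
        return self.mean_lag + 85.0


@dataclass(frozen=True)
class PlatePreset:
    """Condition for the synthetic plate-reader growth experiment."""

    name: str
    lag_true: float  # h
    r_true: float = 2.0  # 1/h
    K_true: float = 1.0  # OD units
    N0_true: float = 0.01  # OD units
    fluor_factor: float = 1.0  # per-OD fluorescence relative to control
    noise_sd: float = 0.003  # OD units
    blank_od: float = 0.08  # OD of sterile medium

    def __post_init__(self) -> None:
        if not self.K_true > self.N0_true > 0:
            raise ValueError("require K_true > N0_true > 0")
        if self.r_true <= 0:
            raise ValueError("r_true must be positive")
        if self.fluor_factor <= 0:
            raise ValueError("fluor_factor must be positive")
        if self.lag_true < 0:
            raise ValueError("lag_true must be non-negative")


@dataclass(frozen=True)
class ZetaPreset:
    """Stated zeta potential of a cell surface, in mV."""

    name: str
    zeta_mv: float


@dataclass(frozen=True)
class RenderConfig:
    """Rasterization settings for synthetic micrographs.

    0.1 μm/px on a 512x512 field resolves 1 μm wide rods; the PSF is an
    isotropic Gaussian; output is 16-bit with additive Gaussian noise.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1  # μm/px
    sigma_psf_px: float = 2.0
    background: float = 100.0
    noise_sd: float = 10.0
    shell_amplitude: float = 3000.0
    shell_band_px: float = 1.0  # half-width of the shell outline band
    fov_margin_um: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def _interp_lag(n_layers: int) -> float:
    # linear in layer count between the encoded endpoints 65.2 and 111.5 min
    return 65.2 + (111.5 - 65.2) * n_layers / 8.0


def _interp_sd(n_layers: int) -> float:
    return 9.9 + (1.3 - 9.9) * n_layers / 8.0


COLONY_PRESETS: dict[str, ColonyPreset] = {
    p.name: p
    for p in [
        ColonyPreset(
            name="control", mean_lag=65.2, sd_lag=9.9, elong_rate=0.028,
            adhesion=0.1, shell_label=False, n_layers=0,
        ),
        ColonyPreset(
            name="layers2", mean_lag=_interp_lag(2), sd_lag=_interp_sd(2),
            elong_rate=0.028, adhesion=0.3, shell_label=True, n_layers=2,
        ),
        ColonyPreset(
            name="layers4", mean_lag=_interp_lag(4), sd_lag=_interp_sd(4),
            elong_rate=0.028, adhesion=0.45, shell_label=True, n_layers=4,
        ),
        ColonyPreset(
            name="layers6", mean_lag=_interp_lag(6), sd_lag=_interp_sd(6),
            elong_rate=0.028, adhesion=0.6, shell_label=True, n_layers=6,
        ),
        ColonyPreset(
            name="layers8", mean_lag=111.5, sd_lag=1.3, elong_rate=0.024,
            adhesion=0.7, shell_label=True, n_layers=8,
        ),
        ColonyPreset(
            name="stalled8", mean_lag=111.5, sd_lag=1.3, elong_rate=0.024,
            stalled_fraction=1.0, stalled_length_factor=2.5,
            stalled_width_factor=2.0, stalled_gfp_factor=5.0,
            adhesion=0.8, shell_label=True, n_layers=8,
        ),
    ]
}

PLATE_PRESETS: dict[str, PlatePreset] = {
    p.name: p
    for p in [
        PlatePreset(name="control", lag_true=1.5, fluor_factor=1.0),
        PlatePreset(name="bilayers1", lag_true=1.5, fluor_factor=1.0),
        PlatePreset(name="bilayers2", lag_true=2.5, fluor_factor=1.0),
        PlatePreset(name="bilayers3", lag_true=2.5, fluor_factor=1.2),
        PlatePreset(name="bilayers4", lag_true=5.0, fluor_factor=2.1),
    ]
}

ZETA_PRESETS: dict[str, ZetaPreset] = {
    p.name: p
    for p in [
        ZetaPreset(name="bare_cell", zeta_mv=-30.0),
        ZetaPreset(name="pei_coated", zeta_mv=20.0),
    ]
}


def preset_to_dict(preset) -> dict:
    """Serializable view of any preset dataclass."""
    d = asdict(preset)
    d["preset_type"] = type(preset).__name__
    return d
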