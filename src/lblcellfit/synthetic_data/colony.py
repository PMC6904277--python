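"""Agent-based simulation and rendering of rod-shaped microcolonies.

Cells are spherocylinders (pole-to-pole length L, width W) on a single
focal plane.  Each cell waits out an individually sampled lag, then
elongates exponentially, dL/dt = g (L - W), and divides once it reaches
its sampled division length.  Division splits the rod into two daughters
along the axis with a small angle jitter; the daughter lengths are
chosen so the summed projected spherocylinder area is conserved.
Entrapped ("stalled") cells never divide; instead they relax toward an
enlarged, GFP-bright phenotype (length, width and expression scaled by
the preset factors).  Overlaps are resolved by iterative pairwise
displacement; a preset's adhesion scales the separation step, so sticky
shells yield compact colonies.

Rendering: per-cell spherocylinder masks carrying the cell's GFP level,
Gaussian PSF blur, constant background and additive Gaussian noise,
16-bit.  The shell channel draws a thin band on each cell outline (the
nanometre-scale true shell is far below optical resolution).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from ..presets import ColonyPreset, COLONY_PRESETS, RenderConfig
from ..stacks import ImageStack

STALL_RELAX_TAU_MIN = 45.0  # time constant of the stalled-phenotype relaxation
MIN_DIVISION_LENGTH_WIDTHS = 1.9  # division length must exceed ~2 widths
MAX_RELAX_SWEEPS = 80
OVERLAP_TOLERANCE_FRAC = 0.35  # sweep target: residual overlap / cell width
OVERLAP_ERROR_FRAC = 0.6  # severe interpenetration left after all sweeps


class OverlapRelaxationError(RuntimeError):
    """Raised when pairwise overlap resolution fails to converge."""

    def __init__(self, cell_ids):
        self.cell_ids = sorted(set(int(i) for i in cell_ids))
        super().__init__(
            f"overlap relaxation did not converge for cells {self.cell_ids}"
        )


@dataclass
class CellAgent:
    """State of one simulated rod cell."""

    id: int
    center: np.ndarray  # (x, y) μm
    angle: float  # radians
    length: float  # μm, pole to pole
    width: float  # μm
    t_birth: float  # min
    t_lag_end: float  # min
    elong_rate: float  # 1/min
    gfp_level: float
    n_layers: int = 0
    stalled: bool = False
    division_length: float = math.inf
    parent: int = -1
    # stalled-phenotype targets (set at creation for stalled cells)
    target_length: float = 0.0
    target_width: float = 0.0
    target_gfp: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not self.length >= self.width > 0:
            raise ValueError("require length >= width > 0")
        if self.t_lag_end < self.t_birth:
            raise ValueError("t_lag_end must be >= t_birth")
        if self.gfp_level < 0:
            raise ValueError("gfp_level must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        return np.array([math.cos(self.angle), math.sin(self.angle)])

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Centers of the two spherocap ends of the axis segment."""
        h = 0.5 * (self.length - self.width)
        a = self.axis
        return self.center - h * a, self.center + h * a

    @property
    def area(self) -> float:
        return spherocylinder_area(self.length, self.width)


def spherocylinder_area(length: float, width: float):
    """Projected area of a spherocylinder: (L-W) W + pi (W/2)^2."""
    return (length - width) * width + math.pi * (width / 2.0) ** 2


@dataclass
class ColonyGroundTruth:
    """Per-frame cell tables and the true parameters behind a movie."""

    preset: ColonyPreset
    table: pd.DataFrame  # one row per cell per frame
    lag_true_min: float
    seed: int
    n_divisions: int
    initial_ids: list[int] = field(default_factory=list)

    def frame_table(self, frame: int) -> pd.DataFrame:
        return self.table[self.table["frame"] == frame]


def _segment_distance(p0, p1, q0, q1):
    """Closest points and distance between segments [p0,p1] and [q0,q1]."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-project s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    cp = p0 + s * u
    cq = q0 + t * v
    diff = cp - cq
    return float(np.hypot(*diff)), cp, cq


def _relax_overlaps(cells: list[CellAgent], adhesion: float, rng) -> None:
    """Push overlapping spherocylinders apart; step scaled by 1 - adhesion."""
    if len(cells) < 2:
        return
    step_scale = 1.0 - adhesion
    worst_ids: list[int] = []
    for _ in range(MAX_RELAX_SWEEPS):
        centers = np.array([c.center for c in cells])
        reach = np.array([0.5 * (c.length + c.width) for c in cells])
        tree = cKDTree(centers)
        pairs = tree.query_pairs(r=2.0 * float(reach.max()), output_type="ndarray")
        worst = 0.0
        worst_ids = []
        for i, j in pairs:
            ci, cj = cells[i], cells[j]
            if np.hypot(*(ci.center - cj.center)) > reach[i] + reach[j]:
                continue
            d, cp, cq = _segment_distance(*ci.endpoints, *cj.endpoints)
            overlap = 0.5 * (ci.width + cj.width) - d
            if overlap <= 0:
                continue
            frac = overlap / min(ci.width, cj.width)
            if frac > worst:
                worst = frac
                worst_ids = [ci.id, cj.id]
            if d > 1e-9:
                n = (cp - cq) / d
            else:  # degenerate: separate along the center line or sideways
                dc = ci.center - cj.center
                nd = np.hypot(*dc)
                if nd > 1e-9:
                    n = dc / nd
                else:
                    n = np.array([-math.sin(ci.angle), math.cos(ci.angle)])
            shift = 0.5 * overlap * step_scale
            ci.center = ci.center + n * shift
            cj.center = cj.center - n * shift
        if worst <= OVERLAP_TOLERANCE_FRAC:
            return
    # adhesion close to 1 deliberately leaves cells in contact; otherwise
    # only severe residual interpenetration counts as a failure (dense
    # microcolonies legitimately keep rods pressed together)
    if step_scale > 0.2 and worst > OVERLAP_ERROR_FRAC:
        raise OverlapRelaxationError(worst_ids)


def _clip_to_field(cells: list[CellAgent], cfg: RenderConfig) -> None:
    field_um = np.array([cfg.shape[1], cfg.shape[0]]) * cfg.pixel_size
    escaped = []
    for c in cells:
        lo = -cfg.fov_margin_um
        hi = field_um + cfg.fov_margin_um
        if np.any(c.center < lo) or np.any(c.center > hi):
            escaped.append(c.id)
            c.center = np.clip(c.center, lo, hi)
    if escaped:
        warnings.warn(
            f"cells {escaped} escaped the field of view and were clipped",
            RuntimeWarning,
        )


def _sample_initial_cells(preset: ColonyPreset, n_cells0: int, cfg: RenderConfig, rng):
    field_um = np.array([cfg.shape[1], cfg.shape[0]]) * cfg.pixel_size
    margin = 4.0
    area = float(np.prod(field_um - 2 * margin))
    min_sep = min(3.5, 0.45 * math.sqrt(area / max(n_cells0, 1)))
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_cells0:
        attempts += 1
        if attempts > 200 * n_cells0:
            raise RuntimeError("could not place initial cells without crowding")
        p = margin + rng.random(2) * (field_um - 2 * margin)
        if all(np.hypot(*(p - q)) >= min_sep for q in positions):
            positions.append(p)

    cells = []
    stalled_draw = rng.random(n_cells0) < preset.stalled_fraction
    for i in range(n_cells0):
        width = max(0.6, rng.normal(preset.width_mean, preset.width_sd))
        div_len = max(
            MIN_DIVISION_LENGTH_WIDTHS * width,
            rng.normal(preset.division_length_mean, preset.division_length_sd),
        )
        length = rng.uniform(0.45, 0.8) * div_len
        length = max(length, width * 1.05)
        lag = max(0.0, rng.normal(preset.mean_lag, preset.sd_lag))
        gfp = max(0.0, rng.normal(preset.gfp_mean, preset.gfp_sd))
        stalled = bool(stalled_draw[i])
        cells.append(
            CellAgent(
                id=i,
                center=positions[i],
                angle=rng.uniform(0.0, math.pi),
                length=length,
                width=width,
                t_birth=0.0,
                t_lag_end=lag,
                elong_rate=preset.elong_rate,
                gfp_level=gfp,
                n_layers=preset.n_layers,
                stalled=stalled,
                division_length=div_len,
                target_length=length * preset.stalled_length_factor,
                target_width=width * preset.stalled_width_factor,
                target_gfp=gfp * preset.stalled_gfp_factor,
            )
        )
    return cells


def _step_cells(
    cells: list[CellAgent],
    preset: ColonyPreset,
    t: float,
    dt: float,
    rng,
    next_id: int,
) -> tuple[list[CellAgent], int, int]:
    """Advance one time step; returns (cells, next_id, n_divisions)."""
    relax_frac = 1.0 - math.exp(-dt / STALL_RELAX_TAU_MIN)
    grown: list[CellAgent] = []
    n_div = 0
    for c in cells:
        if c.stalled:
            c.length += (c.target_length - c.length) * relax_frac
            c.width += (c.target_width - c.width) * relax_frac
            c.gfp_level += (c.target_gfp - c.gfp_level) * relax_frac
            grown.append(c)
            continue
        if t >= c.t_lag_end:
            c.length = c.width + (c.length - c.width) * math.exp(c.elong_rate * dt)
        if c.length >= c.division_length:
            d1, d2 = _divide(c, preset, t + dt, rng, next_id)
            next_id += 2
            n_div += 1
            grown.extend([d1, d2])
        else:
            grown.append(c)
    return grown, next_id, n_div


def _divide(cell: CellAgent, preset: ColonyPreset, t: float, rng, next_id: int):
    L, W = cell.length, cell.width
    # daughter length conserving summed projected spherocylinder area
    ld = 0.5 * (L + W) - math.pi * W / 8.0
    ld = max(ld, W * 1.05)
    gap = 0.25 * (1.0 - preset.adhesion)
    offset = 0.5 * (L - ld) + 0.5 * gap
    daughters = []
    for k, sgn in enumerate((-1.0, 1.0)):
        jitter = rng.normal(0.0, 0.1)
        div_len = max(
            MIN_DIVISION_LENGTH_WIDTHS * W,
            rng.normal(preset.division_length_mean, preset.division_length_sd),
        )
        daughters.append(
            CellAgent(
                id=next_id + k,
                center=cell.center + sgn * offset * cell.axis,
                angle=cell.angle + jitter,
                length=ld,
                width=W,
                t_birth=t,
                t_lag_end=t,  # lag applies only to the founding cells
                elong_rate=cell.elong_rate,
                gfp_level=cell.gfp_level,
                n_layers=cell.n_layers,
                stalled=False,
                division_length=div_len,
                parent=cell.id,
            )
        )
    return daughters


def _paint_cells(cells, cfg: RenderConfig, value_fn, band: float | None = None):
    """Rasterize spherocylinder interiors (or outline bands) onto a float image."""
    h, w = cfg.shape
    img = np.zeros((h, w), dtype=float)
    px = cfg.pixel_size
    pad = 3.0 * cfg.sigma_psf_px * px
    for c in cells:
        p0, p1 = c.endpoints
        r = 0.5 * c.width
        lo = np.minimum(p0, p1) - r - pad
        hi = np.maximum(p0, p1) + r + pad
        j0, i0 = np.floor(lo / px).astype(int)
        j1, i1 = np.ceil(hi / px).astype(int) + 1
        i0, j0 = max(i0, 0), max(j0, 0)
        i1, j1 = min(i1, h), min(j1, w)
        if i0 >= i1 or j0 >= j1:
            continue
        ii, jj = np.meshgrid(
            np.arange(i0, i1), np.arange(j0, j1), indexing="ij"
        )
        # pixel centers in μm; x along columns, y along rows
        pts = np.stack([(jj + 0.5) * px, (ii + 0.5) * px], axis=-1)
        d = _dist_point_segment(pts, p0, p1)
        if band is None:
            mask = d <= r
        else:
            mask = np.abs(d - r) <= band
        sub = img[i0:i1, j0:j1]
        np.maximum(sub, np.where(mask, value_fn(c), 0.0), out=sub)
    return img


def _dist_point_segment(pts, p0, p1):
    u = p1 - p0
    uu = float(u @ u)
    w = pts - p0
    if uu < 1e-12:
        return np.hypot(w[..., 0], w[..., 1])
    s = np.clip((w @ u) / uu, 0.0, 1.0)
    proj = p0 + s[..., None] * u
    diff = pts - proj
    return np.hypot(diff[..., 0], diff[..., 1])


def render_frame(
    cells,
    cfg: RenderConfig,
    rng,
    shell_label: bool = False,
) -> dict[str, np.ndarray]:
    """Render GFP (and optionally shell) channels for one scene."""
    chans: dict[str, np.ndarray] = {}
    gfp = _paint_cells(cells, cfg, lambda c: c.gfp_level)
    gfp = gaussian_filter(gfp, cfg.sigma_psf_px)
    img = cfg.background + gfp
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    chans["gfp"] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    if shell_label:
        band_um = cfg.shell_band_px * cfg.pixel_size
        shell = _paint_cells(
            cells, cfg, lambda c: cfg.shell_amplitude, band=band_um
        )
        shell = gaussian_filter(shell, cfg.sigma_psf_px)
        img2 = cfg.background + shell
        if cfg.noise_sd > 0:
            img2 = img2 + rng.normal(0.0, cfg.noise_sd, img2.shape)
        chans["shell"] = np.clip(np.round(img2), 0, 65535).astype(np.uint16)
    return chans


def simulate_colony_stack(
    preset: ColonyPreset | str,
    n_cells0: int = 15,
    duration: float | None = None,
    dt: float = 5.0,
    render: RenderConfig | None = None,
    seed: int = 0,
) -> tuple[ImageStack, ColonyGroundTruth]:
    """Simulate a time-lapse movie of one condition.

    Returns the rendered stack (channels ``gfp`` and, for shell-labelled
    presets, ``shell``) and the per-frame ground-truth tables.
    Deterministic for a fixed (preset, seed).
    """
    if isinstance(preset, str):
        preset = COLONY_PRESETS[preset]
    if n_cells0 < 1:
        raise ValueError("n_cells0 must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration is None:
        duration = preset.default_duration
    if duration <= 0:
        raise ValueError("duration must be positive")

    cfg = render or RenderConfig()
    rng = np.random.default_rng(seed)
    cells = _sample_initial_cells(preset, n_cells0, cfg, rng)
    initial_ids = [c.id for c in cells]
    next_id = n_cells0
    _relax_overlaps(cells, preset.adhesion, rng)

    times = np.arange(0.0, duration + 1e-9, dt)
    rows = []
    frames: list[dict[str, np.ndarray]] = []
    n_div_total = 0
    for f, t in enumerate(times):
        if f > 0:
            cells, next_id, ndiv = _step_cells(
                cells, preset, float(times[f - 1]), dt, rng, next_id
            )
            n_div_total += ndiv
            _relax_overlaps(cells, preset.adhesion, rng)
            _clip_to_field(cells, cfg)
        for c in cells:
            rows.append(
                {
                    "frame": f,
                    "time_min": float(t),
                    "cell_id": c.id,
                    "x_um": float(c.center[0]),
                    "y_um": float(c.center[1]),
                    "angle_rad": float(c.angle),
                    "length_um": float(c.length),
                    "width_um": float(c.width),
                    "area_um2": float(c.area),
                    "gfp_level": float(c.gfp_level),
                    "stalled": bool(c.stalled),
                    "n_layers": int(c.n_layers),
                    "parent": int(c.parent),
                    "dividing": bool(
                        not c.stalled and c.length >= 0.97 * c.division_length
                    ),
                }
            )
        frames.append(render_frame(cells, cfg, rng, shell_label=preset.shell_label))

    channels = sorted({ch for fr in frames for ch in fr})
    stack = ImageStack(
        frames={
            ch: np.stack([fr[ch] for fr in frames]) for ch in channels
        },
        times=times,
        pixel_size=cfg.pixel_size,
        meta={
            "preset": preset.name,
            "seed": seed,
            "dt_min": dt,
            "n_cells0": n_cells0,
            "sigma_psf_px": cfg.sigma_psf_px,
        },
    )
    truth = ColonyGroundTruth(
        preset=preset,
        table=pd.DataFrame(rows),
        lag_true_min=preset.mean_lag,
        seed=seed,
        n_divisions=n_div_total,
        initial_ids=initial_ids,
    )
    return stack, truth
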