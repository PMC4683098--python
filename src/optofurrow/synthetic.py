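"""Ground-truthed synthetic tissue movies.

Generates two-channel time-lapse stacks that emulate a blastoderm-stage
epithelium imaged with a membrane-anchored marker (channel 1) and a
cytosolic reporter that translocates to the plasma membrane upon
photo-activation (channel 2).  Cells are Voronoi cells of a jittered
hexagonal lattice.  A contractile domain of cells shrinks apically with
growing anterior-posterior (a-p) anisotropy; cells hit by a pulsed
photo-activation protocol stop constricting, are stretched along the
a-p axis by their constricting neighbours, and acquire a bright membrane
ring in the reporter channel following exponential recruitment kinetics.

Every generated frame carries full ground truth (seed points, label
masks, per-cell state), so downstream segmentation and quantification
can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .core import (
    CellState,
    ImageStack,
    LabelMask,
    PhotoactivationProtocol,
    TissueGroundTruth,
)

__all__ = [
    "RecruitmentKinetics",
    "ReversionKinetics",
    "ConstrictionDynamics",
    "NoiseModel",
    "SyntheticParams",
    "make_tissue",
    "evolve_tissue",
    "simulate_recruitment",
    "recruitment_curve",
    "power_plateau_scale",
    "render_frame",
    "simulate_movie",
    "save_movie",
    "load_ground_truth",
]

#: reference laser power (mW) at which the recruitment plateau is the
#: nominal one; matches the standard power used for full activation.
REFERENCE_POWER_MW = 3.0
#: half-saturation constant (mW) of the power -> plateau scaling.
POWER_K_MW = 0.8


@dataclass(frozen=True)
class RecruitmentKinetics:
    """Exponential membrane-recruitment kinetics in log2 pm/cyt units.

    ``r_inf`` is the plateau of the log2 membrane/cytosol intensity
    ratio; ``t_half_s`` is the cumulative *illumination* time (seconds
    of light exposure, not wall-clock) at which half the plateau is
    reached.  The default half-time matches pulsed two-photon (950 nm)
    activation (~9 s of exposure), the regime of the default
    :class:`~optofurrow.core.PhotoactivationProtocol`; single-photon
    488-nm activation is an order of magnitude faster (~1 s).
    """

    r_inf: float = 3.0
    t_half_s: float = 9.0

    def __post_init__(self) -> None:
        if self.t_half_s <= 0:
            raise ValueError("t_half_s must be > 0")


@dataclass(frozen=True)
class ReversionKinetics:
    """Dark-state decay of the log2 pm/cyt ratio, half-time in minutes."""

    t_half_min: float = 8.9

    def __post_init__(self) -> None:
        if self.t_half_min <= 0:
            raise ValueError("t_half_min must be > 0")


@dataclass(frozen=True)
class ConstrictionDynamics:
    """Apical-constriction program of the contractile domain.

    Non-activated contractile cells shrink toward ``1 - shrink_fraction``
    of their initial area with time constant ``tau_s`` while their a-p
    anisotropy grows toward ``1 + anisotropy_gain`` with the same time
    constant.  ``shrink_fraction = 0`` disables the constriction program
    entirely (anisotropy growth is part of constriction).
    """

    shrink_fraction: float = 0.5
    tau_s: float = 300.0
    anisotropy_gain: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.shrink_fraction < 1:
            raise ValueError("shrink_fraction must be in [0, 1)")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if self.anisotropy_gain < 0:
            raise ValueError("anisotropy_gain must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise (intensity units) and optional shot noise.

    ``poisson_scale`` is photons per intensity unit; 0 disables shot
    noise.
    """

    gaussian_sd: float = 10.0
    poisson_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class SyntheticParams:
    """All knobs of the synthetic-tissue generator.

    Defaults describe a gastrulating embryo imaged at 0.2 um/px every
    30 s: ~6 um cells (30 px pitch), a bright ~0.8-um membrane, a dark
    nucleus, and a central contractile domain covering the ventral
    mesoderm primordium (a rectangle spanning the middle of the field).
    """

    field_shape_px: tuple[int, int] = (208, 300)  # (y, x)
    pixel_size_um: float = 0.2
    frame_interval_s: float = 30.0
    n_cells_x: int = 10
    n_cells_y: int = 8
    jitter: float = 0.08  # fraction of lattice pitch
    membrane_amplitude: float = 200.0
    membrane_halfwidth_px: int = 2
    cytosol_intensity: float = 100.0
    nucleus_dim: float = 0.5  # in [0, 1); nuclear intensity factor
    nucleus_radius_frac: float = 0.4  # of cell equivalent radius
    psf_sigma_um: float = 0.08
    noise: NoiseModel = field(default_factory=NoiseModel)
    recruitment: RecruitmentKinetics = field(default_factory=RecruitmentKinetics)
    reversion: ReversionKinetics = field(default_factory=ReversionKinetics)
    constriction: ConstrictionDynamics = field(default_factory=ConstrictionDynamics)
    # contractile domain as fractions of the field along x (a-p) and y (d-v)
    contractile_x_frac: tuple[float, float] = (0.15, 0.85)
    contractile_y_frac: tuple[float, float] = (0.25, 0.75)
    n_z: int = 3
    z_falloff: float = 0.9  # per-plane intensity factor
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.jitter <= 0.5:
            raise ValueError("jitter must be in [0, 0.5]")
        if self.membrane_amplitude < 0 or self.cytosol_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if not 0 <= self.nucleus_dim < 1:
            raise ValueError("nucleus_dim must be in [0, 1)")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")
        if self.membrane_halfwidth_px < 1:
            raise ValueError("membrane_halfwidth_px must be >= 1")
        if self.n_z < 1 or not 0 < self.z_falloff <= 1:
            raise ValueError("n_z >= 1 and 0 < z_falloff <= 1 required")

    @property
    def pitch_px(self) -> tuple[float, float]:
        """(dx, dy) lattice pitch in px."""
        h, w = self.field_shape_px
        return w / self.n_cells_x, h / self.n_cells_y

    def contractile_rect_px(self) -> tuple[float, float, float, float]:
        h, w = self.field_shape_px
        return (
            self.contractile_x_frac[0] * w,
            self.contractile_x_frac[1] * w,
            self.contractile_y_frac[0] * h,
            self.contractile_y_frac[1] * h,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_shape_px"] = list(self.field_shape_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        d = dict(d)
        for key, sub in (
            ("noise", NoiseModel),
            ("recruitment", RecruitmentKinetics),
            ("reversion", ReversionKinetics),
            ("constriction", ConstrictionDynamics),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("field_shape_px", "contractile_x_frac", "contractile_y_frac"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# tessellation
# ---------------------------------------------------------------------------

def _lattice_seeds(params: SyntheticParams) -> np.ndarray:
    """Jittered hexagonal lattice of seed points, (n, 2) as (x, y)."""
    h, w = params.field_shape_px
    dx, dy = params.pitch_px
    if dx < 2 or dy < 2:
        raise ValueError(
            f"field {w}x{h} px too small for {params.n_cells_x}x{params.n_cells_y} cells"
        )
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    pts = []
    for j in range(params.n_cells_y):
        off = 0.25 if j % 2 == 0 else 0.75
        for i in range(params.n_cells_x):
            pts.append(((i + off) * dx, (j + 0.5) * dy))
    pts = np.asarray(pts, dtype=np.float64)
    if params.jitter > 0:
        jit = rng.uniform(-params.jitter, params.jitter, size=pts.shape)
        pts += jit * np.array([dx, dy])
    pts[:, 0] = np.clip(pts[:, 0], 0.5, w - 0.5)
    pts[:, 1] = np.clip(pts[:, 1], 0.5, h - 0.5)
    return pts


def assign_nearest(seeds: np.ndarray, coord_x: np.ndarray, coord_y: np.ndarray) -> np.ndarray:
    """Label each coordinate pair with its Euclidean-nearest seed.

    Ties go to the smaller label id (labels are ``seed index + 1``).
    Vectorized argmin over seeds, chunked by rows to bound memory.
    """
    seeds = np.asarray(seeds, dtype=np.float64)
    if seeds.ndim != 2 or seeds.shape[1] != 2 or len(seeds) == 0:
        raise ValueError("seeds must be a non-empty (n, 2) array")
    h = coord_x.shape[0]
    labels = np.empty(coord_x.shape, dtype=np.int32)
    chunk = max(1, int(4e6 // max(len(seeds) * coord_x.shape[1], 1)))
    for y0 in range(0, h, chunk):
        y1 = min(h, y0 + chunk)
        d2 = (coord_x[y0:y1, :, None] - seeds[:, 0][None, None, :]) ** 2 + (
            coord_y[y0:y1, :, None] - seeds[:, 1][None, None, :]
        ) ** 2
        labels[y0:y1] = np.argmin(d2, axis=2) + 1  # argmin takes smallest index on ties
    return labels


def tessellate(seeds: np.ndarray, shape_yx: tuple[int, int]) -> np.ndarray:
    """Euclidean nearest-seed label map on the pixel grid."""
    h, w = shape_yx
    xs, ys = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    return assign_nearest(seeds, xs, ys)


def make_tissue(params: SyntheticParams) -> TissueGroundTruth:
    """Initial (t = 0) tissue: tessellation plus per-cell ground truth."""
    seeds = _lattice_seeds(params)
    labels = tessellate(seeds, params.field_shape_px)
    mask = LabelMask(labels, params.pixel_size_um)
    cx0, cx1, cy0, cy1 = params.contractile_rect_px()
    areas = np.bincount(labels.ravel(), minlength=len(seeds) + 1)
    state: dict[int, CellState] = {}
    for i, (sx, sy) in enumerate(seeds):
        lab = i + 1
        contractile = cx0 <= sx < cx1 and cy0 <= sy < cy1
        r_eq = float(np.sqrt(areas[lab] / np.pi))
        state[lab] = CellState(
            contractile=contractile,
            activated=False,
            pm_cyt_ratio=1.0,
            nucleus_center=(float(sx), float(sy)),
            nucleus_radius=params.nucleus_radius_frac * r_eq,
        )
    return TissueGroundTruth(seeds=seeds, labels=mask, cell_state=state, time_s=0.0)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def power_plateau_scale(power_mw: float) -> float:
    """Saturating scaling of the recruitment plateau with laser power,
    normalized to 1 at the reference power (3.0 mW)."""
    if power_mw < 0:
        raise ValueError("power must be >= 0")
    ref = REFERENCE_POWER_MW / (REFERENCE_POWER_MW + POWER_K_MW)
    return (power_mw / (power_mw + POWER_K_MW)) / ref


def recruitment_curve(
    t_exposure_s: np.ndarray | float, kinetics: RecruitmentKinetics, power_mw: float = REFERENCE_POWER_MW
) -> np.ndarray | float:
    """log2 pm/cyt ratio as a function of cumulative illumination time."""
    t = np.asarray(t_exposure_s, dtype=np.float64)
    r = power_plateau_scale(power_mw) * kinetics.r_inf * (1.0 - 2.0 ** (-t / kinetics.t_half_s))
    return float(r) if np.isscalar(t_exposure_s) else r


def simulate_recruitment(
    protocol: PhotoactivationProtocol,
    kinetics: RecruitmentKinetics,
    times_s: np.ndarray,
) -> np.ndarray:
    """log2 pm/cyt trajectory of an activated cell at wall-clock times.

    The driving variable is cumulative illumination time under the
    protocol's pulse/interval schedule; the plateau scales with the
    protocol's laser power.
    """
    times = np.asarray(times_s, dtype=np.float64)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a 1-D, non-empty array")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    t_exp = protocol.exposure_time(times)
    return recruitment_curve(t_exp, kinetics, protocol.laser_power_mw)


def _activated_log2_ratio(
    t_s: float, protocol: PhotoactivationProtocol, params: SyntheticParams
) -> float:
    """log2 pm/cyt of an activated cell at wall-clock time t, including
    dark reversion after the protocol stops."""
    t_exp = float(protocol.exposure_time(t_s))
    r = recruitment_curve(t_exp, params.recruitment, protocol.laser_power_mw)
    if protocol.end_s is not None and t_s > protocol.end_s:
        t_dark_min = (t_s - protocol.end_s) / 60.0
        r = r * 2.0 ** (-t_dark_min / params.reversion.t_half_min)
    return float(r)


def _smooth_ramp(v: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    """1 inside [lo, hi], linear ramp to 0 over ``ramp`` outside."""
    up = np.clip((v - (lo - ramp)) / ramp, 0.0, 1.0)
    down = np.clip(((hi + ramp) - v) / ramp, 0.0, 1.0)
    return up * down


def _merge_intervals(ivals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(ivals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


class _TissueWarp:
    """Invertible kinematic warp of the tissue plane.

    Triangular structure: first ``y1 = Y(y0; x0)`` compresses the
    contractile band along y (except in activated columns), then
    ``x1 = X(x0; y1)`` compresses the non-activated core along x,
    stretches activated columns (area compensation), and blends toward
    identity outside the band.  Each 1-D family is monotone piecewise
    linear, so the inverse is exact.  The field borders are pinned.
    """

    def __init__(
        self,
        shape_yx: tuple[int, int],
        core: tuple[float, float, float, float],
        s_x: float,
        s_y: float,
        act_iv: list[tuple[float, float]],
        pitch: tuple[float, float],
    ) -> None:
        self.h, self.w = shape_yx
        self.cx0, self.cx1, self.cy0, self.cy1 = core
        self.s_x, self.s_y = s_x, s_y
        self.act_iv = act_iv
        self.dx, self.dy = pitch

        w = float(self.w)
        core_len = self.cx1 - self.cx0
        l_act = sum(b - a for a, b in act_iv)
        l_non = core_len - l_act
        if l_act > 0:
            self.sigma_a = (core_len - s_x * l_non) / l_act
            self.margin_slope = 1.0
        else:
            self.sigma_a = 1.0
            self.margin_slope = (w - s_x * core_len) / max(w - core_len, 1e-9)
        xs = {0.0, self.cx0, self.cx1, w}
        for a, b in act_iv:
            xs.update((a, b))
        self.x_knots = np.array(sorted(xs))
        out = [0.0]
        for a, b in zip(self.x_knots[:-1], self.x_knots[1:]):
            out.append(out[-1] + self._x_slope(0.5 * (a + b)) * (b - a))
        self.x_knots_out = np.asarray(out) * (w / out[-1])  # kill numeric drift

    def _x_slope(self, x_mid: float) -> float:
        if x_mid < self.cx0 or x_mid >= self.cx1:
            return self.margin_slope
        for a, b in self.act_iv:
            if a <= x_mid < b:
                return self.sigma_a
        return self.s_x

    # -- x family ----------------------------------------------------------
    def _band_weight(self, y: np.ndarray) -> np.ndarray:
        return _smooth_ramp(y, self.cy0, self.cy1, self.dy)

    def x_fwd(self, x0: np.ndarray, y1: np.ndarray) -> np.ndarray:
        w = self._band_weight(y1)
        return x0 + (np.interp(x0, self.x_knots, self.x_knots_out) - x0) * w

    def x_inv_row(self, x1: np.ndarray, y1: float) -> np.ndarray:
        w = float(self._band_weight(np.asarray(y1)))
        kb = self.x_knots + (self.x_knots_out - self.x_knots) * w
        return np.interp(x1, kb, self.x_knots)

    # -- y family ----------------------------------------------------------
    def _s_y_eff(self, x0: np.ndarray) -> np.ndarray:
        a = np.zeros_like(np.asarray(x0, dtype=np.float64))
        for ia, ib in self.act_iv:
            a = np.maximum(a, _smooth_ramp(x0, ia, ib, 0.5 * self.dx))
        return self.s_y + (1.0 - self.s_y) * a

    def _m_y(self, s_eff: np.ndarray) -> np.ndarray:
        band = self.cy1 - self.cy0
        return (self.h - s_eff * band) / max(self.h - band, 1e-9)

    def y_fwd(self, y0: np.ndarray, x0: np.ndarray) -> np.ndarray:
        s = self._s_y_eff(x0)
        m = self._m_y(s)
        return np.where(
            y0 < self.cy0,
            m * y0,
            np.where(
                y0 < self.cy1,
                m * self.cy0 + s * (y0 - self.cy0),
                self.h - m * (self.h - y0),
            ),
        )

    def y_inv(self, y1: np.ndarray, x0: np.ndarray) -> np.ndarray:
        s = self._s_y_eff(x0)
        m = self._m_y(s)
        b0 = m * self.cy0
        b1 = b0 + s * (self.cy1 - self.cy0)
        return np.where(
            y1 < b0,
            y1 / m,
            np.where(y1 < b1, self.cy0 + (y1 - b0) / s, self.h - (self.h - y1) / m),
        )

    # -- full map ----------------------------------------------------------
    def forward_points(self, pts: np.ndarray) -> np.ndarray:
        x0, y0 = pts[:, 0], pts[:, 1]
        y1 = self.y_fwd(y0, x0)
        x1 = self.x_fwd(x0, y1)
        return np.column_stack([x1, y1])

    def inverse_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference-frame coordinates (x0, y0) of every pixel center."""
        cols = np.arange(self.w, dtype=np.float64)
        x0 = np.empty((self.h, self.w))
        y0 = np.empty((self.h, self.w))
        for r in range(self.h):
            xr = self.x_inv_row(cols, float(r))
            x0[r] = xr
            y0[r] = self.y_inv(np.full(self.w, float(r)), xr)
        return x0, y0


def evolve_tissue(
    tissue: TissueGroundTruth,
    protocol: PhotoactivationProtocol,
    params: SyntheticParams,
    t: float,
) -> TissueGroundTruth:
    """Tissue state at absolute time ``t`` (s), evolved from the t = 0
    reference tissue.

    Non-activated contractile cells shrink and gain a-p anisotropy;
    activated cells (seed inside a protocol region once the first pulse
    has been delivered) stop constricting and are stretched along x by
    an area-compensating displacement of the Voronoi seeds.  The
    displacement pins the field borders, so re-tessellation conserves
    total tissue area and preserves label identity.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return tissue
    h, w = tissue.labels.labels.shape
    protocol.validate_field((h, w))
    seeds0 = tissue.seeds
    con = params.constriction
    dx, dy = params.pitch_px

    activation_on = len(protocol.regions) > 0 and protocol.exposure_time(t) > 0
    activated = np.zeros(len(seeds0), dtype=bool)
    if activation_on:
        for i, (sx, sy) in enumerate(seeds0):
            activated[i] = protocol.in_any_region(sx, sy)

    if con.shrink_fraction == 0:
        f_t = 0.0
        a_mult = 1.0
    else:
        growth = 1.0 - np.exp(-t / con.tau_s)
        f_t = con.shrink_fraction * growth
        a_mult = 1.0 + con.anisotropy_gain * growth

    if f_t == 0.0 and not activated.any():
        new_seeds = seeds0.copy()
        labels = tessellate(new_seeds, (h, w))
    else:
        # local scale factors of the non-activated contractile core:
        # area multiplier s_x * s_y = 1 - f, moment-ratio multiplier
        # s_x / s_y = a_mult
        s_x = float(np.sqrt((1.0 - f_t) * a_mult))
        s_y = float(np.sqrt((1.0 - f_t) / a_mult))
        cx0, cx1, cy0, cy1 = params.contractile_rect_px()

        act_iv: list[tuple[float, float]] = []
        if activated.any():
            for r in protocol.regions:
                a, b = max(float(r.x0), cx0), min(float(r.x1), cx1)
                if b > a:
                    act_iv.append((a, b))
            act_iv = _merge_intervals(act_iv)

        warp = _TissueWarp((h, w), (cx0, cx1, cy0, cy1), s_x, s_y, act_iv, (dx, dy))
        new_seeds = warp.forward_points(seeds0)
        # tessellation in the reference frame, looked up through the
        # inverse warp: cells are the warped images of the t = 0 cells,
        # so programmed area and anisotropy hold exactly in the core
        x0g, y0g = warp.inverse_grid()
        labels = assign_nearest(seeds0, x0g, y0g)
    mask = LabelMask(labels, params.pixel_size_um, t_index=int(round(t / params.frame_interval_s)))
    areas = np.bincount(labels.ravel(), minlength=len(new_seeds) + 1)
    ratio_act = 2.0 ** _activated_log2_ratio(t, protocol, params) if activation_on else 1.0
    state: dict[int, CellState] = {}
    for i, (sx, sy) in enumerate(new_seeds):
        lab = i + 1
        old = tissue.cell_state[lab]
        is_act = bool(activated[i])
        r_eq = float(np.sqrt(max(areas[lab], 1) / np.pi))
        state[lab] = CellState(
            contractile=old.contractile,
            activated=is_act,
            pm_cyt_ratio=ratio_act if is_act else 1.0,
            nucleus_center=(float(sx), float(sy)),
            nucleus_radius=params.nucleus_radius_frac * r_eq,
        )
    return TissueGroundTruth(seeds=new_seeds, labels=mask, cell_state=state, time_s=float(t))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def membrane_zone(labels: np.ndarray, halfwidth_px: int) -> np.ndarray:
    """Pixels within Chebyshev distance ``halfwidth_px`` of a pixel with
    a different label (the inter-cell membrane band)."""
    size = 2 * halfwidth_px + 1
    mx = ndimage.maximum_filter(labels, size=size, mode="nearest")
    mn = ndimage.minimum_filter(labels, size=size, mode="nearest")
    return mx != mn


def render_frame(tissue: TissueGroundTruth, params: SyntheticParams) -> ImageStack:
    """Render one two-channel frame (T = 1, Z = ``params.n_z``).

    Channel 1 paints the membrane band at ``membrane_amplitude``.
    Channel 2 is the reporter: uniform cytosol, a membrane ring scaled
    by each cell's pm/cyt ratio, and a darkened nuclear disk.  Both
    channels are blurred with the Gaussian PSF and corrupted per the
    noise model; deeper z planes are intensity-scaled replicas with
    independent noise.  Deterministic given (params, tissue.time_s).
    """
    labels = tissue.labels.labels
    if labels.shape != tuple(params.field_shape_px):
        raise ValueError("tissue and params field sizes disagree")
    h, w = labels.shape
    mem = membrane_zone(labels, params.membrane_halfwidth_px)

    ch1 = np.where(mem, params.membrane_amplitude, 0.0)

    n_lab = int(labels.max())
    ratio_lut = np.ones(n_lab + 1)
    for lab, st in tissue.cell_state.items():
        ratio_lut[lab] = st.pm_cyt_ratio
    ch2 = np.full((h, w), params.cytosol_intensity)
    ch2[mem] = params.cytosol_intensity * ratio_lut[labels[mem]]

    if params.nucleus_dim < 1.0:
        yy, xx = np.mgrid[0:h, 0:w]
        nuc = np.zeros((h, w), dtype=bool)
        for st in tissue.cell_state.values():
            nx, ny = st.nucleus_center
            r = st.nucleus_radius
            if r <= 0:
                continue
            y0, y1 = max(0, int(ny - r - 1)), min(h, int(ny + r + 2))
            x0, x1 = max(0, int(nx - r - 1)), min(w, int(nx + r + 2))
            sub = (xx[y0:y1, x0:x1] - nx) ** 2 + (yy[y0:y1, x0:x1] - ny) ** 2 <= r**2
            nuc[y0:y1, x0:x1] |= sub
        dark = nuc & ~mem
        ch2[dark] *= params.nucleus_dim

    sigma_px = params.psf_sigma_um / params.pixel_size_um
    if sigma_px > 0:
        ch1 = ndimage.gaussian_filter(ch1, sigma_px, mode="reflect")
        ch2 = ndimage.gaussian_filter(ch2, sigma_px, mode="reflect")

    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, int(round(tissue.time_s * 1000)) % (2**31), 777])
    )
    data = np.empty((1, params.n_z, 2, h, w))
    for z in range(params.n_z):
        fall = params.z_falloff**z
        for c, img in enumerate((ch1, ch2)):
            plane = img * fall
            if params.noise.poisson_scale > 0:
                plane = rng.poisson(plane * params.noise.poisson_scale) / params.noise.poisson_scale
            if params.noise.gaussian_sd > 0:
                plane = plane + rng.normal(0.0, params.noise.gaussian_sd, size=plane.shape)
            data[0, z, c] = np.clip(plane, 0.0, None)
    return ImageStack(
        data,
        pixel_size_um=params.pixel_size_um,
        frame_interval_s=params.frame_interval_s,
        channel_roles=("membrane", "reporter"),
    )


def simulate_movie(
    params: SyntheticParams,
    protocol: PhotoactivationProtocol,
    n_frames: int,
) -> tuple[ImageStack, list[TissueGroundTruth]]:
    """Full synthetic movie: ``n_frames`` at the frame interval, with
    per-frame ground truth."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    tissue0 = make_tissue(params)
    frames = []
    truths = []
    for k in range(n_frames):
        t = k * params.frame_interval_s
        gt = evolve_tissue(tissue0, protocol, params, t)
        frames.append(render_frame(gt, params).data)
        truths.append(gt)
    stack = ImageStack(
        np.concatenate(frames, axis=0),
        pixel_size_um=params.pixel_size_um,
        frame_interval_s=params.frame_interval_s,
        channel_roles=("membrane", "reporter"),
    )
    return stack, truths


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def save_movie(
    outdir: str | Path,
    stack: ImageStack,
    truths: list[TissueGroundTruth],
    params: SyntheticParams,
    protocol: PhotoactivationProtocol,
) -> dict[str, Path]:
    """Write movie TIFF (TZCYX), ground-truth label TIFF, and a JSON
    sidecar with seeds, per-cell state per frame, and full parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    movie_path = outdir / "movie.tif"
    labels_path = outdir / "gt_labels.tif"
    sidecar_path = outdir / "ground_truth.json"

    meta = {
        "axes": "TZCYX",
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel_roles": list(stack.channel_roles),
    }
    tifffile.imwrite(movie_path, stack.data.astype(np.float32), description=json.dumps(meta))
    gt_arr = np.stack([gt.labels.labels.astype(np.uint16) for gt in truths])
    tifffile.imwrite(
        labels_path,
        gt_arr,
        description=json.dumps({"axes": "TYX", "pixel_size_um": stack.pixel_size_um}),
        photometric="minisblack",
    )
    sidecar = {
        "params": params.to_dict(),
        "protocol": protocol.to_dict(),
        "frames": [
            {
                "time_s": gt.time_s,
                "seeds": gt.seeds.tolist(),
                "cells": {str(lab): st.to_dict() for lab, st in gt.cell_state.items()},
            }
            for gt in truths
        ],
    }
    sidecar_path.write_text(json.dumps(sidecar))
    return {"movie": movie_path, "labels": labels_path, "ground_truth": sidecar_path}


def load_ground_truth(path: str | Path) -> dict:
    """Load a ground-truth sidecar written by :func:`save_movie`."""
    return json.loads(Path(path).read_text())
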