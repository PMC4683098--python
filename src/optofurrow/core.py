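"""Shared data containers for the tissue-imaging pipeline.

Axis conventions used throughout the package:

* image arrays are indexed ``(t, z, c, y, x)``;
* the image x axis is the embryo anterior-posterior (a-p) axis and the
  y axis is the dorsal-ventral (d-v) axis;
* pixel coordinates are 0-based and rectangles are half-open,
  ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImageStack",
    "LabelMask",
    "CellState",
    "TissueGroundTruth",
    "PhotoactivationProtocol",
    "Rect",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle in pixel coordinates."""

    x0: int
    x1: int
    y0: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"empty rectangle: {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def to_dict(self) -> dict:
        return {"x0": self.x0, "x1": self.x1, "y0": self.y0, "y1": self.y1}

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(int(d["x0"]), int(d["x1"]), int(d["y0"]), int(d["y1"]))


@dataclass
class ImageStack:
    """A multi-channel time-lapse stack with physical calibration.

    ``data`` is indexed ``(t, z, c, y, x)``; intensities are non-negative
    floats.  ``channel_roles`` names each channel, e.g. ``("membrane",
    "reporter")`` for a membrane-anchor channel plus a translocating
    reporter channel.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_roles: tuple[str, ...] = ("membrane", "reporter")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 5:
            raise ValueError(
                f"ImageStack data must be 5-D (t, z, c, y, x), got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.data.shape[2] != len(self.channel_roles):
            raise ValueError(
                f"{self.data.shape[2]} channels but {len(self.channel_roles)} roles"
            )
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    def channel(self, role: str) -> int:
        """Index of the channel with the given role."""
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}") from None


@dataclass
class LabelMask:
    """Per-pixel integer cell labels for one (t, z) plane; 0 = background."""

    labels: np.ndarray
    pixel_size_um: float
    t_index: int = 0
    z_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def label_ids(self) -> np.ndarray:
        """Sorted positive label ids present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellState:
    """Ground-truth state of one synthetic cell."""

    contractile: bool
    activated: bool
    pm_cyt_ratio: float  # linear membrane/cytosol intensity ratio, >= 0
    nucleus_center: tuple[float, float]  # (x, y) px
    nucleus_radius: float  # px

    def __post_init__(self) -> None:
        if self.pm_cyt_ratio < 0:
            raise ValueError("pm_cyt_ratio must be >= 0")

    def to_dict(self) -> dict:
        return {
            "contractile": bool(self.contractile),
            "activated": bool(self.activated),
            "pm_cyt_ratio": float(self.pm_cyt_ratio),
            "nucleus_center": [float(self.nucleus_center[0]), float(self.nucleus_center[1])],
            "nucleus_radius": float(self.nucleus_radius),
        }


@dataclass
class TissueGroundTruth:
    """Ground truth for one synthetic tissue frame (single z).

    ``seeds`` is an (n, 2) array of (x, y) Voronoi seed points, one per
    label, with ``seeds[i]`` belonging to label ``i + 1``.  ``cell_state``
    maps each positive label to its :class:`CellState`.
    """

    seeds: np.ndarray
    labels: LabelMask
    cell_state: dict[int, CellState]
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.seeds = np.asarray(self.seeds, dtype=np.float64)
        ids = set(int(i) for i in self.labels.label_ids)
        if ids != set(self.cell_state):
            raise ValueError("cell_state keys must match labels present in the mask")
        if len(self.seeds) != len(ids):
            raise ValueError("one seed per label required")

    @property
    def n_cells(self) -> int:
        return len(self.cell_state)


@dataclass(frozen=True)
class PhotoactivationProtocol:
    """Pulsed photo-activation schedule over rectangular regions.

    Defaults follow a two-photon pulse train in which the activation
    regions are scanned for 2.5 s every 30 s over five z planes spaced
    1 um apart.  ``start_s`` is the time of the first pulse; ``end_s``
    (if set) is when illumination stops and dark reversion begins.
    """

    regions: tuple[Rect, ...] = ()
    pulse_scan_time_s: float = 2.5
    interval_s: float = 30.0
    laser_power_mw: float = 3.0
    n_z_planes: int = 5
    plane_spacing_um: float = 1.0
    wavelength_nm: float = 950.0
    start_s: float = 0.0
    end_s: float | None = None

    def __post_init__(self) -> None:
        if self.pulse_scan_time_s <= 0:
            raise ValueError("pulse_scan_time_s must be > 0")
        if self.interval_s < 0:
            raise ValueError("interval_s must be >= 0")
        if self.interval_s and self.pulse_scan_time_s > self.interval_s:
            raise ValueError("pulse must fit within the pulse interval")
        if self.laser_power_mw < 0:
            raise ValueError("laser_power_mw must be >= 0")

    def validate_field(self, shape_yx: tuple[int, int]) -> None:
        h, w = shape_yx
        for r in self.regions:
            if r.x0 < 0 or r.y0 < 0 or r.x1 > w or r.y1 > h:
                raise ValueError(f"region {r} outside field {w}x{h}")

    def exposure_time(self, t_s: float | np.ndarray) -> np.ndarray | float:
        """Cumulative illumination time (s) received by time ``t_s``.

        Pulses of length ``pulse_scan_time_s`` start at ``start_s + k *
        interval_s``; a pulse in progress contributes its elapsed part.
        Illumination stops at ``end_s`` when set.
        """
        t = np.asarray(t_s, dtype=np.float64)
        if self.end_s is not None:
            t = np.minimum(t, self.end_s)
        rel = t - self.start_s
        if self.interval_s == 0:
            # continuous illumination after a single pulse start
            exp = np.clip(rel, 0.0, None)
        else:
            n_full = np.floor(rel / self.interval_s)
            frac = rel - n_full * self.interval_s
            exp = np.where(
                rel < 0,
                0.0,
                n_full * self.pulse_scan_time_s + np.clip(frac, 0.0, self.pulse_scan_time_s),
            )
        if np.isscalar(t_s):
            return float(exp)
        return exp

    def in_any_region(self, x: float, y: float) -> bool:
        return any(r.contains(x, y) for r in self.regions)

    def to_dict(self) -> dict:
        return {
            "regions": [r.to_dict() for r in self.regions],
            "pulse_scan_time_s": self.pulse_scan_time_s,
            "interval_s": self.interval_s,
            "laser_power_mw": self.laser_power_mw,
            "n_z_planes": self.n_z_planes,
            "plane_spacing_um": self.plane_spacing_um,
            "wavelength_nm": self.wavelength_nm,
            "start_s": self.start_s,
            "end_s": self.end_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhotoactivationProtocol":
        d = dict(d)
        d["regions"] = tuple(Rect.from_dict(r) for r in d.get("regions", ()))
        return cls(**d)
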