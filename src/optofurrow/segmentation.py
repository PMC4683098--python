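"""Membrane-channel cell segmentation.

The chain is: Gaussian smoothing of the membrane channel, adaptive
thresholding to extract the dark cytoplasmic interiors between the
bright membranes, object filtering of the resulting components, and a
seeded Voronoi-style propagation that assigns every pixel to a cell by
an intensity-weighted geodesic distance.  Each z slice is segmented
independently.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import ImageStack, LabelMask

__all__ = [
    "SegmentationParams",
    "smooth",
    "adaptive_threshold",
    "filter_objects",
    "propagate_voronoi",
    "segment_frame",
    "segment_stack",
    "match_labels",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the segmentation chain.

    ``smooth_sigma_um`` is the Gaussian sigma in microns (~1 um kernel).
    ``window_um`` is the adaptive-threshold local-mean window;
    ``offset`` is subtracted from the local mean, in intensity units,
    so foreground = pixels darker than (local mean - offset).
    ``min_object_area_um2`` removes small components (kept if area >=
    threshold).  ``propagation_lambda`` trades spatial against intensity
    distance in the propagation step: large values approach a plain
    spatial Voronoi, small values follow intensity ridges.
    """

    smooth_sigma_um: float = 1.0
    window_um: float = 8.0
    offset: float = 5.0
    min_object_area_um2: float = 10.0
    border_policy: str = "exclude"  # exclude | keep
    propagation_lambda: float = 1.0

    def __post_init__(self) -> None:
        if self.smooth_sigma_um <= 0:
            raise ValueError("smooth_sigma_um must be > 0")
        if self.min_object_area_um2 < 0:
            raise ValueError("min_object_area_um2 must be >= 0")
        if self.border_policy not in ("exclude", "keep"):
            raise ValueError("border_policy must be 'exclude' or 'keep'")
        if self.propagation_lambda < 0:
            raise ValueError("propagation_lambda must be >= 0")


def smooth(
    image: np.ndarray, sigma_um: float, pixel_size_um: float, mode: str = "reflect"
) -> np.ndarray:
    """Gaussian-smooth a 2-D image; sigma given in microns."""
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma_um == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma_um / pixel_size_um, mode=mode)


def adaptive_threshold(
    image: np.ndarray, window_um: float, offset: float, pixel_size_um: float
) -> np.ndarray:
    """Binary mask of pixels darker than their local mean minus offset.

    Segments the cytoplasmic interiors, which are dark relative to the
    bright membrane; the local mean is taken over a square window of
    ``window_um`` (odd number of pixels, at least 3).
    """
    image = np.asarray(image, dtype=np.float64)
    win = int(round(window_um / pixel_size_um))
    win = max(win, 3)
    if win % 2 == 0:
        win += 1
    if win > min(image.shape):
        raise ValueError(f"window of {win} px exceeds image of shape {image.shape}")
    local_mean = ndimage.uniform_filter(image, size=win, mode="reflect")
    return (image < local_mean - offset).astype(np.uint8)


def filter_objects(
    mask: np.ndarray,
    min_area_um2: float,
    border_policy: str,
    pixel_size_um: float,
) -> LabelMask:
    """Label 4-connected components and drop small / border objects.

    Components of area >= ``min_area_um2`` survive (inclusive
    threshold); with ``border_policy='exclude'`` components touching the
    field edge are removed.  Survivors are renumbered 1..n in raster
    order of their first pixel.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    lab = measure.label(mask, connectivity=1)
    px_area = pixel_size_um**2
    keep = []
    for region in measure.regionprops(lab):
        if region.area * px_area < min_area_um2:
            continue
        if border_policy == "exclude":
            y0, x0, y1, x1 = region.bbox
            if y0 == 0 or x0 == 0 or y1 == lab.shape[0] or x1 == lab.shape[1]:
                continue
        keep.append(region.label)
    out = np.zeros_like(lab, dtype=np.int32)
    # raster order of first pixel == ascending original label, since
    # skimage labels components in raster order of first encounter
    for new, old in enumerate(sorted(keep), start=1):
        out[lab == old] = new
    return LabelMask(out, pixel_size_um)


def propagate_voronoi(
    seeds: LabelMask | np.ndarray,
    guide: np.ndarray,
    lam: float,
    domain: np.ndarray | None = None,
) -> LabelMask:
    """Assign every domain pixel to a seed by intensity-weighted
    geodesic distance (multi-source Dijkstra).

    The step cost between 4-neighbours is ``sqrt((dI)^2 + lam)``: large
    ``lam`` approaches a plain spatial Voronoi, ``lam = 0`` follows
    intensity ridges only.  Equal costs resolve to the smaller label id.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if isinstance(seeds, LabelMask):
        px = seeds.pixel_size_um
        seed_arr = seeds.labels
    else:
        px = 1.0
        seed_arr = np.asarray(seeds)
    guide = np.asarray(guide, dtype=np.float64)
    if guide.shape != seed_arr.shape:
        raise ValueError("guide and seeds shapes differ")
    h, w = seed_arr.shape
    if domain is None:
        domain = np.ones((h, w), dtype=bool)
    else:
        domain = np.asarray(domain, dtype=bool)
    if not (seed_arr > 0).any():
        raise ValueError("no seeds")
    if ((seed_arr > 0) & ~domain).any():
        raise ValueError("seed outside domain")

    flat_guide = guide.ravel()
    dist = np.full(h * w, np.inf)
    label = np.zeros(h * w, dtype=np.int32)
    heap: list[tuple[float, int, int]] = []
    sy, sx = np.nonzero(seed_arr > 0)
    for y, x in zip(sy, sx):
        idx = y * w + x
        lab = int(seed_arr[y, x])
        if 0.0 < dist[idx] or (dist[idx] == 0.0 and lab < label[idx]):
            dist[idx] = 0.0
            label[idx] = lab
            heapq.heappush(heap, (0.0, lab, idx))
    dom_flat = domain.ravel()
    sqrt = np.sqrt
    while heap:
        d, lab, idx = heapq.heappop(heap)
        if d > dist[idx] or (d == dist[idx] and lab > label[idx]):
            continue
        gy = flat_guide[idx]
        y, x = divmod(idx, w)
        for nidx in (
            idx - w if y > 0 else -1,
            idx + w if y < h - 1 else -1,
            idx - 1 if x > 0 else -1,
            idx + 1 if x < w - 1 else -1,
        ):
            if nidx < 0 or not dom_flat[nidx]:
                continue
            nd = d + sqrt((flat_guide[nidx] - gy) ** 2 + lam)
            if nd < dist[nidx] or (nd == dist[nidx] and lab < label[nidx]):
                dist[nidx] = nd
                label[nidx] = lab
                heapq.heappush(heap, (nd, lab, nidx))
    out = label.reshape(h, w)
    out[~domain] = 0
    return LabelMask(out.astype(np.int32), px)


def segment_frame(
    frame: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
) -> LabelMask:
    """Segment one 2-D membrane-channel image into cell labels.

    Runs smooth -> adaptive_threshold -> filter_objects ->
    propagate_voronoi.  Propagation runs with *all* cytoplasm seeds so
    that interior boundaries are contested from both sides; with
    ``border_policy='exclude'`` the labels whose final region touches
    the field edge are then removed and the survivors renumbered.
    """
    sm = smooth(frame, params.smooth_sigma_um, pixel_size_um)
    fg = adaptive_threshold(sm, params.window_um, params.offset, pixel_size_um)
    seeds = filter_objects(fg, params.min_object_area_um2, "keep", pixel_size_um)
    if not (seeds.labels > 0).any():
        return LabelMask(np.zeros_like(seeds.labels), pixel_size_um)
    full = propagate_voronoi(seeds, sm, params.propagation_lambda)
    labels = full.labels
    if params.border_policy == "exclude":
        border = np.zeros_like(labels, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        drop = np.unique(labels[border])
        labels = np.where(np.isin(labels, drop), 0, labels)
    # renumber contiguous 1..n in raster order of first pixel
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    order = []
    seen = set()
    for v in labels.ravel():
        if v > 0 and v not in seen:
            seen.add(v)
            order.append(v)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return LabelMask(remap[labels], pixel_size_um)


def segment_stack(stack: ImageStack, params: SegmentationParams) -> list[list[LabelMask]]:
    """Segment the membrane channel of every (t, z) plane.

    Returns masks indexed ``[t][z]``.
    """
    c = stack.channel("membrane")
    out: list[list[LabelMask]] = []
    for t in range(stack.n_t):
        row = []
        for z in range(stack.n_z):
            m = segment_frame(stack.data[t, z, c], params, stack.pixel_size_um)
            m.t_index = t
            m.z_index = z
            row.append(m)
        out.append(row)
    return out


def match_labels(truth: np.ndarray, pred: np.ndarray) -> dict[int, tuple[int, float]]:
    """Best-overlap matching of ground-truth labels to predicted labels.

    Returns ``{truth_label: (pred_label, jaccard)}`` where the predicted
    label is the one with maximal intersection (0 if none).
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    out: dict[int, tuple[int, float]] = {}
    for lab in np.unique(truth):
        if lab == 0:
            continue
        tm = truth == lab
        votes = pred[tm]
        votes = votes[votes > 0]
        if votes.size == 0:
            out[int(lab)] = (0, 0.0)
            continue
        best = int(np.bincount(votes).argmax())
        pm = pred == best
        inter = np.logical_and(tm, pm).sum()
        union = np.logical_or(tm, pm).sum()
        out[int(lab)] = (best, float(inter / union))
    return out
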