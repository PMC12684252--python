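"""Cell segmentation, colony/brightness filters and normalized coordinates.

Cells are found as ellipse-like connected objects (or taken from a
supplied label mask, the usual path for simulated data).  Each region
carries a straight backbone along its principal axis and a local
half-width profile, which together define the normalized cell coordinate
system: ``l`` runs 0..1 pole to pole, ``s`` is the signed perpendicular
offset divided by the local half-width (|s| ~ 1 at the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .simulate import Movie

__all__ = [
    "CellRegion",
    "NormalizedPoint",
    "segment_cells",
    "group_colonies",
    "filter_colonies",
    "filter_dim_cells",
    "to_cell_coordinates",
]


@dataclass
class NormalizedPoint:
    """Normalized cell coordinates: longitudinal l in [0, 1], radial s."""

    l: float
    s: float


@dataclass
class CellRegion:
    """A segmented cell with its coordinate frame.

    ``axes`` are the half-axes (px) of the second-moment ellipse fit;
    ``backbone`` holds the two pole endpoints (x, y in px) of the
    principal-axis backbone; ``halfwidth`` is an (l-grid, half-width px)
    profile estimated from the per-slab mask area.
    """

    label: int
    mask: np.ndarray  # full-frame boolean mask
    centroid: tuple[float, float]  # (x, y) px
    axes: tuple[float, float]  # (major, minor) half-axes px
    angle: float  # rad, major axis vs image x axis
    backbone: tuple[np.ndarray, np.ndarray]  # pole endpoints, px
    halfwidth_grid: np.ndarray  # l values
    halfwidth: np.ndarray  # half-width (px) at those l values
    colony: int | None = None

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def halfwidth_at(self, l: np.ndarray) -> np.ndarray:
        return np.interp(l, self.halfwidth_grid, self.halfwidth)


def _fit_region(label: int, mask: np.ndarray, n_bins: int | None = None) -> CellRegion:
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T, bias=True)
    vals, vecs = np.linalg.eigh(cov)  # ascending
    major = vecs[:, 1]
    angle = float(np.arctan2(major[1], major[0]))
    # uniform ellipse: second moment along an axis = (half-axis)^2 / 4
    a = 2.0 * np.sqrt(max(vals[1], 0.0))
    b = 2.0 * np.sqrt(max(vals[0], 0.0))
    t = (pts - c) @ major
    t0, t1 = t.min(), t.max()
    p0 = c + t0 * major
    p1 = c + t1 * major
    span = t1 - t0
    if n_bins is None:
        n_bins = max(8, int(round(span / 3.0)))
    edges = np.linspace(t0, t1, n_bins + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    widths = counts / (2.0 * np.diff(edges))  # area-based local half-width, px
    widths = np.clip(widths, 0.5, None)
    grid = ((edges[:-1] + edges[1:]) / 2.0 - t0) / span
    return CellRegion(
        label=label,
        mask=mask,
        centroid=(float(c[0]), float(c[1])),
        axes=(float(a), float(b)),
        angle=angle,
        backbone=(p0, p1),
        halfwidth_grid=grid,
        halfwidth=widths,
    )


def segment_cells(
    image: np.ndarray,
    label_mask: np.ndarray | None = None,
    min_area: int = 50,
    max_area: int = 100000,
    max_aspect: float = 25.0,
) -> list[CellRegion]:
    """Segment ellipse-like cell objects.

    When ``label_mask`` is given (integer labels, 0 = background) the
    thresholding step is bypassed.  Otherwise the reference image is
    Otsu-thresholded, holes are filled, and connected components within
    the area / aspect sanity bounds become regions.  Regions are returned
    ordered by label.
    """
    if label_mask is None:
        img = np.asarray(image, dtype=float)
        if img.ndim != 2:
            raise ValueError("reference image must be 2D")
        if img.max() <= img.min():
            return []
        binary = img > threshold_otsu(img)
        binary = ndimage.binary_fill_holes(binary)
        label_mask, _ = ndimage.label(binary)
    labels = np.unique(label_mask)
    labels = labels[labels > 0]
    regions = []
    for lab in labels:
        mask = label_mask == lab
        area = int(mask.sum())
        if not (min_area <= area <= max_area):
            continue
        reg = _fit_region(int(lab), mask)
        if reg.axes[1] > 0 and reg.axes[0] / max(reg.axes[1], 0.5) > max_aspect:
            continue
        regions.append(reg)
    return regions


def group_colonies(regions: list[CellRegion], gap_px: int = 2) -> list[CellRegion]:
    """Assign colony ids: regions whose ``gap_px``-dilated masks touch share one.

    Returns new regions (input is not mutated) with ``colony`` set; colony
    ids are consecutive integers ordered by the smallest member label.
    """
    if gap_px < 0:
        raise ValueError("gap_px must be >= 0")
    n = len(regions)
    dil = [
        ndimage.binary_dilation(r.mask, iterations=gap_px) if gap_px else r.mask
        for r in regions
    ]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.any(dil[i] & dil[j]):
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    out = []
    order = sorted(range(n), key=lambda i: regions[i].label)
    for i in order:
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        out.append(replace(regions[i], colony=roots[r]))
    return out


def filter_colonies(regions: list[CellRegion], max_cells: int = 8) -> list[CellRegion]:
    """Drop every cell of any colony with more than ``max_cells`` members."""
    counts: dict[int, int] = {}
    for r in regions:
        counts[r.colony] = counts.get(r.colony, 0) + 1
    return [r for r in regions if counts[r.colony] <= max_cells]


def filter_dim_cells(
    movie: Movie,
    regions: list[CellRegion],
    ratio: float = 1.1,
    n_frames: int = 10,
    bg_dilate_px: int = 5,
) -> list[CellRegion]:
    """Drop cells not brighter than ``ratio`` x the background fluorescence.

    Fluorescence means (camera-inverted, photons) are taken over the first
    ``n_frames`` frames; background is the field of view outside all masks
    dilated by ``bg_dilate_px``.  A cell whose in-mask mean is less than or
    equal to ``ratio`` times the background mean is removed.
    """
    if movie.n_frames < n_frames:
        raise ValueError(f"movie has fewer than {n_frames} frames")
    mean_img = movie.camera.to_photons(movie.data[:n_frames].astype(float).mean(axis=0))
    union = np.zeros(mean_img.shape, dtype=bool)
    for r in regions:
        union |= r.mask
    bg_mask = ~ndimage.binary_dilation(union, iterations=bg_dilate_px)
    if not bg_mask.any():
        raise ValueError("no background pixels left to estimate the baseline")
    bg = mean_img[bg_mask].mean()
    kept = []
    for r in regions:
        if mean_img[r.mask].mean() > ratio * bg:
            kept.append(r)
    return kept


def to_cell_coordinates(
    region: CellRegion,
    point_xy: tuple[float, float],
    tol_px: int = 3,
) -> NormalizedPoint:
    """Map an image point (px) to normalized cell coordinates (l, s).

    ``l`` is the normalized projection of the point onto the backbone
    (0 and 1 at the poles); ``s`` is the signed perpendicular offset
    divided by the local half-width.  Points farther than ``tol_px``
    (Chebyshev, via binary dilation) outside the mask raise ValueError.
    """
    x, y = float(point_xy[0]), float(point_xy[1])
    h, w = region.mask.shape
    i, j = int(round(y)), int(round(x))
    inside = 0 <= i < h and 0 <= j < w and region.mask[i, j]
    if not inside:
        dil = _dilated_mask(region, tol_px)
        if not (0 <= i < h and 0 <= j < w and dil[i, j]):
            raise ValueError("point is outside the cell beyond the allowed tolerance")
    p0, p1 = region.backbone
    axis = p1 - p0
    span = np.linalg.norm(axis)
    u = axis / span
    nvec = np.array([-u[1], u[0]])
    rel = np.array([x, y]) - p0
    l = float(np.clip(rel @ u / span, 0.0, 1.0))
    perp = float(rel @ nvec)
    s = perp / float(region.halfwidth_at(l))
    return NormalizedPoint(l=l, s=s)


def _dilated_mask(region: CellRegion, tol_px: int) -> np.ndarray:
    cache = getattr(region, "_dilated_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(region, "_dilated_cache", cache)
    if tol_px not in cache:
        cache[tol_px] = ndimage.binary_dilation(region.mask, iterations=tol_px)
    return cache[tol_px]
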