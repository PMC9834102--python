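"""Activation segmentation of the activity map.

Reproduces the map-to-mask chain used intraoperatively: threshold the raw
activity map at mean + SD computed within the trepanation window, remove
connected components smaller than 10 pixels, keep the three largest
components as the activation area, and rasterize its convex hull.

Conventions (each exposed as a parameter): population SD; strict
inequality at the threshold so a constant map yields an empty mask;
8-connectivity for components; ties between equal-sized components broken
by ascending first raster index after descending size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from skimage import measure, morphology

from .spectral import ActivityMap

__all__ = [
    "RegionMaskSet",
    "ActivationSegmentation",
    "threshold_activity",
    "remove_small_components",
    "select_largest_components",
    "convex_hull_mask",
    "segment_activation",
]


@dataclass
class RegionMaskSet:
    """Trepanation, sensory-cortex (PSC) and reference-activation masks.

    All masks live on the activity map's grid. The expected nesting —
    psc ⊆ trepanation and reference ⊆ trepanation — is validated;
    violations are recorded in ``nesting_violations`` rather than
    raised, because manually segmented masks from real acquisitions can
    be a few pixels sloppy at the borders.
    """

    trepanation: np.ndarray
    psc: np.ndarray | None = None
    reference_activation: np.ndarray | None = None
    nesting_violations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trepanation = np.asarray(self.trepanation, dtype=bool)
        for name in ("psc", "reference_activation"):
            mask = getattr(self, name)
            if mask is None:
                continue
            mask = np.asarray(mask, dtype=bool)
            setattr(self, name, mask)
            if mask.shape != self.trepanation.shape:
                raise ValueError(f"{name} mask shape {mask.shape} does not match "
                                 f"trepanation {self.trepanation.shape}")
            outside = int(np.count_nonzero(mask & ~self.trepanation))
            if outside:
                self.nesting_violations.append(
                    f"{name}: {outside} pixels outside trepanation"
                )


@dataclass
class ActivationSegmentation:
    """Every stage of the threshold → opening → selection chain.

    Invariant: activation ⊆ opened_map ⊆ thresholded_map ⊆ trepanation,
    and hull ⊇ activation. ``components`` lists the retained components
    as ``(label, pixel_count, (centroid_row, centroid_col))`` in the
    deterministic selection order.
    """

    z_thresh: float
    thresholded_map: np.ndarray
    opened_map: np.ndarray
    activation: np.ndarray
    components: list[tuple[int, int, tuple[float, float]]]
    hull: np.ndarray
    k_sd: float = 1.0
    min_size: int = 10
    k: int = 3
    connectivity: int = 8


def _as_ratio(activity: ActivityMap | np.ndarray) -> np.ndarray:
    if isinstance(activity, ActivityMap):
        return activity.ratio
    return np.asarray(activity, dtype=np.float64)


def threshold_activity(
    activity: ActivityMap | np.ndarray,
    trepanation: np.ndarray,
    k_sd: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Threshold the activity map at mean + k_sd · SD within trepanation.

    Statistics use only trepanation pixels (the craniotomy window is the
    only cortex the camera sees) with the population SD. Returns the
    threshold value and the boolean supra-threshold mask, strict
    inequality, restricted to the trepanation.
    """
    ratio = _as_ratio(activity)
    trepanation = np.asarray(trepanation, dtype=bool)
    if ratio.shape != trepanation.shape:
        raise ValueError("activity map and trepanation mask shapes differ")
    if not trepanation.any():
        raise ValueError("trepanation mask is empty")
    values = ratio[trepanation]
    z_thresh = float(values.mean() + k_sd * values.std(ddof=0))
    return z_thresh, (ratio > z_thresh) & trepanation


def _skimage_connectivity(connectivity: int) -> int:
    if connectivity == 8:
        return 2
    if connectivity == 4:
        return 1
    raise ValueError("connectivity must be 4 or 8")


def remove_small_components(
    mask: np.ndarray,
    min_size: int = 10,
    connectivity: int = 8,
) -> np.ndarray:
    """Remove connected components strictly smaller than ``min_size``.

    Area opening: a 10-pixel component survives ``min_size=10`` intact,
    a 9-pixel one is deleted.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_size <= 1:
        return mask.copy()
    # max_size semantics: components <= max_size removed, i.e. < min_size.
    return morphology.remove_small_objects(
        mask, max_size=min_size - 1,
        connectivity=_skimage_connectivity(connectivity),
    )


def _labeled_components(
    mask: np.ndarray, connectivity: int
) -> list[tuple[int, int, tuple[float, float], int]]:
    """(label, size, centroid, first_raster_index) per component."""
    labels = measure.label(mask, connectivity=_skimage_connectivity(connectivity))
    out = []
    flat = labels.ravel()
    for region in measure.regionprops(labels):
        first = int(np.argmax(flat == region.label))
        out.append(
            (int(region.label), int(region.area), tuple(map(float, region.centroid)), first)
        )
    return out


def select_largest_components(
    mask: np.ndarray,
    k: int = 3,
    connectivity: int = 8,
) -> tuple[np.ndarray, list[tuple[int, int, tuple[float, float]]]]:
    """Union of the k largest components, plus their descriptors.

    Fewer than k components means all are kept. Equal sizes are ordered
    by ascending first raster index, so the selection is deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    comps = _labeled_components(mask, connectivity)
    comps.sort(key=lambda c: (-c[1], c[3]))
    kept = comps[:k]
    labels = measure.label(mask, connectivity=_skimage_connectivity(connectivity))
    union = np.isin(labels, [c[0] for c in kept]) if kept else np.zeros_like(mask)
    return union, [(c[0], c[1], c[2]) for c in kept]


def convex_hull_mask(mask: np.ndarray) -> np.ndarray:
    """Rasterized convex hull of the true pixels' centers.

    A grid pixel is in the hull iff its center lies inside (or on) the
    convex hull of all true-pixel centers, so the result is always a
    superset of the input and idempotent. Degenerate inputs — empty,
    single pixel, collinear points — reduce to the input, the point, or
    the rasterized segment respectively.
    """
    mask = np.asarray(mask, dtype=bool)
    points = np.argwhere(mask)
    if len(points) == 0:
        return np.zeros_like(mask)
    out = mask.copy()
    rmin, cmin = points.min(axis=0)
    rmax, cmax = points.max(axis=0)
    grid = np.argwhere(np.ones((rmax - rmin + 1, cmax - cmin + 1), dtype=bool))
    grid = grid + [rmin, cmin]
    try:
        tri = Delaunay(points.astype(np.float64))
        inside = tri.find_simplex(grid.astype(np.float64)) >= 0
        hull_pts = grid[inside]
    except QhullError:
        # Collinear (or single/duplicate) points: hull is the segment
        # between the two extremes along the spread direction.
        centered = points - points.mean(axis=0)
        direction = centered[np.argmax(np.abs(centered).sum(axis=1))]
        if not direction.any():
            return out
        proj = centered @ direction
        p0, p1 = points[np.argmin(proj)], points[np.argmax(proj)]
        n_steps = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1])))
        ts = np.linspace(0.0, 1.0, n_steps + 1)
        hull_pts = np.rint(p0 + ts[:, None] * (p1 - p0)).astype(int)
    result = np.zeros_like(mask)
    result[hull_pts[:, 0], hull_pts[:, 1]] = True
    return result | out


def segment_activation(
    activity: ActivityMap | np.ndarray,
    trepanation: np.ndarray,
    min_size: int = 10,
    k: int = 3,
    k_sd: float = 1.0,
    connectivity: int = 8,
) -> ActivationSegmentation:
    """Full segmentation chain: threshold, open, select, hull."""
    z_thresh, thresholded = threshold_activity(activity, trepanation, k_sd=k_sd)
    opened = remove_small_components(thresholded, min_size=min_size,
                                     connectivity=connectivity)
    activation, components = select_largest_components(opened, k=k,
                                                       connectivity=connectivity)
    hull = convex_hull_mask(activation)
    return ActivationSegmentation(
        z_thresh=z_thresh,
        thresholded_map=thresholded,
        opened_map=opened,
        activation=activation,
        components=components,
        hull=hull,
        k_sd=k_sd,
        min_size=min_size,
        k=k,
        connectivity=connectivity,
    )
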