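"""Quantitative agreement between activation maps.

Three DICE variants against a reference mask (segmented activation,
its convex hull, and the complete thresholded map — all within the
trepanation), per-region quartile statistics of raw activity values over
the disjoint partition {reference activation, PSC minus reference,
surrounding = trepanation minus PSC}, and composition of per-site
segmentations into one topographic label map with a pairwise overlap
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .segment import ActivationSegmentation, RegionMaskSet
from .spectral import ActivityMap

__all__ = [
    "ComparisonReport",
    "TopographicMap",
    "dice",
    "dice_triplet",
    "region_statistics",
    "compose_topography",
]

REGION_NAMES = ("reference_activation", "psc_minus_reference", "surrounding")


@dataclass
class ComparisonReport:
    """DICE triplet plus per-region distribution statistics.

    ``region_stats`` maps each region name to a dict with keys
    ``median``, ``q1``, ``q3`` (NaN when the region is empty) and ``n``.
    The three regions partition the trepanation, so their ``n`` values
    sum to the trepanation pixel count.
    """

    dice_activation: float
    dice_hull: float
    dice_full: float
    region_stats: dict[str, dict[str, float]]
    z_thresh: float | None = None

    def to_dict(self) -> dict:
        return {
            "dice": {
                "activation": self.dice_activation,
                "hull": self.dice_hull,
                "full_thresholded": self.dice_full,
            },
            "z_thresh": self.z_thresh,
            "region_stats": self.region_stats,
        }


@dataclass
class TopographicMap:
    """Integer label image of stimulation-site activations.

    0 is background; label i (1-based) is the activation of
    ``site_names[i-1]``. Overlapping pixels go to the earlier-listed
    site; the full per-site masks are preserved in ``site_masks`` so the
    composition loses nothing, and ``overlap_dsc`` holds the pairwise
    DICE matrix of the original site masks.
    """

    label_map: np.ndarray
    site_names: list[str]
    site_masks: list[np.ndarray]
    overlap_dsc: np.ndarray
    overlap_policy: str = "first_listed_site_wins"
    overlap_pixels: dict[str, int] = field(default_factory=dict)

    def mask_for(self, name: str) -> np.ndarray:
        return self.site_masks[self.site_names.index(name)]

    def centroids(self) -> list[tuple[float, float]]:
        """Per-site centroid of the original (un-resolved) mask."""
        out = []
        for mask in self.site_masks:
            pts = np.argwhere(mask)
            out.append(tuple(pts.mean(axis=0)) if len(pts) else (np.nan, np.nan))
        return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """DICE similarity 2|a∩b| / (|a|+|b|) of two boolean masks.

    Two empty masks have no defined overlap ratio; the conservative
    convention here is 0 with a warning (returning 1 would fabricate
    agreement out of absence).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks is undefined; returning 0.0",
                      stacklevel=2)
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def dice_triplet(
    seg: ActivationSegmentation,
    reference: np.ndarray,
    trepanation: np.ndarray,
) -> tuple[float, float, float]:
    """DICE of the reference against activation, hull and thresholded map.

    The reference mask is clipped to the trepanation first — only the
    craniotomy window is comparable across modalities.
    """
    reference = np.asarray(reference, dtype=bool) & np.asarray(trepanation, dtype=bool)
    return (
        dice(seg.activation, reference),
        dice(seg.hull, reference),
        dice(seg.thresholded_map, reference),
    )


def _quartiles(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {"median": float("nan"), "q1": float("nan"),
                "q3": float("nan"), "n": 0}
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "n": int(values.size)}


def region_statistics(
    activity: ActivityMap | np.ndarray,
    masks: RegionMaskSet,
) -> dict[str, dict[str, float]]:
    """Median/Q1/Q3 of raw activity values in three disjoint regions.

    Regions: the reference activation; the PSC outside the reference;
    and the surrounding — everything in the trepanation outside the
    PSC. Quartiles use linear interpolation between order statistics.
    Empty regions report NaN statistics with n = 0.
    """
    ratio = activity.ratio if isinstance(activity, ActivityMap) else np.asarray(activity)
    if masks.psc is None or masks.reference_activation is None:
        raise ValueError("region statistics need psc and reference_activation masks")
    trep = masks.trepanation
    psc = masks.psc & trep
    reference = masks.reference_activation & psc
    regions = {
        "reference_activation": reference,
        "psc_minus_reference": psc & ~reference,
        "surrounding": trep & ~psc,
    }
    return {name: _quartiles(ratio[sel]) for name, sel in regions.items()}


def compose_topography(
    segmentations: Sequence[ActivationSegmentation],
    site_names: Sequence[str],
) -> TopographicMap:
    """Assemble per-site activations into one topographic label map.

    Sites are painted in listing order; a pixel claimed by several sites
    keeps the earliest label (policy recorded on the result, counts per
    site in ``overlap_pixels``). The pairwise DICE matrix of the raw
    site masks quantifies how much the policy had to resolve.
    """
    if len(segmentations) != len(site_names):
        raise ValueError("one site name per segmentation required")
    names = list(site_names)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicated site names: {names}")
    if not segmentations:
        raise ValueError("at least one segmentation required")
    shapes = {seg.activation.shape for seg in segmentations}
    if len(shapes) != 1:
        raise ValueError("all segmentations must share one grid")

    site_masks = [seg.activation.astype(bool) for seg in segmentations]
    label_map = np.zeros(site_masks[0].shape, dtype=np.int32)
    overlap_pixels: dict[str, int] = {}
    for i, (name, mask) in enumerate(zip(names, site_masks), start=1):
        claimed = mask & (label_map > 0)
        overlap_pixels[name] = int(claimed.sum())
        label_map[mask & (label_map == 0)] = i

    n = len(site_masks)
    dsc = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dsc[i, j] = dsc[j, i] = dice(site_masks[i], site_masks[j])
    return TopographicMap(
        label_map=label_map,
        site_names=names,
        site_masks=site_masks,
        overlap_dsc=dsc,
        overlap_pixels=overlap_pixels,
    )
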