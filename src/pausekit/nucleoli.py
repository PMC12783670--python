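"""Nucleolar-stress image statistics.

Segments fibrillarin/RPL7-positive regions from a 2-D grayscale image by a
global threshold (Otsu by default), labels 8-connected components, and computes
the area statistics used to read out nucleolar stress and ribosome biogenesis:
median nucleolus area, the maximum nucleolus area per nucleus, and the fraction
of cells carrying an intranucleolar aggregate above a size cutoff. Z-stacks are
assumed to be reduced upstream by maximum-intensity projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "NucleolusMask",
    "NucleusRegion",
    "DegenerateThresholdError",
    "segment_nucleoli",
    "median_nucleoli_area",
    "nuclei_from_labels",
    "assign_components_to_nuclei",
    "max_area_per_nucleus",
    "fraction_cells_with_aggregates",
]


class DegenerateThresholdError(ValueError):
    """Otsu thresholding requested on a constant image."""


@dataclass
class NucleolusMask:
    """Binary nucleolar mask with labeled components and per-component areas."""

    mask: np.ndarray
    labels: np.ndarray
    areas: dict[int, int]
    threshold: float
    min_object_size: int

    @property
    def n_components(self) -> int:
        return len(self.areas)

    def centroids(self) -> dict[int, tuple[float, float]]:
        return {p.label: p.centroid for p in regionprops(self.labels)}


@dataclass
class NucleusRegion:
    """One nucleus (e.g. from a DAPI mask) as a boolean pixel region."""

    nucleus_id: int
    mask: np.ndarray
    components: list[int] = field(default_factory=list)


def segment_nucleoli(
    image: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_object_size: int = 4,
) -> NucleolusMask:
    """Global-threshold segmentation of nucleolar regions.

    ``method`` is ``"otsu"`` (data-driven threshold; raises
    :class:`DegenerateThresholdError` on a constant image) or ``"fixed"``
    (requires ``fixed_threshold``). Pixels with intensity ≥ threshold are
    foreground; 8-connected components smaller than ``min_object_size`` pixels
    are removed and the rest relabeled 1..k.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if method == "otsu":
        if image.min() == image.max():
            raise DegenerateThresholdError("constant image: Otsu threshold undefined")
        threshold = float(threshold_otsu(image))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = image >= threshold
    raw_labels = label(mask, connectivity=2)
    areas: dict[int, int] = {}
    labels = np.zeros_like(raw_labels)
    next_id = 1
    for lab in range(1, raw_labels.max() + 1):
        sel = raw_labels == lab
        area = int(sel.sum())
        if area < min_object_size:
            mask[sel] = False
            continue
        labels[sel] = next_id
        areas[next_id] = area
        next_id += 1
    return NucleolusMask(mask=mask, labels=labels, areas=areas, threshold=threshold, min_object_size=min_object_size)


def median_nucleoli_area(mask: NucleolusMask) -> float:
    """Median component area in px²; even counts average the middle two."""
    if not mask.areas:
        raise ValueError("no nucleolar components in mask")
    return float(np.median(sorted(mask.areas.values())))


def nuclei_from_labels(nucleus_labels: np.ndarray) -> list[NucleusRegion]:
    """Build disjoint :class:`NucleusRegion` objects from a labeled image."""
    nucleus_labels = np.asarray(nucleus_labels)
    return [
        NucleusRegion(nucleus_id=int(lab), mask=nucleus_labels == lab)
        for lab in np.unique(nucleus_labels)
        if lab != 0
    ]


def assign_components_to_nuclei(
    mask: NucleolusMask, nuclei: list[NucleusRegion]
) -> dict[int, list[int]]:
    """Assign each component to the nucleus containing its (rounded) centroid.

    Components whose centroid falls in no nucleus are unassigned. Nuclei are
    required to be disjoint, so assignment is unambiguous.
    """
    if nuclei:
        stacked = np.zeros(nuclei[0].mask.shape, dtype=int)
        for nuc in nuclei:
            if (stacked[nuc.mask] != 0).any():
                raise ValueError("nucleus regions overlap")
            stacked[nuc.mask] = nuc.nucleus_id
    assignment: dict[int, list[int]] = {nuc.nucleus_id: [] for nuc in nuclei}
    for comp_id, (r, c) in mask.centroids().items():
        ri = int(np.clip(round(r), 0, mask.mask.shape[0] - 1))
        ci = int(np.clip(round(c), 0, mask.mask.shape[1] - 1))
        if nuclei:
            owner = stacked[ri, ci]
            if owner:
                assignment[int(owner)].append(comp_id)
    for nuc in nuclei:
        nuc.components = assignment[nuc.nucleus_id]
    return assignment


def max_area_per_nucleus(mask: NucleolusMask, nuclei: list[NucleusRegion]) -> dict[int, int]:
    """Largest nucleolar component area within each nucleus (0 if none)."""
    assignment = assign_components_to_nuclei(mask, nuclei)
    return {
        nid: max((mask.areas[c] for c in comps), default=0)
        for nid, comps in assignment.items()
    }


def fraction_cells_with_aggregates(
    mask: NucleolusMask,
    nuclei: list[NucleusRegion],
    min_aggregate_area: int = 9,
    rois: list[np.ndarray] | None = None,
) -> tuple[float, list[dict[str, int]]]:
    """Fraction of nuclei carrying ≥ 1 component of at least the cutoff area.

    With ``rois`` (boolean masks), nuclei are tallied per ROI by the position
    of their own centroid, mirroring region-of-interest counting in widefield
    imaging; the returned list has one ``{"n_nuclei", "n_positive"}`` per ROI.
    """
    if not nuclei:
        raise ValueError("no nuclei supplied")
    assignment = assign_components_to_nuclei(mask, nuclei)
    positive = {
        nid: any(mask.areas[c] >= min_aggregate_area for c in comps)
        for nid, comps in assignment.items()
    }
    fraction = sum(positive.values()) / len(positive)
    tallies: list[dict[str, int]] = []
    if rois is not None:
        centroids = {}
        for nuc in nuclei:
            rr, cc = np.nonzero(nuc.mask)
            centroids[nuc.nucleus_id] = (int(round(rr.mean())), int(round(cc.mean())))
        for roi in rois:
            inside = [nid for nid, (r, c) in centroids.items() if roi[r, c]]
            tallies.append(
                {"n_nuclei": len(inside), "n_positive": sum(positive[n] for n in inside)}
            )
    return float(fraction), tallies
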