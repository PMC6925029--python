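"""Nuclear and whole-cell segmentation from DAPI and pan-CK channels.

Nuclei are segmented from the DAPI channel by global thresholding (Otsu by
default) followed by a distance-transform watershed that splits fused objects
where the distance map has several robust (h-)maxima. Whole-cell masks are
grown from each nucleus over the thresholded cytokeratin signal; cells without
cytokeratin (leukocytes, CK-low tumor cells) fall back to a fixed morphological
dilation of the nucleus so intensity features remain computable for every
object. Conventions: 8-connectivity, 0-based (row, col) coordinates, label 0 =
background, each pixel belongs to exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk as disk_footprint
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "SegmentationResult",
    "segment_nuclei",
    "segment_cells",
    "find_touching_groups",
    "segment_frame",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    """Matched nuclear and cell label masks for one frame.

    Invariants: the two masks share an identical label set, every nuclear mask
    is contained in the cell mask of the same label, 0 is background.
    """

    nuclear_labels: np.ndarray
    cell_labels: np.ndarray
    params_used: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        labs = np.unique(self.nuclear_labels)
        return labs[labs > 0]

    def object_index(self) -> pd.DataFrame:
        """One row per object: centroid of the nucleus, pixel counts."""
        rows = []
        for lab in self.labels:
            nuc = self.nuclear_labels == lab
            r, c = np.nonzero(nuc)
            rows.append(
                {
                    "label": int(lab),
                    "centroid_row": float(r.mean()),
                    "centroid_col": float(c.mean()),
                    "nuclear_area": int(nuc.sum()),
                    "cell_area": int((self.cell_labels == lab).sum()),
                }
            )
        return pd.DataFrame(
            rows, columns=["label", "centroid_row", "centroid_col", "nuclear_area", "cell_area"]
        )


def _global_threshold(image: np.ndarray, method: str, value: float | None) -> float:
    if method == "fixed":
        if value is None:
            raise ValueError("threshold_method='fixed' requires a threshold value")
        return float(value)
    if method == "otsu":
        return float(threshold_otsu(image))
    raise ValueError(f"unknown threshold_method {method!r}")


def segment_nuclei(
    dapi: np.ndarray,
    min_area_px: int = 20,
    threshold_method: str = "otsu",
    threshold: float | None = None,
    split_h: float = 2.0,
) -> np.ndarray:
    """Label nuclei in a single-channel DAPI image.

    An all-background (constant or empty) image yields an empty mask, not an
    error. Fused components are split by watershed when the interior distance
    map has more than one h-maximum (``split_h`` in pixels of distance).
    """
    dapi = np.asarray(dapi)
    if dapi.ndim != 2:
        raise ValueError("dapi must be a 2-D image")
    if np.all(dapi < 0):
        raise ValueError("image must be non-negative")
    if dapi.max() == dapi.min():
        return np.zeros(dapi.shape, dtype=np.int32)

    thr = _global_threshold(dapi, threshold_method, threshold)
    mask = dapi > thr
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    labels, n_components = ndimage.label(mask, structure=_STRUCT8)
    distance = ndimage.distance_transform_edt(mask)
    # markers: per component, the region within split_h of its distance peak.
    # A single convex object yields one connected marker (discrete EDT ridge
    # plateaus stay joined); fused objects separated by a valley deeper than
    # split_h yield one marker per lobe and are split by watershed.
    markers = np.zeros_like(labels)
    n_markers = 0
    needs_split = False
    for comp, sl in enumerate(ndimage.find_objects(labels), start=1):
        region = labels[sl] == comp
        dist = distance[sl]
        peak_region = region & (dist > dist[region].max() - split_h)
        blobs, n_blobs = ndimage.label(peak_region, structure=_STRUCT8)
        markers[sl][peak_region] = blobs[peak_region] + n_markers
        n_markers += n_blobs
        needs_split |= n_blobs > 1
    if needs_split:
        labels = watershed(-distance, markers=markers, mask=mask, connectivity=2)

    # area filter, then compact labels
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area_px)
    labels[np.isin(labels, small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(
    ck: np.ndarray,
    nuclear_labels: np.ndarray,
    dapi: np.ndarray | None = None,
    fallback_dilation_px: int = 4,
    threshold_method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Grow a whole-cell mask for every nucleus.

    Pixels of the thresholded CK foreground (plus a dilated halo around every
    nucleus, which guarantees a cytoplasmic rim for CK-negative cells) are
    assigned to the nearest nucleus; each cell mask is then restricted to the
    connected component containing its nucleus, so the label sets of the
    nuclear and cell masks correspond 1:1 and nucleus <= cell everywhere.
    """
    ck = np.asarray(ck)
    nuclear_labels = np.asarray(nuclear_labels)
    if ck.shape != nuclear_labels.shape:
        raise ValueError("ck image and nuclear mask shapes differ")
    if dapi is not None and np.asarray(dapi).shape != ck.shape:
        raise ValueError("dapi image shape differs from ck image")

    out = np.zeros(ck.shape, dtype=np.int32)
    if nuclear_labels.max() == 0:
        return out

    nuc_binary = nuclear_labels > 0
    halo = ndimage.binary_dilation(
        nuc_binary, structure=disk_footprint(fallback_dilation_px)
    )
    if ck.max() > ck.min():
        thr = _global_threshold(ck, threshold_method, threshold)
        allowed = (ck > thr) | halo
    else:
        allowed = halo  # uniform CK: every cell mask is the dilated nucleus

    # nearest-nucleus assignment (euclidean distance transform indices)
    _, (ir, ic) = ndimage.distance_transform_edt(~nuc_binary, return_indices=True)
    assigned = nuclear_labels[ir, ic]
    assigned[~allowed] = 0

    for sl, lab in zip(ndimage.find_objects(assigned), range(1, assigned.max() + 1)):
        if sl is None:
            continue
        region = assigned[sl] == lab
        comps, _ = ndimage.label(region, structure=_STRUCT8)
        keep = np.unique(comps[(nuclear_labels[sl] == lab) & region])
        keep = keep[keep > 0]
        region &= np.isin(comps, keep)
        out[sl][region] = lab
    out[nuclear_labels > 0] = nuclear_labels[nuclear_labels > 0]
    return out


def find_touching_groups(cell_labels: np.ndarray) -> list[list[int]]:
    """Partition labels into groups of 8-adjacent cell masks.

    Singletons are returned as their own groups; an empty mask yields an empty
    partition. Groups and their members are sorted by label.
    """
    cell_labels = np.asarray(cell_labels)
    labels = np.unique(cell_labels)
    labels = labels[labels > 0]
    if labels.size == 0:
        return []

    parent = {int(lab): int(lab) for lab in labels}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    h, w = cell_labels.shape
    offsets = ((0, 1), (1, 0), (1, 1), (1, -1))  # unique 8-neighbour directions
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        a = cell_labels[r0:r1, c0:c1]
        b = cell_labels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        touching = (a > 0) & (b > 0) & (a != b)
        for la, lb in set(zip(a[touching].tolist(), b[touching].tolist())):
            union(int(la), int(lb))

    groups: dict[int, list[int]] = {}
    for lab in labels:
        groups.setdefault(find(int(lab)), []).append(int(lab))
    return sorted(sorted(g) for g in groups.values())


def segment_frame(
    channels: dict[str, np.ndarray],
    min_area_px: int = 20,
    fallback_dilation_px: int = 4,
    threshold_method: str = "otsu",
    split_h: float = 2.0,
) -> SegmentationResult:
    """Convenience wrapper: nuclei from DAPI, cells from CK, matched labels."""
    nuclear = segment_nuclei(
        channels["dapi"],
        min_area_px=min_area_px,
        threshold_method=threshold_method,
        split_h=split_h,
    )
    cells = segment_cells(
        channels["ck"],
        nuclear,
        dapi=channels.get("dapi"),
        fallback_dilation_px=fallback_dilation_px,
        threshold_method=threshold_method,
    )
    return SegmentationResult(
        nuclear_labels=nuclear,
        cell_labels=cells,
        params_used={
            "min_area_px": min_area_px,
            "fallback_dilation_px": fallback_dilation_px,
            "threshold_method": threshold_method,
            "split_h": split_h,
        },
    )
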