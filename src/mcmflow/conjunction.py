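"""Multimodal conjunction of task-activation maps.

The MCM target region is defined as the voxels activated in *every*
modality (CMRGlu, CBF, BOLD): each statistical map is thresholded and
binarized, the masks are intersected, small clusters are discarded, and
the overlap between modalities is summarised by the Dice coefficient.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["binarize", "intersect", "dice", "cluster_filter"]

# 26-connected neighbourhood (all face/edge/corner neighbours)
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def binarize(stat_map: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a statistical map into a boolean mask (``map > threshold``)."""
    return np.asarray(stat_map) > threshold


def intersect(masks: list[np.ndarray]) -> np.ndarray:
    """Logical AND of two or more grid-aligned boolean masks."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to intersect")
    out = np.asarray(masks[0], dtype=bool)
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError(f"grid mismatch: {out.shape} vs {m.shape}")
        out = out & m
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * np.logical_and(a, b).sum() / denom


def cluster_filter(
    mask: np.ndarray,
    min_volume_cm3: float = 1.0,
    voxel_volume_cm3: float = 1.0,
    merge_symmetric: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Label 26-connected components and drop those below a volume cut.

    Parameters
    ----------
    mask :
        Boolean volume.
    min_volume_cm3 :
        Components strictly smaller than this are removed.
    voxel_volume_cm3 :
        Volume of one voxel.
    merge_symmetric :
        If True, components that map onto each other under reflection
        across the x midplane are given one shared label before the
        volume cut, so homologous left/right clusters are judged (and
        kept or dropped) together.

    Returns
    -------
    labels :
        Integer component labels (0 = background) after filtering.
    filtered :
        Boolean mask of the retained components.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT26)

    if merge_symmetric and n > 1:
        mirrored = labels[::-1, :, :]
        parent = list(range(n + 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        overlap = (labels > 0) & (mirrored > 0)
        for a, b in zip(labels[overlap], mirrored[overlap]):
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        remap = np.array([find(i) for i in range(n + 1)])
        labels = remap[labels]

    out_labels = np.zeros_like(labels)
    filtered = np.zeros_like(mask)
    next_label = 0
    min_voxels = min_volume_cm3 / voxel_volume_cm3
    for lab in np.unique(labels):
        if lab == 0:
            continue
        comp = labels == lab
        if comp.sum() >= min_voxels:
            next_label += 1
            out_labels[comp] = next_label
            filtered |= comp
    return out_labels, filtered
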