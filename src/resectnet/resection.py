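"""Virtual resection: delete streamlines intersecting a resection mask and
infer the predicted post-operative network.

A streamline is removed iff any of its stored points maps to an in-bounds
voxel with mask value 1; points outside the grid count as outside the mask.
The predicted post-operative network therefore always has a subset of the
pre-operative streamlines, so count weights can only decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Parcellation, ResectionMask, StreamlineSet, world_to_voxel
from .network import ConnectivityMatrix, build_connectome

__all__ = [
    "ResectionResult",
    "filter_streamlines",
    "region_volume_remaining",
    "predict_postop_network",
]


@dataclass
class ResectionResult:
    kept: StreamlineSet
    removed: StreamlineSet
    postop_connectome: ConnectivityMatrix
    volume_remaining: dict[int, float]  # region id -> fraction in [0, 1]


def _streamline_hits_mask(points: np.ndarray, mask_values: np.ndarray, affine: np.ndarray) -> bool:
    vox = world_to_voxel(points, affine)
    shape = np.asarray(mask_values.shape)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    if not ok.any():
        return False
    v = vox[ok]
    return bool(mask_values[v[:, 0], v[:, 1], v[:, 2]].any())


def filter_streamlines(streamlines: StreamlineSet, mask: ResectionMask) -> tuple[StreamlineSet, StreamlineSet]:
    """Partition streamlines into (kept, removed) by mask intersection."""
    kept, removed = [], []
    mv = mask.values
    aff = mask.voxel_to_world
    for s in streamlines:
        (removed if _streamline_hits_mask(s, mv, aff) else kept).append(s)
    return (
        StreamlineSet(streamlines=kept, voxel_to_world=streamlines.voxel_to_world),
        StreamlineSet(streamlines=removed, voxel_to_world=streamlines.voxel_to_world),
    )


def region_volume_remaining(parcellation: Parcellation, mask: ResectionMask) -> dict[int, float]:
    """Fraction of each region's voxels left untouched by the mask.

    1 means the region is intact, 0 that it is removed entirely.
    """
    if parcellation.labels.shape != mask.values.shape:
        raise ValueError("mask grid does not match parcellation grid")
    out: dict[int, float] = {}
    labels = parcellation.labels
    masked = mask.values.astype(bool)
    for rid in parcellation.region_ids:
        in_region = labels == rid
        total = int(in_region.sum())
        if total == 0:
            raise ValueError(f"region {rid} has zero voxels")
        hit = int((in_region & masked).sum())
        out[rid] = 1.0 - hit / total
    return out


def predict_postop_network(
    streamlines: StreamlineSet, parcellation: Parcellation, mask: ResectionMask
) -> ResectionResult:
    """Virtual resection: filter streamlines, rebuild the connectome, and
    compute per-region tissue remaining."""
    if parcellation.labels.shape != mask.values.shape:
        raise ValueError("mask grid does not match parcellation grid")
    kept, removed = filter_streamlines(streamlines, mask)
    postop = build_connectome(kept, parcellation)
    vols = region_volume_remaining(parcellation, mask)
    return ResectionResult(kept=kept, removed=removed, postop_connectome=postop, volume_remaining=vols)
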