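"""Endpoint-based connectome construction and weight handling.

A streamline connects region i to region j when its two endpoints (first and
last polyline points) fall inside those regions' label voxels.  Streamlines
with an endpoint in background are discarded; same-region endpoint pairs are
recorded on the diagonal and flagged as self-connections (excluded from all
downstream graph measures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Parcellation, StreamlineSet, world_to_voxel

__all__ = ["ConnectivityMatrix", "build_connectome", "log_transform", "flip_hemispheres"]

WEIGHT_COUNT = "streamline_count"
WEIGHT_LOG10 = "log10_transformed"


@dataclass
class ConnectivityMatrix:
    """Symmetric non-negative region-by-region weight matrix.

    ``weight_kind`` distinguishes raw streamline counts from the
    log10(1+w)-transformed weights used for analysis.  The diagonal holds
    self-connection counts; it is retained for bookkeeping but excluded from
    every graph measure.
    """

    weights: np.ndarray
    region_ids: list[int]
    weight_kind: str = WEIGHT_COUNT
    n_discarded: int = 0
    flipped: bool = False

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        R = len(self.region_ids)
        if W.shape != (R, R):
            raise ValueError(f"weights shape {W.shape} does not match {R} regions")
        if len(set(self.region_ids)) != R:
            raise ValueError("region_ids must be unique")
        if np.any(W < 0):
            raise ValueError("negative weights")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if self.weight_kind not in (WEIGHT_COUNT, WEIGHT_LOG10):
            raise ValueError(f"unknown weight_kind {self.weight_kind!r}")
        self.weights = W

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def offdiagonal(self) -> np.ndarray:
        """Weights with the self-connection diagonal zeroed."""
        W = self.weights.copy()
        np.fill_diagonal(W, 0.0)
        return W

    def index_of(self, region_id: int) -> int:
        return self.region_ids.index(region_id)


def build_connectome(streamlines: StreamlineSet, parcellation: Parcellation) -> ConnectivityMatrix:
    """Count streamlines whose endpoints terminate in each region pair."""
    region_ids = parcellation.region_ids
    if not region_ids:
        raise ValueError("parcellation has no regions")
    id_to_idx = {rid: k for k, rid in enumerate(region_ids)}
    labels = parcellation.labels
    shape = np.asarray(labels.shape)
    R = len(region_ids)
    W = np.zeros((R, R))
    discarded = 0

    if len(streamlines) > 0:
        endpoints = np.array([[s[0], s[-1]] for s in streamlines])  # (n, 2, 3)
        n = endpoints.shape[0]
        vox = world_to_voxel(endpoints.reshape(-1, 3), parcellation.voxel_to_world)
        in_bounds = np.all((vox >= 0) & (vox < shape), axis=1)
        lab = np.zeros(len(vox), dtype=labels.dtype)
        ib = in_bounds.nonzero()[0]
        lab[ib] = labels[vox[ib, 0], vox[ib, 1], vox[ib, 2]]
        lab = lab.reshape(n, 2)
        for la, lb in lab:
            if la == 0 or lb == 0:
                discarded += 1
                continue
            i, j = id_to_idx[int(la)], id_to_idx[int(lb)]
            W[i, j] += 1
            if i != j:
                W[j, i] += 1

    return ConnectivityMatrix(weights=W, region_ids=list(region_ids), n_discarded=discarded)


def log_transform(W: ConnectivityMatrix) -> ConnectivityMatrix:
    """Map each off-diagonal count w to log10(1 + w).

    The +1 offset keeps absent connections at exactly 0 and single-streamline
    connections positive; the diagonal (self-connection counts) is left as
    raw counts since it never enters a measure.
    """
    if W.weight_kind != WEIGHT_COUNT:
        raise ValueError("log_transform requires streamline-count weights (already transformed?)")
    out = np.log10(1.0 + W.offdiagonal())
    np.fill_diagonal(out, np.diag(W.weights))
    return ConnectivityMatrix(
        weights=out, region_ids=list(W.region_ids), weight_kind=WEIGHT_LOG10,
        n_discarded=W.n_discarded, flipped=W.flipped,
    )


def hemisphere_permutation(parcellation: Parcellation) -> np.ndarray:
    """Index permutation swapping each region with its homologue; midline
    regions map to themselves.  Requires an attached region table."""
    if not parcellation.regions:
        raise ValueError("hemisphere flip requires a region table")
    region_ids = parcellation.region_ids
    id_to_idx = {rid: k for k, rid in enumerate(region_ids)}
    perm = np.arange(len(region_ids))
    for r in parcellation.regions:
        if r.hemisphere == "midline":
            continue
        if r.homologue_id is None:
            raise ValueError(f"non-midline region {r.id} ({r.name}) has no homologue")
        perm[id_to_idx[r.id]] = id_to_idx[r.homologue_id]
    return perm


def flip_hemispheres(W: ConnectivityMatrix, parcellation: Parcellation, surgery_side: str) -> ConnectivityMatrix:
    """Swap homologous rows/columns for right-sided resections so the
    surgical hemisphere is always reported as ipsilateral.

    Left-sided patients are returned unchanged (already ipsilateral-left).
    """
    if surgery_side not in ("left", "right"):
        raise ValueError(f"surgery_side must be 'left' or 'right', got {surgery_side!r}")
    if surgery_side == "left":
        return W
    perm = hemisphere_permutation(parcellation)
    flipped = W.weights[np.ix_(perm, perm)]
    return ConnectivityMatrix(
        weights=flipped, region_ids=list(W.region_ids), weight_kind=W.weight_kind,
        n_discarded=W.n_discarded, flipped=not W.flipped,
    )
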