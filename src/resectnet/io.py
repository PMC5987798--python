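"""Geometric data model and file I/O for the resection pipeline.

Volumes (parcellations, resection masks) are NIfTI images; streamlines are
TRK/TCK tractogram files; region tables are tab-separated sidecars carrying
the names, hemispheres and homologue pairings that a label volume cannot.

All world coordinates are millimetres.  Voxel indices are 0-based and follow
the voxel-centre convention: a world point belongs to the voxel whose centre
is nearest after applying the inverse affine, with half-integer coordinates
rounded away from zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram, TckFile, TrkFile

__all__ = [
    "RegionInfo",
    "Parcellation",
    "StreamlineSet",
    "ResectionMask",
    "read_label_volume",
    "write_label_volume",
    "read_mask",
    "write_mask",
    "read_streamlines",
    "write_streamlines",
    "read_region_table",
    "write_region_table",
    "world_to_voxel",
    "voxel_to_world",
]

MASK_BINARISE_THRESHOLD = 0.5


@dataclass(frozen=True)
class RegionInfo:
    """One parcellation region: integer label, name, laterality, homologue."""

    id: int
    name: str
    hemisphere: str  # {"left", "right", "midline"}
    homologue_id: int | None = None

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "midline"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")


@dataclass
class Parcellation:
    """Integer label volume plus affine and (optional) region metadata.

    ``labels`` uses 0 for background; every nonzero label present in the
    volume must appear exactly once in ``regions`` when a region table is
    attached.
    """

    labels: np.ndarray
    voxel_to_world: np.ndarray
    regions: list[RegionInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        self.voxel_to_world = _check_affine(self.voxel_to_world)
        if self.regions:
            ids = [r.id for r in self.regions]
            if len(ids) != len(set(ids)):
                raise ValueError("duplicate region ids in region table")
            present = set(np.unique(self.labels)) - {0}
            missing = present - set(ids)
            if missing:
                raise ValueError(f"labels {sorted(missing)} missing from region table")
            # homologue pairing must be symmetric
            by_id = {r.id: r for r in self.regions}
            for r in self.regions:
                if r.homologue_id is not None:
                    mate = by_id.get(r.homologue_id)
                    if mate is None or mate.homologue_id != r.id:
                        raise ValueError(f"asymmetric homologue pairing for region {r.id}")

    @property
    def region_ids(self) -> list[int]:
        if self.regions:
            return [r.id for r in self.regions]
        return [int(v) for v in np.unique(self.labels) if v != 0]

    def region_voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        out = {int(i): int(c) for i, c in zip(ids, counts) if i != 0}
        for rid in self.region_ids:
            out.setdefault(rid, 0)
        return out


@dataclass
class StreamlineSet:
    """Tractography streamlines: 3-D polylines in world mm plus the
    reference-grid affine they were generated against."""

    streamlines: list[np.ndarray]
    voxel_to_world: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_to_world = _check_affine(self.voxel_to_world)
        cleaned = []
        for s in self.streamlines:
            a = np.asarray(s, dtype=float)
            if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 2:
                raise ValueError("each streamline must be an (n>=2, 3) array")
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite streamline coordinates")
            cleaned.append(a)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class ResectionMask:
    """Binary resection volume on the parcellation grid."""

    values: np.ndarray
    voxel_to_world: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("mask must be 3-D")
        # non-binary inputs are binarised at > 0.5
        self.values = (v > MASK_BINARISE_THRESHOLD).astype(np.uint8)
        self.voxel_to_world = _check_affine(self.voxel_to_world)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def _check_affine(affine: np.ndarray) -> np.ndarray:
    a = np.asarray(affine, dtype=float)
    if a.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(a[:3, :3])) < 1e-12:
        raise ValueError("singular affine")
    return a


# ---------------------------------------------------------------------------
# coordinate transforms


def voxel_to_world(index, affine: np.ndarray) -> np.ndarray:
    """Map a voxel index (or array of indices) to world mm."""
    a = _check_affine(affine)
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    pts = idx @ a[:3, :3].T + a[:3, 3]
    return pts[0] if np.asarray(index).ndim == 1 else pts


def world_to_voxel(point, affine: np.ndarray) -> np.ndarray:
    """Map world-mm point(s) to the nearest integer voxel index.

    Inverse affine then round-to-nearest with ties away from zero
    (voxel-centre convention, 0-based indices).
    """
    a = _check_affine(affine)
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    inv = np.linalg.inv(a)
    cont = pts @ inv[:3, :3].T + inv[:3, 3]
    idx = (np.sign(cont) * np.floor(np.abs(cont) + 0.5)).astype(np.int64)
    return idx[0] if np.asarray(point).ndim == 1 else idx


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_label_volume(path: str | os.PathLike) -> Parcellation:
    """Read an integer NIfTI label volume (region table not attached).

    Floating-point storage is accepted only when every value is integral.
    """
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: non-integer voxel values in label volume")
        data = rounded
    return Parcellation(labels=data.astype(np.int32), voxel_to_world=img.affine)


def write_label_volume(parc: Parcellation, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), parc.voxel_to_world)
    nib.save(img, os.fspath(path))


def read_mask(path: str | os.PathLike) -> ResectionMask:
    """Read a resection mask, binarising at > 0.5."""
    img = nib.load(os.fspath(path))
    return ResectionMask(values=np.asarray(img.dataobj), voxel_to_world=img.affine)


def write_mask(mask: ResectionMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.voxel_to_world)
    nib.save(img, os.fspath(path))


# ---------------------------------------------------------------------------
# streamlines (TRK / TCK)


def read_streamlines(path: str | os.PathLike, reference_affine: np.ndarray | None = None) -> StreamlineSet:
    """Read a TRK or TCK file; polylines are returned in world (RAS) mm.

    ``reference_affine`` supplies the voxel grid the set refers to; TRK
    headers carry one, TCK files do not (identity is assumed if absent).
    """
    path = os.fspath(path)
    tf = nib.streamlines.load(path)  # raises on unknown format / bad header
    sl = [np.asarray(s, dtype=float) for s in tf.streamlines]
    if reference_affine is None:
        hdr_aff = tf.header.get("voxel_to_rasmm") if isinstance(tf.header, dict) else None
        reference_affine = np.asarray(hdr_aff) if hdr_aff is not None else np.eye(4)
        if abs(np.linalg.det(np.asarray(reference_affine)[:3, :3])) < 1e-12:
            reference_affine = np.eye(4)
    return StreamlineSet(streamlines=sl, voxel_to_world=reference_affine)


def write_streamlines(sset: StreamlineSet, path: str | os.PathLike, grid_shape: tuple[int, int, int] | None = None) -> None:
    """Write streamlines to TRK or TCK by extension; coordinates stored in
    world mm so the round-trip is exact to float32 precision."""
    path = os.fspath(path)
    tg = Tractogram([np.asarray(s, dtype=np.float32) for s in sset.streamlines], affine_to_rasmm=np.eye(4))
    if path.endswith(".trk"):
        aff = sset.voxel_to_world
        header = {
            "voxel_to_rasmm": aff.astype(np.float32),
            "voxel_sizes": np.sqrt((aff[:3, :3] ** 2).sum(axis=0)).astype(np.float32),
            "dimensions": np.asarray(grid_shape if grid_shape is not None else (1, 1, 1), dtype=np.uint16),
        }
        TrkFile(tg, header=header).save(path)
    elif path.endswith(".tck"):
        TckFile(tg).save(path)
    else:
        raise ValueError(f"unknown streamline format: {path}")


# ---------------------------------------------------------------------------
# region tables

_REGION_COLUMNS = ["id", "name", "hemisphere", "homologue_id"]


def read_region_table(path: str | os.PathLike) -> list[RegionInfo]:
    """Read the TSV sidecar (columns id, name, hemisphere, homologue_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": int, "name": str, "hemisphere": str})
    missing = set(_REGION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        hom = row.homologue_id
        hom = None if pd.isna(hom) else int(hom)
        out.append(RegionInfo(id=int(row.id), name=str(row.name), hemisphere=row.hemisphere, homologue_id=hom))
    return out


def write_region_table(regions: list[RegionInfo], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(r.id, r.name, r.hemisphere, r.homologue_id if r.homologue_id is not None else "") for r in regions],
        columns=_REGION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
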