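"""Digital phantoms: mirrored two-hemisphere parcellations, streamline
bundles realising a target count connectome, partial-region resection masks,
and outcome-labelled cohorts with planted class structure.

The phantoms exist to exercise conventions and statistics, not anatomy:
regions are axis-aligned boxes, streamlines are straight jittered polylines
densely sampled below the voxel edge so mask-membership tests do not depend
on rasterisation conventions.  Everything is bit-reproducible under a fixed
seed; a single global seed fans out to per-component child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

from .features import BLOCK_CONNECTION, BLOCK_STRENGTH, BLOCK_VOLUME, CohortFeatures
from .io import Parcellation, RegionInfo, ResectionMask, StreamlineSet

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_parcellation",
    "default_target_connectome",
    "make_streamlines",
    "make_resection_mask",
    "make_cohort",
]


@dataclass
class PhantomSpec:
    """Geometry and streamline parameters for one phantom subject.

    ``box_shape`` sets each region's voxel extent (all dims must be >= 3 so
    a box has an interior for endpoint placement); hemispheres mirror across
    the mid-sagittal plane of ``grid_shape``.
    """

    grid_shape: tuple[int, int, int] = (32, 20, 14)
    regions_per_hemisphere: int = 4
    box_shape: tuple[int, int, int] = (4, 4, 4)
    voxel_size_mm: float = 1.0
    target_connectome: dict[tuple[int, int], int] | None = None
    endpoint_jitter_mm: float = 0.2
    point_spacing_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b < 3 for b in self.box_shape):
            raise ValueError("box_shape dims must be >= 3 (interior needed)")
        if self.point_spacing_mm >= self.voxel_size_mm:
            raise ValueError("point spacing must be below the voxel edge")
        if self.regions_per_hemisphere < 1:
            raise ValueError("need at least one region per hemisphere")

    @property
    def region_voxels(self) -> int:
        return int(np.prod(self.box_shape))

    @property
    def n_regions(self) -> int:
        return 2 * self.regions_per_hemisphere


@dataclass
class CohortSpec:
    """Outcome-labelled synthetic cohort with planted informative features.

    Change-ratio features are Beta-distributed (support [0, 1] matches ratio
    semantics), parameterised by mean and concentration.  For the planted
    connection features the class means differ by ``effect_size``: the
    seizure-free (+1) class sits at baseline_mean - effect_size/2 (greater
    reduction) and the not-seizure-free (-1) class at + effect_size/2.
    """

    n_per_class: tuple[int, int] = (30, 30)  # (+1, -1)
    block_sizes: tuple[int, int, int] = (160, 34, 6)  # connection, strength, volume
    n_planted: int = 10
    effect_size: float = 0.4
    baseline_mean: float = 0.5
    concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.block_sizes[0]:
            raise ValueError("cannot plant more features than the connection block holds")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect size must lie in [0, 1]")
        if min(self.n_per_class) < 1:
            raise ValueError("both classes must be non-empty")
        lo = self.baseline_mean - self.effect_size / 2
        hi = self.baseline_mean + self.effect_size / 2
        if lo <= 0.0 or hi >= 1.0:
            raise ValueError("effect size infeasible against [0, 1] truncation")

    @property
    def n_features(self) -> int:
        return int(sum(self.block_sizes))


# ---------------------------------------------------------------------------
# parcellation


def make_parcellation(spec: PhantomSpec) -> Parcellation:
    """Two mirrored hemispheres of labelled boxes.

    Left-hemisphere regions get ids 1..R_h, their right homologues
    R_h+1..2R_h, mirrored across the mid-sagittal (x) plane.
    """
    nx, ny, nz = spec.grid_shape
    bx, by, bz = spec.box_shape
    half = nx // 2
    gap = 1
    # lattice of candidate box origins in the left half, 1-voxel gaps
    xs = list(range(gap, half - bx + 1, bx + gap))
    ys = list(range(gap, ny - by + 1, by + gap))
    zs = list(range(gap, nz - bz + 1, bz + gap))
    slots = [(x, y, z) for z in zs for y in ys for x in xs]
    if len(slots) < spec.regions_per_hemisphere:
        raise ValueError(
            f"grid {spec.grid_shape} fits only {len(slots)} boxes of {spec.box_shape} "
            f"per hemisphere, {spec.regions_per_hemisphere} requested"
        )
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    R_h = spec.regions_per_hemisphere
    regions: list[RegionInfo] = []
    for k in range(R_h):
        x, y, z = slots[k]
        left_id, right_id = k + 1, k + 1 + R_h
        labels[x:x + bx, y:y + by, z:z + bz] = left_id
        # mirror across the mid-sagittal plane
        labels[nx - x - bx:nx - x, y:y + by, z:z + bz] = right_id
        regions.append(RegionInfo(id=left_id, name=f"L{k + 1:02d}", hemisphere="left", homologue_id=right_id))
    for k in range(R_h):
        regions.append(RegionInfo(id=k + 1 + R_h, name=f"R{k + 1:02d}", hemisphere="right", homologue_id=k + 1))
    v = spec.voxel_size_mm
    affine = np.diag([v, v, v, 1.0])
    return Parcellation(labels=labels, voxel_to_world=affine, regions=regions)


def default_target_connectome(n_regions: int, seed: int = 0, density: float = 0.4,
                              min_count: int = 2, max_count: int = 20) -> dict[tuple[int, int], int]:
    """A random symmetric target count connectome over region ids 1..R."""
    rng = np.random.default_rng(seed)
    target: dict[tuple[int, int], int] = {}
    for i in range(1, n_regions + 1):
        for j in range(i + 1, n_regions + 1):
            if rng.random() < density:
                target[(i, j)] = int(rng.integers(min_count, max_count + 1))
    if not target:  # guarantee at least one edge
        target[(1, 2)] = min_count
    return target


# ---------------------------------------------------------------------------
# streamlines


def _interior_voxels(labels: np.ndarray, region_id: int) -> np.ndarray:
    """Voxels of a region at least one voxel away from its boundary, so a
    jittered endpoint that rounds one voxel off still lands in the region."""
    region = labels == region_id
    if not region.any():
        raise ValueError(f"region {region_id} has zero voxels")
    interior = binary_erosion(region)
    if not interior.any():
        interior = region  # degenerate thin region: fall back to all voxels
    return np.argwhere(interior)


def make_streamlines(spec: PhantomSpec, parcellation: Parcellation) -> StreamlineSet:
    """Straight, densely sampled polylines realising the target connectome.

    For each target edge (i, j) with weight w, w polylines run from jittered
    interior points of region i to jittered interior points of region j,
    with consecutive points no further apart than ``point_spacing_mm``.
    """
    target = spec.target_connectome
    if target is None:
        target = default_target_connectome(spec.n_regions, seed=spec.seed)
    valid = set(parcellation.region_ids)
    for (i, j) in target:
        if i not in valid or j not in valid:
            raise ValueError(f"target edge ({i},{j}) references unknown region")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    aff = parcellation.voxel_to_world
    interiors = {rid: _interior_voxels(parcellation.labels, rid) for rid in sorted({r for e in target for r in e})}

    streamlines: list[np.ndarray] = []
    for (i, j) in sorted(target):
        w = int(target[(i, j)])
        if w < 0:
            raise ValueError("negative target count")
        vi, vj = interiors[i], interiors[j]
        for _ in range(w):
            a_vox = vi[rng.integers(len(vi))]
            b_vox = vj[rng.integers(len(vj))]
            a = a_vox @ aff[:3, :3].T + aff[:3, 3] + rng.normal(0.0, spec.endpoint_jitter_mm, 3)
            b = b_vox @ aff[:3, :3].T + aff[:3, 3] + rng.normal(0.0, spec.endpoint_jitter_mm, 3)
            dist = float(np.linalg.norm(b - a))
            n_seg = max(1, int(np.ceil(dist / spec.point_spacing_mm)))
            t = np.linspace(0.0, 1.0, n_seg + 1)[:, None]
            streamlines.append(a[None, :] * (1 - t) + b[None, :] * t)
    return StreamlineSet(streamlines=streamlines, voxel_to_world=aff)


# ---------------------------------------------------------------------------
# resection masks


def make_resection_mask(parcellation: Parcellation, targets: dict[int, float], seed: int = 0) -> ResectionMask:
    """Contiguous partial-region mask covering about the requested fraction
    of each target region, confined to one hemisphere.

    Voxels are taken as anterior-to-posterior slabs (sorted along y) so the
    mask is a contiguous chunk of each box, emulating an anterior-temporal
    style partial resection.
    """
    by_id = {r.id: r for r in parcellation.regions} if parcellation.regions else {}
    hemis = set()
    for rid, frac in targets.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction {frac} out of [0, 1] for region {rid}")
        if by_id:
            hemis.add(by_id[rid].hemisphere)
    if len(hemis - {"midline"}) > 1:
        raise ValueError("target regions must lie in a single hemisphere")
    values = np.zeros(parcellation.labels.shape, dtype=np.uint8)
    for rid, frac in sorted(targets.items()):
        vox = np.argwhere(parcellation.labels == rid)
        if len(vox) == 0:
            raise ValueError(f"region {rid} has zero voxels")
        order = np.lexsort((vox[:, 2], vox[:, 0], vox[:, 1]))  # y-major slabs
        k = int(round(frac * len(vox)))
        take = vox[order[:k]]
        values[take[:, 0], take[:, 1], take[:, 2]] = 1
    return ResectionMask(values=values, voxel_to_world=parcellation.voxel_to_world)


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(spec: CohortSpec) -> tuple[CohortFeatures, dict]:
    """Sample an outcome-labelled cohort of change-ratio features.

    Returns the feature container plus a ground-truth record with the
    planted connection-column indices and per-class means, for recovery
    tests.  Identical seeds give identical matrices.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    n_pos, n_neg = spec.n_per_class
    n = n_pos + n_neg
    m = spec.n_features
    kappa = spec.concentration

    def beta_draw(mean: float, size) -> np.ndarray:
        a = mean * kappa
        b = (1.0 - mean) * kappa
        return rng.beta(a, b, size=size)

    y = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    A = beta_draw(spec.baseline_mean, (n, m))
    planted = rng.choice(spec.block_sizes[0], size=spec.n_planted, replace=False)
    planted = np.sort(planted)
    mean_pos = spec.baseline_mean - spec.effect_size / 2
    mean_neg = spec.baseline_mean + spec.effect_size / 2
    if spec.effect_size > 0:
        A[:n_pos][:, planted] = beta_draw(mean_pos, (n_pos, spec.n_planted))
        A[n_pos:][:, planted] = beta_draw(mean_neg, (n_neg, spec.n_planted))

    blocks = ([BLOCK_CONNECTION] * spec.block_sizes[0]
              + [BLOCK_STRENGTH] * spec.block_sizes[1]
              + [BLOCK_VOLUME] * spec.block_sizes[2])
    names = ([f"conn:{k}" for k in range(spec.block_sizes[0])]
             + [f"strength:{k}" for k in range(spec.block_sizes[1])]
             + [f"volume:{k}" for k in range(spec.block_sizes[2])])
    features = CohortFeatures(A=A, y=y, block_index=blocks, feature_names=names)
    truth = {
        "planted_indices": planted.tolist(),
        "effect_size": spec.effect_size,
        "class_mean_pos": mean_pos,
        "class_mean_neg": mean_neg,
        "seed": spec.seed,
    }
    return features, truth
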