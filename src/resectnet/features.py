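"""Assemble per-subject change metrics into a cohort feature matrix.

The feature space has three blocks, in fixed order: proportional change in
connection strength (one column per eligible region pair, upper-triangle
row-major), proportional change in region strength (one column per region),
and proportion of region volume remaining (one column per region touched by
at least one subject's resection).  Outcomes are +1 (seizure free) / -1
(not seizure free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import ChangeMetrics

__all__ = ["CohortFeatures", "assemble_features", "BLOCK_CONNECTION", "BLOCK_STRENGTH", "BLOCK_VOLUME"]

BLOCK_CONNECTION = "connection_strength"
BLOCK_STRENGTH = "region_strength"
BLOCK_VOLUME = "region_volume"


@dataclass
class CohortFeatures:
    """Subjects-by-features change matrix with block structure and labels."""

    A: np.ndarray  # (n, m)
    y: np.ndarray  # (n,) in {+1, -1}
    block_index: list[str]  # per-column block tag
    feature_names: list[str]
    sample_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.y = np.asarray(self.y)
        n, m = self.A.shape
        if self.y.shape != (n,):
            raise ValueError("y length does not match number of subjects")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("outcomes must be +1 / -1")
        if len(self.block_index) != m or len(self.feature_names) != m:
            raise ValueError("block_index / feature_names length mismatch")
        if self.sample_weights is None:
            self.sample_weights = np.ones(n)
        else:
            self.sample_weights = np.asarray(self.sample_weights, dtype=float)
            if self.sample_weights.shape != (n,):
                raise ValueError("sample_weights length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.A.shape[0]

    @property
    def n_features(self) -> int:
        return self.A.shape[1]

    def block_sizes(self) -> dict[str, int]:
        out = {BLOCK_CONNECTION: 0, BLOCK_STRENGTH: 0, BLOCK_VOLUME: 0}
        for b in self.block_index:
            out[b] += 1
        return out


def assemble_features(
    cohort: list[ChangeMetrics],
    outcomes: np.ndarray,
    pre_connection_counts: list[np.ndarray],
) -> CohortFeatures:
    """Build the cohort feature matrix from per-subject change metrics.

    Connection columns are restricted to region pairs whose pre-operative
    count is nonzero in every subject and whose change ratio is < 1 in at
    least one subject (a connection untouched in everyone carries no
    outcome signal).  Volume columns are restricted to regions intersected
    by at least one subject's mask.

    ``pre_connection_counts`` supplies each subject's pre-operative count
    matrix (off-diagonal), needed for the eligibility rule.
    """
    if not cohort:
        raise ValueError("empty cohort")
    region_ids = cohort[0].region_ids
    for cm in cohort:
        if cm.region_ids != region_ids:
            raise ValueError("subjects use inconsistent region sets")
    if len(pre_connection_counts) != len(cohort):
        raise ValueError("pre_connection_counts length mismatch")
    R = len(region_ids)
    n = len(cohort)

    pre_stack = np.stack([np.asarray(P, dtype=float) for P in pre_connection_counts])  # (n, R, R)
    ratio_stack = np.stack([cm.connection_strength_ratio for cm in cohort])

    cols: list[np.ndarray] = []
    blocks: list[str] = []
    names: list[str] = []

    iu, ju = np.triu_indices(R, k=1)
    present_all = np.all(pre_stack[:, iu, ju] > 0, axis=0)
    changed_any = np.any(ratio_stack[:, iu, ju] < 1, axis=0)
    for k in np.nonzero(present_all & changed_any)[0]:
        i, j = int(iu[k]), int(ju[k])
        cols.append(ratio_stack[:, i, j])
        blocks.append(BLOCK_CONNECTION)
        names.append(f"conn:{region_ids[i]}-{region_ids[j]}")

    for r, rid in enumerate(region_ids):
        cols.append(np.array([cm.region_strength_ratio[r] for cm in cohort]))
        blocks.append(BLOCK_STRENGTH)
        names.append(f"strength:{rid}")

    if all(cm.volume_ratio is not None for cm in cohort):
        vol_stack = np.stack([cm.volume_ratio for cm in cohort])  # (n, R)
        for r, rid in enumerate(region_ids):
            if np.any(vol_stack[:, r] < 1):
                cols.append(vol_stack[:, r])
                blocks.append(BLOCK_VOLUME)
                names.append(f"volume:{rid}")

    A = np.column_stack(cols) if cols else np.empty((n, 0))
    return CohortFeatures(A=A, y=np.asarray(outcomes), block_index=blocks, feature_names=names)
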