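"""End-to-end orchestration: per-subject build -> resect -> metrics, and
cohort-level feature assembly -> grid-searched LOOCV classification.

All randomness flows through explicitly passed seeds; subjects are processed
independently, so any parallelisation cannot change results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CohortFeatures, assemble_features
from .io import Parcellation, ResectionMask, StreamlineSet
from .metrics import ChangeMetrics, change_metrics, compute_metrics
from .model import GridSearchResult, RegularisationGrid, default_grid, grid_search
from .network import ConnectivityMatrix, build_connectome, flip_hemispheres, log_transform
from .resection import predict_postop_network

__all__ = [
    "PipelineConfig",
    "SubjectRecord",
    "run_subject",
    "run_cohort",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "change_to_tidy",
]


@dataclass
class PipelineConfig:
    """Weight handling, grid and evaluation switches for a run.

    ``log_transform_weights`` controls whether graph measures are computed
    on log10(1+count) weights (the default) or raw counts; ratio-type change
    features always use raw counts.
    """

    log_transform_weights: bool = True
    selection_scope: str = "per_fold"
    svm_C: float = 1.0
    lam_values: list[float] = field(default_factory=lambda: default_grid().lam_values.tolist())
    rho_values: list[float] = field(default_factory=lambda: default_grid().rho_values.tolist())
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def grid(self) -> RegularisationGrid:
        return RegularisationGrid(np.asarray(self.lam_values), np.asarray(self.rho_values))


@dataclass
class SubjectRecord:
    """Everything the cohort stage needs from one subject."""

    change: ChangeMetrics
    preop_counts: ConnectivityMatrix
    postop_counts: ConnectivityMatrix
    surgery_side: str


def run_subject(
    streamlines: StreamlineSet,
    parcellation: Parcellation,
    mask: ResectionMask,
    surgery_side: str = "left",
    config: PipelineConfig | None = None,
) -> SubjectRecord:
    """build -> virtual resection -> metrics -> change summary for one subject.

    Right-sided cases are flipped so the surgical hemisphere is always
    reported as ipsilateral (region volumes are remapped through the
    homologue table the same way the matrices are permuted).
    """
    config = config or PipelineConfig()
    pre_counts = build_connectome(streamlines, parcellation)
    result = predict_postop_network(streamlines, parcellation, mask)
    post_counts = result.postop_connectome
    volumes = result.volume_remaining

    if surgery_side == "right":
        pre_counts = flip_hemispheres(pre_counts, parcellation, "right")
        post_counts = flip_hemispheres(post_counts, parcellation, "right")
        hom = {r.id: (r.homologue_id if r.homologue_id is not None else r.id) for r in parcellation.regions}
        volumes = {rid: volumes[hom[rid]] for rid in volumes}
    elif surgery_side != "left":
        raise ValueError(f"surgery_side must be 'left' or 'right', got {surgery_side!r}")

    if config.log_transform_weights:
        pre_w = log_transform(pre_counts)
        post_w = log_transform(post_counts)
    else:
        pre_w, post_w = pre_counts, post_counts

    change = change_metrics(
        compute_metrics(pre_w),
        compute_metrics(post_w),
        pre_counts=pre_counts,
        post_counts=post_counts,
        volume_remaining=volumes,
    )
    return SubjectRecord(change=change, preop_counts=pre_counts, postop_counts=post_counts,
                         surgery_side=surgery_side)


def run_cohort(
    records: list[SubjectRecord],
    outcomes,
    config: PipelineConfig | None = None,
) -> tuple[CohortFeatures, GridSearchResult]:
    """Assemble features across subjects and run the LOOCV grid search."""
    config = config or PipelineConfig()
    outcomes = np.asarray(outcomes)
    if len(records) < 2:
        raise ValueError("need at least two subjects")
    if len(set(outcomes.tolist())) < 2:
        raise ValueError("both outcome classes must be present")
    features = assemble_features(
        [r.change for r in records],
        outcomes,
        [r.preop_counts.offdiagonal() for r in records],
    )
    search = grid_search(features, grid=config.grid(),
                         selection_scope=config.selection_scope, svm_C=config.svm_C)
    return features, search


# ---------------------------------------------------------------------------
# serialisation helpers


def write_matrix_tsv(W: ConnectivityMatrix, path) -> None:
    """Connectome as TSV with region-id header row/column, plus a JSON
    sidecar recording weight kind, flip state and discarded count."""
    df = pd.DataFrame(W.weights, index=W.region_ids, columns=W.region_ids)
    df.to_csv(path, sep="\t", index_label="region")
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"weight_kind": W.weight_kind, "flipped": W.flipped,
                   "n_discarded": W.n_discarded}, fh, indent=2, sort_keys=True)


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    region_ids = [int(c) for c in df.columns]
    kind, flipped, discarded = "streamline_count", False, 0
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        kind = meta.get("weight_kind", kind)
        flipped = meta.get("flipped", flipped)
        discarded = meta.get("n_discarded", discarded)
    except FileNotFoundError:
        pass
    return ConnectivityMatrix(weights=df.to_numpy(dtype=float), region_ids=region_ids,
                              weight_kind=kind, n_discarded=discarded, flipped=flipped)


def change_to_tidy(change: ChangeMetrics, subject: str = "subject") -> pd.DataFrame:
    """Long-format table: one row per (metric, region or edge)."""
    rows = []
    ids = change.region_ids
    for r, rid in enumerate(ids):
        rows.append((subject, "region_strength_ratio", str(rid), change.region_strength_ratio[r]))
        rows.append((subject, "node_betweenness_diff", str(rid), change.node_betweenness_diff[r]))
        rows.append((subject, "clustering_diff", str(rid), change.clustering_diff[r]))
        rows.append((subject, "communicability_diff", str(rid), change.communicability_diff[r]))
        if change.volume_ratio is not None:
            rows.append((subject, "volume_ratio", str(rid), change.volume_ratio[r]))
    R = len(ids)
    for i in range(R):
        for j in range(i + 1, R):
            edge = f"{ids[i]}-{ids[j]}"
            rows.append((subject, "connection_strength_ratio", edge, change.connection_strength_ratio[i, j]))
            rows.append((subject, "edge_betweenness_diff", edge, change.edge_betweenness_diff[i, j]))
    rows.append((subject, "efficiency_pre", "global", change.efficiency_pre))
    rows.append((subject, "efficiency_post", "global", change.efficiency_post))
    rows.append((subject, "efficiency_ratio", "global", change.efficiency_ratio))
    return pd.DataFrame(rows, columns=["subject", "metric", "element", "value"])
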