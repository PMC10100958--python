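"""The indirect-influence procedure: per-subject delta correlation of omics
features with immunity indicators, per-group significance, removal of the
correlations shared by both arms, and the count/proportion effect size.

Significance means Spearman p < alpha (not |rho| < alpha -- a near-zero
correlation filter would contradict the purpose of the analysis; see
``Settings.spearman_threshold_is_pvalue``). Edge identity for overlap
removal is (feature, indicator, sign): the same pair with opposite signs in
the two arms is NOT shared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_formats import FeatureTable, Group, ImmunityPanel, Layer, Timepoint
from .stats import rank_correlation_matrix, spearman  # noqa: F401  (re-export)

logger = logging.getLogger("pairomics")


@dataclass
class DeltaTable:
    """Per-subject endline-minus-baseline changes (one row per subject)."""

    group: Group
    subjects: list[str]
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.ids)):
            raise ValueError("delta values shape does not match subjects x ids")


def subject_deltas(data: FeatureTable | ImmunityPanel, group: Group) -> DeltaTable:
    """Endline - baseline per subject of the group.

    Subjects present at only one timepoint raise (pairing is mandatory
    here; filter the table first if partial cohorts are expected).
    """
    subjects = sorted({k.subject_id for k in data.sample_keys if k.group is group})
    paired = data.paired_subjects(group)
    missing = sorted(set(subjects) - set(paired))
    if missing:
        raise ValueError(f"subject(s) missing a timepoint: {missing}")
    ids = data.feature_ids if isinstance(data, FeatureTable) else data.indicator_ids
    base = np.array([data.sample_row(s, Timepoint.BASELINE) for s in paired])
    end = np.array([data.sample_row(s, Timepoint.ENDLINE) for s in paired])
    return DeltaTable(group=group, subjects=paired, ids=list(ids), values=end - base)


@dataclass(frozen=True)
class CorrelationEdge:
    feature_id: str
    indicator_id: str
    rho: float
    p_value: float
    sign: str  # "+" or "-"
    group: Group

    @property
    def identity(self) -> tuple[str, str, str]:
        return (self.feature_id, self.indicator_id, self.sign)


def correlate_group(
    deltas_omics: DeltaTable, deltas_immunity: DeltaTable, alpha: float = 0.05
) -> list[CorrelationEdge]:
    """All feature x indicator Spearman tests on one group's deltas; keep
    edges with p < alpha. Constant columns are skipped (logged)."""
    if deltas_omics.subjects != deltas_immunity.subjects:
        raise ValueError("subject order mismatch between omics and immunity deltas")
    if deltas_omics.group is not deltas_immunity.group:
        raise ValueError("delta tables come from different groups")
    rho, p, valid_x, valid_y = rank_correlation_matrix(
        deltas_omics.values, deltas_immunity.values
    )
    n_skipped = int((~valid_x).sum() + (~valid_y).sum())
    if n_skipped:
        logger.info("correlate_group: skipped %d constant column(s)", n_skipped)
    edges: list[CorrelationEdge] = []
    sig = np.argwhere(
        (p < alpha) & valid_x[:, None] & valid_y[None, :] & (rho != 0)
    )
    for i, j in sig:
        edges.append(
            CorrelationEdge(
                feature_id=deltas_omics.ids[i],
                indicator_id=deltas_immunity.ids[j],
                rho=float(rho[i, j]),
                p_value=float(p[i, j]),
                sign="+" if rho[i, j] > 0 else "-",
                group=deltas_omics.group,
            )
        )
    logger.info(
        "correlate_group(%s): %d of %d tests significant at alpha=%g",
        deltas_omics.group.value, len(edges), int(valid_x.sum() * valid_y.sum()), alpha,
    )
    return edges


@dataclass
class EdgePartition:
    unique_probiotic: set[CorrelationEdge]
    unique_placebo: set[CorrelationEdge]
    shared: set[tuple[str, str, str]]  # (feature, indicator, sign)


def remove_shared_edges(
    edges_probiotic: Iterable[CorrelationEdge],
    edges_placebo: Iterable[CorrelationEdge],
) -> EdgePartition:
    """Drop (feature, indicator, sign) triples significant in BOTH arms."""
    pro = set(edges_probiotic)
    pla = set(edges_placebo)
    shared = {e.identity for e in pro} & {e.identity for e in pla}
    return EdgePartition(
        unique_probiotic={e for e in pro if e.identity not in shared},
        unique_placebo={e for e in pla if e.identity not in shared},
        shared=shared,
    )


@dataclass
class IndirectInfluenceSummary:
    layer: Layer
    n_implicated: int
    n_total: int
    count_ratio: float
    proportion: float
    n_edges_probiotic: int
    n_edges_placebo: int


def indirect_influence_summary(
    partition: EdgePartition,
    table: FeatureTable,
    group: Group = Group.PROBIOTIC,
    timepoint: Timepoint = Timepoint.ENDLINE,
    include_placebo_edges: bool = False,
) -> IndirectInfluenceSummary:
    """Distinct features carrying >= 1 group-unique edge, and their summed
    mean relative abundance in the probiotic group at endline.

    Default counts probiotic-unique edges only; ``include_placebo_edges``
    switches to the union-of-arms reading.
    """
    edges = set(partition.unique_probiotic)
    if include_placebo_edges:
        edges |= partition.unique_placebo
    implicated = sorted(
        {e.feature_id for e in edges} & set(table.feature_ids)
    )
    sub = table.select(group=group, timepoint=timepoint)
    X = sub.values
    if table.layer is Layer.METABOLITE and table.scale == "raw":
        X = X / X.sum(axis=1, keepdims=True)
    mean_abund = X.mean(axis=0)
    idx = [sub.feature_index(f) for f in implicated]
    proportion = float(mean_abund[idx].sum()) if idx else 0.0
    n_total = table.n_features
    return IndirectInfluenceSummary(
        layer=table.layer,
        n_implicated=len(implicated),
        n_total=n_total,
        count_ratio=len(implicated) / n_total if n_total else 0.0,
        proportion=proportion,
        n_edges_probiotic=len(partition.unique_probiotic),
        n_edges_placebo=len(partition.unique_placebo),
    )
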