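"""Gut-microbiome SNV treatment attribution.

Within-host temporal SNV changes (gained/lost between baseline and
endline), cohort prevalence filtering (>= 30% of a group's paired
subjects, inclusive), placebo subtraction of the cross-arm intersection,
per-species categorisation and SNV-immunity association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .indirect import DeltaTable
from .io_formats import (
    FeatureTable,
    Group,
    IndicatorCategory,
    SnvCallSet,
    SnvKey,
    Timepoint,
)
from .stats import rank_correlation_matrix

logger = logging.getLogger("pairomics")

GAINED = "gained"
LOST = "lost"


@dataclass(frozen=True)
class TemporalSnvChange:
    """One within-host change: gained = absent at baseline, present at endline."""

    subject_id: str
    snv: SnvKey
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (GAINED, LOST):
            raise ValueError(f"direction must be '{GAINED}' or '{LOST}'")


def host_temporal_changes(
    baseline: SnvCallSet, endline: SnvCallSet
) -> frozenset[TemporalSnvChange]:
    """Set differences between one host's two call sets, with directions."""
    if baseline.sample_key.subject_id != endline.sample_key.subject_id:
        raise ValueError(
            f"call sets belong to different subjects: "
            f"'{baseline.sample_key.subject_id}' vs '{endline.sample_key.subject_id}'"
        )
    if baseline.sample_key.timepoint is endline.sample_key.timepoint:
        raise ValueError("call sets are from the same timepoint")
    if baseline.sample_key.timepoint is not Timepoint.BASELINE:
        raise ValueError("first argument must be the baseline call set")
    subject = baseline.sample_key.subject_id
    changes = {
        TemporalSnvChange(subject, k, GAINED) for k in endline.calls - baseline.calls
    } | {
        TemporalSnvChange(subject, k, LOST) for k in baseline.calls - endline.calls
    }
    return frozenset(changes)


@dataclass
class GroupSnvSet:
    """SNVs whose temporal change clears the prevalence filter in one group."""

    group: Group
    snvs: frozenset[SnvKey]
    support_count: dict[SnvKey, int]
    support_fraction: dict[SnvKey, float]
    n_subjects: int


def group_candidate_snvs(
    changes: Mapping[str, Iterable[TemporalSnvChange]],
    group: Group,
    prevalence_threshold: float = 0.30,
    direction_scope: str = "either",
) -> GroupSnvSet:
    """Keep SNV keys changed in >= ``prevalence_threshold`` of the group's
    paired subjects (inclusive). ``changes`` maps each paired subject of the
    group to their temporal change set. ``direction_scope`` is ``"either"``
    (any change counts, the default) or ``"gained"`` (gains only)."""
    if not changes:
        raise ValueError(f"no paired subjects in group {group.value}")
    if direction_scope not in ("either", "gained"):
        raise ValueError(f"unknown direction_scope '{direction_scope}'")
    n = len(changes)
    counts: dict[SnvKey, int] = {}
    for subject, subject_changes in changes.items():
        seen: set[SnvKey] = set()
        for ch in subject_changes:
            if direction_scope == "gained" and ch.direction != GAINED:
                continue
            seen.add(ch.snv)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    kept = {k for k, c in counts.items() if c / n >= prevalence_threshold}
    logger.info(
        "group_candidate_snvs(%s): %d changed keys, %d pass prevalence >= %g over %d subjects",
        group.value, len(counts), len(kept), prevalence_threshold, n,
    )
    return GroupSnvSet(
        group=group,
        snvs=frozenset(kept),
        support_count={k: counts[k] for k in kept},
        support_fraction={k: counts[k] / n for k in kept},
        n_subjects=n,
    )


@dataclass
class AttributionResult:
    """Venn partition of the two arms' candidate SNVs."""

    unique_probiotic: frozenset[SnvKey]
    unique_placebo: frozenset[SnvKey]
    shared: frozenset[SnvKey]
    candidates: dict[Group, GroupSnvSet]

    def __post_init__(self) -> None:
        if (
            self.unique_probiotic & self.unique_placebo
            or self.unique_probiotic & self.shared
            or self.unique_placebo & self.shared
        ):
            raise ValueError("attribution sets must be pairwise disjoint")

    def unique(self, group: Group) -> frozenset[SnvKey]:
        return (
            self.unique_probiotic if group is Group.PROBIOTIC else self.unique_placebo
        )


def venn_subtract(
    candidates_probiotic: GroupSnvSet, candidates_placebo: GroupSnvSet
) -> AttributionResult:
    """Remove the cross-arm intersection (attributed to time, not treatment)."""
    pro = candidates_probiotic.snvs
    pla = candidates_placebo.snvs
    shared = pro & pla
    result = AttributionResult(
        unique_probiotic=frozenset(pro - shared),
        unique_placebo=frozenset(pla - shared),
        shared=frozenset(shared),
        candidates={
            Group.PROBIOTIC: candidates_probiotic,
            Group.PLACEBO: candidates_placebo,
        },
    )
    logger.info(
        "venn_subtract: %d probiotic-unique, %d placebo-unique, %d shared (removed)",
        len(result.unique_probiotic), len(result.unique_placebo), len(result.shared),
    )
    return result


def _dense_rank_desc(counts: pd.Series) -> pd.Series:
    """Dense descending rank over species with a positive count; others null."""
    ranks = counts[counts > 0].rank(method="dense", ascending=False)
    return ranks.reindex(counts.index)


def species_categorize(
    result: AttributionResult,
    sgb_species_map: Mapping[str, str],
    abundances: FeatureTable,
    top_k: int | None = 10,
) -> pd.DataFrame:
    """Per-species unique-SNV counts, dense ranks and mean % relative abundance.

    Rows are species with at least one group-unique SNV, sorted by the
    summed count; ranks are dense within each column and null for species
    with a zero count there (mirroring a top-k table with blank ranks).
    """
    rows: dict[str, dict[str, int]] = {}
    for group, keys in (
        (Group.PROBIOTIC, sorted(result.unique_probiotic)),
        (Group.PLACEBO, sorted(result.unique_placebo)),
    ):
        for key in keys:
            if key.sgb_id not in sgb_species_map:
                raise ValueError(f"sgb_id '{key.sgb_id}' has no species mapping")
            species = sgb_species_map[key.sgb_id]
            rows.setdefault(species, {"probiotic": 0, "placebo": 0})
            rows[species][group.value] += 1
    if not rows:
        return pd.DataFrame(
            columns=[
                "n_probiotic", "n_placebo", "n_sum", "rank_probiotic",
                "rank_placebo", "rank_sum", "mean_pct_abundance_probiotic",
                "mean_pct_abundance_placebo",
            ]
        )
    df = pd.DataFrame(rows).T
    df.columns = ["n_probiotic", "n_placebo"]
    df["n_sum"] = df["n_probiotic"] + df["n_placebo"]
    df["rank_probiotic"] = _dense_rank_desc(df["n_probiotic"])
    df["rank_placebo"] = _dense_rank_desc(df["n_placebo"])
    df["rank_sum"] = _dense_rank_desc(df["n_sum"])

    # mean % relative abundance per group, summed over the species' SGBs
    species_of_sgb = {
        sgb: sp for sgb, sp in sgb_species_map.items() if sgb in abundances.feature_ids
    }
    for group, col in (
        (Group.PROBIOTIC, "mean_pct_abundance_probiotic"),
        (Group.PLACEBO, "mean_pct_abundance_placebo"),
    ):
        sub = abundances.select(group=group)
        mean_abund = sub.values.mean(axis=0)
        per_species: dict[str, float] = {}
        for sgb, sp in species_of_sgb.items():
            per_species[sp] = per_species.get(sp, 0.0) + float(
                mean_abund[sub.feature_index(sgb)]
            )
        df[col] = [100.0 * per_species.get(sp, 0.0) for sp in df.index]
    # species name breaks count ties so the ordering is deterministic
    df = df.sort_index().sort_values("n_sum", ascending=False, kind="stable")
    df.index.name = "species"
    if top_k is not None:
        df = df.head(top_k)
    return df


@dataclass
class SnvImmunityAssociation:
    """Edges between group-unique SNVs and immunity indicator deltas, plus
    per-category counts mirroring the association bar plots."""

    edges: pd.DataFrame
    category_summary: pd.DataFrame
    n_skipped_constant: dict[Group, int]


def correlate_snv_immunity(
    result: AttributionResult,
    changes_by_group: Mapping[Group, Mapping[str, Iterable[TemporalSnvChange]]],
    immunity_deltas: Mapping[Group, DeltaTable],
    categories: Mapping[str, IndicatorCategory],
    alpha: float = 0.05,
) -> SnvImmunityAssociation:
    """Spearman of per-subject change indicators (0/1) against indicator deltas.

    For each group-unique SNV, x_s = 1 when subject s shows the temporal
    change; constant encodings (no carrier or all carriers) are skipped and
    counted. Edges with p < alpha are kept.
    """
    edge_rows = []
    skipped: dict[Group, int] = {}
    for group in (Group.PLACEBO, Group.PROBIOTIC):
        unique_keys = sorted(result.unique(group))
        deltas = immunity_deltas[group]
        changes = changes_by_group[group]
        changed_keys_by_subject = {
            s: {ch.snv for ch in chs} for s, chs in changes.items()
        }
        missing = [s for s in deltas.subjects if s not in changed_keys_by_subject]
        if missing:
            raise ValueError(f"no SNV changes recorded for subject(s) {missing}")
        X = np.array(
            [
                [1.0 if key in changed_keys_by_subject[s] else 0.0 for key in unique_keys]
                for s in deltas.subjects
            ]
        ).reshape(len(deltas.subjects), len(unique_keys))
        if not unique_keys:
            skipped[group] = 0
            continue
        rho, p, valid_x, valid_y = rank_correlation_matrix(X, deltas.values)
        skipped[group] = int((~valid_x).sum())
        if skipped[group]:
            logger.info(
                "correlate_snv_immunity(%s): skipped %d constant SNV encoding(s)",
                group.value, skipped[group],
            )
        sig = np.argwhere(p < alpha)
        for i, j in sig:
            if not (valid_x[i] and valid_y[j]):
                continue
            key = unique_keys[i]
            indicator = deltas.ids[j]
            edge_rows.append(
                {
                    "group": group.value,
                    "sgb_id": key.sgb_id,
                    "contig": key.contig,
                    "position": key.position,
                    "ref": key.ref_allele,
                    "alt": key.alt_allele,
                    "indicator": indicator,
                    "category": categories[indicator].value,
                    "rho": float(rho[i, j]),
                    "p": float(p[i, j]),
                    "sign": "+" if rho[i, j] > 0 else "-",
                }
            )
    edges = pd.DataFrame(
        edge_rows,
        columns=[
            "group", "sgb_id", "contig", "position", "ref", "alt",
            "indicator", "category", "rho", "p", "sign",
        ],
    )
    summary_rows = []
    for group in (Group.PLACEBO, Group.PROBIOTIC):
        sub = edges[edges["group"] == group.value]
        for cat in IndicatorCategory:
            cat_edges = sub[sub["category"] == cat.value]
            n_snvs = cat_edges.drop_duplicates(
                ["sgb_id", "contig", "position", "ref", "alt"]
            ).shape[0]
            indicators = cat_edges["indicator"].value_counts()
            summary_rows.append(
                {
                    "group": group.value,
                    "category": cat.value,
                    "n_snvs": n_snvs,
                    "n_indicators": int(indicators.size),
                    "most_associated": indicators.index[0] if indicators.size else "",
                }
            )
    return SnvImmunityAssociation(
        edges=edges,
        category_summary=pd.DataFrame(summary_rows),
        n_skipped_constant=skipped,
    )


def ceil_prevalence_count(prevalence: float, n_subjects: int) -> int:
    """Hosts needed so a planted change clears an inclusive prevalence filter."""
    return math.ceil(prevalence * n_subjects)
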