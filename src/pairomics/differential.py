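"""Metabolomics QC, CLR preprocessing, per-group paired change testing and
cross-group time-effect subtraction (the "direct influence" analysis).

Features that change the same way in both arms are attributed to time and
discarded; the rest are the treatment-differential set. P-values are raw by
default (an optional BH-FDR switch is provided) because downstream
summaries mirror per-feature significance calls, not a corrected family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .io_formats import FeatureTable, Group, ImmunityPanel, Layer, Timepoint
from .stats import signed_rank_test

logger = logging.getLogger("pairomics")

CLASS_TIME = "time_effect"
CLASS_TREATMENT = "treatment_differential"
CLASS_UNCHANGED = "unchanged"


@dataclass
class QcReport:
    n_features_in: int
    n_removed_intensity: int
    n_removed_prevalence: int
    n_removed_rsd: int
    n_features_out: int

    def __post_init__(self) -> None:
        expected = (
            self.n_features_in
            - self.n_removed_intensity
            - self.n_removed_prevalence
            - self.n_removed_rsd
        )
        if self.n_features_out != expected:
            raise ValueError("QC accounting mismatch: removals do not sum")


def metabolite_qc(
    intensities: FeatureTable,
    min_intensity: float = 1000.0,
    min_prevalence: float = 0.20,
    max_rsd: float = 0.20,
) -> tuple[FeatureTable, QcReport]:
    """Intensity/prevalence/RSD quality control for the metabolite layer.

    Keep features reaching ``min_intensity`` in at least ``min_prevalence``
    of the samples of EACH group, then drop features whose relative
    standard deviation (sd/mean of positive intensities, pooled over all
    samples) exceeds ``max_rsd``. Removal is attributed in the fixed order
    intensity -> prevalence -> RSD so each feature is counted once.
    """
    if intensities.layer is not Layer.METABOLITE:
        raise ValueError("metabolite_qc applies to the metabolite layer only")
    X = intensities.values
    n_in = intensities.n_features
    groups = sorted({k.group for k in intensities.sample_keys})
    above = X >= min_intensity

    fails_intensity = ~above.any(axis=0)
    fails_prevalence = np.zeros(n_in, dtype=bool)
    for g in groups:
        rows = [i for i, k in enumerate(intensities.sample_keys) if k.group is g]
        frac = above[rows].mean(axis=0)
        fails_prevalence |= frac < min_prevalence
    fails_prevalence &= ~fails_intensity

    rsd = np.zeros(n_in)
    for j in range(n_in):
        pos = X[:, j][X[:, j] > 0]
        if pos.size >= 2:
            rsd[j] = pos.std(ddof=1) / pos.mean()
    fails_rsd = (rsd > max_rsd) & ~fails_intensity & ~fails_prevalence

    keep = ~(fails_intensity | fails_prevalence | fails_rsd)
    report = QcReport(
        n_features_in=n_in,
        n_removed_intensity=int(fails_intensity.sum()),
        n_removed_prevalence=int(fails_prevalence.sum()),
        n_removed_rsd=int(fails_rsd.sum()),
        n_features_out=int(keep.sum()),
    )
    logger.info(
        "metabolite QC: %d in, removed %d (intensity) + %d (prevalence) + %d (RSD), %d out",
        report.n_features_in, report.n_removed_intensity,
        report.n_removed_prevalence, report.n_removed_rsd, report.n_features_out,
    )
    filtered = FeatureTable(
        layer=intensities.layer,
        sample_keys=list(intensities.sample_keys),
        feature_ids=[f for f, k in zip(intensities.feature_ids, keep) if k],
        values=X[:, keep],
        scale=intensities.scale,
    )
    return filtered, report


def multiplicative_pseudocount(row: np.ndarray) -> np.ndarray:
    """Replace zeros with 0.65x the row's smallest positive value, shrinking
    the non-zeros multiplicatively so the row total is preserved."""
    row = np.asarray(row, dtype=float)
    zeros = row == 0
    if not zeros.any():
        return row
    positive = row[~zeros]
    delta = 0.65 * positive.min()
    total = row.sum()
    out = row * (1.0 - zeros.sum() * delta / total)
    out[zeros] = delta
    return out


def clr_transform(
    table: FeatureTable,
    pseudocount_policy: Callable[[np.ndarray], np.ndarray] = multiplicative_pseudocount,
) -> FeatureTable:
    """Centred log-ratio transform per sample: y_i = ln x_i - mean_j ln x_j.

    Zeros are replaced per the (pluggable) pseudocount policy first; a
    sample with no positive value is an error.
    """
    X = table.values
    out = np.empty_like(X, dtype=float)
    for i in range(X.shape[0]):
        row = X[i]
        if not np.any(row > 0):
            raise ValueError(f"sample '{table.sample_ids[i]}' is all zeros")
        row = pseudocount_policy(row)
        logs = np.log(row)
        out[i] = logs - logs.mean()
    return FeatureTable(
        layer=table.layer,
        sample_keys=list(table.sample_keys),
        feature_ids=list(table.feature_ids),
        values=out,
        scale="clr",
    )


def _ids_and_deltas(
    data: FeatureTable | ImmunityPanel, group: Group
) -> tuple[list[str], list[str], np.ndarray, np.ndarray, np.ndarray]:
    """(ids, subjects, baseline rows, endline rows, deltas) for paired subjects."""
    ids = data.feature_ids if isinstance(data, FeatureTable) else data.indicator_ids
    subjects = data.paired_subjects(group)
    base = np.array([data.sample_row(s, Timepoint.BASELINE) for s in subjects])
    end = np.array([data.sample_row(s, Timepoint.ENDLINE) for s in subjects])
    return list(ids), subjects, base, end, end - base


def paired_change_test(
    data: FeatureTable | ImmunityPanel,
    group: Group,
    alpha: float = 0.05,
    min_subjects: int = 6,
) -> pd.DataFrame:
    """Per-feature signed-rank test on per-subject (endline - baseline).

    Returns a frame indexed by feature/indicator id with columns ``p``,
    ``direction`` (up/down/none at the given alpha), ``median_diff`` and
    ``median_change_fraction`` (median of (end-base)/base over subjects with
    positive baseline, for percent-change reporting).
    """
    ids, subjects, base, end, deltas = _ids_and_deltas(data, group)
    if len(subjects) < min_subjects:
        raise ValueError(
            f"need at least {min_subjects} paired subjects in {group.value}, "
            f"got {len(subjects)}"
        )
    n_feat = len(ids)
    p = np.empty(n_feat)
    median_diff = np.median(deltas, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(base > 0, deltas / base, np.nan)
    med_frac = np.full(n_feat, np.nan)
    has_any = ~np.all(np.isnan(rel), axis=0)
    med_frac[has_any] = np.nanmedian(rel[:, has_any], axis=0)
    for j in range(n_feat):
        p[j] = signed_rank_test(deltas[:, j])
    direction = np.where(
        p < alpha, np.where(median_diff > 0, "up", np.where(median_diff < 0, "down", "none")),
        "none",
    )
    return pd.DataFrame(
        {
            "p": p,
            "direction": direction,
            "median_diff": median_diff,
            "median_change_fraction": med_frac,
        },
        index=pd.Index(ids, name="feature"),
    )


def time_effect_subtraction(
    res_placebo: pd.DataFrame,
    res_probiotic: pd.DataFrame,
    alpha: float = 0.05,
    strict: bool = False,
) -> pd.DataFrame:
    """Classify features by subtracting changes shared across arms.

    ``time_effect``: significant in both groups with the same direction
    (attributed to time, discarded from the treatment set);
    ``treatment_differential``: significant in at least one group and not a
    time effect (``strict=True`` restricts this to probiotic-significant
    features); ``unchanged`` otherwise.
    """
    if set(res_placebo.index) != set(res_probiotic.index):
        raise ValueError("feature universes differ between the two groups")
    pla = res_placebo
    pro = res_probiotic.reindex(pla.index)

    def _dir(frame: pd.DataFrame) -> np.ndarray:
        sig = frame["p"].to_numpy() < alpha
        med = frame["median_diff"].to_numpy()
        return np.where(
            sig, np.where(med > 0, "up", np.where(med < 0, "down", "none")), "none"
        )

    dir_pla = _dir(pla)
    dir_pro = _dir(pro)
    sig_pla = pla["p"].to_numpy() < alpha
    sig_pro = pro["p"].to_numpy() < alpha
    same_way = sig_pla & sig_pro & (dir_pla == dir_pro) & (dir_pla != "none")
    if strict:
        differential = sig_pro & ~same_way
    else:
        differential = (sig_pla | sig_pro) & ~same_way
    classification = np.where(
        same_way, CLASS_TIME, np.where(differential, CLASS_TREATMENT, CLASS_UNCHANGED)
    )
    return pd.DataFrame(
        {
            "p_placebo": pla["p"].to_numpy(),
            "p_probiotic": pro["p"].to_numpy(),
            "direction_placebo": dir_pla,
            "direction_probiotic": dir_pro,
            "median_change_fraction_probiotic": pro["median_change_fraction"].to_numpy(),
            "classification": classification,
        },
        index=pla.index,
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional multiplicity switch)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class DirectInfluenceSummary:
    layer: Layer
    n_differential: int
    n_total: int
    count_ratio: float
    proportion: float


def direct_influence_summary(
    diff: pd.DataFrame,
    table: FeatureTable,
    group: Group = Group.PROBIOTIC,
    timepoint: Timepoint = Timepoint.ENDLINE,
) -> DirectInfluenceSummary:
    """Count ratio and summed mean relative abundance of the
    treatment-differential features (probiotic group at endline).

    Metabolite intensities are normalised to per-sample proportions before
    averaging so the proportion stays in [0, 1].
    """
    differential = diff.index[diff["classification"] == CLASS_TREATMENT]
    sub = table.select(group=group, timepoint=timepoint)
    X = sub.values
    if table.layer is Layer.METABOLITE:
        X = X / X.sum(axis=1, keepdims=True)
    mean_abund = X.mean(axis=0)
    idx = [sub.feature_index(f) for f in differential if f in sub.feature_ids]
    proportion = float(mean_abund[idx].sum()) if idx else 0.0
    n_total = len(diff)
    return DirectInfluenceSummary(
        layer=table.layer,
        n_differential=int(len(differential)),
        n_total=n_total,
        count_ratio=len(differential) / n_total if n_total else 0.0,
        proportion=proportion,
    )
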