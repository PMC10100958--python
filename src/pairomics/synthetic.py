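"""Synthetic two-arm, two-timepoint cohort generator with recorded effects.

Every planted effect (convergence shrinkage, common temporal drift,
arm-specific abundance shifts, feature<->indicator delta correlations and
per-host SNV gain/loss) is returned as ground truth so downstream stages
can be validated against a known answer. A fixed seed gives bit-identical
outputs; writing and re-reading a cohort reproduces equal objects.

Mechanics, in brief: per-feature log-normal baselines with subject random
effects, closed to relative abundances; endline adds a common drift, an
optional probiotic-only shift and fresh noise, then shrinks each group's
endline samples toward their centroid by the group's convergence factor
(a convex combination, so closure is preserved exactly). Indicator deltas
are coupled to the *realised* per-subject feature deltas, which plants the
target correlation on the scale the analysis actually sees. Planted SNV
changes are forced into ceil(prevalence * n) hosts of the intended arm(s)
and frozen everywhere else; idiosyncratic Poisson background changes come
from a disjoint key pool so they can never collide with planted keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    FeatureTable,
    FilterSettings,
    Group,
    ImmunityPanel,
    IndicatorCategory,
    Layer,
    RELATIVE_LAYERS,
    SampleKey,
    SnvCallSet,
    SnvKey,
    Timepoint,
    read_feature_table,
    read_immunity_panel,
    read_metadata,
    read_contig_map,
    read_species_map,
    read_vcf_calls,
    write_feature_table,
    write_immunity_panel,
    write_metadata,
    write_vcf_calls,
)

# metabolite intensity model constants (kept out of the config on purpose:
# they shape realism, not planted effects)
_MET_LOG_MEAN = math.log(5000.0)
_MET_LOG_SD = 1.2
_MET_SIGMA_RANGE = (0.05, 0.30)
_MET_ZERO_RATE = 0.02
_IMM_DELTA_SCALE = 0.05  # indicator delta sd as a fraction of its scale


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; all planted effects default off."""

    n_subjects_per_group: int = 20
    n_features: dict[Layer, int] = field(
        default_factory=lambda: {
            Layer.BACTERIA: 120,
            Layer.FUNGI: 60,
            Layer.FUNCTION: 150,
            Layer.METABOLITE: 200,
        }
    )
    n_indicators: int = 69
    category_split: tuple[int, int, int] = (34, 29, 6)  # cytokine, cbc, lymphocyte
    convergence_factor: dict[Group, float] = field(
        default_factory=lambda: {Group.PLACEBO: 0.0, Group.PROBIOTIC: 0.0}
    )
    # planted delta-correlation links (probiotic-unique and both-arm shared)
    n_linked_pairs: int = 0
    n_shared_linked_pairs: int = 0
    rho_link: float = 0.6
    # planted differential-abundance effects on the bacteria layer
    n_drift_features: int = 0
    drift_effect: float = 1.0  # in units of the within-subject delta sd
    n_shift_features: int = 0
    shift_effect: float = 1.0
    # SNV process
    n_sgbs: int = 10
    snv_background_rate: float = 2.0  # Poisson changes per host
    snv_group_rate: dict[Group, float] = field(
        default_factory=lambda: {Group.PLACEBO: 3.0, Group.PROBIOTIC: 1.2}
    )
    n_shared_snvs: int = 30
    snv_prevalence_high: float = 0.5
    snv_background_pool: int = 300
    n_snv_links: int = 0
    snv_link_effect: float = 1.5
    # abundance noise model
    feature_sd: float = 2.0
    subject_sd: float = 0.6
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_features = {Layer(k): int(v) for k, v in self.n_features.items()}
        self.convergence_factor = {
            Group(k): float(v) for k, v in self.convergence_factor.items()
        }
        self.snv_group_rate = {
            Group(k): float(v) for k, v in self.snv_group_rate.items()
        }
        self.category_split = tuple(self.category_split)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if any(v < 1 for v in self.n_features.values()):
            raise ValueError("every layer needs at least one feature")
        if Layer.BACTERIA not in self.n_features:
            raise ValueError("the bacteria layer is required (it anchors SNVs and links)")
        if self.n_sgbs < 1:
            raise ValueError("n_sgbs must be >= 1")
        if sum(self.category_split) != self.n_indicators:
            raise ValueError(
                f"category split {self.category_split} must sum to {self.n_indicators}"
            )
        for g in (Group.PLACEBO, Group.PROBIOTIC):
            k = self.convergence_factor.get(g, 0.0)
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"convergence factor for {g.value} must be in [0, 1]")
            if self.snv_group_rate.get(g, 0.0) < 0:
                raise ValueError("SNV group rates must be >= 0")
        if not -1.0 < self.rho_link < 1.0:
            raise ValueError("rho_link must be in (-1, 1)")
        if self.snv_background_rate < 0:
            raise ValueError("snv_background_rate must be >= 0")
        if not 0.0 < self.snv_prevalence_high <= 1.0:
            raise ValueError("snv_prevalence_high must be in (0, 1]")
        n_bact = self.n_features.get(Layer.BACTERIA, 0)
        n_special = (
            self.n_drift_features + self.n_shift_features
            + self.n_linked_pairs + self.n_shared_linked_pairs
        )
        if n_special > n_bact:
            raise ValueError(
                f"planted bacteria features ({n_special}) exceed the layer size ({n_bact})"
            )
        n_linked_ind = (
            self.n_linked_pairs + self.n_shared_linked_pairs + 2 * self.n_snv_links
        )
        if n_linked_ind > self.n_indicators:
            raise ValueError("planted links need more indicators than configured")
        if self.n_linked_pairs > n_bact * self.n_indicators:
            raise ValueError("n_linked_pairs exceeds the feature x indicator grid")
        if self.n_sgbs > n_bact:
            raise ValueError("n_sgbs cannot exceed the bacteria feature count")


@dataclass
class GroundTruth:
    """Planted effects, recorded at generation time."""

    linked_pairs: frozenset[tuple[str, str, int]]  # probiotic-unique
    shared_linked_pairs: frozenset[tuple[str, str, int]]
    drift_features: dict[str, int]  # feature -> sign
    shift_features: dict[str, int]
    shared_snvs: frozenset[SnvKey]
    group_unique_snvs: dict[Group, frozenset[SnvKey]]
    snv_links: frozenset[tuple[Group, SnvKey, str, int]]
    convergence_factor: dict[Group, float]

    def __post_init__(self) -> None:
        upla = self.group_unique_snvs.get(Group.PLACEBO, frozenset())
        upro = self.group_unique_snvs.get(Group.PROBIOTIC, frozenset())
        if upla & upro or self.shared_snvs & (upla | upro):
            raise ValueError("planted SNV sets must be pairwise disjoint")


@dataclass
class Cohort:
    config: CohortConfig
    tables: dict[Layer, FeatureTable]
    immunity: ImmunityPanel
    callsets: list[SnvCallSet]
    truth: GroundTruth
    contig_sgb_map: dict[str, str]
    sgb_species_map: dict[str, str]


def _close(X: np.ndarray) -> np.ndarray:
    return X / X.sum(axis=1, keepdims=True)


def _normal_scores(v: np.ndarray) -> np.ndarray:
    """Rank-Gaussianise (Blom scores): the Gaussian-copula representation of
    v, so couplings planted against it behave like a bivariate normal on the
    rank scale even when v itself is heavy-tailed."""
    from scipy import stats as sps

    ranks = sps.rankdata(v, method="average")
    return sps.norm.ppf((ranks - 0.375) / (v.size + 0.25))


_LAYER_PREFIX = {
    Layer.BACTERIA: "SGB",
    Layer.FUNGI: "FUN",
    Layer.FUNCTION: "PWY",
    Layer.METABOLITE: "MET",
}


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate all layers, the immunity panel, per-sample SNV call sets and
    the ground-truth record. Deterministic for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects_per_group
    subjects = {
        Group.PLACEBO: [f"PLA{i + 1:03d}" for i in range(n)],
        Group.PROBIOTIC: [f"PRO{i + 1:03d}" for i in range(n)],
    }
    subjects_all = subjects[Group.PLACEBO] + subjects[Group.PROBIOTIC]
    group_rows = {
        Group.PLACEBO: np.arange(n),
        Group.PROBIOTIC: np.arange(n, 2 * n),
    }
    sample_keys = [
        SampleKey(subj, g, tp)
        for g in (Group.PLACEBO, Group.PROBIOTIC)
        for subj in subjects[g]
        for tp in (Timepoint.BASELINE, Timepoint.ENDLINE)
    ]

    feature_ids = {
        layer: [f"{_LAYER_PREFIX[layer]}{i + 1:04d}" for i in range(count)]
        for layer, count in config.n_features.items()
    }

    # --- pick the special bacteria features (disjoint roles) ----------------
    bact_ids = feature_ids.get(Layer.BACTERIA, [])
    n_special = (
        config.n_drift_features + config.n_shift_features
        + config.n_linked_pairs + config.n_shared_linked_pairs
    )
    special = rng.choice(len(bact_ids), size=n_special, replace=False) if n_special else np.array([], dtype=int)
    cursor = 0
    drift_idx = special[cursor:cursor + config.n_drift_features]; cursor += config.n_drift_features
    shift_idx = special[cursor:cursor + config.n_shift_features]; cursor += config.n_shift_features
    linked_idx = special[cursor:cursor + config.n_linked_pairs]; cursor += config.n_linked_pairs
    shared_linked_idx = special[cursor:cursor + config.n_shared_linked_pairs]

    delta_sd = config.noise_sd  # within-subject delta sd (log scale)
    drift_signs = rng.choice([-1, 1], size=config.n_drift_features)
    shift_signs = rng.choice([-1, 1], size=config.n_shift_features)

    # --- relative-abundance layers ------------------------------------------
    tables: dict[Layer, FeatureTable] = {}
    bact_delta: np.ndarray | None = None
    for layer in (Layer.BACTERIA, Layer.FUNGI, Layer.FUNCTION):
        if layer not in feature_ids:
            continue
        n_feat = len(feature_ids[layer])
        mu = rng.normal(0.0, config.feature_sd, n_feat)
        b = rng.normal(0.0, config.subject_sd, (2 * n, n_feat))
        # endline = baseline profile + drift/shift + fresh group-specific
        # noise (noise is added on top, not redrawn: endline samples are
        # the ones that moved)
        e1 = rng.normal(0.0, config.noise_sd, (2 * n, n_feat))
        log0 = mu + b
        log1 = mu + b + e1
        if layer is Layer.BACTERIA:
            if len(drift_idx):
                log1[:, drift_idx] += config.drift_effect * delta_sd * drift_signs
            if len(shift_idx):
                log1[np.ix_(group_rows[Group.PROBIOTIC], shift_idx)] += (
                    config.shift_effect * delta_sd * shift_signs
                )
        X0 = _close(np.exp(log0))
        X1 = _close(np.exp(log1))
        for g in (Group.PLACEBO, Group.PROBIOTIC):
            kappa = config.convergence_factor.get(g, 0.0)
            if kappa > 0:
                rows = group_rows[g]
                centroid = X1[rows].mean(axis=0)
                X1[rows] = (1.0 - kappa) * X1[rows] + kappa * centroid
        values = np.empty((4 * n, n_feat))
        values[0::2] = X0
        values[1::2] = X1
        tables[layer] = FeatureTable(
            layer=layer, sample_keys=list(sample_keys),
            feature_ids=feature_ids[layer], values=values,
        )
        if layer is Layer.BACTERIA:
            bact_delta = X1 - X0

    # --- metabolite layer (raw intensities, a few planted zeros) ------------
    if Layer.METABOLITE in feature_ids:
        n_feat = len(feature_ids[Layer.METABOLITE])
        base_log = rng.normal(_MET_LOG_MEAN, _MET_LOG_SD, n_feat)
        sigma = rng.uniform(*_MET_SIGMA_RANGE, n_feat)
        b = rng.normal(0.0, 1.0, (2 * n, n_feat)) * sigma
        e1 = rng.normal(0.0, 1.0, (2 * n, n_feat)) * sigma * 0.6
        I0 = np.exp(base_log + b)
        I1 = np.exp(base_log + b + e1)
        I0[rng.random((2 * n, n_feat)) < _MET_ZERO_RATE] = 0.0
        I1[rng.random((2 * n, n_feat)) < _MET_ZERO_RATE] = 0.0
        for g in (Group.PLACEBO, Group.PROBIOTIC):
            kappa = config.convergence_factor.get(g, 0.0)
            if kappa > 0:
                rows = group_rows[g]
                centroid = I1[rows].mean(axis=0)
                I1[rows] = (1.0 - kappa) * I1[rows] + kappa * centroid
        values = np.empty((4 * n, n_feat))
        values[0::2] = I0
        values[1::2] = I1
        tables[Layer.METABOLITE] = FeatureTable(
            layer=Layer.METABOLITE, sample_keys=list(sample_keys),
            feature_ids=feature_ids[Layer.METABOLITE], values=values,
        )

    # --- SNV catalogue and per-host call sets -------------------------------
    sgb_ids = bact_ids[: config.n_sgbs]
    contig_of = {sgb: f"{sgb}_c1" for sgb in sgb_ids}
    n_unique = {
        g: int(round(config.snv_group_rate.get(g, 0.0) * config.n_sgbs))
        for g in (Group.PLACEBO, Group.PROBIOTIC)
    }
    class_labels = (
        ["shared"] * config.n_shared_snvs
        + ["unique_placebo"] * n_unique[Group.PLACEBO]
        + ["unique_probiotic"] * n_unique[Group.PROBIOTIC]
        + ["background"] * config.snv_background_pool
    )
    total = len(class_labels)
    sgb_idx = rng.integers(0, config.n_sgbs, total)
    positions = np.empty(total, dtype=int)
    for ci in range(config.n_sgbs):
        where = np.flatnonzero(sgb_idx == ci)
        if where.size:
            positions[where] = rng.choice(1_000_000, size=where.size, replace=False) + 1
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, total)
    alt_i = (ref_i + rng.integers(1, 4, total)) % 4
    keys = [
        SnvKey(
            sgb_id=sgb_ids[sgb_idx[j]],
            contig=contig_of[sgb_ids[sgb_idx[j]]],
            position=int(positions[j]),
            ref_allele=str(bases[ref_i[j]]),
            alt_allele=str(bases[alt_i[j]]),
        )
        for j in range(total)
    ]
    labels = np.array(class_labels)
    planted_cols = np.flatnonzero(labels != "background")
    bg_cols = np.flatnonzero(labels == "background")

    base_p = np.where(labels == "background", 0.35, 0.5)
    base = rng.random((2 * n, total)) < base_p
    end = base.copy()
    n_aff = math.ceil(config.snv_prevalence_high * n)
    affected_rows: dict[int, np.ndarray] = {}
    for j in planted_cols:
        direction_gained = rng.random() < 0.5
        targets = (
            [Group.PLACEBO, Group.PROBIOTIC] if labels[j] == "shared"
            else [Group.PLACEBO] if labels[j] == "unique_placebo"
            else [Group.PROBIOTIC]
        )
        rows_for_key = []
        for g in targets:
            aff = rng.choice(group_rows[g], size=n_aff, replace=False)
            base[aff, j] = not direction_gained
            end[aff, j] = direction_gained
            rows_for_key.append(aff)
        affected_rows[int(j)] = np.concatenate(rows_for_key)
    if config.snv_background_rate > 0 and bg_cols.size:
        for h in range(2 * n):
            k = int(rng.poisson(config.snv_background_rate))
            if k:
                cols = rng.choice(bg_cols, size=min(k, bg_cols.size), replace=False)
                end[h, cols] ^= True

    # --- immunity panel with planted delta couplings ------------------------
    n_ind = config.n_indicators
    n_cyt, n_cbc, n_lym = config.category_split
    indicator_ids = (
        [f"CYT{i + 1:03d}" for i in range(n_cyt)]
        + [f"CBC{i + 1:03d}" for i in range(n_cbc)]
        + [f"LYM{i + 1:03d}" for i in range(n_lym)]
    )
    categories = dict(
        [(i, IndicatorCategory.CYTOKINE) for i in indicator_ids[:n_cyt]]
        + [(i, IndicatorCategory.CBC) for i in indicator_ids[n_cyt:n_cyt + n_cbc]]
        + [(i, IndicatorCategory.LYMPHOCYTE) for i in indicator_ids[n_cyt + n_cbc:]]
    )
    n_link_ind = config.n_linked_pairs + config.n_shared_linked_pairs + 2 * config.n_snv_links
    link_ind_idx = (
        rng.choice(n_ind, size=n_link_ind, replace=False) if n_link_ind else np.array([], dtype=int)
    )
    cursor = 0
    pro_link_ind = link_ind_idx[cursor:cursor + config.n_linked_pairs]; cursor += config.n_linked_pairs
    shr_link_ind = link_ind_idx[cursor:cursor + config.n_shared_linked_pairs]; cursor += config.n_shared_linked_pairs
    snv_link_ind = link_ind_idx[cursor:]

    scale = np.exp(rng.normal(math.log(100.0), 1.0, n_ind))
    imm_base = scale * np.exp(rng.normal(0.0, 0.2, (2 * n, n_ind)))
    delta_z = rng.normal(0.0, 1.0, (2 * n, n_ind))

    rho = config.rho_link
    mix = math.sqrt(1.0 - rho * rho)
    linked_pairs: set[tuple[str, str, int]] = set()
    shared_linked_pairs: set[tuple[str, str, int]] = set()
    link_signs = rng.choice([-1, 1], size=config.n_linked_pairs)
    for m, (fi, ii) in enumerate(zip(linked_idx, pro_link_ind)):
        sign = int(link_signs[m])
        rows = group_rows[Group.PROBIOTIC]
        z = _normal_scores(bact_delta[rows, fi])
        delta_z[rows, ii] = sign * rho * z + mix * rng.normal(0.0, 1.0, n)
        linked_pairs.add((bact_ids[fi], indicator_ids[ii], sign))
    shared_signs = rng.choice([-1, 1], size=config.n_shared_linked_pairs)
    for m, (fi, ii) in enumerate(zip(shared_linked_idx, shr_link_ind)):
        sign = int(shared_signs[m])
        for g in (Group.PLACEBO, Group.PROBIOTIC):
            rows = group_rows[g]
            z = _normal_scores(bact_delta[rows, fi])
            delta_z[rows, ii] = sign * rho * z + mix * rng.normal(0.0, 1.0, n)
        shared_linked_pairs.add((bact_ids[fi], indicator_ids[ii], sign))

    # SNV -> indicator couplings: the first planted unique keys of each arm
    snv_links: set[tuple[Group, SnvKey, str, int]] = set()
    if config.n_snv_links:
        offsets = {
            Group.PLACEBO: config.n_shared_snvs,
            Group.PROBIOTIC: config.n_shared_snvs + n_unique[Group.PLACEBO],
        }
        li = 0
        for g in (Group.PLACEBO, Group.PROBIOTIC):
            n_links_g = min(config.n_snv_links, n_unique[g])
            for m in range(n_links_g):
                j = offsets[g] + m
                ii = int(snv_link_ind[li]); li += 1
                sign = int(rng.choice([-1, 1]))
                delta_z[affected_rows[j], ii] += sign * config.snv_link_effect
                snv_links.add((g, keys[j], indicator_ids[ii], sign))

    imm_end = imm_base + _IMM_DELTA_SCALE * scale * delta_z
    imm_end = np.maximum(imm_end, 0.01 * scale)
    imm_values = np.empty((4 * n, n_ind))
    imm_values[0::2] = imm_base
    imm_values[1::2] = imm_end
    immunity = ImmunityPanel(
        sample_keys=list(sample_keys),
        indicator_ids=indicator_ids,
        categories=categories,
        values=imm_values,
    )

    # --- assemble call sets and ground truth --------------------------------
    callsets: list[SnvCallSet] = []
    filters = FilterSettings()
    for si, subj in enumerate(subjects_all):
        g = Group.PLACEBO if si < n else Group.PROBIOTIC
        for tp, row in ((Timepoint.BASELINE, base[si]), (Timepoint.ENDLINE, end[si])):
            calls = frozenset(keys[j] for j in np.flatnonzero(row))
            callsets.append(
                SnvCallSet(
                    sample_key=SampleKey(subj, g, tp), calls=calls,
                    filters_applied=filters,
                )
            )

    truth = GroundTruth(
        linked_pairs=frozenset(linked_pairs),
        shared_linked_pairs=frozenset(shared_linked_pairs),
        drift_features={bact_ids[i]: int(s) for i, s in zip(drift_idx, drift_signs)},
        shift_features={bact_ids[i]: int(s) for i, s in zip(shift_idx, shift_signs)},
        shared_snvs=frozenset(keys[j] for j in np.flatnonzero(labels == "shared")),
        group_unique_snvs={
            Group.PLACEBO: frozenset(
                keys[j] for j in np.flatnonzero(labels == "unique_placebo")
            ),
            Group.PROBIOTIC: frozenset(
                keys[j] for j in np.flatnonzero(labels == "unique_probiotic")
            ),
        },
        snv_links=frozenset(snv_links),
        convergence_factor=dict(config.convergence_factor),
    )
    return Cohort(
        config=config,
        tables=tables,
        immunity=immunity,
        callsets=callsets,
        truth=truth,
        contig_sgb_map={c: s for s, c in contig_of.items()},
        sgb_species_map={sgb: f"s__Species{i + 1:03d}" for i, sgb in enumerate(sgb_ids)},
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_SNV_COLS = ["class", "sgb_id", "contig", "position", "ref", "alt"]


def _snv_sort_key(k: SnvKey):
    return (k.contig, k.position, k.ref_allele, k.alt_allele)


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write every table, the metadata, one VCF per sample, the reference
    maps and the ground truth as plain-text files under ``directory``."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    for layer, table in sorted(cohort.tables.items(), key=lambda kv: kv[0].value):
        write_feature_table(table, root / f"features_{layer.value}.tsv")
    write_metadata(cohort.immunity.sample_keys, root / "metadata.tsv")
    write_immunity_panel(
        cohort.immunity, root / "immunity.tsv", root / "immunity_categories.tsv"
    )
    vcf_dir = root / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for cs in cohort.callsets:
        write_vcf_calls(cs, vcf_dir / f"{cs.sample_key.sample_id}.vcf")
    pd.DataFrame(
        sorted(cohort.contig_sgb_map.items()), columns=["contig", "sgb_id"]
    ).to_csv(root / "contig_sgb_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(cohort.sgb_species_map.items()), columns=["sgb_id", "species"]
    ).to_csv(root / "sgb_species.tsv", sep="\t", index=False)

    gt_dir = root / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    truth = cohort.truth
    pd.DataFrame(
        sorted(
            [(f, i, s, 0) for f, i, s in truth.linked_pairs]
            + [(f, i, s, 1) for f, i, s in truth.shared_linked_pairs]
        ),
        columns=["feature_id", "indicator_id", "sign", "shared"],
    ).to_csv(gt_dir / "linked_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(
            [(f, "drift", s) for f, s in truth.drift_features.items()]
            + [(f, "shift", s) for f, s in truth.shift_features.items()]
        ),
        columns=["feature_id", "role", "sign"],
    ).to_csv(gt_dir / "effect_features.tsv", sep="\t", index=False)
    snv_rows = (
        [("shared", k) for k in sorted(truth.shared_snvs, key=_snv_sort_key)]
        + [
            ("unique_placebo", k)
            for k in sorted(truth.group_unique_snvs[Group.PLACEBO], key=_snv_sort_key)
        ]
        + [
            ("unique_probiotic", k)
            for k in sorted(truth.group_unique_snvs[Group.PROBIOTIC], key=_snv_sort_key)
        ]
    )
    pd.DataFrame(
        [
            (cls, k.sgb_id, k.contig, k.position, k.ref_allele, k.alt_allele)
            for cls, k in snv_rows
        ],
        columns=_SNV_COLS,
    ).to_csv(gt_dir / "snvs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(
            (g.value, k.sgb_id, k.contig, k.position, k.ref_allele, k.alt_allele, i, s)
            for g, k, i, s in truth.snv_links
        ),
        columns=["group", "sgb_id", "contig", "position", "ref", "alt",
                 "indicator_id", "sign"],
    ).to_csv(gt_dir / "snv_links.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((g.value, k) for g, k in truth.convergence_factor.items()),
        columns=["group", "kappa"],
    ).to_csv(gt_dir / "convergence.tsv", sep="\t", index=False)
    with open(root / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(cohort.config), fh, sort_keys=True)
    return root


def _config_to_dict(config: CohortConfig) -> dict:
    return {
        "n_subjects_per_group": config.n_subjects_per_group,
        "n_features": {k.value: v for k, v in config.n_features.items()},
        "n_indicators": config.n_indicators,
        "category_split": list(config.category_split),
        "convergence_factor": {k.value: v for k, v in config.convergence_factor.items()},
        "n_linked_pairs": config.n_linked_pairs,
        "n_shared_linked_pairs": config.n_shared_linked_pairs,
        "rho_link": config.rho_link,
        "n_drift_features": config.n_drift_features,
        "drift_effect": config.drift_effect,
        "n_shift_features": config.n_shift_features,
        "shift_effect": config.shift_effect,
        "n_sgbs": config.n_sgbs,
        "snv_background_rate": config.snv_background_rate,
        "snv_group_rate": {k.value: v for k, v in config.snv_group_rate.items()},
        "n_shared_snvs": config.n_shared_snvs,
        "snv_prevalence_high": config.snv_prevalence_high,
        "snv_background_pool": config.snv_background_pool,
        "n_snv_links": config.n_snv_links,
        "snv_link_effect": config.snv_link_effect,
        "feature_sd": config.feature_sd,
        "subject_sd": config.subject_sd,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }


def config_from_dict(data: Mapping) -> CohortConfig:
    return CohortConfig(**dict(data))


@dataclass
class CohortFiles:
    """A cohort re-read from disk (ground truth included when present)."""

    tables: dict[Layer, FeatureTable]
    immunity: ImmunityPanel
    callsets: list[SnvCallSet]
    contig_sgb_map: dict[str, str]
    sgb_species_map: dict[str, str]
    truth: GroundTruth | None


def read_ground_truth(directory: str | Path) -> GroundTruth:
    gt_dir = Path(directory) / "ground_truth"
    links = pd.read_csv(gt_dir / "linked_pairs.tsv", sep="\t")
    effects = pd.read_csv(gt_dir / "effect_features.tsv", sep="\t")
    snvs = pd.read_csv(gt_dir / "snvs.tsv", sep="\t")
    snv_links = pd.read_csv(gt_dir / "snv_links.tsv", sep="\t")
    conv = pd.read_csv(gt_dir / "convergence.tsv", sep="\t")

    def _keys(frame: pd.DataFrame) -> frozenset[SnvKey]:
        return frozenset(
            SnvKey(r.sgb_id, r.contig, int(r.position), r.ref, r.alt)
            for r in frame.itertuples(index=False)
        )

    return GroundTruth(
        linked_pairs=frozenset(
            (r.feature_id, r.indicator_id, int(r.sign))
            for r in links.itertuples(index=False) if r.shared == 0
        ),
        shared_linked_pairs=frozenset(
            (r.feature_id, r.indicator_id, int(r.sign))
            for r in links.itertuples(index=False) if r.shared == 1
        ),
        drift_features={
            r.feature_id: int(r.sign)
            for r in effects.itertuples(index=False) if r.role == "drift"
        },
        shift_features={
            r.feature_id: int(r.sign)
            for r in effects.itertuples(index=False) if r.role == "shift"
        },
        shared_snvs=_keys(snvs[snvs["class"] == "shared"]),
        group_unique_snvs={
            Group.PLACEBO: _keys(snvs[snvs["class"] == "unique_placebo"]),
            Group.PROBIOTIC: _keys(snvs[snvs["class"] == "unique_probiotic"]),
        },
        snv_links=frozenset(
            (
                Group(r.group),
                SnvKey(r.sgb_id, r.contig, int(r.position), r.ref, r.alt),
                r.indicator_id,
                int(r.sign),
            )
            for r in snv_links.itertuples(index=False)
        ),
        convergence_factor={
            Group(r.group): float(r.kappa) for r in conv.itertuples(index=False)
        },
    )


def read_cohort(directory: str | Path) -> CohortFiles:
    """Read a written cohort back; inverse of :func:`write_cohort`."""
    root = Path(directory)
    meta_path = root / "metadata.tsv"
    meta = read_metadata(meta_path)
    tables: dict[Layer, FeatureTable] = {}
    for layer in Layer:
        path = root / f"features_{layer.value}.tsv"
        if path.exists():
            tables[layer] = read_feature_table(path, layer, meta_path)
    immunity = read_immunity_panel(
        root / "immunity.tsv", meta_path, root / "immunity_categories.tsv"
    )
    contig_map = read_contig_map(root / "contig_sgb_map.tsv")
    species_map = read_species_map(root / "sgb_species.tsv")
    callsets = []
    for sid in sorted(meta):
        vcf = root / "vcf" / f"{sid}.vcf"
        if vcf.exists():
            callsets.append(read_vcf_calls(vcf, meta[sid], contig_map))
    truth = None
    if (root / "ground_truth").is_dir():
        truth = read_ground_truth(root)
    return CohortFiles(
        tables=tables, immunity=immunity, callsets=callsets,
        contig_sgb_map=contig_map, sgb_species_map=species_map, truth=truth,
    )
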