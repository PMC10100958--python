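"""Readers and writers for the study's external representations.

Feature tables, sample metadata and the immunity panel are tab-separated
text; SNV calls travel as a minimal VCF v4.2 subset. Parsing is strict:
samples missing from the metadata, unknown group/timepoint tokens, negative
abundances and duplicate feature ids raise instead of being silently
dropped, so the analysed cohort can never shrink without a trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pairomics")


def _float_repr(x) -> str:
    """Shortest exact round-trip text for a float64 (numpy scalars included)."""
    return repr(float(x))


_BASES = frozenset("ACGT")


class Group(str, Enum):
    PLACEBO = "placebo"
    PROBIOTIC = "probiotic"


class Timepoint(str, Enum):
    BASELINE = "baseline"
    ENDLINE = "endline"


class Layer(str, Enum):
    BACTERIA = "bacteria"
    FUNGI = "fungi"
    FUNCTION = "function"
    METABOLITE = "metabolite"


#: layers whose per-sample values are relative abundances closed to 1
RELATIVE_LAYERS = frozenset({Layer.BACTERIA, Layer.FUNGI, Layer.FUNCTION})

CLOSURE_TOL = 1e-9


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one sample: who, which arm, which visit."""

    subject_id: str
    group: Group
    timepoint: Timepoint

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}_{self.timepoint.value}"


def _check_sample_keys(sample_keys: Sequence[SampleKey]) -> None:
    seen: dict[tuple[str, Timepoint], SampleKey] = {}
    group_of: dict[str, Group] = {}
    for key in sample_keys:
        ident = (key.subject_id, key.timepoint)
        if ident in seen:
            raise ValueError(
                f"duplicate sample for subject '{key.subject_id}' at {key.timepoint.value}"
            )
        seen[ident] = key
        prev = group_of.setdefault(key.subject_id, key.group)
        if prev is not key.group:
            raise ValueError(
                f"subject '{key.subject_id}' assigned to more than one group"
            )


@dataclass
class FeatureTable:
    """One omics layer: samples x features, non-negative (raw scale).

    ``scale`` is ``"raw"`` for abundances/intensities and ``"clr"`` for
    centred log-ratio transformed values (which may be negative).
    """

    layer: Layer
    sample_keys: list[SampleKey]
    feature_ids: list[str]
    values: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_keys), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_keys)} samples x {len(self.feature_ids)} features"
            )
        dupes = pd.Index(self.feature_ids).duplicated()
        if dupes.any():
            bad = [f for f, d in zip(self.feature_ids, dupes) if d]
            raise ValueError(f"duplicate feature id(s): {sorted(set(bad))}")
        _check_sample_keys(self.sample_keys)
        if self.scale == "raw":
            if np.any(self.values < 0):
                raise ValueError("negative abundance in feature table")
            if self.layer in RELATIVE_LAYERS and self.values.size:
                sums = self.values.sum(axis=1)
                if np.any(sums <= 0) or np.any(sums > 1 + CLOSURE_TOL):
                    raise ValueError(
                        f"{self.layer.value} layer row sums must lie in (0, 1]; "
                        f"got range [{sums.min():.6g}, {sums.max():.6g}]"
                    )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_keys)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def sample_ids(self) -> list[str]:
        return [k.sample_id for k in self.sample_keys]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id '{feature_id}'") from None

    def subset(self, predicate: Callable[[SampleKey], bool]) -> "FeatureTable":
        idx = [i for i, k in enumerate(self.sample_keys) if predicate(k)]
        return FeatureTable(
            layer=self.layer,
            sample_keys=[self.sample_keys[i] for i in idx],
            feature_ids=list(self.feature_ids),
            values=self.values[idx],
            scale=self.scale,
        )

    def select(
        self, group: Group | None = None, timepoint: Timepoint | None = None
    ) -> "FeatureTable":
        return self.subset(
            lambda k: (group is None or k.group is group)
            and (timepoint is None or k.timepoint is timepoint)
        )

    def subjects(self, group: Group | None = None) -> list[str]:
        return sorted(
            {k.subject_id for k in self.sample_keys if group is None or k.group is group}
        )

    def paired_subjects(self, group: Group | None = None) -> list[str]:
        """Subjects present at both timepoints (the pairing unit)."""
        by_tp: dict[Timepoint, set[str]] = {tp: set() for tp in Timepoint}
        for k in self.sample_keys:
            if group is None or k.group is group:
                by_tp[k.timepoint].add(k.subject_id)
        return sorted(by_tp[Timepoint.BASELINE] & by_tp[Timepoint.ENDLINE])

    def unpaired_subjects(self, group: Group | None = None) -> list[str]:
        paired = set(self.paired_subjects(group))
        return sorted(set(self.subjects(group)) - paired)

    def sample_row(self, subject_id: str, timepoint: Timepoint) -> np.ndarray:
        for i, k in enumerate(self.sample_keys):
            if k.subject_id == subject_id and k.timepoint is timepoint:
                return self.values[i]
        raise KeyError(f"no sample for subject '{subject_id}' at {timepoint.value}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.layer is other.layer
            and self.scale == other.scale
            and self.sample_keys == other.sample_keys
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.values, other.values)
        )


class IndicatorCategory(str, Enum):
    CYTOKINE = "cytokine"
    CBC = "cbc"
    LYMPHOCYTE = "lymphocyte"


@dataclass
class ImmunityPanel:
    """Immunity indicators (samples x indicators), strictly positive values."""

    sample_keys: list[SampleKey]
    indicator_ids: list[str]
    categories: dict[str, IndicatorCategory]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_keys), len(self.indicator_ids)):
            raise ValueError("values shape does not match samples x indicators")
        missing = [i for i in self.indicator_ids if i not in self.categories]
        if missing:
            raise ValueError(f"indicator(s) without category: {missing}")
        if np.any(self.values <= 0):
            raise ValueError("immunity indicator values must be positive")
        _check_sample_keys(self.sample_keys)

    @property
    def sample_ids(self) -> list[str]:
        return [k.sample_id for k in self.sample_keys]

    def subjects(self, group: Group | None = None) -> list[str]:
        return sorted(
            {k.subject_id for k in self.sample_keys if group is None or k.group is group}
        )

    def paired_subjects(self, group: Group | None = None) -> list[str]:
        by_tp: dict[Timepoint, set[str]] = {tp: set() for tp in Timepoint}
        for k in self.sample_keys:
            if group is None or k.group is group:
                by_tp[k.timepoint].add(k.subject_id)
        return sorted(by_tp[Timepoint.BASELINE] & by_tp[Timepoint.ENDLINE])

    def sample_row(self, subject_id: str, timepoint: Timepoint) -> np.ndarray:
        for i, k in enumerate(self.sample_keys):
            if k.subject_id == subject_id and k.timepoint is timepoint:
                return self.values[i]
        raise KeyError(f"no sample for subject '{subject_id}' at {timepoint.value}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.indicator_ids
        )

    def equals(self, other: "ImmunityPanel") -> bool:
        return (
            self.sample_keys == other.sample_keys
            and self.indicator_ids == other.indicator_ids
            and self.categories == other.categories
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True, order=True)
class SnvKey:
    """One single-nucleotide variant against an SGB reference genome."""

    sgb_id: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNV position must be >= 1, got {self.position}")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"alleles must be single upper-case bases, got "
                f"'{self.ref_allele}'>'{self.alt_allele}'"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class FilterSettings:
    min_quality: float = 60.0
    min_depth: int = 100

    def __post_init__(self) -> None:
        if self.min_quality < 0 or self.min_depth < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class SnvCallSet:
    """Quality-filtered SNV calls for one sample (one host, one timepoint)."""

    sample_key: SampleKey
    calls: frozenset[SnvKey]
    filters_applied: FilterSettings = field(default_factory=FilterSettings)


# ---------------------------------------------------------------------------
# metadata / tables
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> dict[str, SampleKey]:
    """Map sample id -> SampleKey from a 4-column TSV (sample, subject, group, timepoint)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "subject", "group", "timepoint"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"metadata must have columns {sorted(required)}, got {list(df.columns)}"
        )
    mapping: dict[str, SampleKey] = {}
    for row in df.itertuples(index=False):
        try:
            group = Group(row.group)
        except ValueError:
            raise ValueError(f"unknown group token '{row.group}'") from None
        try:
            timepoint = Timepoint(row.timepoint)
        except ValueError:
            raise ValueError(f"unknown timepoint token '{row.timepoint}'") from None
        if row.sample in mapping:
            raise ValueError(f"duplicate sample id '{row.sample}' in metadata")
        mapping[row.sample] = SampleKey(row.subject, group, timepoint)
    _check_sample_keys(list(mapping.values()))
    return mapping


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, float_precision="round_trip"
    )
    if df.index.duplicated().any():
        bad = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate feature id(s) in {path}: {bad}")
    return df


def read_feature_table(
    path: str | Path, layer: Layer | str, metadata_path: str | Path
) -> FeatureTable:
    """Parse a features-x-samples TSV plus metadata into a FeatureTable.

    The TSV has feature ids in the first column and one column per sample.
    Every sample column must be present in the metadata; the join is strict.
    """
    layer = Layer(layer)
    df = _read_matrix(path)
    meta = read_metadata(metadata_path)
    keys = []
    for sid in df.columns:
        if sid not in meta:
            raise ValueError(f"sample '{sid}' missing from metadata")
        keys.append(meta[sid])
    values = df.to_numpy(dtype=float).T
    if np.any(np.isnan(values)):
        raise ValueError(f"malformed TSV {path}: non-numeric or missing values")
    if np.any(values < 0):
        raise ValueError("negative abundance in feature table")
    table = FeatureTable(
        layer=layer,
        sample_keys=keys,
        feature_ids=[str(f) for f in df.index],
        values=values,
    )
    logger.info(
        "read %s table: %d samples x %d features", layer.value, table.n_samples,
        table.n_features,
    )
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(
        table.values.T, index=pd.Index(table.feature_ids, name="feature_id"),
        columns=table.sample_ids,
    )
    # repr is the shortest exact round-trip representation of a float64
    df.to_csv(path, sep="\t", float_format=_float_repr)


def write_metadata(sample_keys: Sequence[SampleKey], path: str | Path) -> None:
    rows = [
        (k.sample_id, k.subject_id, k.group.value, k.timepoint.value)
        for k in sample_keys
    ]
    pd.DataFrame(rows, columns=["sample", "subject", "group", "timepoint"]).to_csv(
        path, sep="\t", index=False
    )


def read_immunity_panel(
    path: str | Path, metadata_path: str | Path, categories_path: str | Path
) -> ImmunityPanel:
    """Parse indicators-x-samples TSV, metadata and an indicator->category TSV."""
    df = _read_matrix(path)
    meta = read_metadata(metadata_path)
    keys = []
    for sid in df.columns:
        if sid not in meta:
            raise ValueError(f"sample '{sid}' missing from metadata")
        keys.append(meta[sid])
    cat_df = pd.read_csv(categories_path, sep="\t", comment="#", dtype=str)
    if not {"indicator", "category"}.issubset(cat_df.columns):
        raise ValueError("categories file must have columns (indicator, category)")
    categories = {
        r.indicator: IndicatorCategory(r.category) for r in cat_df.itertuples(index=False)
    }
    return ImmunityPanel(
        sample_keys=keys,
        indicator_ids=[str(i) for i in df.index],
        categories=categories,
        values=df.to_numpy(dtype=float).T,
    )


def write_immunity_panel(panel: ImmunityPanel, path: str | Path, categories_path: str | Path) -> None:
    pd.DataFrame(
        panel.values.T, index=pd.Index(panel.indicator_ids, name="indicator"),
        columns=panel.sample_ids,
    ).to_csv(path, sep="\t", float_format=_float_repr)
    pd.DataFrame(
        [(i, panel.categories[i].value) for i in panel.indicator_ids],
        columns=["indicator", "category"],
    ).to_csv(categories_path, sep="\t", index=False)


def read_contig_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV contig -> sgb_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("contig map must have two columns (contig, sgb_id)")
    return dict(zip(df[cols[0]], df[cols[1]]))


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV sgb_id -> species name (GTDB-style)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("species map must have two columns (sgb_id, species)")
    return dict(zip(df[cols[0]], df[cols[1]]))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_calls(
    path: str | Path,
    sample_key: SampleKey,
    contig_sgb_map: Mapping[str, str],
    min_quality: float = 60.0,
    min_depth: int = 100,
) -> SnvCallSet:
    """Read one sample's VCF into a quality/depth-filtered SNV call set.

    Records pass when QUAL >= ``min_quality`` (inclusive) and depth >=
    ``min_depth`` (inclusive) and both REF and the ALT allele are single
    bases; multi-allelic records are split and each allele filtered on its
    own. Depth is taken from FORMAT/DP when present, else INFO/DP; records
    with neither are skipped (counted, logged), not fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    calls: set[SnvKey] = set()
    n_records = n_kept = n_no_depth = n_no_qual = 0
    try:
        for rec in vcf:
            n_records += 1
            contig = rec.CHROM
            if contig not in contig_sgb_map:
                raise ValueError(f"contig '{contig}' has no SGB mapping")
            qual = rec.QUAL
            if qual is None:
                n_no_qual += 1
                continue
            depth = None
            fmt_dp = rec.format("DP") if vcf.samples else None
            if fmt_dp is not None:
                first = int(np.asarray(fmt_dp).ravel()[0])
                if first >= 0:  # negative values are htslib missing sentinels
                    depth = first
            if depth is None:
                info_dp = rec.INFO.get("DP")
                if info_dp is not None:
                    depth = int(info_dp)
            if depth is None:
                n_no_depth += 1
                continue
            if qual < min_quality or depth < min_depth:
                continue
            ref = rec.REF.upper()
            if len(ref) != 1 or ref not in _BASES:
                continue
            for alt in rec.ALT:
                alt = alt.upper()
                if len(alt) != 1 or alt not in _BASES or alt == ref:
                    continue
                calls.add(
                    SnvKey(
                        sgb_id=contig_sgb_map[contig],
                        contig=contig,
                        position=rec.POS,
                        ref_allele=ref,
                        alt_allele=alt,
                    )
                )
                n_kept += 1
    finally:
        vcf.close()
    logger.info(
        "VCF %s: %d records in, %d SNV calls kept (QUAL>=%g, DP>=%d); "
        "%d missing depth, %d missing QUAL",
        path, n_records, n_kept, min_quality, min_depth, n_no_depth, n_no_qual,
    )
    return SnvCallSet(
        sample_key=sample_key,
        calls=frozenset(calls),
        filters_applied=FilterSettings(min_quality=min_quality, min_depth=min_depth),
    )


def write_vcf_calls(callset: SnvCallSet, path: str | Path) -> None:
    """Write a minimal VCF v4.2 so that a same-threshold read round-trips.

    QUAL and INFO/DP are written as the call set's own filter thresholds,
    which makes every record pass an inclusive re-read at those thresholds.
    """
    calls = sorted(
        callset.calls, key=lambda k: (k.contig, k.position, k.ref_allele, k.alt_allele)
    )
    qual = callset.filters_applied.min_quality
    depth = callset.filters_applied.min_depth
    contigs = sorted({k.contig for k in calls})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for k in calls:
        lines.append(
            f"{k.contig}\t{k.position}\t.\t{k.ref_allele}\t{k.alt_allele}\t"
            f"{qual:g}\tPASS\tDP={depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
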