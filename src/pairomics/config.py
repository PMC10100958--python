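"""Run settings: every threshold used anywhere in the pipeline, loadable
from one nested YAML file and overridable per CLI flag."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class Settings:
    # VCF filters
    min_quality: float = 60.0
    min_depth: int = 100
    # hypothesis testing
    alpha: float = 0.05
    n_permutations: int = 999
    seed: int = 0
    min_paired_subjects: int = 6
    use_fdr: bool = False
    # interpretation switch: the significance cut is on the Spearman p-value,
    # not on |rho| (recorded explicitly; see indirect module docs)
    spearman_threshold_is_pvalue: bool = True
    strict_differential: bool = False
    include_placebo_edges: bool = False
    standardize_immunity_deltas: bool = False
    # metabolite QC
    min_intensity: float = 1000.0
    min_prevalence: float = 0.20
    max_rsd: float = 0.20
    # SNV attribution
    snv_prevalence_threshold: float = 0.30
    snv_direction_scope: str = "either"  # or "gained"
    snv_pooled_prevalence: bool = False
    top_k_species: int = 10


# YAML section -> field names, purely presentational
_SECTIONS = {
    "vcf": ["min_quality", "min_depth"],
    "testing": [
        "alpha", "n_permutations", "seed", "min_paired_subjects", "use_fdr",
        "spearman_threshold_is_pvalue", "strict_differential",
        "include_placebo_edges", "standardize_immunity_deltas",
    ],
    "metabolite_qc": ["min_intensity", "min_prevalence", "max_rsd"],
    "snv": [
        "snv_prevalence_threshold", "snv_direction_scope",
        "snv_pooled_prevalence", "top_k_species",
    ],
}


def load_settings(path: str | Path | None = None, **overrides) -> Settings:
    """Build Settings from an optional YAML file plus keyword overrides.

    The YAML may be flat (field: value) or nested by section; unknown keys
    are rejected so typos cannot silently fall back to defaults.
    """
    known = {f.name for f in fields(Settings)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key, val in data.items():
            if isinstance(val, dict):
                for sub, subval in val.items():
                    if sub not in known:
                        raise ValueError(f"unknown setting '{key}.{sub}'")
                    values[sub] = subval
            else:
                if key not in known:
                    raise ValueError(f"unknown setting '{key}'")
                values[key] = val
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in known:
            raise ValueError(f"unknown setting override '{key}'")
        values[key] = val
    return Settings(**values)


def dump_settings(settings: Settings, path: str | Path) -> None:
    data = {
        section: {name: getattr(settings, name) for name in names}
        for section, names in _SECTIONS.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
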