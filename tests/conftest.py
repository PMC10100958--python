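from __future__ import annotations

import numpy as np
import pytest

from pairomics.io_formats import (
    FeatureTable,
    Group,
    ImmunityPanel,
    IndicatorCategory,
    Layer,
    SampleKey,
    Timepoint,
)
from pairomics.synthetic import CohortConfig, generate_cohort


def make_keys(n_per_group: int) -> list[SampleKey]:
    keys = []
    for g, prefix in ((Group.PLACEBO, "PLA"), (Group.PROBIOTIC, "PRO")):
        for i in range(n_per_group):
            for tp in (Timepoint.BASELINE, Timepoint.ENDLINE):
                keys.append(SampleKey(f"{prefix}{i + 1:03d}", g, tp))
    return keys


def make_table(
    values: np.ndarray,
    layer: Layer = Layer.METABOLITE,
    feature_ids: list[str] | None = None,
    n_per_group: int | None = None,
) -> FeatureTable:
    """Wrap a (4*n_per_group) x n_features matrix as a FeatureTable."""
    values = np.asarray(values, dtype=float)
    if n_per_group is None:
        n_per_group = values.shape[0] // 4
    if feature_ids is None:
        feature_ids = [f"F{j + 1:03d}" for j in range(values.shape[1])]
    return FeatureTable(
        layer=layer,
        sample_keys=make_keys(n_per_group),
        feature_ids=feature_ids,
        values=values,
    )


def make_panel(values: np.ndarray, n_per_group: int | None = None) -> ImmunityPanel:
    values = np.asarray(values, dtype=float)
    if n_per_group is None:
        n_per_group = values.shape[0] // 4
    ids = [f"IND{j + 1:03d}" for j in range(values.shape[1])]
    return ImmunityPanel(
        sample_keys=make_keys(n_per_group),
        indicator_ids=ids,
        categories={i: IndicatorCategory.CYTOKINE for i in ids},
        values=values,
    )


def null_config(seed: int, n_subjects: int = 10, n_bacteria: int = 40, **kwargs) -> CohortConfig:
    """A cohort config with no planted effects and a minimal SNV catalogue."""
    defaults = dict(
        n_subjects_per_group=n_subjects,
        n_features={Layer.BACTERIA: n_bacteria},
        n_indicators=6,
        category_split=(3, 2, 1),
        n_sgbs=2,
        n_shared_snvs=0,
        snv_group_rate={Group.PLACEBO: 0.0, Group.PROBIOTIC: 0.0},
        snv_background_pool=5,
        snv_background_rate=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with every planted effect switched on."""
    cfg = CohortConfig(
        n_subjects_per_group=12,
        n_features={
            Layer.BACTERIA: 50, Layer.FUNGI: 20, Layer.FUNCTION: 30,
            Layer.METABOLITE: 60,
        },
        n_indicators=12,
        category_split=(6, 4, 2),
        n_linked_pairs=3,
        n_shared_linked_pairs=2,
        n_drift_features=4,
        n_shift_features=4,
        n_sgbs=5,
        n_shared_snvs=10,
        snv_background_pool=50,
        n_snv_links=2,
        seed=421,
    )
    return generate_cohort(cfg)
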