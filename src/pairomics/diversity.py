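"""Alpha diversity, Bray-Curtis beta diversity, within-group convergence
and a from-scratch permutation PERMANOVA.

The pseudo-F statistic is computed directly from the distance matrix
(Anderson's distance-based sums of squares); the p-value is a label
permutation test that always includes the observed statistic, so p can
never be exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .io_formats import FeatureTable, Group, Layer, SampleKey, Timepoint
from .stats import rank_sum_test, signed_rank_test

logger = logging.getLogger("pairomics")


def shannon(abundances: np.ndarray) -> float:
    """Shannon index H = -sum p_i ln p_i over positive entries (natural log)."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC = sum |x_i - y_i| / sum (x_i + y_i), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    denom = (x + y).sum()
    if denom <= 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis distances with a zero diagonal."""

    sample_keys: list[SampleKey]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_keys)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample keys")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > 1 + 1e-9):
            raise ValueError("Bray-Curtis distances must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_keys)


def distance_matrix(
    table: FeatureTable, subset: Callable[[SampleKey], bool] | None = None
) -> DistanceMatrix:
    """All-pairs Bray-Curtis over the selected samples.

    Metabolite intensities are normalised to per-sample proportions first
    (BC on raw intensities would be scale-dependent); this is logged.
    """
    if subset is not None:
        table = table.subset(subset)
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    X = table.values
    if table.layer is Layer.METABOLITE and table.scale == "raw":
        logger.info("normalising metabolite intensities to proportions before Bray-Curtis")
        sums = X.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("all-zero metabolite sample")
        X = X / sums
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    sums = X.sum(axis=1)
    denom = sums[:, None] + sums[None, :]
    with np.errstate(invalid="ignore"):
        d = diff / denom
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(sample_keys=list(table.sample_keys), d=d)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    n_groups: int
    n_samples: int


def _ss_within_batch(D2: np.ndarray, masks: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """SS_within for a batch of label assignments.

    ``masks`` has shape (n_groups, batch, N) of 0/1 floats.
    """
    terms = np.einsum("gpi,ij,gpj->gp", masks, D2, masks)
    return (terms / (2.0 * sizes[:, None])).sum(axis=0)


def permanova(
    dm: DistanceMatrix,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermanovaResult:
    """Distance-based pseudo-F with a uniform label-permutation p-value.

    SS_total = (1/N) sum_{i<j} d_ij^2; SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2; F = (SS_between/(a-1)) / (SS_within/(N-a));
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    N = dm.n_samples
    if labels.shape != (N,):
        raise ValueError("labels must align with the distance matrix samples")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes).astype(float)
    if np.any(sizes < 2):
        raise ValueError("every group needs at least 2 samples")
    D2 = dm.d ** 2
    ss_total = D2[np.triu_indices(N, k=1)].sum() / N

    def f_stat(code_rows: np.ndarray) -> np.ndarray:
        # code_rows: (batch, N) integer labels
        masks = np.stack([(code_rows == g).astype(float) for g in range(a)])
        ss_w = _ss_within_batch(D2, masks, sizes)
        ss_b = ss_total - ss_w
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ss_b / (a - 1)) / (ss_w / (N - a))

    f_obs = float(f_stat(codes[None, :])[0])
    masks_obs = np.stack([(codes[None, :] == g).astype(float) for g in range(a)])
    if _ss_within_batch(D2, masks_obs, sizes)[0] <= 0:
        raise ValueError("zero within-group variance: pseudo-F undefined")
    perm_codes = np.empty((n_permutations, N), dtype=codes.dtype)
    for i in range(n_permutations):
        perm_codes[i] = codes[rng.permutation(N)]
    f_perm = f_stat(perm_codes)
    hits = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs, p_value=p, n_permutations=n_permutations,
        n_groups=a, n_samples=N,
    )


def within_group_dissimilarity(
    dm: DistanceMatrix, group: Group, timepoint: Timepoint
) -> list[float]:
    """The C(n, 2) pairwise distances among one group's samples at one timepoint."""
    return [d for _, d in sorted(subject_pair_dissimilarity(dm, group, timepoint).items())]


def subject_pair_dissimilarity(
    dm: DistanceMatrix, group: Group, timepoint: Timepoint
) -> dict[tuple[str, str], float]:
    """Within-cell pairwise distances keyed by the (sorted) subject pair."""
    idx = [
        i for i, k in enumerate(dm.sample_keys)
        if k.group is group and k.timepoint is timepoint
    ]
    if len(idx) < 2:
        raise ValueError(
            f"need at least 2 samples in ({group.value}, {timepoint.value}), got {len(idx)}"
        )
    out: dict[tuple[str, str], float] = {}
    for i, j in combinations(idx, 2):
        pair = tuple(sorted((dm.sample_keys[i].subject_id, dm.sample_keys[j].subject_id)))
        out[pair] = float(dm.d[i, j])
    return out


@dataclass
class ConvergenceComparison:
    """Within-group dissimilarity lists plus the rank-sum / signed-rank tests.

    ``rank_sum_p[tp]`` compares the two groups' lists at timepoint tp;
    ``signed_rank_p[g]`` compares each subject-pair's baseline distance with
    the same pair's endline distance within group g. ``median_change[g]`` is
    the median of (endline - baseline) over subject pairs (negative means
    convergence).
    """

    dissimilarities: dict[tuple[Group, Timepoint], list[float]]
    rank_sum_p: dict[Timepoint, float]
    signed_rank_p: dict[Group, float]
    median_change: dict[Group, float]


def convergence_tests(
    dm_baseline: DistanceMatrix,
    dm_endline: DistanceMatrix,
    groups: Sequence[Group] = (Group.PLACEBO, Group.PROBIOTIC),
) -> ConvergenceComparison:
    """Convergence analysis: between-group rank-sum at each timepoint and
    within-group signed-rank across timepoints, paired by subject pair."""
    dissim: dict[tuple[Group, Timepoint], list[float]] = {}
    pair_maps: dict[tuple[Group, Timepoint], dict[tuple[str, str], float]] = {}
    for g in groups:
        pair_maps[(g, Timepoint.BASELINE)] = subject_pair_dissimilarity(
            dm_baseline, g, Timepoint.BASELINE
        )
        pair_maps[(g, Timepoint.ENDLINE)] = subject_pair_dissimilarity(
            dm_endline, g, Timepoint.ENDLINE
        )
        dissim[(g, Timepoint.BASELINE)] = [
            d for _, d in sorted(pair_maps[(g, Timepoint.BASELINE)].items())
        ]
        dissim[(g, Timepoint.ENDLINE)] = [
            d for _, d in sorted(pair_maps[(g, Timepoint.ENDLINE)].items())
        ]
    rank_sum_p = {}
    for tp in (Timepoint.BASELINE, Timepoint.ENDLINE):
        rank_sum_p[tp] = rank_sum_test(
            np.asarray(dissim[(groups[0], tp)]), np.asarray(dissim[(groups[1], tp)])
        )
    signed_rank_p = {}
    median_change = {}
    for g in groups:
        base = pair_maps[(g, Timepoint.BASELINE)]
        end = pair_maps[(g, Timepoint.ENDLINE)]
        if base.keys() != end.keys():
            missing = set(base) ^ set(end)
            raise ValueError(
                f"unpaired subject-pair sets across timepoints in {g.value}: "
                f"{sorted(missing)[:5]}"
            )
        pairs = sorted(base)
        diffs = np.array([end[p] - base[p] for p in pairs])
        signed_rank_p[g] = signed_rank_test(diffs)
        median_change[g] = float(np.median(diffs))
    return ConvergenceComparison(
        dissimilarities=dissim,
        rank_sum_p=rank_sum_p,
        signed_rank_p=signed_rank_p,
        median_change=median_change,
    )
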