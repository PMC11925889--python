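"""Indicator-species analysis and specificity–occupancy keystone calling.

The indicator statistic is the point-biserial correlation: the Pearson
correlation between a feature's abundance vector and the 0/1 membership
vector of a candidate group combination.  Each feature is assigned the
combination maximising r, and significance comes from a max-statistic
permutation null (the maximised r is recomputed under label permutation),
which corrects for the best-subset selection.

Specificity of feature i for group g is its mean relative abundance in g
divided by the sum of its group means; occupancy is the fraction of g's
samples where it is present.  A (feature, group) pair is a key species when
both strictly exceed tau (default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import RelAbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "IndicatorResult",
    "SpecOccResult",
    "indicator_analysis",
    "specificity_occupancy",
]


@dataclass
class IndicatorResult:
    table: pd.DataFrame  # feature_id, group_combination, r_pb, p, significant, flag
    alpha: float
    n_permutations: int
    seed: int | None

    def significant_features(self) -> list[str]:
        t = self.table
        return list(t.loc[t["significant"], "feature_id"])


@dataclass
class SpecOccResult:
    table: pd.DataFrame  # feature_id, group, specificity, occupancy, key
    tau: float
    excluded: list[str]  # features absent everywhere

    def key_species(self) -> pd.DataFrame:
        return self.table.loc[self.table["key"]]


def _group_combinations(groups: list[str], max_size: int) -> list[tuple[str, ...]]:
    combos: list[tuple[str, ...]] = []
    for size in range(1, max_size + 1):
        combos.extend(combinations(groups, size))
    return combos


def indicator_analysis(
    rel: RelAbundanceTable,
    meta: SampleMetadata,
    max_combination_size: int | None = None,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> IndicatorResult:
    """Point-biserial indicator analysis over group combinations.

    For every feature the best (r-maximising) non-empty group combination of
    size up to ``g - 1`` is reported with a max-statistic permutation p-value.
    A feature is significant when p < alpha and its best r is positive.
    """
    meta = meta.aligned_to(rel.sample_ids)
    groups = meta.group_names
    if len(groups) < 2:
        raise ValidationError("indicator analysis needs >= 2 groups")
    if max_combination_size is None:
        max_combination_size = len(groups) - 1
    max_combination_size = min(max_combination_size, len(groups) - 1)
    combos = _group_combinations(groups, max_combination_size)

    x = rel.values.astype(float)  # features x n
    n = x.shape[1]
    labels = meta.groups.to_numpy()
    ind = np.array(
        [np.isin(labels, combo).astype(float) for combo in combos]
    ).T  # n x K

    # standardise columns of both matrices; zero-variance features flagged
    x_sd = x.std(axis=1)
    degenerate = x_sd <= 1e-12 * np.maximum(1.0, np.abs(x).max(axis=1))
    xz = np.zeros_like(x)
    ok = ~degenerate
    xz[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / x_sd[ok, None]
    iz = (ind - ind.mean(axis=0)) / ind.std(axis=0)

    r = xz @ iz / n  # features x K
    best_k = np.argmax(r, axis=1)
    r_best = r[np.arange(len(best_k)), best_k]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[0])
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = xz[:, perm] @ iz / n
        exceed += r_perm.max(axis=1) >= r_best
    p = (1 + exceed) / (n_permutations + 1)

    significant = (p < alpha) & (r_best > 0) & ok
    p = np.where(degenerate, 1.0, p)
    rows = pd.DataFrame(
        {
            "feature_id": rel.feature_ids,
            "group_combination": ["+".join(combos[k]) for k in best_k],
            "r_pb": np.where(degenerate, np.nan, r_best),
            "p": p,
            "significant": significant,
            "zero_variance": degenerate,
        }
    )
    return IndicatorResult(
        table=rows, alpha=alpha, n_permutations=n_permutations, seed=seed
    )


def specificity_occupancy(
    rel: RelAbundanceTable,
    meta: SampleMetadata,
    tau: float = 0.7,
    presence_threshold: float = 0.0,
) -> SpecOccResult:
    """Per-(feature, group) specificity and occupancy with strict >tau key rule."""
    meta = meta.aligned_to(rel.sample_ids)
    groups = meta.group_names
    if len(groups) < 2:
        raise ValidationError("specificity–occupancy needs >= 2 groups")
    x = rel.values.astype(float)
    cols = pd.Index(rel.sample_ids)

    group_means = np.empty((x.shape[0], len(groups)))
    occupancy = np.empty_like(group_means)
    for j, g in enumerate(groups):
        idx = cols.get_indexer(meta.samples_in(g))
        group_means[:, j] = x[:, idx].mean(axis=1)
        occupancy[:, j] = (x[:, idx] > presence_threshold).mean(axis=1)

    totals = group_means.sum(axis=1)
    absent = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = group_means / totals[:, None]

    records = []
    for i, fid in enumerate(rel.feature_ids):
        if absent[i]:
            continue
        for j, g in enumerate(groups):
            records.append(
                {
                    "feature_id": fid,
                    "group": g,
                    "specificity": specificity[i, j],
                    "occupancy": occupancy[i, j],
                    "key": bool(specificity[i, j] > tau and occupancy[i, j] > tau),
                }
            )
    table = pd.DataFrame(
        records, columns=["feature_id", "group", "specificity", "occupancy", "key"]
    )
    excluded = [fid for fid, a in zip(rel.feature_ids, absent) if a]
    return SpecOccResult(table=table, tau=tau, excluded=excluded)
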