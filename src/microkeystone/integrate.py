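"""Procrustes/PROTEST ordination concordance and the taxa–gene–trait network.

Procrustes superimposes two sample ordinations after centering and scaling
each to unit sum of squares; the optimal rotation comes from the SVD of the
cross-product and leaves the residual ``m2 = 1 - (sum of singular values)^2``.
PROTEST assesses m2 by permuting the sample rows of the second configuration.

The integration network links key taxa, selected genes and traits through
pairwise Spearman correlations with strict thresholds (taxa–gene edges at
r > 0.8 and p < 0.01 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import RelAbundanceTable, TraitTable, ValidationError
from .diversity import Ordination

__all__ = [
    "ProcrustesResult",
    "OmicsLinkNetwork",
    "procrustes_test",
    "omics_network",
    "trait_feature_correlation",
]


@dataclass
class ProcrustesResult:
    m2: float
    t_stat: float
    p: float
    n_permutations: int
    seed: int | None


@dataclass
class OmicsLinkNetwork:
    graph: nx.Graph
    r_min: float
    alpha: float
    trait_r_min: float
    trait_alpha: float

    def edges_between(self, type_a: str, type_b: str) -> list[tuple[str, str, dict]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            types = {self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]}
            if types == {type_a, type_b}:
                out.append((u, v, d))
        return out


def _unit_configuration(coords: np.ndarray) -> np.ndarray:
    x = coords - coords.mean(axis=0)
    ss = np.sqrt((x ** 2).sum())
    if ss == 0:
        raise ValidationError("degenerate configuration with zero spread")
    return x / ss


def _m2(x: np.ndarray, y: np.ndarray) -> float:
    """Procrustes residual for two centered unit-SS configurations."""
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(
    ord_a: Ordination,
    ord_b: Ordination,
    n_axes: int = 2,
    n_permutations: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Procrustes m2 between two ordinations with a PROTEST permutation p.

    Reflections are allowed (singular values enter with positive sign); rows
    of the second configuration are permuted, and the p-value counts permuted
    m2 values at or below the observed one with the +1 convention.
    """
    if list(ord_a.sample_ids) != list(ord_b.sample_ids):
        only_a = set(ord_a.sample_ids) - set(ord_b.sample_ids)
        only_b = set(ord_b.sample_ids) - set(ord_a.sample_ids)
        if only_a or only_b:
            raise ValidationError(
                f"sample mismatch: only in first {sorted(only_a)}, "
                f"only in second {sorted(only_b)}"
            )
        # same set, different order: align B to A
        order = [ord_b.sample_ids.index(s) for s in ord_a.sample_ids]
        coords_b = ord_b.coordinates[order]
    else:
        coords_b = ord_b.coordinates
    if n_axes > ord_a.coordinates.shape[1] or n_axes > coords_b.shape[1]:
        raise ValidationError(
            f"n_axes={n_axes} exceeds available axes "
            f"({ord_a.coordinates.shape[1]}, {coords_b.shape[1]})"
        )
    x = _unit_configuration(ord_a.coordinates[:, :n_axes])
    y = _unit_configuration(coords_b[:, :n_axes])
    m2_obs = _m2(x, y)

    rng = np.random.default_rng(seed)
    n = x.shape[0]
    count = 0
    for _ in range(n_permutations):
        if _m2(x, y[rng.permutation(n)]) <= m2_obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return ProcrustesResult(
        m2=m2_obs,
        t_stat=float(np.sqrt(max(0.0, 1.0 - m2_obs))),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def _spearman_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    mask = np.isfinite(a) & np.isfinite(b)
    n = int(mask.sum())
    if n < 5:
        return np.nan, np.nan
    rho, p = stats.spearmanr(a[mask], b[mask])
    return float(rho), float(p)


def _cross_spearman(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho/p between every row of ``a`` and every row of ``b``
    (columns = shared samples, pairwise-complete over missing values)."""
    rho = np.empty((a.shape[0], b.shape[0]))
    p = np.empty_like(rho)
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    for i in range(av.shape[0]):
        for j in range(bv.shape[0]):
            rho[i, j], p[i, j] = _spearman_pair(av[i], bv[j])
    return (
        pd.DataFrame(rho, index=a.index, columns=b.index),
        pd.DataFrame(p, index=a.index, columns=b.index),
    )


def omics_network(
    taxa: RelAbundanceTable | pd.DataFrame,
    genes: pd.DataFrame,
    traits: TraitTable | pd.DataFrame,
    r_min: float = 0.8,
    alpha: float = 0.01,
    trait_r_min: float = 0.5,
    trait_alpha: float = 0.05,
) -> OmicsLinkNetwork:
    """Typed taxa–gene–trait Spearman network with strict edge thresholds.

    taxa and genes are feature x sample matrices (key taxa / selected genes);
    traits is sample x trait.  Taxa–gene edges require rho > r_min and
    p < alpha (both strict per the calling rule); taxa–trait and gene–trait
    edges use |rho| > trait_r_min and p < trait_alpha.
    """
    taxa_df = taxa.data if hasattr(taxa, "data") else taxa
    traits_df = (traits.data if hasattr(traits, "data") else traits).T  # trait x sample
    shared = [s for s in taxa_df.columns if s in genes.columns and s in traits_df.columns]
    if len(shared) < 5:
        raise ValidationError(f"only {len(shared)} shared samples; need >= 5")
    taxa_df = taxa_df[shared]
    genes_df = genes[shared]
    traits_df = traits_df[shared]

    g = nx.Graph()
    for fid in taxa_df.index:
        g.add_node(f"taxon:{fid}", kind="taxon", label=str(fid))
    for gid in genes_df.index:
        g.add_node(f"gene:{gid}", kind="gene", label=str(gid))
    for tid in traits_df.index:
        g.add_node(f"trait:{tid}", kind="trait", label=str(tid))

    def add_edges(df_a, df_b, prefix_a, prefix_b, rule):
        rho, p = _cross_spearman(df_a, df_b)
        for ia in df_a.index:
            for ib in df_b.index:
                r, pv = rho.loc[ia, ib], p.loc[ia, ib]
                if np.isnan(r):
                    continue
                if rule(r, pv):
                    g.add_edge(
                        f"{prefix_a}:{ia}", f"{prefix_b}:{ib}",
                        rho=float(r), p=float(pv),
                    )

    add_edges(taxa_df, genes_df, "taxon", "gene",
              lambda r, pv: r > r_min and pv < alpha)
    add_edges(taxa_df, traits_df, "taxon", "trait",
              lambda r, pv: abs(r) > trait_r_min and pv < trait_alpha)
    add_edges(genes_df, traits_df, "gene", "trait",
              lambda r, pv: abs(r) > trait_r_min and pv < trait_alpha)
    return OmicsLinkNetwork(
        graph=g, r_min=r_min, alpha=alpha,
        trait_r_min=trait_r_min, trait_alpha=trait_alpha,
    )


def trait_feature_correlation(
    features: pd.DataFrame,
    traits: TraitTable | pd.DataFrame,
    cor_min: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson and Spearman feature–trait correlations with a strict
    |r| > cor_min, p < alpha pass flag (Pearson r drives the flag).

    ``features`` is feature x sample; missing trait values are handled
    pairwise-complete.  Constant traits are flagged, not dropped.
    """
    traits_df = (traits.data if hasattr(traits, "data") else traits).T
    shared = [s for s in features.columns if s in traits_df.columns]
    if len(shared) < 5:
        raise ValidationError(f"only {len(shared)} shared samples; need >= 5")
    fv = features[shared].to_numpy(dtype=float)
    tv = traits_df[shared].to_numpy(dtype=float)
    rows = []
    for i, fid in enumerate(features.index):
        for j, tid in enumerate(traits_df.index):
            mask = np.isfinite(fv[i]) & np.isfinite(tv[j])
            constant = mask.sum() >= 2 and (
                np.ptp(fv[i][mask]) == 0 or np.ptp(tv[j][mask]) == 0
            )
            if mask.sum() < 5 or constant:
                rows.append(
                    {"feature_id": fid, "trait": tid, "r": np.nan, "p": np.nan,
                     "rho": np.nan, "rho_p": np.nan, "pass": False,
                     "flag": "constant" if constant else "insufficient"}
                )
                continue
            r, p = stats.pearsonr(fv[i][mask], tv[j][mask])
            rho, rho_p = stats.spearmanr(fv[i][mask], tv[j][mask])
            rows.append(
                {"feature_id": fid, "trait": tid, "r": float(r), "p": float(p),
                 "rho": float(rho), "rho_p": float(rho_p),
                 "pass": bool(p < alpha and abs(r) > cor_min), "flag": ""}
            )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "trait", "r", "p", "rho", "rho_p", "pass", "flag"],
    )
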