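"""Differential abundance/expression between two groups.

Counts are scaled by TMM factors into CPM with a pseudocount; log2 fold
changes come from group-mean CPMs.  Two test engines are provided and tagged
in the output:

* ``nb_exact`` — an exact conditional negative-binomial test with a common
  method-of-moments dispersion (counts in each group are scaled to a common
  effective library size; the group-A sum given the pair total follows a
  ratio of NB probabilities under the null).
* ``permutation`` — difference of group-mean log-CPM assessed by label
  permutation.

Two significance dialects are supported: gene mode flags features with
|log2FC| > 1 and raw p < 0.05; microbiome mode flags BH-corrected q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, SampleMetadata, ValidationError
from .partition import TmmFactors, tmm_factors

__all__ = [
    "DifferentialResult",
    "normalized_cpm",
    "differential_test",
    "bh_adjust",
]


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # feature_id, log2fc, p, q, significant, excluded
    method: str
    mode: str
    pair: tuple[str, str]
    lfc_min: float
    alpha: float
    fdr_alpha: float


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalized_cpm(
    table: CountTable, factors: TmmFactors, pseudocount: float = 0.5
) -> pd.DataFrame:
    """TMM-scaled counts per million with a pseudocount.

    cpm = 1e6 * (count + pseudocount) / (library_size * factor + 1)
    """
    if set(factors.factors.index) != set(table.sample_ids):
        raise ValidationError("TMM factors do not match the table's samples")
    f = factors.factors.loc[table.sample_ids].to_numpy()
    lib = table.values.sum(axis=0).astype(float)
    eff = lib * f + 1.0
    cpm = 1e6 * (table.values + pseudocount) / eff
    return pd.DataFrame(cpm, index=table.feature_ids, columns=table.sample_ids)


def _common_dispersion(scaled: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion on library-equalised counts.

    Per feature, phi = (s^2 - mu) / mu^2 pooled within groups; the common
    value is the median over features with positive, finite estimates.
    """
    phis = []
    for idx in groups:
        sub = scaled[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mu) / mu ** 2
        phis.append(phi)
    phi_all = np.concatenate(phis)
    phi_all = phi_all[np.isfinite(phi_all) & (phi_all > 0)]
    if len(phi_all) == 0:
        return 1e-4
    return float(np.median(phi_all))


def _nb_exact_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact conditional two-sided NB test.

    Under a shared mean and dispersion phi, the group sums are NB with sizes
    n_g/phi; conditioned on the total, the observed split's p-value is the
    summed probability of all splits at most as probable.
    """
    t = s_a + s_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    size_a = n_a / phi
    size_b = n_b / phi
    s = np.arange(t + 1)
    logp = stats.nbinom.logpmf(
        s, size_a, size_a / (size_a + n_a * mu)
    ) + stats.nbinom.logpmf(t - s, size_b, size_b / (size_b + n_b * mu))
    probs = np.exp(logp - logp.max())
    probs = probs / probs.sum()
    obs = probs[s_a]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def differential_test(
    table: CountTable,
    meta: SampleMetadata,
    pair: tuple[str, str],
    method: str = "nb_exact",
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
    mode: str = "gene",
    pseudocount: float = 0.5,
    n_permutations: int = 999,
    seed: int | None = None,
    factors: TmmFactors | None = None,
) -> DifferentialResult:
    """Two-group differential test on TMM-normalised counts.

    log2FC is reported as group B over group A.  Features all-zero in both
    groups are excluded with a note.
    """
    if method not in ("nb_exact", "permutation"):
        raise ValidationError(f"unknown method {method!r}")
    if mode not in ("gene", "microbiome"):
        raise ValidationError(f"unknown mode {mode!r}")
    group_a, group_b = pair
    meta = meta.aligned_to(table.sample_ids)
    samples_a = meta.samples_in(group_a)
    samples_b = meta.samples_in(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError(f"both groups in {pair} need >= 2 samples")
    sub = table.subset_samples(samples_a + samples_b)
    if factors is None:
        factors = tmm_factors(sub)
    cpm = normalized_cpm(sub, factors, pseudocount=pseudocount)
    idx_a = np.arange(len(samples_a))
    idx_b = np.arange(len(samples_a), len(samples_a) + len(samples_b))

    counts = sub.values
    nonzero = counts.sum(axis=1) > 0
    mean_a = cpm.to_numpy()[:, idx_a].mean(axis=1)
    mean_b = cpm.to_numpy()[:, idx_b].mean(axis=1)
    log2fc = np.log2(mean_b / mean_a)

    p = np.ones(counts.shape[0])
    if method == "nb_exact":
        # equalise library sizes: scale to the geometric mean effective size
        f = factors.factors.loc[sub.sample_ids].to_numpy()
        eff = counts.sum(axis=0) * f
        common = float(np.exp(np.mean(np.log(eff))))
        scaled = np.rint(counts * (common / eff)).astype(np.int64)
        phi = _common_dispersion(scaled.astype(float), [idx_a, idx_b])
        for i in np.where(nonzero)[0]:
            p[i] = _nb_exact_pvalue(
                int(scaled[i, idx_a].sum()),
                int(scaled[i, idx_b].sum()),
                len(idx_a),
                len(idx_b),
                phi,
            )
    else:
        log_cpm = np.log2(cpm.to_numpy())
        obs = log_cpm[:, idx_b].mean(axis=1) - log_cpm[:, idx_a].mean(axis=1)
        rng = np.random.default_rng(seed)
        n = log_cpm.shape[1]
        exceed = np.zeros(counts.shape[0])
        mask_b = np.zeros(n, dtype=bool)
        mask_b[idx_b] = True
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            pb = mask_b[perm]
            delta = log_cpm[:, pb].mean(axis=1) - log_cpm[:, ~pb].mean(axis=1)
            exceed += np.abs(delta) >= np.abs(obs)
        p = (1 + exceed) / (n_permutations + 1)

    q = np.ones_like(p)
    q[nonzero] = bh_adjust(p[nonzero])
    if mode == "gene":
        significant = (np.abs(log2fc) > lfc_min) & (p < alpha) & nonzero
    else:
        significant = (q < fdr_alpha) & nonzero

    out = pd.DataFrame(
        {
            "feature_id": sub.feature_ids,
            "log2fc": log2fc,
            "p": np.where(nonzero, p, np.nan),
            "q": np.where(nonzero, q, np.nan),
            "significant": significant,
            "excluded": ~nonzero,
        }
    )
    return DifferentialResult(
        table=out,
        method=method,
        mode=mode,
        pair=(group_a, group_b),
        lfc_min=lfc_min,
        alpha=alpha,
        fdr_alpha=fdr_alpha,
    )
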