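"""Alpha diversity, Bray–Curtis dissimilarity, PCoA and one-way PERMANOVA.

PCoA is the classical metric scaling of a distance matrix: Gower
double-centering ``B = -1/2 J D^2 J`` followed by an eigendecomposition, with
coordinates ``v_i sqrt(lambda_i)`` for positive eigenvalues.  Negative
eigenvalues (non-Euclidean distances) are reported, not corrected.

PERMANOVA partitions the sum of squared distances into between- and
within-group components and assesses the pseudo-F statistic by permuting
group labels; the p-value uses the +1 convention and can never be 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import CountTable, RelAbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "DiversityResult",
    "DistanceMatrix",
    "Ordination",
    "PermanovaResult",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
]


@dataclass
class DiversityResult:
    table: pd.DataFrame  # index sample_id; columns observed_features, shannon
    log_base: float


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValidationError("distances must be non-negative")
        self.data = d


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    negative_eigenvalue_fraction: float


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    seed: int | None


def alpha_diversity(table: CountTable, log_base: float = np.e) -> DiversityResult:
    """Observed features and Shannon diversity per sample."""
    counts = table.values.astype(float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has total count 0")
    observed = (counts > 0).sum(axis=0)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0) / np.log(log_base)
    out = pd.DataFrame(
        {"observed_features": observed.astype(int), "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    return DiversityResult(table=out, log_base=float(log_base))


def bray_curtis(table: CountTable | RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples."""
    x = table.values.T.astype(float)  # samples x features
    if x.shape[0] < 2:
        raise ValidationError("need >= 2 samples")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValidationError(
            "Bray–Curtis undefined between all-zero samples: "
            f"{[s for s, z in zip(table.sample_ids, zero) if z]}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(sample_ids=list(table.sample_ids), data=d)


def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis via Gower double-centering."""
    n = d.data.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d.data ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # clamp numerical dust around zero
    eigvals = np.where(np.abs(eigvals) < 1e-10 * max(1.0, np.abs(eigvals).max()), 0.0, eigvals)
    pos = eigvals > 0
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    proportions = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    neg = eigvals[eigvals < 0]
    neg_frac = float(-neg.sum() / np.abs(eigvals).sum()) if len(neg) else 0.0
    if coords.size == 0:
        coords = np.zeros((n, 1))
        proportions = np.zeros(1)
    return Ordination(
        sample_ids=list(d.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportions,
        negative_eigenvalue_fraction=neg_frac,
    )


def _permanova_ss(d2: np.ndarray, group_indices: list[np.ndarray]) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(ss_total: float, ss_within: float, n: int, g: int) -> float:
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    d: DistanceMatrix,
    meta: SampleMetadata,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (adonis) on a distance matrix."""
    meta = meta.aligned_to(d.sample_ids)
    meta.require_group_design(min_groups=2, min_per_group=2)
    labels = meta.groups.to_numpy()
    group_names = meta.group_names
    n, g = len(labels), len(group_names)
    d2 = d.data ** 2
    membership = np.array([labels == gname for gname in group_names])  # g x n
    sizes = membership.sum(axis=1)

    def ss_within_for(member: np.ndarray) -> float:
        # member: g x n boolean; within-SS = sum_g (x_g' D2 x_g / 2) / n_g
        x = member.astype(float)
        quad = np.einsum("gi,ij,gj->g", x, d2, x) / 2.0
        return float((quad / sizes).sum())

    ss_total = float(d2[np.triu_indices(n, 1)].sum() / n)
    ss_within = ss_within_for(membership)
    f_obs = _pseudo_f(ss_total, ss_within, n, g)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = 0
    chunk = 256
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        member_b = membership[:, perms].astype(float)  # g x b x n
        quad = np.einsum("gbi,ij,gbj->bg", member_b, d2, member_b) / 2.0
        ss_w = (quad / sizes).sum(axis=1)
        f_perm = ((ss_total - ss_w) / (g - 1)) / (ss_w / (n - g))
        count += int((f_perm >= f_obs).sum())
        done += b
    p = (1 + count) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(r2),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
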