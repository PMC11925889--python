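"""Relative abundance, prevalence filtering, TMM normalisation and the
six-way rare/abundant taxon partition.

The partition follows the conditionally-rare-and-abundant-taxa scheme used in
community ecology: with ``m``/``M`` the per-feature minimum/maximum relative
abundance across samples and cuts at 0.1% (rare) and 1% (abundant),

* RT   — rare everywhere:       M <= rare_cut
* AT   — abundant everywhere:   m >= abundant_cut
* MT   — moderate everywhere:   rare_cut < m and M < abundant_cut
* CRT  — conditionally rare:    m <= rare_cut < M < abundant_cut
* CAT  — conditionally abundant: rare_cut < m < abundant_cut <= M
* CRAT — spans both cuts:       m <= rare_cut and M >= abundant_cut

Closed bounds mirror the definitions' wording ("<= 0.1%", ">= 1%"); RT/AT/MT
take precedence so the six predicates form a true partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountTable, RelAbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "ABUNDANCE_CLASSES",
    "AbundanceClassAssignment",
    "TmmFactors",
    "to_relative_abundance",
    "prevalence_filter",
    "tmm_factors",
    "classify_abundance",
    "classify_min_max",
]

ABUNDANCE_CLASSES = ("RT", "AT", "MT", "CRT", "CAT", "CRAT")


@dataclass
class AbundanceClassAssignment:
    classes: pd.Series  # feature_id -> class label
    rare_cut: float
    abundant_cut: float
    summary: pd.DataFrame = field(default=None)  # feature, class, min/max/mean RA

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.classes == c).sum()) for c in ABUNDANCE_CLASSES}


@dataclass
class TmmFactors:
    factors: pd.Series  # sample_id -> positive scaling factor
    reference: str
    m_trim: float
    a_trim: float

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("TMM factors must be positive")
        log_gm = float(np.log(self.factors).mean())
        if abs(log_gm) > 1e-9:
            raise ValidationError("TMM factors must have geometric mean 1")


def to_relative_abundance(table: CountTable) -> RelAbundanceTable:
    """Column-normalise counts to per-sample proportions."""
    totals = table.values.sum(axis=0)
    if (totals == 0).any():
        bad = table.data.columns[np.argmax(totals == 0)]
        raise ValidationError(f"sample {bad!r} has total count 0")
    return RelAbundanceTable(table.data / totals)


def prevalence_filter(
    rel: RelAbundanceTable,
    meta: SampleMetadata,
    min_group_prevalence: float = 0.20,
    min_total_relabund: float = 0.025,
) -> RelAbundanceTable:
    """Keep features present in >=20% of the samples of at least one group and
    whose relative abundance summed over all samples exceeds 2.5%.

    Both thresholds are parameters; feature order is preserved.  Note the
    result's columns no longer sum to 1 — it is a feature subset of a
    relative-abundance table, re-wrapped without renormalising.
    """
    for name, thr in (
        ("min_group_prevalence", min_group_prevalence),
        ("min_total_relabund", min_total_relabund),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {thr}")
    meta = meta.aligned_to(rel.sample_ids)
    present = rel.values > 0
    keep_prev = np.zeros(len(rel.feature_ids), dtype=bool)
    cols = pd.Index(rel.sample_ids)
    for g in meta.group_names:
        idx = cols.get_indexer(meta.samples_in(g))
        frac = present[:, idx].mean(axis=1)
        keep_prev |= frac >= min_group_prevalence
    total_ra = rel.values.sum(axis=1)
    keep = keep_prev & (total_ra > min_total_relabund)
    return RelAbundanceTable.from_subset(rel.data.loc[keep])


def _tmm_one_sample(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    m_trim: float, a_trim: float,
) -> float:
    """Weighted trimmed mean of M-values of one library against the reference.

    Follows the published trimmed-mean definition: log2 ratios (M) and average
    log2 abundances (A) over features nonzero in both libraries, double
    trimming (``m_trim`` of each tail of M, ``a_trim`` of each tail of A), and
    inverse-variance weights from the delta-method binomial variance.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("sample shares no nonzero features with reference; factor 1")
        return 1.0
    y, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((y / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((y / n_obs) * (r / n_ref))
    v = (n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    trimmed = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not trimmed.any() or v[trimmed].min() <= 0:
        return 1.0
    f = np.sum(m[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
    return float(2.0 ** f)


def tmm_factors(
    table: CountTable, m_trim: float = 0.30, a_trim: float = 0.05
) -> TmmFactors:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    The reference library is the sample whose upper-quartile/library-size
    ratio is closest to the mean of that ratio across samples.
    """
    counts = table.values.astype(float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("sample with zero library size")
    uq = np.quantile(counts, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_one_sample(counts[:, k], counts[:, ref_idx], lib[k], lib[ref_idx],
                            m_trim, a_trim)
            for k in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return TmmFactors(
        factors=pd.Series(factors, index=table.sample_ids),
        reference=table.sample_ids[ref_idx],
        m_trim=m_trim,
        a_trim=a_trim,
    )


def classify_min_max(m: float, M: float, rare_cut: float, abundant_cut: float) -> str:
    """Class label for a feature with per-sample RA minimum ``m`` / maximum ``M``."""
    if M <= rare_cut:
        return "RT"
    if m >= abundant_cut:
        return "AT"
    if m > rare_cut and M < abundant_cut:
        return "MT"
    if m <= rare_cut and M >= abundant_cut:
        return "CRAT"
    if m <= rare_cut:  # and rare_cut < M < abundant_cut
        return "CRT"
    return "CAT"  # rare_cut < m < abundant_cut <= M


def classify_abundance(
    rel: RelAbundanceTable, rare_cut: float = 0.001, abundant_cut: float = 0.01
) -> AbundanceClassAssignment:
    """Assign every feature exactly one of the six abundance classes."""
    values = rel.values
    mins = values.min(axis=1)
    maxs = values.max(axis=1)
    labels = [
        classify_min_max(m, M, rare_cut, abundant_cut) for m, M in zip(mins, maxs)
    ]
    classes = pd.Series(labels, index=rel.feature_ids, name="class")
    summary = pd.DataFrame(
        {
            "class": classes,
            "min_ra": mins,
            "max_ra": maxs,
            "mean_ra": values.mean(axis=1),
        },
        index=pd.Index(rel.feature_ids, name="feature_id"),
    )
    return AbundanceClassAssignment(
        classes=classes, rare_cut=rare_cut, abundant_cut=abundant_cut, summary=summary
    )
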