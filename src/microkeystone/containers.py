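"""Core tabular containers shared by every pipeline stage.

All tables are thin validated wrappers around :class:`pandas.DataFrame` in the
features-as-rows orientation (features x samples), the dialect most
QIIME2/edgeR-style exports use.  Validation happens at construction so that
downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "RelAbundanceTable",
    "SampleMetadata",
    "TraitTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """A table failed one of its structural invariants."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} id(s): {dupes}")


@dataclass
class CountTable:
    """Integer feature x sample abundance matrix (ASVs or genes).

    Parameters
    ----------
    data:
        DataFrame with feature ids as the index and sample ids as columns.
        Entries must be non-negative integers (or integral floats).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ValidationError(
                f"need >=1 feature and >=2 samples, got shape {self.data.shape}"
            )
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("counts contain missing values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values.astype(float))):
            i, j = np.argwhere(
                ~np.isclose(values, np.round(values.astype(float)))
            )[0]
            raise ValidationError(
                f"non-integer count at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r} (pass round=True to coerce)"
            )
        self.data = self.data.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample id(s): {sorted(missing)}")
        return CountTable(self.data[list(sample_ids)])

    def subset_features(self, feature_ids: list[str]) -> "CountTable":
        missing = set(feature_ids) - set(self.feature_ids)
        if missing:
            raise ValidationError(f"unknown feature id(s): {sorted(missing)}")
        return CountTable(self.data.loc[list(feature_ids)])


@dataclass
class RelAbundanceTable:
    """Per-sample proportions with the same shape conventions as CountTable."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy(dtype=float)
        if ((values < 0) | (values > 1)).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        sums = values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.data.columns[np.argmax(np.abs(sums - 1.0))]
            raise ValidationError(
                f"sample {bad!r} relative abundances sum to {sums.max():.6g}, not 1"
            )
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: list[str]) -> "RelAbundanceTable":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample id(s): {sorted(missing)}")
        return RelAbundanceTable.from_subset(self.data[list(sample_ids)])

    @classmethod
    def from_subset(cls, data: pd.DataFrame) -> "RelAbundanceTable":
        """Wrap a feature/sample subset of a composition.

        Column sums below 1 are legitimate here, so only the range and
        uniqueness invariants are enforced.
        """
        obj = cls.__new__(cls)
        _check_unique(data.index, "feature")
        _check_unique(data.columns, "sample")
        values = data.to_numpy(dtype=float)
        if ((values < 0) | (values > 1)).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        obj.data = data.astype(float)
        return obj


@dataclass
class SampleMetadata:
    """sample -> group assignment for a between-group design."""

    groups: pd.Series  # index: sample_id, values: group label

    def __post_init__(self) -> None:
        _check_unique(self.groups.index, "sample")
        if self.groups.isna().any():
            bad = self.groups.index[self.groups.isna()].tolist()
            raise ValidationError(f"missing group value for sample(s): {bad}")
        self.groups = self.groups.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_names(self) -> list[str]:
        # first-appearance order, deterministic
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.groups == g).sum()) for g in self.group_names}

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def aligned_to(self, sample_ids: list[str]) -> "SampleMetadata":
        """Reorder to the given samples, raising if any is unannotated."""
        missing = [s for s in sample_ids if s not in self.groups.index]
        if missing:
            raise ValidationError(
                f"sample(s) present in table but absent from metadata: {missing}"
            )
        return SampleMetadata(self.groups.loc[list(sample_ids)])

    def require_group_design(self, min_groups: int = 2, min_per_group: int = 2) -> None:
        sizes = self.group_sizes()
        if len(sizes) < min_groups:
            raise ValidationError(f"need >= {min_groups} groups, got {len(sizes)}")
        small = {g: n for g, n in sizes.items() if n < min_per_group}
        if small:
            raise ValidationError(
                f"group(s) with fewer than {min_per_group} samples: {small}"
            )


@dataclass
class TraitTable:
    """Continuous per-sample trait panel (behaviour scores, antioxidant assays).

    Missing values are permitted and treated pairwise-complete in correlations.
    """

    data: pd.DataFrame  # index: sample_id, columns: trait names

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "trait")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValidationError("traits must be finite (NaN allowed for missing)")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)
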