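"""Core in-memory containers for LC-MS feature-table analysis.

A *feature* is an ion species detected by LC-MS, identified by its
mass-to-charge ratio (m/z), retention time, and per-sample integrated
intensity.  Multiple features commonly derive from a single chemical
(adducts, water losses, isotopes), which is why the table keeps m/z and
retention time alongside the intensity matrix instead of collapsing to a
bare matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def make_feature_id(mz: float, rt: float) -> str:
    """Canonical feature identifier ``mz@rt`` (m/z to 5 d.p., rt to 2 d.p.)."""
    return f"{mz:.5f}@{rt:.2f}"


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with m/z and retention time.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample.
        Missing measurements are ``NaN``; present values are >= 0.
    mz
        Per-feature m/z in Daltons (singly charged positive mode assumed),
        indexed like ``data``.
    rt
        Per-feature retention time in seconds, indexed like ``data``.
    """

    data: pd.DataFrame
    mz: pd.Series
    rt: pd.Series

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.mz = pd.Series(self.mz, dtype=float).reindex(self.data.index)
        self.rt = pd.Series(self.rt, dtype=float).reindex(self.data.index)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.mz.isna().any() or (self.mz <= 0).any():
            bad = self.mz.index[self.mz.isna() | (self.mz <= 0)][0]
            raise ValidationError(f"feature {bad!r} has non-positive m/z")
        pairs = pd.MultiIndex.from_arrays([self.mz, self.rt])
        if pairs.has_duplicates:
            i = int(np.nonzero(np.asarray(pairs.duplicated()))[0][0])
            raise ValidationError(
                f"duplicate (mz, rt) pair at row {i}: "
                f"({self.mz.iloc[i]}, {self.rt.iloc[i]})"
            )
        vals = self.data.to_numpy()
        neg = np.nan_to_num(vals, nan=0.0) < 0
        if neg.any():
            i = int(np.nonzero(neg.any(axis=1))[0][0])
            raise ValidationError(f"negative intensity in feature row {i}")

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, feature_ids: Sequence[str]) -> "FeatureTable":
        """Row-subset preserving the given order."""
        return FeatureTable(
            data=self.data.loc[list(feature_ids)],
            mz=self.mz.loc[list(feature_ids)],
            rt=self.rt.loc[list(feature_ids)],
        )

    def log2(self, offset: float = 0.0) -> pd.DataFrame:
        """log2 intensities; non-positive values (after offset) become NaN."""
        shifted = self.data + offset
        return np.log2(shifted.where(shifted > 0))

    def equals(self, other: "FeatureTable", mass_tol: float = 1e-6) -> bool:
        return (
            list(self.data.index) == list(other.data.index)
            and list(self.data.columns) == list(other.data.columns)
            and np.allclose(self.mz, other.mz, atol=mass_tol)
            and np.allclose(self.rt, other.rt, atol=1e-6)
            and np.allclose(
                self.data.to_numpy(), other.data.to_numpy(), equal_nan=True
            )
        )


@dataclass
class MetaboliteRecord:
    """A database entry emulating a KEGG/Metlin metabolite record."""

    record_id: str
    name: str
    monoisotopic_mass: float
    formula: Optional[str] = None
    source_tag: str = ""
    pathway_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.monoisotopic_mass > 0):
            raise ValidationError(
                f"record {self.record_id!r}: monoisotopic mass must be > 0"
            )


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (index = sample id, ``group`` column)."""
    if samples.index.has_duplicates:
        raise ValidationError("duplicate sample ids in sample table")
    if "group" not in samples.columns:
        raise ValidationError("sample table lacks a 'group' column")
    groups = set(samples["group"])
    bad = groups - {CASE, CONTROL}
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    return samples


def group_masks(samples: pd.DataFrame, sample_ids: Sequence[str]):
    """Boolean case/control masks aligned to ``sample_ids``."""
    g = samples.loc[list(sample_ids), "group"]
    return (g == CASE).to_numpy(), (g == CONTROL).to_numpy()
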