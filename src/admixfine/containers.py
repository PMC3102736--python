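"""Core in-memory containers shared by all pipeline stages.

The central object is :class:`DosageMatrix`: a samples x variants matrix of
risk-allele dosages in [0, 2] (NaN = missing call) together with per-variant
metadata (position, alleles, typed/imputed status and imputation quality
``rsq``).  Phenotypes travel as a plain :class:`pandas.DataFrame` validated by
:func:`validate_sample_table`; local ancestry (expected count of population-1
chromosomes, continuous in [0, 2]) as :class:`LocalAncestryTrack`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "risk_allele",
    "other_allele",
    "typed",
    "rsq",
]

SAMPLE_COLUMNS = [
    "sample_id",
    "status",
    "age",
    "study",
    "family_history",
    "severity",
    "sex",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table for the required columns and value ranges."""
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"phenotype table missing columns: {missing}")
    status = table["status"].to_numpy()
    if not np.isin(status, (0, 1)).all():
        raise DataError("status must be 0/1")
    if table["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in phenotype table")
    return table


@dataclass
class DosageMatrix:
    """Risk-allele dosages for ``n_samples`` x ``n_variants``.

    Parameters
    ----------
    dosages
        Float array, shape ``(n_samples, n_variants)``; values in ``[0, 2]``
        or NaN for missing calls.  Dosages count copies of the declared risk
        allele.
    samples
        Sample identifiers, one per row.
    variants
        Per-variant metadata with the columns in :data:`VARIANT_COLUMNS`.
        ``typed`` is a boolean (hard genotype calls vs imputed dosages) and
        ``rsq`` the imputation quality (observed/expected variance ratio);
        typed variants carry ``rsq`` = 1.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = list(self.samples)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise DataError("sample list does not match dosage rows")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise DataError(f"variant table missing columns: {missing}")
        if self.dosages.shape[1] != len(self.variants):
            raise DataError("variant table does not match dosage columns")
        if self.variants["variant_id"].duplicated().any():
            raise DataError("duplicate variant ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise DataError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant: {variant_id}")
        return int(idx[0])

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample: {sample_id}") from None

    def dosage_of(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant (copy)."""
        return self.dosages[:, self.variant_index(variant_id)].copy()

    # -- summaries ------------------------------------------------------
    def call_rate(self, axis: str = "variant") -> np.ndarray:
        """Fraction of non-missing calls per variant or per sample."""
        ok = ~np.isnan(self.dosages)
        if axis == "variant":
            return ok.mean(axis=0)
        if axis == "sample":
            return ok.mean(axis=1)
        raise ValueError("axis must be 'variant' or 'sample'")

    def allele_freq(self) -> np.ndarray:
        """Risk-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)

    def mean_filled(self) -> np.ndarray:
        """Dosage matrix with missing calls replaced by the variant mean."""
        filled = self.dosages.copy()
        means = np.nanmean(np.where(np.isnan(filled), np.nan, filled), axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(filled))
        filled[idx] = means[idx[1]]
        return filled

    # -- subsetting -----------------------------------------------------
    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "DosageMatrix":
        d = self.dosages
        samples = self.samples
        variants = self.variants
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx, dtype=int)
            d = d[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx, dtype=int)
            d = d[:, variant_idx]
            variants = variants.iloc[variant_idx]
        return DosageMatrix(d.copy(), samples, variants.reset_index(drop=True))

    def drop_variants(self, variant_ids: Iterable[str]) -> "DosageMatrix":
        drop = set(variant_ids)
        keep = [i for i, v in enumerate(self.variant_ids) if v not in drop]
        return self.subset(variant_idx=keep)

    def drop_samples(self, sample_ids: Iterable[str]) -> "DosageMatrix":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.samples) if s not in drop]
        return self.subset(sample_idx=keep)


@dataclass
class LocalAncestryTrack:
    """Expected count of population-1 chromosomes per sample per variant.

    Values are continuous in [0, 2]; population 1 is the reference ("European
    -like") ancestry, so 0 means both chromosomes derive from population 2.
    """

    values: np.ndarray  # (n_samples, n_variants)
    samples: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.variant_ids)):
            raise DataError("local ancestry shape mismatch")
        if ((self.values < 0) | (self.values > 2)).any():
            raise DataError("local ancestry outside [0, 2]")

    def subset_samples(self, idx: Sequence[int]) -> "LocalAncestryTrack":
        idx = np.asarray(idx)
        return LocalAncestryTrack(
            self.values[idx, :].copy(),
            [self.samples[i] for i in idx],
            list(self.variant_ids),
        )


@dataclass(frozen=True)
class RiskRegion:
    """A fine-mapping window anchored on one or more index signals."""

    name: str
    chrom: str
    start: int  # 1-based, closed
    end: int
    index_variants: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise DataError(f"invalid region bounds for {self.name}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def variant_mask(self, variants: pd.DataFrame) -> np.ndarray:
        return (
            (variants["chrom"].astype(str) == self.chrom)
            & (variants["pos"] >= self.start)
            & (variants["pos"] <= self.end)
        ).to_numpy()


__all__ = [
    "DataError",
    "DosageMatrix",
    "LocalAncestryTrack",
    "RiskRegion",
    "SAMPLE_COLUMNS",
    "VARIANT_COLUMNS",
    "validate_sample_table",
    "replace",
]
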