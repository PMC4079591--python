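"""Core in-memory containers shared by all analysis stages.

The three primary matrices mirror the shapes of the study data:

* :class:`AlleleCountMatrix` — per (SNP, individual) reference/alternate
  read counts from RNA-seq alignments.
* :class:`GenotypeMatrix` — alternate-allele dosages in {0, 1, 2} with
  ``NaN`` for entries where the read-count scoring rule does not fire.
* :class:`ExpressionMatrix` — per (gene, individual) integer read counts
  with library sizes and TMM normalization factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class AlleleCountMatrix:
    """Reference / alternate read counts per SNP and individual.

    Parameters
    ----------
    snps : pandas.DataFrame
        Indexed by SNP id, with columns ``scaffold`` (str), ``pos``
        (1-based int), ``ref`` and ``alt`` (single-base strings).
    populations : pandas.Series
        Population label per individual; the index is the individual id.
    ref_count, alt_count : numpy.ndarray
        Integer arrays of shape ``(n_snps, n_individuals)``.
    """

    snps: pd.DataFrame
    populations: pd.Series
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count)
        self.alt_count = np.asarray(self.alt_count)
        s, n = self.ref_count.shape
        if self.alt_count.shape != (s, n):
            raise ValueError("ref_count and alt_count shapes differ")
        if len(self.snps) != s:
            raise ValueError("snp table does not match count rows")
        if len(self.populations) != n:
            raise ValueError("population labels do not match count columns")
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    @property
    def individuals(self) -> pd.Index:
        return self.populations.index

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.populations)

    def depth(self) -> np.ndarray:
        """Total read depth per (SNP, individual)."""
        return self.ref_count + self.alt_count

    def subset_snps(self, mask_or_ids) -> "AlleleCountMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = self.snps.index.get_indexer(mask_or_ids)
        return AlleleCountMatrix(
            snps=self.snps.iloc[idx],
            populations=self.populations,
            ref_count=self.ref_count[idx],
            alt_count=self.alt_count[idx],
        )


@dataclass
class GenotypeMatrix:
    """Alternate-allele dosage calls; ``NaN`` marks missing calls."""

    snp_ids: pd.Index
    populations: pd.Series
    dosage: np.ndarray  # float array (n_snps, n_individuals), NaN = missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.snp_ids), len(self.populations)):
            raise ValueError("dosage shape does not match ids")
        valid = self.dosage[~np.isnan(self.dosage)]
        if valid.size and not np.isin(valid, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def individuals(self) -> pd.Index:
        return self.populations.index

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.populations)

    def called(self) -> np.ndarray:
        return ~np.isnan(self.dosage)


@dataclass
class ExpressionMatrix:
    """Gene-by-individual integer read counts with normalization state.

    ``tmm`` is filled in by :func:`metaland.expression.tmm_factors`; until
    then factors of 1 are assumed by the log-CPM accessor.
    """

    counts: pd.DataFrame  # genes x individuals, integer
    tmm: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("expression counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def individuals(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def effective_lib_size(self) -> pd.Series:
        f = self.tmm if self.tmm is not None else pd.Series(1.0, index=self.individuals)
        return self.lib_size * f.reindex(self.individuals)

    def cpm(self) -> pd.DataFrame:
        eff = self.effective_lib_size()
        return self.counts / eff.to_numpy()[None, :] * 1e6

    def log_cpm(self, prior: float = 0.5) -> pd.DataFrame:
        """log2(CPM + prior) on TMM-adjusted library sizes."""
        return np.log2(self.cpm() + prior)


@dataclass
class StudyMetadata:
    """Per-individual annotations used by the downstream contrasts."""

    table: pd.DataFrame  # index individual; population, landscape, sex, age_class, flight

    REQUIRED = ("population", "landscape", "sex", "age_class", "flight")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")

    @property
    def individuals(self) -> pd.Index:
        return self.table.index

    @property
    def populations(self) -> pd.Series:
        return self.table["population"]

    @property
    def landscape(self) -> pd.Series:
        return self.table["landscape"]

    def landscape_of_populations(self) -> dict:
        return (
            self.table.groupby("population")["landscape"].first().to_dict()
        )
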