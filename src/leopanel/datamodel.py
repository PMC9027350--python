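"""Core in-memory containers for the panel-design pipeline.

The central object is :class:`VariantDataset`: a sites x samples matrix of
diploid genotype calls plus a parallel matrix of per-cell read depths.
Genotypes are encoded as small integers:

========  ====================================
code      meaning
========  ====================================
``0``     homozygous reference
``1``     heterozygous
``2``     homozygous alternate
``-1``    missing / ambiguous (not scored)
========  ====================================

A cell that was masked for low coverage and a cell that was missing in the
input share the ``-1`` state; provenance of masking is kept in the optional
boolean ``masked`` channel so the two can still be told apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2

GENOTYPE_CODES = (MISSING, HOM_REF, HET, HOM_ALT)

NUCLEOTIDES = ("A", "C", "G", "T")

#: The four clusters recovered from the autosomal panel data: two clades of
#: the northern subspecies (P. leo leo) and two of the southern
#: (P. leo melanochaita).
CLADES = ("West & Central Africa", "India", "East Africa", "Southern Africa")

NORTHERN_CLADES = frozenset({"West & Central Africa", "India"})
SOUTHERN_CLADES = frozenset({"East Africa", "Southern Africa"})

#: clade -> subspecies label
SUBSPECIES_OF = {
    "West & Central Africa": "northern",
    "India": "northern",
    "East Africa": "southern",
    "Southern Africa": "southern",
}

#: The six mitochondrial haplogroups distinguished by the mtDNA panel SNPs.
HAPLOGROUPS = (
    "West Africa",
    "Central Africa",
    "North East Africa",
    "East/Southern Africa",
    "South West Africa",
    "India",
)

#: Haplogroups of the northern subspecies lineage; the remaining two are
#: southern.  Two of the 14 mtDNA panel SNPs are diagnostic for this split.
NORTHERN_HAPLOGROUPS = frozenset(
    {"West Africa", "Central Africa", "North East Africa", "India"}
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP: scaffold, 1-based position and its two alleles."""

    scaffold: str
    position: int
    ref: str
    alt: str
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"alleles must be single nucleotides: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.scaffold}:{self.position}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.scaffold, self.position)

    @property
    def snp_id(self) -> str:
        return f"{self.scaffold}_{self.position}"

    def with_chromosome(self, chromosome: str) -> "SiteRecord":
        return SiteRecord(self.scaffold, self.position, self.ref, self.alt, chromosome)


@dataclass
class VariantDataset:
    """Genotype calls and read depths for a set of biallelic SNPs.

    Parameters
    ----------
    sites :
        One :class:`SiteRecord` per row of the matrices.
    samples :
        Sample identifiers, one per column.
    genotypes :
        ``(n_sites, n_samples)`` int matrix with codes in
        ``{-1, 0, 1, 2}``.
    depths :
        ``(n_sites, n_samples)`` non-negative int matrix of read depths.
    masked :
        Optional boolean matrix flagging cells set to missing by the
        low-coverage mask (as opposed to missing in the input).
    """

    sites: list[SiteRecord]
    samples: list[str]
    genotypes: np.ndarray
    depths: np.ndarray
    masked: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.genotypes.shape != (n_sites, n_samples):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} != ({n_sites}, {n_samples})"
            )
        if self.depths.shape != self.genotypes.shape:
            raise ValueError("depth matrix shape differs from genotype matrix")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        bad = ~np.isin(self.genotypes, GENOTYPE_CODES)
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.genotypes[bad])}")
        if len(set(self.samples)) != n_samples:
            raise ValueError("sample ids must be unique")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != n_sites:
            raise ValueError("site (scaffold, position) keys must be unique")
        if self.masked is not None:
            self.masked = np.asarray(self.masked, dtype=bool)
            if self.masked.shape != self.genotypes.shape:
                raise ValueError("masked matrix shape differs from genotype matrix")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def subset_sites(self, index: np.ndarray) -> "VariantDataset":
        """Row-subset by boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return VariantDataset(
            sites=[self.sites[i] for i in index],
            samples=list(self.samples),
            genotypes=self.genotypes[index].copy(),
            depths=self.depths[index].copy(),
            masked=None if self.masked is None else self.masked[index].copy(),
        )

    def copy(self) -> "VariantDataset":
        return VariantDataset(
            sites=list(self.sites),
            samples=list(self.samples),
            genotypes=self.genotypes.copy(),
            depths=self.depths.copy(),
            masked=None if self.masked is None else self.masked.copy(),
        )

    def site_ids(self) -> list[str]:
        return [s.snp_id for s in self.sites]


@dataclass
class PanelCalls:
    """Biallelic calls of many samples at the panel SNPs.

    ``calls`` is a samples x SNPs integer frame.  Autosomal SNPs use diploid
    dosage codes ``{0, 1, 2}``; mitochondrial SNPs are haploid ``{0, 1}``
    (reference vs alternate state).  Missing is ``-1`` in memory and a
    configurable token (default ``"NA"``) on disk.
    """

    calls: pd.DataFrame
    is_mtdna: pd.Series  # indexed by SNP id, bool

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(np.int8)
        self.is_mtdna = self.is_mtdna.astype(bool)
        if set(self.calls.columns) != set(self.is_mtdna.index):
            raise ValueError("every SNP id must be flagged exactly once as autosomal or mtDNA")
        self.is_mtdna = self.is_mtdna.reindex(self.calls.columns)
        auto = self.calls.loc[:, ~self.is_mtdna.values]
        mito = self.calls.loc[:, self.is_mtdna.values]
        if not auto.isin([MISSING, 0, 1, 2]).all().all():
            raise ValueError("autosomal calls must be in {-1, 0, 1, 2}")
        if not mito.isin([MISSING, 0, 1]).all().all():
            raise ValueError("mtDNA calls must be in {-1, 0, 1}")
        if self.calls.index.duplicated().any():
            raise ValueError("sample ids must be unique")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def autosomal_ids(self) -> list[str]:
        return list(self.calls.columns[~self.is_mtdna.values])

    @property
    def mtdna_ids(self) -> list[str]:
        return list(self.calls.columns[self.is_mtdna.values])

    def autosomal(self) -> pd.DataFrame:
        return self.calls[self.autosomal_ids]

    def mtdna(self) -> pd.DataFrame:
        return self.calls[self.mtdna_ids]


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet frame (columns sample, population, region[, lat, lon])."""
    required = {"sample", "population", "region"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        dupes = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"duplicate sample ids in sample sheet: {dupes}")
    bad = set(sheet["region"]) - set(CLADES)
    if bad:
        raise FormatError(
            f"unknown region labels {sorted(bad)}; expected one of {CLADES}"
        )
    return sheet
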