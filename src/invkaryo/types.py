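"""Core data containers shared across the toolkit.

The central object is the :class:`GenotypeMatrix`: a samples x sites matrix of
alternate-allele counts (0, 1, 2) with a reserved sentinel for missing
genotypes and an optional parallel layer of per-genotype quality (GQ) scores.
Sites are biallelic SNPs by construction; multiallelic records and indels are
never represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype or missing GQ value. Distinct from every
#: valid alternate-allele count (0/1/2) and from every valid GQ (>= 0).
MISSING: int = -1

#: Recognised taxon labels for sample metadata.
TAXA = ("gambiae", "coluzzii", "bamako", "hybrid", "unknown")

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


class InvKaryoError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(InvKaryoError):
    """Invalid configuration (spans, thresholds, unknown names...)."""


class DataError(InvKaryoError):
    """Input data violates a precondition (unreadable, degenerate...)."""


class VariantSite(NamedTuple):
    """A biallelic SNP: chromosome arm, 1-based position, REF and ALT alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str


def sites_frame(sites: list[VariantSite] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a site list into the canonical (chrom, pos, ref, alt) frame."""
    if isinstance(sites, pd.DataFrame):
        df = sites.loc[:, list(SITE_COLUMNS)].reset_index(drop=True)
    else:
        df = pd.DataFrame(sites, columns=list(SITE_COLUMNS))
    df["pos"] = df["pos"].astype(np.int64)
    return df


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites alternate-allele count matrix.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows).
    sites
        Site table with columns ``chrom, pos, ref, alt``, sorted by
        (chrom, pos) and unique.
    alt_counts
        ``(n_samples, n_sites)`` integer array; each cell is 0, 1, 2 or
        :data:`MISSING`.
    gq
        Optional ``(n_samples, n_sites)`` integer array of genotype qualities;
        :data:`MISSING` marks an absent GQ. GQ missingness is independent of
        genotype missingness.
    """

    samples: list[str]
    sites: pd.DataFrame
    alt_counts: np.ndarray
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = sites_frame(self.sites)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int16)
        if self.alt_counts.shape != (len(self.samples), len(self.sites)):
            raise DataError(
                f"alt_counts shape {self.alt_counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.alt_counts, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("alt_counts contains values outside {0,1,2,MISSING}")
        if self.gq is not None:
            self.gq = np.asarray(self.gq, dtype=np.int32)
            if self.gq.shape != self.alt_counts.shape:
                raise DataError("gq layer shape does not match alt_counts")
        if len(set(self.samples)) != len(self.samples):
            raise DataError("duplicate sample ids")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.sites["chrom"].to_numpy()

    def site_tuples(self) -> list[VariantSite]:
        return [VariantSite(*row) for row in self.sites.itertuples(index=False)]

    # -- subsetting ------------------------------------------------------
    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset to a site index / boolean mask, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index],
            alt_counts=self.alt_counts[:, index],
            gq=None if self.gq is None else self.gq[:, index],
        )

    def take_samples(self, ids_or_index) -> "GenotypeMatrix":
        """Subset to a sample id list or positional index, preserving order given."""
        if len(ids_or_index) and isinstance(next(iter(ids_or_index)), str):
            lookup = {s: i for i, s in enumerate(self.samples)}
            missing = [s for s in ids_or_index if s not in lookup]
            if missing:
                raise DataError(f"samples not in matrix: {missing}")
            index = np.array([lookup[s] for s in ids_or_index], dtype=int)
        else:
            index = np.asarray(ids_or_index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            sites=self.sites,
            alt_counts=self.alt_counts[index],
            gq=None if self.gq is None else self.gq[index],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.copy(),
            alt_counts=self.alt_counts.copy(),
            gq=None if self.gq is None else self.gq.copy(),
        )


@dataclass
class SampleRecord:
    """Per-specimen metadata: taxon, origin, cytogenetic karyotypes, QC fields."""

    sample_id: str
    taxon: str = "unknown"
    population: str = ""
    country: str = ""
    cyt_karyotypes: dict[str, int] = field(default_factory=dict)
    wga: bool = False
    missing_2R: int | None = None

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ConfigError(f"unknown taxon {self.taxon!r}; expected one of {TAXA}")
        for inv, dose in self.cyt_karyotypes.items():
            if dose not in (0, 1, 2):
                raise ConfigError(f"cytogenetic dose for {inv} must be 0/1/2, got {dose}")


@dataclass
class InversionDef:
    """A named rearrangement and its per-inversion analysis thresholds.

    Coordinates are 1-based inclusive. ``exclusion_spans`` lists sub-intervals
    whose SNPs are omitted from karyotyping PCA — used when another inversion
    is nested inside the focal span (e.g. exclude the nested span and keep
    only SNPs proximal to it).
    """

    name: str
    chrom: str
    span: tuple[int, int]
    breakpoints: tuple[int, int] | None = None
    exclusion_spans: list[tuple[int, int]] = field(default_factory=list)
    maf_min_pca: float = 0.15
    mac_min_pca: int = 3
    maf_min_tags: float = 0.05
    concordance_threshold: float = 0.80
    taxon_scope: str = "both"
    flank: int = 5000

    def __post_init__(self) -> None:
        start, end = self.span
        if not start < end:
            raise ConfigError(f"{self.name}: span start must be < end")
        if self.breakpoints is None:
            self.breakpoints = (start, end)
        for b in self.breakpoints:
            if not (start <= b <= end):
                raise ConfigError(f"{self.name}: breakpoint {b} outside span")
        for s, e in self.exclusion_spans:
            if not (start <= s < e <= end):
                raise ConfigError(f"{self.name}: exclusion span [{s},{e}] not inside span")
        for nm, v in (("maf_min_pca", self.maf_min_pca),
                      ("maf_min_tags", self.maf_min_tags),
                      ("concordance_threshold", self.concordance_threshold)):
            if not 0 <= v < 1:
                raise ConfigError(f"{self.name}: {nm} must be in [0,1)")
        if self.taxon_scope not in ("both", "gambiae_only", "coluzzii_only"):
            raise ConfigError(f"{self.name}: bad taxon_scope {self.taxon_scope!r}")
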