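"""Core domain containers.

Coordinates are 0-based half-open throughout the package; file I/O in
:mod:`pantemap.io` converts from/to the 1-based conventions of GFF3 and
VCF-like tables.  Genotypes are diploid dosages of the TE-bearing (or
ALT) allele: 0, 1, 2, with ``NaN`` for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "GenomicInterval",
    "TEAnnotation",
    "SVRecord",
    "PanTELocus",
    "GenotypeMatrix",
    "EffectCall",
    "LTRElement",
    "Clump",
    "SimTruth",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise DataError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if different contigs)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bases between two intervals; 0 when they overlap or abut.

        Returns -1 for intervals on different contigs (no finite distance).
        """
        if self.contig != other.contig:
            return -1
        if self.overlap(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def shift(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable element annotated on one assembly."""

    te_id: str
    genome_id: str
    interval: GenomicInterval
    te_class: str = "I"  # "I" retrotransposons, "II" DNA transposons
    superfamily: str = "unknown"
    family: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.interval) <= 0:
            raise DataError(f"TE {self.te_id} has non-positive length")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class SVRecord:
    """A structural-variant bubble with per-genome alternative placements.

    ``genotypes`` holds the diploid dosage of the ALT allele per accession.
    ``alt_placements`` maps a genome id to the interval that the alternative
    allele occupies in that genome's coordinates; the reference anchor lives
    in ``ref_genome`` coordinates.
    """

    sv_id: str
    anchor: GenomicInterval
    ref_len: int
    alt_len: int
    sv_type: str = ""
    ref_genome: str = "ref"
    alt_placements: dict[str, GenomicInterval] = field(default_factory=dict)
    genotypes: pd.Series | None = None

    def __post_init__(self) -> None:
        from .pante import classify_sv_type  # late import: avoids cycle

        if not self.sv_type:
            self.sv_type = classify_sv_type(self.ref_len, self.alt_len)


@dataclass
class PanTELocus:
    """A TE anchored on the reference with merged population genotypes."""

    te_id: str
    anchor: GenomicInterval
    linked_svs: list[tuple[str, str]]  # (sv_id, carrier allele "REF"/"ALT")
    genotypes: pd.Series  # dosage of the TE-bearing allele, NaN = missing

    @property
    def maf(self) -> float:
        obs = self.genotypes.dropna()
        if obs.empty:
            return float("nan")
        p = float(obs.sum()) / (2 * len(obs))
        return min(p, 1.0 - p)

    @property
    def conservation(self) -> str:
        obs = self.genotypes.dropna()
        if obs.empty:
            return "all_missing"
        p = float(obs.sum()) / (2 * len(obs))
        return "fixed" if p in (0.0, 1.0) else "polymorphic"


class GenotypeMatrix:
    """Variants x accessions dosage table; the substrate of all
    population statistics.

    Thin wrapper over a float DataFrame (rows = variants, columns =
    accessions, values in {0, 1, 2, NaN}).
    """

    def __init__(self, dosages: pd.DataFrame):
        if dosages.empty:
            raise DataError("empty genotype matrix")
        self.dosages = dosages.astype(float)

    @property
    def variants(self) -> pd.Index:
        return self.dosages.index

    @property
    def accessions(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_variants(self) -> int:
        return len(self.dosages.index)

    @property
    def n_accessions(self) -> int:
        return len(self.dosages.columns)

    def missing_rate(self) -> pd.Series:
        """Fraction of missing calls per variant."""
        return self.dosages.isna().mean(axis=1)

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant over non-missing calls."""
        obs = self.dosages.notna().sum(axis=1)
        p = self.dosages.sum(axis=1, skipna=True) / (2 * obs)
        return np.minimum(p, 1.0 - p)

    def het_rate(self) -> pd.Series:
        """Heterozygote fraction per variant over non-missing calls."""
        obs = self.dosages.notna().sum(axis=1)
        return (self.dosages == 1).sum(axis=1) / obs

    def subset(self, variants: Sequence[str] | None = None,
               accessions: Sequence[str] | None = None) -> "GenotypeMatrix":
        d = self.dosages
        if variants is not None:
            d = d.loc[list(variants)]
        if accessions is not None:
            d = d[list(accessions)]
        return GenotypeMatrix(d)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GenotypeMatrix({self.n_variants} variants x "
                f"{self.n_accessions} accessions)")


@dataclass(frozen=True)
class EffectCall:
    """Classification of one TE's effect on its nearest gene."""

    te_id: str
    gene_id: str
    stage: str
    mean_with: float
    mean_without: float
    ratio: float
    effect: str  # promotive | suppressive | none | unevaluable
    n_with: int
    n_without: int


@dataclass
class LTRElement:
    """An intact LTR retrotransposon dated from terminal-repeat divergence.

    Either the two aligned terminal-repeat sequences or a precomputed
    divergence ``K`` (substitutions/site) may be supplied; ``age`` in years
    follows as K / (2 r) for a configured substitution rate r.
    """

    element_id: str
    superfamily: str = "unknown"  # Copia | Gypsy | unknown
    subgenome: str = ""
    ltr5: str | None = None
    ltr3: str | None = None
    divergence: float | None = None
    age: float | None = None


@dataclass
class Clump:
    """A greedy LD clump around an index variant."""

    index_variant: str
    index_p: float
    members: list[str]  # includes the index variant
    span: GenomicInterval | None = None
    min_p: float = float("nan")
    max_p: float = float("nan")


@dataclass
class SimTruth:
    """Ground-truth sidecar emitted by the synthetic-data generators."""

    expression_effects: dict[str, float] = field(default_factory=dict)
    te_target_gene: dict[str, str] = field(default_factory=dict)
    phenotype_effects: dict[str, float] = field(default_factory=dict)
    true_maf: dict[str, float] = field(default_factory=dict)
    fixed_ids: set[str] = field(default_factory=set)
    ltr_ages: dict[str, float] = field(default_factory=dict)
    te_sv_links: set[tuple[str, str]] = field(default_factory=set)
    heritability: float | None = None

    def merge(self, other: "SimTruth") -> "SimTruth":
        """Combine truth channels from successive generator calls."""
        return SimTruth(
            expression_effects={**self.expression_effects,
                                **other.expression_effects},
            te_target_gene={**self.te_target_gene, **other.te_target_gene},
            phenotype_effects={**self.phenotype_effects,
                               **other.phenotype_effects},
            true_maf={**self.true_maf, **other.true_maf},
            fixed_ids=self.fixed_ids | other.fixed_ids,
            ltr_ages={**self.ltr_ages, **other.ltr_ages},
            te_sv_links=self.te_sv_links | other.te_sv_links,
            heritability=(other.heritability if other.heritability is not None
                          else self.heritability),
        )
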