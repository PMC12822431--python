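"""Pan-TE map construction.

Structural variants discovered as pangenome bubbles are typed by REF/ALT
allele lengths, TE annotations are linked to the SV allele whose sequence
hosts them (an SV segment must cover strictly more than half of the TE),
and per-TE population genotypes are obtained by merging the genotypes of
all linked SVs.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError, ParameterError
from .types import GenomicInterval, GenotypeMatrix, PanTELocus, SVRecord, \
    TEAnnotation

__all__ = [
    "classify_sv_type",
    "associate_te_to_sv",
    "merge_genotypes",
    "build_pante_map",
    "filter_variants",
    "conservation_summary",
]

SV_MIN_LEN = 50  # bp; alleles shorter than this on both sides are "small"


def classify_sv_type(ref_len: int, alt_len: int) -> str:
    """Type an allele by REF/ALT lengths.

    DEL: REF >= 50 bp and ALT = 1 bp; INS: REF = 1 bp and ALT >= 50 bp;
    MNP (complex): any remaining allele with length >= 50 bp on either
    side; ``small``: both sides < 50 bp (excluded from SV genotyping).
    """
    if ref_len < 1 or alt_len < 1:
        raise DataError(f"non-positive allele length ({ref_len}, {alt_len})")
    if ref_len >= SV_MIN_LEN and alt_len == 1:
        return "DEL"
    if ref_len == 1 and alt_len >= SV_MIN_LEN:
        return "INS"
    if max(ref_len, alt_len) >= SV_MIN_LEN:
        return "MNP"
    return "small"


def _sv_segments(svs: Sequence[SVRecord]):
    """Yield (genome_id, interval, sv_id, carrier_allele) for every allele
    placement.

    The reference anchor is the REF-allele segment in the reference
    genome's coordinates; each alternative placement is the ALT-allele
    segment in that genome's coordinates.
    """
    for sv in svs:
        yield sv.ref_genome, sv.anchor, sv.sv_id, "REF"
        for genome, iv in sv.alt_placements.items():
            yield genome, iv, sv.sv_id, "ALT"


def associate_te_to_sv(
    tes: Sequence[TEAnnotation],
    svs: Sequence[SVRecord],
) -> list[tuple[str, str, str]]:
    """Link TEs to the SV alleles that host them.

    A TE annotated on genome *g* is linked to an SV when an allele segment
    of that SV, in genome *g* coordinates, covers strictly more than half
    of the TE's length.  The carrier allele is ALT for TEs sitting on an
    alternative placement (insertion-borne) and REF for TEs on the
    reference anchor (deletion-borne).

    Returns sorted ``(te_id, sv_id, carrier_allele)`` triples.
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for genome, iv, sv_id, allele in _sv_segments(svs):
        trees[(genome, iv.contig)].addi(iv.start, iv.end, (sv_id, allele))

    links: list[tuple[str, str, str]] = []
    for te in tes:
        if te.length <= 0:
            raise DataError(f"TE {te.te_id} has zero length")
        tree = trees.get((te.genome_id, te.interval.contig))
        if tree is None:
            continue
        for hit in tree.overlap(te.interval.start, te.interval.end):
            ov = min(hit.end, te.interval.end) - max(hit.begin,
                                                     te.interval.start)
            if 2 * ov > te.length:  # strictly more than half of the TE
                sv_id, allele = hit.data
                links.append((te.te_id, sv_id, allele))
    return sorted(set(links))


def merge_genotypes(
    links: Sequence[tuple[str, str]],
    sv_genotypes: Mapping[str, pd.Series],
    rule: str = "min",
) -> pd.Series:
    """Merge the genotypes of all SVs linked to one TE.

    ``links`` are ``(sv_id, carrier_allele)`` pairs for a single TE.  Per
    accession the TE dosage combines the carrier-allele dosages of the
    linked SVs (ALT dosage as stored; REF dosage is ``2 - ALT``).  Under
    the default ``"min"`` rule the merged dosage is the minimum: a TE
    spanning several hosting segments is present only where all of them
    are.  The ``"any"`` rule takes the maximum instead (present wherever
    any hosting segment is).  Any missing linked genotype makes the
    merged call missing.
    """
    if not links:
        raise ParameterError("merge_genotypes requires at least one link")
    if rule not in ("min", "any"):
        raise ParameterError("rule must be 'min' or 'any'")
    carrier_vectors = []
    index = None
    for sv_id, allele in sorted(set(links)):
        g = sv_genotypes[sv_id].astype(float)
        if index is None:
            index = g.index
        elif not g.index.equals(index):
            raise DataError("linked SV genotype vectors have mismatched "
                            "accession indexes")
        carrier_vectors.append(g if allele == "ALT" else 2.0 - g)
    stacked = pd.concat(carrier_vectors, axis=1)
    if rule == "min":
        merged = stacked.min(axis=1, skipna=False)  # NaN-dominant
    else:
        merged = stacked.max(axis=1, skipna=False)
    return merged


def build_pante_map(
    tes: Sequence[TEAnnotation],
    svs: Sequence[SVRecord],
) -> list[PanTELocus]:
    """Associate TEs with SVs and merge genotypes into pan-TE loci.

    TEs linked to no SV are omitted (they carry no population genotype).
    The locus anchor is the reference anchor of the first linked SV.
    """
    links = associate_te_to_sv(tes, svs)
    sv_by_id = {sv.sv_id: sv for sv in svs}
    per_te: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for te_id, sv_id, allele in links:
        per_te[te_id].append((sv_id, allele))

    geno = {sv.sv_id: sv.genotypes for sv in svs if sv.genotypes is not None}
    loci = []
    for te in tes:
        if te.te_id not in per_te:
            continue
        te_links = per_te[te.te_id]
        missing = [s for s, _ in te_links if s not in geno]
        if missing:
            raise DataError(f"linked SVs without genotypes: {missing}")
        merged = merge_genotypes(te_links, geno)
        anchor = sv_by_id[te_links[0][0]].anchor
        loci.append(PanTELocus(te_id=te.te_id, anchor=anchor,
                               linked_svs=sorted(te_links),
                               genotypes=merged))
    return loci


def filter_variants(
    gm: GenotypeMatrix,
    max_missing: float | None = 0.5,
    min_maf: float | None = None,
    max_het: float | None = None,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Filter variants by missingness, MAF and heterozygosity.

    Keeps variants with missing fraction <= ``max_missing``, MAF strictly
    greater than ``min_maf`` (when set), and heterozygote fraction
    strictly below ``max_het`` (when set).  Criteria are applied jointly;
    the report counts, per criterion, how many variants fail it.
    """
    for name, v in (("max_missing", max_missing), ("min_maf", min_maf),
                    ("max_het", max_het)):
        if v is not None and not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {v}")

    keep = pd.Series(True, index=gm.variants)
    report: dict[str, int] = {}
    if max_missing is not None:
        fail = gm.missing_rate() > max_missing
        report["missing"] = int(fail.sum())
        keep &= ~fail
    if min_maf is not None:
        fail = ~(gm.maf() > min_maf)  # NaN MAF (all-missing) also fails
        report["maf"] = int(fail.sum())
        keep &= ~fail
    if max_het is not None:
        fail = ~(gm.het_rate() < max_het)
        report["het"] = int(fail.sum())
        keep &= ~fail
    report["kept"] = int(keep.sum())
    if report["kept"] == 0:
        raise DataError("no variants pass the filters")
    return GenotypeMatrix(gm.dosages.loc[keep]), report


def conservation_summary(
    loci: Sequence[PanTELocus] | GenotypeMatrix,
    bin_edges: Sequence[float] | None = None,
) -> dict:
    """Summarize fixation vs polymorphism over pan-TE loci.

    A locus is fixed when a single allele is observed among its
    non-missing calls; otherwise polymorphic.  Loci with no non-missing
    call are counted separately and excluded from the fractions.  The MAF
    histogram covers polymorphic loci.
    """
    if isinstance(loci, GenotypeMatrix):
        items = [(vid, row) for vid, row in loci.dosages.iterrows()]
    else:
        items = [(l.te_id, l.genotypes) for l in loci]
    if not items:
        raise DataError("no loci to summarize")

    if bin_edges is None:
        bin_edges = np.linspace(0.0, 0.5, 11)
    fixed = polymorphic = all_missing = 0
    mafs = []
    for _, g in items:
        obs = g.dropna()
        if obs.empty:
            all_missing += 1
            continue
        p = float(obs.sum()) / (2 * len(obs))
        if p in (0.0, 1.0):  # a single allele observed
            fixed += 1
        else:
            polymorphic += 1
            mafs.append(min(p, 1 - p))
    informative = fixed + polymorphic
    hist, _ = np.histogram(mafs, bins=np.asarray(bin_edges))
    return {
        "n_loci": len(items),
        "n_all_missing": all_missing,
        "fixed_fraction": fixed / informative if informative else float("nan"),
        "polymorphic_fraction": (polymorphic / informative
                                 if informative else float("nan")),
        "maf_hist": hist.tolist(),
        "maf_bin_edges": list(map(float, bin_edges)),
    }
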