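"""Readers and writers for the package's tab-separated dialects.

Interval annotations travel as BED (0-based half-open) or minimal GFF3
(1-based inclusive; converted on read/write).  SVs use a documented
VCF-like tab table with per-genome alternative placements; genotype,
expression and phenotype matrices are plain TSV with ids in the first
column.  A truth sidecar serializes the synthetic generators' ground
truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .types import GenomicInterval, GenotypeMatrix, SimTruth, SVRecord, \
    TEAnnotation

__all__ = [
    "read_bed", "write_bed",
    "read_gff3", "write_gff3",
    "read_te_bed", "write_te_bed",
    "read_sv_table", "write_sv_table",
    "read_matrix", "write_matrix",
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes",
    "read_truth", "write_truth",
]

MISSING = "NA"


# ---------------------------------------------------------------- intervals
def read_bed(path) -> dict[str, GenomicInterval]:
    """Read name -> interval from a BED file (cols: contig, start, end,
    name[, score, strand])."""
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise DataError(f"{path}:{i + 1}: fewer than 3 BED columns")
            name = f[3] if len(f) > 3 else f"feature{i}"
            strand = f[5] if len(f) > 5 else "."
            out[name] = GenomicInterval(f[0], int(f[1]), int(f[2]),
                                        strand if strand in "+-" else ".")
    return out


def write_bed(intervals: Mapping[str, GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for name, iv in intervals.items():
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t"
                     f"{iv.strand if iv.strand != '.' else '.'}\n")


def read_gff3(path, feature_types: set[str] | None = None
              ) -> dict[str, GenomicInterval]:
    """Read ID -> interval from a GFF3 file (1-based inclusive -> 0-based
    half-open)."""
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise DataError(f"{path}:{i + 1}: expected 9 GFF3 columns")
            if feature_types and f[2] not in feature_types:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("ID", f"{f[2]}_{i}")
            out[name] = GenomicInterval(
                f[0], int(f[3]) - 1, int(f[4]),
                f[6] if f[6] in "+-" else ".")
    return out


def write_gff3(intervals: Mapping[str, GenomicInterval], path,
               feature_type: str = "gene", source: str = "pantemap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, iv in intervals.items():
            fh.write(f"{iv.contig}\t{source}\t{feature_type}\t"
                     f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                     f"ID={name}\n")


# --------------------------------------------------------------------- TEs
def write_te_bed(tes: Sequence[TEAnnotation], path) -> None:
    """BED6+3 with genome_id, class and superfamily in extra columns."""
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{te.te_id}\t0\t"
                     f"{iv.strand}\t{te.genome_id}\t{te.te_class}\t"
                     f"{te.superfamily}\n")


def read_te_bed(path) -> list[TEAnnotation]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise DataError(f"{path}:{i + 1}: TE BED needs >= 7 columns")
            out.append(TEAnnotation(
                te_id=f[3], genome_id=f[6],
                interval=GenomicInterval(f[0], int(f[1]), int(f[2]),
                                         f[5] if f[5] in "+-" else "."),
                te_class=f[7] if len(f) > 7 else "I",
                superfamily=f[8] if len(f) > 8 else "unknown"))
    return out


# --------------------------------------------------------------------- SVs
def write_sv_table(svs: Sequence[SVRecord], path) -> None:
    """VCF-like tab table: one row per SV.

    Columns: sv_id, contig, start (0-based), end, ref_len, alt_len,
    sv_type, ref_genome, placements (``genome:contig:start-end`` joined
    by ';'), then one dosage column per accession (NA = missing).
    """
    accessions: list[str] = []
    for sv in svs:
        if sv.genotypes is not None:
            accessions = list(sv.genotypes.index)
            break
    with open(path, "w") as fh:
        head = ["sv_id", "contig", "start", "end", "ref_len", "alt_len",
                "sv_type", "ref_genome", "placements"] + accessions
        fh.write("\t".join(head) + "\n")
        for sv in svs:
            plc = ";".join(f"{g}:{iv.contig}:{iv.start}-{iv.end}"
                           for g, iv in sorted(sv.alt_placements.items()))
            row = [sv.sv_id, sv.anchor.contig, str(sv.anchor.start),
                   str(sv.anchor.end), str(sv.ref_len), str(sv.alt_len),
                   sv.sv_type, sv.ref_genome, plc or "."]
            if sv.genotypes is not None:
                row += [MISSING if pd.isna(v) else str(int(v))
                        for v in sv.genotypes.loc[accessions]]
            fh.write("\t".join(row) + "\n")


def read_sv_table(path) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["sv_id", "contig", "start", "end", "ref_len", "alt_len",
             "sv_type", "ref_genome", "placements"]
    if list(df.columns[:9]) != fixed:
        raise DataError(f"{path}: unexpected SV table header")
    acc_cols = list(df.columns[9:])
    out = []
    for _, r in df.iterrows():
        placements = {}
        if r["placements"] and r["placements"] != ".":
            for item in r["placements"].split(";"):
                g, contig, span = item.split(":")
                s, e = span.split("-")
                placements[g] = GenomicInterval(contig, int(s), int(e))
        geno = None
        if acc_cols:
            geno = pd.Series(
                [np.nan if r[a] == MISSING else float(r[a])
                 for a in acc_cols],
                index=acc_cols, dtype=float)
        out.append(SVRecord(
            sv_id=r["sv_id"],
            anchor=GenomicInterval(r["contig"], int(r["start"]),
                                   int(r["end"])),
            ref_len=int(r["ref_len"]), alt_len=int(r["alt_len"]),
            sv_type=r["sv_type"], ref_genome=r["ref_genome"],
            alt_placements=placements, genotypes=geno))
    return out


# ----------------------------------------------------------------- matrices
def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep=MISSING)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    write_matrix(gm.dosages, path, index_label="variant")


def read_genotypes(path) -> GenotypeMatrix:
    return GenotypeMatrix(read_matrix(path))


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="accession", na_rep=MISSING)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])


# -------------------------------------------------------------------- truth
def write_truth(truth: SimTruth, path) -> None:
    """Truth sidecar: a tab-separated key/value table.

    Rows: ``kind  id  value`` where kind is one of expression_effect,
    target_gene, phenotype_effect, true_maf, fixed, ltr_age, link,
    heritability.
    """
    with open(path, "w") as fh:
        fh.write("kind\tid\tvalue\n")
        for t, f in truth.expression_effects.items():
            fh.write(f"expression_effect\t{t}\t{f}\n")
        for t, g in truth.te_target_gene.items():
            fh.write(f"target_gene\t{t}\t{g}\n")
        for t, b in truth.phenotype_effects.items():
            fh.write(f"phenotype_effect\t{t}\t{b}\n")
        for t, m in truth.true_maf.items():
            fh.write(f"true_maf\t{t}\t{m}\n")
        for t in sorted(truth.fixed_ids):
            fh.write(f"fixed\t{t}\t1\n")
        for t, a in truth.ltr_ages.items():
            fh.write(f"ltr_age\t{t}\t{a}\n")
        for te, sv in sorted(truth.te_sv_links):
            fh.write(f"link\t{te}\t{sv}\n")
        if truth.heritability is not None:
            fh.write(f"heritability\t.\t{truth.heritability}\n")


def read_truth(path) -> SimTruth:
    truth = SimTruth()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("kind\t"):
            raise DataError(f"{path}: not a truth sidecar")
        for line in fh:
            kind, key, value = line.rstrip("\n").split("\t")
            if kind == "expression_effect":
                truth.expression_effects[key] = float(value)
            elif kind == "target_gene":
                truth.te_target_gene[key] = value
            elif kind == "phenotype_effect":
                truth.phenotype_effects[key] = float(value)
            elif kind == "true_maf":
                truth.true_maf[key] = float(value)
            elif kind == "fixed":
                truth.fixed_ids.add(key)
            elif kind == "ltr_age":
                truth.ltr_ages[key] = float(value)
            elif kind == "link":
                truth.te_sv_links.add((key, value))
            elif kind == "heritability":
                truth.heritability = float(value)
            else:
                raise DataError(f"{path}: unknown truth kind {kind!r}")
    return truth
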