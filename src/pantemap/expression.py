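"""Expression filtering, TMM normalization, nearest-gene assignment and
TE regulatory-effect classification.

A TE's effect on its nearest gene is classified from the fold ratio of
mean expression between carrier accessions (any non-zero dosage) and
non-carriers: ratio >= 1.5 is promotive, ratio <= 1/1.5 suppressive,
anything between is no detectable effect.  Calls where either genotype
group is smaller than ``min_group`` are flagged unevaluable rather than
dropped silently.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .types import EffectCall, GenomicInterval, TEAnnotation

__all__ = [
    "filter_expressed",
    "tmm_factors",
    "nearest_gene",
    "nearest_genes",
    "classify_te_effect",
    "classify_effects",
    "effect_summary",
]


def filter_expressed(
    em: pd.DataFrame,
    min_tpm: float = 0.01,
    max_low_fraction: float = 0.8,
) -> pd.DataFrame:
    """Drop genes expressed below ``min_tpm`` in more than
    ``max_low_fraction`` of samples."""
    if em.empty:
        raise DataError("empty expression matrix")
    if min_tpm < 0 or not 0.0 <= max_low_fraction <= 1.0:
        raise ParameterError("invalid expression filter thresholds")
    low_frac = (em < min_tpm).mean(axis=1)
    return em.loc[low_frac <= max_low_fraction]


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per library.

    The reference library is the one whose upper quartile of
    depth-normalized counts is closest to the mean upper quartile.
    Against that reference, per-gene log2 fold changes (M) and average
    abundances (A) are computed over genes expressed in both libraries;
    the most extreme 30% of M and 5% of A are trimmed on each side, and
    the factor is the inverse-variance-weighted mean of the retained M
    values (delta-method binomial weights).  Factors are rescaled to a
    geometric mean of 1, so they capture composition bias only, not
    sequencing depth.
    """
    if counts.shape[1] < 2:
        raise ParameterError("TMM needs at least two libraries")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise DataError("library with zero total count")

    norm = counts.div(lib, axis=1)
    uq = norm.quantile(0.75)
    ref_name = (uq - uq.mean()).abs().idxmin()
    yr = counts[ref_name].to_numpy(dtype=float)
    nr = float(lib[ref_name])

    factors = {}
    for name in counts.columns:
        y = counts[name].to_numpy(dtype=float)
        n = float(lib[name])
        if name == ref_name:
            factors[name] = 1.0
            continue
        keep = (y > 0) & (yr > 0)
        yk, yrk = y[keep], yr[keep]
        m = np.log2((yk / n) / (yrk / nr))
        a = 0.5 * np.log2((yk / n) * (yrk / nr))
        finite = np.isfinite(m) & np.isfinite(a)
        m, a = m[finite], a[finite]
        yk, yrk = yk[finite], yrk[finite]
        if m.size == 0:
            factors[name] = 1.0
            continue
        # doubly trimmed set: inner quantile band on both M and A
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abundance_trim, 1 - abundance_trim])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any():
            factors[name] = 1.0
            continue
        w = 1.0 / ((n - yk[sel]) / (n * yk[sel])
                   + (nr - yrk[sel]) / (nr * yrk[sel]))
        factors[name] = 2.0 ** (np.sum(w * m[sel]) / np.sum(w))

    f = pd.Series(factors).reindex(counts.columns)
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    return f


def _signed_distance(te_iv: GenomicInterval, gene: GenomicInterval) -> int:
    """Gap between TE and gene; negative = upstream of the gene (relative
    to gene strand), positive = downstream, 0 = overlapping."""
    gap = te_iv.gap_to(gene)
    if gap <= 0:
        return 0
    te_before = te_iv.end <= gene.start
    if gene.strand == "-":
        upstream = not te_before
    else:
        upstream = te_before
    return -gap if upstream else gap


def _tss(gene: GenomicInterval) -> int:
    return gene.end - 1 if gene.strand == "-" else gene.start


def nearest_gene(
    te: TEAnnotation,
    genes: Mapping[str, GenomicInterval],
) -> tuple[str | None, int | None]:
    """Assign a TE its nearest gene on the same contig.

    Distance is 0 for TEs overlapping the gene body, else the gap to the
    closest gene boundary; the sign marks upstream (negative) vs
    downstream (positive) of the gene, following gene strand.  Ties on
    gap are broken by smaller distance to the transcription start, then
    lexicographic gene id.  Returns ``(None, None)`` when the contig has
    no gene.
    """
    best: tuple[int, int, str] | None = None
    for gid, giv in genes.items():
        if giv.contig != te.interval.contig:
            continue
        gap = te.interval.gap_to(giv)
        tss_gap = min(abs(te.interval.start - _tss(giv)),
                      abs(te.interval.end - 1 - _tss(giv)))
        key = (gap, tss_gap, gid)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    gid = best[2]
    return gid, _signed_distance(te.interval, genes[gid])


def nearest_genes(
    tes: Sequence[TEAnnotation],
    genes: Mapping[str, GenomicInterval],
) -> pd.DataFrame:
    """Vectorized-ish nearest-gene assignment for many TEs.

    Returns a DataFrame indexed by te_id with ``gene_id`` and
    ``distance`` columns (NaN where unassigned).
    """
    by_contig: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for gid, giv in genes.items():
        by_contig.setdefault(giv.contig, []).append((gid, giv))
    rows = []
    for te in tes:
        cands = by_contig.get(te.interval.contig, [])
        gid, dist = nearest_gene(te, dict(cands))
        rows.append({"te_id": te.te_id, "gene_id": gid, "distance": dist})
    return pd.DataFrame(rows).set_index("te_id")


def classify_te_effect(
    te_id: str,
    gene_id: str,
    dosage: pd.Series,
    expression: pd.Series,
    stage: str = "",
    fold: float = 1.5,
    min_group: int = 5,
    eps: float = 0.01,
) -> EffectCall:
    """Classify one TE's effect on one gene at one stage.

    Carriers are accessions with any non-zero dosage (dominant
    presence/absence coding).  The ratio ``(mean_with + eps) /
    (mean_without + eps)`` is promotive when >= ``fold`` (inclusive, "at
    least"), suppressive when <= ``1/fold``, otherwise none.  When either
    group has fewer than ``min_group`` accessions the call is
    ``unevaluable``.
    """
    if fold <= 1.0:
        raise ParameterError("fold threshold must exceed 1")
    common = dosage.index.intersection(expression.index)
    d = dosage.loc[common]
    x = expression.loc[common]
    ok = d.notna() & x.notna()
    d, x = d[ok], x[ok]
    with_mask = d > 0
    n_with = int(with_mask.sum())
    n_without = int((~with_mask).sum())
    if n_with < min_group or n_without < min_group:
        return EffectCall(te_id, gene_id, stage, float("nan"), float("nan"),
                          float("nan"), "unevaluable", n_with, n_without)
    mean_with = float(x[with_mask].mean())
    mean_without = float(x[~with_mask].mean())
    ratio = (mean_with + eps) / (mean_without + eps)
    if ratio >= fold:
        effect = "promotive"
    elif ratio <= 1.0 / fold:
        effect = "suppressive"
    else:
        effect = "none"
    return EffectCall(te_id, gene_id, stage, mean_with, mean_without,
                      ratio, effect, n_with, n_without)


def classify_effects(
    genotypes,
    expression: pd.DataFrame,
    te_to_gene: Mapping[str, str],
    stage: str = "",
    fold: float = 1.5,
    min_group: int = 5,
    eps: float = 0.01,
) -> list[EffectCall]:
    """Classify every TE in ``te_to_gene`` against its assigned gene."""
    calls = []
    for te_id, gene_id in te_to_gene.items():
        if gene_id is None or gene_id not in expression.index:
            continue
        calls.append(classify_te_effect(
            te_id, gene_id, genotypes.dosages.loc[te_id],
            expression.loc[gene_id], stage=stage, fold=fold,
            min_group=min_group, eps=eps))
    return calls


def effect_summary(calls_by_stage: Mapping[str, Sequence[EffectCall]]) -> dict:
    """Per-stage class counts/percentages and cross-stage consistency.

    ``promotive_pct`` is promotive / (promotive + suppressive) x 100 —
    the share among TEs with a regulatory effect; fractions over all
    evaluable TEs are reported alongside.  Consistent sets hold TEs with
    the same non-``none`` class in every stage.
    """
    if not calls_by_stage or all(len(v) == 0 for v in calls_by_stage.values()):
        raise DataError("no effect calls to summarize")

    stages = {}
    class_sets: dict[str, dict[str, set[str]]] = {}
    for stage, calls in calls_by_stage.items():
        counts = {"promotive": 0, "suppressive": 0, "none": 0,
                  "unevaluable": 0}
        sets = {"promotive": set(), "suppressive": set()}
        for c in calls:
            counts[c.effect] += 1
            if c.effect in sets:
                sets[c.effect].add(c.te_id)
        reg = counts["promotive"] + counts["suppressive"]
        evaluable = reg + counts["none"]
        stages[stage] = {
            **counts,
            "n_regulatory": reg,
            "n_evaluable": evaluable,
            "promotive_pct": (100.0 * counts["promotive"] / reg
                              if reg else float("nan")),
            "suppressive_pct": (100.0 * counts["suppressive"] / reg
                                if reg else float("nan")),
            "none_frac_evaluable": (counts["none"] / evaluable
                                    if evaluable else float("nan")),
        }
        class_sets[stage] = sets

    names = list(class_sets)
    consistent_promotive = set.intersection(
        *(class_sets[s]["promotive"] for s in names))
    consistent_suppressive = set.intersection(
        *(class_sets[s]["suppressive"] for s in names))
    return {
        "stages": stages,
        "consistent_promotive": consistent_promotive,
        "consistent_suppressive": consistent_suppressive,
    }
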