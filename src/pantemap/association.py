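"""Single-variant association engine for TE-GWAS and TE-eQTL.

Each variant's dosage is regressed on the response (a trait or a gene's
expression) by ordinary least squares with optional covariates — in
practice the top principal components of the expression or genotype
matrix, which absorb population structure in place of a mixed model.
Significance uses the 1/n rule (p* = 1/#variants, i.e. a -log10
threshold of log10 n); significant variants are grouped into LD clumps
around greedy index variants (smallest p first, 100 kb window, r^2 >=
0.1 by default) and clumps are merged into physical loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .types import Clump, GenomicInterval, GenotypeMatrix

__all__ = [
    "association_scan",
    "significance_cutoff",
    "classify_cis_trans",
    "ld_r2",
    "clump",
    "merge_locus",
    "eqtl_summary",
    "expression_pcs",
]


def expression_pcs(matrix: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """Top principal components of a (features x samples) matrix, as
    sample-indexed covariate columns (``PC1`` ...)."""
    x = matrix.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs < 1:
        raise ParameterError("not enough samples/features for PCs")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(pcs, index=matrix.columns,
                        columns=[f"PC{i + 1}" for i in range(n_pcs)])


def _scan_complete(dos: np.ndarray, resid_y: np.ndarray, q: np.ndarray,
                   n: int, k: int):
    """Vectorized OLS scan for variants with no missing dosage.

    ``dos`` is variants x accessions; ``resid_y`` the response with the
    covariate space (incl. intercept) projected out; ``q`` an orthonormal
    basis of that covariate space.
    """
    g = dos - (dos @ q) @ q.T  # project covariates out of each dosage row
    gg = np.einsum("ij,ij->i", g, g)
    gy = g @ resid_y
    dof = n - k - 2  # intercept + k covariates + dosage
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = resid_y @ resid_y - beta * gy
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    bad = gg <= 1e-12
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return beta, se, p


def association_scan(
    gm: GenotypeMatrix,
    response: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant OLS association of dosage with a response.

    Accessions with a missing response or covariate are dropped globally;
    accessions with a missing dosage are dropped per variant (pairwise
    complete).  Returns a DataFrame indexed by variant with columns
    ``beta``, ``se``, ``p``, ``neg_log10_p`` and ``n_used``; variants
    with zero dosage variance get NaN statistics and are flagged in the
    ``degenerate`` column.
    """
    acc = gm.accessions.intersection(response.index)
    if covariates is not None:
        acc = acc.intersection(covariates.index)
    y_full = response.loc[acc]
    ok = y_full.notna()
    if covariates is not None:
        ok &= covariates.loc[acc].notna().all(axis=1)
    acc = acc[ok]
    if len(acc) < 3:
        raise DataError("fewer than 3 accessions with complete response")

    y = y_full.loc[acc].to_numpy(dtype=float)
    n = len(acc)
    if covariates is not None:
        c = covariates.loc[acc].to_numpy(dtype=float)
        x = np.column_stack([np.ones(n), c])
    else:
        x = np.ones((n, 1))
    k = x.shape[1] - 1
    q, _ = np.linalg.qr(x)
    resid_y = y - q @ (q.T @ y)

    dos = gm.dosages[acc].to_numpy(dtype=float)
    complete = ~np.isnan(dos).any(axis=1)

    beta = np.full(gm.n_variants, np.nan)
    se = np.full(gm.n_variants, np.nan)
    p = np.full(gm.n_variants, np.nan)
    n_used = np.full(gm.n_variants, n)

    if complete.any():
        b, s, pv = _scan_complete(dos[complete], resid_y, q, n, k)
        beta[complete], se[complete], p[complete] = b, s, pv

    for i in np.flatnonzero(~complete):  # per-variant complete cases
        mask = ~np.isnan(dos[i])
        n_i = int(mask.sum())
        n_used[i] = n_i
        if n_i < k + 3:
            continue
        xi = x[mask]
        qi, _ = np.linalg.qr(xi)
        ry = y[mask] - qi @ (qi.T @ y[mask])
        b, s, pv = _scan_complete(dos[i:i + 1, mask], ry, qi, n_i, k)
        beta[i], se[i], p[i] = b[0], s[0], pv[0]

    with np.errstate(divide="ignore"):  # p underflow -> inf, fine
        neg_log10 = -np.log10(p)
    out = pd.DataFrame({
        "beta": beta, "se": se, "p": p,
        "neg_log10_p": neg_log10,
        "n_used": n_used,
        "degenerate": np.isnan(p),
    }, index=gm.variants)
    return out


def significance_cutoff(n_variants: int) -> tuple[float, float]:
    """The 1/n significance rule: p* = 1/n, -log10 p* = log10 n."""
    if n_variants < 1:
        raise ParameterError("n_variants must be >= 1")
    return 1.0 / n_variants, math.log10(n_variants)


def classify_cis_trans(
    variant_anchor: GenomicInterval,
    gene: GenomicInterval,
    window: int = 1_000_000,
) -> str:
    """cis when on the same contig within ``window`` bp of the gene
    (inclusive; overlap counts as distance 0), otherwise trans."""
    gap = variant_anchor.gap_to(gene)
    if gap < 0:  # different contigs
        return "trans"
    return "cis" if gap <= window else "trans"


def ld_r2(dosage_a: pd.Series, dosage_b: pd.Series) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete accessions; NaN when either is constant."""
    a = dosage_a.to_numpy(dtype=float)
    b = dosage_b.loc[dosage_a.index].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise DataError("fewer than 2 complete accession pairs")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va <= 0 or vb <= 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    records: pd.DataFrame,
    gm: GenotypeMatrix,
    positions: Mapping[str, GenomicInterval],
    p1: float = 1e-5,
    window_kb: float = 100.0,
    r2_min: float = 0.1,
) -> list[Clump]:
    """Greedy LD clumping of significant variants.

    Repeatedly takes the unassigned variant with the smallest p <= ``p1``
    as an index, then absorbs every unassigned variant on the same contig
    within ``window_kb`` of the index whose r^2 with the index is at
    least ``r2_min`` (undefined r^2 counts as 0).  Ties on p break by
    position, then by variant id.  Returns clumps in order of discovery.
    """
    if "p" not in records.columns:
        raise DataError("records need a 'p' column")
    sig = records[records["p"] <= p1].copy()
    sig = sig[~sig["p"].isna()]
    if sig.empty:
        return []
    missing_pos = [v for v in sig.index if v not in positions]
    if missing_pos:
        raise DataError(f"variants without positions: {missing_pos[:5]}")

    order = sorted(
        sig.index,
        key=lambda v: (sig.at[v, "p"], positions[v].contig,
                       positions[v].start, v),
    )
    window = window_kb * 1000.0
    unassigned = set(order)
    clumps: list[Clump] = []
    for idx in order:
        if idx not in unassigned:
            continue
        unassigned.discard(idx)
        members = [idx]
        iv = positions[idx]
        for other in order:
            if other not in unassigned:
                continue
            ov = positions[other]
            if ov.contig != iv.contig:
                continue
            if abs(ov.start - iv.start) > window:
                continue
            r2 = ld_r2(gm.dosages.loc[idx], gm.dosages.loc[other])
            if math.isnan(r2):
                r2 = 0.0
            if r2 >= r2_min:
                members.append(other)
                unassigned.discard(other)
        span = GenomicInterval(
            iv.contig,
            min(positions[m].start for m in members),
            max(positions[m].end for m in members),
        )
        ps = [float(sig.at[m, "p"]) for m in members]
        clumps.append(Clump(index_variant=idx,
                            index_p=float(sig.at[idx, "p"]),
                            members=members, span=span,
                            min_p=min(ps), max_p=max(ps)))
    return clumps


def merge_locus(clumps: Sequence[Clump]) -> list[GenomicInterval]:
    """Merge clump spans into per-contig locus intervals (union of
    overlapping spans, sweep-line)."""
    spans = [c.span for c in clumps if c.span is not None]
    if not spans:
        return []
    spans.sort(key=lambda iv: (iv.contig, iv.start, iv.end))
    merged = [spans[0]]
    for iv in spans[1:]:
        last = merged[-1]
        if iv.contig == last.contig and iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.contig, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def eqtl_summary(records: pd.DataFrame, cutoff_p: float | None = None) -> dict:
    """Counts and percentages of significant cis/trans associations and
    the lead (smallest-p) variant per target.

    ``records`` needs columns ``p`` and ``cis`` (boolean), plus
    ``target`` for lead reporting; percentages are over significant
    records only and rounded to two decimals.
    """
    if "cis" not in records.columns:
        raise DataError("records need a 'cis' column")
    sig = records if cutoff_p is None else records[records["p"] <= cutoff_p]
    n_cis = int(sig["cis"].sum())
    n_trans = int((~sig["cis"].astype(bool)).sum())
    total = n_cis + n_trans
    out = {
        "n_significant": total,
        "n_cis": n_cis,
        "n_trans": n_trans,
        "cis_pct": round(100.0 * n_cis / total, 2) if total else float("nan"),
        "trans_pct": (round(100.0 * n_trans / total, 2)
                      if total else float("nan")),
    }
    if "target" in sig.columns and total:
        leads = sig.loc[sig.groupby("target")["p"].idxmin()]
        out["lead_variants"] = {
            row["target"]: idx for idx, row in leads.iterrows()}
    return out
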