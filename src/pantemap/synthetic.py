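"""Synthetic-data generators with a ground-truth channel.

Every downstream stage of the pipeline (pan-TE map construction, effect
classification, association scans, haplotype analysis, LTR dating) can be
exercised on data produced here, where the planted signal is known exactly.

The genotype model is diploid and biallelic: each TE insertion
polymorphism segregates under Hardy-Weinberg equilibrium at its true
allele frequency, and dosage counts copies of the TE-bearing allele.  A
configurable fraction of TEs is fixed (dosage 2 in every accession),
mirroring the empirical observation that the large majority of TEs in a
crop population show no presence/absence polymorphism.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .types import (GenomicInterval, GenotypeMatrix, LTRElement, SimTruth,
                    SVRecord, TEAnnotation)

__all__ = [
    "simulate_genotypes",
    "simulate_expression",
    "simulate_phenotype",
    "simulate_intervals",
    "simulate_ltr_pairs",
]

MafLaw = tuple | Callable[[np.random.Generator, int], np.ndarray]

#: Default frequency law of polymorphic TE insertions.  Uniform on
#: (0.005, 0.5) keeps rare insertions common, consistent with a TIP
#: frequency spectrum dominated by low-frequency variants, while still
#: producing enough intermediate-frequency variants to test every stage.
DEFAULT_MAF_LAW = ("uniform", 0.005, 0.5)


def _draw_maf(law: MafLaw, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(law):
        maf = np.asarray(law(rng, n), dtype=float)
    else:
        name, *params = law
        if name == "uniform":
            lo, hi = params
            maf = rng.uniform(lo, hi, size=n)
        elif name == "beta":
            a, b = params
            maf = rng.beta(a, b, size=n) * 0.5
        elif name == "constant":
            maf = np.full(n, float(params[0]))
        else:
            raise ParameterError(f"unknown MAF law {name!r}")
    if maf.shape != (n,) or np.any(maf < 0) or np.any(maf > 0.5):
        raise ParameterError("MAF law must yield n values in [0, 0.5]")
    return maf


def simulate_genotypes(
    n_accessions: int,
    n_tes: int,
    fixed_fraction: float = 0.8514,
    maf_law: MafLaw = DEFAULT_MAF_LAW,
    missing_rate: float = 0.0,
    seed: int = 0,
    inbreeding: float = 0.0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a TE presence/absence genotype matrix.

    Parameters
    ----------
    n_accessions
        Number of accessions (columns); at least 2.
    n_tes
        Number of TE loci (rows).
    fixed_fraction
        Fraction of loci fixed for the TE-bearing allele (dosage 2 in
        every non-missing call).  The default reflects a population in
        which ~85% of TEs are present in all accessions.
    maf_law
        Frequency law of the polymorphic loci: ``("uniform", lo, hi)``,
        ``("beta", a, b)`` (scaled to [0, 0.5]), ``("constant", m)`` or a
        callable ``f(rng, n) -> array``.
    missing_rate
        Per-call probability of a missing genotype.
    inbreeding
        Wright's F: probability that an accession is autozygous at a
        locus (its two alleles identical by descent).  0 gives plain
        Hardy-Weinberg sampling; values near 1 emulate selfing crop
        panels whose accessions are essentially homozygous lines.
    """
    if n_accessions < 2:
        raise ParameterError("n_accessions must be >= 2")
    if n_tes < 1:
        raise ParameterError("n_tes must be >= 1")
    for name, p in (("fixed_fraction", fixed_fraction),
                    ("missing_rate", missing_rate),
                    ("inbreeding", inbreeding)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {p}")

    rng = np.random.default_rng(seed)
    te_ids = [f"te{i:05d}" for i in range(n_tes)]
    accessions = [f"acc{j:04d}" for j in range(n_accessions)]

    n_fixed = int(round(fixed_fraction * n_tes))
    fixed_mask = np.zeros(n_tes, dtype=bool)
    fixed_mask[rng.choice(n_tes, size=n_fixed, replace=False)] = True

    dosage = np.full((n_tes, n_accessions), 2.0)
    n_poly = n_tes - n_fixed
    maf = np.ones(n_tes)  # frequency of the TE-bearing allele; 1 = fixed
    if n_poly:
        poly_maf = _draw_maf(maf_law, rng, n_poly)
        maf[~fixed_mask] = poly_maf
        # Hardy-Weinberg with inbreeding: autozygous calls (prob F) are
        # 0 or 2 with prob (1-p, p); allozygous ~ Binomial(2, p)
        p = poly_maf[:, None]
        shape = (n_poly, n_accessions)
        hw = rng.binomial(2, p, size=shape).astype(float)
        if inbreeding > 0:
            auto = 2.0 * rng.binomial(1, p, size=shape)
            pick = rng.random(shape) < inbreeding
            hw = np.where(pick, auto, hw)
        dosage[~fixed_mask] = hw
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan

    gm = GenotypeMatrix(pd.DataFrame(dosage, index=te_ids, columns=accessions))
    truth = SimTruth(
        true_maf={t: float(m) for t, m, f in zip(te_ids, maf, fixed_mask)
                  if not f},
        fixed_ids={t for t, f in zip(te_ids, fixed_mask) if f},
    )
    return gm, truth


def simulate_expression(
    genotypes: GenotypeMatrix,
    planted_effects: Mapping[str, float],
    baseline_law: tuple = ("lognormal", 2.0, 1.0),
    noise_cv: float = 0.2,
    stages: int = 2,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Simulate per-stage expression matrices with planted TE effects.

    One target gene is generated per TE locus (``gene_for_<te_id>``); a
    planted TE with fold ``f`` multiplies its target's expression by
    ``f`` in carrier accessions (any non-zero dosage).  Noise is
    multiplicative log-normal with coefficient of variation ``noise_cv``
    and unit mean, so carrier expectation is exactly ``f`` times the
    non-carrier expectation.  Stages share baselines and planted effects
    (only the noise differs), supporting cross-stage consistency tests.

    Returns a mapping ``stage label -> ExpressionMatrix`` (genes x
    accessions, TPM) and the truth channel.
    """
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    if stages < 1:
        raise ParameterError("stages must be >= 1")
    unknown = set(planted_effects) - set(genotypes.variants)
    if unknown:
        raise KeyError(f"planted TE ids not in genotypes: {sorted(unknown)}")
    if any(f < 0 for f in planted_effects.values()):
        raise ParameterError("planted fold must be >= 0")

    rng = np.random.default_rng(seed)
    te_ids = list(genotypes.variants)
    gene_ids = [f"gene_for_{t}" for t in te_ids]
    n_genes, n_acc = len(gene_ids), genotypes.n_accessions

    name, *params = baseline_law
    if name == "lognormal":
        mu, sigma = params
        baseline = rng.lognormal(mu, sigma, size=n_genes)
    elif name == "constant":
        baseline = np.full(n_genes, float(params[0]))
    else:
        raise ParameterError(f"unknown baseline law {name!r}")

    fold = np.ones(n_genes)
    for i, t in enumerate(te_ids):
        if t in planted_effects:
            fold[i] = planted_effects[t]
    carrier = (genotypes.dosages.to_numpy() > 0)  # NaN -> False

    # log-normal with unit mean: sigma^2 = ln(1 + cv^2), mu = -sigma^2/2
    s2 = math.log1p(noise_cv ** 2)
    mu_n, sd_n = -s2 / 2.0, math.sqrt(s2)

    matrices: dict[str, pd.DataFrame] = {}
    for s in range(stages):
        noise = rng.lognormal(mu_n, sd_n, size=(n_genes, n_acc))
        expr = baseline[:, None] * np.where(carrier, fold[:, None], 1.0) * noise
        matrices[f"stage{s + 1}"] = pd.DataFrame(
            expr, index=gene_ids, columns=genotypes.accessions)

    truth = SimTruth(
        expression_effects=dict(planted_effects),
        te_target_gene=dict(zip(te_ids, gene_ids)),
    )
    return matrices, truth


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    qtl_effects: Mapping[str, float],
    heritability: float = 0.5,
    seed: int = 0,
    trait: str = "flowering_time",
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a phenotype table with planted additive TE QTLs.

    The genetic value is ``sum(beta * dosage)`` over the planted QTLs
    (missing dosages treated as the locus mean); Gaussian noise is scaled
    so the genetic variance fraction equals ``heritability``.  Ecotype
    labels follow the dosage of the first planted variant (0 -> spring,
    1 -> semi_winter, 2 -> winter; missing assigned at random), giving
    haplotype tests a deterministic ecotype structure.

    Returns a DataFrame indexed by accession with columns ``trait`` (name
    from the ``trait`` argument), ``ecotype``, ``region`` and ``year``.
    """
    if not 0.0 <= heritability < 1.0:
        raise ParameterError("heritability must be in [0, 1)")
    if heritability > 0 and not qtl_effects:
        raise ParameterError("heritability > 0 requires planted QTL effects")
    unknown = set(qtl_effects) - set(genotypes.variants)
    if unknown:
        raise KeyError(f"QTL ids not in genotypes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    acc = genotypes.accessions
    g = np.zeros(len(acc))
    for te, beta in qtl_effects.items():
        d = genotypes.dosages.loc[te]
        g += beta * d.fillna(d.mean()).to_numpy()

    var_g = float(np.var(g))
    if heritability == 0.0 or var_g == 0.0:
        noise_sd = 1.0
        g = np.zeros_like(g) if heritability == 0.0 else g
    else:
        noise_sd = math.sqrt(var_g * (1 - heritability) / heritability)
    y = g + rng.normal(0.0, noise_sd, size=len(acc))

    ecolabels = {0.0: "spring", 1.0: "semi_winter", 2.0: "winter"}
    if qtl_effects:
        anchor = next(iter(qtl_effects))
    else:
        anchor = genotypes.variants[0]
    anchor_d = genotypes.dosages.loc[anchor]
    ecotype = [
        ecolabels[d] if d in ecolabels
        else rng.choice(["spring", "semi_winter", "winter"])
        for d in anchor_d
    ]
    table = pd.DataFrame(
        {
            trait: y,
            "ecotype": ecotype,
            "region": rng.choice(["north", "south", "east", "west"],
                                 size=len(acc)),
            "year": rng.choice([2019, 2020, 2021], size=len(acc)),
        },
        index=acc,
    )
    truth = SimTruth(phenotype_effects=dict(qtl_effects),
                     heritability=heritability)
    return table, truth


def simulate_intervals(
    n_genes: int,
    n_tes: int,
    n_svs: int,
    contig_lengths: Mapping[str, int],
    seed: int = 0,
    link_fraction: float = 0.6,
) -> tuple[list[GenomicInterval], list[TEAnnotation], list[SVRecord], SimTruth]:
    """Simulate gene/TE/SV interval layouts with known TE<->SV links.

    SV alternative-allele placements are laid out without overlap and with
    generous spacing on a single alternative assembly (``alt``).  A
    ``link_fraction`` share of TEs is placed so that its SV covers
    strictly more than half of the TE (a true link); the remaining decoy
    TEs are placed either in the gaps between SVs or overlapping an SV by
    at most half their length, so brute-force overlap scanning recovers
    exactly the constructed link set.

    Gene intervals are returned as plain intervals on the reference
    contigs (named genes ``gene00000`` ... in order).
    """
    if min(n_genes, n_tes, n_svs) < 0:
        raise ParameterError("counts must be >= 0")
    if not contig_lengths:
        raise ParameterError("contig_lengths must be non-empty")

    rng = np.random.default_rng(seed)
    contigs = sorted(contig_lengths)

    # --- SV placements: non-overlapping slots with >= 400 bp padding ----
    svs: list[SVRecord] = []
    slots: list[tuple[str, int, int]] = []  # (contig, start, end) of ALT seg
    pad = 400
    per_contig_cursor = {c: pad for c in contigs}
    for i in range(n_svs):
        c = contigs[i % len(contigs)]
        length = int(rng.integers(200, 2001))
        start = per_contig_cursor[c]
        end = start + length
        if end + pad > contig_lengths[c]:
            raise DataError(
                f"contig {c} too short for {n_svs} SVs; increase its length")
        per_contig_cursor[c] = end + pad + int(rng.integers(0, 600))
        alt_iv = GenomicInterval(c, start, end)
        svs.append(SVRecord(
            sv_id=f"sv{i:05d}",
            anchor=GenomicInterval(c, start, start + 1),
            ref_len=1,
            alt_len=length,
            ref_genome="ref",
            alt_placements={"alt": alt_iv},
        ))
        slots.append((c, start, end))

    # --- TEs: true links overlap > 50%, decoys <= 50% -------------------
    tes: list[TEAnnotation] = []
    links: set[tuple[str, str]] = set()
    n_linked = min(int(round(link_fraction * n_tes)), n_svs) if n_svs else 0
    linked_svs = rng.choice(n_svs, size=n_linked, replace=False) if n_linked \
        else np.array([], dtype=int)
    for t in range(n_tes):
        te_id = f"te{t:05d}"
        if t < n_linked:
            sv = svs[int(linked_svs[t])]
            seg = sv.alt_placements["alt"]
            te_len = int(rng.integers(60, max(61, len(seg) + 1)))
            # overlap fraction drawn in (0.55, 1.0]: strictly above half
            frac = rng.uniform(0.55, 1.0)
            ov = max(int(math.ceil(frac * te_len)), te_len // 2 + 1)
            ov = min(ov, te_len, len(seg))
            if ov <= te_len // 2:
                ov = te_len // 2 + 1
            if rng.random() < 0.5:  # hang off the left edge of the segment
                start = seg.start - (te_len - ov)
            else:
                start = seg.end - ov
            start = max(start, 0)
            iv = GenomicInterval(seg.contig, start, start + te_len)
            if iv.overlap(seg) * 2 <= te_len:  # clamping pushed it inside
                iv = GenomicInterval(seg.contig, seg.start,
                                     seg.start + te_len)
            links.add((te_id, sv.sv_id))
        else:
            # decoy: in a gap, or overlapping an SV by exactly <= half
            c = contigs[int(rng.integers(len(contigs)))]
            te_len = int(rng.integers(60, 401))
            if n_svs and rng.random() < 0.3:
                sv = svs[int(rng.integers(n_svs))]
                seg = sv.alt_placements["alt"]
                ov = int(rng.integers(0, te_len // 2 + 1))  # <= half
                start = seg.start - (te_len - ov)
                if start < 0:
                    start = seg.end - ov
                iv = GenomicInterval(seg.contig, start, start + te_len)
            else:
                start = _place_in_gap(rng, c, te_len, contig_lengths[c],
                                      [s for s in slots if s[0] == c])
                iv = GenomicInterval(c, start, start + te_len)
            # construction guarantee: never > 50% of the TE inside any SV
            assert all(iv.overlap(s.alt_placements["alt"]) * 2 <= te_len
                       for s in svs), "decoy placement violated its bound"
        tes.append(TEAnnotation(te_id=te_id, genome_id="alt", interval=iv,
                                te_class=str(rng.choice(["I", "II"])),
                                superfamily=str(rng.choice(
                                    ["Copia", "Gypsy", "TIR", "Helitron"]))))

    genes: list[GenomicInterval] = []
    for gidx in range(n_genes):
        c = contigs[gidx % len(contigs)]
        length = min(int(rng.integers(500, 5001)), contig_lengths[c])
        start = int(rng.integers(0, contig_lengths[c] - length + 1))
        genes.append(GenomicInterval(c, start, start + length,
                                     strand=str(rng.choice(["+", "-"]))))

    return genes, tes, svs, SimTruth(te_sv_links=links)


def _place_in_gap(rng: np.random.Generator, contig: str, te_len: int,
                  contig_len: int, slots: list[tuple[str, int, int]]) -> int:
    """Pick a start position whose interval avoids all SV segments."""
    occupied = sorted((s, e) for _, s, e in slots)
    gaps = []
    prev = 0
    for s, e in occupied:
        if s - prev >= te_len:
            gaps.append((prev, s - te_len))
        prev = max(prev, e)
    if contig_len - prev >= te_len:
        gaps.append((prev, contig_len - te_len))
    if not gaps:
        raise DataError(f"no room for a decoy TE on contig {contig}")
    lo, hi = gaps[int(rng.integers(len(gaps)))]
    return int(rng.integers(lo, hi + 1))


_BASES = np.array(list("ACGT"))


def simulate_ltr_pairs(
    ages: Sequence[float],
    r: float = 1.5e-8,
    seq_len: int = 2000,
    seed: int = 0,
) -> tuple[list[LTRElement], SimTruth]:
    """Simulate intact LTR elements whose terminal repeats diverged for a
    known time.

    At insertion the 5' and 3' LTRs are identical; they then diverge at
    substitution rate ``r`` per site per year on each copy, for a total
    expected divergence K = 2 r T.  Substitutions follow the
    Jukes-Cantor process, so the per-site mismatch probability is
    p = (3/4) (1 - exp(-4K/3)).
    """
    if r <= 0:
        raise ParameterError("substitution rate r must be > 0")
    if any(a < 0 for a in ages):
        raise ParameterError("ages must be >= 0")
    if seq_len < 1:
        raise ParameterError("seq_len must be >= 1")

    rng = np.random.default_rng(seed)
    elements: list[LTRElement] = []
    truth_ages: dict[str, float] = {}
    for i, age in enumerate(ages):
        k = 2.0 * r * age
        p = 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))
        anc = rng.integers(0, 4, size=seq_len)
        mutate = rng.random(seq_len) < p
        shift = rng.integers(1, 4, size=seq_len)  # never the same base
        derived = np.where(mutate, (anc + shift) % 4, anc)
        eid = f"ltr{i:05d}"
        elements.append(LTRElement(
            element_id=eid,
            superfamily=str(rng.choice(["Copia", "Gypsy", "unknown"],
                                       p=[0.45, 0.45, 0.1])),
            subgenome=str(rng.choice(["A_n", "C_n"])),
            ltr5="".join(_BASES[anc]),
            ltr3="".join(_BASES[derived]),
        ))
        truth_ages[eid] = float(age)
    return elements, SimTruth(ltr_ages=truth_ages)
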