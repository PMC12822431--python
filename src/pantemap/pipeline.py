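"""End-to-end pipeline orchestration.

A single :class:`PipelineConfig` holds every numeric threshold used by
the stages (documented defaults below) plus a master seed from which
per-stage seeds are derived, so a rerun with the same config is
bit-identical.  Stages write tab-separated outputs into an output
directory and a JSON manifest records the config hash, derived seeds,
input checksums and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import association as assoc
from . import expression as expr
from . import haplotypes as haplo
from . import ltr as ltrmod
from . import pangene
from . import pante
from .errors import ConfigError, DependencyError
from .synthetic import (simulate_expression, simulate_genotypes,
                        simulate_intervals, simulate_ltr_pairs,
                        simulate_phenotype)
from .types import GenomicInterval, GenotypeMatrix

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "pangene", "pante", "ltr", "effects", "gwas",
          "eqtl", "haplo")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    Interval/genotype thresholds: ``overlap_fraction`` (SV must cover
    more than this fraction of a TE), ``max_missing``, ``min_maf``,
    ``max_het``.  Expression: ``fold`` (1.5x promotive/suppressive
    rule), ``min_tpm``/``max_low_fraction`` expression filter, ``n_pcs``
    covariate PCs.  Association: ``cis_window``, clump ``p1`` /
    ``clump_kb`` / ``clump_r2``.  Haplotypes: ``hap_min_freq``.  LTR
    clock: substitution rate ``r``.  Pangenome growth: ``growth_subsets``
    x ``growth_repeats`` samples per size.
    """

    seed: int = 1
    outdir: str = "pantemap_run"
    # synthetic scale
    n_accessions: int = 300
    n_tes: int = 400
    fixed_fraction: float = 0.8514
    missing_rate: float = 0.02
    inbreeding: float = 0.9  # accessions are near-homozygous inbred lines
    n_genes: int = 60
    n_svs: int = 80
    n_clusters: int = 400
    n_genomes: int = 8
    n_ltr: int = 150
    expression_fold: float = 2.0
    n_planted_expression: int = 20
    n_planted_qtl: int = 3
    qtl_beta: float = 1.0
    heritability: float = 0.5
    noise_cv: float = 0.2
    stages_expression: int = 2
    # thresholds (pipeline-wide constants)
    overlap_fraction: float = 0.5
    fold: float = 1.5
    cis_window: int = 1_000_000
    min_maf: float = 0.05
    max_missing: float = 0.5
    max_het: float = 0.5
    min_tpm: float = 0.01
    max_low_fraction: float = 0.8
    clump_p1: float = 1e-5
    clump_kb: float = 100.0
    clump_r2: float = 0.1
    hap_min_freq: float = 0.05
    r: float = 1.5e-8
    n_pcs: int = 10
    growth_subsets: int = 500
    growth_repeats: int = 30

    def __post_init__(self) -> None:
        checks = [
            ("overlap_fraction", 0.0, 1.0), ("fold", 1.0, 100.0),
            ("min_maf", 0.0, 0.5), ("max_missing", 0.0, 1.0),
            ("max_het", 0.0, 1.0), ("max_low_fraction", 0.0, 1.0),
            ("clump_r2", 0.0, 1.0), ("hap_min_freq", 0.0, 1.0),
            ("heritability", 0.0, 1.0), ("fixed_fraction", 0.0, 1.0),
            ("inbreeding", 0.0, 1.0),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        if self.r <= 0:
            raise ConfigError("substitution rate r must be > 0")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh,
                           default_flow_style=False, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed (stable, < 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] | list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; return the manifest.

    Every non-``simulate`` stage reads the files an earlier stage wrote
    into ``config.outdir`` and fails with :class:`DependencyError` if a
    required input is absent, so stages can be rerun individually.
    """
    requested = list(stages) if stages else list(STAGES)
    bad = [s for s in requested if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    ordered = [s for s in STAGES if s in requested]

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    for stage in ordered:
        runner = globals()[f"_stage_{stage}"]
        counts = runner(config, out)
        manifest["stages"][stage] = {
            "seed": config.stage_seed(stage), "counts": counts}

    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed")):
        manifest["files"][p.name] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def _require(out: Path, filename: str, stage: str, needed_by: str) -> Path:
    p = out / filename
    if not p.exists():
        raise DependencyError(
            f"stage '{needed_by}' needs {filename} from stage '{stage}'; "
            f"run it first")
    return p


# ------------------------------------------------------------------ stages
def _stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    seed = cfg.stage_seed("simulate")
    rng = np.random.default_rng(seed)

    gm, truth_g = simulate_genotypes(
        cfg.n_accessions, cfg.n_tes, cfg.fixed_fraction,
        missing_rate=cfg.missing_rate, seed=seed,
        inbreeding=cfg.inbreeding)
    # planted expression effects on polymorphic, common TEs
    mafs = gm.maf()
    candidates = [t for t in gm.variants
                  if t not in truth_g.fixed_ids and mafs[t] >= 0.1]
    n_exp = min(cfg.n_planted_expression, len(candidates))
    planted = {t: cfg.expression_fold
               for t in list(candidates)[:n_exp]}
    mats, truth_e = simulate_expression(
        gm, planted, noise_cv=cfg.noise_cv, stages=cfg.stages_expression,
        seed=seed + 1)
    qtl_ids = list(candidates)[n_exp:n_exp + cfg.n_planted_qtl] \
        or list(candidates)[:cfg.n_planted_qtl]
    pheno, truth_p = simulate_phenotype(
        gm, {t: cfg.qtl_beta for t in qtl_ids},
        heritability=cfg.heritability, seed=seed + 2)

    genes, tes, svs, truth_i = simulate_intervals(
        cfg.n_genes, min(cfg.n_tes, 2 * cfg.n_svs), cfg.n_svs,
        {"chr1": 2_000_000, "chr2": 2_000_000}, seed=seed + 3)
    # SV population genotypes so the pan-TE map has something to merge
    sv_gm, _ = simulate_genotypes(
        cfg.n_accessions, max(1, len(svs)), fixed_fraction=0.3,
        missing_rate=cfg.missing_rate, seed=seed + 4,
        inbreeding=cfg.inbreeding)
    for sv, vid in zip(svs, sv_gm.variants):
        sv.genotypes = sv_gm.dosages.loc[vid].rename(sv.sv_id)

    elements, truth_l = simulate_ltr_pairs(
        ages=list(rng.uniform(0.0, 2e6, size=cfg.n_ltr)),
        r=cfg.r, seq_len=2000, seed=seed + 5)

    presence = pd.DataFrame(
        rng.random((cfg.n_clusters, cfg.n_genomes))
        < rng.uniform(0.3, 1.0, size=(cfg.n_clusters, 1)),
        index=[f"cluster{i:05d}" for i in range(cfg.n_clusters)],
        columns=[f"genome{j}" for j in range(cfg.n_genomes)]).astype(int)
    presence = presence[presence.sum(axis=1) > 0]

    # synthetic reference coordinates for the genotype-matrix TEs: each TE
    # on a 10 kb grid with its target gene adjacent (cis by construction)
    te_pos = {t: GenomicInterval("chrV", i * 10_000, i * 10_000 + 500)
              for i, t in enumerate(gm.variants)}
    gene_pos = {truth_e.te_target_gene[t]:
                GenomicInterval("chrV", i * 10_000 + 1_000,
                                i * 10_000 + 3_000, "+")
                for i, t in enumerate(gm.variants)}

    truth = truth_g.merge(truth_e).merge(truth_p).merge(truth_i) \
        .merge(truth_l)
    pio.write_genotypes(gm, out / "genotypes.tsv")
    for stage_name, m in mats.items():
        pio.write_matrix(m, out / f"expression_{stage_name}.tsv",
                         index_label="gene")
    pio.write_phenotypes(pheno, out / "phenotypes.tsv")
    pio.write_bed(dict((f"gene{i:05d}", g) for i, g in enumerate(genes)),
                  out / "genes.bed")
    pio.write_te_bed(tes, out / "tes.bed")
    pio.write_sv_table(svs, out / "svs.tsv")
    pio.write_bed(te_pos, out / "te_positions.bed")
    pio.write_bed(gene_pos, out / "gene_positions.bed")
    presence.to_csv(out / "clusters.tsv", sep="\t",
                    index_label="cluster_id")
    with open(out / "ltr_pairs.tsv", "w") as fh:
        fh.write("element_id\tsuperfamily\tsubgenome\tltr5\tltr3\n")
        for el in elements:
            fh.write(f"{el.element_id}\t{el.superfamily}\t{el.subgenome}\t"
                     f"{el.ltr5}\t{el.ltr3}\n")
    pio.write_truth(truth, out / "truth.tsv")
    return {"n_tes": gm.n_variants, "n_accessions": gm.n_accessions,
            "n_svs": len(svs), "n_ltr": len(elements),
            "n_clusters": int(presence.shape[0])}


def _stage_pangene(cfg: PipelineConfig, out: Path) -> dict:
    p = _require(out, "clusters.tsv", "simulate", "pangene")
    presence = pd.read_csv(p, sep="\t", index_col=0)
    thresholds = pangene.default_occupancy_thresholds(presence.shape[1])
    labels, counts = pangene.classify_occupancy(presence, thresholds)
    labels.rename("label").to_csv(out / "cluster_labels.tsv", sep="\t",
                                  index_label="cluster_id")
    curves = pangene.growth_curves(
        presence, cfg.growth_subsets, cfg.growth_repeats,
        seed=cfg.stage_seed("pangene"))
    curves.to_csv(out / "growth_curves.tsv", sep="\t")
    return {"n_clusters": len(labels), **counts.to_dict()}


def _stage_pante(cfg: PipelineConfig, out: Path) -> dict:
    tes = pio.read_te_bed(_require(out, "tes.bed", "simulate", "pante"))
    svs = pio.read_sv_table(_require(out, "svs.tsv", "simulate", "pante"))
    loci = pante.build_pante_map(tes, svs)
    with open(out / "pante_map.tsv", "w") as fh:
        fh.write("te_id\tcontig\tstart\tend\tlinked_svs\tmaf\t"
                 "conservation\n")
        for l in loci:
            svs_str = ";".join(f"{s}:{a}" for s, a in l.linked_svs)
            fh.write(f"{l.te_id}\t{l.anchor.contig}\t{l.anchor.start}\t"
                     f"{l.anchor.end}\t{svs_str}\t{l.maf:.4f}\t"
                     f"{l.conservation}\n")
    if loci:
        merged = pd.DataFrame({l.te_id: l.genotypes for l in loci}).T
        pio.write_genotypes(GenotypeMatrix(merged),
                            out / "pante_genotypes.tsv")
    summary = pante.conservation_summary(loci) if loci else {}
    (out / "conservation.json").write_text(json.dumps(summary, indent=2))
    return {"n_loci": len(loci),
            "n_links": sum(len(l.linked_svs) for l in loci)}


def _stage_ltr(cfg: PipelineConfig, out: Path) -> dict:
    p = _require(out, "ltr_pairs.tsv", "simulate", "ltr")
    df = pd.read_csv(p, sep="\t", dtype=str)
    from .types import LTRElement
    elements = [LTRElement(element_id=r["element_id"],
                           superfamily=r["superfamily"],
                           subgenome=r["subgenome"],
                           ltr5=r["ltr5"], ltr3=r["ltr3"])
                for _, r in df.iterrows()]
    ltrmod.estimate_ages(elements, r=cfg.r)
    ages = pd.DataFrame(
        {"element_id": [e.element_id for e in elements],
         "superfamily": [e.superfamily for e in elements],
         "K": [e.divergence for e in elements],
         "age_years": [e.age for e in elements]}).set_index("element_id")
    ages.to_csv(out / "ltr_ages.tsv", sep="\t")
    counts, young = ltrmod.burst_profile(elements, bin_width=1e5)
    counts.to_csv(out / "ltr_burst.tsv", sep="\t")
    young.rename("young_fraction").to_csv(out / "ltr_young_fraction.tsv",
                                          sep="\t", index_label="group")
    return {"n_elements": len(elements),
            "young_fraction_total": float(young["Total"])}


def _stage_effects(cfg: PipelineConfig, out: Path) -> dict:
    gm = pio.read_genotypes(_require(out, "genotypes.tsv", "simulate",
                                     "effects"))
    truth = pio.read_truth(_require(out, "truth.tsv", "simulate",
                                    "effects"))
    calls_by_stage = {}
    for p in sorted(out.glob("expression_stage*.tsv")):
        stage_name = p.stem.replace("expression_", "")
        em = expr.filter_expressed(pio.read_matrix(p), cfg.min_tpm,
                                   cfg.max_low_fraction)
        calls = expr.classify_effects(gm, em, truth.te_target_gene,
                                      stage=stage_name, fold=cfg.fold)
        calls_by_stage[stage_name] = calls
        pd.DataFrame([dataclasses.asdict(c) for c in calls]) \
            .to_csv(out / f"effects_{stage_name}.tsv", sep="\t",
                    index=False)
    if not calls_by_stage:
        raise DependencyError("stage 'effects' needs expression_stage*.tsv "
                              "from stage 'simulate'; run it first")
    summary = expr.effect_summary(calls_by_stage)
    serializable = {
        "stages": summary["stages"],
        "consistent_promotive": sorted(summary["consistent_promotive"]),
        "consistent_suppressive": sorted(summary["consistent_suppressive"]),
    }
    (out / "effects_summary.json").write_text(
        json.dumps(serializable, indent=2))
    return {s: v["n_evaluable"] for s, v in summary["stages"].items()}


def _load_positions(out: Path, filename: str, needed_by: str):
    return pio.read_bed(_require(out, filename, "simulate", needed_by))


def _stage_gwas(cfg: PipelineConfig, out: Path) -> dict:
    gm = pio.read_genotypes(_require(out, "genotypes.tsv", "simulate",
                                     "gwas"))
    pheno = pio.read_phenotypes(_require(out, "phenotypes.tsv", "simulate",
                                         "gwas"))
    trait = pheno.columns[0]
    gm_f, report = pante.filter_variants(gm, cfg.max_missing, cfg.min_maf,
                                         cfg.max_het)
    records = assoc.association_scan(gm_f, pheno[trait])
    cutoff_p, cutoff_log = assoc.significance_cutoff(gm_f.n_variants)
    te_pos = _load_positions(out, "te_positions.bed", "gwas")
    clumps = assoc.clump(records[records["p"] <= cutoff_p], gm_f, te_pos,
                         p1=cfg.clump_p1, window_kb=cfg.clump_kb,
                         r2_min=cfg.clump_r2)
    loci = assoc.merge_locus(clumps)
    records.to_csv(out / "gwas_records.tsv", sep="\t",
                   index_label="variant")
    with open(out / "gwas_loci.bed", "w") as fh:
        for iv in loci:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{trait}\n")
    return {"n_tested": gm_f.n_variants, "cutoff_neg_log10": cutoff_log,
            "n_significant": int((records["p"] <= cutoff_p).sum()),
            "n_clumps": len(clumps), "n_loci": len(loci), **report}


def _stage_eqtl(cfg: PipelineConfig, out: Path) -> dict:
    gm = pio.read_genotypes(_require(out, "genotypes.tsv", "simulate",
                                     "eqtl"))
    truth = pio.read_truth(_require(out, "truth.tsv", "simulate", "eqtl"))
    em_path = _require(out, "expression_stage1.tsv", "simulate", "eqtl")
    em = expr.filter_expressed(pio.read_matrix(em_path), cfg.min_tpm,
                               cfg.max_low_fraction)
    gm_f, _ = pante.filter_variants(gm, cfg.max_missing, cfg.min_maf,
                                    cfg.max_het)
    pcs = assoc.expression_pcs(np.log1p(em), cfg.n_pcs)
    te_pos = _load_positions(out, "te_positions.bed", "eqtl")
    gene_pos = _load_positions(out, "gene_positions.bed", "eqtl")

    # scan the planted target genes (the interesting columns at desk scale)
    genes = [g for g in truth.te_target_gene.values() if g in em.index]
    genes = genes[:max(cfg.n_planted_expression, 5)]
    frames = []
    for g in genes:
        rec = assoc.association_scan(gm_f, em.loc[g], pcs)
        rec["target"] = g
        rec["cis"] = [
            assoc.classify_cis_trans(te_pos[v], gene_pos[g],
                                     cfg.cis_window) == "cis"
            if v in te_pos and g in gene_pos else False
            for v in rec.index]
        frames.append(rec)
    records = pd.concat(frames)
    n_tests = gm_f.n_variants
    cutoff_p, _ = assoc.significance_cutoff(n_tests)
    summary = assoc.eqtl_summary(records.dropna(subset=["p"]), cutoff_p)
    records.to_csv(out / "eqtl_records.tsv", sep="\t",
                   index_label="variant")
    summary.pop("lead_variants", None)
    (out / "eqtl_summary.json").write_text(json.dumps(summary, indent=2))
    return {"n_targets": len(genes), **summary}


def _stage_haplo(cfg: PipelineConfig, out: Path) -> dict:
    gm = pio.read_genotypes(_require(out, "genotypes.tsv", "simulate",
                                     "haplo"))
    truth = pio.read_truth(_require(out, "truth.tsv", "simulate", "haplo"))
    pheno = pio.read_phenotypes(_require(out, "phenotypes.tsv", "simulate",
                                         "haplo"))
    focal = sorted(truth.phenotype_effects) or list(gm.variants[:3])
    combos, states = haplo.build_combos(gm, focal, cfg.hap_min_freq)
    trait = pheno.columns[0]
    summary = haplo.combo_summary(combos, states, pheno, trait)
    combos.to_csv(out / "haplotype_combos.tsv", sep="\t", index=False)
    summary["per_combo"].to_csv(out / "haplotype_summary.tsv", sep="\t")
    summary["carriage"].rename("n_carried").to_csv(
        out / "haplotype_carriage.tsv", sep="\t", index_label="accession")
    return {"n_combos": len(combos),
            "n_retained": int(combos["retained"].sum()),
            "n_classifiable": len(states)}
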