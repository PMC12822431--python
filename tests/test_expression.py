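"""Expression filtering, TMM factors (with an edgeR cross-check),
nearest-gene assignment against brute force, and the 1.5x effect rule."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pantemap import (GenomicInterval, GenotypeMatrix, TEAnnotation,
                      classify_effects, classify_te_effect, effect_summary,
                      filter_expressed, nearest_gene, nearest_genes,
                      simulate_expression, simulate_genotypes, tmm_factors)
from pantemap.errors import DataError, ParameterError


class TestFilterExpressed:
    def test_gene_low_in_85_percent_removed(self):
        vals = [0.001] * 85 + [5.0] * 15
        em = pd.DataFrame([vals, [1.0] * 100], index=["low", "ok"])
        kept = filter_expressed(em, min_tpm=0.01, max_low_fraction=0.8)
        assert list(kept.index) == ["ok"]

    def test_gene_at_threshold_everywhere_kept(self):
        em = pd.DataFrame([[0.01] * 10], index=["g"])
        assert "g" in filter_expressed(em).index

    def test_matches_per_gene_tally(self):
        rng = np.random.default_rng(0)
        em = pd.DataFrame(rng.exponential(0.02, (200, 60)),
                          index=[f"g{i}" for i in range(200)])
        kept = filter_expressed(em)
        for g in em.index:
            should_keep = (em.loc[g] < 0.01).mean() <= 0.8
            assert (g in kept.index) == should_keep

    def test_empty_matrix_raises(self):
        with pytest.raises(DataError):
            filter_expressed(pd.DataFrame())


class TestTmmFactors:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, 300)
        counts = pd.DataFrame({f"s{j}": col for j in range(4)})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_depth_invariance(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, 500) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-8)

    def test_five_gene_toy_matches_hand_computation(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30, 40, 500], "b": [10, 20, 30, 40, 100]})
        f = tmm_factors(counts, logratio_trim=0.0, abundance_trim=0.0)
        # untrimmed oracle, computed from the definition: reference is
        # the library whose upper quartile of count/libsize is nearer
        # the mean upper quartile; weighted mean of M against it
        lib = counts.sum()
        uq = (counts / lib).quantile(0.75)
        ref = (uq - uq.mean()).abs().idxmin()
        other = [c for c in counts if c != ref][0]
        y, n = counts[other].to_numpy(float), lib[other]
        yr, nr = counts[ref].to_numpy(float), lib[ref]
        m = np.log2((y / n) / (yr / nr))
        w = 1.0 / ((n - y) / (n * y) + (nr - yr) / (nr * yr))
        factor = 2.0 ** (np.sum(w * m) / np.sum(w))
        expected = pd.Series({ref: 1.0, other: factor})
        expected /= np.exp(np.log(expected).mean())
        assert f[other] / f[ref] == pytest.approx(
            expected[other] / expected[ref], rel=1e-9)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_agrees_with_edger(self, tmp_path):
        rng = np.random.default_rng(0)
        base = rng.lognormal(4, 1.5, 800)
        counts = pd.DataFrame(
            {f"s{j}": rng.poisson(base * rng.uniform(0.5, 2))
             for j in range(5)})
        counts.iloc[:50, 0] *= 8  # composition bias in one library
        counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.delim("{tmp_path}/counts.tsv", '
            'row.names=1))\n'
            'cat(calcNormFactors(x, method="TMM"), sep="\\n")\n')
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert res.returncode == 0, res.stderr
        edger = np.array([float(v) for v in res.stdout.split()])
        ours = tmm_factors(counts).to_numpy()
        assert np.max(np.abs(ours / edger - 1)) < 0.02

    def test_zero_library_raises(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [1, 2]})
        with pytest.raises(DataError):
            tmm_factors(counts)


def _te_at(start, end, contig="c1"):
    return TEAnnotation("te", "g", GenomicInterval(contig, start, end))


class TestNearestGene:
    def test_te_inside_gene_distance_zero(self):
        genes = {"g1": GenomicInterval("c1", 100, 1000, "+")}
        gid, dist = nearest_gene(_te_at(300, 400), genes)
        assert gid == "g1" and dist == 0

    def test_signed_distance_upstream_negative(self):
        genes = {"g1": GenomicInterval("c1", 1000, 2000, "+")}
        _, dist = nearest_gene(_te_at(500, 600), genes)
        assert dist == -400  # upstream of a + gene
        genes_minus = {"g1": GenomicInterval("c1", 1000, 2000, "-")}
        _, dist = nearest_gene(_te_at(500, 600), genes_minus)
        assert dist == 400  # downstream of a - gene

    def test_equidistant_tie_break_by_tss_then_id(self):
        # TE at [900, 1000); gene gap 100 on both sides
        genes = {"right": GenomicInterval("c1", 1100, 2000, "+"),
                 "left": GenomicInterval("c1", 100, 800, "+")}
        gid, _ = nearest_gene(_te_at(900, 1000), genes)
        # TSS of "right" (1100) is 100 from the TE; TSS of "left" (100)
        # is 800 away -> "right" wins on the TSS tie-break
        assert gid == "right"

    def test_no_gene_on_contig_unassigned(self):
        genes = {"g1": GenomicInterval("c2", 0, 100)}
        assert nearest_gene(_te_at(0, 50), genes) == (None, None)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        genes = {}
        for i in range(120):
            s = int(rng.integers(0, 100_000))
            genes[f"g{i}"] = GenomicInterval(
                f"c{int(rng.integers(2))}", s, s + int(rng.integers(1, 3000)),
                str(rng.choice(["+", "-"])))
        tes = []
        for i in range(150):
            s = int(rng.integers(0, 100_000))
            tes.append(TEAnnotation(
                f"te{i}", "g",
                GenomicInterval(f"c{int(rng.integers(2))}", s,
                                s + int(rng.integers(50, 500)))))
        table = nearest_genes(tes, genes)
        for te in tes:
            # brute force: min gap, then TSS gap, then id
            best = None
            for gid, giv in genes.items():
                if giv.contig != te.interval.contig:
                    continue
                gap = te.interval.gap_to(giv)
                tss = giv.end - 1 if giv.strand == "-" else giv.start
                tgap = min(abs(te.interval.start - tss),
                           abs(te.interval.end - 1 - tss))
                key = (gap, tgap, gid)
                if best is None or key < best:
                    best = key
            expected = best[2] if best else None
            assert table.loc[te.te_id, "gene_id"] == expected or \
                (expected is None and pd.isna(table.loc[te.te_id, "gene_id"]))


class TestClassifyTeEffect:
    acc = [f"a{i}" for i in range(20)]

    def _call(self, mean_with, mean_without, eps=0.0):
        dosage = pd.Series([2.0] * 10 + [0.0] * 10, index=self.acc)
        expr = pd.Series([mean_with] * 10 + [mean_without] * 10,
                         index=self.acc)
        return classify_te_effect("te", "g", dosage, expr, eps=eps)

    def test_ratio_exactly_fold_is_promotive(self):
        assert self._call(3.0, 2.0).effect == "promotive"  # 1.5 inclusive

    def test_equal_means_none(self):
        assert self._call(2.0, 2.0).effect == "none"

    def test_reciprocal_bound_suppressive(self):
        call = self._call(1.0, 1.6)
        assert call.ratio == pytest.approx(0.625)
        assert call.effect == "suppressive"

    def test_small_group_unevaluable(self):
        dosage = pd.Series([2.0] * 3 + [0.0] * 17, index=self.acc)
        expr = pd.Series(1.0, index=self.acc)
        call = classify_te_effect("te", "g", dosage, expr, min_group=5)
        assert call.effect == "unevaluable"

    def test_constant_genotype_unevaluable(self):
        dosage = pd.Series(2.0, index=self.acc)
        expr = pd.Series(1.0, index=self.acc)
        assert classify_te_effect("te", "g", dosage, expr).effect == \
            "unevaluable"

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        dosage = pd.Series(rng.integers(0, 3, 40).astype(float),
                           index=[f"a{i}" for i in range(40)])
        expr = pd.Series(rng.lognormal(1, 1, 40), index=dosage.index)
        base = classify_te_effect("te", "g", dosage, expr, eps=0.01)
        scaled = classify_te_effect("te", "g", dosage, expr * 37.0,
                                    eps=0.01 * 37.0)
        assert base.effect == scaled.effect

    def test_planted_effects_detected_with_high_sensitivity(self):
        gm, _ = simulate_genotypes(300, 200, fixed_fraction=0.0,
                                   maf_law=("constant", 0.3), seed=21)
        planted = {t: 2.0 for t in list(gm.variants)[:100]}
        mats, truth = simulate_expression(gm, planted, noise_cv=0.2,
                                          stages=1, seed=21)
        calls = classify_effects(gm, mats["stage1"], truth.te_target_gene,
                                 stage="stage1")
        by_te = {c.te_id: c for c in calls}
        planted_hits = sum(by_te[t].effect == "promotive" for t in planted)
        nulls = [t for t in gm.variants if t not in planted]
        null_hits = sum(by_te[t].effect == "promotive" for t in nulls)
        assert planted_hits / len(planted) >= 0.95
        assert null_hits / len(nulls) <= 0.05


class TestEffectSummary:
    def _calls(self, n_promo, n_supp, stage):
        calls = []
        for i in range(n_promo):
            calls.append(_mk_call(f"p{i}", stage, "promotive"))
        for i in range(n_supp):
            calls.append(_mk_call(f"s{i}", stage, "suppressive"))
        return calls

    def test_printed_stage_counts_reproduce_percentages(self):
        summary = effect_summary({
            "20DAF": self._calls(7319, 3647, "20DAF"),
            "40DAF": self._calls(5964, 2968, "40DAF"),
        })
        assert summary["stages"]["20DAF"]["promotive_pct"] == \
            pytest.approx(66.74, abs=0.005)
        assert summary["stages"]["40DAF"]["promotive_pct"] == \
            pytest.approx(66.77, abs=0.005)

    def test_percentages_sum_to_100(self):
        s = effect_summary({"s": self._calls(30, 20, "s")})["stages"]["s"]
        assert s["promotive_pct"] + s["suppressive_pct"] == \
            pytest.approx(100.0)

    def test_single_stage_consistency_equals_class_sets(self):
        summary = effect_summary({"s": self._calls(3, 2, "s")})
        assert summary["consistent_promotive"] == {"p0", "p1", "p2"}
        assert summary["consistent_suppressive"] == {"s0", "s1"}

    def test_cross_stage_intersection(self):
        s1 = [_mk_call("a", "s1", "promotive"),
              _mk_call("b", "s1", "promotive"),
              _mk_call("c", "s1", "suppressive")]
        s2 = [_mk_call("a", "s2", "promotive"),
              _mk_call("b", "s2", "none"),
              _mk_call("c", "s2", "suppressive")]
        summary = effect_summary({"s1": s1, "s2": s2})
        assert summary["consistent_promotive"] == {"a"}
        assert summary["consistent_suppressive"] == {"c"}

    def test_no_calls_raises(self):
        with pytest.raises(DataError):
            effect_summary({"s": []})


def _mk_call(te_id, stage, effect):
    from pantemap.types import EffectCall
    return EffectCall(te_id, f"g_{te_id}", stage, 1.0, 1.0, 1.0, effect,
                      10, 10)
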