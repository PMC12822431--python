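"""Association engine: OLS scan calibration and recovery, the 1/n
cutoff, cis/trans partitioning, LD r^2, greedy clumping against a
brute-force oracle, and locus merging."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pantemap import (GenomicInterval, GenotypeMatrix, association_scan,
                      classify_cis_trans, clump, eqtl_summary,
                      expression_pcs, ld_r2, merge_locus,
                      significance_cutoff, simulate_genotypes,
                      simulate_phenotype)
from pantemap.errors import DataError, ParameterError
from pantemap.types import Clump


class TestAssociationScan:
    def test_exact_proportionality_recovers_beta(self):
        gm, _ = simulate_genotypes(100, 10, fixed_fraction=0.0,
                                   maf_law=("constant", 0.4), seed=1)
        y = 3.0 * gm.dosages.iloc[0] + 1.0
        rec = association_scan(gm, y)
        assert rec["beta"].iloc[0] == pytest.approx(3.0)
        assert rec["p"].iloc[0] < 1e-100

    def test_planted_qtl_beta_within_2_se(self):
        gm, _ = simulate_genotypes(500, 50, fixed_fraction=0.0,
                                   maf_law=("constant", 0.3), seed=2)
        te = gm.variants[0]
        pheno, _ = simulate_phenotype(gm, {te: 1.0}, heritability=0.5,
                                      seed=2)
        rec = association_scan(gm, pheno.iloc[:, 0])
        assert abs(rec.loc[te, "beta"] - 1.0) < 2 * rec.loc[te, "se"]

    def test_null_pvalues_uniform(self):
        gm, _ = simulate_genotypes(300, 500, fixed_fraction=0.0,
                                   maf_law=("uniform", 0.1, 0.5), seed=3)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=gm.n_accessions),
                      index=gm.accessions)
        rec = association_scan(gm, y)
        ks = stats.kstest(rec["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm
        gm, _ = simulate_genotypes(80, 5, fixed_fraction=0.0,
                                   maf_law=("constant", 0.3),
                                   missing_rate=0.05, seed=4)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=80), index=gm.accessions)
        cov = pd.DataFrame({"c1": rng.normal(size=80)},
                           index=gm.accessions)
        rec = association_scan(gm, y, cov)
        for v in gm.variants:
            d = gm.dosages.loc[v]
            ok = d.notna()
            x = sm.add_constant(np.column_stack([cov.loc[ok, "c1"], d[ok]]))
            fit = sm.OLS(y[ok], x).fit()
            assert rec.loc[v, "beta"] == pytest.approx(fit.params.iloc[-1])
            assert rec.loc[v, "se"] == pytest.approx(fit.bse.iloc[-1])
            assert rec.loc[v, "p"] == pytest.approx(fit.pvalues.iloc[-1])

    def test_zero_variance_variant_flagged(self):
        d = pd.DataFrame([[2.0] * 10, [0, 1] * 5],
                         index=["fixed", "poly"],
                         columns=[f"a{i}" for i in range(10)])
        gm = GenotypeMatrix(d)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=10), index=d.columns)
        rec = association_scan(gm, y)
        assert rec.loc["fixed", "degenerate"]
        assert not rec.loc["poly", "degenerate"]

    def test_missing_dosage_dropped_pairwise(self):
        d = pd.DataFrame([[0, 1, 2, np.nan, 2, 0, 1, 2]],
                         index=["v"], columns=[f"a{i}" for i in range(8)])
        gm = GenotypeMatrix(d)
        y = pd.Series(range(8), index=d.columns, dtype=float)
        rec = association_scan(gm, y)
        assert rec.loc["v", "n_used"] == 7


class TestSignificanceCutoff:
    def test_n_ten(self):
        p, neg = significance_cutoff(10)
        assert p == 0.1 and neg == 1.0

    def test_genome_wide_n(self):
        _, neg = significance_cutoff(148_323)
        assert neg == pytest.approx(math.log10(148_323))
        assert neg == pytest.approx(5.1712, abs=1e-4)

    def test_degenerate_n_one(self):
        p, neg = significance_cutoff(1)
        assert p == 1.0 and neg == 0.0

    def test_zero_raises(self):
        with pytest.raises(ParameterError):
            significance_cutoff(0)


class TestCisTrans:
    gene = GenomicInterval("c1", 5_000_000, 5_010_000)

    def test_variant_inside_gene_is_cis(self):
        v = GenomicInterval("c1", 5_005_000, 5_005_001)
        assert classify_cis_trans(v, self.gene) == "cis"

    def test_exactly_one_mb_inclusive(self):
        v = GenomicInterval("c1", 6_010_000 + 1_000_000 - 1,
                            6_010_000 + 1_000_000)
        # gap from gene end (5_010_000) to variant start = 1_000_000 + ...
        v = GenomicInterval("c1", 6_010_000, 6_010_001)
        assert classify_cis_trans(v, self.gene) == "cis"  # gap = 1 Mb

    def test_beyond_one_mb_is_trans(self):
        v = GenomicInterval("c1", 6_010_001, 6_010_002)
        assert classify_cis_trans(v, self.gene) == "trans"

    def test_different_contig_is_trans(self):
        v = GenomicInterval("c2", 5_005_000, 5_005_001)
        assert classify_cis_trans(v, self.gene) == "trans"


class TestLdR2:
    idx = [f"a{i}" for i in range(8)]

    def test_identical_vectors(self):
        a = pd.Series([0, 1, 2, 0, 1, 2, 0, 1], index=self.idx,
                      dtype=float)
        assert ld_r2(a, a.copy()) == pytest.approx(1.0)

    def test_complement_vector(self):
        a = pd.Series([0, 1, 2, 0, 1, 2, 0, 1], index=self.idx,
                      dtype=float)
        assert ld_r2(a, 2.0 - a) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(5)
        idx = [f"a{i}" for i in range(2000)]
        a = pd.Series(rng.binomial(2, 0.3, 2000), index=idx, dtype=float)
        b = pd.Series(rng.binomial(2, 0.3, 2000), index=idx, dtype=float)
        assert ld_r2(a, b) < 0.01

    def test_constant_vector_undefined(self):
        a = pd.Series([0, 1, 2, 0, 1, 2, 0, 1], index=self.idx,
                      dtype=float)
        b = pd.Series(1.0, index=self.idx)
        assert math.isnan(ld_r2(a, b))


def _brute_force_clump(records, gm, positions, p1, window_kb, r2_min):
    """Independent greedy reimplementation used as the oracle."""
    sig = {v: records.at[v, "p"] for v in records.index
           if records.at[v, "p"] <= p1}
    unassigned = set(sig)
    clumps = []
    while unassigned:
        idx = min(unassigned,
                  key=lambda v: (sig[v], positions[v].contig,
                                 positions[v].start, v))
        unassigned.discard(idx)
        members = [idx]
        for other in sorted(unassigned,
                            key=lambda v: (sig[v], positions[v].contig,
                                           positions[v].start, v)):
            if positions[other].contig != positions[idx].contig:
                continue
            if abs(positions[other].start - positions[idx].start) > \
                    window_kb * 1000:
                continue
            a = gm.dosages.loc[idx].to_numpy()
            b = gm.dosages.loc[other].to_numpy()
            ok = ~(np.isnan(a) | np.isnan(b))
            if a[ok].var() <= 0 or b[ok].var() <= 0:
                r2 = 0.0
            else:
                r2 = np.corrcoef(a[ok], b[ok])[0, 1] ** 2
            if r2 >= r2_min:
                members.append(other)
                unassigned.discard(other)
        clumps.append((idx, tuple(sorted(members))))
    return clumps


def _random_instance(seed, n_var=60, n_acc=80):
    rng = np.random.default_rng(seed)
    # blocks of correlated variants to make clumping non-trivial
    n_blocks = 6
    base = rng.binomial(2, 0.3, (n_blocks, n_acc)).astype(float)
    rows, positions = [], {}
    for i in range(n_var):
        block = i % n_blocks
        row = base[block].copy()
        flip = rng.random(n_acc) < 0.15
        row[flip] = rng.binomial(2, 0.3, flip.sum())
        rows.append(row)
        contig = f"c{block % 2}"
        pos = int(rng.integers(0, 400_000))
        positions[f"v{i}"] = GenomicInterval(contig, pos, pos + 1)
    gm = GenotypeMatrix(pd.DataFrame(
        rows, index=[f"v{i}" for i in range(n_var)],
        columns=[f"a{j}" for j in range(n_acc)]))
    records = pd.DataFrame(
        {"p": 10.0 ** (-rng.uniform(0, 9, n_var))}, index=gm.variants)
    return records, gm, positions


class TestClump:
    def test_single_significant_variant(self):
        records, gm, pos = _random_instance(0, n_var=5)
        records["p"] = [1e-6, 0.5, 0.5, 0.5, 0.5]
        clumps = clump(records, gm, pos)
        assert len(clumps) == 1
        assert clumps[0].members == ["v0"]

    def test_perfect_ld_within_window_one_clump(self):
        idx = [f"a{i}" for i in range(20)]
        d = pd.Series([0, 1, 2, 0] * 5, index=idx, dtype=float)
        gm = GenotypeMatrix(pd.DataFrame({"v0": d, "v1": d}).T)
        pos = {"v0": GenomicInterval("c1", 10_000, 10_001),
               "v1": GenomicInterval("c1", 60_000, 60_001)}
        records = pd.DataFrame({"p": [1e-8, 1e-6]}, index=["v0", "v1"])
        clumps = clump(records, gm, pos)
        assert len(clumps) == 1
        assert set(clumps[0].members) == {"v0", "v1"}

    def test_nothing_significant_empty(self):
        records, gm, pos = _random_instance(1)
        records["p"] = 0.5
        assert clump(records, gm, pos) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        records, gm, pos = _random_instance(seed)
        ours = clump(records, gm, pos, p1=1e-4, window_kb=100, r2_min=0.1)
        oracle = _brute_force_clump(records, gm, pos, 1e-4, 100, 0.1)
        assert [(c.index_variant, tuple(sorted(c.members)))
                for c in ours] == oracle

    def test_output_partitions_significant_set(self):
        records, gm, pos = _random_instance(7)
        clumps = clump(records, gm, pos, p1=1e-3)
        members = [m for c in clumps for m in c.members]
        assert len(members) == len(set(members))
        assert set(members) == set(records.index[records["p"] <= 1e-3])

    def test_index_p_is_minimum(self):
        records, gm, pos = _random_instance(9)
        for c in clump(records, gm, pos, p1=1e-3):
            assert c.index_p == c.min_p <= c.max_p


class TestMergeLocus:
    def _clump(self, contig, start, end):
        return Clump("v", 1e-9, ["v"],
                     span=GenomicInterval(contig, start, end))

    def test_singleton(self):
        merged = merge_locus([self._clump("c1", 100, 200)])
        assert merged == [GenomicInterval("c1", 100, 200)]

    def test_span_rule(self):
        c = Clump("v", 1e-9, ["v", "w"],
                  span=GenomicInterval("c1", 10_000, 95_000))
        assert merge_locus([c])[0] == GenomicInterval("c1", 10_000, 95_000)

    def test_overlapping_spans_merged(self):
        merged = merge_locus([self._clump("c1", 0, 150),
                              self._clump("c1", 100, 300),
                              self._clump("c1", 500, 600),
                              self._clump("c2", 0, 100)])
        assert merged == [GenomicInterval("c1", 0, 300),
                          GenomicInterval("c1", 500, 600),
                          GenomicInterval("c2", 0, 100)]

    def test_random_matches_interval_union(self):
        rng = np.random.default_rng(11)
        clumps = []
        for _ in range(100):
            s = int(rng.integers(0, 100_000))
            clumps.append(self._clump(f"c{int(rng.integers(3))}", s,
                                      s + int(rng.integers(1, 5_000))))
        merged = merge_locus(clumps)
        # sweep-line oracle on a base-pair bitmap
        for contig in {"c0", "c1", "c2"}:
            bitmap = np.zeros(110_000, dtype=bool)
            for c in clumps:
                if c.span.contig == contig:
                    bitmap[c.span.start:c.span.end] = True
            ours = np.zeros(110_000, dtype=bool)
            for iv in merged:
                if iv.contig == contig:
                    assert not ours[iv.start:iv.end].any()  # disjoint
                    ours[iv.start:iv.end] = True
            assert (ours == bitmap).all()


class TestEqtlSummary:
    def test_printed_cis_trans_split(self):
        records = pd.DataFrame({
            "p": [1e-8] * (537_516 + 329_914),
            "cis": [True] * 537_516 + [False] * 329_914,
        })
        s = eqtl_summary(records)
        assert s["cis_pct"] == 61.97
        assert s["trans_pct"] == 38.03

    def test_all_cis(self):
        records = pd.DataFrame({"p": [1e-8, 1e-7], "cis": [True, True]})
        s = eqtl_summary(records)
        assert s["cis_pct"] == 100.0 and s["trans_pct"] == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(12)
        records = pd.DataFrame({"p": rng.uniform(0, 1e-6, 50),
                                "cis": rng.random(50) < 0.6})
        s = eqtl_summary(records)
        assert s["cis_pct"] + s["trans_pct"] == pytest.approx(100.0,
                                                              abs=0.02)

    def test_lead_variant_per_target(self):
        records = pd.DataFrame(
            {"p": [1e-8, 1e-4, 1e-6], "cis": [True, True, False],
             "target": ["gA", "gA", "gB"]},
            index=["v1", "v2", "v3"])
        s = eqtl_summary(records)
        assert s["lead_variants"] == {"gA": "v1", "gB": "v3"}


class TestTypeIError:
    def test_rejection_rate_at_nominal_alpha(self):
        # 200 permuted responses x 500 null variants, alpha = 0.05
        gm, _ = simulate_genotypes(150, 500, fixed_fraction=0.0,
                                   maf_law=("uniform", 0.1, 0.5), seed=17)
        rng = np.random.default_rng(17)
        rejections = total = 0
        for _ in range(200):
            y = pd.Series(rng.normal(size=gm.n_accessions),
                          index=gm.accessions)
            rec = association_scan(gm, y)
            p = rec["p"].dropna()
            rejections += int((p < 0.05).sum())
            total += len(p)
        rate = rejections / total
        assert 0.04 <= rate <= 0.06
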