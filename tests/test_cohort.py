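import inspect

import numpy as np
import pandas as pd
import pytest

from rhoscan.cohort import (
    allele_on_haplotype,
    bh_critical_values,
    block_distribution_test,
    em_haplotype_frequencies,
    freq_table_from_phased,
    haplotype_fisher_scan,
    hotspot_difference_test,
    odds_ratio_woolf,
    trend_scan,
)
from rhoscan.model import (
    GenotypePanel,
    HaplotypeFreqTable,
    HaplotypePanel,
    SnpInfo,
    genotypes_from_panel,
)
from rhoscan.pac import McmcConfig, PacConfig

from .conftest import make_panel
from .oracles import assignment_enum_oracle, em_grid_oracle, fisher_two_tailed_enum


def geno_panel(geno, groups=None):
    geno = np.asarray(geno, dtype=np.int8)
    n, S = geno.shape
    snps = [SnpInfo(f"rs{j + 1}", "chr6", 100 * (j + 1)) for j in range(S)]
    samples = [f"i{k}" for k in range(n)]
    return GenotypePanel(geno, snps, samples, groups or {s: "all" for s in samples})


class TestEmFrequencies:
    def test_all_homozygous_equals_chromosome_counts(self):
        g = geno_panel([[0, 2], [0, 2], [2, 0], [0, 0]])
        table = em_haplotype_frequencies(g)
        freqs = dict(zip(table.haplotypes, table.freq_by_group["all"]))
        assert freqs["01"] == pytest.approx(4 / 8)
        assert freqs["10"] == pytest.approx(2 / 8)
        assert freqs["00"] == pytest.approx(2 / 8)

    def test_double_heterozygote_matches_grid_search(self):
        # unambiguous individuals pin the frequencies; one double-het is
        # resolved by EM toward the likelier pairing
        g = geno_panel([[1, 1], [0, 2], [0, 2], [2, 0], [1, 1], [0, 0], [1, 2]])
        table = em_haplotype_frequencies(g)
        haps = [tuple(int(c) for c in h) for h in table.haplotypes]
        want = em_grid_oracle(g.genotypes, haps)
        got = table.freq_by_group["all"]
        assert np.abs(got - want).max() < 1e-3

    def test_phased_collapse_without_ambiguity_equals_counting(self, rng):
        # haplotypes drawn from {00, 11} only: no double-heterozygote carries
        # phase ambiguity (01/10 never both present)
        haps = np.array([[0, 0], [1, 1]])
        rows = haps[rng.integers(0, 2, 12)]
        panel = make_panel(rows)
        table = em_haplotype_frequencies(genotypes_from_panel(panel))
        direct = freq_table_from_phased(panel)
        d = dict(zip(direct.haplotypes, direct.freq_by_group["all"]))
        for h, f in zip(table.haplotypes, table.freq_by_group["all"]):
            assert f == pytest.approx(d.get(h, 0.0), abs=1e-7)

    def test_em_matches_grid_on_random_two_snp_panels(self, rng):
        for _ in range(5):
            true = np.array([[0, 0], [1, 1], [0, 1]])
            pick = rng.integers(0, 3, (6, 2))
            geno = true[pick[:, 0]] + true[pick[:, 1]]
            g = geno_panel(geno)
            table = em_haplotype_frequencies(g)
            haps = [tuple(int(c) for c in h) for h in table.haplotypes]
            if len(haps) > 4:
                continue
            want = em_grid_oracle(g.genotypes, haps)
            assert np.abs(table.freq_by_group["all"] - want).max() < 1e-3

    def test_all_missing_individual_dropped(self):
        g = geno_panel([[0, 2], [-1, -1], [2, 0], [0, 0]])
        table = em_haplotype_frequencies(g)
        assert table.n_chromosomes_by_group["all"] == 6


class TestBlockDistributionTest:
    def test_identical_groups_statistic_zero_p_one(self, rng):
        alleles = rng.integers(0, 2, (20, 4))
        case = make_panel(alleles, groups=None)
        control = make_panel(alleles, groups=None)
        res = block_distribution_test(case, control, n_perm=99, seed=1)
        assert res.observed_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.empirical_p == 1.0

    def test_default_permutation_count_is_1000(self):
        sig = inspect.signature(block_distribution_test)
        assert sig.parameters["n_perm"].default == 1000

    def test_single_haplotype_block_degenerates(self):
        alleles = np.tile(np.array([0, 1, 0]), (8, 1))
        case = make_panel(alleles)
        control = make_panel(alleles)
        res = block_distribution_test(case, control, n_perm=20, seed=0)
        assert res.observed_statistic == 0.0
        assert res.empirical_p == 1.0

    def test_power_on_shifted_haplotype_frequency(self, rng):
        """0.30 vs 0.10 frequency shift of one 4-SNP haplotype, 200
        individuals per group: detected at p <= 0.01 in >= 9/10 seeds."""
        haps = np.array(
            [[1, 1, 1, 1], [0, 0, 0, 0], [0, 1, 0, 1], [1, 0, 1, 0]], dtype=np.int8
        )
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            case_rows = haps[r.choice(4, 400, p=[0.30, 0.30, 0.20, 0.20])]
            ctrl_rows = haps[r.choice(4, 400, p=[0.10, 0.40, 0.25, 0.25])]
            res = block_distribution_test(
                make_panel(case_rows), make_panel(ctrl_rows), n_perm=999, seed=seed
            )
            hits += res.empirical_p <= 0.01
        assert hits >= 9

    def test_similarity_statistic_variant_runs(self, rng):
        case = make_panel(rng.integers(0, 2, (12, 3)))
        control = make_panel(rng.integers(0, 2, (12, 3)))
        res = block_distribution_test(
            case, control, n_perm=30, seed=2, statistic="similarity"
        )
        assert 0 < res.empirical_p <= 1

    def test_genotype_input_via_em(self, rng):
        gc = geno_panel(rng.integers(0, 3, (10, 2)))
        gk = geno_panel(rng.integers(0, 3, (10, 2)))
        res = block_distribution_test(gc, gk, n_perm=20, seed=3)
        assert 0 < res.empirical_p <= 1


class TestFisherScan:
    @staticmethod
    def table(freqs_by_group, n_chrom):
        n_h = len(next(iter(freqs_by_group.values())))
        return HaplotypeFreqTable(
            block=None,
            haplotypes=[format(i, f"0{max(1, n_h.bit_length())}b")[-4:] for i in range(n_h)]
            if False
            else [bin(i)[2:].zfill(4) for i in range(n_h)],
            freq_by_group={g: np.asarray(f, float) for g, f in freqs_by_group.items()},
            n_chromosomes_by_group=n_chrom,
        )

    def test_equal_tables_give_p_one(self):
        t = self.table({"case": [0.1, 0.9], "control": [0.1, 0.9]}, {"case": 100, "control": 100})
        df = haplotype_fisher_scan(t)
        assert (df["p"] == 1.0).all()

    def test_block1_c_haplotype_matches_frozen_enumeration(self):
        """Common-haplotype deficit (7.04% of 894 vs 9.91% of 5398): exact
        two-tailed p frozen from the hypergeometric enumeration oracle, and
        of the same order of magnitude as the published 0.0032."""
        t = self.table(
            {"case": [0.0704, 0.9296], "control": [0.0991, 0.9009]},
            {"case": 894, "control": 5398},
        )
        df = haplotype_fisher_scan(t, group_pair=("case", "control"))
        p = float(df.loc[df.index[0], "p"])
        assert p == pytest.approx(0.006647688691263141, abs=1e-10)
        assert p == pytest.approx(
            fisher_two_tailed_enum(63, 894 - 63, 535, 5398 - 535), abs=1e-10
        )
        assert 0.0032 / 10 < p < 0.0032 * 10

    def test_min_freq_filter(self):
        t = self.table(
            {"case": [0.04, 0.03, 0.93], "control": [0.02, 0.06, 0.92]},
            {"case": 200, "control": 200},
        )
        df = haplotype_fisher_scan(t, min_freq=0.05)
        assert len(df) == 2  # only haplotypes >5% in at least one group

    def test_bh_rank1_critical_value_for_14_tests(self):
        crit = bh_critical_values(14, q=0.05)
        assert crit[0] == pytest.approx(0.05 / 14)
        assert round(crit[0], 4) == 0.0036

    def test_bh_flags_smallest_of_14_at_0003(self, rng):
        # 14 p-values, smallest 0.003 < 0.05/14: rank-1 flagged
        freqs1, freqs2 = [], []
        n1, n2 = 894, 5398
        rngl = np.random.default_rng(5)
        # craft 14 haplotypes; one with a strong shift
        f1 = np.full(14, 1 / 14)
        f2 = f1.copy()
        f1[0], f2[0] = 0.03, 0.08
        f1, f2 = f1 / f1.sum(), f2 / f2.sum()
        t = HaplotypeFreqTable(
            None,
            [f"h{i}" for i in range(14)],
            {"case": f1, "control": f2},
            {"case": n1, "control": n2},
        )
        df = haplotype_fisher_scan(t, group_pair=("case", "control"), min_freq=0.01)
        assert len(df) == 14
        best = df.sort_values("p").iloc[0]
        assert best["p"] < 0.05 / 14
        assert bool(best["bh_significant"])

    def test_bh_flags_are_monotone(self, rng):
        for trial in range(5):
            r = np.random.default_rng(trial)
            f1 = r.dirichlet(np.ones(8))
            f2 = r.dirichlet(np.ones(8))
            t = HaplotypeFreqTable(
                None,
                [f"h{i}" for i in range(8)],
                {"a": f1, "b": f2},
                {"a": 400, "b": 600},
            )
            df = haplotype_fisher_scan(t, group_pair=("a", "b"), min_freq=0.0).sort_values("p")
            flags = df["bh_significant"].to_numpy()
            # once a larger p is flagged, all smaller p are flagged
            assert all(flags[i] or not flags[i + 1] for i in range(len(flags) - 1))


class TestOddsRatio:
    def test_identical_rows_or_one(self):
        or_, lo, hi = odds_ratio_woolf(30, 70, 30, 70)
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_row_swap_inverts(self):
        or1, lo1, hi1 = odds_ratio_woolf(721, 173, 4139, 1259)
        or2, lo2, hi2 = odds_ratio_woolf(4139, 1259, 721, 173)
        assert or2 == pytest.approx(1 / or1)
        assert lo2 == pytest.approx(1 / hi1)
        assert hi2 == pytest.approx(1 / lo1)

    def test_zero_cell_haldane_correction(self, caplog):
        or_, lo, hi = odds_ratio_woolf(5, 0, 3, 7)
        assert np.isfinite([or_, lo, hi]).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_woolf(-1, 2, 3, 4)


class TestTrendScan:
    def test_identical_groups_p_one(self):
        g = [[0, 1], [1, 2], [2, 0], [0, 1]]
        df = trend_scan(geno_panel(g), geno_panel(g))
        assert (df["stat"] == 0).all() or (df["p"] == 1).all()

    def test_allele_coding_flip_invariant(self, rng):
        gc = rng.integers(0, 3, (50, 1))
        gk = rng.integers(0, 3, (60, 1))
        p1 = trend_scan(geno_panel(gc), geno_panel(gk))["p"][0]
        p2 = trend_scan(geno_panel(2 - gc), geno_panel(2 - gk))["p"][0]
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_monomorphic_snp_flagged(self):
        df = trend_scan(geno_panel([[0], [0]]), geno_panel([[0], [0]]))
        assert df["monomorphic"].iloc[0]
        assert df["p"].iloc[0] == 1.0

    def test_power_under_additive_risk(self):
        """Per-allele OR 1.5 at MAF 0.3, 500 vs 500 individuals: p < 0.05 in
        >= 8/10 seeds."""
        p0 = 0.3
        odds_case = 1.5 * p0 / (1 - p0)
        p_case = odds_case / (1 + odds_case)
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            gc = r.binomial(2, p_case, (500, 1))
            gk = r.binomial(2, p0, (500, 1))
            df = trend_scan(geno_panel(gc), geno_panel(gk))
            hits += df["p"].iloc[0] < 0.05
        assert hits >= 8


class TestHotspotDifferenceTest:
    tiny_mcmc = McmcConfig(n_runs=1, n_samples_per_run=30, n_burnin=10, seed=0)
    tiny_pac = PacConfig(n_orders=1, seed=0)

    @staticmethod
    def panel_from(rng, n=12, S=5, prefix="s"):
        alleles = rng.integers(0, 2, (n, S)).astype(np.int8)
        alleles[0] = 1 - alleles[1]  # keep columns polymorphic
        p = make_panel(alleles)
        p.sample_of_hap = [f"{prefix}{x}" for x in p.sample_of_hap]
        p.group_of_sample = {s: "g" for s in p.sample_of_hap}
        return HaplotypePanel(
            alleles, p.snps, p.sample_of_hap, p.group_of_sample, allow_monomorphic=True
        )

    def test_identical_panels_zero_difference_p_one(self, rng):
        case = self.panel_from(rng, prefix="a")
        control = self.panel_from(np.random.default_rng(20140624), prefix="b")
        res = hotspot_difference_test(
            case, control, ("rs2", "rs4"), n_perm=9,
            mcmc=self.tiny_mcmc, cfg=self.tiny_pac, seed=5,
        )
        assert res.observed_statistic == pytest.approx(0.0, abs=1e-15)
        assert res.empirical_p == 1.0

    def test_default_permutation_count_is_250(self):
        sig = inspect.signature(hotspot_difference_test)
        assert sig.parameters["n_perm"].default == 250
        assert McmcConfig().n_runs * McmcConfig().n_samples_per_run == 4000

    def test_small_group_rejected(self, rng):
        case = self.panel_from(rng, n=2, prefix="a")
        control = self.panel_from(np.random.default_rng(1), n=12, prefix="b")
        with pytest.raises(ValueError, match="fewer than 2"):
            hotspot_difference_test(
                case, control, ("rs2", "rs4"), n_perm=5,
                mcmc=self.tiny_mcmc, cfg=self.tiny_pac,
            )

    def test_mismatched_snp_lists_rejected(self, rng):
        case = self.panel_from(rng, prefix="a")
        control = self.panel_from(np.random.default_rng(1), S=4, prefix="b")
        with pytest.raises(ValueError, match="identical SNP list"):
            hotspot_difference_test(
                case, control, ("rs2", "rs4"), n_perm=5,
                mcmc=self.tiny_mcmc, cfg=self.tiny_pac,
            )


class TestAlleleOnHaplotype:
    def test_unambiguous_carriage_recovered_exactly(self):
        block_haps = {f"i{k}": ("AA", "BB") for k in range(5)}
        typings = {f"i{k}": ("X", "Y") for k in range(5)}
        # X always with AA, Y always with BB is one ML solution; make it
        # unambiguous via a homozygous anchor individual
        block_haps["anchor"] = ("AA", "AA")
        typings["anchor"] = ("X", "X")
        res = allele_on_haplotype(block_haps, typings)
        assert res.percent[("AA", "X")] == pytest.approx(100.0, abs=1e-6)
        assert res.percent[("BB", "Y")] == pytest.approx(100.0, abs=1e-6)

    def test_six_individual_mixture_matches_enumeration_oracle(self):
        block_haps = {
            "i1": ("AA", "AA"),
            "i2": ("AA", "BB"),
            "i3": ("BB", "BB"),
            "i4": ("AA", "BB"),
            "i5": ("BB", "CC"),
            "i6": ("AA", "BB"),  # ambiguous double-heterozygote
        }
        typings = {
            "i1": ("X", "X"),
            "i2": ("X", "Y"),
            "i3": ("Y", "Y"),
            "i4": ("X", "Y"),
            "i5": ("Y", "Z"),
            "i6": ("X", "Y"),
        }
        want = assignment_enum_oracle(block_haps, typings)
        res = allele_on_haplotype(block_haps, typings)
        for key, pct in want.items():
            assert res.percent[key] == pytest.approx(pct, abs=1.0)

    def test_table_style_formatting(self):
        block_haps = {}
        typings = {}
        for k in range(9):
            block_haps[f"c{k}"] = ("H1", "H1")
            typings[f"c{k}"] = ("*06:01", "*06:01")
        block_haps["d"] = ("H2", "H2")
        typings["d"] = ("*06:01", "*06:01")
        res = allele_on_haplotype(block_haps, typings)
        assert res.format_haplotype("H1") == "*06:01 (90%)"

    def test_untyped_individuals_counted_not_fatal(self):
        block_haps = {"i1": ("AA", "AA")}
        typings = {"i1": ("X", "X"), "ghost": ("Y", "Y")}
        res = allele_on_haplotype(block_haps, typings)
        assert res.n_excluded == 1
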