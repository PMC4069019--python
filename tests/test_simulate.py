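import filecmp

import numpy as np
import pytest

from rhoscan.model import RecombinationMap
from rhoscan.simulate import (
    SimParams,
    attach_multiallelic_locus,
    flat_map,
    generate_fixture_suite,
    hotspot_map,
    interval_map_from_bp,
    simulate_allele_linked_hotspot,
    simulate_case_control_study,
    simulate_panel,
)


def small_params(**kw) -> SimParams:
    defaults = dict(
        n_haplotypes=20,
        theta=8.0,
        rho_map_true=flat_map(10_000, 4e-4),
        maf_ascertainment=0.05,
        seed=1,
    )
    defaults.update(kw)
    return SimParams(**defaults)


def four_gamete_violations(alleles: np.ndarray) -> int:
    n, S = alleles.shape
    bad = 0
    for i in range(S):
        for j in range(i + 1, S):
            pairs = {(int(a), int(b)) for a, b in zip(alleles[:, i], alleles[:, j])}
            bad += len(pairs) == 4
    return bad


class TestSimulatePanel:
    def test_no_recombination_perfect_phylogeny(self):
        """rho = 0 with infinite sites: the four-gamete test never fails."""
        for seed in range(5):
            p, _ = simulate_panel(
                small_params(rho_map_true=flat_map(10_000, 0.0), seed=seed, theta=10.0)
            )
            assert four_gamete_violations(p.alleles) == 0

    def test_watterson_expected_segregating_sites(self):
        """Pre-ascertainment S matches theta * H_{n-1} within Monte-Carlo
        error over 200 replicates."""
        theta, n = 5.0, 20
        counts = [
            simulate_panel(small_params(theta=theta, maf_ascertainment=0.0, seed=s))[1].n_raw_sites
            for s in range(200)
        ]
        h = sum(1 / i for i in range(1, n))
        expect = theta * h
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 4 * se + 0.5

    def test_ld_decay_monotone_in_rho(self):
        """Mean adjacent-pair r^2 among common SNPs decreases from low to
        high rho (100 replicates per level)."""
        means = []
        for rho in (0.0, 2e-3, 2e-2):
            vals = []
            for s in range(100):
                p, _ = simulate_panel(
                    small_params(
                        rho_map_true=flat_map(10_000, rho),
                        seed=s,
                        theta=10.0,
                        n_haplotypes=40,
                        maf_ascertainment=0.1,
                    )
                )
                a = p.alleles.astype(float)
                if p.n_snps < 2:
                    continue
                r2 = [
                    np.corrcoef(a[:, i], a[:, i + 1])[0, 1] ** 2
                    for i in range(p.n_snps - 1)
                ]
                vals.append(np.nanmean(r2))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_reproducible_and_ascertained(self):
        p1, t1 = simulate_panel(small_params(seed=7))
        p2, _ = simulate_panel(small_params(seed=7))
        assert p1 == p2
        assert (p1.maf() >= 0.05 - 1e-12).all()
        assert t1.interval_map.n_intervals == p1.n_snps - 1

    def test_too_little_variation_is_an_error(self):
        with pytest.raises(ValueError, match="theta"):
            simulate_panel(small_params(theta=0.05, seed=3))


class TestCaseControlStudy:
    base = SimParams(
        n_haplotypes=40,
        theta=25.0,
        rho_map_true=hotspot_map(60_000, 4e-4, 28_500, 31_500, 10.0),
        seed=0,
    )

    def test_output_contract(self):
        case, ctrl, truth = simulate_case_control_study(
            self.base, 1, 10.0, n_case_ind=15, n_ctrl_ind=20, seed=2, n_snps=20
        )
        assert case.alleles.shape[0] == 30
        assert ctrl.alleles.shape[0] == 40
        assert [s.id for s in case.snps] == [s.id for s in ctrl.snps]
        assert np.array_equal(case.positions, ctrl.positions)
        assert case.groups() == ["case"] and ctrl.groups() == ["control"]
        i0, i1 = truth.hotspot_span
        assert truth.hotspot_flanks == (truth.snps[i0].id, truth.snps[i1 + 1].id)

    def test_fixed_seed_reproduces_exactly(self):
        a = simulate_case_control_study(self.base, 1, 1.0, 10, 10, seed=4, n_snps=15)
        b = simulate_case_control_study(self.base, 1, 1.0, 10, 10, seed=4, n_snps=15)
        assert a[0] == b[0] and a[1] == b[1]

    def test_truth_maps_reflect_multiplier(self):
        _, _, truth = simulate_case_control_study(
            self.base, 1, 10.0, 10, 10, seed=5, n_snps=20
        )
        assert truth.case_bp_map.rates[1] == pytest.approx(
            10.0 * truth.control_bp_map.rates[1]
        )
        i = truth.hotspot_span[0]
        assert (
            truth.case_interval_map.rates[i] > truth.control_interval_map.rates[i]
        )

    def test_bad_multiplier_rejected(self):
        with pytest.raises(ValueError, match="multiplier"):
            simulate_case_control_study(self.base, 1, 0.0, 10, 10)


class TestAlleleLinked:
    base = SimParams(
        n_haplotypes=60,
        theta=25.0,
        rho_map_true=hotspot_map(60_000, 4e-4, 28_500, 31_500, 1.0),
        seed=0,
    )

    def test_truth_record_contract(self):
        panel, truth = simulate_allele_linked_hotspot(
            self.base, 0.3, 20.0, hotspot_piece=1, seed=3, n_snps=15
        )
        assert truth.split_snp in panel.snp_ids
        assert truth.on_bp_map.rates[1] == pytest.approx(20.0 * truth.off_bp_map.rates[1])
        j = panel.snp_index(truth.split_snp)
        assert int(panel.alleles[:, j].sum()) == truth.n_carrier_haplotypes
        # split SNP frequency within binomial noise of the target MAF
        k, n = truth.n_carrier_haplotypes, panel.n_haplotypes
        assert abs(k / n - 0.3) < 4 * np.sqrt(0.3 * 0.7 / n) + 1e-9

    def test_reproducible(self):
        a, _ = simulate_allele_linked_hotspot(self.base, 0.2, 5.0, 1, seed=6, n_snps=15)
        b, _ = simulate_allele_linked_hotspot(self.base, 0.2, 5.0, 1, seed=6, n_snps=15)
        assert a == b


class TestMultiallelicLocus:
    def test_deterministic_and_round_trip(self):
        from rhoscan.cohort import allele_on_haplotype

        p, _ = simulate_panel(small_params(seed=9, theta=10.0))
        block = (0, min(1, p.n_snps - 1))
        haps = sorted(set(p.restrict_snps(block).hap_strings()))
        carriage = {h: {f"*{i + 1:02d}:01": 1.0} for i, h in enumerate(haps)}
        t1 = attach_multiallelic_locus(p, block, carriage, seed=5)
        t2 = attach_multiallelic_locus(p, block, carriage, seed=5)
        assert t1 == t2
        # deterministic carriage: recovered at exactly 100%
        block_haps = {}
        rows_of = {}
        for i, s in enumerate(p.sample_of_hap):
            rows_of.setdefault(s, []).append(i)
        strings = p.restrict_snps(block).hap_strings()
        for s, rows in rows_of.items():
            block_haps[s] = (strings[rows[0]], strings[rows[1]])
        res = allele_on_haplotype(block_haps, t1)
        for i, h in enumerate(haps):
            assert res.percent[(h, f"*{i + 1:02d}:01")] == pytest.approx(100.0, abs=1e-6)

    def test_noisy_carriage_recovered_within_tolerance(self):
        """90/10 carriage on a haplotype, 500 individuals: the carriage
        proportion is recovered within 4 percentage points in >= 9/10 seeds."""
        from rhoscan.cohort import allele_on_haplotype

        from .conftest import make_panel

        carriage = {"00": {"X": 0.9, "Y": 0.1}, "11": {"Y": 1.0}}
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            rows = np.array([[0, 0], [1, 1]])[r.integers(0, 2, 1000)]
            panel = make_panel(rows)
            typings = attach_multiallelic_locus(panel, (0, 1), carriage, seed=seed)
            strings = panel.hap_strings()
            block_haps = {}
            for i in range(500):
                block_haps[f"s{i}"] = (strings[2 * i], strings[2 * i + 1])
            res = allele_on_haplotype(block_haps, typings)
            counts = res.expected_counts
            got = counts.loc["00", "X"] / counts.loc["00"].sum()
            hits += abs(got - 0.9) < 0.04
        assert hits >= 9

    def test_missing_carriage_distribution_rejected(self):
        p, _ = simulate_panel(small_params(seed=9, theta=10.0))
        block = (0, min(1, p.n_snps - 1))
        with pytest.raises(KeyError):
            attach_multiallelic_locus(p, block, {"nonexistent": {"X": 1.0}}, seed=1)


class TestFixtureSuite:
    def test_byte_identical_trees_and_inventory(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        files1 = generate_fixture_suite(d1, master_seed=11)
        files2 = generate_fixture_suite(d2, master_seed=11)
        assert files1 == files2
        for name in files1:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name
        inventory = (d1 / "inventory.tsv").read_text().splitlines()
        listed = {line.split("\t")[0] for line in inventory[1:]}
        for name in files1:
            if name not in ("inventory.tsv", "MANIFEST.txt"):
                assert name in listed


class TestNullStudyFixture:
    def test_null_study_passes_difference_test_in_most_seeds(self, tmp_path):
        """The fixture suite's null study (multiplier 1) yields p > 0.05 in
        >= 8/10 master seeds of the hotspot difference test."""
        from rhoscan.cohort import hotspot_difference_test
        from rhoscan.io import HAP_LEGEND, read_panel
        from rhoscan.pac import McmcConfig, PacConfig

        mc = McmcConfig(n_runs=1, n_samples_per_run=40, n_burnin=20, seed=0)
        pc = PacConfig(n_orders=1, seed=0)
        ok = 0
        for seed in range(10):
            d = tmp_path / f"s{seed}"
            generate_fixture_suite(d, master_seed=seed)
            case = read_panel(d / "null_study_case.hap", HAP_LEGEND)
            ctrl = read_panel(d / "null_study_ctrl.hap", HAP_LEGEND)
            inv = (d / "inventory.tsv").read_text()
            line = next(
                l for l in inv.splitlines() if l.startswith("null_study_case.hap")
            )
            flanks = line.split("hotspot_flanks=")[1].split(";")[0].split(",")
            res = hotspot_difference_test(
                case, ctrl, (flanks[0], flanks[1]), n_perm=19,
                mcmc=mc, cfg=pc, seed=seed,
            )
            ok += res.empirical_p > 0.05
        assert ok >= 8


class TestIntervalMapAggregation:
    def test_piecewise_mean_onto_snp_intervals(self):
        bp = RecombinationMap(np.array([1e-4, 1e-3]), np.array([1000.0, 1000.0]))
        m = interval_map_from_bp(bp, np.array([500, 1500]))
        # interval [500,1500): half at 1e-4, half at 1e-3
        assert m.rates[0] == pytest.approx(5.5e-4)
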