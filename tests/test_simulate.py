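"""Simulator: coalescent moments, JC69 evolution, filters, determinism."""

import numpy as np
import pytest
from scipy import stats

from mscdelim.io import LocusAlignment
from mscdelim.simulate import (
    RadFilterConfig,
    Scenario,
    SnpCall,
    apply_rad_filters,
    call_snps,
    evolve_sequences,
    generate_dataset,
    jc_expected_diff,
    scenario,
    simulate_gene_trees,
)
from mscdelim.trees import GeneTree, SpeciesTree


def one_pop_tree(theta):
    return SpeciesTree(["X"], [-1], [-1], [-1], tau=[0.0], theta=[theta])


def pair_tree(tau, theta):
    return SpeciesTree.from_newick(
        f"(A[&theta={theta}]:{tau},B[&theta={theta}]:{tau})"
        f"[&theta={theta},tau={tau}];"
    )


class TestGeneTreeSimulation:
    def test_mean_pairwise_age_matches_theta_half(self):
        theta = 0.01
        gts = simulate_gene_trees(one_pop_tree(theta), 2, 10_000, seed=1)
        ages = np.array([gt.age[2] for gt in gts])
        se = ages.std(ddof=1) / np.sqrt(len(ages))
        assert abs(ages.mean() - theta / 2) < 3 * se

    def test_between_species_coalescence_respects_tau(self):
        tau = 0.005
        gts = simulate_gene_trees(pair_tree(tau, 0.01), 1, 500, seed=2)
        assert min(gt.age[2] for gt in gts) >= tau

    def test_same_seed_identical(self):
        st = one_pop_tree(0.01)
        a = simulate_gene_trees(st, 3, 5, seed=3)
        b = simulate_gene_trees(st, 3, 5, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.age, y.age)
            assert np.array_equal(x.parent, y.parent)

    def test_zero_samples_error(self):
        with pytest.raises(ValueError):
            simulate_gene_trees(one_pop_tree(0.01), 0, 5, seed=1)

    def test_coalescent_times_exponential_ks(self):
        """2 lineages, 1 population: T2 ~ Exponential(rate 2/theta)."""
        theta = 0.01
        gts = simulate_gene_trees(one_pop_tree(theta), 2, 10_000, seed=5)
        ages = np.array([gt.age[2] for gt in gts])
        stat = stats.kstest(ages, "expon", args=(0, theta / 2))
        assert stat.pvalue > 0.01

    def test_matches_msprime_distribution(self):
        """Independent oracle: same scenario simulated with msprime."""
        msprime = pytest.importorskip("msprime")
        theta = 0.01
        ours = np.array(
            [gt.age[2] for gt in simulate_gene_trees(one_pop_tree(theta), 2, 4000, seed=6)]
        )
        theirs = np.array(
            [
                ts.max_root_time
                for ts in msprime.sim_ancestry(
                    samples=2,
                    ploidy=1,
                    population_size=theta / 2,
                    num_replicates=4000,
                    random_seed=7,
                )
            ]
        )
        assert stats.ks_2samp(ours, theirs).pvalue > 0.01


class TestSequenceEvolution:
    def two_tip_tree(self, total_path):
        h = total_path / 2
        return GeneTree(
            ["a", "b"],
            np.array([0, 0]),
            np.array([0.0, 0.0, h]),
            np.array([2, 2, -1]),
            np.array([-1, -1, 0]),
            np.array([-1, -1, 1]),
        )

    def test_zero_path_identical_sequences(self):
        loc = evolve_sequences([self.two_tip_tree(0.0)], 200, seed=1)[0]
        assert loc.rows["a"] == loc.rows["b"]

    def test_mismatch_fraction_matches_jc_expectation(self):
        d = 0.01
        loc = evolve_sequences([self.two_tip_tree(d)], 50_000, seed=2)[0]
        mism = np.mean([x != y for x, y in zip(loc.rows["a"], loc.rows["b"])])
        p = jc_expected_diff(d)
        se = np.sqrt(p * (1 - p) / 50_000)
        assert abs(mism - p) < 3 * se
        assert p == pytest.approx(0.009934, abs=1e-6)

    def test_same_seed_identical(self):
        gt = self.two_tip_tree(0.01)
        a = evolve_sequences([gt], 100, seed=3)[0]
        b = evolve_sequences([gt], 100, seed=3)[0]
        assert a.rows == b.rows

    def test_locus_length_validated(self):
        with pytest.raises(ValueError):
            evolve_sequences([self.two_tip_tree(0.01)], 0, seed=1)


def _locus(lid, rows):
    return LocusAlignment(lid, rows)


class TestRadFilters:
    def test_maf_threshold_strict(self):
        # minor allele in 1 of 25 -> MAF 0.04 -> dropped at min_maf 0.05
        alleles = {f"i{k:02d}": "A" for k in range(24)}
        alleles["i24"] = "C"
        snp = SnpCall("L1", 0, alleles)
        assert snp.maf == pytest.approx(0.04)
        rows = {k: v for k, v in alleles.items()}
        loc = _locus("L1", rows)
        kept, snps, drops = apply_rad_filters(
            [loc], [snp], RadFilterConfig(), n_individuals=25
        )
        assert kept == [] and drops["low_maf_snps"] == 1 and drops["no_snp_loci"] == 1

    def test_presence_threshold(self):
        # 12 of 47 (25.5%) dropped; 15 of 47 (31.9%) retained
        def mk(lid, n):
            rows = {f"i{k:02d}": ("A" if k else "C") for k in range(n)}
            return _locus(lid, rows)

        cfg = RadFilterConfig()
        for n, expect in ((12, 0), (15, 1)):
            loc = mk("L", n)
            calls = call_snps([loc])
            kept, _, _ = apply_rad_filters([loc], calls, cfg, n_individuals=47)
            assert len(kept) == expect

    def test_single_snp_keeps_leftmost_retained(self):
        rows = {
            "i1": "AAA",
            "i2": "CCC",
            "i3": "ACA",
        }
        loc = _locus("L1", rows)
        calls = call_snps([loc])
        assert len(calls) == 3
        kept, snps, drops = apply_rad_filters(
            [loc], calls, RadFilterConfig(), n_individuals=3
        )
        assert len(kept) == 1
        assert len(snps) == 1 and snps[0].column == 0
        assert drops["extra_snps"] == 2

    def test_het_locus_dropped(self):
        loc = _locus("L1", {"i1": "AT", "i2": "CT"})
        calls = call_snps([loc], het_loci={"L1"})
        kept, _, drops = apply_rad_filters(
            [loc], calls, RadFilterConfig(), n_individuals=2
        )
        assert kept == [] and drops["het_loci"] == 1

    def test_filters_idempotent(self):
        loci, imap, truth = generate_dataset(
            Scenario(
                name="t",
                n_species=3,
                samples_per_species=4,
                n_loci=40,
                theta=0.01,
                tau_root=0.01,
                missingness=0.3,
                het_artifact_rate=0.1,
            ),
            seed=9,
        )
        calls = call_snps(loci, het_loci=truth.het_loci)
        cfg = RadFilterConfig()
        n_ind = len(imap.assignments)
        kept1, snps1, _ = apply_rad_filters(loci, calls, cfg, n_individuals=n_ind)
        calls2 = [c for c in calls if any(l.locus_id == c.locus_id for l in kept1)]
        kept2, snps2, _ = apply_rad_filters(kept1, calls2, cfg, n_individuals=n_ind)
        assert [l.locus_id for l in kept1] == [l.locus_id for l in kept2]
        assert [(s.locus_id, s.column) for s in snps1] == [
            (s.locus_id, s.column) for s in snps2
        ]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RadFilterConfig(min_maf=0.6)
        with pytest.raises(ValueError):
            RadFilterConfig(min_presence=0.0)


class TestGenerateDataset:
    def test_paper_like_shape(self):
        loci, imap, truth = generate_dataset(scenario("paper-like-small"), seed=5)
        assert len(truth.species_tree.labels) == 17
        assert all(loc.length == 143 for loc in loci)
        assert len(imap.species) == 17

    def test_no_missingness_means_everyone_present(self):
        scn = Scenario(
            name="t", n_species=2, samples_per_species=3, n_loci=10,
            theta=0.005, tau_root=0.002, missingness=0.0,
        )
        loci, imap, _ = generate_dataset(scn, seed=1)
        for loc in loci:
            assert set(loc.labels) == set(imap.assignments)

    def test_same_seed_byte_identical(self):
        scn = scenario("panmictic-pair")
        a = generate_dataset(scn, seed=4)
        b = generate_dataset(scn, seed=4)
        assert [l.rows for l in a[0]] == [l.rows for l in b[0]]
        assert a[1].assignments == b[1].assignments

    def test_inconsistent_scenario_rejected(self):
        with pytest.raises(ValueError):
            Scenario(
                name="bad", n_species=3, samples_per_species=2, n_loci=5,
                theta=0.01, tau_root=0.0,
            )

    def test_within_and_between_distances_match_expectation(self):
        """Moment check: raw distances track JC expectations of theta, 2tau+theta."""
        theta, tau = 0.005, 0.004
        scn = Scenario(
            name="m", n_species=2, samples_per_species=2, n_loci=2000,
            theta=theta, tau_root=tau, locus_length=100,
        )
        loci, imap, truth = generate_dataset(scn, seed=13)
        within, between = [], []
        for loc in loci:
            r = loc.rows
            within.append(np.mean([x != y for x, y in zip(r["A1"], r["A2"])]))
            between.append(np.mean([x != y for x, y in zip(r["A1"], r["B1"])]))
        exp_w = jc_expected_diff(theta)
        exp_b = jc_expected_diff(2 * tau + theta)
        se_w = np.std(within, ddof=1) / np.sqrt(len(within))
        se_b = np.std(between, ddof=1) / np.sqrt(len(between))
        assert abs(np.mean(within) - exp_w) < 3 * se_w
        assert abs(np.mean(between) - exp_b) < 3 * se_b
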