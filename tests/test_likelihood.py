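"""Likelihood and coalescent-density kernels against independent oracles."""

import numpy as np
import pytest
from scipy import integrate

from conftest import brute_force_jc_loglik, make_gene_tree
from mscdelim.io import LocusAlignment
from mscdelim.likelihood import (
    coal_sufficient_stats,
    jc69_pruning_loglik,
    msc_log_density,
)
from mscdelim.trees import GeneTree, SpeciesTree


class TestPruningLikelihood:
    def test_identical_single_site_zero_path(self):
        gt = make_gene_tree(("a", "b", 0.0))
        loc = LocusAlignment("L", {"a": "A", "b": "A"})
        assert jc69_pruning_loglik(gt, loc) == pytest.approx(np.log(0.25), abs=1e-12)

    def test_all_missing_column_contributes_nothing(self):
        gt = make_gene_tree(("a", "b", 0.01))
        base = jc69_pruning_loglik(gt, LocusAlignment("L", {"a": "AC", "b": "AC"}))
        with_n = jc69_pruning_loglik(
            gt, LocusAlignment("L", {"a": "ACN", "b": "ACN"})
        )
        assert with_n == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize(
        "tree, rows",
        [
            ((("a", "b", 0.02), "c", 0.05), {"a": "ACG", "b": "ACT", "c": "GCT"}),
            ((("a", "b", 0.01), "c", 0.3), {"a": "AAA", "b": "CCC", "c": "GTA"}),
            (
                (("a", "b", 0.04), ("c", "d", 0.02), 0.09),
                {"a": "ACT", "b": "A-T", "c": "GCN", "d": "GCA"},
            ),
            (
                ((("a", "b", 0.01), "c", 0.03), "d", 0.08),
                {"a": "ANC", "b": "AGC", "c": "TGC", "d": "TG-"},
            ),
        ],
    )
    def test_matches_brute_force_enumeration(self, tree, rows):
        gt = make_gene_tree(tree)
        loc = LocusAlignment("L", rows)
        assert jc69_pruning_loglik(gt, loc) == pytest.approx(
            brute_force_jc_loglik(gt, loc), abs=1e-10
        )

    def test_tip_without_sequence_is_named(self):
        gt = make_gene_tree(("a", "zz", 0.01))
        loc = LocusAlignment("L", {"a": "A", "b": "A"})
        with pytest.raises(ValueError, match="zz"):
            jc69_pruning_loglik(gt, loc)


def one_pop(theta):
    return SpeciesTree(["X"], [-1], [-1], [-1], tau=[0.0], theta=[theta])


def two_pop(tau, theta):
    return SpeciesTree.from_newick(
        f"(A[&theta={theta}]:{tau},B[&theta={theta}]:{tau})"
        f"[&theta={theta},tau={tau}];"
    )


def pair_tree_at(t, species=(0, 0)):
    gt = make_gene_tree(("a", "b", t))
    gt.tip_species = np.asarray(species, dtype=np.int64)
    return gt


class TestMscDensity:
    def test_textbook_single_pair_density(self):
        theta, t = 0.01, 0.003
        got = msc_log_density(pair_tree_at(t), one_pop(theta))
        assert got == pytest.approx(np.log(2 / theta) - 2 * t / theta, abs=1e-12)

    def test_violating_tau_gives_minus_inf(self):
        st = two_pop(0.005, 0.01)
        gt = pair_tree_at(0.003, species=(0, 1))
        assert msc_log_density(gt, st) == -np.inf

    def test_density_integrates_to_one(self):
        theta = 0.01
        st = one_pop(theta)

        def dens(t):
            return np.exp(msc_log_density(pair_tree_at(t), st))

        val, err = integrate.quad(dens, 0, 20 * theta)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_two_species_density_integrates_to_one(self):
        tau, theta = 0.005, 0.01
        st = two_pop(tau, theta)

        def dens(t):
            return np.exp(msc_log_density(pair_tree_at(t, (0, 1)), st))

        val, err = integrate.quad(dens, tau, tau + 30 * theta)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_sufficient_stats_decompose_density(self):
        """log density == sum_p c_p log(2/theta_p) - A_p / theta_p."""
        st = two_pop(0.004, 0.008)
        gt = make_gene_tree((("a", "b", 0.002), ("c", "d", 0.006), 0.011))
        gt.tip_species = np.asarray([0, 0, 1, 1], dtype=np.int64)
        c, a, valid = coal_sufficient_stats(gt, st)
        assert valid
        assert int(c.sum()) == 3
        manual = float(np.sum(c * np.log(2 / st.theta)) - np.sum(a / st.theta))
        assert msc_log_density(gt, st) == pytest.approx(manual, abs=1e-12)
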