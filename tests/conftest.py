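"""Shared fixtures: tiny hand-built trees/alignments and cached simulations."""

import itertools

import numpy as np
import pytest

from mscdelim.io import LocusAlignment, IndividualMap
from mscdelim.simulate import generate_dataset, scenario
from mscdelim.trees import GeneTree, SpeciesTree


def make_gene_tree(newick_like):
    """Build a GeneTree from (label, age) nested tuples.

    ``newick_like`` is either ``("a",)``-style leaf label strings or
    ``(left, right, age)`` triples, e.g. ``(("a", "b", 0.01), "c", 0.02)``.
    """
    labels, ages, lefts, rights = [], [], [], []

    def walk(n):
        if isinstance(n, str):
            labels.append(n)
            ages.append(0.0)
            lefts.append(-1)
            rights.append(-1)
            return len(labels) - 1
        l, r, age = n
        li = walk(l)
        ri = walk(r)
        labels.append(None)
        ages.append(age)
        lefts.append(li)
        rights.append(ri)
        return len(labels) - 1

    root = walk(newick_like)
    n = len(labels)
    # reorder: tips first, then internals
    tip_ids = [i for i in range(n) if lefts[i] < 0]
    int_ids = [i for i in range(n) if lefts[i] >= 0]
    remap = {old: new for new, old in enumerate(tip_ids + int_ids)}
    n_tips = len(tip_ids)
    age = np.zeros(n)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    tip_labels = [labels[i] for i in tip_ids]
    for old in range(n):
        new = remap[old]
        age[new] = ages[old]
        if lefts[old] >= 0:
            left[new] = remap[lefts[old]]
            right[new] = remap[rights[old]]
            parent[left[new]] = new
            parent[right[new]] = new
    return GeneTree(
        tip_labels,
        np.zeros(n_tips, dtype=np.int64),
        age,
        parent,
        left,
        right,
    )


def brute_force_jc_loglik(gene_tree, locus):
    """Independent oracle: sum over all internal-state assignments."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4}
    n = gene_tree.n_nodes
    n_tips = gene_tree.n_tips
    internals = [v for v in range(n) if gene_tree.left[v] >= 0]
    root = gene_tree.root

    def p_trans(b, same):
        e = np.exp(-4.0 * b / 3.0)
        return 0.25 + 0.75 * e if same else 0.25 - 0.25 * e

    ll = 0.0
    length = locus.length
    seqs = [locus.rows[lab] for lab in gene_tree.tip_labels]
    for site in range(length):
        tip_state = [code[s[site]] for s in seqs]
        site_lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            state = dict(zip(internals, assign))
            for t in range(n_tips):
                state[t] = tip_state[t]
            # tips with missing data: sum over their states
            missing = [t for t in range(n_tips) if tip_state[t] == 4]
            for miss_assign in itertools.product(range(4), repeat=len(missing)):
                for t, s in zip(missing, miss_assign):
                    state[t] = s
                p = 0.25  # uniform root state
                for v in range(n):
                    if v == root:
                        continue
                    par = int(gene_tree.parent[v])
                    b = float(gene_tree.age[par] - gene_tree.age[v])
                    p *= p_trans(b, state[v] == state[par])
                site_lik += p  # missing tips: plain sum = all-ones partial
        ll += np.log(site_lik)
    return ll


def constant_trace(newick, n=50):
    """A degenerate TraceLog whose samples all equal the tree's annotations."""
    from mscdelim.mcmc import McmcConfig, TraceLog, _node_names

    st = SpeciesTree.from_newick(newick)
    tau = np.tile(st.tau, (n, 1))
    theta = np.tile(st.theta, (n, 1))
    return TraceLog(
        species_tree=st,
        node_names=_node_names(st),
        tau=tau,
        theta=theta,
        loglik=np.zeros(n),
        split_flags=None,
        seed=0,
        config=McmcConfig(),
    )


@pytest.fixture(scope="session")
def two_species():
    """100 RADseq-like loci from a 2-species truth (theta .005, tau .002)."""
    loci, imap, truth = generate_dataset(scenario("two-species"), seed=11)
    return loci, imap, truth


@pytest.fixture(scope="session")
def three_deep():
    """3 candidates at 2*tau/theta = 20 (deep divergence everywhere)."""
    loci, imap, truth = generate_dataset(scenario("three-deep"), seed=3)
    return loci, imap, truth


@pytest.fixture
def toy_locus():
    return LocusAlignment(
        "toy",
        {"a": "AATCG", "b": "AATCG", "c": "ACTCG", "d": "ACTCG"},
    )


@pytest.fixture
def cherry_tree():
    return SpeciesTree.from_newick("((A,B),C);")
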