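"""Phylogenetic likelihood and multispecies-coalescent density kernels.

Two numerical primitives drive everything downstream:

* :func:`jc69_pruning_loglik` — Felsenstein pruning on a gene tree under
  JC69 with uniform base frequencies; missing states (``N``/``-``) carry
  all-ones partials, so an all-missing column has likelihood 1.
* :func:`msc_log_density` — the censored-coalescent log density of a gene
  tree embedded in a species tree: within every species-tree branch with
  parameter ``theta``, each pair of lineages coalesces at rate ``2/theta``.

Both reduce to numba kernels over flat arrays; the MCMC sampler calls the
kernels directly and caches the per-population sufficient statistics
``(c_p, A_p)`` = (number of coalescences, integrated pair time
``sum k(k-1) dt``), through which the density is linear in ``1/theta`` —
this is what makes conjugate theta updates possible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .trees import GeneTree, SpeciesTree

__all__ = [
    "encode_alignment",
    "jc69_pruning_loglik",
    "msc_log_density",
    "coal_sufficient_stats",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4, "?": 4}


def encode_alignment(locus, tip_labels):
    """Encode sequences as site-pattern codes.

    Returns ``(codes, weights)`` where ``codes`` is ``(n_tips, n_patterns)``
    int8 with A,C,G,T -> 0..3 and missing -> 4, and ``weights`` the column
    multiplicity of each distinct pattern.
    """
    missing = [lab for lab in tip_labels if lab not in locus.rows]
    if missing:
        raise ValueError(
            f"locus {locus.locus_id!r}: no sequence for tip {missing[0]!r}"
        )
    mat = np.empty((len(tip_labels), locus.length), dtype=np.int8)
    for i, lab in enumerate(tip_labels):
        mat[i] = [_CODE[c] for c in locus.rows[lab]]
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return np.ascontiguousarray(patterns), weights.astype(np.float64)


@njit(cache=True)
def _jc_prune(post, left, right, blen, codes, weights):
    n_nodes = post.shape[0]
    n_pat = codes.shape[1]
    partial = np.empty((n_nodes, n_pat, 4))
    for i in range(n_nodes):
        v = post[i]
        if left[v] < 0:
            for p in range(n_pat):
                c = codes[v, p]
                for s in range(4):
                    partial[v, p, s] = 1.0 if (c == 4 or c == s) else 0.0
        else:
            for p in range(n_pat):
                for s in range(4):
                    partial[v, p, s] = 1.0
            for ci in range(2):
                ch = left[v] if ci == 0 else right[v]
                e = np.exp(-4.0 * blen[ch] / 3.0)
                for p in range(n_pat):
                    tot = (
                        partial[ch, p, 0]
                        + partial[ch, p, 1]
                        + partial[ch, p, 2]
                        + partial[ch, p, 3]
                    )
                    base = 0.25 * (1.0 - e) * tot
                    for s in range(4):
                        partial[v, p, s] *= base + e * partial[ch, p, s]
    root = post[n_nodes - 1]
    ll = 0.0
    for p in range(n_pat):
        site = 0.25 * (
            partial[root, p, 0]
            + partial[root, p, 1]
            + partial[root, p, 2]
            + partial[root, p, 3]
        )
        ll += weights[p] * np.log(site)
    return ll


def jc69_pruning_loglik(gene_tree: GeneTree, locus) -> float:
    """Log-likelihood of one locus on a gene tree under JC69.

    Tips of the tree are matched to alignment rows by label; a tip without
    a sequence is an error.  Branch lengths are node-age differences, in
    expected substitutions per site.
    """
    codes, weights = encode_alignment(locus, gene_tree.tip_labels)
    n = gene_tree.n_nodes
    full_codes = np.full((n, codes.shape[1]), 4, dtype=np.int8)
    full_codes[: gene_tree.n_tips] = codes
    blen = np.zeros(n)
    for v in range(n):
        p = gene_tree.parent[v]
        if p >= 0:
            bl = gene_tree.age[p] - gene_tree.age[v]
            if bl < 0:
                raise ValueError(f"negative branch length at node {v}")
            blen[v] = bl
    post = np.asarray(gene_tree.postorder(), dtype=np.int64)
    return float(
        _jc_prune(post, gene_tree.left, gene_tree.right, blen, full_codes, weights)
    )


@njit(cache=True)
def _sp_mrca(a, b, sp_parent, sp_depth):
    while a != b:
        if sp_depth[a] >= sp_depth[b]:
            a = sp_parent[a]
        else:
            b = sp_parent[b]
    return a


@njit(cache=True)
def _coal_stats(
    g_post, g_left, g_right, g_age, tip_pop, sp_parent, sp_depth, sp_tau, c_out, a_out
):
    """Per-population coalescent sufficient statistics for one gene tree.

    Fills ``c_out[p]`` (coalescences in population p) and ``a_out[p]``
    (integral of k(k-1) dt in p).  Returns True if the embedding is valid,
    i.e. every coalescence is at or above the divergence time of the
    populations it joins.
    """
    n_nodes = g_post.shape[0]
    n_tips = (n_nodes + 1) // 2
    n_pops = sp_parent.shape[0]
    c_out[:] = 0
    a_out[:] = 0.0
    ev_pop = np.full(n_nodes, -1, dtype=np.int64)
    node_sp = np.empty(n_nodes, dtype=np.int64)  # mrca species per gene node
    for i in range(n_nodes):
        v = g_post[i]
        if g_left[v] < 0:
            node_sp[v] = tip_pop[v]
        else:
            s = _sp_mrca(node_sp[g_left[v]], node_sp[g_right[v]], sp_parent, sp_depth)
            node_sp[v] = s
            if sp_tau[s] > g_age[v]:
                return False  # coalescence below the species divergence
            p = s
            while sp_parent[p] >= 0 and sp_tau[sp_parent[p]] <= g_age[v]:
                p = sp_parent[p]
            ev_pop[v] = p
            c_out[p] += 1
    # lineages entering each population
    n_enter = np.zeros(n_pops, dtype=np.int64)
    for t in range(n_tips):
        n_enter[tip_pop[t]] += 1
    # species-tree postorder accumulation: children before parents.
    # process pops by increasing tau, tips first (depth order is enough:
    # iterate pops sorted by (tau, -depth)); simpler: repeat passes.
    order = np.argsort(sp_tau, kind="mergesort")
    for oi in range(n_pops):
        p = order[oi]
        par = sp_parent[p]
        if par >= 0:
            n_enter[par] += n_enter[p] - c_out[p]
    # integrated pair time per population
    for oi in range(n_pops):
        p = order[oi]
        k = n_enter[p]
        if k == 0:
            continue
        t_prev = sp_tau[p]
        # gather & sort event ages in pop p (few per pop)
        cnt = c_out[p]
        if cnt > 0:
            ages = np.empty(cnt, dtype=np.float64)
            j = 0
            for v in range(n_nodes):
                if ev_pop[v] == p:
                    ages[j] = g_age[v]
                    j += 1
            ages.sort()
            for j in range(cnt):
                a_out[p] += k * (k - 1) * (ages[j] - t_prev)
                t_prev = ages[j]
                k -= 1
        par = sp_parent[p]
        if par >= 0 and k > 1:
            a_out[p] += k * (k - 1) * (sp_tau[par] - t_prev)
        elif par >= 0 and k == 1:
            pass  # single lineage: no pair time
    return True


def coal_sufficient_stats(gene_tree: GeneTree, species_tree: SpeciesTree):
    """(c, A, valid): per-population coalescent sufficient statistics.

    ``c[p]`` counts coalescences in population ``p`` and ``A[p]`` is the
    integrated pair time ``sum_intervals k(k-1) dt``; the censored
    coalescent log density is ``sum_p c[p] log(2/theta[p]) - A[p]/theta[p]``.
    """
    n_pops = species_tree.n_nodes
    c = np.zeros(n_pops, dtype=np.int64)
    a = np.zeros(n_pops, dtype=np.float64)
    tau = species_tree.tau
    if tau is None:
        raise ValueError("species tree has no tau annotations")
    valid = _coal_stats(
        np.asarray(gene_tree.postorder(), dtype=np.int64),
        gene_tree.left,
        gene_tree.right,
        gene_tree.age,
        gene_tree.tip_species,
        species_tree.parent,
        species_tree._depth,
        tau,
        c,
        a,
    )
    return c, a, bool(valid)


def msc_log_density(gene_tree: GeneTree, species_tree: SpeciesTree) -> float:
    """Censored multispecies-coalescent log density of a gene tree.

    Returns ``-inf`` when a coalescence predates the divergence of the
    populations it joins (invalid embedding).
    """
    if species_tree.theta is None:
        raise ValueError("species tree has no theta annotations")
    c, a, valid = coal_sufficient_stats(gene_tree, species_tree)
    if not valid:
        return -np.inf
    theta = species_tree.theta
    return float(np.sum(c * np.log(2.0 / theta)) - np.sum(a / theta))
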