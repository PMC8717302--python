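"""RADseq-like synthetic multilocus data with known coalescent truth.

The study system this emulates: short (143-bp) haploid RADseq loci from
lichen-forming fungal (mycobiont) genomes, sampled from one or two
individuals per candidate species, with per-locus missing individuals and
SNP-level quality filters applied before coalescent analysis.  Because the
generating species tree, gene trees and filter decisions are all recorded
in a :class:`SyntheticTruth`, every downstream stage (parameter estimation,
gdi scoring, delimitation) can be validated against known parameter values.

Simulation model
----------------
* genealogies: the censored multispecies coalescent — within a species-tree
  branch carrying ``k`` lineages and parameter ``theta``, the waiting time
  to the next coalescence is Exponential(rate ``k(k-1)/theta``); surviving
  lineages are handed to the parent branch at its divergence time ``tau``;
* sequences: JC69, site-independent, uniform root state, time in expected
  substitutions per site throughout;
* missingness: independent Bernoulli per (locus, individual);
* "heterozygous" loci: haploid mycobionts cannot be heterozygous, so
  apparent heterozygosity marks contamination; a configurable fraction of
  loci is flagged as such solely to exercise the ``max_obs_het`` filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import IndividualMap, LocusAlignment
from .trees import GeneTree, SpeciesTree

__all__ = [
    "RadFilterConfig",
    "SnpCall",
    "Scenario",
    "SyntheticTruth",
    "simulate_gene_trees",
    "evolve_sequences",
    "call_snps",
    "apply_rad_filters",
    "generate_dataset",
    "random_species_tree",
    "scenario",
    "SCENARIOS",
]


# ---------------------------------------------------------------------------
# gene-tree simulation


def simulate_gene_trees(species_tree, samples_per_species, n_loci, seed=None, rng=None):
    """Simulate independent gene trees under the multispecies coalescent.

    Parameters
    ----------
    species_tree : SpeciesTree
        Must carry tau and theta annotations, all theta > 0.
    samples_per_species : int or dict
        Number of sampled sequences per species (dict keyed by tip label
        for unequal sampling).
    n_loci : int
        Number of independent genealogies to draw.
    seed : int, optional
        Seed for a fresh numpy Generator; ignored if ``rng`` is given.

    Tip labels are ``"<species><k>"`` with ``k`` starting at 1 (e.g.
    ``A1``, ``A2``, ``B1``); label/species assignments are identical across
    loci.
    """
    st = species_tree
    if st.theta is None or st.tau is None:
        raise ValueError("species tree must carry tau and theta")
    if np.any(st.theta <= 0):
        raise ValueError("all theta must be > 0")
    if isinstance(samples_per_species, int):
        samples = {lab: samples_per_species for lab in st.labels}
    else:
        samples = dict(samples_per_species)
    if any(v < 1 for v in samples.values()):
        raise ValueError("samples_per_species must be >= 1 for every species")
    n_total = sum(samples.get(lab, 0) for lab in st.labels)
    if n_total == 0:
        raise ValueError("zero total samples")
    tip_labels, tip_species = [], []
    for sp_idx, lab in enumerate(st.labels):
        for k in range(samples.get(lab, 0)):
            tip_labels.append(f"{lab}{k + 1}")
            tip_species.append(sp_idx)
    tip_species = np.asarray(tip_species, dtype=np.int64)
    if rng is None:
        rng = np.random.default_rng(seed)
    return [
        _simulate_one(st, tip_labels, tip_species, rng) for _ in range(n_loci)
    ]


def _simulate_one(st, tip_labels, tip_species, rng, subset=None):
    """One censored-coalescent genealogy; ``subset`` restricts tips."""
    if subset is None:
        subset = range(len(tip_labels))
    labels = [tip_labels[i] for i in subset]
    species = np.asarray([tip_species[i] for i in subset], dtype=np.int64)
    n = len(labels)
    n_nodes = 2 * n - 1
    age = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    # per-population lineage pools, processed in increasing tau order
    pools = {p: [] for p in range(st.n_nodes)}
    for i in range(n):
        pools[int(species[i])].append(i)
    next_node = n
    order = sorted(range(st.n_nodes), key=lambda p: (st.tau[p], -st._depth[p]))
    for p in order:
        t = float(st.tau[p])
        par = st.parent[p]
        t_end = float(st.tau[par]) if par >= 0 else np.inf
        lineages = pools[p]
        theta = float(st.theta[p])
        while len(lineages) > 1:
            k = len(lineages)
            wait = rng.exponential(theta / (k * (k - 1)))
            if t + wait >= t_end:
                break
            t += wait
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            v = next_node
            next_node += 1
            age[v] = t
            left[v], right[v] = a, b
            parent[a] = parent[b] = v
            lineages = [x for x in lineages if x not in (a, b)] + [v]
        if par >= 0:
            pools[par].extend(lineages)
        pools[p] = lineages
    return GeneTree(labels, species, age, parent, left, right)


# ---------------------------------------------------------------------------
# sequence evolution (JC69)


def jc_expected_diff(d: float) -> float:
    """Expected raw mismatch fraction at JC69 path length ``d``."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def jc_corrected_distance(p: float) -> float:
    """JC69 distance from a raw mismatch fraction (inf if saturated)."""
    if p >= 0.75:
        return np.inf
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def evolve_sequences(gene_trees, locus_length: int = 143, seed=None, rng=None):
    """Evolve JC69 sequences down each gene tree.

    Returns one :class:`LocusAlignment` per gene tree, with locus ids
    ``L00001, L00002, ...`` and rows keyed by the gene-tree tip labels.
    Root states are uniform; substitutions are site-independent.
    """
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    out = []
    for li, gt in enumerate(gene_trees):
        states = np.empty((gt.n_nodes, locus_length), dtype=np.int8)
        order = gt.postorder()[::-1]  # preorder: root first
        root = order[0]
        states[root] = rng.integers(0, 4, size=locus_length)
        for v in order[1:]:
            b = gt.age[gt.parent[v]] - gt.age[v]
            p_change = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            s = states[gt.parent[v]].copy()
            hit = rng.random(locus_length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # jump to one of the three other states uniformly
                s[hit] = (s[hit] + rng.integers(1, 4, size=n_hit)) % 4
            states[v] = s
        rows = {
            lab: "".join(alphabet[states[i]]) for i, lab in enumerate(gt.tip_labels)
        }
        out.append(LocusAlignment(f"L{li + 1:05d}", rows))
    return out


# ---------------------------------------------------------------------------
# Stacks-style SNP filters


@dataclass
class RadFilterConfig:
    """Filter thresholds mirroring the Stacks ``populations`` settings.

    max_obs_het
        Maximum number of heterozygous calls tolerated per locus (0 = any
        apparent heterozygosity drops the locus; haploid data, so a het
        call marks contamination).
    min_maf
        Minimum minor-allele frequency per SNP among observed calls.
    min_presence
        Minimum fraction of individuals genotyped at a locus.
    single_snp
        Keep only the first (leftmost) retained SNP per locus.
    """

    max_obs_het: int = 0
    min_maf: float = 0.05
    min_presence: float = 0.30
    single_snp: bool = True

    def __post_init__(self):
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")
        if not (0.0 < self.min_presence <= 1.0):
            raise ValueError("min_presence must be in (0, 1]")


@dataclass
class SnpCall:
    """One variable column of one locus with per-individual haploid alleles."""

    locus_id: str
    column: int  # 0-based position within the locus
    alleles: dict  # individual -> base (observed, non-missing only)
    het_individuals: frozenset = frozenset()

    @property
    def maf(self) -> float:
        """Minor-allele frequency: 1 - (major allele frequency)."""
        counts = {}
        for b in self.alleles.values():
            counts[b] = counts.get(b, 0) + 1
        n = sum(counts.values())
        return 1.0 - max(counts.values()) / n if n else 0.0


def call_snps(loci, het_loci=()):
    """Identify variable columns and their haploid allele calls.

    ``het_loci`` marks loci carrying synthetic contamination artifacts;
    each such locus gets one heterozygous call at its first variable
    column (or column 0 if invariant).
    """
    het_loci = set(het_loci)
    calls = []
    for loc in loci:
        labels = loc.labels
        cols_done = False
        first_var = None
        for col in range(loc.length):
            obs = {
                lab: loc.rows[lab][col]
                for lab in labels
                if loc.rows[lab][col] not in "N-"
            }
            states = set(obs.values())
            if len(states) >= 2:
                if first_var is None:
                    first_var = col
                calls.append(SnpCall(loc.locus_id, col, obs))
        if loc.locus_id in het_loci:
            col = first_var if first_var is not None else 0
            target = None
            for c in calls:
                if c.locus_id == loc.locus_id and c.column == col:
                    target = c
                    break
            if target is None:
                target = SnpCall(loc.locus_id, col, {})
                calls.append(target)
            who = labels[0] if labels else None
            target.het_individuals = frozenset({who} if who else ())
    return calls


def apply_rad_filters(loci, snp_calls, config: RadFilterConfig, n_individuals=None):
    """Apply the het / MAF / presence / single-SNP filter cascade.

    Parameters
    ----------
    loci : list of LocusAlignment
    snp_calls : list of SnpCall
    config : RadFilterConfig
    n_individuals : int, optional
        Presence-filter denominator; defaults to the number of distinct
        individuals across ``loci``.

    Returns
    -------
    (retained_loci, snp_table, drop_counts)
        ``retained_loci``: loci passing every locus-level filter and
        carrying at least one retained SNP; ``snp_table``: the retained
        :class:`SnpCall` rows; ``drop_counts``: per-filter tally
        (het_loci, low_maf_snps, low_presence_loci, no_snp_loci,
        extra_snps).  An empty result is legal.
    """
    if n_individuals is None:
        inds = set()
        for loc in loci:
            inds.update(loc.labels)
        n_individuals = len(inds)
    by_locus = {}
    for c in snp_calls:
        by_locus.setdefault(c.locus_id, []).append(c)
    drops = {
        "het_loci": 0,
        "low_maf_snps": 0,
        "low_presence_loci": 0,
        "no_snp_loci": 0,
        "extra_snps": 0,
    }
    retained_loci, snp_table = [], []
    for loc in loci:
        calls = sorted(by_locus.get(loc.locus_id, []), key=lambda c: c.column)
        n_het = sum(len(c.het_individuals) for c in calls)
        if n_het > config.max_obs_het:
            drops["het_loci"] += 1
            continue
        ok_maf = [c for c in calls if c.maf >= config.min_maf]
        drops["low_maf_snps"] += len(calls) - len(ok_maf)
        presence = loc.n_seqs / n_individuals if n_individuals else 0.0
        if presence < config.min_presence:
            drops["low_presence_loci"] += 1
            continue
        if not ok_maf:
            drops["no_snp_loci"] += 1
            continue
        if config.single_snp:
            drops["extra_snps"] += len(ok_maf) - 1
            ok_maf = ok_maf[:1]
        retained_loci.append(loc)
        snp_table.extend(ok_maf)
    return retained_loci, snp_table, drops


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class Scenario:
    """A named synthetic-data condition (sizes, rates, coalescent scales)."""

    name: str
    n_species: int
    samples_per_species: int
    n_loci: int
    theta: float
    tau_root: float
    locus_length: int = 143
    missingness: float = 0.0
    het_artifact_rate: float = 0.0
    newick: str | None = None  # explicit truth tree (tau/theta annotated)
    candidate_splits: dict = field(default_factory=dict)
    apply_filters: bool = False
    filter_config: RadFilterConfig = field(default_factory=RadFilterConfig)

    def __post_init__(self):
        if self.n_species > 1 and self.tau_root <= 0:
            raise ValueError("tau_root must be > 0 when n_species > 1")
        if self.n_species < 1 or self.samples_per_species < 1 or self.n_loci < 1:
            raise ValueError("n_species, samples_per_species, n_loci must be >= 1")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Immutable record of how a synthetic dataset was generated."""

    scenario: Scenario
    seed: int
    species_tree: SpeciesTree  # the true (generating) tree
    guide_tree: SpeciesTree  # over candidate labels (splits expanded)
    gene_trees: list
    missing: dict  # locus_id -> sorted list of dropped individuals
    het_loci: frozenset
    dropped_sparse_loci: list  # loci left with <2 sequences by missingness
    filter_drops: dict | None = None


def random_species_tree(labels, tau_root, theta, rng) -> SpeciesTree:
    """Random ranked topology with uniform-order-statistic merge times.

    Merge times are ``tau_root`` times sorted Uniform(0,1) order statistics
    (the deepest merge pinned at ``tau_root``); pairs to merge are chosen
    uniformly, giving a random ranked tree shape.  All branches share one
    ``theta``.
    """
    s = len(labels)
    n_nodes = 2 * s - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    tau = np.zeros(n_nodes)
    if s == 1:
        return SpeciesTree(labels, parent, left, right, tau=tau, theta=[theta])
    times = np.sort(rng.uniform(0.0, tau_root, size=s - 1))
    times[-1] = tau_root
    avail = list(range(s))
    for k in range(s - 1):
        i, j = sorted(rng.choice(len(avail), size=2, replace=False))
        b = avail.pop(int(j))
        a = avail.pop(int(i))
        v = s + k
        left[v], right[v] = a, b
        parent[a] = parent[b] = v
        tau[v] = times[k]
        avail.append(v)
    theta_arr = np.full(n_nodes, theta)
    return SpeciesTree(labels, parent, left, right, tau=tau, theta=theta_arr)


def _species_labels(n):
    out = []
    for i in range(n):
        lab = ""
        k = i
        while True:
            lab = chr(ord("A") + k % 26) + lab
            k = k // 26 - 1
            if k < 0:
                break
        out.append(lab)
    return out


def _expand_guide_tree(truth_tree: SpeciesTree, splits: dict) -> SpeciesTree:
    """Expand split tips into cherries to build the candidate guide tree."""
    if not splits:
        g = truth_tree.copy()
        g.theta = None  # guide topology carries no parameters
        g.tau = None
        return g
    newick = truth_tree.to_newick(annotations=False)
    # to_newick with annotations=False still writes branch lengths from tau
    for sp, (c1, c2) in splits.items():
        newick = _replace_tip(newick, sp, f"({c1},{c2})")
    return SpeciesTree.from_newick(newick)


def _replace_tip(newick: str, label: str, replacement: str) -> str:
    import re

    pat = re.compile(r"(?<![\w.])" + re.escape(label) + r"(?![\w.])")
    new, n = pat.subn(replacement, newick)
    if n != 1:
        raise ValueError(f"tip {label!r} matched {n} times in guide newick")
    return new


def generate_dataset(scn: Scenario, seed: int):
    """Generate (loci, individual map, truth) for a scenario.

    The per-stage random streams (tree shape, genealogies, sequences,
    missingness, artifacts) are spawned from one ``SeedSequence`` so the
    output is byte-identical under a fixed seed.
    """
    ss = np.random.SeedSequence(seed)
    rng_tree, rng_gen, rng_seq, rng_miss, rng_art = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    labels = _species_labels(scn.n_species)
    if scn.newick is not None:
        st = SpeciesTree.from_newick(scn.newick)
        labels = st.labels
    else:
        st = random_species_tree(labels, scn.tau_root, scn.theta, rng_tree)
    gene_trees = simulate_gene_trees(
        st, scn.samples_per_species, scn.n_loci, rng=rng_gen
    )
    loci = evolve_sequences(gene_trees, scn.locus_length, rng=rng_seq)
    # candidate map: split designated species' individuals across two labels
    assignments = {}
    for sp_idx, sp in enumerate(st.labels):
        inds = [f"{sp}{k + 1}" for k in range(scn.samples_per_species)]
        if sp in scn.candidate_splits:
            c1, c2 = scn.candidate_splits[sp]
            half = (len(inds) + 1) // 2
            for ind in inds[:half]:
                assignments[ind] = c1
            for ind in inds[half:]:
                assignments[ind] = c2
        else:
            for ind in inds:
                assignments[ind] = sp
    imap = IndividualMap(assignments)
    # per-(locus, individual) Bernoulli missingness
    missing, kept_loci, kept_trees, dropped = {}, [], [], []
    for loc, gt in zip(loci, gene_trees):
        if scn.missingness > 0:
            drop = [
                lab
                for lab in loc.labels
                if rng_miss.random() < scn.missingness
            ]
        else:
            drop = []
        rows = {k: v for k, v in loc.rows.items() if k not in drop}
        if len(rows) < 2:
            dropped.append(loc.locus_id)
            continue
        missing[loc.locus_id] = sorted(drop)
        kept_loci.append(LocusAlignment(loc.locus_id, rows))
        kept_trees.append(gt)
    # contamination artifacts ("heterozygous" loci)
    het = frozenset(
        loc.locus_id
        for loc in kept_loci
        if scn.het_artifact_rate > 0 and rng_art.random() < scn.het_artifact_rate
    )
    filter_drops = None
    if scn.apply_filters:
        calls = call_snps(kept_loci, het_loci=het)
        tree_of = {loc.locus_id: gt for loc, gt in zip(kept_loci, kept_trees)}
        kept_loci, _, filter_drops = apply_rad_filters(
            kept_loci, calls, scn.filter_config
        )
        kept_trees = [tree_of[loc.locus_id] for loc in kept_loci]
    guide = _expand_guide_tree(st, scn.candidate_splits)
    truth = SyntheticTruth(
        scenario=scn,
        seed=seed,
        species_tree=st,
        guide_tree=guide,
        gene_trees=kept_trees,
        missing=missing,
        het_loci=het,
        dropped_sparse_loci=dropped,
        filter_drops=filter_drops,
    )
    return kept_loci, imap, truth


SCENARIOS = {
    # shaped like the study: 17 candidate species, 2 haploid samples each,
    # coalescent scales at the study's priors (theta 1e-4, tau 3e-5)
    "paper-like-small": Scenario(
        name="paper-like-small",
        n_species=17,
        samples_per_species=2,
        n_loci=500,
        theta=1e-4,
        tau_root=3e-5,
        missingness=0.2,
    ),
    # well-powered two-species recovery benchmark
    "two-species": Scenario(
        name="two-species",
        n_species=2,
        samples_per_species=4,
        n_loci=100,
        theta=0.005,
        tau_root=0.002,
    ),
    # four candidates, two of which are one panmictic species (B split
    # into B1/B2); the rest deeply diverged
    "panmictic-pair": Scenario(
        name="panmictic-pair",
        n_species=3,
        samples_per_species=4,
        n_loci=80,
        theta=0.002,
        tau_root=0.02,
        candidate_splits={"B": ("B1", "B2")},
    ),
    # four candidates, all divergences deep (2*tau/theta >= 10)
    "deep-divergence": Scenario(
        name="deep-divergence",
        n_species=4,
        samples_per_species=3,
        n_loci=80,
        theta=0.002,
        tau_root=0.05,
        newick=(
            "((A[&theta=0.002]:0.02,B[&theta=0.002]:0.02)[&theta=0.002,tau=0.02]"
            ":0.03,(C[&theta=0.002]:0.03,D[&theta=0.002]:0.03)"
            "[&theta=0.002,tau=0.03]:0.02)[&theta=0.002,tau=0.05];"
        ),
    ),
    # three candidates at very strong divergence (2*tau/theta = 20)
    "three-deep": Scenario(
        name="three-deep",
        n_species=3,
        samples_per_species=2,
        n_loci=60,
        theta=0.002,
        tau_root=0.04,
        newick=(
            "((A[&theta=0.002]:0.02,B[&theta=0.002]:0.02)[&theta=0.002,tau=0.02]"
            ":0.02,C[&theta=0.002]:0.04)[&theta=0.002,tau=0.04];"
        ),
    ),
}


def scenario(name: str) -> Scenario:
    """Look up a named scenario preset (a fresh copy)."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    return replace(SCENARIOS[name])
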