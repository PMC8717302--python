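"""Full-likelihood multispecies-coalescent inference.

Two statsmodels-style model/results pairs:

* :class:`MscModel` / :class:`MscResults` — posterior estimation of
  divergence times (tau) and population-size parameters (theta) on a fixed
  species tree ("A00"-style analysis);
* :class:`GuideTreeDelimitation` / :class:`DelimitationResults` —
  reversible-jump delimitation on a fixed guide tree whose internal nodes
  may be split (speciation at tau > 0) or collapsed (tau = 0), yielding
  posterior probabilities of delimitation models ("A10"-style analysis).

Priors: inverse-gamma(shape alpha, mean = configured prior mean) on every
theta and on the root tau; non-root divergence times are uniform order
statistics given the root (A00) or Uniform(0, tau_parent) per split node
(A10); the delimitation-model prior is uniform over split-flag vectors
consistent with ancestry closure.

Also here: the moment-based oracle estimator used to cross-validate the
MCMC, effective-sample-size diagnostics, and aggregation of delimitation
posteriors across replicate runs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .io import IndividualMap
from .simulate import jc_corrected_distance
from .trees import SpeciesTree

__all__ = [
    "McmcConfig",
    "TraceLog",
    "MscModel",
    "MscResults",
    "GuideTreeDelimitation",
    "DelimitationResults",
    "DelimitationModel",
    "run_a00",
    "run_a10",
    "aggregate_model_posteriors",
    "AggregatedPosterior",
    "ess",
    "moment_estimates",
    "MomentEstimates",
]


@dataclass
class McmcConfig:
    """Sampler configuration.

    ``iterations`` is the total chain length including burn-in; with
    ``burnin=None`` an A00-style run discards an extra 10% of the retained
    length (total = retained + 10%, i.e. ``iterations // 11``) and an
    A10-style run discards 20,000 iterations (capped at a fifth of short
    runs).  Prior means are in expected substitutions per site.
    """

    iterations: int = 55_000
    burnin: int | None = None
    thin: int = 5
    theta_prior_mean: float = 1e-4
    tau_prior_mean: float = 3e-5
    prior_shape: float = 3.0
    estimate_theta: bool = True
    use_likelihood: bool = True
    n_runs: int = 1
    seed: int = 0
    lam_root_age: float = 1.4
    lam_root_tau: float = 1.4
    lam_mix: float = 0.6
    mix_every: int = 5

    def __post_init__(self):
        if self.iterations <= 0:
            raise ValueError("iterations must be > 0")
        if self.burnin is not None and not (0 <= self.burnin < self.iterations):
            raise ValueError("need iterations > burnin >= 0")
        if self.thin < 1 or self.n_runs < 1:
            raise ValueError("thin and n_runs must be >= 1")
        if self.theta_prior_mean <= 0 or self.tau_prior_mean <= 0:
            raise ValueError("prior means must be > 0")
        if self.prior_shape <= 1:
            raise ValueError("prior_shape must exceed 1 for the mean to exist")

    def resolved_burnin(self, a10: bool = False) -> int:
        if self.burnin is not None:
            return self.burnin
        if a10:
            return min(20_000, self.iterations // 5)
        return self.iterations // 11

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _node_names(tree: SpeciesTree):
    names = []
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            names.append(tree.labels[v])
        else:
            names.append("+".join(sorted(tree.labels[t] for t in tree.tips_below(v))))
    return names


@dataclass
class TraceLog:
    """Retained posterior samples of one MCMC run.

    ``tau`` and ``theta`` are (n_samples, n_nodes) arrays over all
    species-tree nodes (tip tau columns are identically 0; in A10 runs a
    collapsed node's tau is 0 for the samples where it is collapsed).
    """

    species_tree: SpeciesTree
    node_names: list
    tau: np.ndarray
    theta: np.ndarray
    loglik: np.ndarray
    split_flags: np.ndarray | None
    seed: int
    config: McmcConfig
    acceptance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.tau.shape[0]

    def _node(self, label: str) -> int:
        try:
            return self.node_names.index(label)
        except ValueError:
            raise KeyError(
                f"no parameter for group {label!r}; known: {self.node_names}"
            ) from None

    def tau_of(self, group_a: str, group_b: str) -> np.ndarray:
        """Samples of the divergence time of MRCA(group_a, group_b)."""
        st = self.species_tree
        v = st.mrca(st.tip_index(group_a), st.tip_index(group_b))
        return self.tau[:, v]

    def theta_of(self, group: str) -> np.ndarray:
        """Samples of theta for the named tip or internal population."""
        return self.theta[:, self._node(group)]

    def to_tsv(self, path, metadata_path=None) -> None:
        n_tips = self.species_tree.n_tips
        cols = {"iteration": np.arange(self.n_samples)}
        for v in range(self.theta.shape[1]):
            cols[f"theta_{self.node_names[v]}"] = self.theta[:, v]
        for v in range(n_tips, self.tau.shape[1]):
            cols[f"tau_{self.node_names[v]}"] = self.tau[:, v]
        cols["lnL"] = self.loglik
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        if metadata_path is not None:
            meta = {
                "seed": int(self.seed),
                "config": asdict(self.config),
                "config_hash": self.config.hash(),
                "acceptance": self.acceptance,
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def _init_params(tree: SpeciesTree, cfg: McmcConfig):
    """Initial tau (height-proportional) and theta (prior mean) vectors."""
    n = tree.n_nodes
    tau = np.zeros(n)
    if tree.tau is not None:
        tau = tree.tau.copy()
    else:
        height = np.zeros(n, dtype=np.int64)
        for v in tree.postorder():
            if not tree.is_tip(v):
                height[v] = 1 + max(height[tree.left[v]], height[tree.right[v]])
        hmax = max(1, height[tree.root])
        for v in range(n):
            if not tree.is_tip(v):
                tau[v] = cfg.tau_prior_mean * height[v] / hmax
    if tree.theta is not None:
        theta = tree.theta.copy()
    else:
        theta = np.full(n, cfg.theta_prior_mean)
    return tau, theta


def _flatten_loci(loci, imap: IndividualMap, tree: SpeciesTree):
    """Pack per-locus gene-tree skeletons and site patterns into flat arrays."""
    from .likelihood import encode_alignment

    sp_index = {lab: i for i, lab in enumerate(tree.labels)}
    node_off = [0]
    tip_counts = []
    tip_sp_flat = []
    code_off = [0]
    codes_list = []
    pat_off = [0]
    weights_list = []
    tip_labels_per_locus = []
    for loc in loci:
        labels = [lab for lab in loc.labels]
        if len(labels) < 2:
            raise ValueError(
                f"locus {loc.locus_id!r} has fewer than 2 sequences"
            )
        for lab in labels:
            if lab not in imap.assignments:
                raise ValueError(
                    f"individual {lab!r} (locus {loc.locus_id!r}) "
                    "missing from individual map"
                )
            sp = imap.assignments[lab]
            if sp not in sp_index:
                raise ValueError(
                    f"species {sp!r} (individual {lab!r}) not in species tree"
                )
        nt = len(labels)
        nn = 2 * nt - 1
        node_off.append(node_off[-1] + nn)
        tip_counts.append(nt)
        sp_ids = [sp_index[imap.assignments[lab]] for lab in labels]
        tip_sp_flat.extend(sp_ids + [0] * (nn - nt))
        codes, weights = encode_alignment(loc, labels)
        codes_list.append(codes.ravel())
        code_off.append(code_off[-1] + codes.size)
        weights_list.append(weights)
        pat_off.append(pat_off[-1] + len(weights))
        tip_labels_per_locus.append(labels)
    return {
        "node_off": np.asarray(node_off, dtype=np.int64),
        "tip_counts": np.asarray(tip_counts, dtype=np.int64),
        "tip_sp_flat": np.asarray(tip_sp_flat, dtype=np.int64),
        "code_off": np.asarray(code_off, dtype=np.int64),
        "codes_flat": np.concatenate(codes_list).astype(np.int8),
        "pat_off": np.asarray(pat_off, dtype=np.int64),
        "pat_counts": np.diff(pat_off).astype(np.int64),
        "weights_flat": np.concatenate(weights_list),
        "tip_labels": tip_labels_per_locus,
    }


def _run_one_chain(tree, flat, cfg, seed, a10, init_split=None):
    n_pops = tree.n_nodes
    tau0, theta0 = _init_params(tree, cfg)
    sp_tau = tau0.copy()
    sp_theta = theta0.copy()
    split = np.ones(n_pops, dtype=np.uint8)
    if init_split is not None:
        split = init_split.copy()
    sp_order = np.asarray(
        sorted(range(n_pops), key=lambda p: (sp_tau[p], -tree._depth[p])),
        dtype=np.int64,
    )
    sp_desc = np.zeros((n_pops, n_pops), dtype=np.uint8)
    for v in range(n_pops):
        u = v
        while u >= 0:
            sp_desc[v, u] = 1
            u = int(tree.parent[u])
    burnin = cfg.resolved_burnin(a10)
    if burnin >= cfg.iterations:
        raise ValueError("iterations must exceed burn-in")
    n_samples = (cfg.iterations - burnin) // cfg.thin
    total_nodes = int(flat["node_off"][-1])
    g_age = np.zeros(total_nodes)
    g_parent = np.full(total_nodes, -1, dtype=np.int64)
    g_left = np.full(total_nodes, -1, dtype=np.int64)
    g_right = np.full(total_nodes, -1, dtype=np.int64)
    post_flat = np.zeros(total_nodes, dtype=np.int64)
    out_tau = np.empty((n_samples, n_pops))
    out_theta = np.empty((n_samples, n_pops))
    out_ll = np.empty(n_samples)
    out_flags = np.zeros(n_samples, dtype=np.int64)
    acc = np.zeros(_kernels.N_ACC, dtype=np.int64)
    prop = np.zeros(_kernels.N_ACC, dtype=np.int64)
    alpha = cfg.prior_shape
    beta_theta = (alpha - 1.0) * cfg.theta_prior_mean
    beta_tau = (alpha - 1.0) * cfg.tau_prior_mean
    got = _kernels._run_chain(
        tree.parent, tree.left, tree.right, tree._depth, sp_order,
        np.int64(tree.root), sp_desc, sp_tau, sp_theta, split,
        len(flat["tip_counts"]), flat["node_off"], flat["tip_counts"],
        flat["tip_sp_flat"], g_age, g_parent, g_left, g_right, post_flat,
        flat["code_off"], flat["codes_flat"], flat["pat_off"],
        flat["pat_counts"], flat["weights_flat"],
        cfg.iterations, burnin, cfg.thin, np.int64(seed),
        1 if cfg.use_likelihood else 0,
        1 if cfg.estimate_theta else 0,
        1 if a10 else 0,
        alpha, beta_theta, beta_tau, cfg.tau_prior_mean,
        cfg.lam_root_age, cfg.lam_root_tau, cfg.lam_mix, cfg.mix_every,
        out_tau, out_theta, out_ll, out_flags, acc, prop,
    )
    assert got == n_samples
    names = ["resim", "age", "tau", "mix", "rjump"]
    acceptance = {
        k: (float(acc[i] / prop[i]) if prop[i] else float("nan"))
        for i, k in zip(
            (_kernels.ACC_RESIM, _kernels.ACC_AGE, _kernels.ACC_TAU,
             _kernels.ACC_MIX, _kernels.ACC_RJ),
            names,
        )
    }
    template = tree.copy()
    template.tau, template.theta = tau0, theta0
    return TraceLog(
        species_tree=template,
        node_names=_node_names(tree),
        tau=out_tau,
        theta=out_theta,
        loglik=out_ll,
        split_flags=out_flags if a10 else None,
        seed=int(seed),
        config=cfg,
        acceptance=acceptance,
    )


def _run_seeds(cfg: McmcConfig):
    """Distinct 31-bit kernel seeds for the configured number of runs."""
    ss = np.random.SeedSequence(cfg.seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(cfg.n_runs)]


class MscModel:
    """Coalescent tau/theta estimation on a fixed species tree.

    Parameters
    ----------
    loci : list of LocusAlignment
        Each locus needs at least two present sequences.
    imap : IndividualMap
        Individual -> candidate species; every sequence label must appear.
    species_tree : SpeciesTree
        Rooted binary tree whose tips are exactly the map's species.
        Existing tau/theta annotations seed the chain; otherwise the chain
        starts from prior-scale values.
    """

    def __init__(self, loci, imap, species_tree, config: McmcConfig | None = None):
        if set(species_tree.labels) != set(imap.species):
            raise ValueError(
                "species tree tips %s != individual-map species %s"
                % (sorted(species_tree.labels), sorted(imap.species))
            )
        imap.validate_against(loci)
        self.loci = list(loci)
        self.imap = imap
        self.species_tree = species_tree
        self.config = config or McmcConfig()
        self._flat = _flatten_loci(self.loci, imap, species_tree)

    def fit(self, config: McmcConfig | None = None) -> "MscResults":
        cfg = config or self.config
        traces = [
            _run_one_chain(self.species_tree, self._flat, cfg, s, a10=False)
            for s in _run_seeds(cfg)
        ]
        return MscResults(self, traces)


class MscResults:
    """Posterior summaries of one or more A00-style runs."""

    def __init__(self, model: MscModel, traces):
        self.model = model
        self.traces = list(traces)

    @property
    def trace(self) -> TraceLog:
        return self.traces[0]

    def pooled(self, kind: str, name: str) -> np.ndarray:
        """Concatenated samples of ``theta``/``tau`` parameter ``name``."""
        if kind == "theta":
            return np.concatenate([t.theta_of(name) for t in self.traces])
        st = self.trace.species_tree
        v = self.trace._node(name)
        return np.concatenate([t.tau[:, v] for t in self.traces])

    def posterior_mean_tau(self, group_a: str, group_b: str) -> float:
        return float(
            np.mean([t.tau_of(group_a, group_b).mean() for t in self.traces])
        )

    def posterior_mean_theta(self, group: str) -> float:
        return float(np.mean([t.theta_of(group).mean() for t in self.traces]))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        t0 = self.trace
        n_tips = t0.species_tree.n_tips
        for v in range(t0.theta.shape[1]):
            x = np.concatenate([t.theta[:, v] for t in self.traces])
            rows.append(("theta_" + t0.node_names[v], x))
        for v in range(n_tips, t0.tau.shape[1]):
            x = np.concatenate([t.tau[:, v] for t in self.traces])
            rows.append(("tau_" + t0.node_names[v], x))
        rows.append(("lnL", np.concatenate([t.loglik for t in self.traces])))
        out = []
        for name, x in rows:
            out.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "q2.5": np.percentile(x, 2.5),
                    "q97.5": np.percentile(x, 97.5),
                    "ess": ess(x) if x.std() > 0 else float(len(x)),
                }
            )
        return pd.DataFrame(out).set_index("parameter")

    def summary(self) -> str:
        df = self.summary_frame()
        head = (
            "Multispecies coalescent estimation (fixed species tree)\n"
            f"runs: {len(self.traces)}   samples/run: {self.trace.n_samples}   "
            f"loci: {len(self.model.loci)}\n"
        )
        return head + df.to_string(float_format=lambda x: f"{x:.6g}")


def run_a00(loci, imap, species_tree, config: McmcConfig | None = None):
    """Functional wrapper: returns the TraceLog (or list when n_runs > 1)."""
    res = MscModel(loci, imap, species_tree, config).fit()
    return res.traces[0] if len(res.traces) == 1 else res.traces


# ---------------------------------------------------------------------------
# A10-style delimitation


@dataclass(frozen=True)
class DelimitationModel:
    """One split/collapse state of the guide tree's internal nodes."""

    split_flags: tuple  # bool per internal node, in node order
    node_names: tuple  # internal-node names, same order
    n_species: int
    posterior: float

    def __post_init__(self):
        if not (0.0 <= self.posterior <= 1.0 + 1e-12):
            raise ValueError("posterior must be a probability")

    @property
    def key(self):
        return self.split_flags

    def __str__(self):
        on = [n for n, f in zip(self.node_names, self.split_flags) if f]
        return f"{self.n_species}-species model (split: {', '.join(on) or 'none'})"


def _models_from_trace(trace: TraceLog):
    st = trace.species_tree
    n_tips = st.n_tips
    internal = list(range(n_tips, st.n_nodes))
    names = [trace.node_names[v] for v in internal]
    counts = {}
    for f in trace.split_flags:
        counts[int(f)] = counts.get(int(f), 0) + 1
    total = trace.n_samples
    models = []
    for flags_int, c in sorted(counts.items(), key=lambda kv: -kv[1]):
        flags = tuple(bool(flags_int >> (v - n_tips) & 1) for v in internal)
        models.append(
            DelimitationModel(
                split_flags=flags,
                node_names=tuple(names),
                n_species=1 + sum(flags),
                posterior=c / total,
            )
        )
    return models


class GuideTreeDelimitation:
    """Species delimitation on a fixed guide tree (A10-style rjMCMC)."""

    def __init__(self, loci, imap, guide_tree, config: McmcConfig | None = None):
        if set(guide_tree.labels) != set(imap.species):
            raise ValueError(
                "guide tree tips %s != individual-map species %s"
                % (sorted(guide_tree.labels), sorted(imap.species))
            )
        imap.validate_against(loci)
        self.loci = list(loci)
        self.imap = imap
        self.guide_tree = guide_tree
        self.config = config or McmcConfig()
        self._flat = _flatten_loci(self.loci, imap, guide_tree)

    def fit(self, config: McmcConfig | None = None) -> "DelimitationResults":
        cfg = config or self.config
        traces = [
            _run_one_chain(self.guide_tree, self._flat, cfg, s, a10=True)
            for s in _run_seeds(cfg)
        ]
        return DelimitationResults(self, traces)


class DelimitationResults:
    """Delimitation-model posteriors from one or more A10-style runs."""

    def __init__(self, model: GuideTreeDelimitation, traces):
        self.model = model
        self.traces = list(traces)
        self.runs = [_models_from_trace(t) for t in traces]
        self.aggregate = aggregate_model_posteriors(self.runs)

    @property
    def models(self):
        """Aggregated models, highest posterior first."""
        return self.aggregate.models

    @property
    def species_count_probs(self):
        return self.aggregate.species_count_probs

    def summary(self) -> str:
        lines = [
            "Guide-tree species delimitation",
            f"runs: {len(self.runs)}   samples/run: {self.traces[0].n_samples}",
            "",
            "model posteriors (aggregate over runs):",
        ]
        for m in self.models[:10]:
            lines.append(f"  {m.posterior:8.4f}  {m}")
        lines.append("")
        lines.append("species-count marginal:")
        for k in sorted(self.species_count_probs):
            lines.append(f"  {k:3d} species  {self.species_count_probs[k]:8.4f}")
        return "\n".join(lines)


def run_a10(loci, imap, guide_tree, config: McmcConfig | None = None):
    """Functional wrapper: delimitation models of one run (or per-run lists)."""
    res = GuideTreeDelimitation(loci, imap, guide_tree, config).fit()
    return res.runs[0] if len(res.runs) == 1 else res.runs


@dataclass
class AggregatedPosterior:
    """Replicate-averaged delimitation posteriors."""

    models: list
    species_count_probs: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": str(m),
                "n_species": m.n_species,
                "posterior": m.posterior,
            }
            for m in self.models
        ]
        return pd.DataFrame(rows)

    def count_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_species": sorted(self.species_count_probs),
                "probability": [
                    self.species_count_probs[k]
                    for k in sorted(self.species_count_probs)
                ],
            }
        )


def aggregate_model_posteriors(runs) -> AggregatedPosterior:
    """Average each model's posterior across runs (absent model = 0).

    ``runs`` is a list of per-run model lists.  The species-count marginal
    sums the aggregated model probabilities by species count.
    """
    if not runs:
        raise ValueError("need at least one run")
    keys = {}
    for run in runs:
        for m in run:
            keys.setdefault(m.key, m)
    n = len(runs)
    agg = []
    for key, proto in keys.items():
        mean_p = (
            sum(next((m.posterior for m in run if m.key == key), 0.0) for run in runs)
            / n
        )
        agg.append(replace_posterior(proto, mean_p))
    agg.sort(key=lambda m: (-m.posterior, m.key))
    counts = {}
    for m in agg:
        counts[m.n_species] = counts.get(m.n_species, 0.0) + m.posterior
    return AggregatedPosterior(models=agg, species_count_probs=counts)


def replace_posterior(model: DelimitationModel, p: float) -> DelimitationModel:
    return DelimitationModel(
        split_flags=model.split_flags,
        node_names=model.node_names,
        n_species=model.n_species,
        posterior=p,
    )


# ---------------------------------------------------------------------------
# diagnostics and the moment oracle


def ess(series) -> float:
    """Effective sample size, n / (1 + 2 sum of autocorrelations).

    The autocorrelation sum is truncated by Geyer's initial positive
    sequence rule (stop when a consecutive pair-sum of autocorrelations
    turns negative).  A constant series is reported as ESS = n with a
    warning.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short for ESS (need >= 10)")
    v = x.var()
    if v == 0:
        warnings.warn("zero-variance series; reporting ESS = n")
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
        t += 2
    return float(n / (1.0 + 2.0 * s))


@dataclass
class MomentEstimates:
    """Method-of-moments (theta_a, theta_b, theta_ancestral, tau) for a pair."""

    theta_a: float | None
    theta_b: float | None
    theta_ancestral: float
    tau: float


def _pair_jc(seq_i, seq_j):
    same = diff = 0
    for a, b in zip(seq_i, seq_j):
        if a in "N-" or b in "N-":
            continue
        if a == b:
            same += 1
        else:
            diff += 1
    tot = same + diff
    if tot == 0:
        return None
    return jc_corrected_distance(diff / tot)


def moment_estimates(loci, imap: IndividualMap, species_pair) -> MomentEstimates:
    """Moment-based oracle for one species pair.

    Within-species theta is the mean JC-corrected pairwise distance; the
    ancestral theta is approximated by the mean of the two within-species
    values; tau = (mean between-species distance - theta_ancestral) / 2,
    clamped at 0 with a warning when the between-species distance is
    smaller than the within-species level.
    """
    sp_a, sp_b = species_pair
    within = {sp_a: [], sp_b: []}
    between = []
    for loc in loci:
        rows_a = [
            loc.rows[i] for i in loc.rows if imap.assignments.get(i) == sp_a
        ]
        rows_b = [
            loc.rows[i] for i in loc.rows if imap.assignments.get(i) == sp_b
        ]
        for rows, sp in ((rows_a, sp_a), (rows_b, sp_b)):
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    d = _pair_jc(rows[i], rows[j])
                    if d is not None and np.isfinite(d):
                        within[sp].append(d)
        for ra in rows_a:
            for rb in rows_b:
                d = _pair_jc(ra, rb)
                if d is not None and np.isfinite(d):
                    between.append(d)
    if not between:
        raise ValueError(
            f"no between-species comparisons for pair ({sp_a!r}, {sp_b!r})"
        )
    theta_a = float(np.mean(within[sp_a])) if within[sp_a] else None
    theta_b = float(np.mean(within[sp_b])) if within[sp_b] else None
    defined = [t for t in (theta_a, theta_b) if t is not None]
    if not defined:
        raise ValueError(
            "need at least one species with >= 2 sequences for the "
            "ancestral-theta approximation"
        )
    if theta_a is None or theta_b is None:
        warnings.warn(
            "one species has a single sequence; its theta is undefined and "
            "the ancestral approximation uses the other species only"
        )
    theta_anc = float(np.mean(defined))
    tau = (float(np.mean(between)) - theta_anc) / 2.0
    if tau < 0:
        warnings.warn(
            "between-species distance below within-species level; "
            "tau clamped to 0"
        )
        tau = 0.0
    return MomentEstimates(theta_a, theta_b, theta_anc, tau)
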