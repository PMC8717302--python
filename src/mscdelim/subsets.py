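"""Ranking loci by information content and building analysis subsets.

The sensitivity design compares coalescent estimates across differently
sampled locus subsets: the k most variable loci, all loci above or within
a band of parsimony-informative site counts, and fixed-size random draws
replicated several times.  "Most variable" is ranked primarily by
parsimony-informative site count with total variable-site count as the
tiebreaker (then locus id, so the ranking is a total order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SubsetSpec", "LocusSubset", "site_counts", "make_subsets"]


def site_counts(locus):
    """(variable, parsimony-informative) site counts for one locus.

    A column is variable when at least two distinct non-missing states are
    observed, and parsimony-informative when at least two states are each
    observed in at least two sequences.  Missing symbols (``N``, ``-``)
    never count as states.  A single-sequence locus yields (0, 0) with a
    warning.
    """
    rows = [s for s in locus.rows.values() if set(s) - {"N", "-"}]
    if len(rows) < 2:
        warnings.warn(
            f"locus {locus.locus_id!r}: fewer than 2 non-empty sequences; "
            "site counts are (0, 0)"
        )
        return 0, 0
    variable = informative = 0
    for col in range(len(rows[0])):
        counts = {}
        for s in rows:
            c = s[col]
            if c not in "N-":
                counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
    return variable, informative


@dataclass
class SubsetSpec:
    """One subset scheme of the sensitivity design.

    scheme
        ``k_most_variable`` (top-k by informative count), ``min_informative``
        (all loci with >= ``min_count`` informative sites),
        ``informative_range`` (informative count within [lo, hi] inclusive),
        or ``random`` (``n_loci`` drawn without replacement from loci with
        at least one variable site, ``replicates`` independent draws).
    """

    scheme: str
    k: int | None = None
    min_count: int | None = None
    bounds: tuple | None = None
    n_loci: int | None = None
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        need = {
            "k_most_variable": self.k,
            "min_informative": self.min_count,
            "informative_range": self.bounds,
            "random": self.n_loci,
        }
        if self.scheme not in need:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if need[self.scheme] is None:
            raise ValueError(f"scheme {self.scheme!r} is missing its parameter")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def label(self) -> str:
        if self.scheme == "k_most_variable":
            return f"top{self.k}"
        if self.scheme == "min_informative":
            return f"inf>={self.min_count}"
        if self.scheme == "informative_range":
            return f"inf[{self.bounds[0]},{self.bounds[1]}]"
        return f"rand{self.n_loci}"


@dataclass
class LocusSubset:
    """One replicate of one subset scheme: ordered list of locus ids."""

    spec: SubsetSpec
    replicate: int
    locus_ids: list

    @property
    def label(self) -> str:
        if self.spec.replicates > 1:
            return f"{self.spec.label}r{self.replicate + 1}"
        return self.spec.label


def make_subsets(loci, spec: SubsetSpec, counts=None):
    """Build the locus subsets (one :class:`LocusSubset` per replicate).

    ``counts`` may carry precomputed ``{locus_id: (variable, informative)}``
    to avoid rescanning alignments.  Random draws come from independent
    seeded streams per replicate, so replicate r is reproducible on its own.
    """
    if not loci:
        raise ValueError("empty dataset")
    if counts is None:
        counts = {loc.locus_id: site_counts(loc) for loc in loci}
    ids = [loc.locus_id for loc in loci]
    if spec.scheme == "k_most_variable":
        if spec.k > len(ids):
            raise ValueError(
                f"k={spec.k} exceeds the {len(ids)} available loci"
            )
        ranked = sorted(ids, key=lambda i: (-counts[i][1], -counts[i][0], i))
        return [LocusSubset(spec, 0, ranked[: spec.k])]
    if spec.scheme == "min_informative":
        chosen = [i for i in ids if counts[i][1] >= spec.min_count]
        return [LocusSubset(spec, 0, chosen)]
    if spec.scheme == "informative_range":
        lo, hi = spec.bounds
        chosen = [i for i in ids if lo <= counts[i][1] <= hi]
        return [LocusSubset(spec, 0, chosen)]
    # random: sample from loci with at least one variable site
    pool = [i for i in ids if counts[i][0] >= 1]
    if spec.n_loci > len(pool):
        raise ValueError(
            f"n_loci={spec.n_loci} exceeds the {len(pool)} variable loci"
        )
    out = []
    streams = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pick = rng.choice(len(pool), size=spec.n_loci, replace=False)
        chosen = [pool[j] for j in sorted(pick)]
        out.append(LocusSubset(spec, r, chosen))
    return out


def paper_default_specs(seed: int = 0):
    """The study's subset battery, scaled by what the dataset can support.

    10 most variable; all loci with >= 20 informative sites; 500 most
    variable; random 100/500/1000/5000 in replicates of three; and the
    10-20 variable-site band.  Schemes whose size exceeds the dataset are
    simply skipped by the pipeline.
    """
    return [
        SubsetSpec("k_most_variable", k=10),
        SubsetSpec("min_informative", min_count=20),
        SubsetSpec("k_most_variable", k=500),
        SubsetSpec("random", n_loci=100, replicates=3, seed=seed),
        SubsetSpec("random", n_loci=500, replicates=3, seed=seed + 1),
        SubsetSpec("random", n_loci=1000, replicates=3, seed=seed + 2),
        SubsetSpec("random", n_loci=5000, replicates=3, seed=seed + 3),
        SubsetSpec("informative_range", bounds=(10, 20)),
    ]
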