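"""Genealogical divergence index (gdi) scoring and classification.

For a pair of populations A and B with divergence time tau and
population-size parameter theta, ``gdi = 1 - exp(-2 tau / theta)`` is the
probability that two sequences sampled from A coalesce before the A-B
divergence, looking backward in time.  The heuristic reading: gdi < 0.2
suggests a single species, gdi > 0.7 suggests two distinct species, and
anything in between (including the boundaries) is ambiguous.

The formula's single-theta ambiguity is resolved directionally: A-vs-B
uses theta_A, B-vs-A uses theta_B, and the symmetric mean of the two is
the headline value.  Scores are computed per replicate run from the
posterior-mean tau and theta ("mean-params" mode; a per-sample mode with
credible intervals is also available) and averaged across replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import TraceLog

__all__ = [
    "compute_gdi",
    "classify_gdi",
    "GdiScore",
    "gdi_from_trace",
    "GdiEntry",
    "GdiMatrix",
    "gdi_matrix",
    "subset_distribution_summary",
]


def compute_gdi(tau: float, theta: float) -> float:
    """gdi = 1 - exp(-2 tau / theta); tau >= 0, theta > 0."""
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    return 1.0 - math.exp(-2.0 * tau / theta)


def classify_gdi(value: float) -> str:
    """'single' (<0.2), 'distinct' (>0.7), else 'ambiguous' (inclusive)."""
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"gdi must be in [0, 1], got {value}")
    if value < 0.2:
        return "single"
    if value > 0.7:
        return "distinct"
    return "ambiguous"


@dataclass
class GdiScore:
    """Directional and symmetric gdi for one ordered comparison."""

    group_a: str
    group_b: str
    gdi_ab: float
    gdi_ba: float
    mean: float
    ci_ab: tuple | None = None  # (2.5%, 97.5%) in per-sample mode
    ci_ba: tuple | None = None


def gdi_from_trace(trace: TraceLog, comparison, mode: str = "mean-params") -> GdiScore:
    """gdi of a pair of candidate groups from one posterior trace.

    ``mean-params`` evaluates the formula at the posterior-mean tau and
    theta (the headline procedure); ``per-sample`` evaluates it per
    retained sample and summarizes (mean and central 95% interval).
    """
    a, b = comparison
    tau = trace.tau_of(a, b)
    th_a = trace.theta_of(a)
    th_b = trace.theta_of(b)
    if mode == "mean-params":
        ab = compute_gdi(float(tau.mean()), float(th_a.mean()))
        ba = compute_gdi(float(tau.mean()), float(th_b.mean()))
        return GdiScore(a, b, ab, ba, 0.5 * (ab + ba))
    if mode == "per-sample":
        ab = 1.0 - np.exp(-2.0 * tau / th_a)
        ba = 1.0 - np.exp(-2.0 * tau / th_b)
        return GdiScore(
            a,
            b,
            float(ab.mean()),
            float(ba.mean()),
            float(0.5 * (ab.mean() + ba.mean())),
            ci_ab=(float(np.percentile(ab, 2.5)), float(np.percentile(ab, 97.5))),
            ci_ba=(float(np.percentile(ba, 2.5)), float(np.percentile(ba, 97.5))),
        )
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class GdiEntry:
    """Replicate-averaged gdi for one comparison."""

    group_a: str
    group_b: str
    mean: float
    sd: float
    n_replicates: int
    classification: str
    per_replicate: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.mean <= 1.0):
            raise ValueError("mean gdi outside [0, 1]")


@dataclass
class GdiMatrix:
    """Pairwise gdi means/SDs across replicate runs, with classification."""

    entries: dict = field(default_factory=dict)  # (a, b) -> GdiEntry
    label: str = ""

    def entry(self, a, b) -> GdiEntry:
        return self.entries[(a, b)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": f"{a} vs {b}",
                "mean_gdi": e.mean,
                "sd": e.sd,
                "n_replicates": e.n_replicates,
                "classification": e.classification,
            }
            for (a, b), e in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def values(self) -> np.ndarray:
        return np.array([e.mean for e in self.entries.values()])


def gdi_matrix(replicate_traces, comparisons, mode="mean-params", label="") -> GdiMatrix:
    """Average per-run gdi scores across replicates into a matrix.

    ``replicate_traces`` is either a list of traces shared by every
    comparison, or a mapping comparison -> list of traces.  Scores are
    computed independently per run and averaged; the classification is
    applied to the replicate mean.
    """
    entries = {}
    n_ref = None
    for comp in comparisons:
        a, b = comp
        traces = (
            replicate_traces[comp]
            if isinstance(replicate_traces, dict)
            else replicate_traces
        )
        if not traces:
            raise ValueError(f"no replicate traces for comparison {comp}")
        vals = tuple(
            gdi_from_trace(t, (a, b), mode=mode).mean for t in traces
        )
        if n_ref is None:
            n_ref = len(vals)
        elif len(vals) != n_ref:
            warnings.warn(
                f"comparison {comp} has {len(vals)} replicates, others {n_ref}"
            )
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        entries[(a, b)] = GdiEntry(
            a, b, mean, sd, len(vals), classify_gdi(mean), per_replicate=vals
        )
    return GdiMatrix(entries=entries, label=label)


def subset_distribution_summary(matrices: dict) -> pd.DataFrame:
    """Descriptive statistics and min-max-normalized scores per subset.

    ``matrices`` maps subset label -> :class:`GdiMatrix`.  The normalized
    column rescales each subset's scores to [0, 1] (min -> 0, max -> 1;
    a constant subset normalizes to 0.5), the form used to compare score
    distributions across locus subsets.  Rows are ordered by subset mean.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 subsets to compare")
    rows = []
    for lab, mat in matrices.items():
        v = mat.values
        lo, hi = float(v.min()), float(v.max())
        norm = (v - lo) / (hi - lo) if hi > lo else np.full_like(v, 0.5)
        rows.append(
            {
                "subset": lab,
                "n_comparisons": len(v),
                "mean_gdi": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "min": lo,
                "max": hi,
                "normalized": tuple(float(x) for x in norm),
            }
        )
    df = pd.DataFrame(rows).sort_values("mean_gdi").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
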