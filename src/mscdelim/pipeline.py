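"""End-to-end sensitivity experiment: simulate -> subset -> estimate -> gdi.

One call runs the full cross-validation design: generate (or load) a
multilocus dataset, build the configured locus subsets, run the
coalescent estimation on every subset replicate, score pairwise gdi per
run and average across replicates, and emit the cross-subset report
bundle — a tau/theta posterior summary per subset, a gdi matrix
(comparisons x subsets), a gdi distribution summary across subsets, and,
when enabled, aggregate delimitation-model posteriors.

Every stage draws its seed from one master ``SeedSequence`` with a fixed
spawn layout (stage index, subset index, replicate index), so any stage
can be re-run in isolation and the whole bundle is byte-identical under a
fixed configuration and seed.  Output files embed the config hash and
master seed; logs (stderr) carry timestamps but reports do not.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gdi import gdi_matrix, subset_distribution_summary
from .io import (
    IndividualMap,
    load_guide_tree,
    load_imap,
    load_multilocus,
    write_guide_tree,
    write_imap,
    write_multilocus,
)
from .mcmc import (
    GuideTreeDelimitation,
    McmcConfig,
    MscModel,
    aggregate_model_posteriors,
)
from .simulate import Scenario, generate_dataset, scenario
from .subsets import SubsetSpec, make_subsets, site_counts
from .trees import SpeciesTree

__all__ = [
    "ExperimentReport",
    "run_sensitivity_experiment",
    "load_config",
    "log",
]


def log(msg: str) -> None:
    ts = time.strftime("%Y-%m-%d %H:%M:%S")
    print(f"[{ts}] {msg}", file=sys.stderr)


@dataclass
class ExperimentReport:
    """In-memory handle on an experiment's outputs."""

    outdir: Path
    config_hash: str
    seed: int
    params_summary: pd.DataFrame
    gdi_table: pd.DataFrame
    gdi_distribution: pd.DataFrame | None
    model_posteriors: pd.DataFrame | None
    failures: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _comparisons(labels):
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def run_sensitivity_experiment(
    source,
    subset_specs,
    mcmc: McmcConfig,
    outdir,
    seed: int = 0,
    a10: bool = False,
    comparisons=None,
    write_traces: bool = False,
) -> ExperimentReport:
    """Run the subset-sensitivity design and write the report bundle.

    Parameters
    ----------
    source : Scenario or (loci, imap, guide_tree) triple
        A scenario is simulated with a seed spawned from ``seed``.
    subset_specs : list of SubsetSpec
        Schemes whose size exceeds the dataset are recorded as skipped.
    mcmc : McmcConfig
        ``n_runs`` controls the replicate runs per subset draw.
    outdir : path
        Created if needed; all CSV/JSON outputs land here.
    a10 : bool
        Also run guide-tree delimitation per subset and aggregate model
        posteriors across subsets and runs.
    comparisons : list of (group_a, group_b), optional
        Defaults to all unordered pairs of candidate species.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    sim_ss, mcmc_ss = master.spawn(2)
    if isinstance(source, Scenario):
        sim_seed = int(sim_ss.generate_state(1)[0]) % (2**31 - 1)
        log(f"simulating scenario {source.name!r} (seed {sim_seed})")
        loci, imap, truth = generate_dataset(source, sim_seed)
        guide = truth.guide_tree
        write_multilocus(loci, outdir / "dataset.phy")
        write_imap(imap, outdir / "dataset.imap.txt")
        write_guide_tree(truth.species_tree, outdir / "truth.tree.nwk")
        write_guide_tree(guide, outdir / "guide.tree.nwk")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "scenario": asdict(source),
                    "seed": sim_seed,
                    "het_loci": sorted(truth.het_loci),
                    "dropped_sparse_loci": truth.dropped_sparse_loci,
                },
                fh,
                indent=1,
            )
    else:
        loci, imap, guide = source
    labels = list(guide.labels)
    comparisons = comparisons or _comparisons(labels)
    counts = {loc.locus_id: site_counts(loc) for loc in loci}
    manifest_rows = []
    config_hash = mcmc.hash()
    failures = []
    matrices = {}
    param_rows = []
    a10_runs_all = {}
    loci_by_id = {loc.locus_id: loc for loc in loci}
    spec_streams = mcmc_ss.spawn(len(subset_specs))
    for si, spec in enumerate(subset_specs):
        try:
            subs = make_subsets(loci, spec, counts=counts)
        except ValueError as exc:
            log(f"subset {spec.label}: skipped ({exc})")
            failures.append({"subset": spec.label, "error": str(exc)})
            continue
        rep_streams = spec_streams[si].spawn(len(subs))
        for sub, rs in zip(subs, rep_streams):
            run_seed = int(rs.generate_state(1)[0]) % (2**31 - 1)
            chosen = [loci_by_id[i] for i in sub.locus_ids]
            for lid in sub.locus_ids:
                manifest_rows.append(
                    {
                        "subset": sub.label,
                        "locus_id": lid,
                        "variable_sites": counts[lid][0],
                        "informative_sites": counts[lid][1],
                    }
                )
            log(
                f"subset {sub.label}: {len(chosen)} loci, "
                f"{mcmc.n_runs} run(s), seed {run_seed}"
            )
            cfg = replace(mcmc, seed=run_seed)
            try:
                res = MscModel(chosen, imap, guide, cfg).fit()
            except Exception as exc:  # partial failure: record, continue
                log(f"subset {sub.label}: FAILED ({exc})")
                failures.append({"subset": sub.label, "error": str(exc)})
                continue
            mat = gdi_matrix(res.traces, comparisons, label=sub.label)
            matrices[sub.label] = mat
            mat.to_csv(outdir / f"gdi_{sub.label}.csv")
            if write_traces:
                for k, t in enumerate(res.traces):
                    t.to_tsv(
                        outdir / f"trace_{sub.label}_run{k + 1}.tsv",
                        outdir / f"trace_{sub.label}_run{k + 1}.json",
                    )
            st = res.trace.species_tree
            row = {
                "subset": sub.label,
                "n_loci": len(chosen),
                "seed": run_seed,
                "tau_root_mean": float(
                    np.mean([t.tau[:, st.root].mean() for t in res.traces])
                ),
                "tau_root_sd": float(
                    np.mean([t.tau[:, st.root].std(ddof=1) for t in res.traces])
                ),
            }
            for lab in labels:
                row[f"theta_{lab}_mean"] = res.posterior_mean_theta(lab)
            param_rows.append(row)
            if a10:
                a10_seed = (run_seed + 1) % (2**31 - 1)
                a10_cfg = replace(mcmc, seed=a10_seed)
                try:
                    dres = GuideTreeDelimitation(chosen, imap, guide, a10_cfg).fit()
                    a10_runs_all[sub.label] = dres.runs
                except Exception as exc:
                    log(f"subset {sub.label} (delimitation): FAILED ({exc})")
                    failures.append(
                        {"subset": sub.label + ":a10", "error": str(exc)}
                    )
    pd.DataFrame(manifest_rows).to_csv(outdir / "subsets_manifest.csv", index=False)
    params = pd.DataFrame(param_rows)
    params.to_csv(outdir / "params_summary.csv", index=False)
    gdi_rows = []
    for lab, mat in matrices.items():
        for (a, b), e in mat.entries.items():
            gdi_rows.append(
                {
                    "comparison": f"{a} vs {b}",
                    "subset": lab,
                    "mean_gdi": e.mean,
                    "sd": e.sd,
                    "classification": e.classification,
                }
            )
    gdi_table = pd.DataFrame(gdi_rows)
    if not gdi_table.empty:
        wide = gdi_table.pivot(index="comparison", columns="subset", values="mean_gdi")
        wide.to_csv(outdir / "gdi_matrix.csv")
    gdi_table.to_csv(outdir / "gdi_long.csv", index=False)
    dist = None
    if len(matrices) >= 2:
        dist = subset_distribution_summary(matrices)
        dist.to_csv(outdir / "gdi_distribution.csv", index=False)
    model_df = None
    if a10 and a10_runs_all:
        all_runs = [run for runs in a10_runs_all.values() for run in runs]
        agg = aggregate_model_posteriors(all_runs)
        model_df = agg.to_frame()
        model_df.to_csv(outdir / "model_posteriors.csv", index=False)
        agg.count_frame().to_csv(outdir / "species_count_probs.csv", index=False)
    with open(outdir / "experiment.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "config_hash": config_hash,
                "mcmc": asdict(mcmc),
                "subsets": [s.label for s in subset_specs],
                "failures": failures,
            },
            fh,
            indent=1,
        )
    return ExperimentReport(
        outdir=outdir,
        config_hash=config_hash,
        seed=seed,
        params_summary=params,
        gdi_table=gdi_table,
        gdi_distribution=dist,
        model_posteriors=model_df,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# flat config files


def load_config(path):
    """Parse a flat YAML config with scenario/subsets/mcmc/gdi/tipdown blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "scenario" in raw:
        blk = dict(raw["scenario"])
        if "name" in blk and len(blk) == 1:
            out["scenario"] = scenario(blk["name"])
        else:
            blk.setdefault("name", "custom")
            out["scenario"] = Scenario(**blk)
    if "mcmc" in raw:
        out["mcmc"] = McmcConfig(**raw["mcmc"])
    if "subsets" in raw:
        out["subsets"] = [SubsetSpec(**blk) for blk in raw["subsets"]]
    for key in ("gdi", "tipdown"):
        if key in raw:
            out[key] = dict(raw[key])
    return out
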