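# mscdelim

Species-delimitation validation for RADseq-style multilocus data under
the multispecies coalescent (MSC).

Biologists delimiting closely related species — the motivating case is
lichen-forming fungi sampled as short haploid RADseq loci from one or two
individuals per candidate species — face a known failure mode: genome-scale
coalescent methods happily "delimit" population structure as species.  This
package implements the validation side of that workflow:

* **Fixed-tree estimation** (`MscModel.fit()`): full-likelihood MCMC
  estimation of divergence times τ and population-size parameters θ
  (both in expected substitutions/site) on a given species tree, with
  JC69 likelihoods, conjugate inverse-gamma θ updates and rubber-band τ
  moves — the "A00"-style analysis.
* **gdi scoring** (`mscdelim.gdi`): the genealogical divergence index
  `gdi = 1 − exp(−2τ/θ)`, the probability that two sequences coalesce
  before the species divergence; `< 0.2` suggests one species, `> 0.7`
  two, between is ambiguous.  Scores are computed per replicate run from
  posterior means, averaged, and classified.
* **Guide-tree delimitation** (`GuideTreeDelimitation.fit()`):
  reversible-jump MCMC over split/collapse states of the guide tree's
  internal nodes, yielding posterior probabilities of delimitation
  models and species counts — the "A10"-style analysis.
* **Tip-down collapsing** (`run_tipdown`): iteratively merge sister
  candidates whose average pairwise gdi is ≤ 0.2 until a fixed point.
* **Synthetic data with truth** (`mscdelim.simulate`): censored-coalescent
  gene trees, JC69 sequences, per-locus missingness, and the Stacks-style
  SNP filter cascade (`--max-obs-het 0`, MAF ≥ 5%, presence ≥ 30%,
  first SNP per locus), so every stage is testable without any download.
* **Sensitivity design** (`run_sensitivity_experiment` / the `mscdelim`
  CLI): most-variable / informative-band / random locus subsets with
  replicate runs, and cross-subset τ/θ, gdi and model-posterior reports.

## Worked example

Simulate a two-species dataset at known truth (θ = 0.005 on every branch,
τ = 0.002; 100 loci of 143 bp, four haploid sequences per species), fit
the MSC on the true tree, and score the pair:

```python
from mscdelim import McmcConfig, MscModel, gdi_from_trace, scenario
from mscdelim.simulate import generate_dataset

loci, imap, truth = generate_dataset(scenario("two-species"), seed=11)
cfg = McmcConfig(iterations=55_000, thin=5,
                 theta_prior_mean=0.004, tau_prior_mean=0.002, seed=7)
res = MscModel(loci, imap, truth.guide_tree, cfg).fit()
print(res.summary())
s = gdi_from_trace(res.trace, ("A", "B"))
print(f"gdi A vs B: {s.gdi_ab:.3f} / B vs A: {s.gdi_ba:.3f} "
      f"(symmetric mean {s.mean:.3f})")
```

```
Multispecies coalescent estimation (fixed species tree)
runs: 1   samples/run: 10000   loci: 100
                mean          sd       q2.5      q97.5     ess
parameter
theta_A   0.00441685 0.000808848 0.00311478 0.00629761 98.9512
theta_B   0.00464845 0.000794527 0.00328693 0.00638854 298.231
theta_A+B 0.00466928 0.000659422 0.00343514 0.00600674 197.648
tau_A+B   0.00171723 0.000236396 0.00128253 0.00220868 130.206
lnL         -21857.5     13.7549   -21884.7   -21830.8 201.748
gdi A vs B: 0.540 / B vs A: 0.522 (symmetric mean 0.531)
```

The posterior means sit within ~12% of the generating values (θ̂ ≈
0.0044–0.0047 against 0.005; τ̂ ≈ 0.0017 against 0.002 — the residual gap
is the finite-locus coalescent noise of this particular dataset, as the
moment estimator confirms), and the gdi lands in the ambiguous band, as
it should at 2τ/θ ≈ 0.8.

The same machinery drives the shell interface:

```
mscdelim simulate --scenario paper-like-small --seed 7 --out data/
mscdelim a00 --data data/dataset.phy --imap data/dataset.imap.txt \
         --tree data/guide.tree.nwk --seed 1 --out runs/a00
mscdelim gdi --trace runs/a00.run1.tsv --pair A,B
mscdelim tipdown --data data/dataset.phy --imap data/dataset.imap.txt \
         --tree data/guide.tree.nwk --seed 1 --out tipdown.json
```

Study-scale chain lengths (500k/2M iterations) are available behind
`--paper-scale`; defaults are desk-scale.

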