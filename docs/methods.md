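# Methods

`mscdelim` implements a species-delimitation validation workflow for
RADseq-style multilocus data under the multispecies coalescent (MSC):
Bayesian estimation of divergence times and population-size parameters on
a fixed species tree, genealogical-divergence-index (gdi) scoring with
replicate averaging, guide-tree delimitation-model posteriors, an
iterative tip-down collapsing algorithm, and a loci-subsampling
sensitivity design.  Because the kind of dataset this targets (thousands
of short haploid loci from one or two individuals per candidate species)
is rarely redistributable, the package ships a first-class synthetic-data
generator with recorded truth, and every downstream stage is validated
against that truth.

## The model

A rooted binary species tree over `S` candidate species carries a
divergence time `tau` at each internal node and a population-size
parameter `theta = 4*N*mu` on every branch (including the root's
ancestral branch).  Both are expressed in expected substitutions per
site; no generation times or calendar years appear anywhere.  Within a
branch carrying `k` gene-tree lineages, each pair coalesces at rate
`2/theta`, so the waiting time to the next coalescence is
Exponential(`k*(k-1)/theta`); lineages that fail to coalesce are handed
to the parent branch at its `tau` (the censored, or truncated,
coalescent).  Sequences evolve along each gene tree under JC69 with
uniform base frequencies.  JC69 is used consistently in the simulator and
the likelihood; this is a deliberate simplification (see Limitations).

The gdi for an ordered pair (A, B) with divergence time `tau` is

    gdi = 1 - exp(-2*tau/theta_A)

the probability that two sequences from A coalesce more recently than the
A-B divergence.  Heuristic reading: `gdi < 0.2` one species, `gdi > 0.7`
two species, otherwise ambiguous; the boundary values classify as
ambiguous because the labels are defined by strict inequalities.  Since
the formula is written with a single theta, scores are computed
directionally (`theta_A` for A-vs-B, `theta_B` for B-vs-A) and the
symmetric mean of the two is the headline value.

## Inference

### Fixed-tree estimation (`MscModel`, the "A00" analysis)

The posterior targeted is

    p(tau, theta, G | D)  ∝  p(tau, theta) * prod_l [ MSC(G_l | tau, theta) * P(D_l | G_l) ]

over per-locus gene trees `G_l` (topology and node ages), sampled by
Metropolis-within-Gibbs:

* **Genealogy resimulation** — an independence Metropolis–Hastings
  proposal redraws a locus's entire genealogy from the censored
  coalescent at the current `(tau, theta)`.  The MSC prior and the
  proposal density cancel exactly, leaving the JC69 likelihood ratio.
  With short, weakly informative loci (143 bp) acceptance is high and the
  move replaces the usual constrained subtree-regraft kernels.
* **Node-age window moves** — one random internal gene node per locus per
  sweep, proposed uniformly between its structural bounds (children's
  ages, the MSC lower bound of the joined populations, the parent's age);
  the root age moves multiplicatively.
* **Conjugate theta Gibbs** — the censored-coalescent density depends on
  `theta_p` only through the per-population sufficient statistics `C_p`
  (number of coalescences) and `A_p = sum k(k-1) dt` (integrated pair
  time), so with an inverse-gamma prior the full conditional is
  inverse-gamma(`alpha + C_p`, `beta + A_p`) and theta is drawn exactly.
  With `estimate_theta` off, theta stays fixed at the prior means.
* **Rubber-band tau moves** — a proposed `tau` (uniform window between
  the structural neighbors; multiplicative at the root) is accompanied by
  a piecewise-linear rescaling of the gene-node ages in the three
  populations meeting at the moved node, with the matching Jacobian.
  Without this coupling the conditional posterior of `tau` given the
  genealogies is extremely narrow and chains stall; with it, tau
  acceptance sits near 10-30%.
* **Global scale move** — every few sweeps, all node ages and divergence
  times are multiplied by a common factor, decorrelating the overall
  timescale.

Priors: inverse-gamma(shape `alpha = 3`, mean = configured value) on each
theta and on the root tau — the parameterization under which a stated
"prior mean" is well defined — and uniform order statistics on the
non-root tau given the root.  Default prior means are `theta = 1e-4`,
`tau = 3e-5` (the analysis design's values); runs on data simulated at
other scales should set prior means near a pilot (moment) estimate, which
is how the two-stage "naive analysis first" design works in practice.

Chain defaults are desk-scale: 55,000 total iterations of which an extra
10% (5,000) is burn-in, thinning 5.  The study-scale lengths (500,000
retained iterations for estimation runs; 2,000,000 for tip-down rounds;
100,000 with 20,000 burn-in for delimitation) are available through the
configuration and the CLI `--paper-scale` flag; nothing in the algorithm
depends on the run length.

All kernel randomness comes from one MT19937 stream seeded per chain;
multi-run fits spawn distinct 31-bit seeds from the configured master
seed, so every result in the package is exactly reproducible.

### Guide-tree delimitation (`GuideTreeDelimitation`, the "A10" analysis)

Delimitation models are split-flag vectors over the guide tree's internal
nodes under ancestry closure (a split child implies a split parent); a
collapsed node has `tau = 0` and its populations merge.  A
reversible-jump move proposes, at a random eligible node, either a split
(drawing the new `tau` uniformly below the smallest cross-clade
coalescence age, so the genealogies — and hence the likelihood — are
untouched and the acceptance ratio reduces to coalescent-density, prior
and proposal terms) or the reverse merge.  Between jump moves the sampler
applies the full fixed-tree kernel to the current model.  The model prior
is uniform over valid split vectors; within a model, split nodes take
Uniform(0, `tau_parent`) priors with an inverse-gamma root.  Posterior
model probabilities are visit frequencies; aggregation across replicate
runs is the arithmetic mean of each model's posterior (absent model = 0),
and the species-count marginal sums aggregated probabilities by count.

### Moment oracle

`moment_estimates` provides an MCMC-free cross-check for a species pair:
within-species theta is the mean JC-corrected pairwise distance,
ancestral theta is approximated by the mean of the two within-species
values, and `tau = (between-distance - theta_ancestral)/2`, clamped at
zero with a warning.  It is used in tests to validate the sampler, never
the other way around.

### Tip-down sweep (`run_tipdown`)

Each round fits the current tree with `runs_per_iteration` independent
chains (10 by default, matching the replicate design this emulates),
computes for every cherry the average cross-pair gdi from posterior-mean
parameters per run, averages across runs, and collapses **all** cherries
at or below the threshold (`<= 0.2`) simultaneously.  Simultaneous
collapse keeps the round order-independent; the per-round history records
every tested cherry, its per-run scores, mean and SD, so a sequential
reading can be audited after the fact.  Only cherries are tested per
round — deeper nodes become testable as their children merge — and the
candidate count strictly decreases until a fixed point, so at most
`n_tips - 1` rounds occur.  Runs whose log-likelihood effective sample
size falls below a floor (default 50) are flagged in the history, not
discarded.

## Synthetic data

The generator emulates the target data shape: 143-bp haploid loci, one
or two sequences per individual per locus, around 17-35 candidate
species, coalescent scales near `theta = 1e-4` and `tau = 3e-5`, and
per-(locus, individual) Bernoulli missingness whose rate can be set to
mimic the wide per-sample mapping-rate spread of reference-mapped RADseq
(the real missingness process — enzyme-site dropout, coverage — is not
modeled; Bernoulli is a documented stand-in).  Since the mycobiont is
haploid, apparent heterozygosity marks contamination: a configurable
fraction of loci is flagged heterozygous solely so the `max_obs_het 0`
filter has something to remove.

The SNP filter cascade mirrors the Stacks `populations` settings used for
such data, in order: loci with more heterozygous calls than
`max_obs_het` (default 0) are dropped; SNPs with minor-allele frequency
below `min_maf` (default 0.05, computed as 1 minus the major-allele
frequency among observed haploid calls) are dropped; loci genotyped in
fewer than `min_presence` (default 0.30) of individuals are dropped;
with `single_snp` on, only the leftmost retained SNP per locus is kept in
the SNP table.  Thresholds are inclusive on the keep side (MAF exactly
0.05 and presence exactly 30% are retained).  A locus whose SNPs all fail
the MAF filter is dropped as uninformative.  Loci left with fewer than
two sequences by missingness are dropped and recorded.

Named scenarios pin the study conditions used throughout the tests:
`paper-like-small` (17 species x 2 samples, 500 loci, theta 1e-4, tau
3e-5, 20% missingness), `two-species` (theta 0.005, tau 0.002, 100 loci,
4 sequences per species — the recovery benchmark), `panmictic-pair`
(four candidates of which two are one true species), `deep-divergence`
and `three-deep` (all divergences at `2*tau/theta` of 10-20).

What passing tests on these data do and do not show: they validate the
estimator, the scoring and the decision rules against data generated
under the model's own assumptions (JC69, free recombination between and
no recombination within loci, no gene flow, independent missingness).
They cannot detect misspecification effects present in real RADseq —
linked loci, introgression, base-composition bias, allele dropout
correlated with divergence — and the package makes no claims about those.

## Locus subsets

`site_counts` classifies alignment columns (missing symbols never count
as states): variable needs two observed states, parsimony-informative
needs two states each in at least two sequences.  "Most variable"
ranking orders by informative count, then variable count, then locus id —
a total order, chosen because the only precisely defined subset rule in
the emulated design (the at-least-20-informative-sites subset) is stated
in informative sites.  Random subsets draw without replacement from loci
with at least one variable site, with independently seeded replicate
streams.  The default battery is 10 most variable, >= 20 informative,
500 most variable, random 100/500/1000/5000 in triplicate, and the
10-20 informative band.

## Numerical choices

* Felsenstein pruning under JC69 uses the one-exponential form of the
  transition matrix per branch and site-pattern compression; no partial
  rescaling is applied (alignments here are far from underflow).
  Missing states contribute all-ones partials, so an all-missing column
  has likelihood exactly 1.
* The effective sample size is `n / (1 + 2*sum(rho_t))` with Geyer's
  initial-positive-sequence truncation of the autocorrelation sum.
* A gene-tree proposal that would place a coalescence below the
  divergence of the populations it joins has density zero and is
  rejected; the tau rubber band never produces such a state by
  construction.
* Tie-breaking is everywhere lexicographic by locus id or label so that
  reruns are byte-identical.
* Degenerate inputs: single-sequence loci are rejected at model
  construction; a candidate species with one sampled sequence is allowed
  (its theta is then prior-dominated and a warning is the moment
  estimator's response); an empty filter result is legal and reported.

## Limitations

JC69 only; no migration or introgression model; no joint
topology-and-delimitation inference (the guide tree is fixed and comes
from elsewhere); the delimitation prior is uniform over models rather
than tunable; recombination is assumed absent within loci; the
missingness model is independent Bernoulli.  Problem sizes in the test
suite and acceptance script are desk-scale (tens to hundreds of loci,
10^4-10^5 iterations) — chosen so the whole validation battery runs on a
laptop core — and the study-scale settings are exposed but not exercised
by default.
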