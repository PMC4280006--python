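# Methods

This note records the models implemented in `gmycdelim`, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Trees

`treeio.UltrametricTree` holds a rooted, strictly bifurcating tree with
branch lengths in time units.  Node ages are computed once at parse time:
the root age is the maximum tip depth and every tip must sit at age 0
within a relative tolerance of 1e-6 × root age (Newick files written at
finite precision rarely close exactly).  Polytomies are rejected by
default; on request they are resolved randomly with inserted branches of
length 1e-8 × root age — zero-length branches would create empty intervals
in the threshold likelihood, so the inserted length is small but positive.
`lineages_at(t)` counts branches with `child age ≤ t < parent age`
(half-open, tipward-closed), which fixes the behaviour when `t` coincides
with a node age.  Near-zero internal branches are treated as valid
intervals of positive length.

## The single-threshold GMYC model

### Model

Given an ultrametric single-locus tree and a threshold age `T`, nodes at
age `≥ T` are speciation events of a Yule-type process and younger nodes
are coalescences inside their *entity* — the clade subtended by a branch
crossing `T`.  In an inter-event interval the process rates are
`λ_spec·k^p_spec` (with `k` the number of diversification lineages; the
diversification process stops at `T`) and `λ_coal·(n_c(n_c−1))^p_coal`
summed over entities.  The exponents default to 1 (pure Yule / neutral
coalescent) and are exposed in `GmycConfig` as a generalization; no claim
is made that any particular published analysis used generalized exponents.

A node exactly at the threshold is a **speciation** event.  This is the
only reading under which a candidate threshold placed at the youngest
species split ends the diversification exposure exactly there; under the
opposite tie convention, the event-free span between the oldest
coalescence and the youngest speciation is charged to the diversification
process and the scan systematically over-splits.

### Likelihood

The log-likelihood is the joint density of the labeled tree:

- waiting-time terms: each event contributes the log rate of its process
  (speciation with the rootward lineage count, coalescence with the
  tipward count) minus the integrated total rate over all intervals;
- ranked-topology terms: each event contributes `−log C(k,2)` over the
  lineage pairs on its tipward side.  Both the Yule process and the
  Kingman coalescent induce the uniform distribution on ranked labeled
  histories, so these factors make every process — and the one-process
  null — a normalized density of the same observed object.

The topology terms matter: without them the per-process likelihoods and
the null (whose `n(n−1)` law carries large combinatorial factors) are not
mutually comparable, the null spuriously dominates by hundreds of log
units, and the likelihood-ratio test is meaningless.  With them, on data
simulated from the mixed model the mixed maximum exceeds the null in every
tested replicate and the LRT is positive and large.

With the exponents fixed, the two rates are independent Poisson-exposure
parameters, so the per-threshold MLE is events/exposure in closed form;
the 50×50 rate-grid oracle in the tests confirms the closed form is the
maximizer.  (A quasi-Newton refinement step would be a no-op and is
omitted.)

### Scan, weights, supports

Candidate thresholds are the distinct internal-node ages, excluding the
youngest (no coalescent event) and the root age (no diversification
exposure), which are structurally degenerate; a midpoint rule is available
as an option.  All candidates share parameter count 3 (two rates + the
threshold), so AIC differences reduce to log-likelihood differences and
the Akaike weights are `exp(lnL_j − lnL_max)` normalized.

Per split at age `a`: coalescence support `Σ_{T_j ≥ a} w_j`, speciation
support `Σ_{T_j < a} w_j`.  The "older or equal" bookkeeping is kept
verbatim from the field's usage even though, at exact equality, the
likelihood convention classifies the node as speciation; the tie case
carries one candidate's weight and does not affect the 0.95 cutoff in
practice.

The default confidence set is all candidates within 2 log-likelihood units
of the maximum (a cumulative-weight 0.95 rule is available).  The induced
classification is constant for `T ∈ (a_{j−1}, a_j]` over consecutive node
ages, so the reported threshold range extends its lower end down to the
node age below the youngest qualifying candidate.  The entity-count range
is the min/max entity count over the confidence set.  These interval
definitions are this package's choices; no claim is made that they match
any particular published interval construction.

The null model for the LRT is a single branching process with rate law
`λ·(n(n−1))^p` over all lineages jointly (one parameter; LRT df = 2, with
the usual caveat that the threshold is absent under the null, so the χ²
reference is approximate).

### Known limitation

On data with no species structure (a single-population coalescent) the
scan still finds a data-tailored partition, and because the partition is
chosen after seeing the tree the LRT is anticonservative: in simulations
it is an order of magnitude smaller than on structured data but not near
zero.  Significance claims for weakly structured data should rely on the
per-split supports and the entity-count range, not the LRT alone.

## K2P distances, group summaries, haplotypes

`k2p` uses pairwise deletion: a site enters `P` (transitions), `Q`
(transversions) and the site count only if both sequences carry an
unambiguous A/C/G/T there; IUPAC partial ambiguities are treated as
missing rather than probabilistically resolved.  Whether the original
MEGA-style analyses used pairwise or complete deletion is not stated
anywhere authoritative; pairwise deletion is the documented default here.
Pairs with `1−2P−Q ≤ 0` or `1−2Q ≤ 0` are *saturated*: the scalar function
raises an error carrying P and Q, the matrix builder stores NaN with a
warning.  `k2p_variance` implements the standard delta-method variance,
used by the simulation consistency tests.  Distances are proportions
internally; the CLI's percent display is cosmetic.

Haplotype identity is exact full-string equality over all columns, with
gaps and ambiguity codes as literal characters — removing ambiguous
columns pair-by-pair would make identity non-transitive.  An option
removes columns that are ambiguous in *any* sequence before comparing.

## MOTU merging

Entities merge bottom-up over the entity tree: among all sister pairs
(cherries of the current pruned tree) whose mean between-group K2P
distance over all original sequence pairs is below the threshold (default
0.073), the closest pair merges and becomes a leaf; iterate to fixpoint.
Consequences of this design:

- every MOTU is a clade of the entity tree (matching how published MOTUs
  are drawn on trees);
- group means are sums of original pairwise distances, so they are exact
  under merging and monotone-friendly (larger thresholds never produce
  more MOTUs);
- the fixpoint is order-independent: disjoint qualifying cherries do not
  affect each other's means, and merges only create new cherries above —
  the exhaustive all-orders oracle in the tests certifies this on every
  random configuration it checks.

Mean linkage (not minimum) and the monophyly constraint are documented
interpretations; a tree-free mode (`linkage="free"`) is provided but off
by default.  Distances reported for published datasets are group means,
which is why mean linkage is the default.

## Fossil calibration densities

A calibration is `age = offset + X` with `log X ~ Normal(0, sd²)`:
"zero mean" refers to the log scale, because only under that convention do
the printed (sd, offset, 5%, 95%) tuples of the reference calibrations
cohere.  The quantiles are `offset + exp(±z·sd)` with
`z = 1.6448536269514722`.  The inverse problem is solved from
`q95 − q05 = 2·sinh(z·sd)` by bracketed root-finding (Brent, xtol 1e-10)
and back-substitution; the round trip closes to better than 1e-6 over
`sd ∈ [0.05, 3]`, `offset ∈ [0, 50]`.  Display rounding is two decimals,
half-even.  One flag worth surfacing: for the *Apodemus*-style calibration
(sd 0.54, offset 4.89) this convention gives a 95% quantile of 7.32,
while the value is sometimes quoted as 7.30; whether that is a typo or a
deliberate truncation cannot be decided from the numbers alone, so the
discrepancy is documented rather than absorbed.

## Trait CTMC and ancestral reconstruction

A k-state (default 3: mountain / forest / savannah) CTMC with free
nonnegative off-diagonal rates (asymmetric: opposite directions may
differ), scaled by a strict-clock multiplier.  Tips carry exactly one
state — multi-habitat taxa must be coded by their most widespread habitat,
mirroring the single-state coding used with discrete-trait machinery in
dating software.  The likelihood is Felsenstein pruning with per-branch
`exp(Q·t)` (SciPy's scaling-and-squaring Padé implementation, applied to
the stacked branch array); marginal ancestral probabilities use the
standard up–down pass with per-node rescaling; MAP ties break toward the
first state in the state tuple.

The root distribution defaults to uniform (the base frequencies of the
original Bayesian analyses are unrecoverable); a fixed distribution is
available.  Rate fitting is L-BFGS-B over log rates from a fixed start
grid, hence deterministic.  The rates are bounded above by **five times
the parsimony change density** (observed-states−1 per unit of total branch
length): the likelihood surface of a single trait realization is nearly
flat in the high-rate direction, and unbounded fits drift to solutions
whose marginals collapse to the stationary distribution, destroying the
ancestral signal even though the likelihood is marginally higher.  The
bound is a regularization choice, calibrated so that on simulated traits
(~5 expected changes on a 50-tip tree) the fitted model recovers the
generating root state in well over 80% of replicates while the fitted
likelihood still dominates the true-model likelihood.  If all tips share
one state the fit degenerates to a zero-rate model with a warning.

As the rate multiplier grows, interior marginals converge to the
generator's stationary distribution (which plays the role of the base
frequencies), not to the root prior; the tests assert exactly that.

## Synthetic data

The generator is the generative counterpart of the delimitation model and
defines the conditions under which the recovery guarantees are tested:

- **Species tree:** Yule process started from two lineages, run until S
  lineages; going backward from the threshold `T`, the interval with k
  lineages lasts Exp(λ_spec·k), and the youngest split sits a fresh
  Exp(λ_spec·S) above `T` (memoryless stopping), so every speciation is
  strictly older than `T`.
- **Within-species coalescents:** Kingman-style with total rate
  `λ_coal·j(j−1)` for j lineages (matching the likelihood's rate law),
  grafted below `T`; depths exceeding `T` are handled by rejection
  (resimulate, cap 1000 attempts, then error), which keeps the node-age
  distribution exactly the conditional coalescent rather than a truncated
  one.  `lineages_at(tree, T)` therefore equals S by construction.
- **Sequences:** root drawn uniformly over A/C/G/T; branches apply the
  closed-form K2P transition probabilities with transition/transversion
  rate ratio κ and overall rate in substitutions/site/time.
- **Traits:** Gillespie simulation down the tree from a known root state,
  with the internal-node truth retained for recovery tests.
  `scale_rates_to_expected_changes` converts a target expected change
  count into a rate multiplier via the mean exit rate (uniformization).

Defaults: S = 20 species, 4 samples each, λ_spec = 1, λ_coal = 50 (the
50-fold rate separation that makes delimitation well-posed), threshold 1.0,
L = 1000 bp, κ = 4, rate 0.01.  The `nannomys-like` preset mirrors the
empirical regime of a pygmy-mouse-style survey: 27 species, 1–12 samples
per species, 741 bp, threshold 0.46 Mya, rate 0.02 subs/site/Mya, κ = 5 —
chosen so that within-species K2P distances stay below ~2.5% and
between-species distances span roughly the 2–26% band, reproducing the
barcode gap that the 7.3% merge rule relies on.

What the generator does **not** emulate: substitution-rate heterogeneity
across sites or lineages (no gamma), indels and sequencing error,
gene-tree estimation error (trees are used as if known), migration or
incomplete lineage sorting across species boundaries, and uneven
geographic sampling.  Passing recovery tests therefore demonstrate the
correctness of the estimators under the model's own assumptions, not
robustness to the ways real barcoding data violate them.

## Problem sizes used in the tests

Oracle suites run on exhaustively enumerable instances (≤ 5–6 tips, 100–200
random configurations per operation).  Recovery experiments use 50 seeded
replicates per condition: species counts S ∈ {5, 20, 49} for the GMYC scan
and a ~50-tip tree with ~5 expected changes for the trait root-state
experiment.  The K2P consistency check uses 10000-site pairs.  These sizes
give Monte-Carlo error comfortably inside the asserted 3-SE and 90%/80%
bands while keeping the default suite around a minute on one CPU.
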