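# Methods

## The generative model

One community represents a single study site with three trophic levels:
plants (level 1), herbivores (2), and natural enemies of the herbivores
(3, e.g. parasitoids). Links exist only between adjacent levels. The
pre-specified inputs are per-level species richness `R1..R3` (integers),
per-level total abundance `A1..A3` (individuals), and two diet-breadth
exponents `α2, α3 ≥ 1`.

**Species-abundance distributions.** Each level draws `Ri` values from a
lognormal with μ=0 and σ=1, scales them to sum to `Ai`, and rounds to
integers. Rounding can produce zero-abundance species; these are dropped
from the community (richness shrinks, the total is not re-scaled). The
alternative — clamping them to one individual — floods the community with
singletons and roughly doubles every richness estimate downstream, which is
why it is not used.

**Diet breadths.** Each consumer species draws an integer diet breadth k
from the truncated discrete Pareto pmf `p(k) ∝ α k^-(α+1)`, k in
`{1..R_lower}`, the discretized density of the Pareto I distribution with
survival function `S(y) = (1/y)^α`. With α near 1 a level contains a few
broad generalists; by α = 5 almost every species is a strict specialist.
`R_lower` here is the number of resource species *present* (nonzero
abundance): diet lists are then filled by sampling that list uniformly with
replacement, duplicates kept. Enemy diets are drawn over the herbivore
species still present after herbivore attachment, since that is the
community an arriving enemy actually encounters.

**Assembly.** Hosts can carry at most one consumer individual. Consumer
species are processed in a seeded random order (index order would privilege
low-index species); individual i of a species starts at position `i mod L`
of its length-L diet list and walks forward until it finds a host species
with a free individual, claiming one uniformly at random. An individual is
removed from the community only when every species in its diet is fully
occupied or absent. Duplicated diet entries therefore direct proportionally
more individuals to that host. Unattached consumers are pruned, so realized
richness and abundance never exceed the configured values. Communities that
end up with no herbivores or no enemies are retained and flagged, not
re-drawn — re-drawing would distort the configured parameter distributions.

**Sampling.** The field protocol is simulated by censusing plant
individuals one at a time, in a seeded uniform random order, without
replacement, until every plant has been inspected. Each sampled plant
reveals its herbivore and that herbivore's enemy, if present (detection is
perfect by assumption). Interaction types are ordered species pairs (PH,
HE) or complete ordered triples (PHE); counts are of individual interaction
events. Accumulation curves carry the previous value through rows without a
qualifying interaction and are undefined before the first one.

## Metrics

* **Inverse Simpson diversity** `1/Σp²` is used for both species and
  interaction types; it ranges from 1 to the observed richness.
* **Species diversity of a network view**: for the two-level views (PH, HE)
  it is computed over the individuals participating in that view's events;
  for the complete PHE view it is the community species diversity (every
  realized individual, all levels). This asymmetry is deliberate: the
  complete-triple interaction types are conditioned on a chain of sampling
  events that most of the community never completes, which is exactly why
  the species/interaction relationship is much looser for PHE than for the
  two-level views.
* **Chao1** uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`
  (classic `F1²/2F2` available). "Species" Chao1 and species rarefaction
  characterize the *generated* abundance distribution of the view's levels
  (pre-assembly, nonzero species); "interaction" estimates use the realized
  event counts.
* **Rarefaction** comes in two flavours. `rarefy()` is a bootstrap
  accumulation curve: individuals are resampled i.i.d. from the relative
  abundances (with replacement), so its expectation at sample size m is
  `Σ(1−(1−p)^m)` and the curve does not reach S_obs. The slope statistic —
  the finite-difference slope of the curve at the smallest sample size
  reaching half the observed richness — defaults instead to the *classical*
  (hypergeometric, without-replacement) expected-richness curve, evaluated
  in closed form and located by bisection. The classical curve is the
  standard rarefaction of community ecology, is exact and deterministic,
  and is the variant whose slopes are on the scale ecologists report for
  accumulation studies; the bootstrap variant systematically halves the
  slope of singleton-rich count vectors because repeated draws waste
  samples. Both are exposed; the experiment driver uses the classical form.
* **Connectance** = nonzero cells / (rows × cols) of the cleaned weighted
  bipartite matrix (empty rows/columns deleted first; structural zeros
  inside retained rows/columns stay in the denominator). The composite PHE
  matrix stacks producers (plants + herbivores) against consumers
  (herbivores + enemies) with the PH and HE blocks filled, so plant×enemy
  cells are structural zeros and PHE connectance is bounded by the larger
  of the two block connectances.
* **Diet-breadth covariates** are the mean *assigned* (Pareto-drawn)
  breadths of the consumer species present in the realized community. The
  assigned breadth is the community's specialization parameter and remains
  exogenous to assembly; the realized breadth (unique hosts actually used,
  also reported) is an assembly outcome, is heavily right-censored toward 1
  by pruning, and produces regression slopes dominated by a handful of
  high-leverage webs.
* **Interaction density** (no standard definition exists) defaults to the
  number of distinct realized links (distinct PH pairs + distinct HE pairs)
  divided by realized species richness — a linkage-density analogue.
* **Richness/abundance covariates** for the residual regressions are the
  species and individual totals observed within the view's interaction
  events.

## Statistical layer

**Bayesian two-group comparison** (`BestModel`): each group is modelled as
Student-t with its own mean and scale and a shared normality parameter ν.
Priors: Normal(pooled mean, 100 × pooled variance) on the means, uniform on
(pooled sd/1000, pooled sd×1000) for the scales, 1 + Exponential(mean 29)
for ν. The posterior is sampled with an affine-invariant ensemble sampler
(emcee; 16 walkers, 1000 tuning + 1000 kept steps by default) and
summarized by posterior means and 95% highest-density intervals; groups are
called different when the HDI of the mean difference excludes zero. The
effect size is the posterior standardized difference
`(μ1−μ2)/√((σ1²+σ2²)/2)`. Because σ here is the robust t scale, the effect
size exceeds the sample-moment Cohen's d whenever the data are
heavier-tailed than normal — which per-web Chao1 estimates are.

**Recursive path model** (`PathModel`): a DAG over observed variables.
Variables are standardized; each endogenous equation is estimated by least
squares (for recursive systems with independent errors this is the ML
estimator), so coefficients are standardized path coefficients and
indirect effects are products of direct effects along paths (computed via
`(I−A)^{-1} − I`). Fit: the RAM-style implied covariance
`Σ = (I−A)^{-1} Ψ (I−A)^{-T}` (Ψ = free exogenous covariances + residual
variances) enters the ML discrepancy
`F = ln|Σ| − ln|S| + tr(SΣ^{-1}) − p`, with `χ² = (n−1)F`, df = distinct
moments − free parameters, and `AIC = χ² + 2·free`. This replaces the
proprietary covariance-structure machinery (start-value heuristics,
Levenberg–Marquardt iteration) used historically for such models; for
recursive models the estimates coincide and the fit statistics are
implementation-relative.

**Headline structure.** Exogenous: plant abundance, herbivore diet
breadth, enemy diet breadth. Endogenous (in causal order): species
diversity, interaction density, connectance (PHE), interaction diversity
(PHE). All three exogenous variables point at species diversity and
interaction density; connectance receives plant abundance, species
diversity, and interaction density; interaction diversity receives plant
abundance, both diet breadths, species diversity, and connectance. The
four omitted effects (diet breadths → connectance, the species-diversity/
interaction-density residual covariance, interaction density → interaction
diversity) give the model 4 degrees of freedom. The sample-size sweep
refits the same structure without connectance (2 df), recomputing the
endogenous metrics from the first n interaction-bearing sampled rows of
each web for n in {5, 10, 25, 50, 75, 100, 150, 200, 250, 300, 400, 500},
skipping sizes retaining fewer than 30 webs.

## The experiment

The headline run generates 1000 webs with `Ri ~ U{3..120}`,
`Ai ~ U{3..500}`, `αi ~ U[1,5]`. Per-web seeds come from a splittable
SeedSequence tree keyed by web index (three fixed substreams per web:
generation, rarefaction, sampling), so web i is bit-identical regardless of
how many webs are requested or which analyses run. Degenerate webs are
excluded per-analysis via missing values and counted in the manifest; a
run aborts if more than half the webs are degenerate. At these defaults
roughly 1–2% of webs fail outright (all plants round to zero) and ~2–5%
lack enemies.

## What the generator does and does not emulate

The generator reproduces the statistical skeleton of plant–herbivore–
parasitoid census data: lognormal abundances, Pareto-specialist consumer
communities, one-host-per-consumer natural history, and detection-complete
plot sampling. It deliberately omits assembly rules, phylogenetic or trait
constraints, abundance–diet-breadth covariance, spatial structure, and
imperfect detection. Passing tests therefore demonstrate correctness of
the estimators and the internal consistency of the simulation — not that
real communities satisfy these assumptions; in real data, detection error
and trait-structured diets will move every accumulation and regression
statistic.

## Numerical choices and limitations

* Problem sizes in the test suite (1000-web headline run, classical-slope
  rarefaction, 800-draw MCMC) were chosen to keep the full suite around a
  minute of compute while leaving Monte-Carlo error well inside the
  asserted tolerances; the bootstrap rarefaction default stays at 500
  resamples.
* The residual-regression slopes on diet breadth are heavy-tailed across
  replicate studies: a few webs with unusually generalist consumer pools
  dominate the fit, so these slopes can vary severalfold between master
  seeds at 1000 webs. Their signs and ordering (PH < HE < PHE) are stable;
  their magnitudes are not precision quantities.
* χ² p-values are reported only for df > 0; saturated models return χ² ≈ 0.
* MCMC convergence is summarized by split-R̂ with ensemble walkers treated
  as chains (`BestResults.rhat()`, flagging R̂ > 1.1). Walkers of an
  affine-invariant ensemble are not independent chains, so this diagnostic
  is conservative; values in the 1.0–1.1 range at the default chain length
  are expected, and posterior means of the reported quantities are stable
  to ~1% against fourfold longer chains.
* Ties in the half-richness bisection resolve to the smallest qualifying
  sample size; slopes at curve ends fall back to one-sided differences.
* `InteractionTable` CSVs use empty strings for absent consumers; species
  labels are `P#`, `H#`, `E#` with 1-based indices.
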