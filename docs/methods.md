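# Methods

This note records the models behind `bdchrono`, the numerical and
design choices that were genuinely open, what the synthetic data do and
do not emulate, and the known limitations.

## The birth–death chronospecies process

A lineage tree grows from a single ancestor at the (stem) origin age
t₀ by a birth–death process: branching at rate λ > 0, lineage death at
rate μ ≥ 0, with ages measured before the present (present = 0).
Morphospecies are delimited on top of the tree: each branching is a
bifurcation with probability β (ancestor replaced by two new species)
or a budding (one daughter, chosen with probability ½ each, continues
the ancestral species — the symmetric choice leaves all range
statistics invariant); anagenetic replacements occur along each branch
as a Poisson process with rate λ_a. A speciation event of any mode is
cryptic with probability κ, in which case the daughter inherits the
ancestor's identity; a cryptic species' range is the union interval
from its earliest origination to its latest extinction, closing any
gaps, since a morphologically indistinguishable species is recorded as
one taxon.

Stratigraphic rates follow from counting: λ* = λ(1−β) + 2λβ + λ_a and
μ* = λβ + λ_a + μ. Only the interval
λ_a ∈ [max(0, λ*−2λ), λ*−λ] (equivalently β ∈ [0, min(1, λ*/λ−1)]) is
identifiable from a rate quadruple; the package therefore reports
intervals and the sign statistic λ* − 2λ, never point estimates of
(β, λ_a).

## Likelihoods

*Extant phylogeny.* The reconstructed-process density of the n−1
branching ages given t₀, with sampling fraction ρ: a factor
p₁(t₀)/(1−p₀(t₀)) for the stem conditioned on survival and λp₁(tᵢ) per
branching, where p₀/p₁ are the classic no-descendant/one-descendant
probabilities. Crown conditioning is not uniquely defined in the
literature we follow; the standard form conditioning both crown
lineages on survival, [p₁(t₁)/(1−p₀(t₁))]² ∏_{i≥2} λp₁(tᵢ), is used.
Estimation constrains λ > μ (reparameterised as d = λ−μ > 0, with
log-transformed parameters in a bounded quasi-Newton optimiser); the
Bayesian samplers lift the constraint because the density remains
valid on the whole positive quadrant and the gamma priors keep the
posterior proper.

*Ranges.* With B origination events, D extinction events and summed
durations S, the likelihood is λ*^B μ*^D e^{−(λ*+μ*)S}, maximised in
closed form at (B/S, D/S). The process start is not an origination
event, so B excludes the root species; after subsampling, the oldest
retained range plays that role (preserving the complete-data identity
B = N − 1). D counts every range ending before the present, whether by
true extinction, bifurcation or anagenetic replacement — that is
precisely why μ* ≥ μ.

*Skyline.* Both likelihoods generalise to piecewise-constant rates on
age bins. p₀/p₁ propagate across bin boundaries by composing the
Möbius (linear-fractional) maps of the population-size generating
function, with the value at a boundary serving as the initial
condition of the older bin; the kernels are validated against direct
integration of the Kolmogorov equations to ~1e−8. The range likelihood
sums per-bin terms over (B_b, D_b, S_b).

Proportionality constants are dropped consistently everywhere; only
log-likelihood differences are used.

## Simulating trees conditioned on n extant tips

Two samplers target the same distribution (origin age with density
∝ P(N(T) = n) under a uniform origin prior; tree given the origin
conditioned on n survivors):

* **Analytic sampler (default).** The population size of any
  time-inhomogeneous binary branching process is geometric given
  survival, so P(N(T)=n) = p₁(T)u(T)^{n−1} with u = 1 − p₁/(1−p₀); the
  origin is drawn from this density by grid inverse-CDF (adaptive
  range, 4096 points). Given T, the n−1 reconstructed node depths are
  i.i.d. with density λ(t)p₁(t)/u(T) — the identity du/dt = λp₁ makes
  u the unnormalised CDF — and the tree is assembled as a coalescent
  point process. Extinct subtrees are grafted along every surviving
  edge (stem included) as a Poisson process with rate 2λ(t)p₀(t): on a
  lineage conditioned to survive, branchings occur at the
  survival-tilted rate and either daughter may be the one that dies
  out, hence the factor 2. Each subtree is drawn conditioned on
  extinction before the present, by p₀-thinning plus rejection where
  p₀ is appreciable and by single unconditioned attempts discarded on
  survival where p₀ < 0.05 (the two realisations of the same thinned
  process bound the work per point). This sampler handles
  present-anchored piecewise schedules exactly, which a forward
  simulation cannot: the forward process is only defined once the
  present is placed.

* **Forward GSA (cross-check; constant rates).** The process is run
  forward until 10n lineages or extinction; spans with exactly n alive
  are recorded; a run is accepted with probability proportional to its
  total n-lineage occupation time (weighted rejection against a cap
  calibrated as 3× the maximum over six pilot runs; runs exceeding the
  cap — a few per mil — are clamped to acceptance, the only
  approximation); the present is then uniform within the accepted
  run's spans. Occupation-time weighting matters: selecting uniformly
  within each qualifying run, as the algorithm is sometimes stated,
  under-weights runs that linger at n and measurably biases the
  reconstructed node depths (~7% at n = 20 in our checks).

The two samplers are compared distributionally in the test suite
(origin ages, extinct-tip counts, node depths); both reproduce the
expected origin ages of the study conditions (≈108 at λ=0.2, μ=0.16,
n=200; ≈32 at μ=0.02; ≈40 under the shift schedule with a recent
zero-net-diversification interval). Fixed-origin forward simulation
conditioned on N(T)=n serves as the independent oracle for the
conditional tree law.

## Model testing

The joint log-likelihood treats phylogeny and ranges as independent
(the generating process links them; the approximation is the standard
one and its empirical type-I behaviour is what the selection
experiments measure). Fits: equal (2 free parameters), compatible
(λ, μ, c ≥ 0 with λ* = λ+c, μ* = μ+c), incompatible (phylogeny pair
optimised; range pair closed-form). Five random restarts (initial
rates log-uniform in [0.01, 2]) plus warm starts at the nested optima
guarantee the nesting inequality up to optimiser tolerance; c's lower
bound (e⁻²⁰) makes the boundary reachable.

Cascade: equal-vs-compatible relaxes a boundary constraint, so the
null LR is ½δ₀ + ½χ²₁ and rejection at level α requires the χ²₁ tail
probability to fall below 2α (threshold 2.71 at α = 0.05, 5.41 at
0.01); compatible-vs-incompatible uses χ²₁, equal-vs-incompatible χ²₂.
The selected model is the simplest not rejected; ties at the threshold
go to the simpler model. Decisions are invariant to rescaling time
(rates rescale reciprocally, LRs are unchanged), which is tested.

A caveat the selection experiments quantify: the extant-tree
likelihood is informative about net diversification but comparatively
flat in turnover, so an occasional tree "looks" high-turnover and lets
the equal model chase the range rates; at the study conditions this
produces the few-percent error rates seen in the experiments, and it
is also why the Bayesian credible-interval check (below) has less
power than the cascade when λ* − λ is small.

## Bayesian estimation

Metropolis–Hastings with independent Gamma(1.1, 1.1) priors on every
rate (under constrained models the prior is applied to the implied
quadruple), log-scale random-walk proposals updated one parameter at a
time, scales tuned during a 25% burn-in toward acceptance 0.3, no
thinning. Prior-only runs reproduce the gamma marginals exactly (a
sampler-validity test). The posterior model check applies, in order:
equal if 0 lies in the credible intervals of λ*−λ and of μ*−μ;
compatible if 0 lies in the credible interval of (λ*−λ)−(μ*−μ) and
P(λ* ≥ λ) > 1 − level (one-sided, as stated); else incompatible. The
skyline sampler draws per-bin quadruples (independent priors per bin,
no smoothing) and flags empty bins, whose fossil rates are
prior-dominated. Desk-scale chains are 10⁴–10⁵ iterations — far
shorter than production analyses would use; the tests check
distributional properties, not tail quantiles.

## Fossil sampling and range recovery

Occurrences fall in each true range as a Poisson process with
preservation rate ψ; unobserved ranges vanish, so observation is
length-biased. Extant species optionally carry a present-day (age 0)
record — their living status is treated as known, reflecting standard
practice — which pins t_e = 0 but is *not* a preservation event and
does not enter the occurrence count. Observed ranges run from first to
last appearance; S is thereby underestimated and B/S overestimates λ*
(a directional property the tests assert).

The recovery sampler infers true (ts, te) per taxon jointly with ψ and
the range birth–death rates: sliding-window Metropolis updates of the
times (a random third of taxa per sweep), a multiplier update of ψ,
and conjugate gamma Gibbs updates of (λ*, μ*) given the current
(B, D, S). The per-taxon likelihood is the plain HPP form
ψ^k e^{−ψ(ts−te)}; the per-taxon conditioning constant 1/(1−e^{−ψd})
is deliberately omitted because it diverges for single-occurrence taxa
(d → 0) and collapses the duration posterior onto the observed span. A
correction for species never observed is out of scope. Effective
sample sizes (initial-positive-sequence estimator) below 100 trigger a
warning. Calibration: ψ credible intervals attain near-nominal
coverage when ranges carry several occurrences each (the regime the
coverage test uses); in very sparse regimes (ψ·duration ≲ 2) ψ is
biased upward — an incidental-parameters effect of one or two nuisance
times per taxon — and estimated durations, while always extending the
observed spans, remain somewhat short of the truth.

## Synthetic data: what it does and does not emulate

The generator reproduces the study conditions end to end: trees
conditioned on the number of extant species (n = 200 in the headline
experiments), chronospecies under (β, λ_a, κ) on the generating grid
{(0,0), (0.5, 0.04), (0.7, 0.16)} with λ = 0.2 and μ ∈ {0.02, 0.1,
0.16}, uniform or status-restricted range removal (x up to 0.9),
Poisson fossilisation at ψ = 0.5, an "incompatible" generator with two
unrelated clades whose rates are drawn λ ~ U(0.1, 1.5), μ ~ U(0, λ),
and the empirical-calibration loop that raises λ_a in steps of 0.1
until a target range count is met, then prunes uniformly. It does not
emulate: dating error in either data type, non-uniform (e.g.
taxonomically or temporally biased) fossil sampling beyond the
status-restricted schemes, trait evolution or geographically
structured speciation, or epoch-variable preservation. Passing tests
therefore show the estimators and tests behave as claimed under the
model's own assumptions at study scale, not that real datasets are
free of the biases the model excludes.

Selection experiments in the tests and acceptance script use 100
replicates (25 for estimator-bias checks, with 3-Monte-Carlo-SE
tolerances), and simulator checks use 200 trees per regime — sizes
chosen to put Monte-Carlo error comfortably inside the stated
tolerances on a single core.

## Numerical choices

* p₀/p₁ in log space with expm1-based denominators; survival
  probabilities that underflow (deep subcritical proposals in the
  unconstrained sampler) return −∞ rather than propagating ±∞.
* Origin-age and node-depth sampling by inverse CDF on dense grids
  (4096/8192 points, adaptive range to a 34-nat tail cutoff);
  discretisation error is far below Monte-Carlo noise at the sizes
  used.
* Optimiser bounds: log-rates in [−15, 3], log-c in [−20, 3];
  degenerate fits (all restarts non-finite) raise rather than return.
* Forward simulation guards: 10⁶ events per run, explicit failure
  beyond; rejection caps raise `SimulationError`, never truncate
  silently.
* Ages are uniformly time-before-present; the io layer enforces
  TSV/UTF-8/'.'-decimal and validates ultrametricity (tolerance 1e−6)
  for extant trees.

## Known limitations

* (β, λ_a) are interval-identified only; no attempt is made to resolve
  them pointwise.
* The joint phylogeny × range likelihood ignores the dependence
  between the two data sets generated by one clade.
* The HPP recovery model's ψ is biased in very sparse fossil regimes
  (above); epoch-variable preservation is not modelled.
* The forward GSA is limited to constant rates and carries the
  clamping approximation described above; the analytic sampler is
  exact and preferred.
* Skyline bins with no events are reported prior-dominated rather than
  merged or smoothed.
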