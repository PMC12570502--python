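# Methods

## The experimental system being modeled

A transcription elongation complex (EC) is assembled promoter-independently:
a 9-nt RNA primer anneals to positions 36–44 of a 64-nt template DNA
(coordinates are 1-based, inclusive, on the template as written 5′→3′ — the
only convention under which the scaffold's printed coordinates make sense),
RNA polymerase binds the hybrid, and the complementary non-template strand
completes the duplex.  The RNA 3′ end at template position *r* ("register")
is extended by the NTP complementary to the residue at *r − 1*; extension
walks toward the template 5′ end and exhausts at register 1, giving a
maximum RNA length of 44 nt on this scaffold.  One α-³²P-CTP addition makes
the 10-mer `AUCGAGAGGC`; with only ATP and GTP supplied the complex walks to
the 19-mer `AUCGAGAGGCAGGAGGGAA` and stalls where UTP is templated (+20).

RNase A cleaves 3′ of pyrimidines.  The package digests at *every* internal
pyrimidine (C and U) — the enzymological rule — rather than only at the
single internal C usually drawn for this 10-mer; both conventions give the
same 3′-labeled 7-mer `GAGAGGC`, and the full fragment set is returned so
either can be read off.

The optional hybrid melting temperature uses Biopython's nearest-neighbor
machinery with the Sugimoto RNA/DNA parameter set, 250 nM strands, and a
log-linear monovalent-salt correction.  The method behind the assay's
"~30 °C" expectation is not standardized, so this is a documented
configuration choice; the 9-mer at 40 mM monovalent salt evaluates to
26.3 °C, and the value should be treated as an estimate within roughly
25–35 °C, not a thermodynamic claim.

## Kinetic schemes

Two mechanisms cover the measurements:

* **Single addition** (`build_scheme1`): `EC10 + ATP ⇌ EC10·ATP → EC11`,
  with bimolecular association `k1` fixed at the diffusion limit
  1×10⁸ M⁻¹s⁻¹ (floatable behind a flag for sensitivity analysis),
  dissociation `k−1 = Kd·k1` (Kd in µM, converted to M only where it meets
  `k1`), and irreversible catalysis `k3` in s⁻¹.  Pyrophosphate release is
  treated as instantaneous and folded into the catalytic step.
* **Multi addition** (`build_scheme2`): a linear chain
  `M10 ⇌ M11 ⇌ M12 ⇌ M13plus` of *observed* species (13plus lumps every
  product ≥13 nt at the species level, before normalization).  Rate symbols
  map odd→forward (`kobs1`: M10→M11, `kobs3`: M11→M12, `kobs5`:
  M12→M13plus), even→reverse; the mapping lives in one function so it can
  be flipped wholesale.  `reversible=False` drops the even rates — the
  irreversible variant used for model comparison.  NTP concentration enters
  this chain only through the per-condition rate values; the chain itself
  is concentration-blind.

Under single-turnover conditions (heparin traps free polymerase; the trap is
assumed absolute) the bimolecular step folds to pseudo-first-order
`k1·[ATP]`, so every scheme is a linear ODE system `dy/dt = K·y` with a
constant rate matrix whose columns sum to zero (conservation).
`simulate()` integrates with LSODA at rtol 1e−8 / atol 1e−10 — published
rates span 0.019–8485 s⁻¹, a genuinely stiff range — and the exact
eigendecomposition propagator (`propagate_linear`, falling back to a matrix
exponential for defective matrices) provides the same solution analytically.
The fitting layer uses the analytic propagator for speed; the test suite
holds both routes to the scipy matrix-exponential oracle at ≤1e−6 absolute.

Derived quantities: the rapid-equilibrium observed rate
`kobs = k3·[L]/([L]+Kd)`, and an intermediate decay half-life defined as the
time from a species' peak until it relaxes halfway toward its end-of-window
level.  That convention is one of several defensible ones: in a reversible
chain the intermediates settle at a nonzero quasi-equilibrium, so a
peak-to-half-of-peak rule can be undefined even for a clearly transient
species.  Measured this way, the half-life reduces to ln2/k for a simple
decay and no claim is made of reproducing any particular published
half-life figure.  Terminal accumulators raise a no-peak error.

## Synthetic quench-flow data

The generator emulates the statistical structure the analysis assumes, not
gel images: species fractions sampled on a log grid from the 5 ms
instrument dead time to 10 s (25 points by default — typical of a
quench-flow time course), concentrations {10, 50, 250, 1000} µM, three
replicates.  Each replicate's whole curve is scaled by an amplitude drawn
uniformly from [0.85, 1.05] (radiolabel decays between experiment days;
amplitude is signal, not kinetics), then additive Gaussian noise
(SD 0.03) is applied to the normalized fractions and values are clipped to
[0, 1] with a logged clip count.  Both defaults are stated assumptions
chosen to look like typical replicate scatter in phosphorimage-quantified
band fractions; the true replicate variance of any given instrument is not
derivable from published figures.  Everything is driven by one recorded
seed; zero noise with unit amplitude reproduces `simulate()` bit-for-bit.

EC-stability curves are generated separately on an hours grid
(`exp(−rate·t)` out to a stated horizon, noised, renormalized to t = 0)
because the stability assay lives on a 0–96 h timescale, not the
quench-flow grid.

What the generator deliberately does not model: gel densitometry and its
saturation, radioactive decay as a process (only its amplitude effect),
misincorporation, temperature-dependent rate laws.  Passing recovery tests
therefore show that the *analysis chain* is correct and well-conditioned
for data with this structure — not that real gels obey additive Gaussian
noise.

## Model-independent fits

Rising exponentials `A(1−e^{−kt})` and
`A_f(1−e^{−k_f t}) + A_s(1−e^{−k_s t})` are fit by bounded least squares
(lmfit), amplitudes always floated.  Initialization is deterministic: the
plateau seeds A, a log-linear regression on the rising phase seeds k, and
the two-exponential fit multi-starts from (k/3, 3k), (k/10, 10k) and a
near-degenerate pair, keeping the best converged start with the fast phase
stored first.  Fits with `k_fast/k_slow < 1.5` carry an identifiability
warning.  Model order is chosen per condition by an F-test on the nested
pair (df 2, α = 0.05, configurable), with small-sample AIC reported; ties
prefer the single exponential.  Replicates are averaged point-wise by
default (per-point SDs available as weights).

**Lower limits.**  When a reaction finishes inside the dead time, the data
start at the plateau and the rate is unidentifiable — only a bound can be
stated.  The flag fires when the first observed point reaches 95 % of the
fitted plateau, softened by three estimated noise SDs so one unlucky noise
draw cannot suppress it; the reported rate is capped at
`−ln(1−0.95)/t_dead` (≈599 s⁻¹ for a 5 ms dead time) — the fastest rate the
first observable point can attest to — which guarantees the bound does not
exceed the true rate of any reaction that is genuinely complete by then.

## Global fitting

The model-dependent fitter is a multi-start evolutionary/NLLS hybrid,
re-implemented here: a generational GA (tournament selection, blend
crossover, Gaussian mutation, elitism) searches log₁₀ parameter space
inside box bounds — rates in [1e−4, 1e5] s⁻¹, Kd in [1e−3, 1e4] µM, wide
because published rates span five decades — and each generation's top
elites are polished with L-BFGS-B; several independently seeded starts run
and the best point ever seen wins, with a monotone best-so-far trace kept.
Defaults (population 48, 60 generations, elite fraction 0.15, 8 starts)
are deliberately generous; the recovery and calibration studies in the
test suite use lighter settings (population 24–32, 20–30 generations, 2
starts) that were verified to reach the same optima on these problems —
estimates reproduce to six digits across optimizer seeds.

The objective is unweighted chi-square on the fraction scale (per-point
variance weighting is available and the policy is recorded in every
result).  Published chi-square magnitudes for this kind of analysis differ
by orders of magnitude between reports, implying unstated normalizations;
rather than matching any of them the policy here is explicit and logged.
One multiplicative amplitude per replicate (shared across that replicate's
species — label freshness scales whole lanes) is profiled analytically by
linear least squares before the residuals are formed, so the stochastic
search only ever sees kinetic parameters.  Scheme-1 fits require ≥2
concentrations (the concentration dependence is what separates Kd from
k3); chain fits are per-concentration by default, with an explicit opt-in
for pooling conditions under one shared rate set.

**Grid-search confidence bounds.**  A parameter is profiled over a
log-spaced grid, re-optimizing all other parameters at each node; the 68 %
bound is where the profile crosses `χ²min·(1 + F(1, N−p; 0.68)/(N−p))`,
located precisely by root-finding once a grid step brackets it.  The walk
expands outward (doubling span) until it crosses or hits the search box;
box-truncated intervals are flagged on the result.  The `F`-form threshold
self-scales with the residual variance, which makes it the standard choice
when noise variance is not known a priori; a Δχ²=1 policy would be a
straightforward alternative.

## Stability analysis

`fraction_intact = intact/(intact+cleaved)` per lane; series are normalized
to each replicate's t = 0 value (so t = 0 is exactly 1 and the computation
is invariant to rescaling all signals by a common constant) and summarized
as mean ± sample SD (ddof = 1) across replicates, with no curve fitting —
matching how such stability curves are conventionally presented.  An
exponential refit exists behind a function boundary for validating the
synthetic generator only.

## Problem sizes and known limitations

The heavier studies in the test suite run at desk scale: 20-seed recovery
studies for both schemes, a 20-seed reversible-vs-irreversible model
comparison, 30-dataset interval-coverage calibration, and a 25-seed check
that the optimizer finds the deeper basin of a bimodal toy.

Two limitations are worth stating plainly, both measured with this
package's own oracles:

* **Dead-time-hidden rates are not recoverable.**  With the fastest
  published chain rates as truth (forward rate ≈373 s⁻¹), the M10→M11
  transient completes inside the 5 ms dead time, and the fitted forward
  rate for that step scatters with a median error of ~33 % even when all
  twelve study-design time courses are pooled — the fit's chi-square at
  its optimum is *below* the chi-square at the truth, so this is an
  information limit of the design, not an optimizer failure.  The slower
  steps of the same chain recover within ~14 % and ~3 %.  This mirrors the
  experimental reality that fast intermediates cannot be quantified by a
  5 ms instrument.
* **Boundary clipping biases near-zero data.**  Clipping noised fractions
  to [0, 1] raises the mean of early, near-zero points by ~0.4·SD,
  which biases the fitted catalytic rate high by ~1.5 % at the default
  noise level.  That bias is comparable to the 68 % interval half-width,
  so nominal interval coverage at the study conditions drops to ~40 %
  (with clipping disabled in a diagnostic, coverage is ~60 %, inside the
  expected band — the profiling machinery itself is calibrated).  Users
  fitting data with many points near a hard boundary should treat
  confidence intervals as optimistic or model the censoring explicitly.

Out of scope by design: translocation sub-steps, explicit PPi states,
misincorporation, Arrhenius/temperature-coupled fits, Bayesian posterior
sampling, secondary-structure or bubble-geometry modeling, and gel/image
simulation.
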