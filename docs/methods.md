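# Methods

This note documents the models and estimators implemented in `mikana`, the
design decisions behind them, and what the simulation benchmarks do and do
not establish.

## 1. The inference model

Each gene's transcript level x_i is modelled by

    dx_i/dt = c_i + Σ_j w_ij f(x_j) − λ_i x_i,      f(x) = xⁿ/(Kⁿ + xⁿ),

a weighted sum of Hill activation terms of candidate regulators (only
independent single-regulator effects; no product terms), a constant basal
transcription rate c_i, and first-order degradation λ_i.  A nonzero w_ij is
an edge j → i with sign(w_ij) giving activation/inhibition.

**Basis.**  Hill exponent n = 2 by default.  The half-saturation K is, per
regressor gene, the median of that gene's expression over the rows entering
the regression (floored at 10⁻⁶), which centres each basis in its own data
range without tuning; a fixed shared K is available
(`BasisConfig(half_saturation_rule="fixed", k_fixed=...)`) and is what the
well-specified recovery checks use.  Negative (noisy) expression values are
floored at zero before entering any Hill term; responses and degradation
columns use the raw values.

**The basal column.**  The regression carries two *structural* columns —
the constant and −x_i — that are always fitted and never count as edges or
penalised terms.  The constant is essential, not cosmetic: real (and
simulated) transcription has a basal component, and without a constant
basis every gene with weak or no regulatory input forces the selection to
fabricate several spurious Hill terms purely to represent its constant
production.  In benchmark runs at zero noise the time-series mode's FDR
drops from ≈0.93 to ≈0.7 by adding this single column.

**Self-regulation** is excluded (f(x_i) is not a candidate for gene i): it
is nearly collinear with the degradation column over typical operating
ranges, and the ground-truth generator contains no self-loops.

## 2. The three regressions

- *Steady state* (ssMIKANA): at equilibrium the model reads
  0 = c + Σ w f(x_j) − λ x_i per knockdown sample.  The sample that
  perturbed gene i itself is excluded (its perturbation strength u_i is
  unknown).  Because the response is identically zero, the unconstrained
  least-squares problem is degenerate (the all-zero solution is optimal);
  the degradation coefficient is therefore pinned to 1, i.e. the classical
  form x_i = c̃ + Σ (w_ij/λ_i) f(x_j).  Only the ratios w/λ are identified
  from steady-state data — edge presence and sign are unaffected — and the
  results object flags λ as unidentified in this mode.
- *Time series* (tsMIKANA): forward differences over consecutive time pairs
  within a replicate (never across replicates) give the response; all
  regressors are evaluated at the left time point.  No smoothing is applied
  to the series.
- *Combined* (cMIKANA): the two row types share one column structure and are
  stacked into a single regression; the steady-state rows (response 0) are
  informative exactly because the time-series rows pin the coefficient
  scale.

**Row weighting in the combined stack.**  Measurement noise of size
level·x enters a finite-difference row at scale √2·x/Δt (differencing
amplifies it) but a steady-state identity row only at scale λ·x.  Under a
single unweighted least-squares cost, whichever block is noisier dilutes
the other's evidence — in matched-budget runs the naive unweighted stack
scored *below both* of its component modes.  Rows are therefore scaled by
the inverse of these known propagation factors: finite-difference rows by
their time step (equivalently, fitted in Δx units), and, in mixed problems,
blocks by 1/(√2·med|x|) and 1/(λ̂·med|x|) respectively (the common noise
level cancels; λ̂ is the profiled degradation estimate of §3).  For pure
single-block problems a common row scale shifts the selection cost by a
constant, so this weighting is exactly neutral there.  An
estimated-residual (feasible GLS) weighting was evaluated and rejected: a
null-model pilot counts genuine knockdown signal as noise and downweights
the informative block.

## 3. Model selection

Candidate Hill terms are chosen per target gene by iterative local search:
repeatedly apply the best single move — add the term with the largest
marginal improvement, or remove the term whose removal does least damage —
and, when no single move improves, try one-for-one swaps (and, for small
candidate sets, joint pair additions/removals, where a pair of
complementary regressors can improve a fit that neither improves alone; the
pair scan is quadratic in the candidate count and is disabled above
12 candidates).  The accepted-move cost sequence is recorded and is
non-increasing; the returned model is the minimum-cost state encountered.

**Cost.**  C(S) = (m/2)·ln(RSS(S)/m) + |S|·(½·ln m + γ·ln p), with m rows,
p candidates and |S| selected Hill terms — the BIC description-length
compromise extended by the γ·ln p model-space term.  With γ = 0 (plain BIC)
the selector over-admits badly whenever p ≈ m, which is the generic
situation in a genes-wide regression (p = N−1 candidates vs m ≈ N rows);
γ = 0.5 is the standard extended-BIC recommendation for that regime and is
the default (`SelectionConfig.complexity_gamma`).  RSS is floored at
m·(10⁻⁸·rms(y))² so that, among models that all fit to machine precision,
the complexity penalty rather than floating-point noise decides.

**Profiled degradation for combined problems.**  The combined stack
inherits a scale degeneracy: its steady-state rows are homogeneous, so when
the time-series rows are noise-dominated the joint fit can collapse all
coefficients toward zero and the knockdown evidence is lost.  The search
therefore profiles λ: a pilot λ̂ comes from the time-series rows' own decay
(structural-only fit), the subset search runs with λ pinned at λ̂ (making
the steady-state rows inhomogeneous and fully informative), the selected
support is refitted jointly (free λ), and the estimate is iterated (at most
three passes; a non-positive joint λ keeps the decay-based pilot).  On
exactly-realisable data the iteration converges to the exact joint fit, so
recovery results are unaffected.

**Numerics.**  Rank-deficient subsets are repaired by dropping the
latest-indexed dependent column; ties in the move choice resolve to the
lowest column index; exactly-zero fitted coefficients are pruned so that
every reported edge has a nonzero weight.  Everything is deterministic.

## 4. The simulation benchmark

**Topology.**  Scale-free directed signed networks grown by preferential
attachment: node scores u_i ~ U[0,1]; a uniformly drawn ordered pair (a,b)
becomes an edge iff both attachment probabilities
P_i = (u_i + k_i)/max_j(u_j + k_j) (k_i = current total degree) clear fresh
uniform thresholds; growth stops at round(k_av·N/2) edges ("average
connectivity" is read as average total degree).  Defaults: k_av = 3; the
power-law exponent r ≈ 0.65 is a descriptive target of this construction,
not an enforced constraint.  Edge signs are + with probability p_pos = 0.5.

**Kinetics.**  dx_i/dt = V_i·g_i(x) − λ_i·x_i with saturating regulation

    g_i(x) = (b_i + Σ_{a∈act(i)} x_a/(θ_a + x_a)) / (1 + Σ_{z∈inh(i)} x_z/(φ_z + x_z)),

saturation constants attached to the regulator gene (θ = φ, drawn once per
gene).  Parameter ranges: V ~ U[100,1000] h⁻¹, λ ~ U[0.1,1] h⁻¹ (transcript
half-lives of ~0.7–7 h), b ~ U[0.05,0.2], θ = φ ~ U[300,3000] expression
units.  This rate law is deliberately *not* the linear-in-Hill form the
regression fits, so benchmark runs probe the realistic, misspecified
regime.  A consequence worth knowing: the additive-share structure of g
caps most single-edge effects — the median steady-state response of a
target to a 50% knockdown of one parent is ≈8%, below a 10% noise floor —
so absolute sensitivities in the noisy benchmarks are modest and the
meaningful outputs are the comparisons *between* modes.  (Re-calibrating
V, λ, θ, or anchoring θ at the operating point, was tried and does not
change this; it is the regulation-share arithmetic, not saturation
mismatch.)

**Reference state.**  Initial conditions ~ N(1000, 1000) with negative
draws re-sampled; the ODEs are integrated (LSODA, rtol 10⁻⁸) in chunks
until every gene's time-constant-scaled residual |dx_i/dt|/λ_i — an
estimate of the remaining distance to the fixed point — falls below 10⁻⁶
of the state scale.  Non-convergence raises a stability error naming the
worst genes; experiment runners re-draw parameters with fresh derived seeds.

**Knockdowns.**  Gene t is clamped at (1−δ)·x_ref[t] with δ ~ U[0,1] drawn
once per experiment; the remaining N−1 equations are integrated to their
new equilibrium.  A full dataset knocks each gene down in turn.

**Time courses.**  Per replicate, every gene's initial condition is
displaced to (1+ρ_i)·x_ref with ρ ~ U[−1,1], emulating a broad stimulus.
Samples lie on a uniform grid including t = 0 with the sampling interval
pinned at 0.75 fastest degradation time constants and the window growing
with the number of points (the 9-interval default spans ~6 fast time
constants — an hourly 0–6 h course when the fastest transcripts turn over
hourly).  The interval is the resolution limit of forward differencing:
windows sized to the *slowest* gene would space samples several fast time
constants apart and reduce the differences to noise.  Fast and typical
genes settle within the window; the slowest may still be relaxing, as in a
real short time course.

**Noise.**  x̃ = x + ε with ε ~ N(0, (level·x)²) — signal-proportional
measurement noise, applied independently per value; noisy values may go
negative and are floored only inside Hill terms.

**The well-specified oracle.**  For recovery checks the generator is the
inference model itself (`HillODEModel`, `well_specified_instance`): an
activating ring plus random extra edges, ring weights ≈4λK so the positive
fixed point of the Hill-squared recursion sits safely above its unstable
lower branch.  Steady states come from a Newton solve; time courses are the
exact discrete-time (forward-Euler on the sampling grid) trajectory, so the
forward-difference response satisfies the regression identity to machine
precision — the discrete counterpart *is* the model the regression fits,
and continuous integration would leave O(Δt) bias incompatible with
1%-level coefficient-recovery checks.  Initial perturbations use
ρ ~ U[−0.5, 0.5] to stay inside the positive basin.

## 5. Evaluation

Edges are compared as directed (parent, child) pairs ignoring sign and
weight (a strict-sign mode exists): sensitivity = TP/(TP+FN),
FDR = FP/(TP+FP), both NaN (never silently 0) when undefined.
Directionality is measured as the proportions of true edges present in the
inferred network as-is (forward) and after reversing every inferred edge
(reversed).  Overlap and union of networks obey inclusion–exclusion
exactly; hubs are ranked by out-degree with ties broken by gene label.

## 6. Benchmark studies and problem sizes

Three runners reproduce the standard study designs, at two scales:
full-scale defaults (100 genes, 50 simulations) and a `desk_scale` preset
(30 genes, 10 simulations) that finishes in minutes and is what the test
suite and acceptance script use — at that scale the qualitative orderings,
not absolute scores, are the meaningful output.

- **Noise sweep**: per simulation, full knockdown coverage plus a 10-point,
  3-replicate time course; all three modes inferred and scored at each
  noise level (full scale: 1–20%; desk: 10%).
- **Matched budgets**: T×3 time-series samples (tsMIKANA) vs T×1 plus 2T
  knockdowns (cMIKANA) at identical totals and 10% noise; arms share the
  network, kinetics and reference state per simulation index, and the
  sample-count match is asserted.  Desk budgets are {15, 30, 45}
  (T ∈ {5,10,15}) because the combined arm needs 2T *distinct* knockdown
  targets and the 30-gene network caps that at T = 15; full scale keeps
  {15, 30, 60, 120}.
- **Directionality**: full knockdown coverage plus a 10-replicate time
  course at 10% noise; forward and reversed proportions per mode.

Every condition's seed derives deterministically from (base_seed,
simulation index, condition index), so studies are exactly reproducible and
paired across arms.

At desk scale the combined mode dominates the time-series mode in
sensitivity at equal FDR or better (noise sweep and all matched budgets),
and keeps the false-discovery rate below the steady-state mode's.  One
qualitative expectation is *not* reproduced here: the time-series mode's
forward-recovery proportion is not consistently above the steady-state
mode's — under this simulator, full-coverage single-gene interventions are
simply stronger directional evidence than noise-amplified finite
differences; the time-series mode does show the better reversed/forward
ratio (higher directional purity).

## 7. Known limitations

- The simulator is deterministic ODE kinetics with measurement noise only:
  no intrinsic stochasticity, translation layer, delays, or time-varying
  stimulus input.
- Steady-state-only inference identifies w/λ, not w and λ separately.
- Forward differencing makes the time-series modes intrinsically
  noise-sensitive at high sampling rates; no smoothing is applied by
  design.
- Absolute sensitivity in the noisy misspecified benchmark is limited by
  the simulator's small per-edge effect sizes (§4); conclusions should be
  drawn from mode comparisons under identical conditions.
- Desk-scale studies (10 simulations) carry Monte-Carlo error of a few
  percentage points on mean sensitivities; orderings with smaller margins
  than that are not stable across base seeds.
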