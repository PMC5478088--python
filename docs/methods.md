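# Methods

## The model

`shadowtrack` reconstructs the full dynamical state — position p, velocity
v and acceleration a — of a moving object from noisy, possibly gappy and
irregularly sampled position fixes P_i at times t_i. The only physical
assumption is Newtonian motion with piecewise-constant acceleration: on
each sampling interval [t_i, t_{i+1}) of length T_i,

    p_{i+1} = p_i + v_i T_i + a_i T_i²/2,        v_{i+1} = v_i + a_i T_i.

Among all trajectories in this model class, the filter returns the
minimizer of

    J(p, v, a) = ½ Σ_i σ_i⁻² (P_i − p_i)²  +  η Σ_i T_i a_i²,

a whole-series (batch) criterion: unlike sequential filters, every fix
constrains every state. The weight η trades observation fidelity against
acceleration energy; η → 0 interpolates the fixes, η → ∞ yields the
σ⁻²-weighted straight-line fit. Multi-dimensional tracks are filtered as
independent scalar problems per coordinate, which is exact for isotropic
uncorrelated noise and a good approximation otherwise.

The acceleration-energy term descends from a hard physical bound
Σ T_i a_i² ≤ (t_n − t_0) ξ², but the bound itself is never enforced: its
constant drops out of every derivative, and sweeping η directly is both
simpler and what the error tables of the original study do. `FilterConfig`
retains `xi_bound` as documentation only.

## Solvers

**reduced** (default). The two constraints are eliminated by
parameterizing trajectories with u = (p_0, v_0, a_0, …, a_{n−1}); the
closed form

    p_k = p_0 + v_0 (t_k − t_0) + Σ_{i<k} [T_i²/2 + T_i (t_k − t_{i+1})] a_i

gives a dense linear map from u to the sampled positions. Residual rows
are weighted by 1/σ_i and n acceleration-penalty rows by √(2ηT_i), so the
squared system equals 2J; the least-squares problem is solved by SVD
(LAPACK `gelsd`) with the minimum-norm convention and relative truncation
`svd_rcond` (default 1e−12). Because the solution is re-propagated through
the recursions, the returned trajectory is Newton-consistent to machine
precision by construction.

**kkt**. The full first-order stationarity system in
(p, v, a, λ, μ) — the objective gradient balanced against the constraint
Jacobian — is assembled explicitly and solved by the same SVD routine. It
returns the Lagrange multipliers and the maximum stationarity residual as
diagnostics and exists as an independent verification route; the test
suite checks both solvers against a third, generic dense
equality-constrained QP oracle and against finite-difference gradients of
J. Rank deficiency beyond `svd_rcond` raises a degenerate-problem error
carrying the rank deficit.

At η = 0 the reduced problem is underdetermined by exactly one degree of
freedom (n+2 unknowns, n+1 fixes); the minimum-norm solution is returned
together with a `ConditionReport` flagging it rather than raising.

### Identifiability at the η → 0 limit

The one-dimensional nullspace has a concrete form: the alternating mode
δa_i = (−1)^i c (with δv_i = ∓cT/2) is a C¹ piecewise-quadratic position
perturbation vanishing at every sample. Noiseless positions therefore
determine p exactly in the η → 0⁺ limit, while v and a are determined only
up to this mode; the limit returned is the minimum-penalty interpolant,
i.e. the truth minus its alternating-mode component, whose amplitude for a
rough random acceleration sequence is of order accel_scale/√n. Exact
full-phase-space recovery holds precisely when the true acceleration has
no alternating component (e.g. constant acceleration over an even number
of intervals); the test suite demonstrates both facts. Users who need
trustworthy accelerations should keep η at the noise-matched value rather
than pushing it toward zero.

## Choosing η

Two routes, consistent with each other within a decade on smooth tracks:

* **Closed form**: η_b = 0.046 β³ + 0.054, with β the observational noise
  variance in m². Valid for high sampling rates. (The published prose
  describes the relation as cubic in the noise's standard deviation while
  defining β as the variance; the formula is implemented exactly as
  printed and never silently rounded — β = 0.4 m² gives 0.056944, not
  0.05.) At β = 0 it returns its intercept 0.054.
* **Simulation sweep** (`optimize_eta`): generate n_replicates (default
  100) noisy copies of a known true track, average the true-position RMS
  error per η over a broad grid (10 … 1e−7, the published sweep), then
  refine: each round re-sweeps 9 log-spaced points around the argmin, the
  first refinement spanning one decade each way and the log-span halving
  per round (3 rounds by default). The replicate noise is drawn once from
  the seeded generator and reused across rounds. Error is the mean (not
  median) RMS over replicates; an η where every replicate fails records
  infinity. The filter objective keeps σ² = 1 while the replicates carry
  variance β, so η alone absorbs the noise scale, as in the published
  sweeps.

`sweep_eta` is the single-sweep primitive and can use the observations
themselves as reference — the only option on real data, where the
resulting e_position is monotone in η by construction and the "optimum"
reflects closeness to observations, not to reality.

## Windowing test

`windowing_test` filters suffix windows of increasing length n at fixed η
and records D_{j,n} = ‖P_{N−j} − q_{N−j}‖ plus the reconstructed last
state. `min_window_length` returns the smallest tested n such that the
last state agrees with the full-window estimate within tol for *all*
tested n′ ≥ n — a uniform-tail criterion, deliberately stricter than the
first crossing. The full window serves as reference only; if no shorter
window converges, the result is "not reached" (None). The default
tolerance max(0.05 m, σ/10) is this package's convention; the original
study reads convergence off the distance plots without a numeric
threshold.

## Sliding-average baseline

The comparison baseline estimates position as a centered n-point moving
mean (n odd, default 5) on a regular grid, then differentiates forward:
v_i = (p_{i+1} − p_i)/Δt, a_i = (v_{i+1} − v_i)/Δt. Edges are truncated,
not padded. Two quantified pathologies motivate the shadowing filter: the
double difference inflates fix-noise variance by 6β/Δt⁴ (spikes), and the
moving mean attenuates a sinusoid of angular frequency ω by
sin(nωΔt/2)/(n sin(ωΔt/2)) (underestimated turning points). Whether
forward or centered differences were used in the original comparison is
unstated; forward is implemented as printed.

## Synthetic data

The generator emulates avian GPS telemetry: 0.2 s sampling, isotropic
Gaussian fix noise of variance 0.4 m² per coordinate, 36% of fixes flagged
as dropouts, accelerations within the ±8 m/s² envelope of recorded pigeon
flight, and a 4 m/s speed threshold (strict inequality) separating flight
from non-flight. Defaults chosen where no value was prescribed, as this
package's study conditions: duration 30 s (151 fixes — a desk-scale
analogue of the 1,500-point flight segments analysed in the source study),
accel_scale 4 m/s² (mid-envelope), 2 dimensions (flight is essentially
planar), smooth_random acceleration with ~1 s correlation time as the
default maneuvering-flight model. Four acceleration models are provided:
`piecewise_constant` (i.i.d. uniform per interval — the roughest member of
the filter's model class), `smooth_random`, `circular` (an exact discrete
rotation: constant speed to machine precision, per-interval acceleration
orthogonal to the interval's mean velocity) and `sinusoid`. All tracks are
Newton-consistent by construction and deterministic under the spec's seed.

What the generator does *not* emulate: wing-beat dynamics, wind, flock
interactions, GPS error correlation in time or across coordinates, and the
Gaussian-kernel/B-spline preprocessing applied to the original pigeon
files. Passing tests therefore demonstrate correctness of the estimator on
its stated noise model, not performance bounds on real telemetry.

## Numerical choices and problem sizes

SVD truncation 1e−12; solver-equivalence tests at relative 1e−8; Newton
consistency enforced to 1e−9 × max(1, |p|). The acceptance-style
experiments run at desk scale by design: η-scaling with 100 replicates on
a 151-sample track (~30 s of compute), the baseline comparison over 100
seeds, and the windowing stability check on 200-sample, 2 s-resolution
tracks over 10 seeds. Times are plain float seconds; no calendar or
geodetic handling — inputs are assumed already in a planar metric frame.

## Known limitations

Batch only (no streaming); the dense reduced solve is O(n³) and intended
for segments of up to a few thousand fixes — decimate or split longer
tracks; per-coordinate independence ignores cross-coordinate error
correlation; accelerations are piecewise-constant, so genuinely smooth
maneuvers are represented in a weak (integrated) sense.
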