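# Methods

## The model

`spinesim` simulates the spontaneous shape fluctuations of a dendritic
spine head in 2D.  The membrane is a closed, counterclockwise polygon of
vertices `x^k` with target edge length δ_s = 0.03 μm.  Two regions are
constrained throughout: vertices at the post-synaptic density (PSD) are
projected onto the chord y = h_PSD = √(r_s² − r_PSD²) and vertices at the
neck onto y = h_neck = −√(r_s² − r_neck²); both sets never move.  This
encodes the observation that PSD size and neck width are stable on the
hour timescale of interest.

**Membrane mechanics.**  The membrane carries a Helfrich-type energy

    E_mem = P·Ω + τ·S + 2κ ∫ H² ds

with pressure difference P, line tension τ and bending modulus κ; Ω is
the enclosed (shoelace) area, S the perimeter, and the integral is
discretized as Σ_k H_k² ds_k with the circumradius curvature
H_k = 2·cross(e1, e2)/(L1·L2·L3) of each vertex triple and arc weight
ds_k = (L1 + L2)/2.  The force on a vertex is the exact analytic gradient
of this *discretized* energy, F_mem(x^k) = −∂E_mem/∂x^k, which makes the
force verifiable against central finite differences of the energy to
round-off accuracy (the test-suite asserts < 1e−4 agreement).  The
dimensional bookkeeping follows the parameter table literally (P in
pN·μm⁻² against a 2D area); only force balance matters for the dynamics.

**Actin dynamics.**  Protrusive force originates from a handful of
discrete actin polymerization foci.  A focus tracks only filament counts
by minus-end state: `m_c` (minus end capped/Arp2/3-bound) and `m_u`
(minus end uncapped); its force-generating barbed-end count is
B = m_c + m_u.  Per time-step Δt = 1/8 s each filament can, in order:
branch (probability Δt·γ_branch), have its barbed end capped and leave
the simulation (Δt·γ_cap), have its minus end uncapped (Δt·γ_uncap), and
— once uncapped — be severed (Δt·γ_sever).  The per-filament branching
rate is the Brownian-ratchet-attenuated free treadmilling velocity shared
among the focus's barbed ends,

    γ_branch = φ·k_on·δ·a · exp(−‖F_mem‖·δ/(k_B T·B)) / B,

with ‖F_mem‖ evaluated at the focus's center vertex at the start of the
step.  Because all filaments of a class share identical rates, the
per-filament sweep is sampled with chained binomial draws per class —
statistically identical and much faster.  B = 0 is absorbing; dead foci
are removed and their lifetime logged.

The deterministic twin treats the counts as continuous; its stationary
state B* solves B = K·exp(−c/B) with c = ‖F_mem‖·δ/(k_B T) and
K = φ k_on δ a (1 + γ_uncap/(γ_sever+γ_cap)) / (γ_uncap+γ_cap).  The
solver scans g(B) = B − K e^{−c/B} downward from B = K and brackets the
largest (stable) root for Brent's method.  Beyond a critical force
(≈ 4.6 pN at default rates) g has no positive root — a saddle-node — and
the solver returns 0: a focus cannot sustain itself against such loads.
The long-run mean of the stochastic focus matches B* (tested at 0 and
3 pN against 50-run Monte-Carlo ensembles).

**Nucleation.**  New foci appear at rate γ_f (one Bernoulli attempt per
step with probability Δt·γ_f).  1,000 uniform candidate points are drawn
inside the polygon; candidates farther than 0.1 μm from the membrane or
closer than 0.1 μm to the PSD chord are discarded (the branching
machinery concentrates near the membrane and filaments must stay short);
one survivor is selected with probability ∝ exp(−d_PSD/λ).  The center
vertex X_c is drawn uniformly among mesh vertices within 0.1 μm of the
nucleation point X_n; if no candidate or no nearby vertex survives the
attempt fails (this is rare and simply costs one attempt).  A fresh focus
starts with a single minus-end-capped filament (m_c = 1) — the nascent
Arp2/3-bound state; the seed count is a constructor argument
(`initial_filaments`) since no canonical value exists.

**Actin force on the membrane.**  Each focus pushes vertex k with

    W(‖x^k − X_c‖)·B·(x^k − X_n)/‖x^k − X_n‖,
    W(x) = α/(σ√2π)·exp(−x²/2σ²),

using straight-line distances; X_n is fixed for the focus's lifetime, so
per-vertex push directions are fixed as well.  X_c is a mesh vertex and
rides along with the membrane; after remeshing (or lobe excision, below)
centers are re-mapped to the nearest surviving vertex.

**Movement.**  Vertices move by dx/dt = ζ(F_mem + F_fil), integrated per
tick with classical RK4: F_mem is re-evaluated at every stage, F_fil is
frozen for the tick.  If any free vertex would move farther than
d_tol = 1e−4 μm within a sub-step, the sub-step is halved (and doubled
again after 8 consecutive acceptances, never beyond Δt); every accepted
sub-step therefore satisfies the displacement bound.  A sub-step below
Δt/2²⁰ raises a stability error.  The bending term makes the dynamics
stiff — the practical stable sub-step near d_min-length edges is ~1 ms —
so a tick typically comprises ~100 sub-steps; the integrator lives in a
single allocation-free numba kernel for this reason.

After each movement tick, free vertices are kept out of the plateau
regions: a vertex that crossed the PSD or neck chord within the chord's
x-extent is projected back onto it.  The regions beyond the chords are
excluded volume — the neck is filled by its stable actin core and the
PSD chord abuts the synaptic contact (the same facts that motivate
fixing the plateau vertices) — and without the clamp a vertex slipping
past a plateau corner seeds an inverted lobe that the pressure term
inflates.

**Remeshing.**  After every tick, edges longer than d_max = (4/3)δ_s are
split at their midpoint and edges shorter than d_min = (3/5)δ_s lose one
endpoint, repeated until no rule fires.  Fixed vertices are never
removed; an edge between two fixed vertices is exempt from collapsing,
and a midpoint inserted between two fixed vertices is itself fixed (it
lies on the same plateau).  When an edge must lose an endpoint the free
one goes; if both are free, the second in cyclic order.  Splits run
before collapses; the result is idempotent.

## Resting shape

With the PSD and neck fixed and no actin, the membrane shrinks to a
characteristic resting shape with area A_s, the baseline of all area
fluctuations.  Two facts shape the implementation:

1. The discrete energy has no isolated static minimum: without the
   remeshing bounds, adjacent free vertices could collapse onto each
   other (ds → 0 silences the bending penalty) and the polygon could then
   invert, making P·Ω arbitrarily negative.  The resting shape exists
   only as the quasi-stationary state of the gradient flow *combined
   with* remeshing.
2. The explicit RK4 at full Δt is linearly unstable for the stiffest
   bending modes, so the displacement-tolerance mechanism sustains a
   bounded numerical jitter of ~1e−4 μm/step around the attractor rather
   than letting displacements decay to zero.

`relax_to_rest` therefore iterates the ordinary movement step (zero actin
force) plus remeshing and declares convergence when either the largest
per-step displacement falls below `max_disp_tol` (default 1e−4 μm) or the
mean area over consecutive 500-step windows drifts by less than
5e−4 μm².  The residual ambiguity in A_s (~1e−3 μm²) is far below every
tolerance that depends on it.  The relaxed mesh is cached per mechanical
parameter set (the resting shape does not depend on actin kinetics).

## Self-intersection guard

The continuum model has no self-contact force, so colliding membrane
walls can cross: the flanks of a retracting protrusion collide after its
foci die, or line tension zips shut the narrow crevice between a lobe
and the neck.  Once edges cross, the inverted lens between them is
*rewarded* by the pressure term (negative signed area lowers P·Ω) and
grows without bound, eventually driving the area trace negative.  The
simulator therefore enforces steric contact: polygon validity is checked
every tick, and a tick whose movement would cross two walls is reverted
whole — the membrane jams in contact while the actin dynamics continue.
A transient brush releases by itself within a few ticks.  If the jam
persists for 8 consecutive ticks the walls are being pressed together,
and the membrane is fused at the contact by a single 2-opt uncross (the
vertex subchain between the most local crossing pair is reversed, which
reconnects the boundary through the contact point while preserving every
vertex position and fixed flag bitwise and strictly increasing the
signed area).  Remeshing across a tight fold can itself create a
crossing; such a remesh is deferred to a later tick.  Real membranes
exhibit steric repulsion before fusion; jam-then-fuse is the minimal
contact resolution consistent with the forces the model does have.

A related consequence of the energy P·Ω + τ·S at the default
coefficients deserves emphasis: the symmetric resting shape is only
metastable.  Deep inward folding trades enclosed area against a modest
amount of boundary at a net energy gain, so after an unusually
long-lived focus pushes out a large protrusion, the retraction can leave
the membrane in a lower-energy infolded configuration whose area lies
below A_s for extended episodes before fresh foci re-inflate it.  Such
episodes — during which area fluctuations largely cease even though
nucleation continues — are genuine behavior of the stated model under
this discretization, and they widen the realization-to-realization
spread of every long-run statistic.  This guard is
mesh maintenance in the same spirit as remeshing, not a change to the
physics; without it a measurable fraction of the prescribed 90-minute
experiments diverges.

## Simulation protocol

A full run: relax to rest; insert n_f0 = 4 foci by the ordinary
nucleation procedure; then per tick (1) membrane force field,
(2) stochastic update of every focus using ‖F_mem‖ at its center vertex,
(3) removal and logging of dead foci, (4) one nucleation attempt with
probability Δt·γ_f, (5) actin force field, (6) membrane movement,
(7) remeshing/guarding and center re-mapping, (8) recording of time,
area, focus count and mean barbed-end count.  This ordering keeps the
force entering the branching rate contemporaneous with the actin update.
Each run owns a single seeded NumPy generator, so traces are bitwise
reproducible per seed.  Simulation times quoted anywhere start after the
relaxation phase.

Parameter sweeps run replicate simulations per value with distinct seeds
and summarize each run by mean area, area SD, mean completed-focus
lifetime and mean focus count.  The analysis stack provides temporal
mean/SD, the biased-normalization autocorrelation function (up to
min(n/2, 10 min) lags), a 50-resample i.i.d. bootstrap SD of the temporal
mean (it ignores autocorrelation and therefore understates uncertainty —
it is used for error bars, not inference), Welch's unequal-variance
t-test for replicate comparisons, and Pearson correlations.

## The recursive area estimator

The number of active foci alone predicts the area trajectory through

    Ā(t_j) = Ā(t_{j−1}) − Φ(Ā(t_{j−1}) − A_s) + m·n_f(t_j) + b :

per step the estimate relaxes toward the resting area at rate Φ and
gains m per active focus plus a baseline b.  Fitting minimizes the
squared deviation between the recursion and the observed area over a
training window.  Because the recursion is linear in (A0, m, b) for
fixed Φ, those three are profiled out exactly with linear least squares
(the basis responses are computed with a first-order linear filter) and
the remaining one-dimensional problem in Φ ∈ [0, 1] is solved by a grid
scan, bounded scalar minimization and a parabolic polish — deterministic
and equivalent to the four-parameter nonlinear least-squares problem.
The polish matters: the recursion accumulates Φ-errors across the
window, so Φ must be resolved to ~1e−13 for the noise-free fit to reach
round-off-level RMSE (asserted in the tests).  On synthetic recursion
data with per-step noise of 1e−4 μm² the parameters are recovered within
5%.  Δarea in correlation analyses is the per-step first difference of
the area series.

## Synthetic data and what passing tests show

All inputs are generated programmatically: analytic polygons (squares,
regular n-gons, a fixture pentagon) for the geometric and mechanical
oracles, scripted focus schedules for the force-field checks, and
recursion-generated area/foci traces for estimator recovery.  The
simulator itself is the generator for the end-to-end checks.  None of
this emulates measured microscopy data: real spines live in 3D, have
variable neck geometry, molecular noise beyond four reaction channels,
and membrane proteins the Helfrich description ignores.  Passing tests
show the implementation is faithful to the stated model and internally
consistent — not that the model captures any particular biological
spine.

## Problem sizes

Default runs use the Table-defaults geometry (~110–210 vertices).  The
end-to-end suite uses two seeded 90-minute runs for the estimator
checks, 50 seeded 30-second runs for the die-out experiment, 50-run
single-focus ensembles, and 15-minute replicate sweeps comparing the two
extreme values of each swept parameter — five replicates for the strong
effects (branching amplitude, nucleation-distance scale, kernel width)
and twelve for the nucleation rate, whose lifetime effect is weak.
These sizes keep the whole suite within a practical runtime while
leaving every trend test with clear statistical margin.

## Known limitations

- 2D only; no 3D membrane, no projections.
- No activity-dependent plasticity; G-actin concentration is constant.
- No explicit filament geometry (lengths, branch angles, positions).
- The contact guard implements fusion-on-contact; real membranes
  exhibit steric repulsion before fusion.
- The i.i.d. bootstrap and the raw Welch p-values ignore temporal and
  multiple-comparison structure respectively.
- Estimator windows assume the trace is stationary after the first
  minute; fits anchored in a large excursion degrade accordingly.
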