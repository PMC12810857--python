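# Methods

## Model

The package implements a three-population evolutionary game of
healthcare-safety supervision under replicator dynamics. The state is a
point (δ, η, ζ) in the unit cube: the frequencies of public participation in
supervision, institutional compliance, and strict regulatory supervision.
Each population is a large, well-mixed pool of bounded-rational agents; a
strategy's frequency grows in proportion to the gap between that strategy's
expected payoff and the population's mean payoff, which for two-strategy
populations collapses to

x' = x(1−x)·G(state),   G = H(strategy 1) − H(strategy 2).

The three payoff-difference brackets are

- Gp = Ip1 − Ip2 + (1−η)(1−ζ)·μ·Bp — the public's gain from participating:
  the base payoff gap plus the inaction loss Bp avoided (with probability μ)
  whenever care is non-compliant and supervision lax;
- Gm = −Cm1 − Im2 + Cm2 + (1−ζ)·Cc + δ·μ·Bm + ζ·θ·Vm2 — the institution's
  gain from complying: it forgoes the non-compliance margin (Im2 plus the
  cost saving Cm1−Cm2) but avoids the capture cost Cc under lax supervision,
  the fine θ·Vm2 under strict supervision, and the reputational damage μ·Bm
  scaled by public participation;
- Gg = W + (1−η)(θ·Vm2 + δ·μ·Bg − Ig2) — the regulator's gain from strict
  supervision: the reward W plus, against the non-compliant share, collected
  fines and the avoided superior-authority penalty, minus forgone capture
  income.

All payoffs are normalized to a common unit scale; no monetary calibration
is attempted. The published payoff table contains one internal
inconsistency: its lax-regulation/non-compliant cells deduct the fine θ·Vm2
from the institution although no strict supervisor is present to levy it,
while the expected-utility equations (which define the dynamics throughout
this package) charge the capture cost Cc there instead. `payoff_cell`
exposes both versions behind a `reconciled` flag so the discrepancy is
inspectable; nothing else uses the verbatim table.

## Parameters

The reference parameterization (`trigame.BASELINE`) is Ip1=30, Ip2=20,
μ=0.8, Bp=15, Im1=40, Cm1=30, Im2=20, Cm2=15, θ=0.6, Vm2=20, Bm=70, Cc=15,
Ig1=30, W=25, Cg1=15, Ig2=20, Bg=25. Units: μ and θ are probabilities /
intensities in [0,1]; everything else is a nonnegative payoff in normalized
units. The constraint Cm2 < Cm1 (cutting corners is cheaper than compliant
care) is enforced at validation. With μ = 0.8 the cooperative corner
E8(1,1,1) satisfies the sufficient stability condition and is the unique
ESS; at low exposure rates the deterrence terms are too weak and the
defecting corner E6(1,0,1) takes over.

## Stability analysis

The replicator field vanishes at all eight cube corners. The Jacobian is
derived analytically from the field (diagonal entries (1−2x)·Gx; every
off-diagonal entry carries a factor x(1−x)), so at a corner it is diagonal
and its eigenvalues are available in closed form. Classification follows
Lyapunov's first method with an eigenvalue tolerance (default 1e-9):

- ESS — all eigenvalues < −tol (asymptotically stable);
- unstable — any eigenvalue > +tol (a positive direction dominates any
  zero one, so instability takes precedence);
- indeterminate — otherwise: some eigenvalue within tol of zero and none
  positive; the linearization is inconclusive on the center manifold and no
  stability claim is made.

A central-difference oracle (step 1e-6) verifies the analytic Jacobian at
random interior states in the test suite, and the corner spectra are checked
against independent closed-form formulas over hundreds of random parameter
sets.

Two sufficient-condition inequality pairs are exposed by
`proposition_check`: condition 1 (Cm2−Cm1−Im2+θVm2+μBm < 0 and Ip2−Ip1 < 0)
covers the defecting corner E6, condition 2 (Cm1−Cm2+Im2−Cc−μBm < 0 and
Ip2−Ip1 < 0) the cooperative corner E8. Three caveats, all verified in
tests:

1. Each pair constrains only two of the three eigenvalues; the third
   (Ig2−W−θVm2−μBg at E6, −W at E8) is reported in `auxiliary_signs` and
   checked rather than assumed.
2. Condition 2's second inequality carries the capture cost Cc, but at the
   fully supervised corner the institution pays the fine θ·Vm2, not Cc:
   differentiating the replicator field gives λ2(E8) = Cm1−Cm2+Im2−θVm2−μBm
   (the negative of λ2(E6), since both corners share δ=ζ=1). Classification
   uses the derived eigenvalue. Consequently (a) condition 2 is sufficient
   for E8's stability only where the corrected expression is also negative,
   and (b) E6 and E8 are never simultaneously ESS — in the window of
   exposure rates between (Cm1−Cm2+Im2−Cc)/Bm = 2/7 and
   (Cm1−Cm2+Im2−θVm2)/Bm = 23/70 (reference values) the condition-2
   inequality holds while the flow still abandons compliance and converges
   to E6.
3. The two conditions can hold simultaneously (e.g. μ=0.31 on the reference
   set), so "unique ESS" phrasing attached to either condition alone is not
   literally correct; `ess_set` is the authoritative classification.

`threshold_scan`'s `e8_stability` criterion deliberately uses the published
condition-2 expression (boundary 2/7 on the reference set) as its interface;
the dynamic attractor flip, available as the `attractor_flip` criterion,
occurs at the Jacobian boundary 23/70. Both are exposed so the gap itself is
measurable.

## Numerical integration

Trajectories are computed with adaptive RK45 (`scipy.integrate.solve_ivp`,
rel_tol 1e-8, abs_tol 1e-10, horizon 200 model-time units, ≥ 201 stored
samples) in log-odds coordinates y = logit(x), in which each replicator
equation reduces to dy/dt = G(x(y)). This coordinate choice is load-bearing:

- the open cube is preserved exactly and every face remains exactly
  invariant (components starting at 0 or 1 are held fixed);
- distances to the faces are retained far below floating-point resolution
  of x itself, so a trajectory that transiently approaches a saddle face
  escapes later at the true exponential rate. Clamped direct integration
  was tried first and glues trajectories onto faces at solver precision,
  producing spurious "convergence" to saddle corners.

Halving the solver tolerances changes the reference final state by far less
than the 1e-3 corner tolerance, so attractor detection is
solver-independent.

`detect_convergence` labels a trajectory with a corner only when the final
state is within the corner tolerance (max-norm, default 1e-3), the
replicator field there is slower than the tolerance, and no bracket drives
the state away from the corner. The last condition matters because x(1−x)
underflows next to a face: a trajectory dwelling beside a saddle face moves
arbitrarily slowly without having converged, and is honestly reported as
`None` (not yet converged) rather than as an attractor.

The default initial condition for all experiments is the maximum-entropy
midpoint (0.5, 0.5, 0.5); basin sampling draws initial states uniformly from
(0.01, 0.99)³, keeping a margin off the boundary because the faces are
invariant. Reported crossing times are normalized by the horizon (t*/T), a
convention of this package: with T = 200 the reference run crosses η = 0.96
at normalized time ≈ 0.005.

## Experiments

- **Sweeps** integrate once per grid point over one or two parameters and
  extract a trajectory metric: a final frequency, the attractor label, or
  the normalized time for compliance to reach 0.9. "System stability" as a
  plotted surface is not a numerically defined quantity; the package exposes
  `final_eta` and `time_to_eta_0.9` as the two defensible surface metrics.
- **Threshold scans** bisect a parameter interval to width ≤ tol on either
  the closed-form corner-stability criterion or the integrated attractor
  label. Bisection assumes a single flip in the interval; the criterion must
  differ at the endpoints.
- **Sensitivity indices** are first-order Sobol' indices of the final
  compliance rate, estimated by the Saltelli pick-and-freeze scheme (two
  independent sample matrices plus one hybrid matrix per parameter; cost
  n·(k+2) integrations), with raw estimates clipped to [0,1] since the
  estimator can dip slightly negative at finite n. Default ranges bracket
  the reference values: Vm2 ∈ [10,30], θ ∈ [0.2,0.8], μ ∈ [0.1,0.9]. On
  these ranges the exposure rate dominates because it alone moves the
  system across its attractor boundary. One-at-a-time elasticities
  (central differences, ±1% of the reference value, scaled to relative
  units) are reported alongside; at the reference point the long-run
  compliance sits flat at 1, so all elasticities vanish there. This
  transparent variance decomposition deliberately replaces any
  machine-learned surrogate importance analysis: the ranked quantity is the
  model's own output.
- **The parameter sampler** draws payoffs/costs uniformly on [1,100] and
  μ, θ on [0.05,0.95], enforces Cm2 < Cm1 by swapping, and
  rejection-samples against either sufficient condition with an explicit
  budget. It defines the package's notion of a "random game" for property
  tests.

## Case studies

Three fixtures ship as package data (TOML): Saudi TB adherence (δ=0.795,
η=0.825, ζ=0.733; μ=0.8, Vm2=20, θ=0.6), Guangdong COVID-19 vaccination
(δ=0.72, η=0.91, ζ=0.85; μ=0.83, Vm2=18, θ=0.7), and Vietnamese rural
antibiotic supervision (δ=0.65, η=0.76, ζ=0.70; μ=0.78, Vm2=22, θ=0.65).
Only these three parameters and the observed means are reported per case;
all other payoff constants fall back to the reference parameterization when
a case is simulated, and case-level conclusions inherit that fill-in (a
caller can supply a different base). Observed means are used as initial
conditions, not calibration targets; no fitting is performed. The
cross-case Pearson correlation between observed participation and observed
compliance computed from the three fixture pairs is 0.414 and is flagged as
descriptive (n = 3); published summaries quoting a substantially higher
correlation for these data do not reproduce from the printed pairs.

## Synthetic inputs and what the tests show

The package has no external data dependency: all inputs are either the
printed constants above or draws from the documented parameter sampler.
Property tests therefore certify the mathematics (corner fixed points,
bracket/payoff-difference identities, Jacobian vs finite differences,
attractor/ESS agreement) on random games from those ranges — they say
nothing about how well any parameterization describes a real supervision
program, and the case fixtures are observed summary means, not longitudinal
trajectories. Passing tests show the dynamics, classification and
experiment machinery are internally correct, not that the game is an
adequate model of a given healthcare system.

## Problem sizes

Default experiment sizes are desk-scale by design: 100 initial conditions
for the global-convergence check, 500 random parameter sets for symbolic
Jacobian verification, 200 interior states for the finite-difference oracle,
50 random games for attractor/ESS agreement, and n = 256–512 Saltelli
samples for sensitivity ranking. Each integration of the three-equation
system takes milliseconds, so the full test suite runs in well under a
minute.

## Known limitations

- Only the eight corner equilibria are classified; interior (mixed)
  equilibria are not enumerated.
- No stochastic (SDE) variant and no time-varying parameters; the model is
  deterministic with fixed constants over the horizon.
- Zero eigenvalues are reported as indeterminate rather than resolved by
  center-manifold analysis.
- Bisection threshold scans assume monotone single-flip behaviour on the
  scanned interval.
- The printed behavioural thresholds sometimes quoted for this class of
  model (penalty intensity above one half, exposure above 0.7) are
  finite-horizon, initial-condition-dependent transients; the package
  reports computed scan outputs instead of asserting them.
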