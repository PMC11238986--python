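# Methods

This note records the modelling assumptions, parameter provenance and
numerical choices behind `fmloop`, in the spirit of the methods sections of
simulation packages: enough detail that every number the package prints can
be traced to an equation, a packaged table, or a documented design choice.

## Thalamocortical loop

The pain-processing loop is a three-node firing-rate model: VPL excites SSC
(f₁, maximal rate m₁ = 100 Hz), VPL and SSC jointly excite TRN (f₂, maximal
rate m₂ = 80 Hz, reflecting inhibitory-population physiology), and TRN
inhibits the VPL response to SSC input.  Inhibition acts twice on the VPL
Hill response: it depresses the maximal rate (the decreasing factor g(aT))
and desensitizes the input (the raised half-saturation f_a(aT) = e₀ +
m₂-Hill(aT)).  The typeset composite in the source equation is ambiguous
about parenthesization; we follow the reading the accompanying prose
supports — inhibition lowers m and raises e — which also reproduces the
published fold anchors far better than the alternatives we evaluated
(â(1,1) = 0.2644 vs 0.265 printed; â(0.5,1) = 0.1171 vs 0.116; â(0.6,1) =
0.1551 at the default bisection tolerance vs 0.16 printed, the one anchor
that agrees only to ~0.005).

All firing-rate constants (τ = 0.5 s, m₁, m₂, e = e₀ = 20 Hz, h = 2.5) are
literature-set and fixed; the analysis varies only the dimensionless
couplings a, b, θ ∈ (0, 1].

**Equilibrium enumeration.**  At steady state S* and T* are explicit in V*,
so the problem reduces to one scalar equation on V ∈ [0, m₁/θ].  We scan a
2001-point grid, refine 10× around each sign change (so closely spaced
roots near a fold are separated), polish with Brent's method (xtol 1e-12)
and deduplicate within 1e-4 Hz.  The origin is appended explicitly: every
Hill numerator vanishes there, so it is an equilibrium for all admissible
parameters.  Stability comes from the eigenvalues of the 3×3 Jacobian,
computed by central finite differences (relative step 1e-6, one-sided at
the orthant boundary).  A state is stable iff every eigenvalue real part is
below −1e-6 s⁻¹; real parts inside ±1e-6 are labelled *marginal* and
excluded from stable counts, which keeps the bisection below from
flickering exactly at the fold.

**Bifurcation location.**  â(b, θ) is found by bisection on the
stable-equilibrium count over a ∈ [0.02, 0.6] to a default bracket width of
1e-3, after verifying bistability at the lower end and monostability at the
upper.  The reported â is the final bracket midpoint; tighter tolerances
converge to the fold itself (e.g. 0.15489 at b = 0.6).

## Neurosteroid map

The map a(A) adds a withdrawal component (span a_f, EC₅₀ e_w, coefficient
h_w) and an allosteric component (span 1−a_f, EC₅₀ e_g, coefficient h_g).
Both are increasing, so a(A) is strictly increasing and bounded by 1.
Defaults: a_f = 0.4, e_w = 1.8 ng/mL, h_w = 6.5, e_g = 18 ng/mL, h_g = 2.

Parameter provenance, all recomputable via `calibration_chain()`:

- **a_f = 0.4** from a_f(1 + fold) = 1 with fold = 1.5, the mean of the two
  published maximal GABA_A activity increases (100% and 200%).
- **a_w ≈ 0.133** by dividing a_f by the fold decrease of integrated GABA_A
  current at withdrawal.  Note an internal tension in the source material:
  a 6-fold drop of the current decay constant gives an exact integral ratio
  of 6 (∫I₀e^(−t/τ)dt = I₀τ), yet the applied factor is stated as "about
  3-fold".  We compute the exact ratio (`integrated_current_ratio`) and
  keep the applied factor as an explicit configurable defaulting to 3, so
  both numbers stay visible.
- **A_w = 1.6 ng/mL** by scaling the follicular brain level 2.4 ng/mL by
  the finasteride plasma drop 9 → 6 ng/mL.
- **(e_w, h_w)** from a bounded 2-D least-squares solve of
  a(A_w) = a_w and f_w(A_sat)/a_f = 0.866 with A_sat = 2.4 ng/mL.  The
  saturation fraction 0.866 is reverse-derived from the published (e_w,
  h_w) pair, because "asymptotically approached at A ≈ 2.4" is not by
  itself operational; it is exposed as a configurable.  The solve recovers
  (1.797, 6.443), within 5% of the published values; residuals must close
  below 1e-8 or the calibration reports infeasibility.

The brain-from-plasma estimates use the luteal ratio 20/1.2.  The packaged
concentration table stores the printed estimates (2.4, 260 ng/mL) while the
operation computes the exact arithmetic (2.5, 266.7); both are retained,
flagged by provenance, and deliberately not reconciled.

## Endocrine loop

Both axes share identical parameters, so the vector field commutes with
coordinate exchange and every reported object (equilibria, basins) must
respect that symmetry — the test suite asserts it.  The mutual-inhibition
parameters (e_x = 28, h_x = 4.2) are the medians of the packaged collection
of fitted hormone-interaction Hill parameters; the self-limiting constants
(e_k = 25.57, h_k = 6.6, α = 0.48) are model-calibration values taken as
given; τ = 30 min is a typical endocrine response timescale.

**Equilibria** are found twice over: a dense scalar scan of
f(x) = k(x)·x on the diagonal (symmetric states) and 2-D root finding
started from a 25×25 grid over [0, 100]² (asymmetric states); every root's
mirror is pushed explicitly so round-off cannot break the exchange pairing.
Roots deduplicate within 1e-4 and must have residual < 1e-8.  At defaults
this yields exactly three stable states — (17.5, 17.5), (86.1, 0.18) and
its mirror — plus a saddle pair, and the enumeration is unchanged under 2×
grid refinement.

**Basins** are mapped by integrating each grid initial condition in
convergence-checked chunks (20τ per chunk, LSODA, rtol 1e-8/atol 1e-10)
until the right-hand-side max-norm falls below 1e-6 per minute, then
assigning the endpoint to the stable equilibrium within a 0.5-unit capture
radius; unresolved points are labelled −1 and counted separately.  The
default production grid is 101×101 with a 10⁴-minute horizon (a few
minutes on one CPU); tests and the shipped examples use 15–21 point grids
with an 8000-minute horizon, which resolve the same three basins in
seconds.  Circadian forcing is deliberately not modelled: the limit-cycle
refinement it would add is negligible for the pathogenesis question the
package addresses.

## Scenario coupling

The published material pins only anchor values, not map shapes, for the
endocrine → coupling translation.  The defaults are the simplest monotone
interpolants through those anchors and are labelled "configured" in every
report:

- HPG → A: piecewise-linear through (0, 1.6), (15, 2.4), (100, 20) ng/mL.
  The interior anchor places the follicular level at HPG = 15, just below
  the symmetric endocrine equilibrium (≈ 17.5), so normal endocrine
  operation maps to at-or-above-follicular allopregnanolone.
- HPA → b: linear, b = 0.5·(1 + 0.2·HPA/100), i.e. physiological b = 0.5
  at rest rising to the stressed b = 0.6 at full activation (b = 1 is the
  excitotoxic ceiling, not reachable through this map).

Both maps are constructor arguments, so alternative couplings can be
plugged in without touching the classification logic.

The prevalence calculation uses the *unrounded* daily withdrawal
probability p_woman = 460/(37·365) ≈ 0.0341; rounding it to 0.037 first
would not reproduce the published ratio G = 6.8, and the package surfaces
the exact value it uses.

## Hill fitting and the synthetic generator

`fit_hill` is bounded trust-region least squares (scipy) with multi-start
initials — e at the positive-input quartiles, h ∈ {1, 2, 4, 8} — keeping
the best residual and breaking ties toward the smaller (less cooperative)
h.  Normalization maps each column's observed min → 0 and max → 100; a
constant column is a reported failure, not a silent pass-through.  Because
the original per-study fitting protocol is unspecified, both a fixed-(m,
offset) mode and an all-free mode are exposed.  The Spearman rank p-value
of the monotone association is attached as a diagnostic only.

The synthetic generator draws log-spaced inputs over [e/10, 10e] and adds
seeded Gaussian noise in response units.  It emulates the smooth,
monotone, homoscedastic dose-response tables the fitting code is meant
for; it does not emulate real assay pathologies (heteroscedastic error,
censoring at assay limits, non-Hill shapes), so fit-recovery tests
demonstrate correctness of the estimator, not robustness on arbitrary
laboratory data.

## Numerical conventions

- 0^h := 0 for all h > 0 (continuous limit), so Hill curves are defined at
  the origin.
- Integration: LSODA with rtol 1e-8, atol 1e-10; states are evaluated on
  the projection onto the nonnegative orthant and clamped to 0 within
  1e-6; deeper excursions raise.
- Convergence: right-hand-side max-norm < 1e-6 state-units per time unit.
- All stochastic fixtures and spot-checks take explicit seeds and record
  them in their outputs.

## Known limitations

- The thalamocortical model is a lumped three-node rate model: no spatial
  cortex structure, conduction delays, or stochastic spiking.
- The endocrine model resolves axes as single activity variables; no
  hormone species, pulsatility or sex-specific parameters.
- The coupling maps between the two systems are anchored but not
  measured; conclusions that depend on their interior shape (rather than
  the anchors) should be treated as qualitative.
- The prevalence prediction counts withdrawal-episode frequency only; it
  deliberately does not model the population frequency of the triggering
  conditions themselves.
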