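# Methods

## Model and assumptions

The package implements the deterministic continuous-time dynamics of two
diallelic loci (A, B) in two demes coupled by migration.  Selection is
genic (no dominance, no epistasis) and diversifying: `A1`, `B1` are
favoured in deme 1 with Malthusian coefficients `alpha_1/2`, `beta_1/2`
and disfavoured in deme 2 (`alpha_2, beta_2 < 0`).  Selection is soft
(regulation within demes), so deme contributions are fixed; migration
replaces a fraction of deme `k` per unit time at rate `m_k`.  Drift and
mutation are absent.  Because the continuous-time model is the weak-force
limit of the discrete-time life cycle, all parameters are rates and only
their ratios matter for the equilibrium structure; no discrete-time
variant is provided.

The same right-hand side describes a haploid population with allelic
fitnesses `±alpha_k`, `±beta_k`; this is checked in the tests.

### Canonical form

`canonicalize` searches the sixteen relabelings (allele flips per locus,
locus exchange, deme exchange) for one satisfying
`alpha1 > 0 > alpha2`, `beta1 > 0 > beta2`, `beta1 >= alpha1`,
`theta = alpha1*beta2 - alpha2*beta1 >= 0`, preferring the identity and
transforms with fewer components.  The transform record maps states in
both directions, so results can be reported in the caller's labels.  The
degenerate regime `theta = 0` (including the super-symmetric case
`alpha_k = beta_k = -alpha_{k*}`, `m1 = m2`) is admitted only behind an
explicit flag, because several classification results change there.

### Linkage equilibrium as a mode, not a large rate

`rho = "LE"` selects the exactly decoupled one-locus dynamics on
`[0,1]^4` instead of a huge finite recombination rate.  Rationale: the
decoupled equations are exact in the limit, and a finite surrogate (say
`rho = 1e9`) makes the system needlessly stiff while adding no
information.

## Numerics

* **Integration** uses LSODA (stiff-capable, adaptive) in geometrically
  growing time chunks, each terminated early by an event that fires when
  the sup-norm of the right-hand side falls below the convergence
  threshold (default `1e-10`; horizon default `1e6` time units, both
  configurable).  After each chunk the state is projected back onto the
  constraint set if the violation is below a clip tolerance (default
  `1e-9`, matching the default solver tolerances `rtol 1e-10 / atol
  1e-12`); larger violations abort, because silent clipping masks solver
  failure.  Callers that loosen the solver tolerances (the bifurcation
  conformance tests use `rtol 1e-7`) must loosen the clip tolerance
  correspondingly.
* **Jacobians**: the 6×6 Jacobian of the two-locus flow is analytic.  The
  4-dimensional linkage-equilibrium flow, the complete-linkage
  tri-gametic subsystem and the 14-dimensional three-locus flow are
  differentiated by complex-step (`h = 1e-200`), which is exact to
  machine precision for these polynomial vector fields — no symbolic
  algebra is needed.
* **Stability**: eigenvalue real parts within `1e-8` of zero are reported
  as `marginal`, never rounded to stable/unstable.  For complete linkage
  the classification runs in the tri-gametic subsystem `{A1B1, A2B1,
  A2B2}` after discarding the repulsion gamete `A1B2`, which is always
  lost (verified dynamically in the tests).  The single-locus
  polymorphisms' transversal stability at general finite `rho` is
  computed numerically from the analytic Jacobian; the quartic
  characteristic factor has no useful closed form.
* **Interior roots** (`find_internal`): multi-start Powell-hybrid search
  seeded from the weak-migration expansion, the QLE expansion, the
  complete-linkage polymorphism (pulled slightly off its edge) and a
  coarse interior grid, plus caller-supplied continuation seeds; roots
  are merged within `1e-8` in state space and points within `1e-4` of a
  second root carry a `near_bifurcation` flag rather than being silently
  merged.  Only strictly interior roots are returned; zero, one or two
  are the generic outcomes, more are flagged.
* **`m_max_numeric`**: continuation of the stable interior equilibrium in
  the total migration rate (two dozen upward steps with the previous root
  as seed), then bisection of the loss point to relative tolerance
  `1e-6`.  The loss mechanism is reported as `boundary_exchange` when the
  last stable root approaches the state-space boundary (exchange of
  stability with a boundary equilibrium) and as `fold` when it disappears
  in the interior (saddle-node; the bistable pattern of highly asymmetric
  migration at intermediate recombination).
* **Infinity sentinels**: the critical rates `m^A`, `m^B`, `m^F0`, `m*`
  take the value `inf` exactly when their denominators vanish (detected
  by exact comparison, not an epsilon band), so downstream `min`/ordering
  logic is total.  In the bifurcation classifiers, equality of `phi` with
  a threshold ratio is decided exactly when the inputs are exact
  (`fractions.Fraction` survives the threshold arithmetic), otherwise
  within a relative tolerance of `1e-12`; the degenerate diagrams occur
  on measure-zero parameter sets.

## Design choices where the design was open

* **Initial conditions** for convergence runs default to a lightly
  perturbed undifferentiated interior state (`p = q = 0.5 ± 0.05`,
  `D = 0`); no initial condition is canonical in the source theory, and
  the choice is documented rather than inferred.
* **The complete-linkage edge polymorphism** on the `M2`–`M3` edge is
  computable but excluded from bifurcation diagrams (it is unstable for
  every parameter choice and leaves the state space for any positive
  recombination).  Similarly, the never-stable `PA2`/`PB1` (and `M2`)
  are tracked but only rendered on request.
* **Deme weights for `F_ST` and load** default to equal (`c1 = c2 =
  1/2`); the load definition presumes demes of equal size, and the
  variance in `F_ST` is a weighted population (not sample) variance over
  the two demes.
* **M1/M4 stability closed form.**  The linkage-disequilibrium direction
  at the monomorphic equilibria contributes a 2×2 block
  `[[±(a1+b1) - rho - m1, m1], [m2, ±(a2+b2) - rho - m2]]`; the
  implementation uses its trace/determinant signs directly rather than a
  rearranged scalar inequality in `m2`.  The two are equivalent where the
  rearrangement is valid, and the block form is immune to
  sign-of-denominator slips; it is cross-checked against the full 6×6
  spectrum on a thousand random draws.
* **Invasion analysis** at `PB2` exploits the exact linear decoupling of
  the `(p1, p2, D1, D2)` directions from the B-locus marginal system at
  the boundary: the transversal spectrum is that 4×4 block of the
  analytic Jacobian.  `rho_max` and `alpha_min` are bisections of its
  leading eigenvalue (relative tolerance `1e-8`), cross-validated by
  direct 8-dimensional gamete-space linearization and by forward
  integration from perturbed boundary states.  Two limits deserve note:
  at strong recombination the invasion criterion is the one-locus
  protection condition `sigma1 + sigma2 < 1` (not admissibility of the
  full LE polymorphism, which also requires the mirrored bound); and
  "arbitrarily small effects invade under tight linkage" holds for
  mutants whose effects are small in **both** demes — with the deme-2
  disadvantage held fixed, the threshold advantage tends to a small
  positive limit as `rho -> 0` (Perron–Frobenius argument on the
  `A1B1`-invasion matrix, whose leading eigenvalue is exactly zero when
  the mutant is neutral everywhere).
* **Three-locus construction.**  The neutral-site system is built from
  first principles in the 8-gamete-per-deme representation: additive
  selection contributions (zero at N), single-crossover recombination at
  rates `rho_AN`, `rho_NB` (no interference parameter), and migration.
  The 14 moment coordinates (allele frequencies and all disequilibria,
  including the three-way `D_ANB`) are derived by pushing the gamete flow
  through the differential of the moment map; exact marginalization to
  the two-locus dynamics and invariance of the neutral manifold are
  tested.  The structural zero of the neutral Jacobian block is
  identified by eigenvector alignment with the neutral-line tangent, not
  by magnitude, so a genuinely tiny `m_eff` is never confused with the
  structural mode.

## What the synthetic sweeps emulate — and what they do not

`generate_sweep` draws selection magnitudes log-uniformly on
`[0.05, 2]` per unit time, total migration uniformly on `[0, m_high]`
and the migration ratio uniformly on `(0, 1)` — a broad cloud of
migration–selection regimes spanning weak to strong coupling, used for
the property checks (oracle equivalences, structural inequalities,
bifurcation conformance).  These are mathematical stress tests of a
deterministic model: they say nothing about finite-population noise,
mutation, dominance/epistasis, more than two demes or loci, or sampling
error in real data, all of which are outside the model class.  Passing
them shows the implementation agrees with the theory's closed forms and
with independent numerical oracles, not that the model describes any
particular empirical system.

## Problem sizes in the test-suite

Closed-form residual and stability-agreement checks run at 1000 random
draws; structural inequalities at 1000 draws; the bifurcation-theorem
conformance check integrates the full dynamics at 5 migration rates per
predicted stability interval from 2 random interior starts, for 200
random regimes under linkage equilibrium and 120 under complete linkage
(complete-linkage integrations are several times costlier; the smaller
sample already exercises every diagram class).  Conformance points whose
predicted polymorphic equilibrium lies within 0.02 of a fixation state
are skipped: there the flanking diagram applies within solver
resolution.  Perturbation-order checks use decade grids
(`m ∈ {1e-2, 1e-3, 1e-4}`, `rho ∈ {10, 100, 1000}`, QLE-collision
`rho ∈ {50, 100, 200}`) and assert log–log slopes of 2 within 0.2
(0.35 for the collision rate, whose bisection tolerance contributes).

## Known limitations

* No certificate that the numerical interior-root search is exhaustive;
  more than two interior equilibria would be reported, not suppressed,
  but none were observed.
* Global stability is probed by integration from random starts, not
  proven.
* The continent–island limit (`phi` exactly 0 or 1) is handled by the
  general machinery; the dedicated closed form for its maximum migration
  rate is not implemented, and `m_max` there comes from the numerical
  continuation.
* Hopf bifurcations are not searched for beyond eigenvalue monitoring;
  none were encountered.
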