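# Methods

This note records the modelling assumptions, conventions, and numerical
choices behind `dsdesign`, and what its tests do and do not establish.

## Model class and recasting

The toolkit accepts ODE models whose right-hand sides are sums of terms,
each a product of power laws optionally divided by sums of power laws with
positive coefficients (the rational rate laws of biochemical kinetics).
Recasting is exact and purely syntactic: numerator sums are multiplied
through (preserving left-to-right term order), each distinct multi-term
denominator becomes one auxiliary variable `X` defined by a zero-constraint,
and the auxiliary replaces the denominator in the ODEs. Auxiliary variables
are named after the equation's left-hand-side variable with the first free
two-digit suffix (`X1` → `X100`, two denominators in the `X4` equation →
`X400`, `X401`). Term order is load-bearing: case numbers are derived from
it, so recasting emits the constant term first and then each regulated term
in source order.

Exponents are rationals (parsed exactly, including `^0.5` and `^(1/2)`);
irrational exponents have no written form and are rejected. Rate-constant
symbols may be products of named parameters and numeric literals
(`a1*rho1`); they are kept symbolic so per-parameter tolerances remain
computable, with only numeric literals folded into the term coefficient.

## Phenotypes and the design space

The case signature `[p1 q1 … pn qn]` selects one positive and one negative
term per equation. Case numbers are the mixed-radix value of
`(p1−1, q1−1, …)` with radices `(P1, Q1, …, Pn, Qn)` plus one — the last
equation's indices vary fastest and the positive index is more significant
than the negative one within an equation. The all-ones signature is case 1.

Dominance conditions are the pairwise log-inequalities "dominant term ≥
sibling term"; each equation contributes `(P_i − 1) + (Q_i − 1)` rows over
all `n + m` log-variables. Substituting the S-system's affine steady-state
solution eliminates the dependent variables and yields the boundary
conditions over the `m` log-parameters. A case whose dependent log-linear
block is singular has no solution hyperplane; it is reported with
`has_solution = False` and counted invalid (the repertoire counts cases
with a phenotypic region, not merely a dominance region).

Strict dominance inequalities are relaxed to `≥` for LP purposes; validity
requires an interior point with slack ≥ δ = 1e-6 log10 units. Boundaries
are measure-zero and do not affect the repertoire; point-membership queries
(`valid_cases_at_point`) use slack ≥ 0 with a 1e-9 tolerance, so a point
lying exactly on shared boundaries reports every touching case — this is
the desired behaviour when counting coexisting fixed points.

Every log-variable lives in the global box [−20, 20] (values 1e-20–1e20,
generous against physical limits such as solubility and diffusion). The LP
backend is scipy's HiGHS with fixed options; it is deterministic for fixed
input, which makes enumeration, prediction, and the CLI reproducible
byte for byte.

## S-system analysis

Steady states solve `(G − H) y_dep = (b − a) − (G_I − H_I) y_I`. The
dependent block is inverted in exact rational arithmetic (sympy), so the
affine coefficient matrix — the logarithmic gains and parameter
sensitivities — is exact; only the constant offsets (logarithms of numeric
coefficients) are floating point. Gains are signed derivatives
`∂log X_i/∂log X_j`. In the memory circuit the heterodimer-coupled cases
satisfy `X1·X2 = α1/k` at steady state, so `L(X1, X3) = −L(X2, X3)` there:
couplings of equal magnitude and opposite sign.

Stability is evaluated on the reduced S-system only: the auxiliary block is
solved (`y_c = −R y_t − S y_I + U`, exact rationals) and substituted, and
the Jacobian at the steady state is formed analytically from the power-law
derivatives, `J_ij = F_i (g_ij − h_ij)/X_j` with `F_i` the balanced flux.
Eigenvalues with `|Re λ| < 1e-9 ×` the spectral radius are flagged
borderline and counted as non-positive (no tie rule is defined for
measure-zero cases). The Routh first-column count is an independent
cross-check; a zero pivot raises a status that callers answer by falling
back to eigenvalues.

## Parameter prediction

* **Vertex sets** optimize the zero objective (or the log-linear form of a
  power-law objective) over the boundary polytope — a basic feasible point.
* **Interior sets** maximize the minimum row slack, capped at 1.0 log10
  unit per row so unbounded regions stay well-posed, then break the
  (common) LP degeneracy by minimizing the L1 norm of the log-parameters at
  that slack. The second stage makes the interior point unique in practice
  and returns the box centre (all parameters 1) for an unconstrained
  region. Published reference points are treated as admissible witnesses —
  they must re-validate, but the solver is not required to return them.
* **Tolerances** fix all parameters but one; each boundary row then gives a
  closed-form bound on the free log-parameter, and the folds are
  `10^(bound − current)`. Directions that never hit a row are reported as
  the box limits 1e-20/1e20 exactly.
* **Ensembles** stack member boundary rows over the shared parameters
  (intersection) or over shared parameters plus per-member replicas
  `$V_i` of the slice variables (co-localization); arrangement constraints
  are additional log-linear rows over the replicas. Feasibility is tested
  exactly as for a single case. The replicated polytope has
  `m + (n_members − 1)·s` dimensions for `s` slice variables — the count
  follows from giving each of the `n` members its own copy while the
  original slice coordinates drop out.
* **Stable-intersection search** grows subsets breadth-first; since adding
  rows can only shrink a polytope, supersets of infeasible combinations are
  pruned without testing. The pruned search is verified equivalent to
  exhaustive enumeration on the single-gene system.

## Fixture conventions

The single-gene fixture sets `k = 1` in its default parameter set and
carries the model-level constraint `rho1 ≥ 1` (a capacity below one would
invert the meaning of "activation"); the memory fixture carries `rho1,
rho2 ≥ 1` likewise. With these conventions the packaged reference point
reproduces the published tolerance table exactly; without them the `k`,
`X2`, and `rho1` rows would saturate differently.

## Attractor counting and its sensitivity

Bistable-only and tristable-only instances are identified by predicting an
ensemble's interior point and counting the stable cases containing it.
This filter is *sensitive to the interior-point rule*: every valid pair of
stable phenotypes extends to a valid triple and every triple to a
quadruple, so whether an interior point of a pair also lies inside a third
region depends entirely on where the rule lands. The tests therefore
assert the robust facts — instances with exactly 2 and exactly 3
attractors exist, every size-4 ensemble yields exactly 4 — rather than a
specific tally. Quadrant-occupancy analysis does not suffer from this:
it is a pure feasibility question (24 of the 35 size-4 multisets over the
four quadrants are realizable, and all 18 quadrastable ensembles admit the
one-attractor-per-quadrant arrangement).

## Landscape analysis and simulation

Grids are log-uniform (defaults: 100×100 for parameter slices, 60×60 for
basins; the test suite uses 5–25 points per axis, which is sufficient
because slice labels are piecewise-constant over polytopes and verified
stable under refinement). Dominance at a *state* point is decided by
numeric term ranking, not LP — it is a pointwise question.

Fixed-point candidates are the S-system steady states of the cases valid at
the parameter point, refined by damped Newton iteration in log-state
coordinates (positivity preserved by construction; up to 30 halvings per
step) against the full GMA right-hand sides; refined residuals are below
1e-9 relative. Duplicates within 1e-6 relative log-distance merge, keeping
the refined representative, and stability is re-evaluated on the
full-system Jacobian (central differences with relative step 1e-6 — the
refinement target, unlike the S-system Jacobian, involves the
auxiliary-solution chain, where finite differences are simpler and
amply accurate at these scales).

Simulation integrates the full ODEs in log-state coordinates with LSODA
(rtol 1e-8, atol 1e-10), guaranteeing strictly positive trajectories;
boluses are instantaneous state jumps between integration segments.
Auxiliary constraints are solved pointwise in closed form, which requires
each auxiliary to appear alone, to the power ±1, in exactly one term of its
constraint — the form recasting produces; cyclically coupled constraints
are rejected rather than solved iteratively.

The counter demonstration is predicted end to end: the quadrastable
parameter set is the interior point of the first size-4 stable ensemble
under one-attractor-per-quadrant constraints with thresholds fixed at 1,
the attractors come from the fixed-point solver, and the bolus is the
first candidate amount that drives the full forward and reverse
three-state cycle (the 275-unit default is kept when the predicted
instance supports it, which it does). Reporter parameters default to
α4 = β4 = 1 and activation/repression capacities ρ41 = ρ42 = 100 — strong
but physiological regulation chosen so the three count states map to
well-separated expression levels. Stimulations are spaced 20 time units
apart; state labels are read just before each subsequent event.

## Known limitations

* Only acyclic design spaces: each auxiliary's constraint must be solvable
  for it explicitly; implicit (cyclic) constraint systems are out of scope.
* Vertex enumeration of polytopes is not implemented beyond the 2-D grid
  classification used for slices.
* The attractor-count filter inherits the interior-point convention (see
  above); figures built on it are reproduced qualitatively (region counts
  and transition sequences), not pixel-wise.
* Stability letters summarize one representative interior point per case;
  for architectures where stability varies within a phenotypic region a
  single letter is an undersummary (the packaged circuits are uniform in
  this respect).
* No global optimization over non-log-linear objectives and no
  sampling-based parameter estimation — avoiding the latter is the point
  of the method.
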