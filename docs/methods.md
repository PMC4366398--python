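# Methods

## The process

The model is a continuous-time multi-type branching process. A cell type
("class") is a pair (genotype *i*, compartment *j*), flattened genotype-major
(k = i·M + j) so the minimal two-genotype, two-compartment model orders its
dummy variables (x00, x01, x10, x11). Events per class:

* division without mutation, rate `b_ij (1-u)` → two (i, j) cells;
* division with mutation, rate `b_ij u` → one (i, j) and one (i+1, j) cell
  (the top genotype divides at full rate `b_ij` and never mutates; mutation
  is strictly stepwise, no back-mutation);
* death, rate `d_ij = alpha_j` (drug-independent: cytostatic drug action);
* migration to a neighbouring compartment at the topology's per-target rates
  (genotype preserved).

Birth rates come from the Hill landscape
`b_ij = beta_j (1 - i s) / (1 + (D_j/(rho^i IC50))^m)`. A genotype whose
cumulative cost reaches `i·s >= 1` is rejected at configuration time rather
than clamped, to surface misconfigured genotype counts early.

Internally `BranchingModel` is more general than the genotype grid: per-class
birth/death rates, an arbitrary single-target mutation map and an arbitrary
sparse migration graph. The constrained pathway chains (below) are ordinary
instances, so every engine works on them unchanged.

### Migration topologies

`pairwise` (M=2, rate v each way), `ring` (v/2 to each nearest neighbour;
at M=2 the two neighbours coincide and the topologies degenerate to the same
model), `global` (v/(M-1) to every other compartment), and `line` for the
radial shells of the solid-tumor geometry. The stated per-neighbour rate is
v/2; for a line the edge shells have one neighbour, and we keep the
per-neighbour rate v/2 there (total edge outflow v/2). The alternative —
full rate v to the single neighbour — is exposed as `edge_mode="full"`. The
choice is invisible at small v and documented because no convention is
canonical for edges.

## Survival-form integration

The backward PGF system is integrated as G = 1 − F:

```
dG_ij/dt = (b_ij(1-u) - d_ij - v) G_ij + b_ij u G_(i+1)j
           + sum_k v_(j->k) G_ik - b_ij(1-u) G_ij^2 - b_ij u G_ij G_(i+1)j
```

This is an exact algebraic transform, but G = 0 (F = 1) becomes an exact
fixed point of the numerics: probabilities within 1e-9 of one are carried
with absolute, not relative, accuracy. That matters because census
composition takes `sum N_ij log1p(-G_ij)` with counts up to 1e11 and
per-cell escape probabilities of order u ~ 1e-9; the naive F-form loses
these digits to cancellation, and `(1-eps)^1e11` underflows without the
log1p/expm1 path. Conditional probabilities are assembled as
`exp(L_inf)·expm1(L_t - L_inf)` when the no-escape probability is large and
as a direct difference otherwise, so neither end of the scale cancels.

Real solves use LSODA with an analytic Jacobian, rtol 1e-10 / atol 1e-14
(relapse differences of order u·v must survive). The torus inversions use
DOP853 on the complex system (stacked as a real vector), rtol 1e-10 /
atol 1e-12, batching all N² initial conditions into one solve — only the
initial conditions differ, so one vectorised integration replaces a million
scalar ones.

### Limits

"t → infinity" is operationalised by integrating over doubling horizons
until the RHS sup-norm falls below 1e-12, then Newton-polishing the
algebraic fixed-point system (scipy hybr with the same Jacobian). The
polish is kept only if it stays within 1e-6 of the integrated value — the
backward flow started at the evaluation point selects the relevant minimal
fixed point in [0,1]^K, and the root-finder must not jump to another one
(e.g. the trivial fixed point at 1).

### Mean time to resistance

`T = integral p_s dt` uses trapezoid quadrature on 4097 points over a
horizon that doubles until p_s drops below 1e-4, plus an analytic
exponential-tail correction fitted by least squares to the final decade of
decay; truncating at a finite horizon alone biases the mean low. The mean
is stable to ~1e-4 relative under quadrature refinement (tested). A
conditioning event below probability 1e-12 raises an explicit error rather
than returning NaN.

## Count-distribution inversion

`p_mn(t)` is the 2-D inverse DFT of the PGF evaluated with the two target
dummy variables on the N-point unit circle and all other coordinates at 1 —
the trapezoid approximation of the double Cauchy integral. Defaults:
N = 128 for routine work (stable to <1e-6 against N = 256 at the reference
parameters), N = 1000 supported. Aliasing folds counts ≥ N back onto the
grid; N must be at least twice the largest count of interest (enforced),
and the configuration deliberately refuses coarser grids. Imaginary residue
and negative entries are checked against 1e-8 *before* clipping, so
clipping can never mask an integrator failure. The on-grid mass equals
F(1;t) = 1 exactly in survival form, so normalisation is a structural
identity rather than a numerical achievement; accuracy is instead probed by
grid refinement and by total-variation distance against 1e5-replicate
simulation histograms (~3e-4 at the reference parameters).

At late times, established resistant clones grow beyond any fixed grid
(e^{rt} cells); the windowed p_mn then describes the small-count corner
only, and expected abundances are better obtained from the first-moment
matrix exponential (the mean generator is the transpose of the survival
linear part). The test suite uses exactly that oracle for the
"drug-compartment abundance overtakes the sanctuary" claim.

## Pathways

The migration-mutation and mutation-migration routes are bespoke
three-class chains (origin → intermediate → destination) with
one-directional transitions, not the full model with rates zeroed: the full
model's bidirectional migration mixes the routes by construction. The
low-rate dominance condition

```
b00/((b00-d00)-(b10-d10)) > b01/((b00-d00)-(b01-d01))
```

predicts mutation-migration to be faster; under equal deaths and
b10 = (1-s) b00, b01 = (1-delta) b00 it reduces exactly to
delta > s/(1+s). When the resistant sanctuary class grows at least as fast
as the sensitive one (neutral or advantageous resistance, left denominator
≤ 0) the mutation-first route wins for any positive drug effect and the
predicate returns true; a non-positive right denominator (no drug effect)
is outside the condition's domain and raises. The landscape's canonical
"rugged" pattern (sensitive subcritical under drug) is enforced only under
`strict=True`, because threshold scans in delta legitimately cross it.

The numeric crossing delta* is located by bisection on
delta → T_migration-mutation(delta) − T_mutation-migration to 1e-4; the
mutation-migration time is independent of delta (its chain never visits the
sensitive-under-drug class) and is computed once. At u = v = 1e-4 the
crossing lands within 3e-3 of s/(1+s); residual offset is the finite-rate
correction to the low-rate limit, shrinking with u and v.

Sanctuary microenvironments that slow proliferation are modelled by scaling
all four sanctuary rates by phi ∈ (0,1] (`scaled_sanctuary`), which delays
both pathways without reordering them.

## Scenarios

**Two lesions.** Concentrations are parameterised by the fixed mean D̄ = 50
and difference dD, so the drug budget is constant while heterogeneity
varies. Defaults: N0 = 1e3 slow cells (beta 0.05, alpha 0.04), N1 = 1e8
fast cells (beta 0.5, alpha 0.4), IC50 = 50, m = 2, rho = 5, s = 0.01,
u = 1e-9 (a realistic point-mutation probability). At dD = 50 the
compartment-0 sensitive class crosses criticality (b = alpha); below it
there is no true sanctuary and escape stays below a few percent, above it
escape rises to ~1 and the conditional relapse time decreases strictly in
dD (7.9e3 → 745 days at v = 1e-3). Within the eradication regime the
conditional relapse time is *not* monotone and loses its clinical meaning:
with 1e8 cells, transient doomed mutants dominate the presence probability
(N·b·u ≈ 0.02/day against an establishment probability ~0.01), so the
presence-conditional mean time collapses to under a day — conditioning on
an almost-impossible event selects its fastest realisations. The monotonicity
claim is therefore asserted over the failure regime, and sweeps report
escape alongside time so the regime is always visible.

**Migration sweep.** Across v ∈ [1e-6, 1] at dD = 100 the failure regime
spans v ≤ 1e-2; within it the relapse time has an interior minimum
(v ≈ 1e-3): moderate migration feeds the sanctuary, excessive migration
averages the compartments and rescues the treatment (escape collapses to
~0.005 above v ≈ 0.03).

**Ring.** M = 20 compartments, n = 5 genotypes, rho = 1.1, IC50 = 100,
b0 = 0.2, d0 = 0.1, u = 1e-4. The concentration profile is a Gaussian bump
in ring distance from the central compartment, rescaled to mean D̄ = 50,
with the bump width solved by bisection so the standard deviation of the
per-compartment concentrations equals the stated sigma (24.7 by default;
sigma = 0 degenerates to a homogeneous profile). This is the one reading
under which a sigma far larger than the compartment count is meaningful.
The census is a single sensitive cell, by default in the
lowest-concentration compartment; "full resistance" is presence of the top
genotype anywhere. Local (ring) migration reaches full resistance sooner
than global (285 vs 302 days at v = 0.01): sequential hops along the
gradient let each new mutation establish in the next-harsher compartment.

**Onion tumor.** N = 1e11 cells, radius 2.3 cm, M = 30 shells of equal
width; birth and death decay as exp(-x/tau_g), drug as exp(-x/tau_d) from
D0 = 500 at the central vessel, n = 3 genotypes, v = 2e-4 on the radial
line. Shell populations are proportional to the integral of
x² exp(-x/tau_c) over the shell — cell density per unit *volume*, the
spherical reading; a cylindrical x¹ weighting is a config switch since the
geometry's dimensionality is a modelling choice. Rates and drug are
evaluated at shell midpoints (compartments are homogeneous subpopulations;
refining M changes results negligibly). Fractional populations are resolved
by largest-remainder rounding so the total is exact. Perfect penetration
(1/tau_d → 0) gives escape ~1e-10; strong gradients give escape ~1 with
relapse accelerating as the gradient deepens.

## Stochastic oracle

The simulator is a direct Gillespie SSA over the same event list
(numba-compiled; ~1e6–1e7 events/s). Tau-leaping is deliberately absent:
the module exists to be exact, and large-population regimes belong to the
PGF engine. Per-replicate seeds come from `SeedSequence(seed)` state
spawning, so ensembles are reproducible and order-independent. A population
cap (default 1e6 cells) flags runaway supercritical replicates; their later
checkpoints repeat the state at truncation, which preserves
resistance-presence indicators (established resistance does not vanish).
First-resistance times are recorded when a masked class first becomes
occupied.

Comparisons against the PGF engine are made on presence probabilities
(P(no resistant cells at t)), the quantity the conditional relapse
machinery is actually built from, using 3-sigma binomial bands with the
standard error evaluated at the reference probability — for rare events the
empirical standard error is itself too noisy to normalise by.

## What the scenarios do and do not emulate

All experiments are generated from printed parameter sets; there is no
fitted data. The generator families emulate compartment-structured
populations with concentration-dependent proliferation only: no
pharmacokinetic time variation, no cytotoxic (death-raising) drug action,
no density dependence or carrying capacity, no genotype-dependent motility,
no explicit vasculature, and single-drug resistance ladders only. Passing
tests therefore demonstrate internal consistency of the branching-process
machinery and agreement with its exact stochastic counterpart under these
idealisations — not calibration to any clinical dataset.

## Problem sizes

Routine computations use K = n·M ≤ 100 classes; ODE solves take
milliseconds to seconds. Oracle ensembles use 1e4 replicates for
probability checks and 1e5 for distribution histograms; inversions use
grids of 128–256 (1000 supported). The full acceptance run completes in
about half a minute on one CPU.

## Known limitations

* The conditional relapse time degenerates whenever the conditioning event
  is very rare (see the two-lesion discussion above); callers should gate
  on escape probability, as the sweeps do.
* Presence-based p_s(t) is not strictly monotone when transient doomed
  mutants are abundant; the mean-time integral remains well defined.
* The windowed count inversion describes small counts only; late-time
  abundances need the moment equations.
* The closed-form small-rate pathway approximations are not implemented;
  the ODE curves are the implementation of record.
* k-dimensional inversion for k > 2 free coordinates is out of scope
  (cost N^k).
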