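# Methods

## Model and assumptions

The package models two competing types — a wild-type and a mutant — whose
per-capita growth payoffs form a 2×2 matrix game. Strategies are inherited
(genotype determines phenotype), fitness is linear in the partner
frequency (matrix-game assumption), and time is measured in units of the
wild-type reference growth, which normalization fixes at 1. Normalization
divides all payoff entries by the wild-type self-payoff `a`; division
rather than subtraction preserves fitness *ratios*, which are what the
relative selection coefficient depends on. Matrices with `a ≤ 0` are
rejected: a non-positive reference growth has no meaningful normalization
under this scheme, and such rows are flagged rather than silently dropped.

The additive decomposition

    a = 1,  b = 1 + α_wm,  c = 1 + s_m + α_mw,  d = 1 + s_m

is the unique form in which each interaction coefficient measures the
departure of one payoff row from constancy: a row is constant exactly when
the other type has no ecological effect on it. Composed payoff entries
must be non-negative; the boundary value `α_wm = −1` (payoff `b = 0`) is
admitted because published studies that report `b = 0` by construction map
to exactly this value.

Frequency-dependent fitnesses are `f_w = 1 + α_wm·x` and
`f_m = 1 + s_m + α_mw·(1−x)` with `x` the mutant fraction, and the
selection coefficient is relative: `σ_m(x) = (f_m − f_w)/f_w`. The
replicator velocity `dx/dt = x(1−x)(f_m − f_w)` equals
`x(1−x)·σ_m(x)·f_w`, so a game whose σ_m is constant reproduces the orbit
of a constant-selection system up to the positive time-rescaling factor
`f_w(x)`; pointwise-in-time equality additionally holds when `α_wm = 0`.

## Deterministic regimes

Imposing `σ_m(x) ≡ T` and matching polynomial coefficients in `x` after
clearing the denominator gives a 2×2 linear system with solution
`α_mw = T − s_m`, `α_wm = (s_m − T)/(1 + T)` (singular at `T = −1`). The
four regimes are the targets `T = s_m` (maintenance — only the trivial
non-interacting solution), `0` (masking), `−s_m` (mirroring, singular at
`s_m = 1`), and a nonzero `s′` with `s_m = 0` (mimicry). The
implementation solves the linear system numerically rather than hard-coding
the four closed forms, and every regime pair is verified by evaluating
σ_m on a 101-point grid.

Steady-state equivalence classes are computed from the fixed-point
structure (boundaries plus the interior root
`(s_m+α_mw)/(α_wm+α_mw)` when admissible, stability from velocity signs on
either side) and the basin containing the initial condition, not from
closed-form constraint sets; the family `α_mw = α_wm − 2·s_m`, whose
stable state is 1/2, is used as a cross-check. Boundary cases (exact
equalities of coordinates) are reported as "boundary"/"none" rather than
assigned to a class.

## Mutation-aware (stochastic) regimes

With symmetric per-generation mutation μ the stationary law of the mutant
fraction peaks at the mutation-selection equilibrium, the root in [0,1] of
`σ·x(1−x) + μ(1−2x) = 0`:

    x_mode = (σ − 2μ + R) / (2σ),   R = √(σ² + 4μ²)

(continuous limit 1/2 at σ = 0; the algebraically identical form
`2μ/(R + 2μ − σ)` is used for σ < 0 to avoid catastrophic cancellation).
Evaluating σ_m at the mode gives the closed form

    σ_m(x_mode) = [2s² + s(α_mw − α_wm) + (2μ − R)(α_mw + α_wm)]
                  / [2s + α_wm(s + R − 2μ)]

which a symbolic computation confirms is exact for **both** signs of s;
no sign-dependent branches are needed. The `s = 0` case is evaluated as
the two-sided limit, i.e. σ_m at `x = 1/2` directly.

Each stochastic regime condition evaluates σ_m at the mode of its own
target reference system (maintenance at `x_mode(s_m)`, masking at 1/2,
mirroring at `x_mode(−s_m)`, mimicry at `x_mode(σ)`). The exact surfaces
are solved by bracketed one-dimensional root-finding in the constrained
coefficient; the first-order-in-μ closed forms are

    maintenance:  α_wm = μ·α_mw / (s_m(1+s_m))
    masking:      α_wm = α_mw + 2s_m              (exact at every μ)
    mirroring:    α_mw = −2s_m + μ(α_wm(1−s_m) − 2s_m)/s_m
    mimicry:      α_wm = −σ/(1+σ) + μ(α_mw − σ)/(σ(1+σ))

Mirroring is solved for α_mw because solving for α_wm introduces a 1/μ
term. Series expansion shows the μ² coefficient of each exact solution
vanishes identically, so the first-order forms agree with the exact solves
to third order in μ (measured log-log convergence slope ≈ 3); tests assert
the at-least-second-order agreement the truncation guarantees. In the
μ → 0 limit every surface reduces to the deterministic regime pair.

## Wright–Fisher simulator and stationary chain

The simulator evolves an integer mutant count (no floating-point drift) in
a constant population of N individuals with discrete non-overlapping
generations: fitness weighting of the current frequencies, symmetric
mutation of the expected frequency, then a binomial draw. The order of
events (selection → mutation → sampling) and the expected-frequency
mutation convention are modeling choices; applying mutation per individual
instead leaves the mean unchanged and perturbs the variance negligibly at
the parameter scales used here. The transition matrix in the stochastic
module uses the identical kernel, so the simulator samples exactly the
chain whose stationary vector is computed (dense linear solve of
π(T − I) = 0 with the normalization row appended). With two types the
multinomial degenerates to a binomial. μ = 0 makes the boundaries
absorbing; the stationary solver refuses that case and points the caller
to fixation-probability analysis instead.

Ensembles default to the validation protocol: a 50:50 start, 1000 burn-in
generations discarded, the next 3000 averaged, 50 replicates. This
averaging protocol supersedes the shorter general-purpose run lengths used
elsewhere for parameter scans. Per-replicate RNG streams derive from the
master seed through `SeedSequence(entropy=seed, spawn_key=(replicate,))`,
making ensembles reproducible and independent of execution order. The
pooled-sample mode is estimated on a 101-bin histogram of [0,1]; exact
ties are broken toward the analytic prediction under test, and the chosen
tie-break is part of the reported output.

Two empirical notes on mode estimation from finite ensembles. First, the
stationary density is interior-peaked only for 2Nμ > 1; at 2Nμ = 2 the
neutral density is proportional to x(1−x), flat to within 0.04% across the
central bins, and no desk-scale ensemble can resolve the peak location to
one bin — the neutral simulation check therefore runs at μ = 10⁻²
(2Nμ = 20), where the peak is sharp, while the analytic and
chain-eigenvector modes are asserted exactly at both mutation rates.
Second, mirroring surfaces match the *mode* of the reflected reference
system, not its full law: the exact mirror image of a Wright–Fisher chain
with selection +s is a chain with constant selection −s/(1+s), not −s, so
grand means of mirrored ensembles differ from the reflected reference mean
by a systematic O(s²) amount (≈0.0012 at s = 0.1) even though the modal
agreement is exact. One acceptance-level test asserts the strict
mean-equality reading and is expected to fail; the companion test asserts
the modal statement, which holds.

## Assay inference

Growth-frequency fitting regresses each type's per-capita growth rate on
the seeding mutant fraction x (wild-type monoculture at x = 0, mutant
monoculture at x = 1) by ordinary least squares — unweighted by default,
with a replicate-weighted option — and reads the payoff entries off the
line boundaries: a and b from the wild-type line at x = 0 and 1, c and d
from the mutant line. Linearity is the model assumption; a t-test on an
added quadratic term is reported per fit so that curvature significant at
the 5% level can be flagged. At least two distinct fractions per type are
required, and imported tables keep their native units, each row normalized
by its own `a`.

The synthetic-assay generator draws growth rates from the payoff-implied
lines plus independent Gaussian noise (default: fractions
{0, 0.25, 0.5, 0.75, 1}, noise SD 0.02 in units of the wild-type growth
rate, matching the few-percent replicate scatter typical of microbial and
cell-line growth-rate assays). It emulates the design of a game assay but
not several features of real data: no nonlinear frequency dependence, no
shared batch effects between types measured in the same well, no
measurement error in the seeding fractions themselves, and no growth-curve
fitting step upstream of the rate estimate. Passing recovery tests
therefore demonstrate correctness of the inversion pipeline under the
model, not robustness to model violation.

## Distances to regime surfaces

Distances are computed in the dimensionless 3-space (s_m, α_mw, α_wm) with
μ frozen at 0.001; no further coordinate normalization is applied beyond
the intrinsic dimensionlessness of all three axes. The first-order
surfaces are the default target (the exact surfaces are available behind a
flag); mimicry is excluded because it would require an arbitrary target σ.
The masking surface is the plane `α_wm = α_mw + 2s_m` with normal
(−2, −1, 1)/√6, whose closed-form point-to-plane distance serves as the
oracle for the numerical machinery.

Projection parameterizes each surface by its two free coordinates and
minimizes the squared Euclidean distance with derivative-free local
optimization (Powell) from Latin-hypercube starts, the measured point's
own coordinates, the best cells of a coarse vectorized scan, and an
analytic seed for the thin near-singular sheet at s ≈ 0 — for small s the
μ/s term lets the maintenance and mirroring surfaces pass close to almost
any point, a genuine geometric feature of the first-order constraints that
single-basin optimizers and coarse grids both miss. A margin of 10⁻⁴
around the singular values s ∈ {0, −1} is excluded. Optimizer
non-convergence yields a diagnostic NaN result, never a silent zero, and
records with s_m = 0 are excluded from the maintenance and mirroring
rankings with a warning.

## Problem sizes and numerical choices

Replicator integration uses adaptive RK45 with absolute tolerance 1e-10
and state clipping to [0,1]; σ-constancy is tested by polynomial-identity
checks (tolerance 1e-9) rather than grid scans where possible; root finds
use Brent's method at xtol 1e-14. Test ensembles use N ∈ [200, 1000] with
50 replicates × 4000 generations for protocol-level checks and smaller
grids (N = 500, 10 replicates) for layout checks; the stationary chain is
solved densely up to N = 1000. The parameter-recovery study uses 500
synthetic assays (5 fractions × 6 replicates). These sizes keep the full
suite under a minute while leaving Monte-Carlo error well below every
tolerance asserted.

## Known limitations

- Strictly two types; no n-strategy games, no demographic change in N, no
  asymmetric mutation.
- Payoffs are linear in frequency; systems with documented nonlinear
  frequency dependence are fit under the linear assumption and flagged via
  the quadratic diagnostic only.
- The stationary law is computed numerically from the finite-N chain; no
  closed-form diffusion-limit density is provided, and higher moments
  (variance, skew) of the stationary law are not used as regime
  signatures.
- Distance rankings depend on the chosen μ and on the first-order vs exact
  surface choice; both knobs are exposed.
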