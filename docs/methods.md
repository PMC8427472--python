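# Methods

## The problem being modelled

Alchemical relative free energy calculations transform one ligand into
another along a coupling parameter λ ∈ [0, 1], once bound to the protein
and once free in solvent; the relative binding free energy is
ΔΔG = ΔG_complex − ΔG_solvent. Production protocols of this kind run 13 λ
windows per transformation, stagger the electrostatic coupling (charges of
disappearing atoms scaled off linearly over λ ∈ [0, 0.55], charges of
appearing atoms on over [0.45, 1], so charges vanish before atoms do and
appear after they exist), and run an ensemble of five replicas per window
with identical coordinates and randomized velocities. `alchemble`
reimplements the *analysis* layer of this workflow — estimation,
uncertainty quantification and benchmark statistics — against synthetic
data whose true answers are known in closed form. It does not simulate
molecules: force fields, soft-core van der Waals potentials, topology
mapping and MD engines are out of scope by design.

## Synthetic data models

**Harmonic alchemy (exact oracle).** U_λ(x) = ½ k_λ x² with
k_λ = (1−λ)k₀ + λk₁. Positions are drawn from the exact Boltzmann
distribution N(0, kT/k_λ) per window, so ∂U/∂λ = ½(k₁−k₀)x² and the true
free energy change is ΔG = (kT/2)·ln(k₁/k₀). Cross-evaluating every sample
under every window's potential yields an exact u_kn matrix for MBAR. This
system exercises both estimators end-to-end with zero model error: any
discrepancy beyond sampling noise is an implementation defect. An optional
`sigma_replica` adds a per-replica bias c_r ~ N(0, σ) linearly in λ, which
shifts replica r's dU/dλ by c_r and its exact ΔG by exactly c_r — a clean
way to inject replica-level systematic variability (differing effective
potentials between runs) while keeping every replica's ground truth
analytic. MBAR's asymptotic error is blind to such between-replica
variability by construction, which is precisely the phenomenon the
replica-range reports quantify.

**Gaussian dU/dλ model.** Each series is profile(λ) + c_r + AR(1) noise,
where profile is a user-chosen polynomial (truth = its exact integral over
[0, 1], so independent quadrature can verify it to 1e-10), c_r ~ N(0,
σ_replica) is a constant per-replica offset, and the AR(1) noise has
marginal SD σ_within and lag-1 correlation ρ (stationary initialization,
so the marginal SD holds from the first sample). The offset-plus-AR(1)
structure is the simplest model reproducing the two empirical features of
ensemble MD output that matter for the statistics: autocorrelated
within-run noise and run-to-run spread that no amount of within-run
sampling removes. It is a modelling choice, not a claim about MD dynamics.

**Benchmark pair sets.** ΔΔG_exp ~ Uniform(−5, 5) kcal/mol (spanning all
three analysis bins, as typical kinase/bromodomain benchmark sets do);
ΔΔG_cal = b·ΔΔG_exp + N(0, σ_noise). The multiplicative shrinkage b < 1
emulates the systematic underestimation of large experimental differences
observed with REST-based protocols. Experimental uncertainties default to
0.41 kcal/mol (0.3 log units of activity at 298.15 K), the convention for
affinity data reported without errors. Per-replica values are jittered
about ΔΔG_cal from an independent random stream, so ΔΔG_cal — and hence
every evaluation metric — is invariant to the replica count.

**Randomness.** One root seed; every (replica, window) series, every
replica offset and every pair draws from
`SeedSequence(seed, spawn_key=...)` children. Changing the number of
replicas, windows or pairs therefore never reshuffles earlier draws, and
equal seeds give byte-identical datasets.

## Estimators

**TI.** Window means use the autocorrelation-corrected SEM: statistical
inefficiency g = 1 + 2Σ ρ̂(t), with the autocovariance summed until its
first non-positive value (initial-positive-sequence truncation — standard,
and testable against the AR(1) closed form g = (1+ρ)/(1−ρ)); SEM =
sd·√(g/n), n_eff = n/g. The integral uses composite trapezoid weights
(w₀ = Δλ/2, interior wᵢ = Δλ, for an even grid), with error
√(Σ wᵢ² semᵢ²) under the independent-windows assumption — the quadrature
treated as a stochastic integral. A natural-cubic-spline quadrature is
available behind a flag for sensitivity checks (its weights are obtained
by integrating the cardinal spline basis); for the smooth harmonic
integrand it reduces discretization bias, but trapezoid is the default
because the published protocol names TI without specifying a quadrature
and trapezoid makes the weight algebra transparent.

**MBAR.** The self-consistent equations
f_k = −ln Σ_n exp(−u_kn)/Σ_l N_l exp(f_l − u_ln) are solved anchored at
f_0 = 0: up to 100 self-consistent sweeps as warm start, then damped
Newton on the convex MBAR objective (step halved until the objective does
not increase, with a self-consistent fallback sweep if Newton stalls).
All log-domain, via log-sum-exp. Convergence is max |Δf| < 1e-10 within
10⁴ iterations; non-convergence raises, never passes silently. Errors come
from the standard asymptotic covariance Θ, evaluated via the thin SVD of
the N×K weight matrix (Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ) so no N×N matrix is
formed; the error of f_k − f_0 is √(Θ_kk + Θ_00 − 2Θ_k0), scaled by kT.

**Ensemble combination.** Replica estimates are combined as mean,
between-replica sample SD (n−1), and SEM = SD/√n. Within-replica errors
(TI stochastic-integral, MBAR asymptotic) and the between-replica SD are
deliberately never merged into one number: both are exposed, since which
one is the honest precision statement is exactly the question
ensemble-based protocols exist to answer. ΔΔG from two legs subtracts
values, adds errors in quadrature, and pairs per-replica values by index
when both legs carry equal replica counts (the protocol runs equal
counts); on a mismatch it warns and falls back to unpaired propagation.

## Toy λ-REST sampler

Replicas on a ladder of (λ, scale) rungs sample 1-D reduced potentials
u(x) = scale·[(1−λ)·u_A(x) + λ·u_B(x)] + u_env(x), with u_A a quartic
double well, u_B a harmonic well and u_env an optional unscaled harmonic
term. The REST2-style convention — the effective-temperature scale
multiplies only the solute term — is adopted because the concept is cited
in the protocol literature without a restated formula. Moves are Gaussian
random-walk Metropolis; neighbour swaps use min(1, e^(−Δ)) with
Δ = [u_i(x_j) + u_j(x_i)] − [u_i(x_i) + u_j(x_j)], in alternating
odd/even pair sweeps every `exchange_interval` steps.

The sampling-enhancement demonstration uses a 14 kT barrier, well
separation 4, fixed step 0.35 and 10⁵ steps: calibrated once by brute
force so that an un-exchanged replica essentially never crosses (right-well
occupancy < 0.01) while a 6-rung geometric ladder (scale 1 → 0.1)
equilibrates the base replica (~0.5). With good step sizes a Metropolis
walker crosses an 8 kT barrier at rate ~e⁻⁸ per step, i.e. dozens of times
in 10⁵ steps, so a taller barrier is required for a meaningful contrast at
this run length. Step-size auto-tuning (targeting 30–50% acceptance) is
the default when no step size is given; the demonstration fixes the step
because tuning's larger steps shortcut the barrier geometrically.

Detailed balance is verified on a discrete 3-site double well with two
replicas, where each step uniformly picks move-replica-1 /
move-replica-2 / exchange; every move type is Metropolis with respect to
the product of scaled Boltzmann distributions, so that product is the
exact stationary distribution, and the composite chain's transition
matrix (9 states) can be enumerated and its stationary eigenvector
compared with the empirical occupancy (TV distance < 1% at 10⁶ steps).

## Evaluation statistics

Pairs are rearranged so ΔΔG_exp ≥ 0 before MSE and the binned analysis
(MUE/RMSE are invariant); pairs with ΔΔG_exp exactly 0 are not flipped,
making rearrangement an involution. Underestimation is strict
(ΔΔG_cal < ΔΔG_exp); ties count as not underestimated. Bin edges default
to the printed constants 1.37 and 2.73 kcal/mol rather than recomputing
RT·ln10 multiples at run time, so outputs match the published table
convention exactly (1 log unit at 298.15 K is 1.364; the separate
conversion function returns the exact value). Empty bins report NaN, not
0 — absence of pairs is not evidence of zero bias. Regression is
unweighted OLS of ΔΔG_cal on ΔΔG_exp (no weighting convention is published
for this statistic); bootstrap SDs resample pairs with replacement, 1000
draws by default, seeded. Bootstrap is reported as the SD estimator for
all metrics and labelled as such.

## Problem sizes and numerical choices

The test suite and the acceptance script run the harmonic system at 13
windows × 5 replicas × 5000 samples (estimator recovery), 200-pair
benchmark sets over 50 seeds (bias recovery and bin trends), 25-seed
averages at 5/20/80 replicas (SEM scaling — a single 5-replica SD estimate
has ~35% relative sampling error, so the 1/√n law is checked on
seed-averaged SEMs), and 10⁶ discrete REST steps (detailed balance).
These sizes keep every check comfortably inside a laptop-minute while
leaving the statistical tolerances (3σ, 20%, 1% TV) meaningful.

Degenerate inputs: constant series have g = 1 and SEM 0; ensemble
combination of a single replica reports SD 0; MBAR refuses states with
zero samples (they are not sampled states; reweighting to unsampled
states is not implemented); schedules must start at 0, end at 1, and be
strictly increasing.

## What passing tests do and do not show

The generators reproduce the *statistical* structure the analysis layer
assumes — known truths, autocorrelation, replica-level spread, shrinkage
bias — but none of the physics that makes real alchemical data hard:
anharmonic potentials, soft-core endpoint behaviour, slow conformational
degrees of freedom, force-field error. Green tests certify the estimators
and statistics are implemented correctly and calibrated on data satisfying
their assumptions; they say nothing about the accuracy of any particular
MD protocol on proteins. Published benchmark tables from proprietary-engine
MD are correspondingly not reproduction targets here.
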