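# alchemble

Ensemble-based analysis of alchemical relative binding free energy
calculations, at desk scale.

Relative binding free energies (ΔΔG) between ligand pairs are routinely
computed by alchemically transforming one ligand into another along a
coupling parameter λ, in both the protein complex and in solvent, and
subtracting the two legs. Because molecular dynamics trajectories are
chaotic, a single simulation's error bar badly understates run-to-run
variability; robust protocols run an *ensemble* of replicas (identical
start, randomized velocities) and report the between-replica spread.
`alchemble` implements the statistical machinery of that workflow on
synthetic data with analytically known answers:

- **Synthetic generators** — a harmonic "alchemy" (U_λ(x) = ½[(1−λ)k₀ + λk₁]x²,
  exact ΔG = (kT/2)·ln(k₁/k₀)) serving as an exact oracle for estimators; an
  AR(1) dU/dλ model with per-replica offsets emulating ensemble structure;
  and ligand-pair benchmark sets with a controllable multiplicative
  shrinkage bias. Includes the staggered electrostatic decoupling schedule
  (charges off over λ ∈ [0, 0.55], on over [0.45, 1]) and a 13-window
  default λ grid.
- **Estimators** — thermodynamic integration, ΔG = ∫₀¹ ⟨∂U/∂λ⟩ dλ, with the
  quadrature treated as a stochastic integral (autocorrelation-corrected
  window SEMs propagated through trapezoid weights), and a from-scratch
  MBAR solver (self-consistent iteration + damped Newton, log-sum-exp,
  asymptotic covariance errors). Replica-level combination reports mean,
  between-replica SD and SEM.
- **Toy λ-REST** — a minimal replica-exchange-with-solute-tempering sampler
  on 1-D potentials (Metropolis moves, alternating neighbour swaps with
  p = min(1, e^(−Δ))), including a discrete variant whose stationary
  distribution is exactly enumerable.
- **Evaluation** — the benchmark statistics suite: sign rearrangement so
  ΔΔG_exp ≥ 0, MUE/MSE/RMSE, OLS regression (ΔΔG_cal = α·ΔΔG_exp + β) with
  Pearson r, pair-resampling bootstrap SDs, binned underestimation analysis
  (bin edges 1.37 and 2.73 kcal/mol, the 1- and 2-log-unit activity
  boundaries), and log-unit ↔ kcal/mol conversion.

## Worked example

```python
import alchemble as al

spec = al.HarmonicAlchemySpec(k0=1.0, k1=4.0, temperature=300.0,
                              n_samples_per_window=5000, n_replicas=5, seed=1)
ens, _ = al.sample_harmonic_alchemy(spec)           # 13 windows x 5 replicas
ti = al.ti_ensemble(ens)
mbar = al.mbar_ensemble(al.harmonic_replica_potentials(spec))
print(f"exact {spec.truth:.4f}  TI {ti.value:.4f}+/-{ti.error:.4f}  "
      f"MBAR {mbar.value:.4f}+/-{mbar.error:.4f}")
```

prints

```
exact 0.4132  TI 0.4133+/-0.0012  MBAR 0.4125+/-0.0012
```

— both estimators recover the analytic free energy (kT/2)·ln 4 at 300 K
within their ensemble SEMs. Benchmark statistics on a biased pair set:

```python
recs = al.build_pair_dataset(200, bias_factor=0.7, noise_sd=0.3, seed=1)
report = al.evaluate(recs, n_boot=1000, seed=1)
print(report.format_bin_table())
```

```
|ddG_exp| bin             n   %under   meandev
[0, 1.37)                58     70.7     -0.22
[1.37, 2.73)             58     94.8     -0.58
[2.73, inf)              84    100.0     -1.20
total                   200     90.0     -0.74
```

The shrinkage bias (slope 0.7) produces underestimation that grows with the
size of the experimental difference — the signature the binned analysis is
designed to expose.

A CLI mirrors the library: `alchemble generate | estimate | evaluate |
rest-demo | pipeline` (see `alchemble --help`).

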