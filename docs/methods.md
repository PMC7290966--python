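# Methods

## Model and conventions

One binary spin per brain region, coupled through the subject's
structural connectome, in the absence of an external field:

```
E(s) = − Σ_{i,j} J_ij s_i s_j,   s_i ∈ {+1, −1},   k_B = 1.
```

The double sum runs over the **full index range**, so each unordered
pair contributes twice and the energy change of a single flip is
`ΔE_k = 4 s_k Σ_j J_kj s_j`. This convention doubles all temperatures
relative to the pair-counted-once convention; every temperature this
package reports (Tc, T*, grids) is in double-sum units. For
orientation, the exact critical point of the infinite 2-D
nearest-neighbour lattice at J = 1 is `2·2/ln(1+√2) ≈ 4.539` in these
units (2.269 in pair-counted-once units).

**Connectome normalization.** Raw streamline-count matrices are
symmetrized, the diagonal is zeroed, and the matrix is divided by its
maximum entry (max J = 1). This puts every subject on a comparable
temperature scale and anchors the connectome-distance map (below). A
sum-preserving alternative was considered and is easy to construct from
the raw matrix; see Limitations for how this choice interacts with
lesion effects on Tc.

**Dynamics.** Metropolis single-spin-flip: one sweep proposes N flips at
uniformly random sites (with replacement), each accepted with
probability `min(1, exp(−ΔE/T))`. Simulations start from a uniform
random configuration, discard `n_equil_sweeps` sweeps, then record
`n_samples` configurations every `sample_interval_sweeps` sweeps.
Defaults (1000 / 1000 / 2) are declared package defaults chosen so an
84-region sweep runs in seconds; the underlying study reports no
equilibration or sampling settings. The kernel stores couplings in CSR
form and maintains the local field `h_i = Σ_j J_ij s_j`, so proposals
cost O(1) and accepted flips O(degree); it is numba-compiled and
bit-reproducible given a seed.

**Seeding.** One master seed per analysis; every stochastic stage
((subject, temperature, run), scans, lesions) derives a 31-bit sub-seed
by SHA-256 hashing the master seed with a token tuple naming the stage.
Identical inputs give bit-identical outputs, and any single stage can be
re-derived in isolation.

## Susceptibility and Tc

`χ = N (⟨m²⟩ − ⟨|m|⟩²)/T` from the sampled magnetization
`m = (1/N) Σ_i s_i`. The |m| convention suppresses the spurious
variance that global ±m tunnelling adds in finite systems below the
transition; the raw-⟨m⟩ estimator is available
(`susceptibility(trace, use_abs=False)`). The temperature grid is
linear from 0.1·T̂ to 3·T̂ with T̂ = mean_i Σ_j 2·J_ij (the mean-field
transition estimate in double-sum units). Each grid point is simulated
`n_runs` times (default 10) from fresh random starts; Tc is the grid
point maximizing the run-averaged χ after an optional centred
moving-average smoothing (window 3 in the pipeline; truncated at the
grid edges; ties break toward the lowest temperature). Locating the
peak per run and averaging the per-run peaks is exposed
(`find_critical_temperature(..., per_run=True)`) but the averaged-curve
peak is the default, matching the repeat-and-average protocol.

**Quench artifact.** At temperatures far below Tc, random starts on
*sparse* graphs (lattices) freeze into metastable domain states whose
slow wall wandering inflates the χ estimate; on a 16×16 lattice this
produces a spurious χ bump near T ≈ 1.4 that can exceed the true
critical peak. Equilibrating through it is impractical (stripe states
relax on ~10⁵-sweep timescales), so lattice oracle checks scan a window
around the transition (3.0–6.5) rather than the full default grid.
Dense 84-region connectomes equilibrate mean-field-like and do not show
the artifact at default settings.

## Functional connectivity and T*

Empirical FC is the Pearson correlation matrix of the region-averaged
BOLD time series (used as-is; the up/down-spin thresholding picture is
interpretive, not a processing step). Simulated FC is the Pearson
correlation matrix of the sampled spin series, averaged entrywise over
the runs at one temperature *before* comparison (average-then-Mantel,
not Mantel-then-average). Zero-variance regions (e.g. frozen spins at
low T) are flagged and their correlations set to 0, never NaN.

The Mantel statistic is the Pearson correlation of the
strictly-upper-triangle vectors; the permutation null applies a shared
random node relabelling to both axes of the second matrix; the
one-tailed (greater) p is `(#{r_perm ≥ r_obs} + 1)/(n_perm + 1)` with
10,000 permutations by default. T* is the grid temperature maximizing
the Mantel r of simulated vs empirical FC (ties to the lowest
temperature); with two scans, both are fitted and the scan with the
higher best r is selected (ties to t1). The direct SC–FC correlation —
Pearson between upper triangles of J and empirical FC — is reported as
the no-model baseline. In the pipeline, the sweep's retained spin
traces provide the simulated FCs for every grid temperature, so Tc and
the Mantel curve come from the same simulations.

## Connectome-distance dimensionality

Distance is defined from connection strength, not anatomy: with max-one
normalized couplings, `d_ij = 1/J_ij` on connected pairs (strongest
pair at distance 1); unconnected pairs are excluded and counted. A
`−log` variant (`1 − log J`) is available for sensitivity analyses.
Functional correlation is averaged in 12 log-spaced distance bins
(geometric bin centres; bins with fewer than 3 pairs dropped), and
ordinary least squares of log mean correlation on log distance over the
bins with positive mean correlation gives the decay exponent
γ = −slope. Dimensionality is `D = γ + 2 − η` with η = 0 by default
(γ is always reported alongside so any η convention can be applied post
hoc); a constant curve therefore has D = 2 and faster decay a higher D.
γ is invariant to rescaling all distances. The default FC source is the
run-averaged simulated FC at the Tc grid point; simulated-at-T* and
empirical sources are available and every estimate records its source.

## Group statistics

Welch two-sample t (Satterthwaite df), paired t (one-sample t on
differences), one-way ANOVA, all two-tailed, via scipy; FDR is
Benjamini–Hochberg via statsmodels. The post-hoc family after ANOVA is
declared as the three patient-group-vs-control contrasts, BH-adjusted
within that family. The paired scan comparison uses subjects with both
scans (listwise deletion). Degenerate inputs (zero variance where the
test is undefined) raise rather than returning arbitrary numbers; the
cohort pipeline records these as warnings and continues.

## Synthetic cohorts

The generator emulates the study's *shape* with known ground truth:

* **Geometric connectomes** — N = 84 regions uniform in the unit
  3-cube; raw weight `(10⁻³ + ‖x_i − x_j‖)^(−α)` with α = 2, scaled to
  a maximum expected count of 10⁴ and Poisson-rounded to integer
  pseudo-streamline counts. This yields symmetric integer matrices
  spanning ~4 decades with 85–99% edge density, the gross shape of
  Desikan–Killiany streamline matrices. α = 2 keeps the weight tail
  moderate; steeper decay concentrates the count mass on a handful of
  near pairs and makes Poisson thinning unrealistically sparse.
* **Lesions** — each edge deleted independently with a group-specific
  probability (0 / 0.15 / 0.30 / 0.45 for HC / MCS+ / MCS− / VS-UWS),
  survivors attenuated ×0.8, result renormalized to max-one. Diffuse
  random damage only; no focal lesions.
* **Scans** — two per subject (t1/t2, 480 time points by default): spin
  dynamics at the subject's mean-field temperature estimate T̂ (near
  criticality, where correlation structure is richest) plus i.i.d.
  Gaussian sensor noise (σ = 0.2).
* A JSON sidecar records every parameter and sub-seed, sufficient to
  re-derive the cohort byte-identically.

What this does **not** emulate: hemodynamics (no BOLD convolution),
spatially structured or focal damage, tractography biases
(length/curvature-dependent undercounting), inter-subject anatomical
variability beyond point-placement randomness, and scanner drift.
Passing pipeline tests on these cohorts therefore demonstrates
*methodological* correctness (estimators recover known ground truth;
directions that follow from the damage model appear), not clinical
validity on real MRI.

## Problem sizes in tests and the acceptance script

Oracle checks run at full fidelity (exact enumeration at N ≤ 5; 16×16
lattice with 5×1500 samples per temperature; 10,000 Mantel
permutations). Cohort-level checks use the study-shaped 38-subject
cohort with reduced Monte Carlo settings (12 temperatures, 3 runs,
400 + 800 sweeps, 200 time points per scan) — the package's standard
desk-scale profile; all settings scale up through `AnalysisConfig`.

## Numerical choices

* Asymmetry up to a tolerance is averaged, beyond it is an error;
  matrices are validated (symmetric, non-negative, zero diagonal) at
  construction.
* Constant (zero-variance) data: correlation 0 + degenerate flag at the
  FC layer; r = 0, p = 1 + flag in the Mantel test; errors in the
  t-tests/ANOVA where the statistic is undefined.
* Peak/argmax ties always break toward the lowest temperature; scan
  ties toward t1.
* Result tables are TSV with sorted columns and 17-significant-digit
  floats; read-back is exact.

## Limitations and negative findings

* **Random dilution does not raise Tc in this model family.** Across
  α ∈ {1.5, 2, 2.5, 3}, embedding dimensions 2 and 3, and both max-one
  and sum-preserving normalization, deleting 40% of edges leaves the
  detected susceptibility-peak temperature flat or *lower* on average
  (mean-field anchors and leading eigenvalues of 2J agree). Randomly
  deleting edges removes ~40% of the coupling mass, and the occasional
  renormalization boost (when the maximal edge is deleted) does not
  compensate on average. The familiar observation that sparser networks
  sit at higher critical temperatures arises when comparing differently
  *constructed* networks under max-one normalization — e.g. a sparse
  near-binary lattice (Tc ≈ 4.9) against a dense heavy-tailed
  connectome (Tc ≈ 0.9), which this package reproduces — not from
  random dilution of a fixed connectome. Cohort-level mean Tc of
  lesioned groups is therefore *not* reliably above controls in the
  synthetic cohorts, and the acceptance checks asserting that direction
  fail; they are kept as stated rather than weakened.
* **Dimensionality does rise with lesioning** (mean D of lesioned
  connectomes exceeds intact across seeds): deleting structural paths
  makes functional correlation fall off faster with connectome
  distance. But recovered D does **not** track the *embedding*
  dimension of the generator monotonically at realistic decay
  exponents: at α ≥ 2, 2-D-embedded connectomes yield slightly larger
  mean D than 3-D ones, because the connectome-distance decay exponent
  conflates geometry with weight heterogeneity. The acceptance check
  asserting the 3-D > 2-D ordering fails at the package defaults and is
  kept as stated.
* The exact functional form of the distance map, the binning, and the
  γ → D relation are declared package conventions (the reciprocal map
  is the simplest strictly decreasing choice and is isolated behind one
  configurable operation); η is exposed but defaults to 0.
* Tc and T* are grid-quantized; refine the grid for finer comparisons.
* The Mantel permutation count and tail, and the equilibration/sampling
  lengths, are declared defaults, not reconstructions of the original
  analysis.
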