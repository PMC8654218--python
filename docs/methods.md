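# Methods

## Scope and model

fepcycles analyses alchemical free-energy-perturbation (FEP) output for
two-state receptors — G protein-coupled receptors with an inactive (R)
and an active (R\*) conformation — under the end-state assumption: each
FEP leg is simulated within one fixed receptor conformation, and
experimentally meaningful quantities arise as differences between legs
simulated in R\* and in R. The package does not model the activation
pathway or intermediate conformations; it treats R and R\* as the two
fixed end states of a thermodynamic cycle.

Three cycles are implemented:

1. **Conformational selectivity** of a ligand pair L1→L2:
   ΔΔG_cs = ΔG_b,R\* − ΔG_b,R, where ΔG_b,X is the free energy of the
   alchemical L1→L2 transformation bound to conformation X.
2. **Basal-activity shift** of a point mutation: ΔΔG_R\*→R =
   ΔG_m,R\* − ΔG_m,R, from the side-chain perturbation simulated in the
   apo receptor in each conformation.
3. **Efficacy shift** (combined cycle): ΔΔG_EC50 = ΔG_m,R\*+L − ΔG_m,R,
   decomposable through the shared apo-R\* leg into a basal term
   (ΔG_m,R\* − ΔG_m,R) and a ligand-affinity term
   (ΔG_m,R\*+L − ΔG_m,R\*).

### Sign conventions (authoritative)

| quantity | definition | positive means |
|---|---|---|
| selectivity | ΔG_b,R\* − ΔG_b,R | FEP start species (agonist) prefers R\* |
| basal shift | ΔG_m,R\* − ΔG_m,R | mutation destabilizes R\* (CIM, lower basal activity) |
| efficacy shift | ΔG_m,R\*+L − ΔG_m,R | efficacy/potency loss upon mutation |

The literature is not consistent about the subscript direction of the
basal-shift label (R→R\* vs R\*→R appear with the same positive value
for a constitutively inactive mutation); fepcycles therefore pins its
own orientation, above, and the toy CIM scenario verifies that a
mutation which destabilizes the active basin comes out positive.

## Free-energy estimation

### BAR

For each adjacent λ pair the Bennett acceptance ratio solves

  ⟨f(+β(ΔU − C))⟩_i = ⟨f(−β(ΔU − C))⟩_j,  f(x) = 1/(1+e^x),

where ΔU = U_j − U_i (j always the higher-λ window) is averaged over
both bracketing ensembles, and ΔG = C at the fixed point. No
ln(n_j/n_i) offset is applied (sample counts are equal per window in
all data the package generates). The constant is found as the root of
the monotone function g(C) = ln⟨f_i⟩ − ln⟨f_j⟩ with Brent's method:

- initial bracket `[min(mean_i, mean_j) − 10σ, max + 10σ]` with σ the
  pooled ΔU standard deviation, doubled up to 8 times if needed;
- absolute tolerance 10⁻⁸ kcal/mol, at most 200 iterations;
- Fermi logarithms evaluated as −logaddexp(0, x) plus log-sum-exp, so
  arbitrarily large |ΔU| cannot overflow;
- β = 1/RT with R = 1.9872×10⁻³ kcal/(mol·K); default T = 298 K, the
  simulation temperature of the data the format was designed for.

Degenerate input where both ensembles are constant at the same value
short-circuits to that constant (the fixed point is exact and the root
finder would see a flat function). If the two ΔU ensembles are
disjoint, g develops a plateau on which every C "solves" the
self-consistency with both Fermi averages numerically equal to 1; such
roots carry no information, so the estimator refuses them with a
non-convergence error carrying both ensemble means. This, rather than
histogram overlap, is the refusal criterion, because finite-sample
histogram overlap can be zero for pairs BAR still handles.

Rationale for root-finding over plain fixed-point iteration: g is
strictly monotone in C, so a bracketed root is unique and Brent
converges deterministically; fixed-point iteration can stall when
overlap is poor.

### Replicates

Legs are estimated per replica (sum of window-pair ΔG along the
schedule), then summarized as mean ± SEM over replicas, with SEM the
sample standard deviation divided by √n. This matches the practice of
reporting SEM over independent replica simulations, which requires
per-replica estimates rather than pooled samples. SEM over a single
replica is reported as undefined (`None`), not zero. The analytic
(delta-method) BAR variance per window pair is available as a
diagnostic (`bar_pair_standard_error`) but never enters reported leg
or cycle uncertainties — replicate scatter is the only uncertainty the
package reports, because it also captures conformational-sampling
variance that the per-window analytic formula cannot see.

### Uncertainty propagation in cycles

Cycle SEMs combine component SEMs in quadrature, treating legs as
independent — they come from independent sets of simulations. When the
efficacy-shift decomposition is requested, ΔΔG is computed as
basal + affinity (the shared leg cancels analytically), which keeps
the decomposition additive bit-for-bit; the direct two-leg difference
can disagree by one ulp. `cycle_closure` uses compensated summation
(`math.fsum`) so exactly telescoping cycles return exactly zero.

### Diagnostics

One-sided exponential (Zwanzig) averages in both directions and a
histogram Bhattacharyya overlap coefficient (shared bin edges, bin
count ⌈√min(n_i, n_j)⌉ with floor 10) are provided per window pair.
They are diagnostics only; all reported free energies come from BAR.

## The toy receptor model

The synthetic-data generator is a one-dimensional two-basin
Hamiltonian:

  U(x) = barrier·((x/a)² − 1)² + b·(x/a) + Σ_s [k_s (x − x_s)²/2 + c_s]

with half-width a (minima near ±a), tilt b (positive b lowers the
active x<0 basin; a constitutively inactive mutation is a negative
change in b), and harmonic ligand couplings. Mutations act as additive
changes to (barrier, b). A reflecting wall at x = 0 (proposal
rejection outside the domain) implements "simulate within one
conformation", mirroring the end-state assumption; the finite domain
extends 6a on each side of the wall, wide enough that the Boltzmann
weight at the edge is negligible for all parameter sets used.

A one-dimensional model was chosen over a particle system because its
partition function is computable by adaptive quadrature to ~10⁻⁹
relative accuracy in milliseconds, giving every sampled leg an exact
oracle, while preserving everything the cycle layer needs: two basins,
conformation-selective ligand coupling, and basin-selective mutations.

**What it emulates:** per-window overlapping forward/reverse ΔU
distributions with a known total ΔG, replica structure, linear
(50-window, ligand-style) and staged (4×20, side-chain-annihilation
style) λ schedules, and acceptance-rate pathologies when windows are
too far apart. **What it does not emulate:** atomistic realism,
soft-core potentials, dual-topology bookkeeping, correlated slow
degrees of freedom, or equilibration artefacts. Tests passing on this
model validate the estimator and cycle algebra, not the accuracy of
any molecular force field or sampling protocol on real receptors.

### Sampling

Per λ window (U_λ = (1−λ)U_start + λU_end) an independent Metropolis
chain with Gaussian proposals of width 0.3a runs 10·n burn-in steps
followed by n recorded samples at stride 5; chains start at the window
Hamiltonian's minimum. ΔU to the adjacent higher-λ window is recorded
from both bracketing ensembles. For linear coupling this is
(λ_{k+1} − λ_k)(U_end − U_start), so a pure constant offset between
end states telescopes to the offset exactly. Windows with post-burn-in
acceptance outside [0.05, 0.95] are flagged in leg metadata rather
than rejected. Replica r draws from stream `seed XOR r`; note that
nearby master seeds therefore share replica streams (two runs whose
seed blocks overlap reuse chains) — scripts that need independent
repetitions space their seeds by more than the replica count.

Staged schedules map stage s of S, local λ ∈ [0,1], onto the global
path as (s + λ)/S with shared boundaries deduplicated. For this
model's linear coupling the staged path is the same state function as
the linear one, so staged and linear estimates must agree — a
path-independence check the tests exercise.

### Scripted CIM scenario

`cim_scenario()` freezes one wild-type receptor (barrier 4 kcal/mol,
a = 1, b = 0, T = 298 K), one mutation (Δb = −3: stabilizes the
inactive basin, the CIM signature) and two agonist-like ligands
(k = 8, x₀ = −1.2 "deep" and x₀ = −0.4 "shallow"). By construction —
verified against quadrature, not tuned — the basal shift is positive
(≈ +5.7 kcal/mol), the deep binder loses affinity upon mutation
(amplification: net shift above the basal term) and the shallow binder
gains it (compensation: net shift below), reproducing the
compensation-vs-amplification pattern that makes the efficacy-shift
decomposition informative.

## Pharmacology

EC50 shifts map to the energy scale as RT·ln(EC50_mut/EC50_wt),
computed as a difference of logarithms so antisymmetry under swapping
the arguments is exact. The orientation (potency gain = negative)
matches the efficacy-shift cycle's sign convention; published
formulas sometimes print the inverted ratio while reporting values
consistent with this orientation, so the convention is fixed here
explicitly. The conversion defaults to T = 298.15 K (RT = 0.59248
kcal/mol), the standard condition of the functional assays being
converted; simulation-side defaults stay at 298 K.

Δ-efficacy is E_max,ago − E_max,antago (% of the assay's reference
full agonist) with SEM in quadrature. Profile classification:
neutral antagonist when |E_max| ≤ z·SEM (z = 2 by default, the usual
"not significantly different from 0%" criterion), full agonist at
E_max ≥ 80% (configurable; only the neutral-antagonist rule is a fixed
definition). Concordance between a calculated ΔΔG and an experimental
Δ-efficacy is the package's own operational rule: sign agreement with
a significance gate (|ΔΔG| > z·SEM), with double-null agreement
counted as concordant; both choices are parameters.

Packaged E_max values lacking a printed SEM are stored with SEM 0.

## Numerical choices and problem sizes

- Quadrature: `scipy.integrate.quad`, domain as above, relative
  tolerance 10⁻¹⁰, with the integrand exponent shifted by the grid
  minimum of U to avoid underflow.
- Validation problem sizes: the BAR calibration uses 200 Gaussian
  fixtures of 10³ samples/side; oracle-equivalence legs use 2000
  samples/window × 10 replicas (50 linear or 4×20 staged windows);
  sampled cycle closure uses 10⁴ samples/window on a 10-window
  triangle × 4 replicas; the CIM scenario uses 400 samples/window ×
  10 replicas. These sizes put Monte Carlo error well below the
  effects being checked while keeping the whole validation suite in
  the minutes range on one CPU.
- Equilibrium sampler validation: pooled histogram over 200 chains ×
  500 samples against the quadrature Boltzmann density,
  total-variation distance < 0.05.

## Known limitations

- BAR per pair, no multi-state estimator across all windows (MBAR),
  and no autocorrelation or equilibration analysis: samples are
  treated as given. Stride-5 recording in the toy sampler leaves mild
  correlation that replicate SEM absorbs.
- The deposited-raw-data converter is mapping-driven by design: the
  layout of any given archive must be described by the user; the
  package validates and logs provenance but cannot guess layouts.
- One-dimensional synthetic data cannot probe errors specific to
  high-dimensional sampling (slow orthogonal degrees of freedom,
  soft-core singularities).
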