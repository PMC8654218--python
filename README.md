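# fepcycles

Free-energy cycles for receptor conformational selectivity: Bennett
acceptance ratio (BAR) estimation over alchemical λ-window data, and
thermodynamic-cycle composition linking ligand and mutation
perturbations in active (R\*) vs inactive (R) receptor states to
pharmacologically meaningful quantities.

## Who this is for

Computational chemists and structural pharmacologists who run
free-energy perturbation (FEP) on two-state receptors — typically G
protein-coupled receptors — and want to turn per-window energy
differences into:

- **conformational selectivity** of a ligand pair,
  ΔΔG_cs = ΔG_b,R\* − ΔG_b,R (positive: the agonist prefers the active
  state);
- **basal-activity shift** of a point mutation,
  ΔΔG_R\*→R = ΔG_m,R\* − ΔG_m,R (positive: constitutively inactive
  mutation);
- **efficacy shift** of a mutation on a bound ligand,
  ΔΔG_EC50 = ΔG_m,R\*+L − ΔG_m,R, decomposed into basal and
  ligand-affinity terms (negative: predicted potency gain), comparable
  to the experimental RT·ln(EC50_mut/EC50_wt);

with replicate-based uncertainties, strict annotation checking, and
qualitative comparison against E_max/EC50 pharmacology.

The estimator core is BAR: for each adjacent λ pair, the constant C
solving ⟨f(+β(ΔU−C))⟩_i = ⟨f(−β(ΔU−C))⟩_j with f(x) = 1/(1+eˣ) gives
ΔG = C; legs are accumulated per replica and reported as mean ± SEM
over replicas.

A self-contained one-dimensional two-basin receptor model (quartic
double well, λ-coupled harmonic ligand terms, tilt-type mutations,
reflecting wall implementing the end-state assumption) generates
realistic synthetic FEP output and — because its partition function is
computable by quadrature — provides exact ground truth for the whole
pipeline.

## Worked example

Conformational selectivity of a toy agonist (binds the active basin)
against a conformation-neutral antagonist, from sampled legs in both
restrained receptor states:

```python
from fepcycles import (ToyModelSpec, LigandTerm, LambdaSchedule,
                       sample_leg, estimate_leg, exact_selectivity,
                       conformational_selectivity)

receptor = ToyModelSpec(barrier=4.0, half_width=1.0)
agonist = receptor.with_ligands([LigandTerm(k=8.0, x0=-1.0)])
antagonist = receptor.with_ligands([LigandTerm(k=8.0, x0=0.0)])

legs = {}
for state, restraint in [("Rstar", "active_basin"),
                         ("R", "inactive_basin")]:
    leg = sample_leg(agonist.restrained(restraint),
                     antagonist.restrained(restraint),
                     LambdaSchedule.linear(50),
                     n_samples=1000, n_replicas=10, seed=2024)
    leg.transformation = "agonist->antagonist"
    legs[state] = estimate_leg(leg)
    print(f"{state:5s}: dG = {legs[state].mean_dg:+.3f} ± "
          f"{legs[state].sem_dg:.3f} kcal/mol")

sel = conformational_selectivity(legs["Rstar"], legs["R"])
print(f"selectivity: {sel.ddg:+.3f} ± {sel.sem:.3f} kcal/mol "
      f"-> {sel.qualitative_call()}")
print(f"exact (quadrature): "
      f"{exact_selectivity(agonist, antagonist, receptor):+.3f} kcal/mol")
```

Output:

```
Rstar: dG = +2.665 ± 0.002 kcal/mol
R    : dG = -6.134 ± 0.002 kcal/mol
selectivity: +8.799 ± 0.003 kcal/mol -> agonist prefers active state
exact (quadrature): +8.799 kcal/mol
```

The two printed ΔG values are the alchemical agonist→antagonist
transformation in each receptor conformation (10 replicas, 50 linear λ
windows, BAR per window pair); their difference, +8.8 kcal/mol, says
the agonist strongly prefers the active state — and matches the exact
quadrature value of the model.

The same pipeline is scriptable from the shell
(`fepcycles simulate / estimate / cycle / pharm / report`); try the
bundled constitutively-inactive-mutation demo:

```sh
fepcycles cycle --demo cim --out demo/ --seed 3
fepcycles pharm --pair ADO:Cyp-Ade --out pharm.json
```

The demo writes leg estimates, cycle JSONs and a report table showing
a positive basal shift with amplification for a deep-binding agonist
and compensation for a shallow one; the `pharm` call reports the
45% Δ-efficacy gap between adenosine and its neutral-antagonist
analogue from the packaged table of published E_max values.

Interchange formats (leg TSV with `#`-header, estimate/cycle JSON with
explicit units, pharmacology CSV, run manifests) are documented in
`src/fepcycles/io.py`; `convert_deposited_energies` turns downloaded
raw FEP archives into leg TSVs via a user-written mapping config.

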