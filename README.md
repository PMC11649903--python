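# e2chase

Kinetic and geometric analysis of serine-selective ubiquitination by
J2-family E2 conjugating enzymes.

Some E2 enzymes (yeast Ubc6, human Ube2J2) attach ubiquitin not only to
lysine side chains (isopeptide bonds) but also to serine and threonine
hydroxyls (oxyester bonds), a reaction thought to proceed by general base
catalysis through a conserved active-site histidine.  Two kinds of
quantitative evidence support this picture, and this package implements the
machinery for both:

1. **Discharge kinetics.**  In a chase assay the ubiquitin-loaded thioester
   species E2~Ub (written E2_L) is generated by E1, then E1 is quenched with
   EDTA and the decay of E2_L is followed by gel densitometry or fluorescence
   anisotropy.  E2_L partitions between three competing pathways:

   ```
   E2_L + H2O -> E2 + Ub         hydrolysis            k1   (min^-1)
   E2_L + Nu  -> E2 + Ub-Nu      nucleophile attack    k2   (mM^-1 min^-1)
   E2_L       -> E2_Ub           autoubiquitination    k3   (min^-1)
   ```

   With [Nu] fixed, the loaded fraction decays as
   `[E2_L](t) = [E2_L]0 exp(-k_obs t)` with `k_obs = k1 + k2 [Nu] + k3`, and
   the autoubiquitinated species builds up to the branching plateau
   `k3 [E2_L]0 / k_obs`.  Because E2_Ub co-migrates with E2_L on non-reducing
   gels, the measurable band is their sum; pairs of time courses without and
   with nucleophile are fitted globally (shared E2L0, k1, k2, k3; [Nu] fixed
   per course) to separate the pathways.

2. **Conjugate geometry.**  For base catalysis the unprotonated histidine
   ring nitrogen must sit a few Angstroms off the thioester plane (through
   Cys Sγ and the ubiquitin Gly76 carbonyl C/O), oriented toward the
   carbonyl.  The package computes this signed plane offset, the
   His-orientation angle, hydrogen bonds, salt bridges, interaction
   frequencies, χ1/χ2 dihedrals, per-residue RMSF and grid-flood pocket
   volumes on multi-model PDB ensembles.

Auxiliary estimators cover the surrounding arithmetic: mono- and
double-exponential fits, linear rate-vs-concentration fits for E3 (RING)
titrations, a 4-parameter logistic pH dose-response, fold-change error
propagation, kinetic solvent isotope ratios, and the gel densitometry /
NaOH-partition bookkeeping that distinguishes oxyester from isopeptide
linkages.  A `synthetic` module generates every input format with known
ground truth.

## Worked example

```python
import numpy as np
from e2chase import KineticParams, fit_global_discharge, half_life_from_rate
from e2chase.synthetic import NoiseModel, gen_chase

truth = KineticParams(k1=0.015, k2=3.8e-4, k3=0.002)   # a slow conjugate
times = np.linspace(0, 120, 12)                        # minutes
design = gen_chase(truth, [0.0, 250.0], times, NoiseModel(sigma=0.02, seed=1))
res = fit_global_discharge(design)
print(res.summary())
print(f"hydrolysis half-life: {res.half_life():.1f} min")
```

prints

```
Global E2~Ub discharge fit
  courses: 2   points: 24   residual RMS: 0.01233   converged: True
  param      estimate       stderr         unit  note
  E2L0              1     0.008449            -
  k1          0.01519    0.0004385        1/min
  k2        0.0003912    1.446e-05   1/(mM*min)
  k3         0.002124    0.0003736        1/min
hydrolysis half-life: 45.6 min
```

The paired design (one course without nucleophile, one at 250 mM) lets the
global fit separate hydrolysis (k1, recovered here as 0.0152 ± 0.0004 min⁻¹,
a ~46 min half-life) from nucleophile discharge (k2, recovered as
(3.9 ± 0.1)×10⁻⁴ mM⁻¹ min⁻¹) despite 2% densitometry noise; both estimates
bracket the generating truth.

The same workflow is available from the shell:

```sh
e2chase synth chase --sigma 0.02 --seed 1 --out chase.csv
printf 'courses:\n  - csv: chase.csv\n' > design.yaml
e2chase fit global --design design.yaml --out fit.json
```

and the geometry side (`e2chase synth frame`, `e2chase geometry`,
`e2chase pocket`, `e2chase report`) runs the ensemble analyses on PDB input.

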