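# Methods

## The discharge model

The chase phase of a ubiquitin discharge assay is modelled from the moment
E1 reloading is quenched (quenching is treated as instantaneous; loading
kinetics are not modelled, and t = 0 is the first chase sample).  The loaded
thioester species E2_L is consumed by three competing reactions — hydrolysis
(first order, k1), attack by an added nucleophile in large excess
(pseudo-second order, k2·[Nu] with [Nu] constant), and intramolecular
autoubiquitination (first order, k3):

    d[E2_L]/dt  = -(k1 + k2[Nu] + k3) [E2_L]
    d[E2]/dt    =  (k1 + k2[Nu]) [E2_L]
    d[E2_Ub]/dt =  k3 [E2_L]

with closed-form solution

    [E2_L](t)  = [E2_L]0 e^(-k_obs t),                    k_obs = k1 + k2[Nu] + k3
    [E2_Ub](t) = (k3 [E2_L]0 / k_obs)(1 - e^(-k_obs t))

State variables are densitometric *fractions* (dimensionless, summing to 1;
the apo pool starts at 1 − E2L0), not concentrations, because gels and
anisotropy report relative signal.  Units are fixed package-wide: minutes
and millimolar, so k2 is in mM⁻¹ min⁻¹.  The observable fitted to gel data
is [E2_L] + [E2_Ub], since the autoubiquitinated species co-migrates with
the loaded one on non-reducing gels.

An independent numerical oracle (`ode_oracle`, DOP853 at rtol 1e-12 /
atol 1e-14) integrates the rate laws directly; the test suite requires
closed-form agreement ≤ 1e-8 over 100 random parameter draws and mass
conservation ≤ 1e-10.

## Global fitting

`DischargeModel.fit()` minimises the summed squared residuals of the
observable across all courses of a design, with E2L0, k1, k2, k3 shared and
[Nu] fixed per course, using Levenberg–Marquardt least squares.  Design
choices:

* **Log-scale rates.**  k1, k2, k3 are fitted as log-parameters.  This
  enforces positivity without box constraints and equalises step sizes for
  rates spanning orders of magnitude.  A rate driven to the floor
  (1e-12 min⁻¹) reads as zero.  E2L0 is fitted on the linear scale and
  clipped into (0, 1] only when constructing the returned parameter set.
* **Deterministic initialisation.**  k1 from a mono-exponential pre-fit of
  the lowest-[Nu] course; k2 from (k_obs([Nu]) − k1)/[Nu] of the
  highest-[Nu] course; k3 from the late-time plateau; E2L0 from the first
  sample.
* **Uncertainties.**  Standard errors come from the Jacobian-based
  covariance at the optimum, scaled by the residual variance, and are mapped
  from the log scale to the natural scale by the delta method.  No bootstrap.
* **Equal weighting.**  All points weigh equally; whether the original
  assays weighted paired courses by replicate count is unknown, so the
  simplest convention is used.
* **Replicates.**  Replicate experiments are fitted separately and the rate
  constants averaged (`average_rates`), with the SD of per-fit estimates as
  the error — matching how replicate assays are conventionally reported —
  rather than pooling all replicates into one fit.
* **RING-containing reactions** are fitted with the same equation but the
  results carry an `apparent=True` tag: discharge then proceeds from a
  mixture of E3-bound and free E2~Ub, so the constants are only meaningful
  at that RING concentration.  No binding equilibrium is deconvolved.

Auxiliary fits: the mono-exponential (A·e^(−kt) + C) flags non-decaying or
unidentifiable data (k ≤ 0, or stderr ≥ k) and then reports k_obs = 0 with a
large standard error; an exact fit with singular covariance is *not*
flagged.  The double exponential orders its components fast-first and flags
rate collapse (relative separation < 1e-3) as degenerate.  The pH
dose-response is a 4-parameter logistic in pH units,
k(pH) = floor + (ceiling − floor)/(1 + 10^(slope·(mid − pH))); the
parameterisation is a modelling choice, as is reading the midpoint as an
apparent pKa.  The fold-change error is the standard relative-error
quadrature ratio·sqrt((σ_WT/k_WT)² + (σ_Mut/k_Mut)²), which the tests verify
against Monte-Carlo sampling (it is a first-order approximation, accurate
for relative errors ≲ 10%).

## Densitometry

Loaded fraction = loaded/(loaded + apo).  Modified fraction subtracts a
per-condition background *from the modified signal* before forming
modified/(modified + unmodified); subtracting from the modified signal
rather than from the lane total is a documented choice where the original
procedure is ambiguous.  The no-ATP baseline is a single condition-level
scalar, not per-lane.  Over-subtraction clamps at zero and every clamp is
surfaced as a `ClampWarning`, never absorbed silently.  The NaOH-resistant
share of modification is (modified with NaOH)/(modified without), capped at
1 (cap flagged); the sensitive share is its complement, so the two always
sum to exactly 1.  All fractions are invariant under uniform rescaling of
lane intensities.

## Ensemble geometry

* **Plane offset.**  The thioester plane passes through Cys Sγ and the
  Gly76 carbonyl C and O; coordinates are centred on Sγ and the offset is
  the dot product of the unit normal with the centred His-Nε position.  The
  normal is oriented so a caller-supplied cavity-reference atom scores
  positive (positive offsets = solvent-cavity side).  Collinear plane atoms
  are rejected.
* **Orientation angle** at Nε between the imidazole ring centre of mass
  (mass-weighted, 3 C + 2 N) and the carbonyl carbon.
* **Base-catalysis call.**  Default |offset| ≤ 3.5 Å with an open
  orientation window (0°, 180°); the window is configurable and no tighter
  default is asserted, since no numeric window is established.
* **Hydrogen bonds.**  Donor–H covalent identification ≤ 1.2 Å,
  donor–acceptor ≤ 3.0 Å, donor–H–acceptor angle ≥ 150°.  The angle
  threshold is interpreted as a *minimum*: a maximum would accept
  near-right-angle contacts while rejecting ideal linear bonds, and 1.2 Å
  is read as the covalent D–H cutoff rather than an H···A criterion.  The
  literal alternative reading (angle ≤ threshold, H···A ≤ 1.2 Å) remains
  available behind `ContactCriteria(literal_hbond=True)`.
* **Salt bridges.**  Ion-pair centre-of-mass distance ≤ 5 Å (a deliberately
  lenient cutoff appropriate for 300 K trajectory snapshots rather than
  averaged structures).  Charged groups: Lys Nζ; Arg Cζ/NH1/NH2; Asp
  Cγ/Oδ1/Oδ2; Glu Cδ/Oε1/Oε2.
* **Dihedrals.**  χ1 = N–Cα–Cβ–Cγ, χ2 = Cα–Cβ–Cγ–Nδ1 (histidine
  convention), signed per the IUPAC convention (0 = cis), verified against
  MDAnalysis and an independent two-normal oracle.
* **RMSF.**  Each frame is Kabsch-superposed onto the first frame over a
  fit selection (default: all Cα atoms, falling back to all atoms);
  fluctuations are measured about the ensemble-mean atom positions and
  pooled per residue as the root mean squared fluctuation over the
  residue's atoms and frames.  Note that with few, spatially clustered fit
  atoms the superposition itself is noisy and inflates apparent RMSF at
  long lever arms — the tests therefore fit over all atoms.
* **Pocket volume.**  The inclusion sphere (default radius 12 Å) is centred
  at the midpoint of the segment joining the midpoints of two
  caller-chosen atom pairs (the reading adopted for "centred on the axis
  between" two residue pairs).  A cubic grid with 0.5 Å pitch, anchored at
  the centre, floods the sphere; points strictly closer than 1.09 Å to any
  heavy atom are deleted (a point exactly at the cutoff is retained — a
  tie-break that only matters on constructed inputs); points outside the
  convex hull of the heavy atoms are removed when hull pruning is on; the
  volume is the surviving count × spacing³.  Heavy atom = element ≠ H,
  with the element taken from PDB columns 77–78 and a name-based fallback.
  Frames are expected to be pre-aligned to a common reference, which makes
  the anchored grid exactly reproducible across frames; volumes are
  computed per frame and summarised however the caller chooses (the CLI
  reports mean and median).
* **His tautomers.**  HID/HSD (δ-protonated, free Nε), HIE/HSE
  (ε-protonated, free Nδ) and HIP/HSP (none free) dialects are normalised
  to HIS on input with the tautomer retained; a plain HIS defaults to
  δ-protonated, the arrangement with a free ε-nitrogen required for base
  catalysis.

All geometric operators are invariant to 1e-9 under rigid-body transforms
(pocket volume via the pre-alignment convention above) and are tested
against brute-force oracles: explicit point–plane distance, law of cosines,
O(n²) contact scans, and exact per-point grid counts.

## Synthetic data

The generators produce the exact input formats the analyses read, from
known truth.  Chase noise is additive Gaussian on fractions, *unclipped* by
default — real densitometry scatters slightly outside [0, 1] and the fits
must tolerate that (clipping is available).  The error distribution of real
densitometry is not characterised; Gaussian is an assumption, stated as
such.  Default chase conditions are a paired design ([Nu] = 0 and 250 mM),
12 samples over 0–120 min, σ = 0.02 — a sampling grid and noise level
typical of a gel-based chase on a conjugate with a ~46 min hydrolysis
half-life — with rate constants (k1 = 0.015 min⁻¹, k2 = 3.8×10⁻⁴
mM⁻¹ min⁻¹, k3 = 0.002 min⁻¹) characteristic of an intrinsically slow,
minimally autoubiquitinating UBC domain.  One integer seed fans out through
`SeedSequence([seed, generator_id, stream])`, so adding a generator never
perturbs existing streams and identical seeds give bitwise-identical data.

The toy geometry frames place an idealised thioester plane, a
regular-pentagon imidazole proxy and a probe nitrogen at prescribed offset
and angle; they exercise the geometric operators exactly but do not emulate
real protein stereochemistry, packing or solvent.  Likewise the jitter
ensembles have independent isotropic per-atom fluctuations (RMSF → σ√3),
unlike the correlated motions of a real trajectory.  Passing tests
therefore demonstrate correctness of the *operators and estimators*, not
realism of any force field — wet-lab-derived quantities that depend on the
actual gels or structures are exercised only through these synthetic
analogues.

## Problem sizes and tolerances

The test suite uses 100-draw oracle sweeps, 50-seed recovery/coverage
experiments, 2000-frame jitter ensembles and 10⁵-sample Monte-Carlo checks;
the whole suite runs in a few seconds on one CPU.  Round-trip recoveries at
zero noise are required to 1e-6 relative (kinetics) and 1e-6 to 1e-9
absolute (geometry); noisy recoveries are judged against their own
standard errors (|error| ≤ 3·stderr, coverage ≥ 80%).

## Known limitations

* The model assumes a single well-mixed E2~Ub pool: no E1 reloading, no
  chain elongation, no Michaelis–Menten saturation in [Nu], no explicit
  RING binding equilibrium (apparent constants only).
* k3 is identifiable only through the late-time plateau; with courses that
  end well before the plateau, k3 and k1 trade off and a flat signal makes
  k3 formally unidentifiable (any k3 with k1 = k2 = 0 is constant).
* The densitometry module consumes already-quantified band intensities;
  image processing and band detection are out of scope.
* Coordinate input is PDB only (Å, residue numbering as-authored); binary
  trajectory formats are out of scope.
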