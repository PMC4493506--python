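# Methods

`amphimem` models how PEGylated, carbohydrate-derived amphiphilic
macromolecules (AMs) bind to model lipid membranes, combining a
coarse-grained molecular-dynamics arm with a quartz-crystal-microbalance
(QCM-D) analysis arm and a descriptor-based QSAR layer.  This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Coarse-grained force field

Beads follow the four-class CG taxonomy — polar (P), nonpolar (N), apolar
(C), charged (Q) — with sub-types for polarity level (1–5) and
hydrogen-bonding character (d/a/da/0).  Standard beads are 0.47 nm and
72 amu (≈4 heavy atoms); small ring beads are 0.43 nm and 45 amu.

* **Nonbonded.**  12-6 Lennard-Jones, smoothly force-shifted to zero
  between 0.9 and 1.2 nm, and a screened Coulomb term (relative
  permittivity ε_r = 15) shifted between 0 and 1.2 nm.  The shift applied
  to a 1/r^p term adds A(r−r1)² + B(r−r1)³ to the force with coefficients
  chosen so force and its first derivative vanish at the cutoff; energies
  gain the matching polynomial and constant.  Forces therefore equal the
  analytic −dU/dr everywhere (verified by central differences at 10⁻⁶
  relative tolerance).
* **Interaction table.**  Pairwise ε values follow a documented ten-level
  well-depth table (5.6 → 2.0 kJ/mol, σ = 0.47 nm, plus one 2.0/0.62
  repulsive level) shipped as `data/interaction_table.csv`; pairs of two
  ring beads use σ = 0.43 nm with ε scaled by 0.75.  All tests needing
  exact numbers pin that file.
* **Bonded.**  Harmonic bonds (default R_b = 0.47 nm,
  k_b = 1250 kJ·mol⁻¹·nm⁻²); angles in the cosine-harmonic form
  U = ½k(cosθ − cosθ₀)², which is regular at θ = 180° and keeps aliphatic
  chains linear (θ₀ = 180°, k_θ = 25 kJ/mol); harmonic improper dihedrals
  (k = 500 kJ·mol⁻¹·rad⁻²) keep four-bead rings planar.
* **Structure library.**  Eleven AMs plus a PEG control.  Each AM is a
  sugar-acid backbone (N0 beads) with aliphatic arms parameterized as lipid
  tails (C1 chains), a head group (Qa carboxylate, Qd protonated amine, or
  neutral P1), optionally a small-bead ring, and a PEG tail of one N0-like
  bead per ethylene-oxide monomer (default 45 monomers, bond 0.33 nm /
  7000 kJ·mol⁻¹·nm⁻², angle 130°/50 kJ/mol).  Bead-level connectivity is a
  best-effort reconstruction from the published class legend; stereoisomer
  pairs (1cM/1cS, L-1cT/M-1cT, 0cG/0cG-L) share an identical topology and
  differ only in a stereo tag and the geometry seed that drives the
  conformer generator: exposed-charge species splay their arms away from
  the head, caged species fold them around it.  The conformers are
  deterministic geometric constructions, not energy minima.

## Dynamics

Velocity-Verlet integration at dt = 10 fs, Berendsen weak-coupling
thermostat (T₀ = 310 K, τ_T = 1 ps) and barostat (P₀ = 1 bar, τ_P = 2 ps,
compressibility 3×10⁻⁵ bar⁻¹), an all-pairs Verlet list with 1.4 nm list
cutoff refreshed every 10 steps, and COM-motion removal (N_dof = 3N − 3) at
each refresh in NVE/NVT.  Pressure comes from the per-axis virial
accumulated over all pairwise and angular terms; coupling is isotropic by
default with a semi-isotropic option (lateral xy vs normal z) used for
planar bilayers.  Scaling factors are clamped (λ ∈ [0.8, 1.25],
μ ∈ [0.98, 1.02]) for robustness against construction transients.  The
Berendsen λ at zero instantaneous temperature is defined as 1 (nothing to
scale).  Neighbor-list forces match brute-force all-pairs forces exactly
whenever no bead crosses the 0.1 nm skin between refreshes.

Desk scale: the engine targets 10²–10³ beads per test; a full 512-lipid /
20 000-water system is supported by the same code path but is not a test
fixture.  On the 128-lipid solvated fixture (~2900 beads) NVE drift is
< 10⁻³ kJ/mol/bead over 10 ps.

## System construction

Bilayers are built as two lipid leaflets on a jittered square lattice at
0.64 nm²/lipid with the phosphate planes 4 nm apart, head beads outward.
Water beads (1 CG bead = 4 real waters) fill the free volume on a
0.48 nm grid (close to liquid CG-water density); ions replace waters, with
counterions neutralizing the solute charge before 120 mM NaCl pairs
(molarity from the CG water count).  A single AM is placed with its
backbone COM 7 nm above the bilayer midplane (flag available for an
outer-phosphate reference); clashing waters are removed.  All builders are
pure functions of (spec, seed).

## Umbrella sampling and WHAM

The reaction coordinate is the z-component distance between the AM
head-group COM and the bilayer COM, absolute-valued across the midplane
(flag for a signed coordinate).  The bilayer COM uses a circular mean in z
so periodic wrapping cannot bias it.  The published protocol is the
default: pull at 0.0014 nm/ps from 7 nm to coincidence, seventy windows
0.1 nm apart, restraint 1000 kJ·mol⁻¹·nm⁻², 50 ns per window with 20 ns
discarded; fixtures use ~100× shorter windows.  WHAM iterates the standard
binned self-consistency equations (bin width 0.05 nm, tolerance
10⁻⁶ kJ/mol, 10⁵ iterations max), reports kcal/mol (4.184 exactly), and
normalizes profiles to zero at 5 nm by linear interpolation.
Non-overlapping windows produce a connectivity warning; the result is
invariant under window permutation and reproduces a dense fixed-point
oracle to 10⁻⁸ on small cases.

## Trajectory statistics

An insertion event is a frame with head-group-to-bilayer-COM distance
< 2 nm — half the ≈4 nm DPPC bilayer thickness — evaluated instantaneously
per frame.  First-insertion times are censored at the trajectory end.  PEG
orientation is the angle between the first→terminal PEG bead vector and
the membrane normal; PEG heights are measured from the outer-leaflet mean
phosphate plane.  Replicate summaries report inserted fraction, median
first-insertion time and censoring counts (the study design used 10
replicates per AM).

## QCM-D

The data model stores Δf (Hz) and ΔD (units of 10⁻⁶) for overtones
n ∈ {3,5,7,9,11} of a 5 MHz fundamental, with five protocol phases
(baseline, SLB formation, rinse, AM binding, final rinse).  The quoted
"5 Hz" fundamental in the source hardware description is treated as a typo
for 5 MHz, consistent with C = 17.7 ng·cm⁻²·Hz⁻¹.

* **Sauerbrey:** Δm = −C·Δf/n with C = 17.7 ng·cm⁻²·Hz⁻¹; mass time
  series default to the third overtone.
* **Voigt film:** one viscoelastic layer (shear modulus μ, viscosity η,
  density ρ, thickness h) under semi-infinite Newtonian liquid in the
  small-load approximation, baseline-subtracted so a zero-thickness film
  gives (0, 0).  The quartz areal mass is ρ_q h_q = C·f₀, which makes the
  rigid limit collapse exactly onto Sauerbrey.  Fitting is joint
  least-squares over all overtones' Δf and ΔD in log-parameter space with
  the film density held fixed (ρ and h are near-degenerate in the
  small-load response); optional seeded multi-start between bounds.
* **Kinetics:** deposition rate = OLS slope of Sauerbrey mass over the
  first 5 min of the binding phase after a 30 s skip; plateau = mean mass
  over the final 10% of the phase with a slope-flatness warning.  The
  slope estimator is linear in additive noise and hence exactly unbiased.
* **Segmentation:** explicit protocol times, or detection from the
  third-overtone rolling-regression slope (0.5 min window) with
  6×MAD threshold, hysteresis (release at threshold/3) and 1 min gap
  merging; phase starts are activity onsets, and the SLB phase is
  validated by its minimum-then-recovery frequency signature.

## QSAR

Descriptors are computed from the CG topologies (an open set: composition
and class fractions, graph indices including Wiener and Randić, a
Crippen-style logP analog from per-class increments, polar/hydrophobic
surface-area estimates from bead classes) plus conformational descriptors
when coordinates are supplied (radius of gyration, span, charge-exposure
fraction, charge-to-COM distance).  The conformational block is what
separates stereoisomer pairs whose 2D graphs are identical — the package's
interpretation of how stereochemistry can enter a descriptor model.  A
name map (`DESCRIPTOR_ANALOGS`) records which conventionally reported
descriptors (slogP, ASA_H, ASA_P) have analogs here.

Filtering drops near-constant columns and the later member (by name order)
of any pair correlated above the ceiling.  PLS uses NIPALS on autoscaled
data with at most four latent variables (component count optionally chosen
by maximizing leave-one-out q², ties to fewer); validation is LOO
q² = 1 − PRESS/TSS with fold-wise removal of zero-variance columns;
predictions flag rows outside the training descriptor ranges
(applicability domain).  The response is plateau mass, used raw or
normalized to the panel maximum.  PCA is autoscaled; loading reports rank
descriptors by absolute contribution with signs.

## Synthetic data

Generators are seeded and bit-reproducible; each can write a
ground-truth JSON sidecar so recovery tests never hard-code truth.

* **QCM-D traces:** mass program = smoothed SLB step with a liposome
  overshoot/rupture hump, exponential-approach binding
  m(t) = M(1 − e^{−kt}) (bi-exponential option), and transient
  fully-recovering dips at the rinse onsets (buffer-exchange artifacts)
  that give segmentation detectable onsets.  Frequency shifts invert
  Sauerbrey (rigid mode) or come from the Voigt model (viscoelastic mode);
  Gaussian noise per overtone at the instrument sensitivities
  (1.8 ng/cm² mass, 0.1×10⁻⁶ dissipation).  Defaults (M = 750 ng/cm²,
  k = 0.1 min⁻¹, SLB 450 ng/cm², 5/15/5/60/5 min phases) mirror the
  strong-binder experiments.  Not emulated: drift, bubbles, flow
  transients.
* **Umbrella samples:** exact inverse-CDF Boltzmann draws under
  U(z) + ½k(z−z_c)² on a fine grid — an oracle input for WHAM, free of MD
  sampling error.
* **QSAR datasets:** 12 structures (10 train / 2 test), 20 descriptors, 4
  informative.  The informative columns are manifest variables of one
  driving latent trait (loading 0.85, loading signs matching their
  coefficients ±3/±2) — the typical QSAR situation where several
  descriptors report the same property that drives activity; nuisance
  columns carry independent rank-4 latent structure.  Noise is set from
  SNR 10.  This design makes the planted signal identifiable at n = 10:
  coefficient signs recover in ≥95% of seeded replicates and LOO q²
  reaches ~0.7, which a generic unstructured random design cannot achieve
  at this sample size.
* **Bilayer fixtures:** 128-lipid scaled replicas of the 512-lipid system.

Passing tests on these generators demonstrates correctness of the
estimators and the simulation machinery under known ground truth; they do
not certify force-field accuracy against experiment, descriptor relevance
for real chemistry, or kinetics beyond the single-exponential model.

## Verification problem sizes

The suite runs the physics checks at fixture scale: NVE conservation over
10 ps and thermostat regulation over 100 ps on ~300–2900-bead systems;
WHAM recovery on 20 windows × 2000 exact samples; the bilayer-thickness
check relaxes the 128-lipid fixture with 20 ps NVT plus 100 ps
semi-isotropic NPT and averages the phosphate-plane separation over the
final 50 ps (expected within 15% of the ≈4 nm reference).  The same
computation, re-seeded, is what `scripts/acceptance.py` reports.

## Known limitations

* The AM bead assignments beyond the published class legend are
  reconstructions; absolute binding energetics should not be compared to
  experiment.
* Berendsen coupling does not generate a rigorous canonical/isobaric
  ensemble; fluctuation-based observables (e.g. instantaneous-pressure
  statistics on small boxes, where fluctuations are O(100 bar)) are
  meaningful only as means with appropriate statistical bands.
* No long-range electrostatics (PME), constraint algorithms, or
  reverse-mapping to atomistic detail.
* The QCM-D arm models one film layer; multilayer or rough films are out
  of scope, as are instrument artifacts beyond additive noise.
* Whether the experimental mass figures derived from Sauerbrey or Voigt
  analysis is unrecorded; the package defaults to Sauerbrey on n = 3 and
  exposes both.
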