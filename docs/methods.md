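# Methods

This note records the model conventions, numerical choices and limitations
of `ride`. Units throughout: nm, ps, K, mPa·s, and 10⁻⁵ cm² s⁻¹ for
diffusion coefficients.

## Hydrodynamic-radius assembly

The central quantity is the squared hydrodynamic radius assembled additively
over the solvent-excluded surface,

    R_H,total² = C_term·SESA_term + Σ_i C_i·SESA_i ,

with per-residue-type hydrodiffusivity coefficients

    C_i = (R_H,capped-i² − R_H,NMA²) / (SESA_capped-i − SESA_NMA).

R_H values come from simulated infinite-dilution diffusion coefficients via
Stokes–Einstein (CODATA k_B); the capped-peptide and N-methylacetamide (NMA)
diffusion inputs are shipped as data (`data/table_peptide_diffusion.tsv`,
`NMA_D0 = 3.32`), all at 310.15 K with TIP3P viscosity 0.275 mPa·s. The
NMA subtraction removes the contribution of the ACE/NME caps, isolating the
residue itself.

**Terminus convention.** `SESA_term` is always the SES area of an isolated
NMA molecule (the scale stores the value computed from its own fixtures).
`C_term` is the NMA coefficient (R_H,NMA²/SESA_NMA) for capped chains and
the ASP/LYS monopeptide average for zwitterionic backbones. For zwitterionic
structures the terminus term is purely additive on top of the full
residue-area sum (terminal residues are not treated specially).

**Cap-area handling in prediction.** For a capped input structure the
measured residue areas are rescaled by a common factor so that they sum to
(total SESA − SESA_term). Rationale: the coefficients were derived from
*whole-molecule* area differences, in which the cap contribution is removed
as one fully exposed NMA-equivalent patch. In an intact capped peptide the
cap atoms are partially buried by the residue, so attributing measured
cap-atom areas naively would double-count the buried interface; the
rescaling restores the derivation's accounting exactly, and makes the
prediction for any capped monomer reproduce its input diffusion coefficient
algebraically (the suite checks all twenty at 0.5%).

Two scale variants ship as plain-text package data, regenerable with
`scripts/build_scales.py`:

* **M** — derived from capped monopeptide D₀ values and extended
  (φ=ψ=180°) monomer fixtures;
* **D** — derived from capped decapeptide D₀ values and ideal α-helix
  (φ=−57°, ψ=−47°) decamer fixtures, folding secondary-structure propensity
  into the coefficients.

With these fixtures the D coefficients are smaller than M for 18 of 20
residue types (faster predictions, as expected from backbone burial); GLY
and PRO come out slightly larger because an ideal glycine/proline "helix"
is a poor stand-in for their real conformational ensembles. Predictions for
mixed sequences dominated by the other 18 types preserve the expected
RIDE(D) > RIDE(M) ordering.

## Solvent-excluded surface areas

No installed library computes per-atom solvent-*excluded* areas, so the
engine is implemented here. The SES solid is the morphological closing of
the van-der-Waals union with a probe ball of radius 0.15 nm (the probe is a
parameter): a point is solute iff every probe sphere covering it clashes
with an atom. The area is extracted as the zero level set of the signed
probe-distance field

    F(p) = d(p, accessible region) − r_probe,

computed exactly (sub-voxel) in a thin band around the surface from a
KD-tree over quasi-uniform Fibonacci-lattice samples of the accessible
(probe-center) surface, then triangulated with marching cubes
(scikit-image). Each triangle is attributed to the atom whose vdW sphere
surface is nearest; reentrant area therefore goes to the nearest
contributing atom rather than being split among all definers — per-residue
totals, the only quantities the model consumes, are insensitive to this
choice, and the capped-structure rescaling removes any residual cap/residue
interface ambiguity.

Numerical parameters:

* **grid spacing** (`resolution`, default 0.010 nm): controls accuracy and
  cost. An isolated 0.15 nm sphere is reproduced to 0.013% at the default;
  self-convergence between a 0.020 nm and a 4×-finer 0.005 nm grid agrees
  within 2%, the engine's correctness criterion. A capped monopeptide costs
  ~2 s, a decapeptide ~10–20 s on one CPU.
* **surface-sample spacing**: 2× the grid spacing, capped at half the probe
  radius. The point-cloud distance error is second order in the spacing
  when the query distance (≈ probe) is much larger, which the cap
  guarantees; without it the probe→0 limit degrades to first order.
* Sampling is a deterministic lattice: repeated runs are bit-identical
  (the `seed` field exists for interface stability only).
* Distant atom groups are meshed on independent sub-grids (connected
  components of the expanded-sphere overlap graph), so widely separated
  clusters do not inflate the grid.
* Interior cavities large enough to admit a probe count as solvent
  (geometric SES definition); coincident equal-radius atoms are rejected.

**Radius sets.** Two sets ship: Bondi explicit-atom radii and a
Chothia/Richards-style united-atom set (C 0.187, N 0.165, O 0.140,
S 0.185 nm). The united set is the default and the one the shipped scales
are derived with, because all fixture structures are heavy-atom only —
united radii absorb the missing hydrogens. The scale files record the
radius-set name; coefficients are only meaningful together with the radii
and conformers they were derived from.

## Peptide fixtures

Ideal conformers are built from internal coordinates by natural-extension
(NeRF) placement: standard backbone bond lengths/angles, ω = 180°, and
φ/ψ = (180°, 180°) extended, (−57°, −47°) α-helix, or (−75°, 145°)
polyproline II (included because polyproline is the natural state of
PRO-rich chains). Backbone dihedrals of built structures were verified
against biotite's independent measurement; the ideal helix shows a 0.160 nm
rise per residue and 0.52 nm CA(i)→CA(i+3) spacing. Side chains use one
canonical rotamer (free χ torsions trans) from idealized geometry; the
five-membered rings of PRO and the TRP five-ring close only approximately
(< 0.01 nm seam), and mild inter-residue contacts (≥ 0.15 nm) can occur in
bulky helices — acceptable for a surface-area substrate, not for energetics.
ACE/NME caps are three and two heavy atoms; NMA is the fused ACE+NME
fragment. Zwitterionic termini add an OXT; masses add one water per chain
instead of cap masses.

Brownian trajectories are cumulative Gaussian steps with per-axis step
variance 2·D·dt; finite-size series evaluate the periodic-box model with
optional Gaussian noise whose σ is recorded as the per-point uncertainty.
These generators emulate ideal, homogeneous diffusion — no hydrodynamic
memory, no wrapping artifacts (an unwrap helper exists for wrapped input),
no force-field specificity — so passing tests demonstrate the estimators'
statistical correctness, not agreement with any particular solvent model.

## Diffusion toolkit

* **MSD**: multiple-time-origin averaging at every lag; `average_msd`
  combines independent traces the way simulation protocols average
  replicas (a single 100 ns trace leaves ~10% spread in the fitted D;
  ten averaged traces bring it to ~3%).
* **Window fit**: least squares on a lag window, D = slope/(2·dims), with
  the slope's standard error propagated. Default windows follow the
  simulation practice of 30–500 ps for small solutes and 30–3000 ps for
  proteins; both are explicit arguments.
* **Finite-size model**: D_app(L) = D₀ − α·k_B·T·ξ_EW/(6πηL). Extrapolation
  fits D_app against 1/L (inverse-variance weighted when uncertainties are
  present, with known-variance parameter covariance; OLS otherwise). The
  single-box correction requires the caller to supply α — it is
  solute-dependent and never guessed.
* **ξ_EW**: Ewald summation (real-space erfc + reciprocal Gaussian +
  self/background terms) with cutoffs grown to the requested tolerance and
  a splitting-parameter invariance check; converges to 2.8372975, and a
  literature value is kept as a cached constant. An independent
  smooth-window direct lattice sum reproduces it to ~1e-4 in the tests.

## Viscosity

Tabulated TIP3P and experimental water viscosities (273.15–323.15 K, 5 K
steps) ship as data and are interpolated linearly — the trend is nearly
linear at this spacing; ±2.5 K extrapolation warns, more errors. The scales
use the independently computed 0.275 mPa·s at 310.15 K rather than the
table interpolation (0.277). NaCl enters as a linear relative-viscosity law
η(c)/η(0) = 1 + 0.094·c (L/mol), fit to standard experimental relative
viscosities at 293.15 K and declared valid to 1 M; the slope is a plain
`SaltModel` field and overridable. The periodic-perturbation estimator fits
the steady-state response v_x(z) = offset + V·cos(2πz/L_z) (the offset
absorbs drift) and inverts η = A·ρ/(V·k²); its correctness criterion is the
exact round trip against the generating formula.

## Mass-relation baseline

D = A·M^(−1/3) with A = D_ref·M_ref^(1/3). The shipped default calibrates
on the Arc-repressor reference (M = 6.14 kg/mol, D = 0.150 at 293.15 K in
pure water) because the original hemoglobin prefactor is not published;
users may calibrate on any pair. `correct_to_state` applies the literal
composition D·(T/293.15)/(η_target/η_exp,293) and returns the ratios in
metadata: which experimental viscosity belongs in the denominator is
ambiguous in the source description, so the package surfaces the choice
instead of resolving it silently, and published state-corrected values are
deliberately not used as test anchors.

## Problem sizes

The test suite (one CPU, ~3 min) uses: monopeptide/NMA surfaces at the
default grid for the full 20-residue scale derivation; sphere clusters of
≤ 8 atoms for surface anchors; ten 100 ns / 3 ps Brownian traces for MSD
recovery; 300 short traces for the unbiasedness check; 200 seeded series
for extrapolation coverage. The acceptance script re-derives the M scale
(21 surface computations, ~40 s) before the round-trip prediction.

## Known limitations

* Coefficients cover the 20 standard residues at pH-7 protonation; no
  PTMs, nucleic acids, ligands or ions.
* Predictions inherit the conformer the caller supplies; the package never
  selects conformers implicitly, and ideal fixtures are not equilibrium
  ensembles (no ensemble averaging of C or of areas).
* The GLY/PRO exception to the RIDE(D)-faster ordering, above.
* Rotational diffusion, anisotropic mobility tensors and non-cubic box
  corrections are out of scope.
* The scale values are tied to their radius set, probe, conformer and grid;
  comparing coefficients across differently derived scales is meaningless.
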