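# Methods

This note documents the models, conventions and numerical choices behind
`twimsccs`, and what the synthetic-data tests do and do not demonstrate
about real instrument data.

## Traveling-wave calibration

**Model.** A traveling-wave drift cell has no closed-form drift-time→CCS
relation, so CCS is transferred from calibrant ions of known CCS measured
under identical instrument settings. The chain is:

1. *EDC correction.* The enhanced-duty-cycle delay is mass-dependent:
   `t′_D = t_D − C_EDC·√(m/z)/1000`, with `t_D` in ms and m/z in Th.
   `C_EDC` is an instrument constant; presets `C_EDC_PROTEIN = 1.57` and
   `C_EDC_RNA = 1.41` cover the two instrument configurations the package
   was built around, and any value can be supplied. A corrected time ≤ 0 is
   an error (the measured drift time cannot be shorter than the delay).

2. *Exponent fit.* Each calibrant's literature CCS is reduced by charge and
   ion–gas reduced mass, `Ω′ = Ω·√μ/z` with `μ = m·m_gas/(m + m_gas)`, and
   the power law `Ω′ = A·t′_D^X` is fitted by OLS in log–log form,
   `ln Ω′ = X·ln t′_D + ln A`, over all calibrant charge states jointly.

   The log–log form is a deliberate reading. Writing the fit with Ω′ itself
   as the response would make the subsequent "linear" calibration plot
   systematically curved: only with `ln Ω′` linear in `ln t′_D` does
   `Ω = A·t″_D` hold exactly (substitute Ω′ and t″_D below), which is the
   property the linearisation step relies on and the property our
   round-trip tests verify to machine precision. This is the single
   interpretive choice in the calibration chain, and the standard one in
   published TWIMS calibration protocols.

3. *Linearisation and estimation.* The doubly corrected time
   `t″_D = t′_D^X · z · (1/μ)^½` folds exponent, charge and reduced mass
   into one axis; published CCS is regressed on t″_D with a free intercept
   (an intercept absorbs residual instrument offsets; `--through-origin`
   forces the ideal-data form `Ω = A·t″_D`). Unknown ions are pushed through
   the same chain and read off the line. Estimates whose t″_D falls outside
   the calibrant range are flagged `extrapolated`.

**Units.** Internally: ms, Th, Da, Å². nm² (1 nm² = 100 Å² exactly) appears
only at the reporting layer.

**Drift gas.** μ uses N₂ (28.0134 Da) by default; helium (4.0026 Da) or any
other mass is configurable per model. The gas assumed by the calibrants'
literature CCS values is the user's responsibility to match.

**Diagnostics.** Both fits report R²; the model records `n_calibrants` and
the calibrant t″_D range, and serialises to JSON.

## Projection-approximation CCS

**Estimator.** PA is the rotation average of the area of the union of
projected atom disks. Orientations are drawn Haar-uniformly
(`scipy.spatial.transform.Rotation.random`, seeded); per orientation the
union area is estimated by uniform dart-throwing inside the tight 2-D
bounding box of the projected disks (area = box area × hit fraction). This
estimator is unbiased for any sphere union, and for a single sphere
converges to the Cauchy value (surface/4 = πr²) — both asserted in tests
against analytic areas.

**Sampling defaults.** 300 orientations × 5000 darts; the reported standard
error is the between-orientation standard error of the mean, which includes
dart noise, so users can tighten sampling until the stderr meets their
needs. Defaults converge typical structures to well under 1% relative error
at interactive cost.

**Radii.** Hydrogens 2.2 Å, all other elements 2.7 Å by default, a common
hard-sphere parameterisation for projection CCS; fully overridable via a
JSON table (`{"H": 2.2, "C": 2.7, "default": 2.7}`). Hydrogens are used
when present in the file and never reconstructed, so H-free crystal
structures and H-containing MD frames are both handled reproducibly; the
radius table is where any systematic difference is absorbed. Because the
effective radius set of published reference PA values is generally
undisclosed, absolute agreement with third-party PA numbers to better than
a few percent may require tuning this table.

**PSA.** `PSA = (PA − 81) × 1.299` (Å²) is an empirical affine correction
for the PA's underestimation of macromolecular CCS. It is intended for
protein-sized PA values; for small bodies it goes negative, which is
permitted (the map is kept exactly affine) but logged. For RNA both raw PA
and PSA are reported, since reference practice varies on whether the
correction is applied to nucleic acids.

## Structures

PDB I/O goes through gemmi: fixed-column parsing, element symbols from
columns 77–78 with name-based inference as fallback (MD-written frames
often lack element columns), multi-model files default to MODEL 1, waters
(HOH) excluded by default, other HETATM records kept. No mmCIF, bond
inference, protonation or symmetry expansion. Rg is mass-unweighted; RMSD
is computed without superposition — both are used as trajectory
equilibration indicators, where the unfitted frame is the quantity of
interest.

## Masses and charge states

Average masses from IUPAC 2021 atomic weights. Nucleic acids are summed as
free 5′-monophosphate nucleotides minus one condensation water per bond;
the default 5′-hydroxyl terminus removes one HPO₃ (79.980 Da). 5′-OH/3′-OH
is the synthetic-oligonucleotide convention and reproduces the package's
anchor RNA masses (11,217 / 11,219 Da for the two 35-mers) to the nearest
dalton, whereas a 5′-phosphate would overshoot by ~80 Da — that agreement
is why it is the default. Proteins are free amino acids minus waters
(residue masses plus one water). The charge carrier is a proton
(1.00728 Da) in both polarities; no adducts, modifications or isotope
distributions. A DNA table (including thymidine) supports oligonucleotide
calibrants such as poly-dT.

## Compaction reporting

`percent_compaction = (Ω_ref − Ω_meas)/Ω_ref × 100`, with the *reference*
in the denominator — the convention consistent with how headline
percentages are quoted for predicted-vs-measured comparisons (e.g. 68.2
measured vs 101 predicted ⇒ 32.5%; a measured-denominator convention would
give 48%). Negative values are reported as expansion. `nearest_reference`
minimises |Ω_meas − Ω_ref|, ties broken by list order with a warning. When
several charge states are present all are reported; the lowest charge state
is the conventional headline value, as the least likely to be
Coulombically unfolded. Reports are emitted in nm² and are deterministic
and idempotent.

## Synthetic data

**Calibrant tables** are manufactured by inverting the calibration forward
model: from (mass, z, CCS), compute Ω′, invert the power law for t′_D, add
back the EDC delay, then (optionally) multiply the drift time by
`1 + σ·N(0,1)`. Noise-free tables are exactly consistent with the model, so
fitting them must return the generating `X` and `ln A` and reproduce every
CCS to machine precision — the strongest available correctness oracle for
the whole chain. Because `Ω = A·t″_D` exactly, the implied linear-map truth
is slope `e^{ln A}` and intercept 0 (exposed as derived properties of the
spec, not free parameters).

Note on noisy recovery: drift-time noise perturbs the *predictor* of the
exponent regression, so the fitted `X` carries the classic errors-in-x
attenuation (≈1% low at 1% noise with the default panel). CCS estimates are
much less affected (mean bias < 0.5% over 100 instruments in the tests)
because the attenuated exponent partially self-compensates through the
linearisation.

The default calibrant panel is four protein species × three charge states
with masses 37–237 kDa and CCS values growing roughly as mass^(2/3) —
shaped like the classic native calibrant ladder, but synthetic numbers, not
literature database values (which are deliberately not bundled; a template
CSV documents the input columns).

**Bead chains** emulate a multidomain protein: `n_domains` spherical
domains of uniform-random beads, centroids either collinear at
(domain diameter + linker length) spacing ("extended") or packed on an FCC
cluster at domain-diameter spacing ("collapsed", a deterministic greedy
closest-packing — no physics; only the projected-area ordering matters).
Bead content and radii are identical across conformations for a given seed,
so PA(extended) > PA(collapsed) is a purely conformational signal; the
tests require 3σ separation over 10 seeds for 5-domain chains. Defaults:
5 domains × 40 beads, bead radius 2.7 Å, linker 12 Å (4–6 residues of
extended chain), domain radius `1.2·r_bead·n_beads^{1/3}`.

**What passing these tests does not show.** The generators share the
implementation's equations (by design: they are inversions), so round
trips validate internal consistency and the fitting code, not the physical
adequacy of the power-law model for any real instrument; the bead chains
have no secondary structure, charge effects or realistic collapse pathway.
Agreement with real measured CCS additionally depends on calibrant CCS
database accuracy, instrument settings, and the hard-sphere radius set.

## Known limitations

- No raw-spectrum peak picking or arrival-time-distribution modelling:
  inputs are tabulated drift times.
- The projection approximation ignores gas scattering and long-range
  interactions; no trajectory-method CCS.
- Instrument-specific quantities (measured CCS values, MD end-point
  structures) cannot be regenerated offline; they enter the compaction
  report as user-supplied reference/measurement inputs only.
- Calibration statistics assume independent errors; replicate-level
  uncertainty propagation is out of scope.
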