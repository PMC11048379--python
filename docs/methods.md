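# Methods

This note documents the models implemented in `cidtherm`, their assumptions,
the calibration parameters that matter, and what the synthetic-data tests do
and do not establish about measured data.

## Ion calculus

Monoisotopic masses are summed from tabulated atomic masses (pyteomics'
NIST table); oligomer ions are protonated pseudo-molecular ions, so charging
adds z proton masses (1.007276 Da), not hydrogen atoms, and

    m/z = (Σ monomer masses + z·m_p) / z.

Atom numbers are summed over monomers without the added protons; they set
the vibrational mode count 3N−6 of the temperature conversion, which is why
compositions must be exact. A proteoform may be declared either by formula
or by monoisotopic mass; when both are present the formula-derived mass wins
(printed 2-decimal masses carry rounding error) and disagreements beyond
0.02 Da raise a warning — user input is validated, never silently
"corrected". The biotinylated-foldon fixture is therefore defined by its
declared mass (3594.82 Da) and atom count (505), because its vendor formula
is not self-consistent with either.

Trimer dissociation reactions are enumerated as all distinct dimer+monomer
partitions of the stoichiometry; hetero-trimers have two release channels.
Default product charge splits are 3+/2+ for 5+ educts and 4+/2+ for 6+
educts, configurable per ion. Mass, atom and charge conservation are
enforced identities.

## Course construction

Peak *heights* (not areas) are extracted as the maximum centroid intensity
inside a ±0.5 m/z window (configurable, also in ppm) around each expected
ion; overlapping windows resolve each peak to the nearest window center with
a warning. Species declared as satellites (oxidation, sodiation) are summed
into their parent before normalization. Every scan is normalized to a total
of 100 % on its own; replicates are averaged only after per-scan
normalization, so a voltage present in a single series is kept with
undefined standard deviation. Whether satellites enter the normalization
denominator is a user decision (they do if assigned).

## Sigmoid fit

Unweighted least squares (scipy `curve_fit`) on replicate means, initialized
from the data (plateaus at the extreme values, midpoint at the half-range
point, width at a tenth of the voltage span) and bounded (plateaus in
[0, 110] %, width positive and at most the voltage span) to prevent plateau
swap; initialization is clipped into the bounds. R² < 0.99 flags the fit but
does not reject it. Degenerate inputs error early: fewer than five points,
a span below 5 % (no transition), or a rising educt course (wrong species
selected). Rounding to table precision happens only in the report layer.

## Temperature, rate and equilibrium conversions

The ΔCV → effective-temperature conversion is an instrument calibration, not
a first-principles result, and is pluggable (`ThermoConfig.temperature_model`).
The default is

    T_eff(ΔCV) = T0 + n_coll · z·e·ΔCV · m_gas/(m_gas + M_ion) / ((3N−6)·k_B),

i.e. the centre-of-mass collision energy of an effective number of
activating collisions equipartitioned over the vibrational modes — affine
and strictly increasing in ΔCV. A single collision would heat a ~1300-atom
trimer ion by only ~1 K over the studied voltage range, incompatible with
the observed complete dissociation; hard-sphere mean-free-path arithmetic
for a ~10 cm collision cell near 10⁻² mbar (σ ≈ 3×10³ Å² for a protein
trimer) gives several hundred collisions per transit, and the default is
n_coll = 500. T0 defaults to 300 K (near-source conditions), the collision
gas to argon (39.948 Da).

Rates assume first-order decay over the cell transit, k = −ln(S)/τ with
residence time τ = 10⁻⁴ s by default; τ scales every k# multiplicatively and
cancels nowhere, so it is printed in every summary.

The dissociation quotient is the mole-fraction quotient
q = x_dimer·x_monomer/x_trimer (hetero-trimer channels summed by default),
referred to the 1 M standard state by an effective ion activity
a = c_ions/c° with c_ions = 1.7×10⁻¹⁴ mol/L by default (≈10⁷ ions/cm³, a
space-charge-scale ion density): K = a·q. This dilution factor carries the
translational-entropy cost of dissociation at realistic ion densities; it is
what makes the extrapolated TΔS# negative. Without it, a fraction-quotient
Gibbs–Helmholtz fit can never produce a negative entropy along a breakdown
curve (ΔG crosses zero where q = 1, which lies inside every steep region, so
the fitted ΔG-vs-T slope is forced negative). All extrapolated quantities
are "apparent": conditional on (T0, n_coll, a, τ). Comparisons between
complexes measured under one calibration are meaningful; absolute values are
not transferable between calibrations.

## Extrapolations

There is one midpoint tangent per complex, hence one Arrhenius and one
Gibbs–Helmholtz line: both operate on the *fitted* sigmoid, evaluated at 25
evenly spaced voltages over the steep region (educt between 10 % and 90 % of
the fitted amplitude; all three numbers configurable), not on raw points.
ln k vs 1/T gives Ea, ln A and k#(298 K); ΔG(T) = −RT ln K vs T gives ΔH#
(intercept), ΔS# (−slope), ΔG#(298 K) and KD# = exp(−ΔG#/RT). The reported
identities ΔG = ΔH − TΔS and ΔG = −RT ln KD are re-checked by
`consistency_report` with a flag threshold of 0.005 kJ/mol — half a unit of
the 2-decimal reporting precision, so table rows whose printed values
disagree by 0.01 kJ/mol through rounding are flagged rather than hidden.
Energies are computed in J/mol internally and reported in kJ/mol.

## Synthetic data

The generator emulates the study conditions: educt decay on the published
17-point (0–55 V) and sparse 8-point voltage grids, two replicate series
(one for the doubly biotinylated hetero-trimer), sigmoid parameters of the
four published courses as defaults, statistical release-channel branching
(n/3 for a subunit present n times), equal dimer/monomer detection within a
channel, and additive Gaussian noise in absolute % (default σ = 1 %)
truncated at zero and renormalized per scan. Identical seeds give
bit-identical tables. `emit_peak_tables` places one peak per species at its
calculated m/z with intensity proportional to its fraction, so
generator → peak tables → course reconstruction is an exact identity.

A second generator drives the educt fraction through the thermodynamic
forward model: K(T) = exp(−(ΔH−TΔS)/RT) is inverted to the educt fraction
via q = K/a and s = 1 + 2q − 2√(q²+q). Its defaults (ΔH = 160 kJ/mol,
ΔS = −93 J mol⁻¹ K⁻¹) are the values the default calibration recovers from
the canonical homo-trimer course, placing the simulated transition on the
study grid. Note that sub-10-kJ/mol enthalpies combined with negative
entropies cannot produce a visible transition under any monotone
temperature model with fraction-based quotients (K stays below e^{ΔS/R});
observable breakdown with those headline numbers requires the activity
scaling above.

What the synthetic tests show: the analysis chain exactly inverts both
generators without noise, and recovers the midpoint voltage within 2 % and
the generating enthalpy within a few percent at 1 % noise. What they do not
show: correctness of the temperature/activity calibration for a given
instrument, robustness to chemical noise, isotope envelopes, overlapping
charge states or detector saturation — none of which the generator emulates.

Known systematic: the truncate-at-zero + renormalize noise model distorts
courses slightly but systematically (plateau offsets of ~0.4 % at σ = 1 %,
fitted width biased by ~−2.5 %), which propagates into a ~2 % bias of the
recovered entropy term that does not average out over seeds; enthalpy
recovery stays within ~1 %.

## Problem sizes

Default analyses and tests run on the study-sized grids (17 + 8 voltages,
two replicates); Monte-Carlo checks use 50–100 seeds with 25-point grids.
A full four-complex analysis completes in well under a second.

## Limitations

Profile-mode spectra, centroiding, charge deconvolution, isotope patterns,
adduct/oxidation satellite modelling beyond summation, alternative sigmoid
families (Hill, Gompertz), multi-transition fits, and master-equation/RRKM
treatments of collisional activation are out of scope. The package does not
attempt to reproduce any particular instrument's absolute k#, ΔH# or TΔS#
values; those require the instrument's own conversion constants, supplied
through `ThermoConfig` or a custom temperature model.
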