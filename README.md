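# cidtherm

Breakdown-curve kinetics and quasi-thermodynamics of non-covalent protein
oligomer dissociation in the gas phase.

In native electrospray mass spectrometry, an intact non-covalent complex ion
(here: trimers of the T4 fibritin foldon miniprotein, with and without an
N-terminal biotin tail that mimics an intrinsically disordered region) is
isolated and subjected to collision-induced dissociation at a series of
collision cell voltage differences (ΔCV). The normalized educt-ion intensity
decays sigmoidally with ΔCV while the dimer and monomer product ions rise
complementarily. `cidtherm` turns such per-voltage peak tables into apparent
kinetic and quasi-thermodynamic quantities of the dissociation reaction,
extrapolated to ambient temperature. It is aimed at native-MS practitioners
who quantify relative complex stabilities from breakdown curves.

## Model

The educt breakdown course is fitted with a Boltzmann sigmoid

    y(ΔCV) = Final + (Initial − Final) / (1 + exp((ΔCV − ΔCV50)/dx)),

whose single midpoint tangent has the analytic slope −(Initial−Final)/(4·dx).
The ΔCV axis is converted to an effective ion temperature by equipartitioning
the centre-of-mass collision energy of an effective number of ion/gas
collisions over the ion's 3N−6 vibrational modes (N = atom number of the
complex, hence the need for exact elemental compositions). On the steep
region of the fitted curve each point yields

* a first-order rate constant k = −ln(S)/τ from the educt survival S and the
  collision-cell residence time τ, and
* a standard-state dissociation quotient K = a·(x_dimer·x_monomer/x_trimer)
  from the normalized mole fractions (a = effective ion activity).

Two linear extrapolations to T_amb = 298 K then give the five apparent
quantities: the Arrhenius line ln k vs 1/T yields k#; the Gibbs–Helmholtz
line ΔG(T) = −RT ln K vs T yields ΔH# (intercept) and ΔS# (−slope), whence
ΔG# = ΔH# − T_amb·ΔS# and KD# = exp(−ΔG#/(R·T_amb)). Both conversions are
instrument calibrations and are pluggable/configurable; see
`docs/methods.md`.

## Worked example

Simulate a two-replicate homo-trimer experiment at 1 % intensity noise and
analyze it (the same works on measured peak tables via
`cidtherm.course_io.read_peak_tables_csv` and `build_course`):

```python
import cidtherm as ct
from cidtherm.foldon import foldon_proteoforms, foldon_ions
from cidtherm.synthetic import study_spec, simulate_course

pf, ions = foldon_proteoforms(), foldon_ions()
course, _ = simulate_course(study_spec("F-F-F", noise_sd=1.0, seed=42))
res = ct.BreakdownModel(course, ions["F-F-F"], pf).fit()
print(res.summary())
```

prints

```
Breakdown-curve analysis
============================================================
educt ion:        F-F-F 5+
data points:      17 ΔCV settings, 2 replicate series

Boltzmann sigmoid (normalized educt % vs ΔCV)
------------------------------------------------------------
  initial       98.91 ± 0.303  [%]
  final          0.36 ± 0.267  [%]
  dcv50         16.95 ± 0.046  [V]
  dx             1.71 ± 0.042  [V]
  slope        -14.37  [%/V] (midpoint tangent)
  R²           0.9998

Extrapolated apparent quantities at 298 K
------------------------------------------------------------
  k#         3.27e-05  [1/s]   (Ea = 73.31 kJ/mol, R² = 0.9985)
  KD#        5.61e-33  [-]
  ΔG#          184.00  [kJ/mol]
  ΔH#          155.06  [kJ/mol]  (GH line R² = 0.9996)
  TΔS#         -28.94  [kJ/mol]

  residence time 0.0001 s; t0 300 K; collision gas 39.948 Da × 500 collisions
  check dg == dh - tds: Δ = +0.000 kJ/mol [ok]
  check dg == -R*T*ln(kd): Δ = +0.000 kJ/mol [ok]
```

The sigmoid parameters recover the generating course (midpoint 16.95 V vs
17.03 V true, within the noise). The extrapolated energies carry the expected
sign structure — dissociation of the trimer in the gas phase is endergonic
(ΔG# > 0), endothermic (ΔH# > 0) and entropically disfavored (TΔS# < 0) —
and the two internal identities (ΔG = ΔH − TΔS and ΔG = −RT ln KD) close to
machine precision. Absolute magnitudes are conditional on the
temperature/activity calibration (`ThermoConfig`); only comparisons made
under one calibration are meaningful.

The same workflow is available from the shell:

```sh
cidtherm simulate --out sim --educt F-F-F --seed 1
cidtherm extract  --peaks sim/peaks_FFF.csv --educt F-F-F --out course.csv
cidtherm analyze  --course course.csv --out analysis
```

`cidtherm species --out species.csv` writes the molecular-information table
(m/z, charge, atom number) of all nine oligomer species of the foldon /
biotinylated-foldon mixture; a custom mixture is described by a YAML file
(see `examples/foldon_species.yaml`).

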