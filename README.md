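# g4kit

Tools for processing biophysical characterization data of DNA
G-quadruplexes (G4): UV-melting thermodynamics, circular dichroism (CD),
native electrospray mass spectrometry (ESI-MS), imino-proton NMR
bookkeeping, and a small multi-technique results database with report
generation. A synthetic-data module emulates every supported input so the
entire pipeline is testable without instrument files.

## Scientific background

G-quadruplexes are four-stranded nucleic-acid structures built from stacked
guanine quartets. Their formation and topology are routinely characterized
by a standard panel of solution techniques, each of which has a small,
well-defined numerical core that this package implements:

- **Extinction coefficient and concentration** (`g4kit.seqcore`).
  Single-strand concentrations are obtained from A260 via the
  nearest-neighbor extinction coefficient
  ε260 = Σᵢ ε(doublet i,i+1) − Σᵢ ε(monomer i, interior), with the
  standard nearest-neighbor coefficient table shipped as package data.
  Then C = A / (ε·l).

- **CD normalization and stacking classification** (`g4kit.cd`).
  Blank-subtracted ellipticity θ (mdeg) is converted to molar circular
  dichroism Δε = θ / (32980 · C · l). Spectra are classified by the
  classic empirical band signatures: parallel (type I) +265/−245 nm,
  hybrid (type II) +270 and +290/−245 nm, antiparallel (type III)
  +290/−260 nm, via a deterministic window-based rule.

- **UV-melting thermodynamics** (`g4kit.melting`). Absorbance curves are
  fit to the two-state model with sloped linear baselines,
  A(T) = (a_F·T + b_F)·θ(T) + (a_U·T + b_U)·(1 − θ(T)), where the folded
  fraction is θ = 1/(1+K) and K = exp(−ΔH°·(1 − T/Tm)/(R·T)) (ΔH° is the
  unfolding enthalpy at Tm, R = 8.314 J mol⁻¹ K⁻¹). The fit returns Tm,
  ΔH° and the four baseline coefficients, plus θ at any temperature
  (e.g. θ at 25 °C). When a baseline is missing from the scanned range
  the fit is flagged and a [0, 1] min–max normalization fallback is
  provided instead of reporting unreliable thermodynamics.

- **Native MS species annotation** (`g4kit.ms`). Specific potassium
  binding is read from [M + bK − (z+b)H]ᶻ⁻ adduct peaks:
  m/z = (M + b·(m_K − m_H) − z·m_H)/z, so consecutive adducts at charge z
  are spaced by (m_K − m_H)/z. Peaks are matched within a ±1 Th window,
  relative abundances are reported per charge state (default 5−), and the
  quartet count is inferred from the "b specific K⁺ ⇒ b+1 quartets" rule.
  Includes fraction-of-base-peak intensity filtering and arrival-time
  distribution (ATD) extraction for ion-mobility data.

- **Imino-proton accounting** (`g4kit.nmr`). A folded quadruplex with n
  quartets shows up to 4n guanine imino protons at 10.5–12 ppm. The module
  crops the imino window, picks peaks above a robust noise floor (5×MAD),
  and matches them against published chemical-shift assignments.

- **Database, workbook import, reports** (`g4kit.database`,
  `g4kit.report`). Results for oligonucleotide × buffer conditions are
  consolidated from a templated XLSX workbook, filterable by sequence,
  family, topology or buffer composition, serialized losslessly to a
  versioned CSV archive, and rendered to HTML/Markdown reports with
  inline plots. A 28-sequence reference panel (10 of them human-telomeric
  variants) ships as a packaged fixture.

- **Synthetic data** (`g4kit.synthgen`). Seeded generators for melting
  curves (two-state + Gaussian noise), CD spectra (Gaussian bands per
  stacking type), mass spectra (Gaussian peaks at predicted adduct m/z
  over a noise floor), Lorentzian imino traces and Gaussian ATDs.

## Worked example

```python
from g4kit.seqcore import epsilon260, concentration_from_A260
from g4kit.melting import fit_two_state, theta_at_25
from g4kit.ms import annotate, intensity_filter, infer_quartets
from g4kit.synthgen import make_melting_curve, make_mass_spectrum

TEL24 = "TTGGGTTAGGGTTAGGGTTAGGGA"   # human telomeric variant (PDB 2GKU)

# 1. Concentration from absorbance
eps = epsilon260(TEL24)
print(eps)                                  # 244300.0  (M^-1 cm^-1)
print(concentration_from_A260(0.35, eps))   # 1.4326647564469913e-06  (M)

# 2. Melting thermodynamics (synthetic curve, Tm 41 degC, dH0 180 kJ/mol)
curve = make_melting_curve(Tm_K=314.15, dH0_J_mol=180e3, sigma=0.002, seed=11)
fit = fit_two_state(curve)
print(fit.Tm_C)             # 41.090225183572215
print(fit.dH0_J_mol / 1e3)  # 181.49405329331458
print(theta_at_25(fit))     # 0.9769959614506168

# 3. Native MS potassium stoichiometry at the 5- charge state
spec = make_mass_spectrum(TEL24, abundances={(0, 5): 8.0, (1, 5): 17.0,
                                             (2, 5): 75.0},
                          noise_floor=0.002, seed=3)
spec = intensity_filter(spec, 0.005)
for s in annotate(spec, TEL24):
    print(s.label, round(s.expected_mz, 2),
          round(s.relative_abundance, 1), infer_quartets(s.b))
# [M+0K]5- 1513.97  8.0 unfolded/no core
# [M+1K]5- 1521.59 17.0 2
# [M+2K]5- 1529.21 74.9 3
```

The dominant 2 K⁺ species at ~75% indicates a three-quartet fold.

## Command line

The `g4kit` entry point groups the same operations as subcommands:

```bash
g4kit epsilon TTGGGTTAGGGTTAGGGTTAGGGA
g4kit cd-normalize --sample s.csv --blank b.csv --conc 1e-5 --path 0.2
g4kit melt fit --input melt.csv
g4kit ms-annotate --spectrum spec.csv --seq TTGGGTTAGGGTTAGGGTTAGGGA
g4kit db template panel.xlsx        # write the templated workbook
g4kit db import panel.xlsx outdir   # import and archive
g4kit db report archive 2GKU --format html
g4kit simulate melting --seed 1 --out curve.csv
```

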