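# Methods

Models, parameter choices and numerical details for `g4kit`. All defaults
quoted here are the code defaults; every one can be overridden per call.

## 1. Extinction coefficient and concentration (`seqcore`)

The 260 nm molar extinction coefficient of a single-stranded
oligodeoxynucleotide is computed with the nearest-neighbor approximation

ε260 = Σ_{i=1..N−1} ε(b_i b_{i+1}) − Σ_{i=2..N−1} ε(b_i),

using the standard nearest-neighbor coefficient table (16 doublet and 4
monomer values, M⁻¹ cm⁻¹, 25 °C, neutral pH), shipped as
`g4kit/data/epsilon_cws260.tsv` and validated for completeness at load
time. For N = 1 the monomer value is returned with a warning (the
nearest-neighbor sum is undefined). Concentration follows from Beer's
law, C = A260/(ε·l), with path length defaulting to 1 cm.

*Assumption*: the coefficient refers to the unfolded single strand;
folded G4s are hypochromic at 260 nm, so concentrations should be
determined on thermally denatured samples. The code does not correct for
folding.

## 2. Circular dichroism (`cd`)

Ellipticity spectra in mdeg are blank-subtracted (with linear
interpolation onto the sample grid when the blank grid differs; disjoint
grids are an error) and converted to molar circular dichroism

Δε = θ / (32980 · C · l)   [M⁻¹ cm⁻¹],

where θ is in mdeg, C in mol/L and l in cm. The constant 32980 combines
the mdeg→deg factor and the ellipticity→absorbance conversion
(32.980 = 100 · ln 10 · 180/(4π) / 1000, the conventional value).

### Stacking classification

The classifier is a deterministic window rule on a Δε spectrum covering
at least 230–310 nm:

| class | positive band(s) | negative band |
|---|---|---|
| parallel (type I) | 255–275 nm | 240–250 nm |
| hybrid (type II) | 255–275 nm **and** 285–295 nm | 240–250 nm |
| antiparallel (type III) | 285–295 nm | 255–265 nm |

A band counts when its window extremum exceeds `secondary_fraction`
(default 0.20) of the global |max|. Spectra whose global |max| is below
`noise_floor` (default 0.5 Δε units) are `ambiguous`, as is any spectrum
matching no rule. The hybrid rule is checked first because its 270 nm
band also satisfies the parallel positive window. Before window extrema
are read, the signal is smoothed with a Gaussian kernel of 2 nm
bandwidth — small against the ≥10 nm width of G4 CD bands, but enough to
keep single noisy points in the 290 nm window from mimicking a hybrid
shoulder. With synthetic spectra at signal-to-noise 10 the classifier
recovers the generating label in 60/60 seeded trials
(`cd_classifier_accuracy_snr10 = 1.0` in `results/acceptance.json`).

*Limitation*: these signatures are empirical heuristics; unusual loop
arrangements and mixtures can defeat them, which is why the classifier
returns `ambiguous` rather than guessing.

## 3. UV-melting thermodynamics (`melting`)

The absorbance of a monomolecular two-state equilibrium with sloped
linear baselines is

A(T) = (a_F·T + b_F)·θ(T) + (a_U·T + b_U)·(1 − θ(T)),
θ(T) = 1/(1 + K(T)),
K(T) = exp(−ΔH°·(1 − T/Tm)/(R·T)),

with T in kelvin, R = 8.314462618 J mol⁻¹ K⁻¹ (`scipy.constants.R`) and
ΔH° the van't Hoff unfolding enthalpy at Tm (positive; ΔS° is implicit
via ΔS° = ΔH°/Tm, i.e. ΔCp = 0). At T = Tm, K = 1 and θ = 1/2 exactly;
the folded and unfolded mixing weights 1/(1+K) and K/(1+K) sum to one
identically.

### Fitting

Six free parameters (Tm, ΔH°, a_F, b_F, a_U, b_U) are fit with `lmfit`
least squares (trust-region reflective, `xtol=ftol=gtol=1e-10`, max 5000
evaluations). Initial guesses: Tm at the extremum of the smoothed |dA/dT|
curve; baselines from ordinary least squares over the first and last 15%
of points; ΔH° = 200 kJ/mol (typical G4 magnitude). The exponent is
clipped at ±700 to avoid overflow; this cannot affect any observable
region (θ is 0 or 1 to machine precision long before then). Fewer than 20
points is an error; a non-converged optimizer result is returned flagged
(`converged=False`), not raised.

On noiseless synthetic curves all six parameters are recovered to ~1e-13
relative; with σ = 0.002 absorbance noise (typical instrument level) the
median |ΔTm| over 100 replicates is ≈0.05 K and the median relative ΔH°
error ≈0.8% (see `results/acceptance.json`).

### Baseline guard and normalization fallback

Thermodynamic parameters from a melting curve are only meaningful when
both folded and unfolded baselines are sampled. `has_both_baselines`
declares a baseline missing when the initial Tm estimate lies within 10%
of the scanned range of either edge, or either baseline segment has fewer
than 5 points. In that case the fit is flagged
(`baselines_ok=False`, `no_thermodynamics=True`) and `normalize_curve`
provides a min–max [0, 1] normalization as the honest fallback
(monotone affine invariant; constant curves are an error).

`hysteresis` flags heating/cooling Tm differences above 1 K, the usual
indicator that the ramp outpaced equilibration and the two-state
equilibrium model does not apply.

## 4. Native ESI-MS (`ms`)

### Masses

Neutral average/monoisotopic masses of linear DNA are assembled from
nucleoside elemental compositions (dA C₁₀H₁₃N₅O₃, dC C₉H₁₃N₃O₄,
dG C₁₀H₁₃N₅O₄, dT C₁₀H₁₄N₂O₅) plus (N−1) phosphodiester linkages
(+HPO₃ −H₂O), evaluated with the `pyteomics` NIST mass tables. The
package's own contribution is the composition bookkeeping; element masses
are not re-derived. The test suite checks the result against an
independent frozen table of IUPAC standard atomic weights.

### Species m/z and annotation

A quadruplex retaining b specific K⁺ observed at charge z is
[M + bK − (z+b)H]ᶻ⁻ with

m/z = (M + b·(m_K − m_H) − z·m_H)/z,

so consecutive adducts at fixed z are spaced by (m_K − m_H)/z — at z = 5,
7.6181 Th. Annotation sums intensity in a ±`tolerance_Th` (default 1.0)
window around each predicted m/z, attributing each point to the nearest
window center when windows overlap (and warning). Relative abundances are
percentages within one charge state (default 5−, the charge state where
nonspecific adducts are minimal in ammonium-based buffers); species with
zero matched intensity are retained so absences are explicit. The quartet
count follows the "b specific K⁺ ⇒ b+1 quartets" rule; b = 0 is reported
as "unfolded/no core".

Intensity filtering removes points strictly below a given fraction of the
base peak (ties retained, hence idempotent; the base peak itself always
survives). On synthetic spectra with Dirichlet-random (0K, 1K, 2K)
abundances, a 0.5% filter followed by re-annotation recovers the
generating percentages to ≤0.2% absolute over 50 replicates, and reported
abundances always sum to 100.

### Ion mobility

`extract_atd` marginalizes long-format (arrival time, m/z, intensity)
triples over a chosen m/z window to give the arrival-time distribution of
one species; a disjoint window is an error.

*Limitation*: abundances are point sums, not fitted peak areas; with
well-resolved Gaussian peaks and a common peak width the two agree, but
strongly overlapping adducts at low charge states would require explicit
peak fitting, which is out of scope.

## 5. Imino-proton NMR (`nmr`)

Guanine imino protons of a folded quadruplex resonate at 10.5–12 ppm
(4 per quartet); the module crops a 9.5–12.5 ppm window, picks peaks with
`scipy.signal.find_peaks` above a floor of 5× the median absolute
deviation of the trace (robust to the sparse-peak baseline), and matches
them to published assignments greedily, closest pair first, within
0.02 ppm. Unmatched picked peaks are reported as minor/unassigned
species; a trace with no peaks above the floor is flagged. No spectral
processing (phasing, baseline, solvent suppression) is attempted — inputs
are assumed processed by instrument software.

## 6. Database, workbook and reports (`database`, `report`)

A `Database` holds oligonucleotides (identity, 5′→3′ sequence, origin,
family, topology annotations, star rating), buffer compositions, and
records keyed by oligonucleotide × buffer with per-technique datasets
(cd, melting, nmr, ms, ims). Input is a templated XLSX workbook (one
metadata sheet `oligos`, one sheet per technique); malformed rows are
rejected individually and collected in `import_errors` with their row
numbers, while technique rows referencing unknown oligonucleotides are a
hard error (silent data loss would be worse). A 28-sequence reference
panel, 10 of them human-telomeric variants, ships as packaged CSV and is
also written into the template workbook.

Archives are versioned directories (`manifest.json` with
`schema_version`, plus tidy CSVs). Floats are written with the `%.17g`
format and read back with pandas `float_precision="round_trip"`, which
makes save/load bit-faithful (verified to exact equality in tests).
Unknown schema versions are refused explicitly rather than guessed at.

Reports (HTML or Markdown, jinja2 templates, matplotlib SVG panels
inlined) show one section per condition with all five technique panels;
missing techniques render an explicit "not available" placeholder rather
than being dropped.

## 7. Synthetic data (`synthgen`)

All generators take a `seed` and use `numpy.random.default_rng`, so any
dataset is exactly reproducible.

- **Melting**: exact two-state model (§3) plus i.i.d. Gaussian absorbance
  noise (default σ = 0.002, a realistic spectrophotometer level);
  defaults Tm = 328.15 K, ΔH° = 200 kJ/mol, sloped baselines, 4–90 °C in
  0.5 °C steps.
- **CD**: sums of Gaussian bands (σ = 8 nm) at the signature positions of
  §2, 220–320 nm, plus Gaussian noise. Band widths and positions are
  stylized, not instrument-accurate; they are adequate for exercising the
  classifier, not for simulating real lineshapes.
- **MS**: Gaussian peaks (σ = 0.15 Th) at the predicted adduct m/z with
  areas proportional to requested abundances, over a uniform noise floor.
  Real ESI peaks carry isotope structure and tailing; this generator
  checks the annotation arithmetic, not instrument realism.
- **NMR**: Lorentzian lines (the natural NMR lineshape) at given
  (ppm, amplitude, width) plus noise.
- **IMS**: Gaussian arrival-time components in long format.

## 8. Open design decisions

- Temperatures are stored in °C as measured; kelvin conversions use
  273.15 exactly. Thermodynamics are always computed in kelvin.
- Whether reported melting temperatures derive from heating, cooling or
  their average varies between laboratories; the fit takes whatever curve
  it is given and `hysteresis` makes the heating/cooling comparison
  explicit instead of hiding a convention.
- The star rating of a structure's biological relevance is stored as an
  annotation only; no numerical judgment is computed from it.
- The classifier thresholds (0.20 secondary fraction, 0.5 Δε noise
  floor, 2 nm smoothing) are choices validated against the synthetic
  generator, not fitted to experimental corpora.

## 9. Limitations

- No multi-state or ΔCp ≠ 0 melting models; curves with intermediates
  will show systematic residuals and should not be trusted to two-state
  parameters.
- MS abundances assume response factors are equal across K⁺ stoichiometries
  at a given charge state.
- Collision-cross-section calibration and 3D structure comparison are out
  of scope; only ATD extraction is provided.
- NMR support is bookkeeping on processed traces, not spectral
  processing or structure determination.
- The reference-panel fixture carries literature annotations (topology,
  Tm, K⁺ stoichiometry) for browsing and filtering; the package does not
  re-derive them, and the acceptance test that would re-derive four of
  them from deposited experimental traces (`data/deposited/`) fails until
  that dataset is downloaded into place.
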