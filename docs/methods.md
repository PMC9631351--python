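# Methods

This note documents the models, defaults and numerical choices behind
`isofine`, and what the synthetic-data tests do and do not demonstrate
about real instrument data.

## Estimator

For an immonium ion with composition `C_nC H_nH N_nN O_nO`, isotopic
substitution is modelled as independent per atomic site. With `r_X` the
heavy/light isotope ratio of element X and `a_X = r_X/(1+r_X)` the
per-site heavy fraction, the abundance of a fine-structure line with
`k_X` substitutions, relative to the all-light (monoisotopic) line, is
exactly

    A(line)/A(M) = prod_X C(n_X, k_X) · r_X^k_X

so a single substitution gives `n_X·r_X` and a same-element double
substitution gives `C(n_X,2)·r_X²`. Inverting the single-substitution
identity yields the per-spectrum estimator `r̂_X = A(M+1,X)/A(M)/n_X`
(`r̂_O` from the M+2 ¹⁸O line). This is exact under the independence
assumption, not a truncated expansion; truncation only enters in that
shells above M+2 (≲10⁻⁵ of the ion population at natural abundance) are
ignored.

Hydrogen is special: the ionizing proton and heteroatom-bonded
hydrogens exchange with the solvent. Internally these sites form a
second hydrogen class (`Hx`), so the measured M+1 deuterium line has
relative abundance `h_cb·r_cb + h_exch·r_solv`; the affine correction
`r_cb = (h_tot·r_raw − h_exch·r_solv)/(h_tot − h_exch)` recovers the
C-bonded level exactly within this model. Default solvent ²H/¹H is
150 ppm (typical reported range 140–150 ppm), configurable per design
row.

## m/z conventions

The registry stores immonium cations as neutral-radical formulas (Pro =
C4H8N). Under the **H-atom convention** (no electron-mass subtraction)
the registry reproduces the reference values used in practice
(70.0656/86.0606/72.0813 for the Pro/Hyp/Val immonium ions, and MH⁺ =
neutral + H at 116.0712/132.0661/118.0868). The physical-cation
convention differs by exactly one electron mass (−0.00055 Da, ≈7.8 ppm
at m/z 70 — more than the 5 ppm lookup tolerance, so lookup and data
must use the same convention). Both peak lookup and the simulator
default to `h_atom`; both accept `cation_physical`.

Exchangeable-H counts are not tabulated in standard references for
immonium ions; the defaults derive from the H₂N⁺=CHR structure
(Pro h_exch=1 for its cyclic iminium N–H; Hyp 2 = N–H + O–H; Val,
Leu/Ile, Phe 2 = two N–H). They are editable in the species table.
Leu and Ile are one species ("Leu/Ile"): their immonium ions are
isobaric and indistinguishable here. Gly and Ala are registered but
flagged out-of-range (their immonium m/z of 30 and 44 fall below the
m/z 50 low-mass cutoff of the acquisition range).

## Resolution model and peak fitting

Orbitrap-type resolving power falls as the inverse square root of m/z:
`R(m/z) = R₀·sqrt(200/m/z)`, FWHM = m/z / R(m/z); R₀ defaults to the
nominal 60,000 setting. Peaks are Gaussian (no Lorentzian tails) — at
the sub-mDa spacings involved, area *ratios* are insensitive to the
tail family, and the shape is pluggable in principle.

Extraction per spectrum and species:

1. find the monoisotopic apex within a 5 ppm tolerance of the expected
   m/z (optionally pre-corrected by a run-level median mass offset,
   `run_mass_offset`);
2. refine the apex to a sub-grid centroid by a log-parabola (exact for
   a noiseless Gaussian) and anchor all fine-structure lines at the
   *observed* centroid plus exact isotope mass-difference offsets
   (¹³C−¹²C = 1.00335, ¹⁵N−¹⁴N = 0.99703, ²H−¹H = 1.00628,
   ¹⁸O−¹⁶O = 2.00424 Da) — this cancels calibration offsets common to
   the whole spectrum;
3. fit each shell by non-negative linear least squares of
   fixed-position, fixed-width Gaussians (widths from the resolution
   model); area = amplitude·σ·√(2π). The M+2 fit always includes the
   ¹³C₂, ¹³C¹⁵N and ¹³C²H (and other combination) nuisance components
   so the ¹⁸O amplitude is not inflated;
4. flag components: `below_noise` when the fitted amplitude is under
   3× the local noise floor, `unresolved` when a neighbor closer than
   κ·FWHM (κ = 1.0) has a prior abundance ≥ 1 % of the component's own.
   The 1 % weighting matters: the negligible ¹⁵N²H line sits 0.96 mDa
   from ¹⁸O (≈1 FWHM at m/z 88) and would otherwise spuriously
   disqualify the ¹⁸O measurement, while a merged neighbor at <1 %
   biases an area by less than the shot-noise floor. Flagged components
   yield absent ratios and are excluded from statistics.

The noise floor is the 84.1−50 inter-percentile distance of a
signal-free strip (M+0.30…M+0.70 Da), which estimates the baseline σ
correctly both for plain Gaussian noise and for profiles clipped at
zero intensity. Monoisotopic detection requires a 5σ apex.

## Statistics

A "datapoint" is one (scan, species) ratio record. Per replicate,
records are trimmed at median ± 5 MAD (full-profile mode retains noise
spikes; threshold configurable, `mad_k=None` disables) before
mean/median/SD/SEM. The headline statistic is the mean; medians are
always carried alongside. Between-replicate CV = SD/mean of replicate
means × 100. The precision-vs-datapoints curve subsamples k records
without replacement per (replicate, species) — so each analyzed
distribution has exactly k datapoints — and averages the resulting CVs
over draws, species and the elements C, N, H; on shot-noise-limited
data it falls as k^(−1/2). The deuterium-incorporation degree is 100×
the OLS slope of the C-bonded ²H/¹H (ppm) on the media ²H content
(ppm). δ-standards default to VSMOW (²H/¹H = 1.5576·10⁻⁴,
¹⁸O/¹⁶O = 2.0052·10⁻³), VPDB (¹³C/¹²C = 1.11802·10⁻²) and AIR
(¹⁵N/¹⁴N = 3.6765·10⁻³); an interim multiplicative correction per
element can be applied by the user where absolute accuracy matters.

## Simulator

The forward model emulates the wide-isolation HCD acquisition: exactly
`AGC × microscans` ions per reported spectrum (defaults 5·10⁴ × 20),
allocated multinomially over species (molar abundances) and over
isotopologue lines up to M+2, with carbon-bonded and exchangeable
hydrogen at separately planted deuterium levels. Summing the fills
before the draw is statistically identical to drawing each microscan
separately, since a sum of independent multinomials with equal
probabilities is multinomial. Each line renders as a Gaussian with the
model FWHM at positions scaled by a calibration offset plus per-scan
jitter (default 0 ± 0.2 ppm); one ion contributes unit area per
microscan. Profiles are rendered on windows [m/z−1.0, m/z+2.6] around
each species at FWHM/8 spacing (≥5 points per FWHM), merged when
overlapping; additive Gaussian baseline noise (SD 0.1 ion-equivalents)
is clipped at zero as in real profile data. Every line's exact ion
count goes to a ground-truth ledger.

Scenario defaults follow the study conditions: direct infusion =
constant Pro/Hyp/Val mixture at the rounded natural abundances (1.1 %
¹³C, 0.37 % ¹⁵N, 150 ppm ²H, 0.2 % ¹⁸O, available as the
`rounded_natural` abundance set next to the IUPAC-derived `natural` one);
titration = 10 media levels linearly spaced 150→1000 ppm (the level
spacing is not specified anywhere, so an even grid is used), 3
replicates, incorporation 0.04 (Leu/Ile) and 0.15 (Pro), exchangeable
sites pinned at the 150 ppm LC solvent; depletion = ¹³C/20 and ¹⁵N/10
below natural with 80 ppm C-bonded ²H. Experiment sizes in the test
suite and the acceptance script (300 scans per titration run, 600 for
the subsampling control so that k = 500 draws are possible) are the
package's scaled stand-ins for multi-hour acquisitions; a scan every
2 s is assumed for retention-time metadata.

**What the simulator does not model:** chimeric co-isolation background
(chemical background invisible in FT spectra, which defeats
internal-standard designs in practice), space-charge coalescence,
resolution-dependent systematic biases, centroiding artifacts, and
Lorentzian tails. Passing recovery tests therefore demonstrates the
correctness of the estimator and fitting chain under shot-noise-limited
conditions, not immunity to those instrument effects; on real data the
TIC-trend diagnostic and the QC flags are the first line of defense.

## Numerical choices and degenerate inputs

- NNLS (scipy) for shell fits: non-negativity prevents negative-area
  cancellation between overlapping components; with well-separated
  components it reduces to independent projections.
- A plain ±2σ numerical-integration fallback is intentionally *not* the
  default; it is equivalent only for fully separated components.
- Empty spectra, blanks and species outside the detected m/z range
  produce explicit "not found"/skip reasons, never silent zeros.
- Scan metadata missing from an mzML file stays `None`; scan selection
  treats missing values as failing only criteria that are restrictive.
- CSV serialization uses `repr` floats (shortest exact round-trip), so
  write→read is bit-identical.
- All randomness flows through `numpy.random.Generator` seeded from
  user-supplied integers via `SeedSequence.spawn`; fixed seeds give
  byte-stable CSVs and reports.

## Known limitations

- Only shells M…M+2 and one heavy isotope per element (¹⁷O is carried
  in the table but not estimated); no general fine-structure prediction
  beyond that, no peptide b/y-ion masses, no charge >1 fragments.
- No Thermo .raw reading (convert with MSConvert) and no mzXML/MGF.
- The mzML layer targets mzML 1.1 with uncompressed or zlib binary
  arrays; numpress compression is not supported.
- Hyp vs Leu/Ile immonium ions are 0.036 Da apart — fully separate
  peaks at the resolutions considered, so no disambiguation logic
  exists.
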