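# Methods

`acidscale` reconstructs acidity scales in low-permittivity solvents from
three kinds of raw measurement: UV-vis spectra of jointly titrated acid
pairs, differential-potentiometry traces of solution pairs, and external
anchor values (computational pKa values, bridging-solution unified pH).
The working solvent throughout the defaults is 1,2-difluorobenzene
(1,2-DFB, relative permittivity 13.4), but every constant is a parameter.

## Spectral titration and unmixing

Two acids HA1 and HA2 share a cuvette and are titrated stepwise with a
strong, UV-transparent base.  Under Beer-Lambert additivity each recorded
mixture spectrum is a linear combination of four previously recorded
pure-form spectra (HA and A- of both acids).  Each mixture column is
regressed on the four basis columns by plain linear least squares over
the full wavelength grid (uniform weighting; no weighting scheme is
claimed by the measurement method, and the information content is
dominated by the distinct band shapes).  The dissociation degree of acid
*i* is the coefficient ratio

    alpha_i = c(A_i-) / (c(HA_i) + c(A_i-)),

which cancels titrant dilution, so explicit volume tracking is
unnecessary.  Each spectrum with both alphas inside the inclusion window
yields one estimate of

    Delta pK_ip = log10[ alpha_1 (1 - alpha_2) / (alpha_2 (1 - alpha_1)) ],

and the pair value is the unweighted mean over usable spectra (median
selectable); the spread column reports their sample standard deviation.

Numerical choices:

* **Inclusion window** `[0.05, 0.95]` on both alphas.  Near the
  endpoints the log-ratio variance diverges, so endpoint spectra are
  flagged unusable rather than entering the estimate.
* **Conditioning guard.**  The stacked basis must have condition number
  below 1e8 (configurable); a nearly collinear pair raises an error
  naming the offending basis rather than returning meaningless
  coefficients.
* **Nonnegativity** is off by default (the regression is the same plain
  multilinear one used during measurement processing); an NNLS option
  exists for noisy data.  With plain least squares, a coefficient more
  negative than 5% of the acid's total signal flags the point instead of
  being clipped.
* **Baseline term** (flat offset regressor) is available but off by
  default; baseline drift is not part of the assumed data model.

## Ion-pairing correction (Fuoss model)

At epsilon_r = 13.4 deprotonation yields ion pairs, so the measured
quantity is the ion-pair acidity difference.  Conversion to the free-ion
scale uses Delta pK_a = Delta pK_ip + Delta pK_d, with Delta pK_d from
the Fuoss sphere-in-continuum expression evaluated literally in CGS
units (q = 4.80e-10 cm^3/2 g^1/2 s^-1, k = 1.38e-16 cm^2 g s^-2 K^-1,
N = 6.02e23 mol^-1) to avoid silent unit-conversion errors; public
interfaces take angstroms and kelvin.  The interion distance is the sum
of the anion and cation radii, each the arithmetic mean of up to three
estimators (sphere-volume, bounding-cuboid, surface-centroid); missing
estimators fall back to the mean of those present, with a warning.
Default temperature is 297.25 K (the 24.1 C at which the titrations are
assumed to run); the default counterion is the protonated phosphazene
t-BuP1(pyrr)3 cation, overridable per edge for salts with
tetraalkylammonium counterions.

For realistic ion sizes (delocalized organic anions 3.5-5.5 A, the bulky
phosphazenium cation 4.5-5.5 A) the correction magnitude stays below 0.2
units, and this is enforced as a soft warning on user data, not an
assertion.  No shape correction for nonspherical ions is applied; since
the measurements are relative and concentrations low, residual over- or
undercompensation shifts individual compounds without stretching the
scale.

## Ladder least squares

Scale values are assigned by minimizing the sum of squared differences
between each measured pairwise delta and the corresponding assigned
difference, with anchors pinned.  The solver builds the incidence system
of the measurement graph and solves it by SVD-backed least squares
(equivalent to the normal equations, with a pseudo-inverse fallback);
disconnected graphs raise an error listing the components rather than
fitting them separately.  The consistency standard deviation is
s = sqrt(SS / (n_m - n_c)).

* **Degrees-of-freedom convention.**  n_c defaults to the number of
  freely fitted parameters: nodes minus pinned anchors, plus one for the
  offset in offset/bridging mode.  The alternative reading (count every
  assigned value) is exposed as `nc_counts_anchors=True`; with it, an
  exactly determined system reports s as undefined rather than 0.
* **Anchoring.**  `fixed_single` pins one node (a relative scale);
  `offset_multi` fits a gauge-fixed relative scale and shifts it by the
  mean difference to the external anchor values, which is the exact
  minimizer of the squared anchor misfit (assumed unweighted);
  `bridging` is the same machinery with bridging-solution unified-pH
  anchors.
* **Exclusion.**  Measurement series inconsistent with the rest of the
  graph by at least 0.75 units (default) are removed iteratively, worst
  absolute residual first, ties by input order, refitting after each
  removal and stopping if a removal would disconnect the graph.
  Excluded edges stay in the edge report, flagged.  Note that least
  squares dilutes an outlier's residual by roughly its leverage, so on
  sparse graphs a genuinely bad series can sit below any fixed cutoff;
  the tests characterize this.
* **Reporting** rounds scale values to 1 decimal; full precision is kept
  internally and in the machine-readable outputs.

## Potentiometry

A trace is the potential difference between two glass electrodes in two
solutions joined by an ionic-liquid salt bridge, sampled nominally every
10 s for at least an hour.  The most stable 15-minute window (minimum
standard deviation; windows defined over time so +-2 s cadence jitter is
tolerated) is averaged; drift is the least-squares slope over that same
window, in mV/h.  A series passes QC only if the window standard
deviation is under 1 mV and |drift| under 4 mV/h; the drift criterion is
applied window-locally.  The potential difference converts to
Delta pH_abs through the mean calibration slope (-58.35 mV per pH unit
by default).  The cell orientation does not itself fix the sign, so each
trace carries an explicit polarity tag; with polarity +1,
Delta E = +58.35 mV means the first solution is one pH unit more acidic.

The Delta pH_abs measurements feed the same ladder solver in bridging
mode, anchored by two bridging solutions of known aqueous-aligned
unified pH: acetonitrile / aqueous pH 4 formate buffer 60/40 (6.0) and
10 mM ammonium formate in ethanol (8.9).  The combined standard
uncertainty of anchored values is the root sum square of the bridging
reference uncertainty (0.13), the liquid-junction cancellation term
(6.3 mV -> 0.11) and the scale consistency; with consistency 0.30 this
gives 0.34, reported conservatively as 0.4 (rounded upward).

## Cross-solvent transfer and recommended values

Compounds measured in both the working solvent and a source solvent
(acetonitrile or 1,2-dichloroethane) define an unweighted OLS line
(implemented via `scipy.stats.linregress`; slope/intercept standard
errors, residual standard deviation with n-2 degrees of freedom by
default - plain RMSE selectable - and r^2 as the squared Pearson
correlation).  Predictions outside the fitted abscissa range carry an
extrapolation flag.  The packaged regressions are fitted on the printed
(1-2 decimal) table values; coefficients refitted from full-precision
scale values can differ in the last printed digit, which is why the
slope checks in the tests allow one unit in the second decimal.

Recommended values: with estimates from both source solvents, the
recommendation is their average and the uncertainty is
max(baseline, |difference|/2 + 0.1); with one source, the lone estimate
with uncertainty 1.0.  The baseline is the RMS of the dual-source
individual uncertainties over the input table (0.5 for the packaged
table); a fixed override reproduces that convention on any input.  All
reported values and uncertainties are rounded half-away-from-zero to one
decimal - the convention that matches the printed tables except for a
handful of exact .x5 cells, which are documented rather than replicated.

Literature alignment: a scale anchored elsewhere is shifted by the
offset of a shared reference compound (offset rounded to one decimal
before application), preserving pairwise differences up to the final
rounding.

## Unified pH from pKa

For an equimolar acid/salt buffer the solvent-scale pH is taken equal to
the acid's pKa - an ideal-solution assumption that deliberately ignores
activity corrections, homoconjugation and ion aggregation (aggregation
is the leading explanation for systematic differences from
potentiometric values, and is reported, not modeled).  Alignment to the
aqueous scale adds the constant transfer term
(dG_solv_w - dG_solv_s)/(R T ln 10); with the defaults (-1105 and -899
kJ/mol, 298.15 K - the temperature is fixed here even though parts of
the experiment run at 24.1 C, and is configurable) the shift is -36.09
units.  The conversion is affine with unit slope, so differences of
converted values are exactly differences of pKa values, and an
uncertainty u_G on either solvation energy maps to u_G/(R T ln 10) pH
units (10 kJ/mol -> 1.75).

## Synthetic data

The generators produce inputs with the statistical structure each stage
assumes, at the study's stated conditions:

* **Ladder**: default 33 nodes and 64 edges (the dimensions of the
  measured scale) spanning 15.6 units, Gaussian edge noise 0.07; a
  random spanning tree guarantees connectivity, extra edges pair random
  nodes, and optional outlier edges shift by a planted magnitude.  Truth
  is returned for recovery tests.
* **Titration**: total concentrations 1e-4 mol/L, 12 steps, absorbance
  noise 0.002; per-form absorptivities are sums of 1-3 Gaussian bands
  (peak ~1e4 L mol^-1 cm^-1, redrawn until the 4-form basis condition
  number is below 1e4).  Per-step dissociation states come from the
  exact two-acid equilibrium: the proton-transfer constraint fixes the
  alpha log-ratio and strong-base mass balance closes the system, solved
  by Brent root finding to ~1e-12.  The generator works on the ion-pair
  acidity level; Fuoss corrections apply downstream as for real data.
* **Trace**: baseline + drift + white noise at 10 s cadence, 1 h
  duration, noise 0.3 mV.

What the generators do **not** emulate - and hence what passing
recovery tests cannot show about real data: homoconjugation and triple
ions, wavelength-correlated (non-white) spectral noise, electrode
drift with structure beyond a linear trend, day-to-day systematic shifts
that bias whole measurement series coherently, and anchor values whose
errors correlate across compounds.  Systematic scale compression or
expansion is invisible to the consistency parameter by construction.

## Problem sizes in the checked runs

The packaged-table computations are closed-form and instantaneous.  The
synthetic checks use 25-100 seeded replicates of the 33-node/64-edge
graph, 12-step/200-wavelength titrations, and 1-hour traces; the full
test suite runs in a few seconds on one CPU.

## Known limitations

* Anchor pKa computation (DFT/COSMO-RS level) is out of scope; anchor
  values are inputs, and their large uncertainty (at least ~2 units for
  absolute values) passes through to any absolute reading of the scale.
* The consistency parameter is a within-scale scatter estimate only; it
  does not cover anchoring uncertainty and averages over heterogeneous
  measurement quality.
* Ion radii for real compounds are user inputs; no molecular-volume
  computation from structures is attempted.
* The exclusion rule is greedy; for strongly overlapping outliers the
  order of removal can matter, though for well-separated outliers it is
  order-independent.
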