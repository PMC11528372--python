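# Methods

This note documents the models behind `rhodotools`, the defaults and their
units, and the design choices made where several conventions were possible.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data model

The generators in `synthgen` stand in for the instruments of a rhodopsin
characterization study. They are forward models, not simulators of
instrument physics:

* **Absorption bands** are Gaussian in wavelength (not wavenumber), default
  full width at half maximum 100 nm — the broad, featureless visible band of
  a retinal chromophore. Gaussian-in-wavelength is a modelling
  simplification: real retinal bands are asymmetric with vibronic shoulders.
  It is adequate for peak-position recovery, which is what the analyses are
  scored on. The optional protein band is a Gaussian at 280 nm (FWHM 50 nm,
  amplitude 1.5× the visible band).
* **Noise** is additive i.i.d. Gaussian in absorbance (or pH) units. Stray
  actinic light, detector saturation, baseline wander and wavelength
  calibration error are not modelled; passing tests therefore demonstrate
  correctness of the estimators under the stated noise model, not robustness
  to instrument artifacts.
* **Randomness** flows through one `numpy.random.Generator` per generator
  call, seeded explicitly; there is no global state, and a fixed seed gives
  byte-identical output. The CLI derives per-modality child seeds from one
  global `--seed` via `SeedSequence.spawn`.

Every generator returns a `GroundTruth` record next to the data, and the
test suite's acceptance layer scores each analysis by recovering those
parameters.

## Titration model

Spectra at each pH are population-weighted mixtures of protonation-state
spectra. Weights use one independent Henderson–Hasselbalch sigmoid per
transition (Hill coefficient fixed to 1; no cooperativity term):
θᵢ(pH) = 1/(1 + 10^(pKaᵢ−pH)), state weights w₀ = 1−θ₁, wᵢ = θᵢ−θᵢ₊₁,
wₙ = θₙ. This "stepwise transition" form is exact for well-separated pKa
values and makes the single-wavelength observable identical to the fitted
model, so zero-noise round trips are exact up to optimizer tolerance. For
pKa values closer than ~1.5 units the independent-sigmoid weights deviate
from a coupled two-site equilibrium; the fitted pKa values are then
operational (curve-shape) parameters, as they are in practice.

The fitted observable defaults to the difference absorbance (versus the
reference-pH spectrum, by default the lowest pH) at the wavelength of
maximal |ΔA| across the series — the most sensitive single-wavelength
readout. Fitting is bounded multi-start least squares (default 16 seeded
starts, pKa ∈ [0, 14], `scipy.optimize.least_squares`/TRF). Estimates
within 0.1 pH unit of the data range edge are flagged `at_boundary` and
reported as inequalities (e.g. `<1.2`): a transition outside the sampled
range is bounded, not located. Model selection between one and two pKa
values uses AICc with the residual variance counted as a parameter.

## Photocycle model

The kinetic scheme is the irreversible first-order chain
ground → K → M → ground with exactly two rates (ms⁻¹ throughout). L/N/O
intermediates are deliberately omitted: the pumps this package targets
resolve only a red-shifted K-like state and the blue-absorbing M state.
Concentrations are closed-form; the degenerate equal-rate case uses the
analytic limit f·k·t·e^(−kt), switched on below a relative rate difference
of 1e-12. The ground state's difference spectrum is identically zero; the
bleach enters through the −ε_ground term in each intermediate's Δε.

Intermediate detection assigns: positive transient inside the M window
(default 390–440 nm) → M; positive band red of ground λmax + 60 nm → K;
negative band at ground λmax → bleach. Features below 3× a robust noise
estimate (median absolute second difference along wavelength, scaled) are
suppressed. Rise/decay times are the first/last half-peak crossings;
at ties the earliest crossing wins. A wavelength mask excludes channels
contaminated by scattered actinic light (the usual practice is to drop the
channels at and next to the excitation wavelength); fixtures replicate such
masks.

M-decay is fitted on the 415-nm band trace by default, from the time of
peak |signal| onward, as Σaᵢe^(−kᵢt) + c with multi-start over log-spaced
rates; an option fits the pyranine trace instead, since a proton-release
signal tracks M decay. Turnover time is the first time after the bleach
minimum at which |ΔA| has recovered by a configurable fraction (default
99%); the threshold is exposed rather than fixed because "photocycle
complete" has no unique definition.

The global fit alternates closed-form concentrations (given trial rates)
with linear least squares for the species spectra, optimizing the two log
rates with bounded TRF from several seeded starts. Label switching is
removed by canonicalizing the faster rate as K→M inside the objective. A
condition number above 1e8 on the concentration matrix flags the rate pair
as degenerate.

## Chromatogram quantification

Baseline is a rolling minimum (default window 2 min); peaks are local
maxima above a prominence threshold (`scipy.signal.find_peaks`), integrated
by the trapezoidal rule between prominence bases, with adjacent peaks split
at the valley between apexes (perpendicular-drop convention). Perpendicular
drop mis-assigns tail area between strongly overlapping unequal peaks
(order 5% at 3σ separation); isomer standards in practice elute well
separated, and the bundled defaults keep ≥ 1.2 min between retention
times. Assignment to isomers is greedy nearest-retention-time, one-to-one,
ties to the earlier-eluting isomer, tolerance 0.5 min. Composition is
extinction-corrected molar fraction; the ε table ships as editable data
(the bundled values are literature-convention placeholders — relative ε of
13-cis ≈ 0.72 vs all-trans at 370 nm detection — and any self-consistent
table works because only ratios enter).

## Pump assay

The pump term in the generator saturates exponentially (default τ = 240 s,
so a 120-s illumination stays near-linear), recovers after light-off
(τ = 600 s), and is multiplied by a leak factor (default 0.02) under CCCP.
Analysis estimates drift from the pre-light segment only, fits the initial
slope over the first 30 s of illumination (pump flux before buffering
saturates), and classifies: acidification beyond threshold (default 1e-4
pH/s) abolished below ratio 0.2 by CCCP → outward H⁺ pump; symmetric
alkalization → inward H⁺ transport; sub-threshold → none; otherwise
ambiguous. The 0.2 abolition ratio encodes "almost completely abolished"
and is a parameter, not a measurement.

## Sequence analysis

Alignment is global Needleman–Wunsch/Gotoh with affine gaps, end gaps
penalized, BLOSUM62, gap open 11 / extend 1 (gap of length L costs
open + (L−1)·extend). Opsins are full-length homologs, so global alignment
with penalized end gaps is appropriate. Traceback tie-breaks are fixed —
substitution over reference-consuming gap over query-consuming gap — for
reproducibility. Reference numbering counts from residue 1 of the bundled
template.

The bundled reference template is a **synthetic** BR-like scaffold
(`data/reference_opsin_synthetic.fasta`): a constructed seven-helix-pattern
sequence carrying the canonical functional residues (D85, T89, D96, E194,
E204, D212, K216) at the canonical BR positions. It serves purely as a
numbering frame for position mapping; swapping in a real reference sequence
is a one-file change and alters nothing in the code path.

The motif rule table is data (YAML), not code: motif→function labels are
clade-level generalizations that users may need to edit. The Schiff-base
viability rule requires Lys at 216 and Asp/Glu at both 85 and 212.

## Structure comparison

Chains are paired residue-by-residue via the same global aligner on their
one-letter sequences; the Kabsch algorithm (SVD with determinant
correction, reflections excluded) gives the optimal rigid transform and
RMSD over all matched Cα pairs. Default is no trimming — the most
reproducible convention, since published RMSDs rarely state their atom
selection; optional iterative trimming removes the worst pair and re-fits
until a requested fraction is gone, which mimics core-selection tools.
Published rhodopsin-vs-rhodopsin RMSDs computed with unknown protocols
should therefore be compared against a tolerance band (±0.1 Å is used in
the acceptance layer) rather than exactly. Collinear point sets (second
singular value below 1e-12 of the first) are rejected.

## Problem sizes and tolerances in the test suite

Property sweeps run at sizes chosen to keep the full suite under a minute
on one CPU while leaving the statistical thresholds unchanged: 12 + 8
random alignment pairs against the independent DP oracle, 10 random rate
pairs (plus the default pair) against the adaptive-ODE oracle at 1e-8,
210 quaternion-oracle superposition instances at 1e-9, 135 titration fits
in the pKa-recovery sweep (median error bounds 0.02 / 0.15), 120
exponential fits in the M-decay sweep (median relative error bounds
1%/3%/10%), 12 random chromatogram compositions (max error 1%), and 42
pump truth-table fixtures. Hypothesis drives the key-residue extraction
property (30 examples, derandomized by default settings).

## Known limitations

* No branched or reversible photocycles, no temperature/ionic-strength
  dependence, no SVD preprocessing of ΔA matrices.
* The titration observable is single-wavelength; no spectral decomposition
  into chromophore sub-bands.
* Isomer quantification is relative only; syn/anti oxime splitting is not
  modelled.
* ΔpH is not converted to absolute proton flux (buffering capacity is not
  an input).
* The synthetic generators share their band-shape conventions with the
  analyses; recovery tests validate the estimators, not the band-shape
  assumptions themselves.
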