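# Methods

## The measurement model

An MRM-HR assay schedules one product-ion experiment per targeted
precursor: while an analyte elutes, the quadrupole repeatedly isolates its
[M−H]⁻ precursor (unit-resolution isolation, modelled as ±0.7 Da
acceptance and co-isolation), the collision cell fragments it, and the TOF
records a centroided high-resolution MS2 spectrum. The quantifier channel
for an analyte is reconstructed afterwards: every scan whose isolation
target lies within the precursor tolerance contributes one chromatogram
point, the sum of centroid intensities inside a window of 0.05 Da full
width around the product ion. Analytes that share both precursor and
product windows within these tolerances (PGE2/PGD2; LTB4/6-*trans*-LTB4;
LTD4/11-*trans*-LTD4) produce *identical* channels and are distinguished
only by retention time — this drives two design choices below.

Quantification is stable-isotope dilution: concentration = (analyte peak
area / IS peak area) × IS concentration, valid because a deuterated IS
co-elutes with its natural form and shares its response. Calibration
curves regress response on nominal concentration with 1/x weighting, the
standard choice for a series spanning 2.3–500 ng/mL where the variance
grows with the signal; r² is the weighted coefficient of determination so
that it measures the same objective the fit minimizes.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| fragment window (`window_da`) | 0.05 | Da | full width of the post-acquisition extraction window |
| precursor tolerance | 0.7 | Da | unit-resolution quadrupole isolation; also the co-isolation width in the simulator |
| RT tolerance (`rt_tolerance_min`) | 0.5 | min | search half-window around the expected RT; brackets the isomer RT gaps (e.g. 10.09 vs 10.54 min) |
| scheduling window | ±0.5 | min | monitored interval per transition around its expected RT |
| dwell time | 10 | ms | per-channel acquisition time; cycle time = dwell × concurrently scheduled channels |
| peak width (`peak_sigma_min`) | 0.05 | min | Gaussian sigma, ~7 s base width, typical of a 2.7 µm C18 column at 0.6 mL/min |
| calibration weighting | 1/x | — | bioanalytical convention for multi-decade dilution series |
| LLOQ rule | S/N ≥ 10 and CV ≤ 20% | — | lowest calibration level passing both |
| FDA gates | RSD ≤ 15 (20 at LLOQ), \|RE\| ≤ 15 (20), accuracy 80–120%, replicate CV ≤ 15 | % | acceptance thresholds applied by `fda_gate` |

## What the simulator emulates — and what it does not

`eicoquant.synthetic` generates scheduled acquisitions with known ground
truth. Peaks are exponentially modified Gaussians (`asymmetry` = the
exponential tail constant in units of sigma; 0 gives a symmetric Gaussian),
placed at the bundled pH 5.8 retention times plus a per-run uniform
±0.1 min shift that all channels share — exactly the situation IS-based
alignment is meant to correct. Scan content is physically consistent with
co-isolation: every analyte whose precursor falls inside the isolation
tolerance of a scheduled channel contributes its fragments to that
channel's scans, which is what makes the shared-channel isomer pairs a real
test rather than an artefact. Noise has three components: additive Gaussian
detector noise per centroid (floored at zero) over a flat chemical
background, Poisson-count spurious centroids at uniform random m/z in the
50–700 acquisition range, and a per-injection multiplicative area factor
(`area_cv`, default 5% in campaigns) representing injection-to-injection
variability.

Because the analyte's and the IS's multiplicative draws are independent,
the area-ratio concentration of a QC replicate has a coefficient of
variation of 5%·√2 ≈ 7.07% — the campaign-level precision the tests
assert. Recovery and matrix effect are injected as two factors with
distinct semantics: extraction efficiency applies only to pre-extraction
spikes, ionization suppression/enhancement to anything measured in matrix.
The defaults reproduce the PGE2-d4 behaviour of the reference method —
e.g. plasma HQC recovery 74.7% of neat with an 88.5% matrix effect, lung
53.9%/77.1%, culture medium 56.6%/64.2% — the measured pre/neat ratio
being extraction efficiency × matrix factor.

Features of real data the simulator does not model: MS1 survey scans,
isotope envelopes, structured chemical background, gradient-dependent RT
behaviour (RTs come from the bundled table), carry-over, and analyte
degradation. Passing tests therefore demonstrate that the *computational*
pipeline is correct and unbiased under realistic peak shapes, noise and
drift — not that the chromatography itself would behave.

## Numerical choices in peak processing

* **Apex selection.** Candidate apexes are local maxima with prominence
  above 5× the point noise; among candidates inside the RT search window
  the one *nearest the expected RT* wins (ties: higher, then earlier).
  A plain "highest point in window" rule would mis-assign an isomer pair
  whenever the wrong member is more abundant.
* **Noise and baseline.** Point noise is estimated from first differences
  (1.4826 · MAD(Δy)/√2), which stays correct even when peaks occupy much
  of the trace; the baseline is the median of the trace after masking
  points more than 3 noise-sd above the lower quartile. The reported S/N
  uses the classical estimator — baseline-corrected height over
  1.4826 · MAD of the out-of-bounds intensities — with `inf` as the
  noiseless sentinel and an error below 8 out-of-peak points.
* **Integration bounds.** Bounds extend from the apex down each flank
  until the trace reaches baseline + max(1 noise-sd, 10⁻⁴ × apex height).
  The low fractional cutoff is deliberate: stopping at 1% of apex height
  and subtracting a baseline drawn through those bounds clips ~2.7% of a
  Gaussian's analytic area h·σ·√(2π), while the chosen cutoff keeps the
  noiseless error below 0.1%. Bounds never cross a genuine valley toward
  a neighbouring candidate peak (genuine = the trace descends essentially
  to baseline there), which separates partially resolved isomers without
  letting noise bumps on a flank truncate the peak.
* **Baseline under the peak.** Linear between the bounds, with endpoint
  heights taken as the median of each out-of-peak flank capped by the
  global baseline estimate — robust both to residual tail signal near the
  bounds and to a co-monitored isomer peak sitting in one flank.
* **Degenerate inputs.** Empty chromatograms, all-zero traces, and windows
  without a gated point return `found=False` with zero area rather than
  raising; back-calculated values at or below zero are flagged below-LLOQ;
  values above the top standard are flagged, never extrapolated.

## Design decisions that were genuinely open

* **Replicates for recovery/matrix effect**: the reference tables state
  n = 6 while the narrative says quintuplicate; the campaign default is
  n = 6 with `n_recovery_replicates` exposed.
* **Calibration response**: curves are fitted on peak area by default
  (`response_mode="area"`), with `area_ratio` available, since sample
  quantification itself is IS-ratio based; both are recorded in outputs.
* **Interday pooling**: interday statistics pool all 15 replicates (3 days
  × 5) rather than averaging daily means; intraday cells are per day.
* **Duplicate channels**: the panel lists 12-HETE twice with slightly
  different product m/z; both are kept as distinct ids (`12-HETE`,
  `12-HETE-2`) rather than silently merged.
* **IS retention times**: deuterated standards are assigned their natural
  form's RT (they co-elute); RvD1-d4, whose natural form is not in the RT
  reference, is placed at RvD2's 6.23 min — an assumption recorded in the
  data file.
* **Neat standards**: QC and neat-standard runs are simulated in solvent
  (no matrix factors), mirroring a standards-based validation; QC samples
  carry the IS at the mid spiking level (148.1 ng/mL).

## Problem sizes

The bundled campaign sizes are the study design itself: 50 calibration
runs (10 levels × 5), 45 QC runs (3 × 5 × 3 days), and 54 spike runs per
matrix (3 levels × 6 replicates × pre/post/neat) across plasma, lung and
culture medium. A full campaign is ~250 simulated injections and ~7 million
scans; `scripts/acceptance.py` completes it in about 90 s on one CPU.
Simulated panels default to six analytes covering early/late eluters and
two of the shared-channel isomer pairs, with their six internal standards.

## Known limitations

* The mzML layer handles centroided MS2 spectra only — no MS1, profile
  data, or chromatogram objects — and reads zlib/32-bit variants but
  always writes uncompressed 64-bit arrays.
* The spectral library carries published fragment m/z only for 5-HETE;
  other entries are constructed (quantifier plus one neutral-loss
  qualifier) and marked synthetic.
* LTD4 and 11-*trans*-LTD4 share both channel and printed retention time
  (6.90 min), so their peaks merge by construction; the assignment test
  treats the merged apex as correct for both, and real samples would need
  chromatography that actually separates them.
* Calibration is strictly linear; saturation/quadratic behaviour at the
  top of the range is out of scope, as are stability, carry-over and
  selectivity-interference panels.
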