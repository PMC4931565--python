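# Methods

`cvtquant` quantifies the composition and morphology of Cvt (cytoplasm-to-
vacuole targeting) vesicles in budding yeast from three kinds of raw data:
two-channel fluorescence z-stacks (molecule counting), particle-center tables
from electron micrographs (aggregation statistics), and correlated
light/electron microscopy (CLEM) site tables (morphometrics). A synthetic-data
generator replaces the microscopes, planting known ground truth so that every
stage of the analysis can be validated end to end.

## Fluorescence molecule counting

### Measurement model

A punctum is a diffraction-limited spot in a z-stack (21 or 23 frames, 200 nm
apart). Quantification proceeds:

1. **Background subtraction.** Each frame is median-filtered with a 21 px
   square window and the filtered image subtracted. The window is the
   published 20 px kernel normalized to the nearest odd size so that the
   median has an unambiguous center; the effective kernel is logged.
   Clipping the negative residuals at zero is available (and is what a
   display-oriented subtraction does), but the quantitative chain measures on
   the signed residuals: clipping rectifies zero-mean noise into a positive
   offset of about sd/√(2π) per voxel, and summed over an ROI × all frames
   this adds thousands of photons — enough to double the apparent intensity
   of a dim reference spot.
2. **Detection.** Candidates are connected components of the thresholded
   maximum-intensity projection. The default threshold is 5 robust noise SDs
   (normal-consistent MAD of the residuals, with a quantile fallback for
   clipped input), minimum area 4 px. The ROI is the component bounding box
   grown by 2 px — large enough to surround the thresholded patch while
   adapting to its size. The detector is this package's stand-in for the
   original operator-drawn rectangular selections.
3. **Edge-of-stack rule.** The ROI's axial intensity profile is computed; a
   spot whose profile peaks in the first or last frame is flagged and
   excluded from medians, since its axial extent is truncated.
4. **Intensity read-out.** Two procedures, matching the two published
   experiment designs: the ROI sum in the single brightest frame
   (fold-change comparisons), or the ROI sum integrated through all frames
   (absolute molecule counting). Both subtract, per frame, the median
   residual of a 3 px ring around the ROI times the ROI area. This local
   correction removes what the global median filter leaves behind where the
   cellular background is curved; without it the 21-frame integral of a
   ~1 photon/px/frame residual is a large additive bias on dim spots.
5. **Colocalization gating.** Only green puncta coinciding with a red marker
   spot (Atg19-mCherry for cargo proteins, Ape1-mCherry for the receptor) are
   quantified, excluding free cytosolic complexes. Gating is greedy
   one-to-one nearest matching with a closed 300 nm boundary (~2 camera
   pixels); distance ties break by lower spot id.

### Calibration chain

Median spot intensities convert to absolute copy numbers by ratio to a
calibration standard imaged under identical settings: Nuf2-GFP kinetochore
patches at 280.6 ± 16.1 molecules per patch (anchored to 5 Cse4 molecules per
kinetochore),

    molecules = 280.6 × median(I_target) / median(I_reference).

Because the read-out is a ratio of medians measured with the same procedure,
multiplicative unknowns — camera gain, exposure, and any shared measurement
bias — cancel.

### Uncertainty

The standard error of a median intensity uses the robust formula

    σ = 1.4826 · exp(m) · MAD_ln / √N,

where m is the median of the natural-log intensities and MAD_ln their median
absolute deviation. 1.4826·MAD is the normal-consistent robust SD on the log
scale, where punctum intensity distributions are roughly symmetric, and
exp(m) carries the error back to the intensity scale. The log statistic
(median vs mean of logs) and base are selectable; the default is the median
with natural logs. Note that this estimator targets σ/√N and therefore sits
about 20% below the asymptotic standard error of a median (which carries an
extra √(π/2) ≈ 1.2533); bootstrap comparisons in the test suite account for
this by checking the central ratio over replicate samples. Errors of ratios
(normalized intensities, fold-changes) propagate to first order:
sem(a/b) = (a/b)·√((sem_a/a)² + (sem_b/b)²). Two-sided Z tests compare
quantities with known standard errors; a fold-change is tested against the
null value 1 with the ratio's propagated sem. No multiple-testing correction
is applied.

### Stoichiometry arithmetic

Per-punctum molecule counts divide by the known oligomeric states (prApe1
dodecamer, Ams1 tetramer, Atg19 trimer) to give oligomer counts, expressed as
ratios to a reference protein. Reported ratio strings round half-up
(1.13 → 1, 2.70 → 3), with floats always retained. These are population
averages over many puncta, not per-complex assignments.

## EM particle aggregation

Particle centers (18 nm prApe1 dodecamers picked from negative-stain
micrographs) are grouped by single-linkage clustering: particles at most
`link_distance` apart are connected, assemblies are the connected components,
and clustering never crosses micrograph boundaries. The default link distance
is 21.6 nm — one particle diameter plus 20% picking tolerance. Assemblies are
classed single / double / triple / multiple (≥ 4) and two conditions are
compared with Pearson's chi-squared test on the 2 × k contingency table (no
continuity correction; classes empty in both conditions are dropped; the
p-value is reported unfloored — the published "P < 2.2 × 10⁻¹⁶" is a software
display floor, not a computed value).

## CLEM morphometrics

Correlated sites carry a biogenesis category (cytoplasmic aggregate without
membrane, partially enwrapped aggregate, double-membrane vesicle,
autophagosome, or excluded when poorly preserved) plus optional cross-section
dimensions and double-membrane width. Summaries report category fractions
over non-excluded sites (percentages rounded half-up), mean cross-section
dimensions, mean ellipticity, and membrane width as mean ± sample SD.
Ellipticity is the flattening (max − min)/max of the cross-section — with the
mean 165 × 185 nm cross-section this gives 11%. (Both common flattening
conventions agree on these dimensions; this one is the package's declared
choice.) Note that with 28 sites, the partial-membrane class (3 sites) rounds
to 11%, so the four categories sum to 101; the published figures (which show
10%) presumably rounded that class down.

## The synthetic microscope

The generator emulates the study's wide-field acquisitions deterministically
from a seed (same seed ⇒ byte-identical stacks):

- **Optics.** Spots render as 3D Gaussians (σ_xy = 1.5 px, σ_z = 2 frames),
  integrated per voxel with error functions so the planted photon total is
  conserved to tail truncation. The real point-spread function is not
  Gaussian, but this is the simplest model that exercises the
  brightest-frame vs integrate-through-stack distinction.
- **Scene.** Cells are disk-shaped background plateaus (radius 24–40 px
  depending on field size) with edges Gaussian-softened by 8 px, mimicking
  out-of-focus cell-body light; a hard intensity step would leave
  median-filter ring artifacts that real images do not show. Spots are
  placed uniformly inside cells with a 14 px hard-core separation and an
  interior axial band (> 2.5 σ_z from either stack end).
- **Camera.** Expected photons receive Poisson shot noise then additive
  Gaussian read noise (6 photons), the standard CCD model. The
  photon-per-molecule gain (50) is arbitrary: the paper reports no
  conversion, and every read-out is anchored by the calibration reference,
  so only ratios matter.
- **Populations.** Per-spot molecule counts are lognormal around the
  configured median: σ_log = 0.4 (geometric SD ≈ 1.5×) for cargo/receptor
  puncta, whose aggregate sizes vary; σ_log = 0.25 for the stereotyped Nuf2
  kinetochore patches. Red marker partners render at a configurable offset
  (default 0, i.e. perfectly colocalized) with a fixed 20,000-photon
  brightness.
- **Chain fields.** EM coordinate fields draw assembly sizes from a
  probability mass over {1, 2, 3, ≥4} ("multiple" draws 4 + Poisson(1)),
  lay chains out linearly with one-diameter spacing and jitter clipped at
  1.5 sd, and keep distinct assemblies more than two diameters apart — so
  the planted partition is exactly recoverable at the default link distance.

What the generator does **not** model: aberrations, photobleaching, stage
drift, chromatic shift, channel misregistration (a constant-shift hook exists
but defaults to zero), cell autofluorescence texture, or EM image formation
(aggregation works on coordinate tables). Passing recovery tests therefore
demonstrates the correctness of the analysis chain under idealized but
realistically noisy conditions, not robustness to those instrument effects.

## Numerical choices and degenerate inputs

- Even median kernels normalize to the next odd size with a warning; kernels
  not smaller than the image are rejected.
- A noise-free stack has zero robust noise SD; the detector then falls back
  to a threshold of 10⁻³ of the projection maximum (explicit thresholds are
  preferred in that regime).
- Non-positive intensities are rejected wherever logs are taken; ratios
  require positive denominators; Z tests require a positive combined error
  except for the exactly-equal-means case (z = 0, p = 1).
- Greedy gating sorts candidate pairs by (distance, green id, red id);
  colocalization uses a closed boundary (a pair at exactly the gate distance
  passes).
- Spot tables serialize with full float precision; all JSON outputs embed the
  package version and a configuration hash.

## Known limitations

- The median filter leaves a curvature-dependent residual on domed cell
  backgrounds; the ring correction removes the local offset but individual
  peripheral spots can still carry a bias of up to ~10% of a dim spot's
  intensity (measured noise-free). The bias is position-dependent with
  near-zero population median and is shared between target and reference
  populations, so calibrated medians and fold-changes are unaffected — the
  end-to-end recovery tests measure exactly this.
- The detector is a simple threshold/connected-components stand-in for
  operator-drawn selections; it does not split merged puncta closer than
  about 2 ROI widths (the generator's hard-core separation avoids this
  regime).
- The SEM-of-median estimator inherits the published formula's ~20%
  underestimate of the true sampling error of a median (see above).
- Simulation problem sizes follow the study designs (54 + 52 and 217 target
  spots, 80–98 reference spots, ~3,100 particles per EM condition); image
  fields are 256–448 px so those populations fit at realistic densities.
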