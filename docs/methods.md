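# Methods

`fluopipe` analyses two-photon calcium-imaging movies together with
simultaneously recorded field potentials. This note documents the models,
conventions and numerical choices behind each stage, what the synthetic
generator does and does not emulate, and the known limitations.

## Coordinate and timing conventions

Pixels are addressed 0-based as (row, col) with the origin top-left. Frame
`i` of a movie with sampling interval `dt` sits at `t = i * dt` seconds; in
line-scan mode the same rule applies per scan line. Channel roles are
named: `green` carries the calcium indicator (OGB-1, GCaMP), `red` the
astrocyte marker (SR-101). Sessions persist in a versioned HDF5 container;
save → load reproduces every stored array bit-exactly.

## Electrophysiology loading

The plain-text interchange format is two columns (time s, value) with
optional `# marker: <time_s> <tag>` header lines. On loading, the segment
matching the imaging session — starting at a tagged marker when one is
given, otherwise at `t = 0` of the shared clock — is decimated by a factor
of 10. Decimation applies an order-8 Chebyshev-I low-pass at 0.8x the
target Nyquist frequency, forward-backward for zero phase, before taking
every 10th sample (scipy's standard decimator); plain subsampling would
alias high-frequency content into the bands the spectral stage analyses.
The decimated trace's sample 0 is aligned to imaging frame 0.

Marker semantics: a marker time is the *start* of its segment, and the
segment length equals the imaging duration. Duplicate tags are an error
(all occurrences listed) rather than a silent first-match.

## ROI detection

A reference image reduces a frame range pixel-wise (average, max or
standard deviation — std highlights active cells; external references are
accepted with a dimension check). Thresholding supports Otsu,
fraction-of-max and absolute modes, with the applied threshold recorded
for reports. Our Otsu resolves the degenerate case of cleanly bimodal
images — where every threshold in the empty gap between modes maximises
the between-class variance — to the midpoint of the optimal plateau,
which is stable against histogram binning; a flat image yields an empty
mask and a warning rather than an error.

Connected components use 8-connectivity, the default most imaging
toolchains assume for soma segmentation. Components outside
`[min_area, max_area]` are dropped and survivors relabelled 1..K in raster
order. Eccentricity is that of the ellipse with identical second central
moments, e = sqrt(1 - (b/a)^2), the standard `regionprops` definition.

For line scans, each ROI is annotated with the scan-path indices falling
inside it; ROIs represented by fewer than `min_line_pixels` path pixels
(default 3) are removed. Three pixels give a usable trace while rejecting
grazing intersections; the parameter is exposed because any fixed choice
is a judgement call.

## Cell validation and classification

An ROI is validated as a cell when all three published criteria hold:

* area strictly greater than 100 px,
* eccentricity strictly lower than 0.85 (somata are compact),
* mean intensity at least 2x the mean of its vicinity.

The vicinity is a ring 5 px wide obtained by binary dilation, with all
*other* ROIs excluded so a bright neighbour cannot inflate the local
background; the contrast is therefore cell-versus-neuropil. The strict/
inclusive directions of the three comparisons follow the published wording
exactly ("higher than", "lower than", "at least").

Valid cells are classified from the ratio of mean red to mean green
intensity over the ROI on the reference images: ratio >= 1.5 → astrocyte
(SR-101-bright), ratio <= 0.75 → neuron, in between → `unclassified`.
The deliberate gap forces user review of ambiguous cells instead of
forcing a class; both boundaries are configuration. A zero green mean is
guarded (astrocyte if red is positive, else unclassified). Whether
astrocytes should face geometric criteria beyond the shared validation is
left open in the source material; we implement shared validation plus the
ratio split only.

Manual (`override_label`) and imported labels always outrank automatic
ones and survive re-classification and session round-trips. Per-cell
bounding-box crops plus a CSV manifest support external annotation;
`import_annotations` applies a `roi_id,label` CSV transactionally (any
unknown id aborts the import, naming every unmatched id).

## Traces

F is the mean intensity over the ROI's pixels per frame and channel (per
scan line in line mode). dF/F0 is computed on the background-corrected
green channel: `auto` background subtracts the per-frame mean of all
pixels outside every ROI (robust to global illumination drift),
`manual_roi` uses a user mask, `constant` a scalar. F0 is the mean of the
corrected trace over the control range — by default the first 10% of
frames (a pre-stimulus-baseline convention; the range is always logged
into reports), with the median available as an option. A non-positive F0
marks that cell's dF/F0 undefined (NaN) with a warning rather than
crashing the batch.

dG/R = (G[t] - G[0]) / R[t]. A movement artefact that scales both
channels multiplicatively is attenuated in dG/R by the green/red
brightness ratio (the bright, static red channel acts as the reference),
whereas dF/F0 reproduces it at full amplitude; note the artefact is
attenuated, not removed, since the `G[0]` reference retains the artefact's
value at frame 0.

Smoothing is a centred moving average with odd window, shrinking at the
edges; window 1 is the identity. Shrinking edges slightly perturb the
trace mean when activity sits at the ends — an accepted trade-off against
edge padding artefacts.

## Wavelet analysis

The continuous wavelet transform uses the analytic Morlet wavelet
psi(t) = pi^(-1/4) exp(i w0 t) exp(-t^2 / 2) with centre-frequency
parameter w0 = 6, the standard time-frequency compromise. The frequency
grid is log-spaced, 64 voices over 0.5-30 Hz by default, clipped below
Nyquist (with a warning) for slowly sampled movies. Scale maps to
frequency via f = w0 / (2 pi s), which places the across-scale response
maximum for a pure tone exactly at the tone frequency, so ridge
localisation is unbiased on the grid.

Coefficients are L1-normalised per scale (the 1/s convention) and further
calibrated by 2 / psî(w0) so that a unit-amplitude sinusoid produces a
ridge magnitude of ~1 at any frequency; the scheme is recorded in the
result (`l1-amplitude`) so alternatives can be added unambiguously.
Signals are demeaned before the transform: the wavelet is zero-mean, so
band content is unchanged, but this prevents the truncated kernels from
responding to the DC step at the signal edges. Kernels are truncated at
5 standard deviations; a cone-of-influence mask (one e-folding time,
sqrt(2)·s, per edge) marks edge-contaminated coefficients.

Band power is the sum of coefficient magnitudes over grid frequencies in
the half-open interval [f_low, f_high). The default physiological bands —
delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30 Hz — therefore tile the
grid with no frequency counted twice (the shared printed endpoints 4, 8
and 13 Hz belong to the upper band). `analyze_session` runs the same band
set over every cell at the imaging rate and over the ephys at its own
rate, both time axes sharing t = 0 for direct overlay.

## Network synchrony

Instantaneous phase comes from a 4th-order Butterworth band-pass applied
forward-backward (zero phase) followed by the analytic-signal angle; the
wavelet phase at band centre is available as a cross-check. The
phase-locking value of a pair is |mean_t exp(i(phi_a - phi_b))|. Samples
within `edge_zero_s` (default: two periods of the band's lower edge) of
either end are *excluded* from the mean rather than literally zeroed:
writing zeros into the phase difference would bias the estimate toward
phase difference 0, defeating the stated purpose of the edge handling.
For independent phases the PLV follows the Rayleigh null,
E[PLV] = sqrt(pi)/2 / sqrt(N).

Sliding-window cross-correlation reports, per window and pair, the
maximum Pearson correlation over integer-sample lags in [-L, +L] and the
lag attaining it. Window defaults derive from the sampling interval:
256 samples window, 64 samples step, maximum lag a quarter window.
Lag > 0 means the second trace trails the first; `max_corr` is symmetric
and `lag_at_max` antisymmetric by construction. Ties in the argmax
(e.g. lags one period apart on a sinusoid) resolve deterministically to
the smallest |lag|, negative first, with a 1e-12 tolerance so exact ties
are not broken by rounding noise. Zero-variance windows yield NaN, not an
error. Autocorrelation reuses the machinery with lag 0 excluded from the
argmax.

## Reports and batch processing

Reports are plain HTML plus PNG panels — deterministic (no timestamps),
diffable and testable. The per-cell report carries the imaging settings, a
summary table, and per cell: field-of-view location, channel crops, the
dF/F0 trace and one band-power panel per band. "Spike detection" is
realised as event flagging: samples where dF/F0 exceeds the trace median
by k median absolute deviations (k = 5) are marked, and rising edges
counted as events. The network report stacks per-cell band power
colour-coded by type (astrocytes red, neurons green, other regions blue)
above the ephys band power, and tabulates each cell's Pearson correlation
with the ephys per band.

Folder-level batch processing loads every session container in
lexicographic order and applies a catalogue operation per session;
a failure on one session is recorded and does not abort the rest, and
`apply` is equivalent to mapping the operation over sessions one by one.

## Synthetic data

The generator emulates the target measurement regimes: frame scans
(default 20 disk-shaped somata of radius 5 px in 128x128 px, 30 s at
68 Hz; 1 Hz also supported) and line scans at 125 Hz in which two crossing
chords traverse each cell, echoing the double-crossing scan paths used to
tame scan-head inertia in vivo. The green channel is
`baseline * (1 + dF/F0(t))` on each disk over a flat background plus
white Gaussian pixel noise; SNR is defined as disk contrast
(baseline - background) over pixel noise SD, default 5. The red channel is
static disks at planted red/green ratios (3.0 astrocytes, 0.25 neurons —
at least 2x beyond the 1.5/0.75 decision boundaries, so classification
errors are attributable to the pipeline, not to ambiguous truth).

Calcium dynamics are sinusoidal dF/F0 oscillations (amplitude 0.2,
frequencies drawn from {1, 2, 3, 5} Hz unless specified) because the
analysis surface of this pipeline is spectral; an optional
exponential-transient mode supports event-flagging tests. A "network
source" — a 3 Hz sinusoid with a slow amplitude envelope (0.1 Hz, depth
0.8) — can be shared between chosen cells and the generated LFP (plus 1/f
noise); the envelope is what makes band-power time courses correlate, as
strictly stationary sinusoids would have flat envelopes and no
correlation structure to recover. Not emulated: neuropil contamination,
motion artefacts, photobleaching, spike-to-calcium convolution kernels.
Passing tests therefore demonstrate correctness of the measurement
pipeline, not robustness to those real-data nuisances.

Everything regenerates bit-exactly from the seed; no binary fixtures are
stored.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` recompute, from
freshly generated data: behavioural boundary sweeps of the four pipeline
constants (downsampling factor, area/eccentricity/contrast thresholds);
ROI recovery (20 cells, SNR 5, 68 Hz, 30 s) over 20 seeds; classification
accuracy over 20 seeds; dF/F0 closed forms; CWT ridge localisation for 10
planted frequencies at 68 and 125 Hz against an FFT-periodogram oracle;
PLV calibration (identity, constant offset, 1000-draw null at N = 10^4
against the Rayleigh expectation); lag recovery for delays of 1, 3, 7 and
25 samples against a brute-force all-lag scan; imaging/ephys delta-band
coupling over 3 seeds (coupled cells' minimum r, uncoupled cells' mean
|r| — the mean is used because band-power autocorrelation leaves only
~15 effective degrees of freedom in 30 s, so individual null correlations
scatter to ~0.25); and container/annotation/batch round-trip identities.

## Known limitations

* Motion correction is not provided; imported ROIs can only be rigidly
  translated between sessions.
* Touching cells are not split (no watershed); the generator plants
  non-overlapping somata.
* No spike inference/deconvolution — event flagging is threshold-based.
* PLV significance (surrogate testing) and graph-level metrics are out of
  scope.
* Proprietary acquisition formats are not read; movies enter as multipage
  TIFF and electrophysiology as the documented text format.
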