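# Methods

## Scope and model

The package quantifies membrane-protein nanoclusters from single-molecule
localization (PALM) data.  The underlying physical picture: photoconvertible
fluorophores (mEOS2-like) attached to a membrane protein are activated
sparsely, each emits for a short run of consecutive camera frames and then
bleaches irreversibly; every emission is localized by Gaussian fitting of
its point-spread function to a few-nanometre precision.  A protein that
partitions into nanoscale membrane domains produces localization clouds
whose local density is far above the dispersed-monomer background and whose
radial profile is approximately Gaussian.

A cluster's size is summarized by the pooled per-axis standard deviation of
its member localizations about their centre of mass,
`sigma = sqrt((sum dx^2 + sum dy^2) / 2n)` (population form, no Bessel
correction), reported as a FWHM diameter `2*sqrt(2*ln 2)*sigma` with the
exact constant, not 2.35.

## Pipeline order and fixed thresholds

The analysis order is fixed: per-frame ("untracked") events feed the
nearest-neighbour pre-filter and the candidate mask; the merged ("tracked")
localizations are the ones cropped by the mask and counted.  Three
thresholds are intrinsic to the method and not meant to be changed:

- photon filter: an event is kept only with **strictly more than 250
  photons**;
- NN pre-filter: a localization is discarded when its nearest neighbour is
  **strictly farther than 50 nm** (a sole localization has no neighbour and
  is discarded);
- candidate acceptance: a candidate with **two or fewer tracked
  localizations** is rejected (`min_locs = 3`).

## Declared parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `bin_size_nm` | 10 | nm | super-res histogram bin ≈ localization precision scale |
| `mask_smoothing_nm` | 30 | nm | see mask calibration below |
| `mask_density_multiplier` | 10 | – | see mask calibration below |
| `link_radius_nm` | 100 | nm | several localization precisions at the photon floor |
| `max_gap_frames` | 0 | frames | strictly consecutive frames define a track |
| `pixel_size_nm` | 106 | nm | camera pixel in the sample plane |
| `psf_sigma_nm` | 130 | nm | PSF sigma of a high-NA oil objective at ~580 nm |
| `loc_precision_floor_nm` | 10 | nm | precision floor under the `s/sqrt(N)` model |

Track positions are the **photon-weighted** mean of member events (higher
photon counts mean better precision under `sigma ∝ 1/sqrt(N)`); an
unweighted mode exists.  Tracking links each open track to the nearest
unclaimed event of the next frame within the link radius, ties broken by
lower event index; unclaimed events open new tracks.

## Candidate mask and its calibration

The mask renders the NN-filtered untracked events at the super-res bin
size, smooths with a Gaussian kernel (`mask_smoothing_nm`), thresholds at
`mask_density_multiplier` times the mean of the nonzero smoothed density,
and labels 8-connected components (8-connectivity avoids splitting diagonal
pixel chains at 10 nm bins).

The two mask parameters trade off two failure modes, and their defaults
were calibrated once on the simulator's default conditions:

- threshold too low / smoothing too narrow: blobs formed by the multi-frame
  bursts of two or three *dispersed monomers* survive the mask and, when
  they contain ≥3 tracks, appear as spurious tiny clusters — inflating the
  count and deflating the mean diameter;
- threshold too high: the mask boundary cuts into a genuine cluster's
  Gaussian tail, truncating the localization cloud and biasing the FWHM
  down by up to ~10% for the larger (FloT-like) clusters.

At 30 nm smoothing and a 10x multiplier the mask boundary sits beyond
~3 sigma of a default cluster while remaining an order of magnitude above
the smoothed density of few-event monomer blobs; parameter recovery then
returns both scenarios' cluster counts essentially exactly and mean FWHM
within ~3%.  Both parameters are configurable and echoed into every run's
resolved configuration.

## Gaussian-coherence diagnostic

`gaussianity_score` tests whether a cluster's radial distances from its
centre of mass follow the Rayleigh law implied by an isotropic Gaussian
cloud (Kolmogorov–Smirnov distance).  Because sigma is estimated from the
same data, the score is computed by a parametric bootstrap (scale-free, so
exact up to the Monte Carlo resolution of `1/(n_boot+1)`); under the null
it is uniform on [0,1], and ring-like clouds score below 0.01.  It is a
*diagnostic only* — spatial Gaussian coherence is indicative of genuine
clustering — and never filters clusters by default.

## Simulator: what it emulates, and what it does not

Defaults encode the study conditions: ~20000 frames at 10 Hz, 106 nm
pixels; FloA-like cells carry 13 clusters of true FWHM 46.73 nm and
FloT-like cells 6 clusters of 63.39 nm, each with 60 emitters per cluster
(≥50 tracked localizations per cluster after the photon filter) and 20% of
emitters dispersed as background monomers on a 3 µm x 1 µm spherocylinder
footprint.  Activation is one-shot per emitter (irreversible
photoconversion then bleaching; a re-activation probability exists,
default 0), activation probability 5e-4 per frame (virtually every emitter
activates within the movie), geometric burst lengths of mean 3 frames,
lognormal photon yields (median 500, log-sigma 0.7, so ~84% of events pass
the 250-photon filter), localization error `max(psf_sigma/sqrt(N), 10 nm)`,
and 0.02 spurious uniform events per frame.  Cluster centres keep a 200 nm
minimum separation so ground-truth clusters are resolvable.  None of these
acquisition statistics are reported for the original data; they are this
package's declared, realistic choices.

Not emulated: 3D, stage drift, chromatic offsets, EMCCD gain noise,
re-blinking kinetics of real mEOS2, dual-colour acquisitions, and emitter
motion.  Passing parameter recovery therefore shows the *analysis* is
unbiased under these idealized acquisition statistics; it does not certify
robustness to drift or strong re-blinking, which real data may add.

## Numerical conventions

Coordinates are nm throughout, x right / y down, origin at the field's
top-left; frames are 0-based; histogram bins are half-open
`[origin + i*b, origin + (i+1)*b)`.  Pixelation enters only when rendering
or fitting raw frames; spots are rendered and refit with pixel-integrated
Gaussians (erf form), so a noiseless rendered spot refits to sub-nanometre
accuracy.  Degenerate inputs: a localization cloud with zero spread has
diameter exactly 0; a cell with no tracks reports percent-in-clusters as
missing; an empty localization file is an empty table, not an error.  All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
give byte-identical output tables.

## Problem sizes

The recovery experiments use 50 simulated cells per scenario (roughly
1000–3200 events per cell), which puts the Monte Carlo error of the
recovered means well inside the validation tolerances (±1 cluster, 10%
FWHM) while keeping a full two-scenario run in a few seconds.

## Colocalization

Pearson correlation of two co-registered channels is computed over the
pixels of each cell mask and aggregated as the mean over cells (a
pooled-pixel mode exists; the per-cell convention matches sampling a fixed
number of cells).  No Costes randomization or Manders coefficients are
provided.  Focus counting uses a difference-of-Gaussians band-pass, a
threshold relative to the in-mask mean intensity, and brightest-first
merging of maxima closer than a minimum separation; it is monotone
non-increasing in both the threshold and the separation.

## Known limitations

- The mask threshold is global; strong cell-to-cell density variation
  within one field would call for per-cell normalization.
- Percent-in-clusters counts *tracked* localizations (each spurious
  detection also becomes a single-event track), so heavy false-positive
  rates dilute the percentage; the per-stage record counts in the run log
  make this visible.
- The tracking linker is greedy and zero-gap by default; fluorophores that
  blink with gaps are split into multiple tracks, slightly inflating
  localizations-per-cluster counts.
- Cluster-count recovery by widefield focus counting (`count_foci`) is a
  diffraction-limited, per-cell alternative to the PALM mask path; the two
  need not agree when clusters sit closer than the diffraction limit.
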