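# palmquant

Quantification of bacterial membrane-microdomain nanoclusters from
photoactivated localization microscopy (PALM) data, with a ground-truthed
synthetic acquisition simulator for validating the whole analysis chain by
parameter recovery.

Flotillin scaffold proteins (FloA, FloT) organize the *Bacillus subtilis*
membrane into functional membrane microdomains that appear in PALM as
nanoclusters a few tens of nanometres across.  Quantifying them means
turning ~20000 camera frames of single-molecule blinking events into
per-cell statistics: how many clusters a cell carries, how large they are,
and what fraction of the protein is clustered.  This package implements
that pipeline for localization tables (and, optionally, raw image stacks),
plus the dual-channel Pearson colocalization used to relate two labelled
proteins in diffraction-limited imaging.

## The analysis

Starting from per-frame localization events (frame, x/y in nm, photons):

1. **Photon filter** — only events with strictly more than 250 photons are
   kept.
2. **Emission tracking** — events of one fluorophore appearing in strictly
   consecutive frames are merged into a single *track* at the
   photon-weighted mean position, improving localization precision.
3. **Nearest-neighbour pre-filter** (untracked events) — localizations
   whose nearest neighbour lies farther than 50 nm are discarded as pseudo
   background.
4. **Candidate mask** — the NN-filtered events are rendered as a 10 nm-bin
   super-resolved histogram, Gaussian-smoothed, and thresholded at a
   multiple of the mean nonzero density; 8-connected components are
   cluster candidates.
5. **Cluster extraction** — tracks are cropped by the mask; candidates
   with two or fewer tracks are rejected.
6. **Statistics** — for each accepted cluster, the pooled standard
   deviation about the centre of mass

   σ = sqrt( (Σ(xᵢ−x̄)² + Σ(yᵢ−ȳ)²) / 2n )

   and the reported diameter is the FWHM, 2·sqrt(2·ln 2)·σ ≈ 2.3548·σ.
   Per cell: cluster count, diameters, localizations per cluster, and the
   percentage of tracked localizations inside accepted clusters.

The simulator (`palmquant.simulate`) generates the matching study
conditions: spherocylindrical cell footprints, Gaussian emitter clusters of
known FWHM plus dispersed monomers, mEOS2-like one-shot photoactivation
with geometric multi-frame bursts, lognormal photon yields,
photon-dependent localization error, and spurious background detections —
with every event carrying its true emitter identity.

## Worked example

```sh
python analysis/01_simulate_cells.py
python analysis/02_cluster_single_cell.py
```

simulates one FloA-like cell (13 clusters of true FWHM 46.73 nm, 20%
dispersed background) and analyses it end to end:

```
stage record counts:
  events                   3212
  photon_filtered_events   2684
  tracks                   1396
  nn_filtered_events       2486
  candidates               13
  clusters                 13
  clustered_tracks         835

13 clusters (truth 13); mean diameter 48.36 nm FWHM (truth 46.73);
59.8% of tracked localizations in clusters
```

The 3212 raw events lose ~16% to the photon filter, merge ~2:1 into
tracks, and the mask finds exactly the 13 planted clusters; the mean FWHM
diameter recovers the planted 46.73 nm to ~3%.  The remaining ~40% of
tracks outside clusters are the dispersed monomers and spurious
background detections, as constructed.

`python analysis/03_parameter_recovery.py` repeats this over 50 cells per
scenario (FloA-like and FloT-like), and
`python analysis/04_colocalization.py` demonstrates the per-cell Pearson
readout on synthetic two-colour cells with partially overlapping foci.

There is also a CLI: `palmquant simulate|localize|cluster|coloc|report`
(see `palmquant --help`), e.g.

```sh
palmquant cluster --seed 1 --out out/ \
    --nn-threshold-nm 50 --min-photons 250 --min-locs 3 --bin-size-nm 10
```

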