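"""Mask-based nanocluster analysis of localization data.

This is the core analysis: from a table of localizations it builds a
super-resolved 2D histogram, removes the dispersed pseudo-background with a
nearest-neighbour distance pre-filter, thresholds a smoothed density map
into a labelled candidate mask, crops the tracked localizations by that
mask, rejects candidates with fewer than three tracked localizations, and
reports per-cluster geometry.  Cluster "diameter" throughout means the FWHM
of the localization cloud, ``2 * sqrt(2 * ln 2)`` times the pooled per-axis
standard deviation about the cloud's centre of mass.

The pipeline order is fixed: the *untracked* (per-frame) localizations feed
the NN pre-filter and the candidate mask, while the *tracked* localizations
are the ones cropped and counted per cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

#: FWHM of a Gaussian in units of its standard deviation (exact form).
FWHM_FACTOR: float = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: 8-connectivity structuring element for candidate labelling.
_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class SuperResImage:
    """A 2D localization-count histogram on a square sub-diffraction grid.

    ``counts[iy, ix]`` is the number of localizations whose position falls
    in the half-open bin ``[origin + i*b, origin + (i+1)*b)`` along each
    axis.  ``n_dropped`` counts localizations outside the field.
    """

    counts: np.ndarray
    bin_size_nm: float
    origin: tuple[float, float]
    n_dropped: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def bin_indices(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map (n, 2) nm positions to (ix, iy, inside-mask) on this grid."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ix = np.floor((xy[:, 0] - self.origin[0]) / self.bin_size_nm).astype(int)
        iy = np.floor((xy[:, 1] - self.origin[1]) / self.bin_size_nm).astype(int)
        ny, nx = self.counts.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        return ix, iy, inside


@dataclass
class CandidateMask:
    """Labelled cluster-candidate regions aligned to a super-res grid.

    Label 0 is background; labels 1..n_labels are connected components
    (8-connectivity) of the thresholded smoothed density map.
    """

    labels: np.ndarray
    n_labels: int
    bin_size_nm: float
    origin: tuple[float, float]
    threshold: float = float("nan")

    def label_at(self, xy: np.ndarray) -> np.ndarray:
        """Candidate label under each (n, 2) nm position (0 = outside/background)."""
        tmpl = SuperResImage(self.labels, self.bin_size_nm, self.origin)
        ix, iy, inside = tmpl.bin_indices(xy)
        out = np.zeros(len(ix), dtype=int)
        out[inside] = self.labels[iy[inside], ix[inside]]
        return out


@dataclass
class Cluster:
    """An accepted cluster candidate with its member tracked localizations."""

    label: int
    member_indices: np.ndarray
    centroid: tuple[float, float]
    sigma_nm: float
    diameter_fwhm_nm: float
    n_tracked_locs: int
    gaussianity: float = float("nan")


@dataclass
class CellClusterSummary:
    """Per-cell cluster statistics (cluster count, diameters, occupancies)."""

    n_clusters: int
    diameters_nm: list = field(default_factory=list)
    locs_per_cluster: list = field(default_factory=list)
    percent_in_clusters: float = float("nan")


def render_superres(
    xy,
    bin_size_nm: float,
    extent: tuple[float, float, float, float] | None = None,
) -> SuperResImage:
    """Bin localization positions into a super-resolved count image.

    Parameters
    ----------
    xy : (n, 2) array
        Localization positions in nm.
    bin_size_nm : float
        Square bin edge, nm.
    extent : (xmin, xmax, ymin, ymax), optional
        Field to render.  Defaults to the data bounding box (every point is
        then inside).  Points outside an explicit extent are dropped and
        counted in ``n_dropped``.
    """
    if bin_size_nm <= 0:
        raise ValueError("bin_size_nm must be positive")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        origin = (0.0, 0.0) if extent is None else (extent[0], extent[2])
        if extent is None:
            shape = (1, 1)
        else:
            shape = (
                max(1, math.ceil((extent[3] - extent[2]) / bin_size_nm)),
                max(1, math.ceil((extent[1] - extent[0]) / bin_size_nm)),
            )
        return SuperResImage(np.zeros(shape, dtype=int), bin_size_nm, origin, 0)
    if extent is None:
        x0, y0 = xy[:, 0].min(), xy[:, 1].min()
        nx = int(np.floor((xy[:, 0].max() - x0) / bin_size_nm)) + 1
        ny = int(np.floor((xy[:, 1].max() - y0) / bin_size_nm)) + 1
    else:
        x0, y0 = extent[0], extent[2]
        nx = max(1, math.ceil((extent[1] - extent[0]) / bin_size_nm))
        ny = max(1, math.ceil((extent[3] - extent[2]) / bin_size_nm))
    ix = np.floor((xy[:, 0] - x0) / bin_size_nm).astype(int)
    iy = np.floor((xy[:, 1] - y0) / bin_size_nm).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    counts = np.zeros((ny, nx), dtype=int)
    np.add.at(counts, (iy[inside], ix[inside]), 1)
    return SuperResImage(counts, float(bin_size_nm), (float(x0), float(y0)), int((~inside).sum()))


def nn_prefilter(xy, threshold_nm: float = 50.0, return_mask: bool = False):
    """Discard localizations whose nearest neighbour is farther than a threshold.

    Keeps exactly the points whose Euclidean distance to their nearest
    *other* point is ``<= threshold_nm`` ("above threshold" is discarded);
    a sole point has no neighbour and is discarded.  Input order is
    preserved.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be positive")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) < 2:
        keep = np.zeros(len(xy), dtype=bool)
    else:
        tree = cKDTree(xy)
        dist, _ = tree.query(xy, k=2)
        keep = dist[:, 1] <= threshold_nm
    if return_mask:
        return keep
    return xy[keep]


def build_candidate_mask(
    untracked_xy,
    superres: SuperResImage,
    smoothing_sigma_nm: float = 30.0,
    density_multiplier: float = 10.0,
) -> CandidateMask:
    """Threshold a smoothed localization density map into labelled candidates.

    The (already NN pre-filtered) untracked localizations are rendered on
    the grid of ``superres``, smoothed with a Gaussian kernel, and
    thresholded at ``density_multiplier`` times the mean of the nonzero
    smoothed density.  Connected components under 8-connectivity become
    candidate labels.  The multiplier must sit well above the diffuse
    monomer background so that only genuine density peaks survive; see the
    package methods note for how the default was chosen.
    """
    if smoothing_sigma_nm < 0:
        raise ValueError("smoothing_sigma_nm must be nonnegative")
    grid = render_superres(
        untracked_xy,
        superres.bin_size_nm,
        extent=(
            superres.origin[0],
            superres.origin[0] + superres.shape[1] * superres.bin_size_nm,
            superres.origin[1],
            superres.origin[1] + superres.shape[0] * superres.bin_size_nm,
        ),
    )
    dens = grid.counts.astype(float)
    if smoothing_sigma_nm > 0:
        dens = ndimage.gaussian_filter(dens, sigma=smoothing_sigma_nm / superres.bin_size_nm)
    nz = dens[dens > 0]
    if nz.size == 0:
        return CandidateMask(
            np.zeros_like(superres.counts, dtype=int), 0, superres.bin_size_nm, superres.origin
        )
    thr = density_multiplier * float(nz.mean())
    labels, n_labels = ndimage.label(dens > thr, structure=_STRUCT8)
    return CandidateMask(labels, int(n_labels), superres.bin_size_nm, superres.origin, thr)


def cluster_diameter_fwhm(positions) -> tuple[float, float]:
    """Pooled standard deviation and FWHM diameter of a localization cloud.

    The centre of mass is the unweighted mean; per-axis squared deviations
    are pooled with divisor ``2n`` (population form), and the diameter is
    ``2 * sqrt(2 * ln 2)`` times that sigma.

    Returns ``(sigma_nm, diameter_fwhm_nm)``; requires at least 3 positions.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(pos)
    if n < 3:
        raise ValueError(f"need at least 3 positions, got {n}")
    dev = pos - pos.mean(axis=0)
    sigma = math.sqrt(float(np.sum(dev**2)) / (2.0 * n))
    return sigma, FWHM_FACTOR * sigma


def gaussianity_score(positions, n_boot: int = 199, seed: int = 0) -> float:
    """Diagnostic p-value for Gaussian spatial coherence of a cluster.

    Radial distances from the centre of mass are compared against the
    Rayleigh distribution implied by an isotropic Gaussian cloud with the
    cluster's pooled sigma (Kolmogorov-Smirnov distance).  Because sigma is
    estimated from the same data, the null distribution of the distance is
    obtained by a parametric bootstrap (scale-free, so exact up to Monte
    Carlo resolution ``1 / (n_boot + 1)``); the returned score is uniform
    on [0, 1] for genuinely Gaussian clouds and small for e.g. ring-like
    clouds.  This is a diagnostic, not a filter.  Returns NaN below 10
    positions.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(pos)
    if n < 10:
        return float("nan")
    r = np.linalg.norm(pos - pos.mean(axis=0), axis=1)
    d_obs = _rayleigh_ks(r)
    rng = np.random.default_rng(seed)
    d_boot = np.empty(n_boot)
    for b in range(n_boot):
        sim = rng.normal(size=(n, 2))
        rb = np.linalg.norm(sim - sim.mean(axis=0), axis=1)
        d_boot[b] = _rayleigh_ks(rb)
    return float((1 + np.sum(d_boot >= d_obs)) / (n_boot + 1))


def _rayleigh_ks(r: np.ndarray) -> float:
    sigma = math.sqrt(float(np.sum(r**2)) / (2.0 * len(r)))
    if sigma == 0:
        return 1.0
    return float(stats.kstest(r, stats.rayleigh(scale=sigma).cdf).statistic)


def extract_clusters(
    mask: CandidateMask,
    tracks: pd.DataFrame,
    min_locs: int = 3,
    with_gaussianity: bool = False,
) -> tuple[list[Cluster], np.ndarray]:
    """Crop tracked localizations by the candidate mask and accept clusters.

    Each track is assigned the candidate label of the mask bin containing
    its position (0 = unclustered).  Candidates with fewer than ``min_locs``
    tracks are rejected ("two or less" under the default of 3).  Returns the
    accepted clusters and the per-track candidate label array.
    """
    xy = tracks[["x_nm", "y_nm"]].to_numpy(dtype=float)
    track_labels = mask.label_at(xy) if len(xy) else np.zeros(0, dtype=int)
    clusters: list[Cluster] = []
    for lab in range(1, mask.n_labels + 1):
        members = np.flatnonzero(track_labels == lab)
        if len(members) < min_locs:
            continue
        pos = xy[members]
        sigma, diam = cluster_diameter_fwhm(pos)
        gscore = gaussianity_score(pos) if with_gaussianity else float("nan")
        clusters.append(
            Cluster(
                label=int(lab),
                member_indices=members,
                centroid=(float(pos[:, 0].mean()), float(pos[:, 1].mean())),
                sigma_nm=sigma,
                diameter_fwhm_nm=diam,
                n_tracked_locs=int(len(members)),
                gaussianity=gscore,
            )
        )
    return clusters, track_labels


def summarize_cell(clusters: list[Cluster], n_total_tracks: int) -> CellClusterSummary:
    """Per-cell summary: cluster count, diameters, occupancies, percent clustered.

    ``percent_in_clusters`` is 100 times the fraction of all tracked
    localizations that belong to an accepted cluster; NaN when there are no
    tracks at all.
    """
    n_in = sum(c.n_tracked_locs for c in clusters)
    if n_total_tracks > 0:
        pct = 100.0 * n_in / n_total_tracks
    else:
        pct = float("nan")
    return CellClusterSummary(
        n_clusters=len(clusters),
        diameters_nm=[c.diameter_fwhm_nm for c in clusters],
        locs_per_cluster=[c.n_tracked_locs for c in clusters],
        percent_in_clusters=pct,
    )


def clusters_to_frame(clusters: list[Cluster], cell_id=0) -> pd.DataFrame:
    """Tabulate clusters as one row each (TSV-ready)."""
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "cluster_id": [c.label for c in clusters],
            "centroid_x_nm": [c.centroid[0] for c in clusters],
            "centroid_y_nm": [c.centroid[1] for c in clusters],
            "n_locs": [c.n_tracked_locs for c in clusters],
            "sigma_nm": [c.sigma_nm for c in clusters],
            "diameter_fwhm_nm": [c.diameter_fwhm_nm for c in clusters],
            "gaussianity": [c.gaussianity for c in clusters],
        }
    )
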