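"""Synthetic PALM acquisitions with ground truth.

Emulates a sptPALM-style acquisition of mEOS2-tagged membrane proteins in a
rod-shaped cell: clustered emitters (isotropic Gaussian clouds of known
FWHM) plus dispersed background monomers on the cell footprint, sparse
stochastic photoactivation, a short multi-frame emission burst followed by
an irreversible bleach, lognormal per-frame photon yields, photon-count
dependent localization error (sigma = s / sqrt(N) with a floor), and a
uniform rate of spurious background detections.  Every localization event
carries the identity of its true emitter so downstream stages can be
validated by parameter recovery.

Positions are continuous nanometre coordinates; pixelation only enters when
rendering raw camera frames with :func:`render_frames`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import CellGeometry
from .clusters import FWHM_FACTOR

#: emitter_id assigned to spurious (false-positive) background events.
FALSE_EVENT_ID: int = -1
#: cluster_id assigned to dispersed background monomers.
BACKGROUND_ID: int = -1


class PlacementError(RuntimeError):
    """Raised when cluster centres cannot be placed at the requested separation."""


@dataclass
class SimConfig:
    """Acquisition parameters for the PALM simulator.

    Defaults follow a typical bacterial PALM acquisition: ~20000 frames at
    10 Hz with 106 nm pixels.  ``activation_prob`` is the per-emitter,
    per-frame probability of photoconversion (each emitter converts at most
    once by default; ``reactivation_prob`` > 0 allows residual re-blinking).
    Photon yields per frame are lognormal with the given median and log-sigma
    shape; localization error is isotropic Gaussian with
    ``sigma = max(psf_sigma_nm / sqrt(photons), loc_precision_floor_nm)``.
    ``background_rate_per_frame`` adds spurious events uniformly over the
    field.
    """

    n_frames: int = 20000
    frame_rate_hz: float = 10.0
    pixel_size_nm: float = 106.0
    activation_prob: float = 5e-4
    mean_burst_frames: float = 3.0
    photon_median: float = 500.0
    photon_sigma_ln: float = 0.7
    psf_sigma_nm: float = 130.0
    loc_precision_floor_nm: float = 10.0
    background_rate_per_frame: float = 0.02
    reactivation_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        for name in ("activation_prob", "reactivation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.mean_burst_frames < 1:
            raise ValueError("mean_burst_frames must be >= 1")
        if self.background_rate_per_frame < 0:
            raise ValueError("background_rate_per_frame must be nonnegative")
        if self.psf_sigma_nm <= 0 or self.photon_median <= 0:
            raise ValueError("psf_sigma_nm and photon_median must be positive")

    def localization_sigma(self, photons) -> np.ndarray:
        """Thompson-style precision: ``s / sqrt(N)`` with a constant floor."""
        photons = np.maximum(np.asarray(photons, dtype=float), 1.0)
        return np.maximum(self.psf_sigma_nm / np.sqrt(photons), self.loc_precision_floor_nm)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EmitterGroundTruth:
    """Simulator truth: emitter positions, cluster memberships, cluster geometry."""

    positions: np.ndarray
    cluster_ids: np.ndarray
    cluster_centers: np.ndarray
    true_fwhm_nm: float
    geometry: CellGeometry | None = None

    @property
    def n_emitters(self) -> int:
        return len(self.positions)

    @property
    def background_fraction(self) -> float:
        if self.n_emitters == 0:
            return float("nan")
        return float(np.mean(self.cluster_ids == BACKGROUND_ID))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "emitter_id": np.arange(self.n_emitters),
                "x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
                "cluster_id": self.cluster_ids,
            }
        )


def place_emitters(
    geometry: CellGeometry,
    n_clusters: int,
    emitters_per_cluster: int,
    true_fwhm_nm: float,
    n_background: int,
    seed: int = 0,
    min_separation_nm: float = 200.0,
    max_attempts: int = 10000,
) -> EmitterGroundTruth:
    """Place clustered and dispersed emitters on a cell footprint.

    Cluster centres are drawn uniformly in the footprint subject to a
    minimum pairwise separation; members are isotropic Gaussian about their
    centre with per-axis ``sigma = true_fwhm_nm / (2 sqrt(2 ln 2))``,
    redrawn until inside the footprint.  Background monomers are uniform in
    the footprint.  Deterministic for a fixed seed.
    """
    if min(n_clusters, emitters_per_cluster, n_background) < 0:
        raise ValueError("counts must be nonnegative")
    if n_clusters > 0 and true_fwhm_nm <= 0:
        raise ValueError("true_fwhm_nm must be positive when placing clusters")
    rng = np.random.default_rng(seed)
    centers = np.empty((n_clusters, 2))
    placed = 0
    attempts = 0
    while placed < n_clusters:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n_clusters} cluster centres at separation "
                f">= {min_separation_nm} nm within {max_attempts} attempts"
            )
        cand = geometry.sample_interior(1, rng)[0]
        attempts += 1
        if placed == 0 or np.all(
            np.linalg.norm(centers[:placed] - cand, axis=1) >= min_separation_nm
        ):
            centers[placed] = cand
            placed += 1

    sigma = true_fwhm_nm / FWHM_FACTOR
    pos_parts, id_parts = [], []
    for k in range(n_clusters):
        members = np.empty((emitters_per_cluster, 2))
        got = 0
        while got < emitters_per_cluster:
            draw = centers[k] + rng.normal(0.0, sigma, size=(emitters_per_cluster - got, 2))
            ok = geometry.contains(draw)
            take = draw[ok]
            members[got : got + len(take)] = take
            got += len(take)
        pos_parts.append(members)
        id_parts.append(np.full(emitters_per_cluster, k))
    if n_background > 0:
        pos_parts.append(geometry.sample_interior(n_background, rng))
        id_parts.append(np.full(n_background, BACKGROUND_ID))
    if pos_parts:
        positions = np.concatenate(pos_parts)
        cluster_ids = np.concatenate(id_parts)
    else:
        positions = np.empty((0, 2))
        cluster_ids = np.empty(0, dtype=int)
    return EmitterGroundTruth(positions, cluster_ids.astype(int), centers, float(true_fwhm_nm), geometry)


EVENT_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "sigma_nm", "emitter_id"]


def simulate_acquisition(
    truth: EmitterGroundTruth,
    config: SimConfig,
    extent: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Simulate the event table of a PALM movie over the given emitters.

    Each emitter photoconverts at most once (optionally re-activating with
    ``reactivation_prob``), emits in a geometric-length run of consecutive
    frames, and every frame-emission yields one localization event at the
    emitter position plus isotropic Gaussian error whose sigma follows the
    photon-dependent precision model.  Spurious events are added uniformly
    over ``extent`` (defaults to the cell bounding box padded by 500 nm) at
    ``background_rate_per_frame``.  Returns a DataFrame with columns
    ``frame, x_nm, y_nm, photons, sigma_nm, emitter_id`` sorted by frame;
    ``emitter_id`` is -1 for spurious events.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if extent is None:
        if truth.geometry is not None:
            extent = truth.geometry.bounding_box(pad=500.0)
        elif truth.n_emitters:
            x, y = truth.positions[:, 0], truth.positions[:, 1]
            extent = (x.min() - 500, x.max() + 500, y.min() - 500, y.max() + 500)
        else:
            extent = (0.0, 1000.0, 0.0, 1000.0)

    frames, xs, ys, phots, sigmas, ids = [], [], [], [], [], []

    def emit_burst(emitter_idx: int, start_frame: int) -> int:
        burst = rng.geometric(1.0 / config.mean_burst_frames)
        last = min(start_frame + burst - 1, config.n_frames - 1)
        for f in range(start_frame, last + 1):
            n_phot = rng.lognormal(np.log(config.photon_median), config.photon_sigma_ln)
            s_loc = float(config.localization_sigma(n_phot)[()])
            dx, dy = rng.normal(0.0, s_loc, size=2)
            frames.append(f)
            xs.append(truth.positions[emitter_idx, 0] + dx)
            ys.append(truth.positions[emitter_idx, 1] + dy)
            phots.append(n_phot)
            sigmas.append(s_loc)
            ids.append(emitter_idx)
        return last

    for i in range(truth.n_emitters):
        if config.activation_prob <= 0.0:
            break
        first = rng.geometric(config.activation_prob) - 1
        if first >= config.n_frames:
            continue
        last = emit_burst(i, first)
        while (
            config.reactivation_prob > 0.0
            and last + 1 < config.n_frames
            and rng.random() < config.reactivation_prob
        ):
            gap = rng.geometric(config.activation_prob)
            nxt = last + 1 + gap
            if nxt >= config.n_frames:
                break
            last = emit_burst(i, nxt)

    if config.background_rate_per_frame > 0:
        n_false = rng.poisson(config.background_rate_per_frame * config.n_frames)
        if n_false:
            f_bg = rng.integers(0, config.n_frames, n_false)
            x_bg = rng.uniform(extent[0], extent[1], n_false)
            y_bg = rng.uniform(extent[2], extent[3], n_false)
            p_bg = rng.lognormal(np.log(config.photon_median), config.photon_sigma_ln, n_false)
            s_bg = config.localization_sigma(p_bg)
            frames.extend(f_bg.tolist())
            xs.extend(x_bg.tolist())
            ys.extend(y_bg.tolist())
            phots.extend(p_bg.tolist())
            sigmas.extend(s_bg.tolist())
            ids.extend([FALSE_EVENT_ID] * n_false)

    events = pd.DataFrame(
        {
            "frame": np.asarray(frames, dtype=int),
            "x_nm": np.asarray(xs, dtype=float),
            "y_nm": np.asarray(ys, dtype=float),
            "photons": np.asarray(phots, dtype=float),
            "sigma_nm": np.asarray(sigmas, dtype=float),
            "emitter_id": np.asarray(ids, dtype=int),
        }
    )
    return events.sort_values("frame", kind="stable").reset_index(drop=True)


class FieldOfViewError(ValueError):
    """Raised when events fall outside the rendered field and clipping is off."""


def render_frames(
    events: pd.DataFrame,
    config: SimConfig,
    psf_sigma_nm: float | None = None,
    extent: tuple[float, float, float, float] | None = None,
    camera_background: float = 0.0,
    clip: bool = True,
    n_frames: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Render an event table into a raw camera image stack.

    Each event becomes a pixel-integrated 2D Gaussian spot of total
    intensity equal to its photon count (PSF sigma ``psf_sigma_nm``,
    defaulting to the config's).  Optional Poisson camera background with
    mean ``camera_background`` counts/pixel is added.  Returns a float
    array of shape ``(n_frames, H, W)``.
    """
    if psf_sigma_nm is None:
        psf_sigma_nm = config.psf_sigma_nm
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    if n_frames is None:
        n_frames = config.n_frames
    px = config.pixel_size_nm
    if extent is None:
        pad = 5 * psf_sigma_nm
        if len(events):
            extent = (
                events["x_nm"].min() - pad,
                events["x_nm"].max() + pad,
                events["y_nm"].min() - pad,
                events["y_nm"].max() + pad,
            )
        else:
            extent = (0.0, 10 * px, 0.0, 10 * px)
    x0, y0 = extent[0], extent[2]
    w = max(1, int(np.ceil((extent[1] - extent[0]) / px)))
    h = max(1, int(np.ceil((extent[3] - extent[2]) / px)))
    stack = np.zeros((n_frames, h, w), dtype=float)
    half_win = int(np.ceil(5 * psf_sigma_nm / px))

    for row in events.itertuples(index=False):
        if row.frame < 0 or row.frame >= n_frames:
            continue
        cx = (row.x_nm - x0) / px
        cy = (row.y_nm - y0) / px
        if not (0 <= cx < w and 0 <= cy < h):
            if clip:
                continue
            raise FieldOfViewError(f"event at ({row.x_nm}, {row.y_nm}) nm outside field")
        j0, j1 = max(0, int(cx) - half_win), min(w, int(cx) + half_win + 1)
        i0, i1 = max(0, int(cy) - half_win), min(h, int(cy) + half_win + 1)
        jj = np.arange(j0, j1 + 1)  # pixel edges, px units
        ii = np.arange(i0, i1 + 1)
        s = psf_sigma_nm / px
        fx = 0.5 * (1 + erf((jj - cx) / (s * np.sqrt(2))))
        fy = 0.5 * (1 + erf((ii - cy) / (s * np.sqrt(2))))
        spot = row.photons * np.outer(np.diff(fy), np.diff(fx))
        stack[row.frame, i0:i1, j0:j1] += spot

    if camera_background > 0:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
        stack += rng.poisson(camera_background, size=stack.shape)
    return stack
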