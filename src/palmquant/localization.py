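"""Spot localization, photon filtering and emission tracking.

The localization path mirrors a standard SMLM workflow: candidate spots are
detected per frame with a difference-of-Gaussians band-pass and refined by
least-squares fitting of a pixel-integrated 2D Gaussian, yielding sub-pixel
positions in nm and integrated photon counts above background.  Events with
too few photons are discarded (default: strictly more than 250 photons are
required), and emissions of the same fluorophore in strictly consecutive
frames are merged into a single higher-precision "track" whose position is
the photon-weighted mean of its members.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.ndimage import gaussian_filter
from scipy.special import erf
from skimage.feature import peak_local_max

EVENT_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "sigma_nm"]
TRACK_COLUMNS = [
    "track_id",
    "x_nm",
    "y_nm",
    "first_frame",
    "last_frame",
    "n_events",
    "total_photons",
]


def _integrated_gaussian(coords, n_phot, x0, y0, sigma, bg):
    """Pixel-integrated isotropic 2D Gaussian plus flat background (nm units)."""
    xl, xr, yl, yr = coords
    rt2 = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xr - x0) / rt2) - erf((xl - x0) / rt2))
    fy = 0.5 * (erf((yr - y0) / rt2) - erf((yl - y0) / rt2))
    return n_phot * fx * fy + bg


def detect_and_fit_spots(
    image: np.ndarray,
    pixel_size_nm: float,
    psf_sigma_nm: float,
    threshold: float,
    frame: int = 0,
) -> pd.DataFrame:
    """Detect and fit single-molecule spots in one camera frame.

    Candidates are local maxima of a difference-of-Gaussians band-passed
    image above ``threshold``; each is refined by least-squares fitting of
    a pixel-integrated 2D Gaussian (free centre, sigma, amplitude and flat
    background) over a window of +-3 PSF sigma.  Returns an event table
    with positions in nm (field origin at the top-left pixel edge) and
    ``photons`` the fitted integrated intensity above background.
    Non-converging fits are dropped.
    """
    if pixel_size_nm <= 0 or psf_sigma_nm <= 0:
        raise ValueError("pixel_size_nm and psf_sigma_nm must be positive")
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")

    s_px = psf_sigma_nm / pixel_size_nm
    dog = gaussian_filter(img, s_px) - gaussian_filter(img, 2.0 * s_px)
    peaks = peak_local_max(
        dog,
        min_distance=max(1, int(round(2 * s_px))),
        threshold_abs=threshold,
        exclude_border=False,
    )

    win = max(2, int(np.ceil(3 * s_px)))
    h, w = img.shape
    rows = []
    for py, px_i in peaks:
        i0, i1 = max(0, py - win), min(h, py + win + 1)
        j0, j1 = max(0, px_i - win), min(w, px_i + win + 1)
        sub = img[i0:i1, j0:j1]
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        # pixel edges in nm; pixel j spans [j*p, (j+1)*p)
        xl = (jj * pixel_size_nm).ravel()
        xr = xl + pixel_size_nm
        yl = (ii * pixel_size_nm).ravel()
        yr = yl + pixel_size_nm
        bg0 = float(sub.min())
        n0 = max(float(sub.sum() - bg0 * sub.size), 1.0)
        p0 = [
            n0,
            (px_i + 0.5) * pixel_size_nm,
            (py + 0.5) * pixel_size_nm,
            psf_sigma_nm,
            bg0,
        ]
        bounds = (
            [0.0, j0 * pixel_size_nm, i0 * pixel_size_nm, 0.2 * psf_sigma_nm, -np.inf],
            [np.inf, j1 * pixel_size_nm, i1 * pixel_size_nm, 5.0 * psf_sigma_nm, np.inf],
        )
        try:
            popt, _ = curve_fit(
                _integrated_gaussian,
                (xl, xr, yl, yr),
                sub.ravel(),
                p0=p0,
                bounds=bounds,
                maxfev=2000,
            )
        except (RuntimeError, ValueError):
            continue
        n_phot, x0, y0, sig, _bg = popt
        rows.append((frame, x0, y0, n_phot, sig))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def localize_stack(
    stack: np.ndarray, pixel_size_nm: float, psf_sigma_nm: float, threshold: float
) -> pd.DataFrame:
    """Run :func:`detect_and_fit_spots` over every frame of an image stack."""
    parts = [
        detect_and_fit_spots(frm, pixel_size_nm, psf_sigma_nm, threshold, frame=f)
        for f, frm in enumerate(stack)
    ]
    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def filter_photons(events: pd.DataFrame, min_photons: float = 250.0) -> pd.DataFrame:
    """Keep only events with strictly more than ``min_photons`` photons.

    Order is preserved; the default reproduces the ">250 photons" raw-data
    filter applied before image reconstruction.
    """
    if min_photons < 0:
        raise ValueError("min_photons must be nonnegative")
    return events[events["photons"] > min_photons].copy()


def track_emissions(
    events: pd.DataFrame,
    link_radius_nm: float = 100.0,
    max_gap: int = 0,
    photon_weighted: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge consecutive-frame emissions of one fluorophore into tracks.

    Greedy frame-by-frame linking: for each open track (in creation order),
    the nearest unclaimed event of the next frame within ``link_radius_nm``
    of the track's current position is appended (ties broken by lower event
    index); unclaimed events start new tracks.  A track closes when no
    continuation exists in the next frame (``max_gap`` frames of silence
    are tolerated if nonzero; the default 0 enforces strictly consecutive
    frames).  Track position is the photon-weighted mean of its member
    events (unweighted with ``photon_weighted=False``).

    Returns ``(tracks, events_out)`` where ``events_out`` is a copy of the
    input with a ``track_id`` column.
    """
    if link_radius_nm <= 0:
        raise ValueError("link_radius_nm must be positive")
    ev = events.reset_index(drop=True)
    n = len(ev)
    frames = ev["frame"].to_numpy(dtype=int) if n else np.zeros(0, dtype=int)
    xs = ev["x_nm"].to_numpy(dtype=float) if n else np.zeros(0)
    ys = ev["y_nm"].to_numpy(dtype=float) if n else np.zeros(0)
    ph = ev["photons"].to_numpy(dtype=float) if n else np.zeros(0)
    has_emitter = "emitter_id" in ev.columns

    track_of = np.full(n, -1, dtype=int)
    # per-track accumulators
    t_wx, t_wy, t_w = [], [], []
    t_first, t_last, t_n, t_phot, t_members = [], [], [], [], []
    open_tracks: list[int] = []

    order = np.argsort(frames, kind="stable")
    pos = 0
    while pos < len(order):
        f = frames[order[pos]]
        grp = []
        while pos < len(order) and frames[order[pos]] == f:
            grp.append(int(order[pos]))
            pos += 1
        open_tracks = [t for t in open_tracks if f - t_last[t] <= 1 + max_gap]
        claimed = set()
        for t in open_tracks:
            if f - t_last[t] < 1:
                continue
            cx, cy = t_wx[t] / t_w[t], t_wy[t] / t_w[t]
            best, best_d = -1, np.inf
            for i in grp:
                if i in claimed:
                    continue
                d = np.hypot(xs[i] - cx, ys[i] - cy)
                if d <= link_radius_nm and d < best_d:
                    best, best_d = i, d
            if best >= 0:
                claimed.add(best)
                w = ph[best] if photon_weighted else 1.0
                t_wx[t] += w * xs[best]
                t_wy[t] += w * ys[best]
                t_w[t] += w
                t_last[t] = f
                t_n[t] += 1
                t_phot[t] += ph[best]
                t_members[t].append(best)
                track_of[best] = t
        for i in grp:
            if i in claimed:
                continue
            w = ph[i] if photon_weighted else 1.0
            t_wx.append(w * xs[i])
            t_wy.append(w * ys[i])
            t_w.append(w)
            t_first.append(f)
            t_last.append(f)
            t_n.append(1)
            t_phot.append(ph[i])
            t_members.append([i])
            tid = len(t_wx) - 1
            track_of[i] = tid
            open_tracks.append(tid)

    n_tracks = len(t_wx)
    tracks = pd.DataFrame(
        {
            "track_id": np.arange(n_tracks, dtype=int),
            "x_nm": np.array(t_wx) / np.array(t_w) if n_tracks else np.zeros(0),
            "y_nm": np.array(t_wy) / np.array(t_w) if n_tracks else np.zeros(0),
            "first_frame": np.array(t_first, dtype=int),
            "last_frame": np.array(t_last, dtype=int),
            "n_events": np.array(t_n, dtype=int),
            "total_photons": np.array(t_phot, dtype=float),
        }
    )
    if has_emitter and n_tracks:
        emit = ev["emitter_id"].to_numpy()
        maj = [Counter(emit[m].tolist()).most_common(1)[0][0] for m in t_members]
        tracks["emitter_id"] = np.asarray(maj)
    elif has_emitter:
        tracks["emitter_id"] = np.zeros(0, dtype=int)
    events_out = ev.copy()
    events_out["track_id"] = track_of
    return tracks, events_out
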