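#!/usr/bin/env python
"""Dual-channel colocalization on synthetic two-colour cells.

Builds a field of cells in which a fraction of the foci in channel 1
(FloA-like, 13 foci/cell) coincide with the foci of channel 2 (FloT-like,
6 foci/cell) - the partial-overlap situation seen when two differently
distributed membrane proteins share a subset of microdomains.  Computes the
per-cell Pearson coefficient and focus counts, and writes the table to
results/colocalization.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from palmquant import SimConfig, count_foci, pearson_per_cell, render_frames

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_CELLS = 12
PIXEL_NM = 106.0
CELL_NM = 4000.0


def render_channel(spots_nm, rng, noise=1.0):
    cfg = SimConfig(n_frames=1, pixel_size_nm=PIXEL_NM)
    ev = pd.DataFrame(
        {"frame": 0, "x_nm": [s[0] for s in spots_nm], "y_nm": [s[1] for s in spots_nm],
         "photons": 2000.0}
    )
    img = render_frames(ev, cfg, psf_sigma_nm=160.0, extent=(0, CELL_NM, 0, CELL_NM), n_frames=1)[0]
    return img + np.abs(rng.normal(0, noise, img.shape))


def separated_points(n, rng, existing=(), min_sep=500.0):
    """Uniform focus positions kept at least one PSF width apart."""
    pts = list(existing)
    while len(pts) < n + len(existing):
        cand = (rng.uniform(500, 3500), rng.uniform(500, 3500))
        if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep for p in pts):
            pts.append(cand)
    return pts[len(existing):]


def main() -> None:
    rng = np.random.default_rng(5)
    rows = []
    for cell_id in range(1, N_CELLS + 1):
        # 6 shared foci plus 7 channel-1-only foci
        shared = separated_points(6, rng)
        only1 = separated_points(7, rng, existing=shared)
        ch1 = render_channel(shared + only1, rng)
        ch2 = render_channel(shared, rng)
        labels = np.ones(ch1.shape, dtype=int)
        table = pearson_per_cell(ch1, ch2, labels)
        n1, _ = count_foci(ch1, min_separation_nm=300.0, pixel_size_nm=PIXEL_NM)
        n2, _ = count_foci(ch2, min_separation_nm=300.0, pixel_size_nm=PIXEL_NM)
        rows.append(
            {"cell_id": cell_id, "R": table["R"].iloc[0], "R2": table["R2"].iloc[0],
             "n_pixels": table["n_pixels"].iloc[0], "foci_ch1": n1, "foci_ch2": n2}
        )
    out = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    out.to_csv(RESULTS / "colocalization.tsv", sep="\t", index=False)
    print(out.round(3).to_string(index=False))
    print(
        f"\nmean per-cell R^2 = {out['R2'].mean():.2f} with "
        f"{out['foci_ch1'].mean():.1f} vs {out['foci_ch2'].mean():.1f} foci/cell: "
        "partial overlap of the two channels' microdomains"
    )


if __name__ == "__main__":
    main()
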