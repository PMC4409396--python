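"""End-to-end cluster-analysis pipeline for one cell / one acquisition.

Stages: simulate (or read a localization CSV) -> photon filter -> branch
into (a) untracked events -> nearest-neighbour pre-filter -> candidate
mask, and (b) tracked localizations -> crop by mask -> reject small
candidates -> per-cluster and per-cell statistics.  Outputs are plain-text
tables plus the fully resolved configuration, so every run is reproducible
from its output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import io as pio
from . import localization as loc
from . import simulate as sim
from .config import RunConfig
from .geometry import make_cell_geometry

logger = logging.getLogger("palmquant")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""


@dataclass
class PipelineResult:
    """In-memory bundle of one pipeline run."""

    events: pd.DataFrame
    filtered_events: pd.DataFrame
    tracks: pd.DataFrame
    mask: cl.CandidateMask
    clusters: list
    summary: cl.CellClusterSummary
    stage_counts: dict = field(default_factory=dict)
    truth: sim.EmitterGroundTruth | None = None


def _simulate_events(config: RunConfig):
    geom = make_cell_geometry(config.cell_length_nm, config.cell_radius_nm)
    truth = sim.place_emitters(
        geom,
        n_clusters=config.n_clusters,
        emitters_per_cluster=config.emitters_per_cluster,
        true_fwhm_nm=config.true_fwhm_nm,
        n_background=config.n_background_emitters,
        seed=config.seed,
        min_separation_nm=config.min_cluster_separation_nm,
    )
    sim_cfg = sim.SimConfig(
        n_frames=config.n_frames,
        frame_rate_hz=config.frame_rate_hz,
        pixel_size_nm=config.pixel_size_nm,
        activation_prob=config.activation_prob,
        mean_burst_frames=config.mean_burst_frames,
        photon_median=config.photon_median,
        photon_sigma_ln=config.photon_sigma_ln,
        psf_sigma_nm=config.psf_sigma_nm,
        loc_precision_floor_nm=config.loc_precision_floor_nm,
        background_rate_per_frame=config.background_rate_per_frame,
        seed=config.seed + 1,
    )
    events = sim.simulate_acquisition(truth, sim_cfg)
    return events, truth


def run_pipeline(
    config: RunConfig,
    out_dir=None,
    cell_id=0,
    with_gaussianity: bool = False,
) -> PipelineResult:
    """Execute the full analysis described in the module docstring.

    With ``out_dir`` set, writes ``localizations.csv`` (simulate mode),
    ``ground_truth.csv`` (simulate mode), ``clusters.tsv``, ``summary.tsv``,
    ``config_resolved.yaml`` and ``pipeline.log`` into it.
    """
    counts: dict[str, int] = {}
    truth = None
    stage = "input"
    try:
        if config.input_path is None:
            events, truth = _simulate_events(config)
        else:
            events = pio.read_localizations(config.input_path)
        counts["events"] = len(events)

        stage = "photon_filter"
        filtered = loc.filter_photons(events, config.min_photons)
        counts["photon_filtered_events"] = len(filtered)

        stage = "tracking"
        tracks, _ = loc.track_emissions(
            filtered, link_radius_nm=config.link_radius_nm, max_gap=config.max_gap_frames
        )
        counts["tracks"] = len(tracks)

        stage = "nn_prefilter"
        untracked_xy = filtered[["x_nm", "y_nm"]].to_numpy(dtype=float)
        nn_xy = cl.nn_prefilter(untracked_xy, config.nn_threshold_nm)
        counts["nn_filtered_events"] = len(nn_xy)

        stage = "mask"
        superres = cl.render_superres(nn_xy, config.bin_size_nm)
        mask = cl.build_candidate_mask(
            nn_xy,
            superres,
            smoothing_sigma_nm=config.mask_smoothing_nm,
            density_multiplier=config.mask_density_multiplier,
        )
        counts["candidates"] = mask.n_labels

        stage = "extract_clusters"
        accepted, _labels = cl.extract_clusters(
            mask, tracks, min_locs=config.min_locs, with_gaussianity=with_gaussianity
        )
        counts["clusters"] = len(accepted)
        counts["clustered_tracks"] = sum(c.n_tracked_locs for c in accepted)

        stage = "summarize"
        summary = cl.summarize_cell(accepted, len(tracks))
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(
        events=events,
        filtered_events=filtered,
        tracks=tracks,
        mask=mask,
        clusters=accepted,
        summary=summary,
        stage_counts=counts,
        truth=truth,
    )
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir), cell_id)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig, out: Path, cell_id) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if result.truth is not None:
        pio.write_localizations(result.events, out / "localizations.csv")
        pio.write_ground_truth(result.truth, out / "ground_truth.csv")
    cl.clusters_to_frame(result.clusters, cell_id=cell_id).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    s = result.summary
    pd.DataFrame(
        {
            "cell_id": [cell_id],
            "n_clusters": [s.n_clusters],
            "mean_diameter_fwhm_nm": [float(np.mean(s.diameters_nm)) if s.diameters_nm else np.nan],
            "mean_locs_per_cluster": [
                float(np.mean(s.locs_per_cluster)) if s.locs_per_cluster else np.nan
            ],
            "percent_in_clusters": [s.percent_in_clusters],
        }
    ).to_csv(out / "summary.tsv", sep="\t", index=False)
    config.to_yaml(out / "config_resolved.yaml")
    lines = [f"{k}\t{v}" for k, v in result.stage_counts.items()]
    (out / "pipeline.log").write_text("\n".join(lines) + "\n")
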