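import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from palmquant import (
    SimConfig,
    detect_and_fit_spots,
    filter_photons,
    place_emitters,
    render_frames,
    simulate_acquisition,
    track_emissions,
)
from conftest import random_events
from oracles import link_bruteforce


class TestDetectAndFit:
    def test_blank_frame_gives_no_events(self):
        out = detect_and_fit_spots(np.zeros((32, 32)), 106.0, 130.0, threshold=1.0)
        assert len(out) == 0

    def test_nonfinite_pixels_rejected(self):
        img = np.zeros((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            detect_and_fit_spots(img, 106.0, 130.0, threshold=1.0)

    def test_single_spot_recovered_subpixel(self):
        """A noiseless rendered 1000-photon spot is refit to <1 nm and <2% photons."""
        cfg = SimConfig(n_frames=1, pixel_size_nm=106.0)
        x_true, y_true = 1003.7, 861.2  # deliberately off pixel centres
        ev = pd.DataFrame({"frame": [0], "x_nm": [x_true], "y_nm": [y_true], "photons": [1000.0]})
        frame = render_frames(ev, cfg, psf_sigma_nm=130.0, extent=(0, 2120, 0, 2120), n_frames=1)[0]
        found = detect_and_fit_spots(frame, 106.0, 130.0, threshold=5.0)
        assert len(found) == 1
        assert found["x_nm"].iloc[0] == pytest.approx(x_true, abs=1.0)
        assert found["y_nm"].iloc[0] == pytest.approx(y_true, abs=1.0)
        assert found["photons"].iloc[0] == pytest.approx(1000.0, rel=0.02)

    def test_two_spots_resolved_and_matched(self):
        cfg = SimConfig(n_frames=1, pixel_size_nm=106.0)
        truth = np.array([[600.0, 700.0], [600.0 + 10 * 106.0, 700.0]])
        ev = pd.DataFrame(
            {"frame": [0, 0], "x_nm": truth[:, 0], "y_nm": truth[:, 1],
             "photons": [800.0, 1200.0]}
        )
        frame = render_frames(ev, cfg, psf_sigma_nm=130.0, extent=(0, 2400, 0, 1400), n_frames=1)[0]
        found = detect_and_fit_spots(frame, 106.0, 130.0, threshold=5.0)
        assert len(found) == 2
        # brute-force nearest ground-truth matching
        pos = found[["x_nm", "y_nm"]].to_numpy()
        d = np.linalg.norm(pos[:, None] - truth[None], axis=-1)
        assert set(d.argmin(axis=1)) == {0, 1}
        assert d.min(axis=1).max() < 5.0


class TestFilterPhotons:
    def test_strict_threshold_semantics(self):
        ev = pd.DataFrame(
            {"frame": [0, 0, 0], "x_nm": [0.0] * 3, "y_nm": [0.0] * 3,
             "photons": [249.0, 250.0, 251.0]}
        )
        kept = filter_photons(ev)
        assert kept["photons"].tolist() == [251.0]

    def test_empty_input(self):
        ev = pd.DataFrame(columns=["frame", "x_nm", "y_nm", "photons"])
        assert len(filter_photons(ev)) == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_survivors_match_exhaustive_recount(self, seed):
        rng = np.random.default_rng(seed)
        photons = rng.integers(1, 501, 1000).astype(float)
        ev = pd.DataFrame(
            {"frame": np.zeros(1000, dtype=int), "x_nm": np.zeros(1000),
             "y_nm": np.zeros(1000), "photons": photons}
        )
        kept = filter_photons(ev, 250)
        assert len(kept) == sum(1 for p in photons if p > 250)
        # idempotent, order preserved
        again = filter_photons(kept, 250)
        assert again["photons"].tolist() == kept["photons"].tolist()


class TestTrackEmissions:
    def test_single_event_single_track(self):
        ev = pd.DataFrame({"frame": [5], "x_nm": [10.0], "y_nm": [20.0], "photons": [400.0]})
        tracks, ev_out = track_emissions(ev)
        assert len(tracks) == 1
        row = tracks.iloc[0]
        assert (row.x_nm, row.y_nm, row.n_events) == (10.0, 20.0, 1)
        assert ev_out["track_id"].tolist() == [0]

    def test_weighted_mean_merge(self):
        """Consecutive-frame events merge at the photon-weighted position."""
        ev = pd.DataFrame(
            {"frame": [3, 4], "x_nm": [0.0, 4.0], "y_nm": [0.0, 3.0],
             "photons": [300.0, 100.0]}
        )
        tracks, _ = track_emissions(ev, link_radius_nm=50.0)
        assert len(tracks) == 1
        row = tracks.iloc[0]
        assert row.x_nm == pytest.approx(1.0)   # (300*0 + 100*4) / 400
        assert row.y_nm == pytest.approx(0.75)  # (300*0 + 100*3) / 400
        assert row.total_photons == pytest.approx(400.0)
        assert row.first_frame == 3 and row.last_frame == 4

    def test_frame_gap_breaks_linking(self):
        ev = pd.DataFrame(
            {"frame": [3, 5], "x_nm": [0.0, 0.0], "y_nm": [0.0, 0.0],
             "photons": [300.0, 300.0]}
        )
        tracks, _ = track_emissions(ev)
        assert len(tracks) == 2
        tracks_gap, _ = track_emissions(ev, max_gap=1)
        assert len(tracks_gap) == 1

    def test_conservation_of_events_and_photons(self, rng):
        ev = random_events(rng, 400, n_frames=30, box=1000.0)
        tracks, ev_out = track_emissions(ev, link_radius_nm=80.0)
        assert tracks["n_events"].sum() == len(ev)
        assert tracks["total_photons"].sum() == pytest.approx(ev["photons"].sum())
        assert (ev_out["track_id"] >= 0).all()
        # strictly consecutive frames under the default zero-gap rule
        assert (tracks["last_frame"] - tracks["first_frame"] == tracks["n_events"] - 1).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_partition_matches_bruteforce_linker(self, seed):
        rng = np.random.default_rng(seed)
        ev = random_events(rng, 250, n_frames=12, box=400.0)
        tracks, ev_out = track_emissions(ev, link_radius_nm=60.0)
        got = {
            frozenset(np.flatnonzero(ev_out["track_id"].to_numpy() == t))
            for t in tracks["track_id"]
        }
        expected = link_bruteforce(
            ev["frame"].tolist(), ev["x_nm"].tolist(), ev["y_nm"].tolist(),
            ev["photons"].tolist(), link_radius=60.0,
        )
        assert got == expected

    def test_tracking_improves_precision(self, cell):
        """Track positions beat single events in RMS error when bursts exceed one frame."""
        truth = place_emitters(cell, 0, 0, 50.0, n_background=500, seed=20)
        cfg = SimConfig(n_frames=20000, activation_prob=5e-4, mean_burst_frames=4.0,
                        background_rate_per_frame=0.0, seed=21)
        events = simulate_acquisition(truth, cfg)
        tracks, _ = track_emissions(events)
        assert tracks["n_events"].mean() > 1
        ev_dev = events[["x_nm", "y_nm"]].to_numpy() - truth.positions[events["emitter_id"]]
        tr_dev = tracks[["x_nm", "y_nm"]].to_numpy() - truth.positions[tracks["emitter_id"]]
        rms_events = np.sqrt(np.mean(ev_dev**2))
        rms_tracks = np.sqrt(np.mean(tr_dev**2))
        assert rms_tracks < rms_events
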