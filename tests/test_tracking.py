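"""Session matching, track building, fate calls and tangle objects."""

import numpy as np
import pytest

from neurofate import (
    SimulationConfig,
    assign_tangle_status,
    build_tracks,
    crop_to_overlap,
    fate_agreement,
    filter_tangle_objects,
    load_tracks,
    match_sessions,
    register_sessions,
    save_tracks,
    simulate_longitudinal,
)
from neurofate.tracking import TangleObject

from conftest import make_cloud


def grid_cloud(week=1, jitter=None, drop=None, rng=None):
    """A 4x4x3 grid with 20 um spacing; optionally jittered or with rows dropped."""
    g = np.stack(
        np.meshgrid(np.arange(4) * 20.0, np.arange(4) * 20.0, np.arange(3) * 20.0),
        -1,
    ).reshape(-1, 3) + 10.0
    if jitter is not None:
        g = g + rng.normal(0, jitter, g.shape)
    ids = np.arange(len(g))
    if drop is not None:
        keep = ~np.isin(ids, drop)
        g, ids = g[keep], ids[keep]
    return make_cloud(g, week=week, ids=ids, bounds=np.array([[0.0, 0, 0], [80, 80, 60]]))


class TestMatching:
    def test_identical_clouds_perfect_matching(self):
        a, b = grid_cloud(1), grid_cloud(2)
        ri, ni, d = match_sessions(a, b, gate_um=8.0)
        assert len(ri) == a.n
        np.testing.assert_array_equal(a.ids[ri], b.ids[ni])
        assert d.max() == 0.0

    def test_gate_semantics(self, rng):
        a = grid_cloud(1)
        b = grid_cloud(2, jitter=1.0, rng=rng)
        ri, _, _ = match_sessions(a, b, gate_um=8.0)
        assert len(ri) == a.n  # jitter << gate: all matched
        shifted = make_cloud(a.xyz + 9.0, week=2, bounds=a.bounds)
        ri2, _, _ = match_sessions(a, shifted, gate_um=8.0)
        assert len(ri2) == 0  # uniform shift beyond gate: none matched

    def test_matches_bruteforce_mutual_nn_oracle(self, rng):
        for trial in range(5):
            a = make_cloud(rng.random((120, 3)) * 150)
            b = make_cloud(rng.random((110, 3)) * 150, week=2)
            ri, ni, _ = match_sessions(a, b, gate_um=10.0)
            got = set(zip(ri.tolist(), ni.tolist()))
            dm = np.linalg.norm(a.xyz[:, None] - b.xyz[None], axis=-1)
            expect = set()
            for i in range(a.n):
                j = int(np.argmin(dm[i]))
                if int(np.argmin(dm[:, j])) == i and dm[i, j] <= 10.0:
                    expect.add((i, j))
            assert got == expect

    def test_nonpositive_gate_rejected(self):
        a = grid_cloud()
        with pytest.raises(ValueError):
            match_sessions(a, a, gate_um=0.0)


class TestTracks:
    def test_planted_single_disappearance_called_at_week3(self):
        sessions = [
            grid_cloud(1),
            grid_cloud(2),
            grid_cloud(3, drop=[21]),
            grid_cloud(4, drop=[21]),
        ]
        tracks = build_tracks(sessions, edge_margin_um=0.0)
        dead = [t for t in tracks if t.fate == "disappeared"]
        assert len(dead) == 1
        assert dead[0].track_id == 21 and dead[0].death_week == 3

    def test_transient_invisibility_is_ambiguous(self):
        sessions = [
            grid_cloud(1),
            grid_cloud(2, drop=[21]),
            grid_cloud(3),
            grid_cloud(4),
        ]
        tracks = build_tracks(sessions, edge_margin_um=0.0)
        t21 = next(t for t in tracks if t.track_id == 21)
        assert t21.fate == "ambiguous"
        assert sum(t.fate == "disappeared" for t in tracks) == 0

    def test_all_persist_simulation_calls_no_deaths(self):
        cfg = SimulationConfig(
            n_neurons=400, hazard_nontangle=0.0, hazard_tangle=0.0, seed=13
        )
        sessions, _ = simulate_longitudinal(cfg)
        reg, _, _ = register_sessions(sessions)
        tracks = build_tracks(crop_to_overlap(reg))
        assert sum(t.fate == "disappeared" for t in tracks) == 0

    def test_simulation_roundtrip_fate_agreement(self):
        sessions, truth = simulate_longitudinal(SimulationConfig(seed=17))
        reg, _, _ = register_sessions(sessions)
        tracks = build_tracks(crop_to_overlap(reg), gate_um=8.0)
        assert fate_agreement(tracks, truth) >= 0.98

    def test_death_counts_invariant_under_global_scale_and_shift(self):
        # axis-aligned similarity: gate and edge margin are physical
        # lengths, so they scale with the frame
        from neurofate import SimilarityTransform, apply_transform

        sessions, _ = simulate_longitudinal(SimulationConfig(seed=19, n_neurons=500))
        reg, _, _ = register_sessions(sessions)
        cropped = crop_to_overlap(reg)
        n_dead = sum(t.fate == "disappeared" for t in build_tracks(cropped))
        g = SimilarityTransform(1.3, np.eye(3), np.array([40.0, -25.0, 10.0]))
        moved = [apply_transform(c, g) for c in cropped]
        n_dead_moved = sum(
            t.fate == "disappeared"
            for t in build_tracks(moved, gate_um=8.0 * g.scale, edge_margin_um=2.0 * g.scale)
        )
        assert n_dead_moved == n_dead

    def test_tracks_csv_roundtrip(self, tmp_path):
        sessions, _ = simulate_longitudinal(SimulationConfig(seed=23, n_neurons=300))
        reg, _, _ = register_sessions(sessions)
        tracks = build_tracks(crop_to_overlap(reg))
        save_tracks(tracks, tmp_path / "tracks.csv")
        back = load_tracks(tmp_path / "tracks.csv")
        assert len(back) == len(tracks)
        for a, b in zip(tracks, back):
            assert (a.track_id, a.fate, a.death_week, a.tangle_onset_week) == (
                b.track_id,
                b.fate,
                b.death_week,
                b.tangle_onset_week,
            )
            for w, p in a.positions.items():
                np.testing.assert_allclose(b.positions[w], p, atol=1e-5)


class TestTangleObjects:
    def make_labels(self, sizes):
        """One labelled cube-ish component per requested voxel count."""
        labels = np.zeros((20, 30, 30 * len(sizes)), dtype=int)
        for k, size in enumerate(sizes):
            nz = int(np.ceil(size / 25))
            flat = np.zeros(nz * 25, dtype=bool)
            flat[:size] = True
            block = flat.reshape(nz, 5, 5)
            labels[2 : 2 + nz, 2:7, 30 * k + 2 : 30 * k + 7][block] = k + 1
        return labels

    def test_threshold_boundary_99_rejected_100_retained(self):
        labels = self.make_labels([99, 100])
        objs = filter_tangle_objects(labels)
        assert len(objs) == 1
        assert objs[0].voxel_count == 100

    def test_100_voxels_native_pitch_is_49_um3(self):
        labels = self.make_labels([100])
        (obj,) = filter_tangle_objects(labels)
        assert obj.volume_um3 == pytest.approx(49.0, abs=0.5)

    def test_planted_five_above_five_below(self):
        sizes = [40, 60, 80, 90, 99, 100, 120, 150, 200, 400]
        objs = filter_tangle_objects(self.make_labels(sizes))
        assert len(objs) == 5

    def test_missing_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            filter_tangle_objects(self.make_labels([100]), voxel_size_um=None)


class TestTangleStatus:
    def build_simple_tracks(self):
        sessions = [grid_cloud(w) for w in range(1, 5)]
        return build_tracks(sessions, edge_margin_um=0.0)

    def test_no_tangles_all_never_tangled(self):
        tracks = self.build_simple_tracks()
        tracks = assign_tangle_status(tracks, {w: [] for w in range(1, 5)})
        assert not any(t.ever_tangled for t in tracks)

    def test_tangle_2um_from_neuron_sets_onset_week3(self):
        tracks = self.build_simple_tracks()
        target = tracks[5]
        obj = TangleObject(
            centroid_um=target.positions[3] + np.array([2.0, 0, 0]),
            voxel_count=150,
            volume_um3=74.0,
            first_week_seen=3,
        )
        tracks = assign_tangle_status(tracks, {3: [obj]}, radius_um=10.0)
        assert target.tangle_onset_week == 3
        assert sum(t.ever_tangled for t in tracks) == 1

    def test_far_tangle_not_associated(self):
        tracks = self.build_simple_tracks()
        obj = TangleObject(
            centroid_um=np.array([200.0, 200.0, 200.0]), voxel_count=150, volume_um3=74.0
        )
        tracks = assign_tangle_status(tracks, {2: [obj]}, radius_um=10.0)
        assert not any(t.ever_tangled for t in tracks)
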