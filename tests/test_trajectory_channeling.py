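"""Residence time, censoring, occupancy and path adherence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiroscan.trajectory_channeling import (
    LigandTrajectory, ResidenceResult, hbond_occupancy, mean_residence,
    path_adherence, point_to_polyline_distance, read_trajectory,
    residence_time, write_xyz_trajectory,
)
from spiroscan.tunnel_finder import Tunnel


def traj_from_distances(distances, dt=0.1):
    """Trajectory whose per-frame min ligand-protein distance is prescribed:
    a single ligand atom on the x axis, a single protein atom at the origin."""
    d = np.asarray(distances, float)
    lig = np.zeros((len(d), 1, 3))
    lig[:, 0, 0] = d
    prot = np.zeros((len(d), 1, 3))
    return LigandTrajectory(dt=dt, ligand_coords=lig, protein_coords=prot,
                            ligand_labels=["LIG:C1"], protein_labels=["PRO:C1"])


def sliding_window_oracle(distances, escape_distance, sustain):
    """Brute-force scan over every window for the first sustained escape."""
    d = np.asarray(distances, float)
    for f in range(len(d) - sustain + 1):
        if all(d[f + k] > escape_distance for k in range(sustain)):
            return f
    return None


class TestReaders:
    def test_xyz_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(5, 4, 3)) * 10
        p = tmp_path / "t.xyz"
        write_xyz_trajectory(p, ["L", "P", "P", "P"], frames)
        traj = read_trajectory(p, dt=0.1, ligand_selection="L")
        assert traj.n_frames == 5
        assert traj.ligand_coords.shape == (5, 1, 3)
        np.testing.assert_allclose(traj.ligand_coords[:, 0], frames[:, 0], atol=1e-4)

    def test_multimodel_pdb_matches_xyz(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = np.round(rng.normal(size=(3, 2, 3)) * 5, 3)
        xyz = tmp_path / "t.xyz"
        write_xyz_trajectory(xyz, ["L", "P"], frames)
        pdb = tmp_path / "t.pdb"
        with open(pdb, "w") as fh:
            for f, frame in enumerate(frames):
                fh.write(f"MODEL     {f + 1}\n")
                for i, (name, res) in enumerate([("C1", "LIG"), ("C1", "PRO")]):
                    x, y, z = frame[i]
                    fh.write(f"ATOM  {i + 1:5d} {name:<4s} {res:<3s} A   1    "
                             f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
                fh.write("ENDMDL\n")
        t_xyz = read_trajectory(xyz, dt=0.1, ligand_selection="L")
        t_pdb = read_trajectory(pdb, dt=0.1, ligand_selection="LIG")
        np.testing.assert_allclose(t_xyz.ligand_coords, t_pdb.ligand_coords, atol=1e-3)
        np.testing.assert_allclose(t_xyz.protein_coords, t_pdb.protein_coords, atol=1e-3)

    def test_inconsistent_frame_names_the_frame(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\nframe 0\nL 0 0 0\nP 1 1 1\n"
                     "1\nframe 1\nL 0 0 0\n")
        with pytest.raises(ValueError, match="frame 2"):
            read_trajectory(p, dt=0.1, ligand_selection="L")


class TestResidenceTime:
    def test_programmed_escape_frame(self):
        d = np.full(200, 3.0)
        d[50:] = 15.0
        res = residence_time(traj_from_distances(d, dt=0.1))
        assert res.escape_frame == 50
        assert res.time == pytest.approx(5.0)
        assert not res.censored

    def test_never_escaping_is_censored_at_full_duration(self):
        d = np.full(2000, 4.0)
        res = residence_time(traj_from_distances(d, dt=0.1))
        assert res.censored and res.escape_frame is None
        assert res.time == pytest.approx(200.0)

    def test_short_excursion_ignored(self):
        d = np.full(300, 3.0)
        d[40:43] = 20.0        # 3-frame excursion < sustain_frames
        d[100:] = 20.0         # true escape
        traj = traj_from_distances(d, dt=0.1)
        res = residence_time(traj, sustain_frames=5)
        assert res.escape_frame == 100
        assert res.escape_frame == sliding_window_oracle(d, 10.0, 5)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 20, size=100)
        traj = traj_from_distances(d)
        for sustain in (1, 3, 5):
            res = residence_time(traj, escape_distance=10.0, sustain_frames=sustain)
            assert res.escape_frame == sliding_window_oracle(d, 10.0, sustain)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_escape_distance_and_sustain(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 20, size=80)
        traj = traj_from_distances(d)
        times_dist = [residence_time(traj, escape_distance=e).time
                      for e in (5.0, 10.0, 15.0)]
        assert times_dist == sorted(times_dist)
        times_sustain = [residence_time(traj, sustain_frames=s).time
                         for s in (1, 2, 5, 10)]
        assert times_sustain == sorted(times_sustain)

    def test_censored_result_cannot_carry_escape_frame(self):
        with pytest.raises(ValueError):
            ResidenceResult(time=1.0, censored=True, escape_frame=3)


class TestMeanResidence:
    def test_equal_times(self):
        res = [ResidenceResult(4.0, False, 10)] * 3
        out = mean_residence(res)
        assert out["mean"] == 4.0 and out["sd"] == 0.0 and out["n_censored"] == 0
        assert not out["is_lower_bound"]

    def test_censored_mix_is_lower_bound(self):
        res = [ResidenceResult(9.0, False, 90),
               ResidenceResult(200.0, True, None),
               ResidenceResult(125.0, False, 1250)]
        out = mean_residence(res)
        assert out["mean"] == pytest.approx(111.3333, abs=1e-3)
        assert out["n_censored"] == 1 and out["is_lower_bound"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_residence([])


class TestOccupancy:
    def _pair_traj(self, distances):
        n = len(distances)
        lig = np.zeros((n, 1, 3))
        prot = np.zeros((n, 2, 3))
        prot[:, 1, 0] = distances
        return LigandTrajectory(dt=0.1, ligand_coords=lig, protein_coords=prot,
                                ligand_labels=["LIG:C1"],
                                protein_labels=["ACC:O1", "DON:N1"])

    def test_always_bonded(self):
        t = self._pair_traj(np.full(50, 2.9))
        assert hbond_occupancy(t, ("protein", [1]), ("protein", [0])) == 1.0

    def test_never_bonded(self):
        t = self._pair_traj(np.full(50, 6.0))
        assert hbond_occupancy(t, ("protein", [1]), ("protein", [0])) == 0.0

    def test_bernoulli_fraction_recovered(self):
        rng = np.random.default_rng(5)
        contact = rng.random(1000) < 0.30
        d = np.where(contact, 2.9, 6.0)
        t = self._pair_traj(d)
        occ = hbond_occupancy(t, ("protein", [1]), ("protein", [0]))
        assert occ == pytest.approx(contact.mean())


class TestPathAdherence:
    def _tunnel(self):
        x = np.linspace(0, 30, 31)
        return Tunnel(centerline=np.column_stack([x, np.zeros(31), np.zeros(31)]),
                      radii=np.full(31, 3.0), grid_spacing=0.6)

    def test_glued_to_centerline(self):
        n = 100
        lig = np.zeros((n, 1, 3))
        lig[:, 0, 0] = np.linspace(0, 30, n)
        prot = np.zeros((n, 1, 3))  # ligand stays within escape distance
        t = LigandTrajectory(dt=0.1, ligand_coords=lig, protein_coords=prot,
                             ligand_labels=["L:C"], protein_labels=["P:C"])
        assert path_adherence(t, self._tunnel(), escape_distance=100.0) == 1.0

    def test_far_ligand_never_adheres(self):
        n = 50
        lig = np.full((n, 1, 3), 50.0)
        prot = np.full((n, 1, 3), 50.0)
        prot[:, 0, 1] = 55.0
        t = LigandTrajectory(dt=0.1, ligand_coords=lig, protein_coords=prot,
                             ligand_labels=["L:C"], protein_labels=["P:C"])
        assert path_adherence(t, self._tunnel(), escape_distance=100.0) == 0.0

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 5000))
    def test_matches_geometry_oracle(self, seed):
        """Adherence equals a per-frame brute-force point-to-segment check."""
        rng = np.random.default_rng(seed)
        n = 60
        lig = rng.uniform(-5, 35, size=(n, 1, 3))
        prot = np.zeros((n, 1, 3))
        t = LigandTrajectory(dt=0.1, ligand_coords=lig, protein_coords=prot,
                             ligand_labels=["L:C"], protein_labels=["P:C"])
        tun = self._tunnel()
        cutoff = 5.0
        got = path_adherence(t, tun, cutoff=cutoff, escape_distance=1e6)

        def seg_dist(p, a, b):
            ab = b - a
            tt = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + tt * ab))

        centroids = lig[:, 0, :]
        within = 0
        for p in centroids:
            dmin = min(seg_dist(p, tun.centerline[i], tun.centerline[i + 1])
                       for i in range(len(tun.centerline) - 1))
            if dmin <= cutoff:
                within += 1
        assert got == pytest.approx(within / n)


def test_point_to_polyline_matches_single_segment():
    poly = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    pts = np.array([[5.0, 2.0, 0], [-3.0, 0, 0], [12.0, 0, 4.0]])
    d = point_to_polyline_distance(pts, poly)
    np.testing.assert_allclose(d, [2.0, 3.0, np.hypot(2.0, 4.0)])
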