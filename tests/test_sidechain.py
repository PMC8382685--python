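"""Sidechain orientation frames, spherical coordinates and state counting."""
import numpy as np
import pytest

from fvstates.errors import UnsupportedResidueError
from fvstates.sidechain import (
    OrientationSeries,
    SphericalKMeans,
    orientation_states,
    residue_frame,
    sidechain_vectors,
)
from fvstates.structures import Trajectory, build_fv
from fvstates.synthetic import PROBE_RESIDUE
from tests_util import random_rigid


def _stub_residue_traj(cb_offsets, c_offset=(0.7, 1.2, 0.0), extra_atoms=()):
    """Single-residue trajectory with N, CA, C fixed and CB per frame at
    CA + offset; optional extra sidechain atoms appended per frame."""
    n_frames = len(cb_offsets)
    names = ["N", "CA", "C", "CB"] + [name for name, _ in extra_atoms]
    elements = [nm[0] for nm in names]
    base = {
        "N": np.array([-1.0, -1.0, 0.0]),
        "CA": np.zeros(3),
        "C": np.asarray(c_offset, float),
    }
    coords = np.zeros((n_frames, len(names), 3))
    for f in range(n_frames):
        coords[f, 0] = base["N"]
        coords[f, 1] = base["CA"]
        coords[f, 2] = base["C"]
        coords[f, 3] = np.asarray(cb_offsets[f], float)
        for j, (_, offs) in enumerate(extra_atoms):
            coords[f, 4 + j] = np.asarray(offs[f], float)
    numbering = {("H", 1): 1, ("L", 1): 1}
    # chain L is a far-away dummy so the Fv invariant (both chains) holds
    l_names = ["N", "CA", "C"]
    fv = build_fv(
        atom_name=names + l_names,
        element=elements + [n[0] for n in l_names],
        chain=["H"] * len(names) + ["L"] * 3,
        res_name=["ALA"] * len(names) + ["GLY"] * 3,
        res_id=[1] * len(names) + [1] * 3,
        coords=np.concatenate([coords[0], np.tile([50.0, 0, 0], (3, 1))]),
        numbering=numbering,
    )
    full = np.concatenate(
        [coords, np.tile([50.0, 0.0, 0.0], (n_frames, 3, 1))], axis=1
    )
    return Trajectory(topology=fv, coords=full)


class TestResidueFrame:
    def test_constructed_axes_follow_the_convention(self):
        """CB at (1.5,0,0), C at (0.7,1.2,0): x=(1,0,0), y=(0,1,0), z=(0,0,1)."""
        traj = _stub_residue_traj([[1.5, 0, 0]] * 3)
        frame = residue_frame(traj, 0)
        np.testing.assert_allclose(frame.x_axis, [1, 0, 0], atol=1e-10)
        np.testing.assert_allclose(frame.y_axis, [0, 1, 0], atol=1e-10)
        np.testing.assert_allclose(frame.z_axis, [0, 0, 1], atol=1e-10)

    def test_rigid_tumbling_is_fully_removed(self):
        rng = np.random.default_rng(1)
        traj = _stub_residue_traj([[1.5, 0, 0]] * 8)
        coords = traj.coords.copy()
        for f in range(len(coords)):
            r, t = random_rigid(rng)
            coords[f] = coords[f] @ r.T + t
        tumbled = Trajectory(topology=traj.topology, coords=coords)
        frame = residue_frame(tumbled, 0)
        # aligned backbone triads coincide with the average in every frame
        triads = np.einsum(
            "fij,faj->fai", frame.rotations, tumbled.coords[:, :3]
        ) + frame.translations[:, None, :]
        assert np.max(np.std(triads, axis=0)) < 1e-8

    def test_glycine_without_cb_is_unsupported(self, synthetic_result):
        traj = _stub_residue_traj([[1.5, 0, 0]] * 3)
        ri = traj.topology.residue_index_of("L", 1)  # dummy chain has no CB
        with pytest.raises(UnsupportedResidueError):
            residue_frame(traj, ri)


class TestSidechainVectors:
    def test_cb_along_x_gives_theta_90_phi_0(self):
        traj = _stub_residue_traj([[1.5, 0, 0]] * 4)
        series = sidechain_vectors(traj, 0)
        np.testing.assert_allclose(series.theta_deg, 90.0, atol=1e-8)
        np.testing.assert_allclose(series.phi_deg, 0.0, atol=1e-8)

    def test_com_at_pole_uses_phi_zero_convention(self):
        # CB split symmetrically about +z so that the mean stays on x but a
        # single frame with CB straight up lands exactly at the pole
        traj = _stub_residue_traj([[1.5, 0, 0], [0, 0, 1.5], [1.5, 0, 0], [0, 0, -1.5]])
        series = sidechain_vectors(traj, 0)
        assert series.theta_deg[1] == pytest.approx(
            np.degrees(np.arccos(series.vectors[1, 2])), abs=1e-8
        )
        at_pole = np.isclose(np.abs(series.vectors[:, 2]), 1.0, atol=1e-12)
        assert np.all(series.phi_deg[at_pole] == 0.0)

    def test_com_is_mass_weighted(self):
        # heavy sulfur pulls the COM toward itself
        cb = [[1.5, 0, 0]] * 3
        sg = [[0.0, 3.0, 0.0]] * 3
        traj = _stub_residue_traj(cb, extra_atoms=[("SG", sg)])
        series = sidechain_vectors(traj, 0)
        m_c, m_s = 12.011, 32.06
        com = (m_c * np.array([1.5, 0, 0]) + m_s * np.array([0, 3, 0])) / (m_c + m_s)
        expected = com / np.linalg.norm(com)
        np.testing.assert_allclose(series.vectors[0], expected, atol=1e-10)

    def test_generator_stub_rotation_recovered_as_great_circle_arc(
        self, synthetic_result, system
    ):
        chain, rid = PROBE_RESIDUE
        ri = synthetic_result.fv.residue_index_of(chain, rid)
        series = sidechain_vectors(synthetic_result.trajectory, ri)
        states = synthetic_result.state_labels
        means = []
        for s in range(system.n_states):
            v = series.vectors[states == s].mean(axis=0)
            means.append(v / np.linalg.norm(v))
        arc01 = np.degrees(np.arccos(np.clip(means[0] @ means[1], -1, 1)))
        arc02 = np.degrees(np.arccos(np.clip(means[0] @ means[2], -1, 1)))
        assert arc01 == pytest.approx(
            abs(system.stub_angles_deg[1] - system.stub_angles_deg[0]), abs=1.0
        )
        assert arc02 == pytest.approx(
            abs(system.stub_angles_deg[2] - system.stub_angles_deg[0]), abs=1.0
        )

    def test_series_invariant_under_global_rigid_transforms(self, synthetic_result):
        rng = np.random.default_rng(4)
        chain, rid = PROBE_RESIDUE
        ri = synthetic_result.fv.residue_index_of(chain, rid)
        sub = Trajectory(
            topology=synthetic_result.fv,
            coords=synthetic_result.trajectory.coords[:30].copy(),
        )
        base = sidechain_vectors(sub, ri)
        for _ in range(5):
            r, t = random_rigid(rng)
            moved = Trajectory(topology=synthetic_result.fv, coords=sub.coords @ r.T + t)
            series = sidechain_vectors(moved, ri)
            np.testing.assert_allclose(series.theta_deg, base.theta_deg, atol=1e-8)
            np.testing.assert_allclose(series.phi_deg, base.phi_deg, atol=1e-8)

    def test_mean_vector_norm_at_most_one(self, synthetic_result):
        chain, rid = PROBE_RESIDUE
        ri = synthetic_result.fv.residue_index_of(chain, rid)
        series = sidechain_vectors(synthetic_result.trajectory, ri)
        assert np.linalg.norm(series.vectors.mean(axis=0)) <= 1.0
        np.testing.assert_allclose(np.linalg.norm(series.vectors, axis=1), 1.0, atol=1e-12)


def _series_from_vectors(v):
    v = np.asarray(v, float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    theta = np.degrees(np.arccos(np.clip(v[:, 2], -1, 1)))
    phi = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return OrientationSeries(
        res_index=0, label="H:1", vectors=v, theta_deg=theta, phi_deg=phi
    )


class TestOrientationStates:
    def test_two_antipodal_bundles_populations(self):
        rng = np.random.default_rng(5)
        a = np.array([0.0, 0, 1]) + rng.normal(0, 0.05, size=(700, 3))
        b = np.array([0.0, 0, -1]) + rng.normal(0, 0.05, size=(300, 3))
        states = orientation_states(_series_from_vectors(np.concatenate([a, b])), seed=0)
        assert states.n_states == 2
        assert states.populations[0] == pytest.approx(0.7, abs=0.02)
        assert states.populations[1] == pytest.approx(0.3, abs=0.02)

    def test_isotropic_vectors_yield_single_state(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal((2000, 3))
        states = orientation_states(_series_from_vectors(v), seed=0)
        assert states.n_states == 1
        assert states.populations[0] == 1.0

    def test_constant_series_is_one_state(self):
        v = np.tile([0.0, 1.0, 0.0], (50, 1))
        states = orientation_states(_series_from_vectors(v), seed=0)
        assert states.n_states == 1
        assert states.populations[0] == 1.0

    def test_population_ranks_stable_under_subsampling(self, synthetic_result):
        chain, rid = PROBE_RESIDUE
        ri = synthetic_result.fv.residue_index_of(chain, rid)
        series = sidechain_vectors(synthetic_result.trajectory, ri)
        full = orientation_states(series, seed=0)
        half = orientation_states(
            _series_from_vectors(series.vectors[::2]), seed=0
        )
        assert full.n_states == half.n_states
        # matching states by direction, rank order must agree
        order = [int(np.argmax(half.mean_directions @ d)) for d in full.mean_directions]
        assert order == sorted(order)

    def test_spherical_kmeans_is_deterministic_per_seed(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal((500, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        a = SphericalKMeans(n_clusters=3, random_state=7).fit(v)
        b = SphericalKMeans(n_clusters=3, random_state=7).fit(v)
        np.testing.assert_array_equal(a.labels_, b.labels_)
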