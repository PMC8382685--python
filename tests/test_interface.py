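"""VH-VL interface orientation measures, invariances and distributions."""
import dataclasses

import numpy as np
import pytest

from fvstates.errors import GeometryError, InputError
from fvstates.interface import (
    MEASURE_NAMES,
    angle_kde,
    dc_variance,
    fit_domain_frames,
    interface_measures,
    measures_from_frames,
    orientation_statistics,
)
from fvstates.structures import Trajectory
from tests_util import random_rigid


@pytest.fixture(scope="module")
def measures(synthetic_result):
    sub = Trajectory(
        topology=synthetic_result.fv,
        coords=synthetic_result.trajectory.coords[:600].copy(),
    )
    return interface_measures(sub, synthetic_result.reference), synthetic_result.state_labels[:600]


class TestFitDomainFrames:
    def test_reference_pose_self_consistency(self, synthetic_result):
        """Fitting the consensus onto the frame it was built from gives
        zero fit RMSD and anchors at the core centroids."""
        ref = synthetic_result.reference
        # frame 0 of a zero-noise regeneration equals the reference pose for
        # the rigid core, so core fit residuals vanish
        frames = fit_domain_frames(synthetic_result.fv, ref, coords=synthetic_result.trajectory.coords[0])
        assert frames.h_rmsd == pytest.approx(0.0, abs=1e-8)
        assert frames.l_rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(frames.h_anchor, ref.heavy.anchor, atol=1e-8)

    def test_global_rotation_co_rotates_frames_and_preserves_dc(self, synthetic_result):
        rng = np.random.default_rng(8)
        coords = synthetic_result.trajectory.coords[0]
        base = fit_domain_frames(synthetic_result.fv, synthetic_result.reference, coords=coords)
        r, t = random_rigid(rng)
        moved = fit_domain_frames(
            synthetic_result.fv, synthetic_result.reference, coords=coords @ r.T + t
        )
        assert np.linalg.norm(moved.c_vector) == pytest.approx(
            np.linalg.norm(base.c_vector), abs=1e-8
        )
        np.testing.assert_allclose(moved.h_pc1, base.h_pc1 @ r.T, atol=1e-8)

    def test_insufficient_core_coverage_raises(self, synthetic_result):
        ref = synthetic_result.reference
        # keep only 8 of 12 core positions in the definition of H, then ask
        # for a structure missing more than 20%: drop 5 positions instead
        short = dataclasses.replace(
            synthetic_result.fv,
            numbering=synthetic_result.fv.numbering[
                ~(
                    (synthetic_result.fv.numbering["chain"] == "H")
                    & (synthetic_result.fv.numbering["imgt_position"].isin([1, 2, 3, 4]))
                )
            ].reset_index(drop=True),
        )
        with pytest.raises(GeometryError):
            fit_domain_frames(short, ref)


class TestInterfaceMeasures:
    def test_macrostate_hl_shifts_match_generator_rotations(self, measures, system):
        df, states = measures
        hl = df["HL"].to_numpy()
        base = hl[states == 0].mean()
        for s in (1, 2):
            shift = hl[states == s].mean() - base
            assert shift == pytest.approx(system.interdomain_angles_deg[s], abs=0.5)

    def test_identical_frames_have_zero_spread(self, synthetic_result):
        traj = synthetic_result.trajectory
        frozen = Trajectory(
            topology=synthetic_result.fv, coords=np.repeat(traj.coords[:1], 4, axis=0)
        )
        df = interface_measures(frozen, synthetic_result.reference)
        for m in MEASURE_NAMES:
            assert df[m].std() == pytest.approx(0.0, abs=1e-10)

    def test_all_measures_invariant_under_global_rigid_transforms(self, synthetic_result):
        rng = np.random.default_rng(9)
        traj = synthetic_result.trajectory
        sub = Trajectory(topology=synthetic_result.fv, coords=traj.coords[:5].copy())
        base = interface_measures(sub, synthetic_result.reference)
        for _ in range(10):
            r, t = random_rigid(rng)
            moved = Trajectory(topology=synthetic_result.fv, coords=sub.coords @ r.T + t)
            df = interface_measures(moved, synthetic_result.reference)
            for m in MEASURE_NAMES:
                np.testing.assert_allclose(df[m], base[m], atol=1e-6)

    def test_plane_vector_order_antisymmetry_of_hl(self, synthetic_result):
        """Exchanging which plane vector is measured first negates the
        signed torsion about the (unchanged) interdomain axis."""
        frames = fit_domain_frames(
            synthetic_result.fv,
            synthetic_result.reference,
            coords=synthetic_result.trajectory.coords[0],
        )
        swapped = dataclasses.replace(
            frames,
            h_pc1=frames.l_pc1,
            h_pc2=frames.l_pc2,
            l_pc1=frames.h_pc1,
            l_pc2=frames.h_pc2,
        )
        hl = measures_from_frames(frames)["HL"]
        hl_swapped = measures_from_frames(swapped)["HL"]
        assert hl_swapped == pytest.approx(-hl, abs=1e-8)

    def test_dc_positive_and_angles_finite(self, measures):
        df, _ = measures
        assert (df["dc"] > 0).all()
        assert np.isfinite(df[list(MEASURE_NAMES)].to_numpy()).all()


class TestAngleKDE:
    def test_standard_normal_density_at_mode(self):
        rng = np.random.default_rng(10)
        v = rng.standard_normal(100_000)
        grid, dens = angle_kde(v)
        at_zero = dens[np.argmin(np.abs(grid))]
        assert at_zero == pytest.approx(0.39894, rel=0.05)

    def test_density_integrates_to_one(self, measures):
        df, _ = measures
        grid, dens = angle_kde(df["HL"].to_numpy())
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_repeated_value_gives_delta_like_peak(self):
        grid, dens = angle_kde(np.full(50, 12.5))
        assert grid[np.argmax(dens)] == pytest.approx(12.5, abs=0.1)

    def test_shrinking_bandwidth_approaches_empirical_histogram(self):
        rng = np.random.default_rng(11)
        v = np.concatenate([rng.normal(-5, 0.3, 400), rng.normal(5, 0.3, 600)])
        grid = np.linspace(-10, 10, 400)
        hist, edges = np.histogram(v, bins=grid.size, range=(-10, 10), density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        sups = []
        for bw in (2.0, 1.0, 0.5):
            g, dens = angle_kde(v, bandwidth=bw, grid=centers)
            sups.append(np.max(np.abs(dens - hist)))
        assert sups[0] > sups[1] > sups[2]

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError):
            angle_kde([1.0])


class TestOrientationStatistics:
    def test_single_state_reduces_to_global_mean(self, measures):
        df, _ = measures
        stats = orientation_statistics(df)
        hl_row = stats[(stats["measure"] == "HL")].iloc[0]
        assert hl_row["mean"] == pytest.approx(df["HL"].mean())

    def test_per_state_hl_means_recover_generator_values(self, measures, system):
        df, states = measures
        stats = orientation_statistics(df, states)
        means = {
            int(row["state"]): row["mean"]
            for _, row in stats[stats["measure"] == "HL"].iterrows()
        }
        base = means[0]
        for s in (1, 2):
            # noise-free interface: SEM is tiny, check against ground truth
            assert means[s] - base == pytest.approx(
                system.interdomain_angles_deg[s], abs=0.5
            )

    def test_constant_dc_has_zero_variance(self, measures):
        df, _ = measures
        const = df.copy()
        const["dc"] = 42.0
        assert dc_variance(const) == 0.0
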