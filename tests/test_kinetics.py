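"""tICA, free-energy surfaces, MSM estimation, PCCA+ and the CK test."""
import numpy as np
import pytest
import scipy.linalg

from fvstates.errors import EstimationError, FeatureError, InputError
from fvstates.features import FeatureLabel, FeatureMatrix
from fvstates.kinetics import (
    KB_KCAL,
    TICA,
    MarkovStateModel,
    ck_test,
    estimate_msm,
    free_energy_surface,
    implied_timescales,
    kmeans_microstates,
    pcca,
    reversible_transition_matrix,
)
from fvstates.synthetic import simulate_state_sequence

TWO_STATE_T = np.array([[0.95, 0.05], [0.10, 0.90]])


class TestTICA:
    def test_white_noise_has_no_slow_modes(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((100_000, 5))
        model = TICA(lag=1).fit(x)
        assert np.max(np.abs(model.eigenvalues_)) < 0.05

    def test_first_component_tracks_the_slow_coordinate(self):
        rng = np.random.default_rng(1)
        n = 50_000
        slow = simulate_state_sequence(TWO_STATE_T, n, seed=3).astype(float)
        x = np.column_stack([slow + 0.1 * rng.standard_normal(n),
                             rng.standard_normal((n, 4))])
        model = TICA(lag=1, n_components=1).fit(x)
        proj = model.transform(x)[:, 0]
        r = np.corrcoef(proj, slow)[0, 1]
        assert abs(r) > 0.9

    def test_duplicated_column_handled_by_regularization(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((5000, 3))
        base[:, 0] = np.cumsum(rng.standard_normal(5000)) * 0.01 + base[:, 0]
        dup = np.column_stack([base, base[:, 0]])
        lam_single = TICA(lag=2).fit(base).eigenvalues_
        lam_dup = TICA(lag=2).fit(dup).eigenvalues_
        np.testing.assert_allclose(lam_dup[:3], lam_single[:3], atol=1e-6)

    def test_matches_generalized_eigensolver_oracle(self):
        """Direct scipy.linalg.eigh(C_tau, C_0) on the same covariances."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.standard_normal((200, 5)) @ rng.standard_normal((5, 5))
            model = TICA(lag=1).fit(x)
            lam_oracle = np.sort(scipy.linalg.eigh(model.ctau_, model.c0_, eigvals_only=True))[::-1]
            np.testing.assert_allclose(model.eigenvalues_, lam_oracle, atol=1e-8)
            # C0-orthonormality of the eigenvectors
            v = model.eigenvectors_
            np.testing.assert_allclose(v.T @ model.c0_ @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_projected_training_variance_is_unit(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.standard_normal((20_000, 4)), axis=0) * 0.01
        x += rng.standard_normal((20_000, 4))
        model = TICA(lag=1).fit(x)
        proj = model.transform(x)
        np.testing.assert_allclose(np.var(proj, axis=0), 1.0, rtol=0.05)

    def test_mean_projects_to_origin_and_projection_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((500, 3))
        model = TICA(lag=1).fit(x)
        np.testing.assert_allclose(model.transform(model.mean_), 0.0, atol=1e-10)
        np.testing.assert_allclose(model.transform(x[10]), model.transform(x[10]))

    def test_label_mismatch_rejected_without_reordering(self):
        rng = np.random.default_rng(6)
        labels = [
            FeatureLabel("H", "H1", 27 + i, "psi", trig) for i in range(2) for trig in ("sin", "cos")
        ]
        fm = FeatureMatrix(values=rng.standard_normal((50, 4)), labels=labels)
        model = TICA(lag=1).fit(fm)
        swapped = FeatureMatrix(values=fm.values, labels=labels[::-1])
        with pytest.raises(FeatureError):
            model.transform(swapped)

    def test_lag_longer_than_trajectory_rejected(self):
        with pytest.raises(InputError):
            TICA(lag=10).fit(np.zeros((5, 3)))


class TestFreeEnergySurface:
    def test_two_bin_ratio_closed_form(self):
        """0.8/0.2 at 300 K: dF = kB*300*ln4 = 0.826 kcal/mol."""
        pts = np.concatenate([np.zeros((8000, 2)), np.ones((2000, 2))])
        fes = free_energy_surface(pts, temperature=300.0, bins=2)
        finite = fes.free_energy[np.isfinite(fes.free_energy)]
        expected = KB_KCAL * 300.0 * np.log(4.0)
        assert np.max(finite) - np.min(finite) == pytest.approx(expected, abs=1e-10)
        assert np.min(finite) == 0.0
        assert expected == pytest.approx(0.826, abs=5e-4)

    def test_uniform_population_is_flat_zero(self):
        x = np.repeat(np.arange(4.0), 10)
        pts = np.column_stack([x, np.zeros_like(x)])
        fes = free_energy_surface(pts, bins=(4, 1))
        np.testing.assert_allclose(fes.free_energy, 0.0, atol=1e-12)

    def test_single_point_single_zero_bin(self):
        fes = free_energy_surface(np.array([[0.3, 0.4]]), bins=10)
        finite = np.isfinite(fes.free_energy)
        assert finite.sum() == 1
        assert fes.free_energy[finite][0] == 0.0

    def test_invalid_temperature_rejected(self):
        with pytest.raises(InputError):
            free_energy_surface(np.zeros((5, 2)), temperature=0.0)


class TestKMeansMicrostates:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        blobs = [rng.normal(c, 0.05, size=(200, 2)) for c in ((0, 0), (5, 0), (0, 5))]
        x = np.concatenate(blobs)
        truth = np.repeat([0, 1, 2], 200)
        centers, dtraj = kmeans_microstates(x, k=3, seed=1)
        # each blob maps to exactly one center
        for b in range(3):
            assert len(np.unique(dtraj[truth == b])) == 1
        assert len(np.unique(dtraj)) == 3

    def test_k_equal_one_returns_data_mean(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((100, 3))
        centers, _ = kmeans_microstates(x, k=1, seed=0)
        np.testing.assert_allclose(centers[0], x.mean(axis=0), atol=1e-8)

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((500, 2))
        c1, d1 = kmeans_microstates(x, k=10, seed=42)
        c2, d2 = kmeans_microstates(x, k=10, seed=42)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(d1, d2)

    def test_k_larger_than_points_rejected(self):
        with pytest.raises(InputError):
            kmeans_microstates(np.zeros((3, 2)), k=5, seed=0)


class TestMarkovStateModel:
    def test_two_state_chain_recovered_within_sampling_error(self):
        d = simulate_state_sequence(TWO_STATE_T, 100_000, seed=11)
        msm = estimate_msm(d, lag=1)
        np.testing.assert_allclose(msm.transition_matrix_, TWO_STATE_T, atol=0.01)
        # stationary distribution matches empirical visit frequencies
        emp = np.bincount(d) / len(d)
        np.testing.assert_allclose(msm.stationary_distribution_, emp, atol=0.01)

    def test_transition_matrix_properties(self):
        d = simulate_state_sequence(TWO_STATE_T, 20_000, seed=12)
        msm = estimate_msm(d, lag=2)
        t, pi = msm.transition_matrix_, msm.stationary_distribution_
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(pi @ t, pi, atol=1e-8)
        np.testing.assert_allclose(pi[:, None] * t, (pi[:, None] * t).T, atol=1e-8)

    def test_deterministic_alternating_sequence(self):
        d = np.array([0, 1] * 50)
        msm = estimate_msm(d, lag=1)
        np.testing.assert_allclose(
            msm.transition_matrix_, [[0.0, 1.0], [1.0, 0.0]], atol=1e-12
        )

    def test_absorbing_tail_pruned_by_connectivity(self):
        d = np.array([0, 1] * 30 + [2] * 40)  # state 2 never left
        msm = estimate_msm(d, lag=1)
        assert set(msm.active_set_) == {0, 1}

    def test_reversible_mle_preserves_row_sums_of_counts(self):
        rng = np.random.default_rng(13)
        c = rng.integers(1, 50, size=(4, 4)).astype(float)
        t, pi = reversible_transition_matrix(c)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(pi[:, None] * t, (pi[:, None] * t).T, atol=1e-10)


class TestImpliedTimescales:
    def test_exact_two_state_chain_closed_form(self):
        """t2 = -1/ln(0.85) ~ 6.15 steps for [[.95,.05],[.10,.90]]."""
        msm = MarkovStateModel(lag=1)
        msm.transition_matrix_ = TWO_STATE_T
        msm.stationary_distribution_ = np.array([2 / 3, 1 / 3])
        msm.active_set_ = np.array([0, 1])
        ts = msm.timescales()
        assert ts[0] == pytest.approx(-1.0 / np.log(0.85), abs=1e-10)
        assert ts[0] == pytest.approx(6.15, abs=0.005)

    def test_no_observed_transitions_yields_undefined_not_fabricated(self):
        d = np.array([0] * 30 + [1] * 30)  # one transition, absorbing
        msm = estimate_msm(d, lag=1)
        # active set collapses to a single state: no finite timescale exists
        assert msm.n_states_ == 1
        assert len(msm.timescales()) == 0

    def test_lag_consistency_on_markovian_chain(self):
        d = simulate_state_sequence(TWO_STATE_T, 200_000, seed=14)
        lags, its = implied_timescales(d, [1, 2, 4], k=1)
        t1, t2, t4 = its[:, 0]
        assert t2 == pytest.approx(t1, rel=0.1)
        assert t4 == pytest.approx(t1, rel=0.1)


class TestPCCA:
    @staticmethod
    def _metastable_dtraj(n=200_000, seed=21):
        # 6 microstates in 3 metastable blocks
        block_t = np.array(
            [[0.98, 0.015, 0.005], [0.015, 0.975, 0.01], [0.005, 0.012, 0.983]]
        )
        macro = simulate_state_sequence(block_t, n, seed=seed)
        rng = np.random.default_rng(seed + 1)
        micro = macro * 2 + rng.integers(0, 2, size=n)  # fast intra-block flips
        return micro, macro

    def test_recovers_metastable_blocks_up_to_relabeling(self):
        micro, macro = self._metastable_dtraj()
        msm = estimate_msm(micro, lag=5)
        p = pcca(msm, 3)
        assign = p.assignments_
        blocks = {tuple(sorted(np.nonzero(assign == a)[0])) for a in range(3)}
        assert blocks == {(0, 1), (2, 3), (4, 5)}
        np.testing.assert_allclose(p.memberships_.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(p.memberships_ >= 0) and np.all(p.memberships_ <= 1)

    def test_macrostate_populations_sum_to_one(self):
        micro, _ = self._metastable_dtraj(n=50_000, seed=22)
        p = pcca(estimate_msm(micro, lag=5), 3)
        assert p.populations_.sum() == pytest.approx(1.0, abs=1e-10)
        assert p.fuzzy_populations_.sum() == pytest.approx(1.0, abs=1e-8)

    def test_as_many_macrostates_as_microstates_gives_identity(self):
        d = simulate_state_sequence(TWO_STATE_T, 20_000, seed=23)
        msm = estimate_msm(d, lag=1)
        p = pcca(msm, 2)
        np.testing.assert_allclose(np.sort(p.memberships_, axis=1), [[0, 1], [0, 1]], atol=1e-8)

    def test_free_energy_difference_matches_population_ratio(self):
        """dF(a,b) = -kB T ln(pi_a/pi_b) consistency on the coarse model."""
        micro, macro = self._metastable_dtraj(n=100_000, seed=24)
        p = pcca(estimate_msm(micro, lag=5), 3)
        emp = np.bincount(macro) / len(macro)
        # macrostate labels are a permutation: block a holds microstates 2a, 2a+1
        of_block = {a: int(p.assignments_[2 * a]) for a in range(3)}
        for a in range(3):
            for b in range(3):
                df_model = -KB_KCAL * 300 * np.log(
                    p.populations_[of_block[a]] / p.populations_[of_block[b]]
                )
                df_emp = -KB_KCAL * 300 * np.log(emp[a] / emp[b])
                assert df_model == pytest.approx(df_emp, abs=0.1)


class TestChapmanKolmogorov:
    def test_markovian_data_within_bootstrap_ci(self):
        micro, _ = TestPCCA._metastable_dtraj(n=150_000, seed=31)
        msm = estimate_msm(micro, lag=2)
        ck = ck_test(micro, msm, 3, factors=(2, 3, 4, 5), seed=0)
        assert ck.factors == [2, 3, 4, 5]
        assert ck.within_ci().all()

    def test_factor_one_is_exact_by_construction(self):
        micro, _ = TestPCCA._metastable_dtraj(n=50_000, seed=32)
        msm = estimate_msm(micro, lag=2)
        ck = ck_test(micro, msm, 3, factors=(1,), seed=0)
        np.testing.assert_allclose(ck.predicted, ck.estimated, atol=1e-10)

    def test_non_markovian_data_reports_deviation_without_crash(self):
        # hidden fast sub-states: observed 2-state projection of a 3-state
        # chain where one observed state lumps a fast and a slow state
        t3 = np.array([[0.99, 0.01, 0.0], [0.3, 0.4, 0.3], [0.0, 0.01, 0.99]])
        d3 = simulate_state_sequence(t3, 200_000, seed=33)
        lumped = np.where(d3 == 2, 1, d3)  # lump states 1 and 2
        msm = estimate_msm(lumped, lag=1)
        ck = ck_test(lumped, msm, 2, factors=(2, 5), seed=0)
        assert ck.predicted.shape == ck.estimated.shape
        assert np.all(np.isfinite(ck.predicted))
        # systematic deviation must be visible at longer lags
        assert not ck.within_ci().all()
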