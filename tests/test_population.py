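"""Population analyses: reliability, overlap, noise correlations, capacity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurorecon import (
    EvokedResponseTensor,
    capacity_fit,
    image_accumulation,
    noise_correlation,
    overlap_index,
    overlap_sets,
    running_modulation_index,
    shuffle_trials,
    trial_reliability,
)
from neurorecon.population import RepresentationArea


def make_area(cell_id, pixels, p=64):
    mask = np.zeros(p, dtype=bool)
    mask[list(pixels)] = True
    return RepresentationArea(cell_id=cell_id, mask=mask, reverse_filter=np.zeros(p))


class TestTrialReliability:
    def test_identical_trials_are_perfectly_reliable(self, rng):
        pattern = rng.normal(size=50)
        A = np.tile(pattern, (6, 1))
        rep = trial_reliability(A)
        assert rep.across_trial_similarity == pytest.approx(1.0)
        assert rep.across_trial_variability == pytest.approx(0.0, abs=1e-12)

    def test_variability_equals_inverse_anova_f(self, rng):
        """The DoF-corrected variability ratio is exactly 1/F with units as
        groups and trials as samples — checked on 100 random instances."""
        for _ in range(100):
            n_trials = int(rng.integers(2, 8))
            n_units = int(rng.integers(2, 30))
            A = rng.normal(size=(n_trials, n_units)) + 3 * rng.normal(size=n_units)
            f_stat, _ = stats.f_oneway(*[A[:, u] for u in range(n_units)])
            rep = trial_reliability(A)
            assert rep.across_trial_variability == pytest.approx(1.0 / f_stat, abs=1e-10)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            trial_reliability(rng.normal(size=(1, 10)))
        with pytest.raises(ValueError):
            trial_reliability(np.tile(np.ones(5), (3, 1)))  # flat trial average

    def test_averaging_independent_cells_reduces_variability(self, rng):
        """More independently noisy units -> lower variability of the mean
        pattern (the overlap-area intuition)."""
        signal = rng.normal(size=40)
        var_few, var_many = [], []
        for n_units in (4, 32):
            sims = []
            for _ in range(10):
                A = signal[None, :40] + rng.normal(0, 1.0, size=(5, 40))
                # average n_units noisy copies of the same pattern
                stack = np.mean(
                    [signal + rng.normal(0, 1.0, size=(5, 40)) for _ in range(n_units)],
                    axis=0,
                )
                sims.append(trial_reliability(stack).across_trial_variability)
            (var_few if n_units == 4 else var_many).append(np.median(sims))
        assert var_many[0] < var_few[0]


class TestOverlap:
    def test_identical_masks_give_index_one(self):
        a = make_area(0, range(10))
        assert overlap_index(a.mask, a.mask) == 1.0

    def test_disjoint_masks_give_zero(self):
        assert overlap_index(make_area(0, range(5)).mask, make_area(1, range(5, 10)).mask) == 0.0

    def test_nested_half_mask_gives_half(self):
        big = make_area(0, range(10))
        small = make_area(1, range(5))
        assert overlap_index(big.mask, small.mask) == pytest.approx(0.5)

    def test_symmetry_and_translation_invariance(self, rng):
        a = make_area(0, rng.choice(64, 20, replace=False))
        b = make_area(1, rng.choice(64, 25, replace=False))
        assert overlap_index(a.mask, b.mask) == overlap_index(b.mask, a.mask)
        shift = 3
        a2 = np.roll(a.mask, shift)
        b2 = np.roll(b.mask, shift)
        assert overlap_index(a2, b2) == pytest.approx(overlap_index(a.mask, b.mask))

    def test_overlap_sets_threshold_and_membership(self):
        areas = [
            make_area(0, range(10)),
            make_area(1, range(2, 12)),  # Jaccard 8/12 = 0.67 with cell 0
            make_area(2, range(9, 19)),  # Jaccard 1/19 with cell 0
            make_area(3, []),  # empty -> excluded
        ]
        sets = overlap_sets(areas, responsive_cells=np.array([0, 1, 2, 3]), threshold=0.2)
        by_ref = {s.reference: s for s in sets}
        assert set(by_ref) == {0, 1, 2}  # empty-area cell is no reference
        assert list(by_ref[0].members) == [0, 1]
        assert 0 in by_ref[1].members


class TestNoiseCorrelation:
    def planted_tensor(self, rng, rho, n_cells=30, n_stim=40, n_trials=10):
        shared = rng.normal(size=(1, n_stim, n_trials))
        eps = rng.normal(size=(n_cells, n_stim, n_trials))
        noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps
        signal = 5.0 * rng.normal(size=(n_cells, n_stim, 1))
        return EvokedResponseTensor(evoked=signal + noise)

    def test_planted_shared_gain_recovered(self, rng):
        rho = 0.3
        nc = noise_correlation(self.planted_tensor(rng, rho))
        iu = np.triu_indices_from(nc, k=1)
        assert np.nanmedian(nc[iu]) == pytest.approx(rho, abs=0.07)

    def test_duplicated_cell_has_correlation_one(self, rng):
        tensor = self.planted_tensor(rng, 0.0, n_cells=4)
        tensor.evoked[1] = tensor.evoked[0]
        nc = noise_correlation(tensor)
        assert nc[0, 1] == pytest.approx(1.0)

    def test_trial_shuffling_removes_correlations(self, rng):
        tensor = self.planted_tensor(rng, 0.5)
        shuffled = shuffle_trials(tensor, seed=1)
        nc = noise_correlation(shuffled)
        iu = np.triu_indices_from(nc, k=1)
        assert abs(np.nanmedian(nc[iu])) < 0.05
        # shuffling permutes within (cell, stimulus): sorted values unchanged
        np.testing.assert_allclose(
            np.sort(shuffled.evoked, axis=2), np.sort(tensor.evoked, axis=2)
        )

    def test_constant_cell_reported_missing(self, rng):
        tensor = self.planted_tensor(rng, 0.0, n_cells=3)
        tensor.evoked[2] = 1.0
        nc = noise_correlation(tensor)
        assert np.isnan(nc[2, 0]) and np.isnan(nc[0, 2])


class TestImageAccumulation:
    def fake_responsiveness(self, image_sets, n_cells=20):
        n_images = len(image_sets)
        flags = np.zeros((n_cells, n_images), dtype=bool)
        for i, cells in enumerate(image_sets):
            flags[list(cells), i] = True
        from neurorecon.responsiveness import ResponsivenessResult

        return ResponsivenessResult(
            cell_responsive=flags.any(axis=1),
            image_responsive=flags,
            anova_p=np.zeros(n_cells),
            ttest_p=np.zeros((n_cells, n_images)),
            amplitude_pass=flags,
            cell_tested=np.ones(n_cells, dtype=bool),
        )

    def test_shared_set_adds_nothing_after_first(self):
        res = self.fake_responsiveness([{1, 2, 3}] * 4)
        df = image_accumulation(res, np.arange(4))
        assert df["newly_added"].tolist() == [3, 0, 0, 0]
        assert df["cumulative"].iloc[-1] == 3

    def test_disjoint_sets_add_their_sizes(self):
        res = self.fake_responsiveness([{0, 1}, {2, 3, 4}, {5}])
        df = image_accumulation(res, np.arange(3))
        assert df["newly_added"].tolist() == [2, 3, 1]

    def test_final_union_matches_direct_computation(self, rng):
        sets = [set(rng.choice(20, rng.integers(0, 6), replace=False)) for _ in range(8)]
        res = self.fake_responsiveness(sets)
        df = image_accumulation(res, rng.permutation(8))
        assert df["cumulative"].iloc[-1] == len(set().union(*sets))


class TestCapacityFit:
    def test_feature_span_fits_exactly(self, paper_bank, rng):
        H = rng.normal(size=(paper_bank.f, 30))
        B = rng.normal(size=(30, 5))
        F = H @ B + rng.normal(size=(paper_bank.f, 1))  # offset absorbed by d
        fit = capacity_fit(H, F, paper_bank)
        assert np.nanmax(fit.error_percent) < 1e-6

    def test_single_image_absorbed_by_offset(self, paper_bank, rng):
        H = rng.normal(size=(paper_bank.f, 10))
        F = rng.normal(size=(paper_bank.f, 1))
        fit = capacity_fit(H, F, paper_bank)
        assert fit.error_percent[0] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_target_errors_near_hundred(self, paper_bank, rng):
        """A target orthogonal (in image space) to everything the weights can
        produce is 100% unexplained."""
        # span a small pixel subspace with the weights
        basis = rng.normal(size=(1024, 8))
        H = paper_bank.forward @ basis  # f x 8 (so G_rev H spans basis cols)
        # targets orthogonal to that span, in +/- pairs so the shared offset
        # d (the target mean) cannot absorb any of them
        q, _ = np.linalg.qr(np.hstack([basis, rng.normal(size=(1024, 3))]))
        ortho = np.hstack([q[:, 8:], -q[:, 8:]])
        F = paper_bank.forward @ ortho  # features of the orthogonal images
        fit = capacity_fit(H, F, paper_bank)
        # decoding goes through G_rev = alpha G^T (approximate identity), so
        # a little energy leaks; errors stay close to 100%
        assert np.nanmin(fit.error_percent) > 80.0


class TestRMI:
    def tensor_with_states(self, rng, run_mean, rest_mean, n_cells=8, n_stim=4):
        n_trials = 10
        ev = np.full((n_cells, n_stim, n_trials), rest_mean, dtype=float)
        loco = np.full((n_stim, n_trials), "rest", dtype=object)
        loco[:, :5] = "run"
        ev[:, :, :5] = run_mean
        ev += rng.normal(0, 1e-6, ev.shape)
        tensor = EvokedResponseTensor(evoked=ev, locomotion=loco.astype(str))
        from neurorecon.responsiveness import ResponsivenessResult

        flags = np.ones((n_cells, n_stim), dtype=bool)
        res = ResponsivenessResult(
            cell_responsive=np.ones(n_cells, dtype=bool),
            image_responsive=flags,
            anova_p=np.zeros(n_cells),
            ttest_p=np.zeros((n_cells, n_stim)),
            amplitude_pass=flags,
            cell_tested=np.ones(n_cells, dtype=bool),
        )
        return tensor, res

    def test_equal_means_give_zero(self, rng):
        tensor, res = self.tensor_with_states(rng, 5.0, 5.0)
        df = running_modulation_index(tensor, res)
        assert np.allclose(df["rmi"], 0.0, atol=1e-6)

    def test_rest_zero_gives_one(self, rng):
        tensor, res = self.tensor_with_states(rng, 4.0, 0.0)
        df = running_modulation_index(tensor, res)
        assert np.allclose(df["rmi"], 1.0, atol=1e-5)

    def test_run_three_rest_one_gives_half(self, rng):
        tensor, res = self.tensor_with_states(rng, 3.0, 1.0)
        df = running_modulation_index(tensor, res)
        assert np.allclose(df["rmi"], 0.5, atol=1e-5)

    def test_state_filters_applied(self, rng):
        tensor, res = self.tensor_with_states(rng, 3.0, 1.0)
        tensor.locomotion[:, :] = "run"  # no resting trials anywhere
        df = running_modulation_index(tensor, res)
        assert df.empty

    def test_missing_labels_rejected(self, rng):
        tensor, res = self.tensor_with_states(rng, 3.0, 1.0)
        tensor.locomotion = None
        with pytest.raises(ValueError):
            running_modulation_index(tensor, res)
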