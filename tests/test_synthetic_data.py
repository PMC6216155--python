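"""Generator tests: ground-truth structure, trial statistics, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synergia import (MUSCLES, make_cop_trace, make_ground_truth,
                      make_metadata, match_synergies, strike_index,
                      synthesize_trial)


class TestGroundTruth:
    def test_default_bump_centers_fall_in_the_four_quadrants(self):
        gt = make_ground_truth(seed=0)
        centers = gt.H_true.argmax(axis=1)
        for c, (lo, hi) in zip(centers, [(0, 50), (50, 100), (100, 150), (150, 200)]):
            assert lo <= c < hi

    def test_templates_peak_at_one_and_are_nonnegative(self):
        gt = make_ground_truth(seed=1)
        np.testing.assert_allclose(gt.H_true.max(axis=1), 1.0)
        assert np.all(gt.H_true >= 0) and np.all(gt.W_true >= 0)

    def test_rank_one_is_single_bump_with_positive_module(self):
        gt = make_ground_truth(r=1, seed=2)
        assert gt.H_true.shape == (1, 200)
        assert np.all(gt.W_true > 0)
        d = np.diff(gt.H_true[0])
        turn = np.sum(np.sign(d[:-1]) > np.sign(d[1:]))
        assert turn == 1  # single interior maximum

    def test_propulsion_module_dominated_by_plantar_flexors(self):
        gt = make_ground_truth(seed=3)
        w = gt.W_true[:, 1]  # second synergy: propulsion
        plantar = [MUSCLES.index(m) for m in ("PL", "GM", "GL", "SO")]
        others = [i for i in range(13) if i not in plantar]
        assert w[plantar].min() > w[others].max()

    def test_rank_exceeding_muscle_count_rejected(self):
        with pytest.raises(ValueError):
            make_ground_truth(m=5, r=6)


class TestSynthesizeTrial:
    def test_cycle_durations_match_the_cycle_model(self):
        gt = make_ground_truth(seed=4)
        # many cycles for tight means: contact 288 +/- 42 ms, swing 452 +/- 45 ms
        _, ct, _ = synthesize_trial(gt, n_cycles=200, duration=160.0)
        contact = ct.stance_duration[:-1] * 1e3
        swing = (np.diff(ct.touchdown) - ct.stance_duration[:-1]) * 1e3
        assert abs(contact.mean() - 288) < 3 * 42 / np.sqrt(len(contact))
        assert abs(swing.mean() - 452) < 3 * 45 / np.sqrt(len(swing))

    def test_noise_free_constant_carrier_raw_equals_envelope(self, noise_free_trial):
        gt, (trial, ct, env) = noise_free_trial
        raw = trial.channel_matrix()
        np.testing.assert_allclose(np.abs(raw), env, rtol=0, atol=1e-12)

    def test_same_seed_gives_identical_trials(self):
        gt1 = make_ground_truth(seed=5)
        gt2 = make_ground_truth(seed=5)
        t1, ct1, e1 = synthesize_trial(gt1, n_cycles=5, duration=6.0)
        t2, ct2, e2 = synthesize_trial(gt2, n_cycles=5, duration=6.0)
        assert t1.data.equals(t2.data)
        np.testing.assert_array_equal(ct1.touchdown, ct2.touchdown)
        np.testing.assert_array_equal(e1, e2)

    def test_cycle_table_defines_the_requested_complete_cycles(self):
        gt = make_ground_truth(seed=6)
        _, ct, _ = synthesize_trial(gt, n_cycles=12, duration=12.0)
        assert ct.n_complete_cycles == 12

    def test_carrier_is_band_limited_and_signed(self, synthetic_trial):
        trial, _, _ = synthetic_trial
        raw = trial.channel_matrix()
        assert (raw < 0).mean() > 0.3  # roughly symmetric around zero
        # spectral mass below the 20 Hz band edge is small
        f = np.fft.rfftfreq(raw.shape[1], d=1e-3)
        spec = np.abs(np.fft.rfft(raw[0])) ** 2
        assert spec[f < 10].sum() < 0.02 * spec.sum()


class TestMetadata:
    def test_cohort_size_and_reproducibility(self):
        a = make_metadata(135, seed=1)
        b = make_metadata(135, seed=1)
        assert len(a) == 135
        assert a == b

    def test_single_record_valid(self):
        (rec,) = make_metadata(1, seed=2)
        assert rec.speed > 0 and rec.height > 0 and rec.mass > 0

    def test_strike_indices_within_unit_interval(self):
        recs = make_metadata(200, seed=3)
        sis = np.array([r.si for r in recs])
        assert np.all((sis >= 0) & (sis <= 1))


class TestCopTrace:
    @pytest.mark.parametrize("si_true", [0.0, 0.2, 1.0])
    def test_geometry_encodes_the_strike_index(self, si_true):
        heel, toe, cop = make_cop_trace(0.25, si_true, seed=4)
        assert strike_index(heel, toe, cop) == pytest.approx(si_true, abs=1e-9)

    def test_on_axis_distance_is_ratio_times_foot_length(self):
        heel, toe, cop = make_cop_trace(0.25, 0.2, seed=5)
        axis = (toe - heel) / np.linalg.norm(toe - heel)
        assert float((cop - heel) @ axis) == pytest.approx(0.05, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(si=st.floats(0.0, 1.0), length=st.floats(0.1, 0.4),
       seed=st.integers(0, 10_000))
def test_strike_index_recovers_any_generated_geometry(si, length, seed):
    heel, toe, cop = make_cop_trace(length, si, seed=seed)
    assert strike_index(heel, toe, cop) == pytest.approx(si, abs=1e-9)


def test_match_synergies_identifies_a_permuted_scaled_copy(rng):
    W = rng.uniform(0.1, 1.0, (13, 4))
    perm_true = [2, 0, 3, 1]
    W_est = W[:, perm_true] * np.array([3.0, 0.5, 1.7, 9.0])
    perm, cos = match_synergies(W_est, W)
    assert [perm_true[j] for j in perm] == [0, 1, 2, 3]
    np.testing.assert_allclose(cos, 1.0, atol=1e-12)
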