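"""MAE/PCC/SNR metric oracles, overall score, acceptance rate, Bland-Altman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roipulse import (
    ComputationError,
    InputError,
    PairedHR,
    WindowedSignalPair,
    acceptance_rate,
    bland_altman,
    mae,
    overall_score,
    snr,
    windowed_pcc,
)

FS = 30.0


def make_pair(est, ref, t=None):
    est = np.asarray(est, float)
    if t is None:
        t = np.arange(est.size, dtype=float)
    return PairedHR(t, est, np.asarray(ref, float))


class TestMAE:
    def test_identity_zero(self):
        assert mae(make_pair([70, 72], [70, 72])) == 0.0

    def test_hand_example(self):
        assert mae(make_pair([70, 72, 74], [68, 72, 70])) == pytest.approx(2.0)

    def test_constant_offset(self):
        ref = np.array([60.0, 70.0, 80.0])
        assert mae(make_pair(ref + 5.0, ref)) == pytest.approx(5.0)

    @given(st.floats(-20, 20), st.integers(0, 100))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_translation_bound(self, c, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(50, 150, 20)
        est = ref + rng.normal(0, 3, 20)
        base = mae(make_pair(est, ref))
        shifted = mae(make_pair(est + c, ref))
        assert shifted <= base + abs(c) + 1e-9
        assert shifted >= abs(c) - base - 1e-9


def segs_pair(xs, ys, hr=72.0):
    xs, ys = np.atleast_2d(xs), np.atleast_2d(ys)
    return WindowedSignalPair(FS, xs, ys, np.full(xs.shape[0], hr))


class TestWindowedPCC:
    def test_perfect_correlation(self):
        x = np.random.default_rng(0).normal(size=(3, 50))
        assert windowed_pcc(segs_pair(x, x)) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.random.default_rng(0).normal(size=(3, 50))
        assert windowed_pcc(segs_pair(x, -x)) == pytest.approx(-1.0)

    def test_two_segment_hand_oracle(self):
        # segment 1 correlates perfectly; segment 2 is the hand-checkable
        # X=(1,2,3,4), Y=(1,1,3,3) pair with r = 16 / (4*sqrt(20))
        x = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        y = np.array([[2.0, 4.0, 6.0, 8.0], [1.0, 1.0, 3.0, 3.0]])
        expected = (1.0 + 0.8944271909999159) / 2.0
        assert windowed_pcc(segs_pair(x, y)) == pytest.approx(expected, abs=1e-12)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(6, 80))
        y = 0.5 * x + rng.normal(size=(6, 80))
        expected = np.mean([np.corrcoef(a, b)[0, 1] for a, b in zip(x, y)])
        assert windowed_pcc(segs_pair(x, y)) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_segment_excluded(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        y = np.array([[2.0, 4.0, 6.0, 8.0], [1.0, 2.0, 3.0, 4.0]])
        assert windowed_pcc(segs_pair(x, y)) == pytest.approx(1.0)

    def test_all_degenerate_rejected(self):
        x = np.ones((2, 4))
        with pytest.raises(ComputationError):
            windowed_pcc(segs_pair(x, x))

    @given(st.floats(0.1, 10), st.floats(-5, 5), st.integers(0, 50))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_positive_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 60))
        y = rng.normal(size=(4, 60))
        r1 = windowed_pcc(segs_pair(x, y))
        r2 = windowed_pcc(segs_pair(a * x + b, y))
        assert r1 == pytest.approx(r2, abs=1e-8)


def tone(freq_hz, n, amplitude=1.0):
    t = np.arange(n) / FS
    return amplitude * np.sin(2 * np.pi * freq_hz * t)


class TestSNR:
    # segment length chosen so the test tones sit on exact FFT bins
    N = 180  # 6 s at 30 Hz -> bin width 1/6 Hz

    def test_pure_inmask_tone_hits_ceiling(self):
        f_ref = 7 / 6.0  # 70 BPM, on an exact FFT bin of the 6 s segment
        x = tone(f_ref, self.N)
        pair = segs_pair(x, x, hr=f_ref * 60)
        assert snr(pair) == pytest.approx(60.0)

    def test_pure_outofmask_tone_hits_floor(self):
        f_ref = 1.0
        x = tone(3.5, self.N)  # 3.5 Hz on an exact bin, outside both lobes
        pair = segs_pair(x, x, hr=f_ref * 60)
        assert snr(pair) == pytest.approx(-60.0)

    def test_two_tone_closed_form(self):
        f_ref = 7 / 6.0
        x = tone(f_ref, self.N, amplitude=2.0) + tone(3.5, self.N, amplitude=1.0)
        pair = segs_pair(x, x, hr=f_ref * 60)
        assert snr(pair) == pytest.approx(10 * np.log10(4.0), abs=0.1)

    def test_first_harmonic_counted_as_signal(self):
        f_ref = 7 / 6.0
        x = tone(2 * f_ref, self.N)
        pair = segs_pair(x, x, hr=f_ref * 60)
        assert snr(pair) == pytest.approx(60.0)

    def test_monotone_in_noise_amplitude(self):
        f_ref = 7 / 6.0
        values = []
        for b in (0.2, 0.5, 1.0, 2.0):
            x = tone(f_ref, self.N, 2.0) + tone(3.5, self.N, b)
            values.append(snr(segs_pair(x, x, hr=f_ref * 60)))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_zero_power_rejected(self):
        with pytest.raises(InputError):
            snr(segs_pair(np.zeros(self.N), np.zeros(self.N)))


class TestOverallScore:
    def table(self, mae_v, pcc_v, snr_v):
        return pd.DataFrame({"mae": mae_v, "pcc": pcc_v, "snr": snr_v},
                            index=[1, 2, 3])

    def test_best_in_all_scores_one(self):
        os = overall_score(self.table([2, 4, 6], [0.9, 0.5, 0.1], [6, 0, -6]))
        assert os[1] == pytest.approx(1.0)

    def test_worst_in_all_scores_zero(self):
        os = overall_score(self.table([2, 4, 6], [0.9, 0.5, 0.1], [6, 0, -6]))
        assert os[3] == pytest.approx(0.0)

    def test_middle_roi_half(self):
        os = overall_score(self.table([2, 4, 6], [0.9, 0.5, 0.1], [6, 0, -6]))
        assert os[2] == pytest.approx(0.5)

    def test_degenerate_metric_neutral(self):
        os = overall_score(self.table([3, 3, 3], [0.9, 0.5, 0.1], [6, 0, -6]))
        # constant MAE contributes 0.5 to everyone
        assert os[1] == pytest.approx((0.5 + 1 + 1) / 3)
        assert os[3] == pytest.approx(0.5 / 3)

    @given(st.floats(0.1, 5), st.floats(-10, 10), st.integers(0, 50))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_affine_rescaling_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        t1 = self.table(rng.uniform(1, 10, 3), rng.uniform(-1, 1, 3),
                        rng.uniform(-10, 10, 3))
        t2 = t1.copy()
        t2["snr"] = a * t2["snr"] + b
        np.testing.assert_allclose(overall_score(t1), overall_score(t2),
                                   atol=1e-8)

    def test_bounds(self):
        rng = np.random.default_rng(9)
        t = self.table(rng.uniform(1, 10, 3), rng.uniform(-1, 1, 3),
                       rng.uniform(-10, 10, 3))
        os = overall_score(t)
        assert ((os >= 0) & (os <= 1)).all()


def staircase_pair(window_errors, window_s=25.0, rate_hz=1.0):
    """Paired series whose i-th 25 s window has a constant error."""
    n_per = int(window_s * rate_hz)
    t = np.arange(n_per * len(window_errors) + 1) / rate_hz  # close the span
    ref = np.full(t.size, 70.0)
    errors = np.repeat(np.asarray(window_errors, float), n_per)
    est = ref + np.append(errors, errors[-1])
    return PairedHR(t, est, ref)


class TestAcceptanceRate:
    def test_enumerated_windows(self):
        pair = staircase_pair([5.0, 12.0, 8.0, 20.0])
        assert acceptance_rate(pair) == pytest.approx(0.5)

    def test_all_perfect(self):
        assert acceptance_rate(staircase_pair([0.0] * 3)) == 1.0

    def test_all_bad(self):
        assert acceptance_rate(staircase_pair([50.0] * 3)) == 0.0

    def test_boundary_counts_as_acceptable(self):
        assert acceptance_rate(staircase_pair([10.0, 10.0])) == 1.0

    def test_short_span_rejected(self):
        pair = make_pair(np.full(10, 70.0), np.full(10, 70.0))
        with pytest.raises(InputError):
            acceptance_rate(pair)


class TestBlandAltman:
    def test_identity(self):
        pair = staircase_pair([0.0, 0.0])
        res = bland_altman(pair)
        assert (res.mean_diff, res.loa_lower, res.loa_upper) == (0.0, 0.0, 0.0)

    def test_symmetric_differences(self):
        pair = staircase_pair([2.0, -2.0])
        res = bland_altman(pair)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.loa_upper == pytest.approx(5.5437171645025325)
        assert res.loa_lower == pytest.approx(-5.5437171645025325)

    def test_constant_offset(self):
        pair = staircase_pair([5.0, 5.0, 5.0])
        res = bland_altman(pair)
        assert res.mean_diff == pytest.approx(5.0)
        assert res.loa_lower == pytest.approx(5.0)
        assert res.loa_upper == pytest.approx(5.0)

    def test_single_window_rejected(self):
        with pytest.raises(InputError):
            bland_altman(staircase_pair([1.0]))
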