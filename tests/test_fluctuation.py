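import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dfa7
from dfa7 import encodings, fluctuation


def brute_force_matrix(d1, d2, d3, l):
    """Covariance of the 3-vector increment list, enumerated window by window."""
    incs = []
    series = [np.asarray(s, dtype=float) for s in (d1, d2, d3)]
    for i in range(len(series[0]) - l):
        incs.append([s[i + l] - s[i] for s in series])
    incs = np.array(incs)
    mean = incs.mean(axis=0)
    return (incs - mean).T @ (incs - mean) / len(incs)


class TestWindowIncrements:
    def test_direct_subtraction(self):
        assert fluctuation.window_increments(np.array([1, 2, 4, 8]), 2).tolist() == [3, 6]

    def test_constant_series(self):
        assert np.all(fluctuation.window_increments(np.full(10, 3.0), 4) == 0)

    @pytest.mark.parametrize("l", [0, 4, 5])
    def test_degenerate_width(self, l):
        with pytest.raises(fluctuation.FluctuationError):
            fluctuation.window_increments(np.arange(4), l)


class TestCrossFluctuation:
    def test_hand_covariance(self):
        # increments at l=1 are (1, 3): population variance 1
        s = np.array([0.0, 1.0, 4.0])
        assert fluctuation.cross_fluctuation(s, s, 1) == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = np.array([0.0, 1.0, 4.0])  # increments (1, 3)
        b = np.array([0.0, 3.0, 4.0])  # increments (3, 1)
        assert fluctuation.cross_fluctuation(a, b, 1) == pytest.approx(-1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        s = np.cumsum(rng.normal(size=100))
        f0 = fluctuation.cross_fluctuation(s, s, 8)
        f1 = fluctuation.cross_fluctuation(s + 17.0, s + 17.0, 8)
        assert f1 == pytest.approx(f0)

    def test_length_mismatch(self):
        with pytest.raises(fluctuation.FluctuationError):
            fluctuation.cross_fluctuation(np.arange(10), np.arange(9), 2)


class TestFluctuationMatrix:
    def test_identical_series_rank_one(self):
        rng = np.random.default_rng(1)
        s = np.cumsum(rng.normal(size=200))
        m = fluctuation.fluctuation_matrix(s, s, s, 8)
        lams = np.linalg.eigvalsh(m)
        assert lams[0] == pytest.approx(0, abs=1e-9)
        assert lams[1] == pytest.approx(0, abs=1e-9)

    def test_constant_second_and_third_series(self):
        rng = np.random.default_rng(2)
        s = np.cumsum(rng.normal(size=100))
        c = np.zeros(100)
        m = fluctuation.fluctuation_matrix(s, c, c, 4)
        assert m[0, 0] > 0
        assert np.all(m[1:, :] == 0) and np.all(m[:, 1:] == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("l", [3, 17, 64])
    def test_equals_brute_force_covariance(self, seed, l):
        rng = np.random.default_rng(seed)
        d = [np.cumsum(rng.normal(size=400)) for _ in range(3)]
        m = fluctuation.fluctuation_matrix(*d, l)
        np.testing.assert_allclose(m, brute_force_matrix(*d, l), atol=1e-9, rtol=1e-12)

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(3)
        d = [np.cumsum(rng.normal(size=300)) for _ in range(3)]
        m = fluctuation.fluctuation_matrix(*d, 16)
        assert np.array_equal(m, m.T)
        assert np.linalg.eigvalsh(m)[0] >= -1e-9


class TestEigenTracks:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            (np.eye(3), (1, 1, 1)),
            (np.diag([4.0, 1.0, 0.0]), (4, 1, 0)),
            (np.ones((3, 3)), (3, 0, 0)),
        ],
    )
    def test_known_spectra(self, matrix, expected):
        lams = fluctuation.eigen_tracks([matrix])[0]
        np.testing.assert_allclose(lams, expected, atol=1e-12)

    def test_rejects_asymmetric(self):
        m = np.array([[1.0, 2.0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(fluctuation.FluctuationError):
            fluctuation.eigen_tracks([m])

    def test_trace_identity_over_grid(self):
        rng = np.random.default_rng(4)
        d = [np.cumsum(rng.normal(size=2048)) for _ in range(3)]
        widths = fluctuation.default_window_grid(2048)
        mt = fluctuation.matrix_track(*d, widths)
        traces = np.trace(mt.matrices, axis1=1, axis2=2)
        np.testing.assert_allclose(mt.eigenvalues.sum(axis=1), traces, atol=1e-9)

    def test_sorted_descending(self):
        rng = np.random.default_rng(5)
        d = [np.cumsum(rng.normal(size=512)) for _ in range(3)]
        mt = fluctuation.matrix_track(*d, [4, 8, 16, 32])
        assert np.all(np.diff(mt.eigenvalues, axis=1) <= 0)


class TestLogLogSlope:
    @given(
        beta=st.floats(min_value=-2, max_value=2),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=80, deadline=None)
    def test_recovers_exact_power_law(self, beta, c):
        widths = [2, 4, 8, 16, 32, 64]
        fit = fluctuation.loglog_slope([(l, c * l**beta) for l in widths])
        assert abs(fit.slope - beta) < 1e-10

    @pytest.mark.parametrize(
        "points, slope, r2",
        [
            ([(2, 4), (4, 16), (8, 64)], 2.0, 1.0),
            ([(l, 5 * l**0.5) for l in (4, 8, 16, 32)], 0.5, 1.0),
            ([(2, 1), (4, 1), (8, 1)], 0.0, None),
        ],
    )
    def test_examples(self, points, slope, r2):
        fit = fluctuation.loglog_slope(points)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        if r2 is not None:
            assert fit.r_squared == pytest.approx(r2, abs=1e-12)

    def test_nonpositive_value_names_width(self):
        with pytest.raises(fluctuation.FluctuationError, match="width 4"):
            fluctuation.loglog_slope([(2, 1.0), (4, 0.0), (8, 2.0)])

    def test_too_few_points(self):
        with pytest.raises(fluctuation.FluctuationError):
            fluctuation.loglog_slope([(2, 1.0), (4, 2.0)])

    def test_non_increasing_widths(self):
        with pytest.raises(fluctuation.FluctuationError):
            fluctuation.loglog_slope([(4, 1.0), (4, 2.0), (8, 3.0)])


class TestWindowGrid:
    def test_powers_of_two_capped(self):
        assert fluctuation.default_window_grid(32768) == (4, 8, 16, 32, 64, 128, 256, 512, 1024)
        assert fluctuation.default_window_grid(256) == (4, 8, 16, 32, 64)

    def test_too_short(self):
        with pytest.raises(fluctuation.FluctuationError):
            fluctuation.default_window_grid(15)


class TestExponents:
    def test_iid_single_series_near_half(self, iid_sequence):
        track = encodings.zcurve_components(iid_sequence)
        fits = fluctuation.zcurve_exponents(track)
        for fit in fits:
            assert 0.44 <= fit.slope <= 0.58

    def test_periodic_sequence_bounded_fluctuations(self):
        # period 3 does not divide the power-of-two widths, so F(l) is
        # positive and essentially l-independent: exponent ~ 0
        seq = dfa7.GeneSequence("p3", ("ACG" * 1366)[:4096])
        fits = fluctuation.zcurve_exponents(encodings.zcurve_components(seq))
        for fit in fits:
            assert -0.1 <= fit.slope <= 0.1

    def test_period_four_degenerates_to_zero_fluctuation(self):
        # every power-of-two width is a multiple of the period, so all
        # end-increments vanish exactly and the exponent is undefined
        seq = dfa7.GeneSequence("p4", "ACGT" * 1024)
        with pytest.raises(fluctuation.FluctuationError), pytest.warns(UserWarning):
            fluctuation.zcurve_exponents(encodings.zcurve_components(seq))

    def test_persistent_exponents_exceed_iid(self, iid_sequence, persistent_sequence):
        f_iid = fluctuation.zcurve_exponents(encodings.zcurve_components(iid_sequence))
        f_per = fluctuation.zcurve_exponents(
            encodings.zcurve_components(persistent_sequence)
        )
        for fi, fp in zip(f_iid, f_per):
            assert fp.slope > 0.6
            assert fp.slope > fi.slope

    def test_iid_eigen_exponents_near_one(self, iid_sequence):
        tracks = encodings.cumulative_distances(iid_sequence)
        fits = fluctuation.cross_exponents(*tracks.combined)
        for fit in fits:
            assert fit is not None
            assert 0.85 <= fit.slope <= 1.15

    def test_duplicated_series_degenerate_tracks(self):
        rng = np.random.default_rng(8)
        s = np.cumsum(rng.normal(size=4096))
        with pytest.warns(UserWarning):
            fits = fluctuation.cross_exponents(s, s, s)
        assert fits[0] is not None
        assert fits[1] is None and fits[2] is None
        # the surviving track follows 3 * F_11(l)
        widths = fluctuation.default_window_grid(4096)
        solo = fluctuation.loglog_slope(
            [(l, 3 * fluctuation.cross_fluctuation(s, s, l)) for l in widths]
        )
        assert fits[0].slope == pytest.approx(solo.slope, abs=1e-9)

    def test_eigen_scaling_twice_single_series(self):
        # three independent copies of the same uncorrelated walk process:
        # covariance eigen-slopes sit near twice the single-series exponent
        rng = np.random.default_rng(9)
        walks = [np.cumsum(rng.choice([-1.0, 1.0], size=32768)) for _ in range(3)]
        singles = [
            fluctuation.loglog_slope(
                [
                    (l, fluctuation.single_series_fluctuation(w, l))
                    for l in fluctuation.default_window_grid(32768)
                ]
            ).slope
            for w in walks
        ]
        crosses = [f.slope for f in fluctuation.cross_exponents(*walks)]
        assert abs(np.median(crosses) - 2 * np.median(singles)) <= 0.15

    def test_dfa1_variant_also_near_half_on_iid(self, iid_sequence):
        track = encodings.zcurve_components(iid_sequence)
        fits = fluctuation.zcurve_exponents(track, method="dfa1")
        for fit in fits:
            assert 0.4 <= fit.slope <= 0.65

    def test_deterministic(self, iid_sequence):
        track = encodings.zcurve_components(iid_sequence)
        a = fluctuation.zcurve_exponents(track)
        b = fluctuation.zcurve_exponents(track)
        assert [f.slope for f in a] == [f.slope for f in b]
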