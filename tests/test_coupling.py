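"""The coupling statistic: lag grid, windowed lagged xcorr, summaries."""

import numpy as np
import pytest

from btbc.coupling import (
    DyadCoupling,
    LagGrid,
    LagProfile,
    R_CLIP,
    summarize_btbc,
    windowed_lagged_xcorr,
)
from btbc.motion import MotionSeries
from btbc.simulate import SimulationConfig, generate_dyad_series

from conftest import standardized_series


def brute_force_profile(x, y, fs, window, step, grid):
    """Two-pass nested-loop Pearson oracle, independent of the fast path."""
    w, s = int(round(window * fs)), int(round(step * fs))
    n = len(x)
    lags = [int(round(off * fs)) for off in grid.offsets]
    vals = []
    for lag in lags:
        acc = []
        for t in range(0, n - w + 1, s):
            if t + lag < 0 or t + lag + w > n:
                continue
            a, b = y[t : t + w], x[t + lag : t + lag + w]
            am, bm = a - a.mean(), b - b.mean()
            denom = np.sqrt((am @ am) * (bm @ bm))
            if denom == 0:
                continue
            r = np.clip((am @ bm) / denom, -R_CLIP, R_CLIP)
            acc.append(abs(np.arctanh(r)))
        vals.append(np.mean(acc))
    return np.array(vals)


class TestLagGrid:
    def test_default_structure(self):
        grid = LagGrid()
        offs = grid.offsets
        assert grid.n_lags == 251
        assert (offs > 0).sum() == 125 and (offs < 0).sum() == 125
        assert 0.0 in offs
        assert np.allclose(offs, -offs[::-1])  # symmetric about zero
        assert np.allclose(np.diff(offs), 0.04)

    def test_lag_step_must_divide_sampling(self):
        with pytest.raises(ValueError, match="integer number of samples"):
            LagGrid(5.0, 0.05).lag_samples(25.0)  # 1.25 samples
        assert np.array_equal(
            LagGrid(1.0, 0.2).lag_samples(25.0), np.arange(-5, 6) * 5
        )


class TestWindowedXcorr:
    def test_matches_brute_force_oracle(self, toy_series_pair):
        inst, lear = toy_series_pair
        grid = LagGrid(2.0, 0.2)
        prof = windowed_lagged_xcorr(inst, lear, 30.0, 1.0, grid)
        ref = brute_force_profile(inst.values, lear.values, 25.0, 30.0, 1.0, grid)
        assert np.max(np.abs(prof.values - ref)) < 1e-10

    def test_fallback_path_matches_oracle(self, toy_series_pair):
        # a window that is not a multiple of the 1-s step exercises the
        # general prefix-sum path instead of the blocked matmul
        inst, lear = toy_series_pair
        grid = LagGrid(1.0, 0.2)
        prof = windowed_lagged_xcorr(inst, lear, 30.04, 1.0, grid)
        ref = brute_force_profile(inst.values, lear.values, 25.0, 30.04, 1.0, grid)
        assert np.max(np.abs(prof.values - ref)) < 1e-10

    def test_shifted_copy_peaks_at_shift(self, rng):
        # learner's motion occurs 2 s earlier than the instructor's copy
        fs = 25.0
        lag = int(2.0 * fs)
        base = rng.normal(size=int(120 * fs) + lag)
        learner = standardized_series(base[lag:], fs)
        instructor = standardized_series(base[: int(120 * fs)], fs)
        prof = windowed_lagged_xcorr(instructor, learner, 30.0, 1.0, LagGrid())
        assert np.all(np.isfinite(prof.values))  # atanh capped via R_CLIP
        peak = prof.offsets[np.argmax(prof.values)]
        assert peak == pytest.approx(2.0)
        assert prof.values.max() == pytest.approx(abs(np.arctanh(R_CLIP)), rel=1e-6)

    def test_swap_reverses_lag_axis(self, toy_series_pair):
        # with the window step equal to the lag step, the (window, lag)
        # segment pairs map one-to-one under a swap, so the reversal is exact
        inst, lear = toy_series_pair
        grid = LagGrid(2.0, 0.2)
        fwd = windowed_lagged_xcorr(inst, lear, 10.0, 0.2, grid)
        rev = windowed_lagged_xcorr(lear, inst, 10.0, 0.2, grid)
        assert np.allclose(fwd.values, rev.values[::-1], atol=1e-12)
        assert np.array_equal(fwd.n_windows_used, rev.n_windows_used[::-1])

    def test_sign_flip_invariance(self, toy_series_pair):
        inst, lear = toy_series_pair
        grid = LagGrid(1.0, 0.2)
        a = windowed_lagged_xcorr(inst, lear, 30.0, 1.0, grid)
        flipped = inst.with_values(-inst.values)
        b = windowed_lagged_xcorr(flipped, lear, 30.0, 1.0, grid)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_abs_and_fisher_z_commute(self, rng):
        r = rng.uniform(-0.99, 0.99, 1000)
        assert np.allclose(np.abs(np.arctanh(r)), np.arctanh(np.abs(r)))

    def test_n_windows_shrink_with_lag(self, toy_series_pair):
        inst, lear = toy_series_pair
        prof = windowed_lagged_xcorr(inst, lear, 30.0, 1.0, LagGrid())
        center = prof.n_windows_used[125]
        assert prof.n_windows_used[0] < center  # extreme lags lose windows
        assert prof.n_windows_used[-1] < center

    def test_errors(self, rng):
        short = standardized_series(rng.normal(size=100))
        with pytest.raises(ValueError, match="shorter than one window"):
            windowed_lagged_xcorr(short, short, 30.0, 1.0, LagGrid(1.0, 0.2))
        raw = MotionSeries(rng.gamma(2, 1, 3000), 25.0)
        std = standardized_series(rng.normal(size=3000))
        with pytest.raises(ValueError, match="not standardized"):
            windowed_lagged_xcorr(raw, std, 30.0, 1.0, LagGrid(1.0, 0.2))
        other_rate = standardized_series(rng.normal(size=3000), fs=30.0)
        with pytest.raises(ValueError, match="sampling rates"):
            windowed_lagged_xcorr(other_rate, std, 30.0, 1.0, LagGrid(1.0, 0.2))


class TestSummaries:
    def _profile(self, values, grid=None):
        grid = grid or LagGrid(1.0, 0.2)
        return LagProfile(grid, np.asarray(values, float), np.ones(grid.n_lags, int))

    def test_constant_profile(self):
        s = summarize_btbc(self._profile(np.full(11, 0.3)))
        for v in (s.overall, s.learner_leading, s.instructor_leading, s.zero_lag):
            assert v == pytest.approx(0.3)

    def test_symmetric_profile_balances_directions(self):
        v = np.abs(np.arange(-5, 6)) * 0.1
        s = summarize_btbc(self._profile(v))
        assert s.learner_leading == pytest.approx(s.instructor_leading)

    def test_direction_subsets_average_correct_lags(self):
        v = np.zeros(11)
        v[:5] = 1.0  # negative lags only
        s = summarize_btbc(self._profile(v))
        assert s.instructor_leading == 1.0
        assert s.learner_leading == 0.0
        assert s.overall == pytest.approx(5 / 11)

    def test_peak_tie_breaks_prefer_small_then_negative_lag(self):
        v = np.zeros(11)
        v[[1, 9]] = 0.9  # lags -0.8 and +0.8
        assert summarize_btbc(self._profile(v)).peak_lag == pytest.approx(-0.8)
        v2 = np.zeros(11)
        v2[[3, 9]] = 0.9  # -0.4 beats +0.8 on |lag|
        assert summarize_btbc(self._profile(v2)).peak_lag == pytest.approx(-0.4)


class TestModelObject:
    def test_fit_runs_preprocessing_and_summarizes(self):
        cfg = SimulationConfig(duration=120.0, n_dyads=2, seed=3)
        inst, lear = generate_dyad_series(cfg, seed=4)
        res = DyadCoupling(inst, lear, dyad_id="d01", condition="scaffolding").fit()
        assert res.profile.grid.n_lags == 251
        assert res.model.preprocess_reports is not None
        assert 0 < res.overall < abs(np.arctanh(R_CLIP))
        text = res.summary()
        assert "overall BtBC" in text and "d01" in text
        min_v, max_v = res.profile.values.min(), res.profile.values.max()
        assert min_v <= res.overall <= max_v

    def test_from_file_round_trip(self, tmp_path):
        from btbc.motion import write_motion_file

        cfg = SimulationConfig(duration=120.0, n_dyads=2, seed=3)
        inst, lear = generate_dyad_series(cfg, seed=4)
        write_motion_file(tmp_path / "d.tsv", [inst, lear])
        res = DyadCoupling.from_file(tmp_path / "d.tsv").fit()
        ref = DyadCoupling(inst, lear).fit()
        assert res.overall == pytest.approx(ref.overall, abs=1e-12)

    def test_mismatched_inputs_rejected(self, rng):
        a = standardized_series(rng.normal(size=1000))
        b = standardized_series(rng.normal(size=999))
        with pytest.raises(ValueError, match="lengths differ"):
            DyadCoupling(a, b)
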