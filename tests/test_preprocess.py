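"""AVT filter and GLR relabeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emgelm as eg
from emgelm.preprocess import SegmentStats, _find_bursts
from conftest import burst_onsets, burst_runs

FS = 1000.0  # 1 kHz in these tests: window 200 ms -> 200 samples, stride -> 10


def naive_avt(signal, fs, cfg):
    """Independent per-channel reference: explicit slide loop on each channel."""
    x = np.atleast_2d(np.asarray(signal, float))
    W = int(round(cfg.window_ms / 1000 * fs))
    S = int(round(cfg.stride_ms / 1000 * fs))

    def outside(v, msa, msd):
        return abs(v - msa) > msd + 1e-12 * abs(msa)

    out = []
    for ch in np.abs(x):
        y = ch.copy()
        seg = y[:W]
        msa, msd = np.mean(seg), np.std(seg)
        for i in range(W):
            if outside(y[i], msa, msd):
                y[i] = msa
        for k in range(1, (y.size - W) // S + 1):
            s0 = k * S
            old, inc = y[s0: s0 + W - S], y[s0 + W - S: s0 + W]
            msa = cfg.ff1 * np.mean(old) + cfg.ff2 * np.mean(inc)
            msd = cfg.ff1 * np.std(old) + cfg.ff2 * np.std(inc)
            for i in range(s0 + W - S, s0 + W):
                if outside(y[i], msa, msd):
                    y[i] = msa
        out.append(y)
    return np.array(out)


class TestAvtConfig:
    def test_defaults_follow_segmentation_convention(self):
        cfg = eg.AvtConfig()
        assert (cfg.window_ms, cfg.stride_ms, cfg.ff1, cfg.ff2) == (200, 10, 0.8, 0.2)

    @pytest.mark.parametrize("kw", [
        dict(window_ms=10, stride_ms=10), dict(stride_ms=0),
        dict(ff1=0.9, ff2=0.2), dict(ff1=-0.1, ff2=1.1),
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            eg.AvtConfig(**kw)


def test_segment_stats_band():
    s = SegmentStats(msa=2.0, msd=0.5)
    assert (s.lower, s.upper) == (1.5, 2.5)
    with pytest.raises(ValueError):
        SegmentStats(msa=1.0, msd=-0.1)


class TestAvtFilter:
    def test_constant_signal_is_fixed_point(self):
        x = np.full((2, 1000), 3.7)
        assert np.array_equal(eg.avt_filter(x, FS), x)

    def test_single_spike_replaced_by_segment_msa(self):
        """Hand-checked toy: one 10-sample window, spike at ~10x the rest.

        values [1]*4 + [10] + [1]*5: mean 1.9, sd 2.7 -> band [-0.8, 4.6];
        only the spike falls outside and becomes 1.9."""
        x = np.array([1, 1, 1, 1, 10, 1, 1, 1, 1, 1.0])
        cfg = eg.AvtConfig(window_ms=10, stride_ms=1)
        out = eg.avt_filter(x, FS, cfg)
        expected = x.copy()
        expected[4] = 1.9
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_no_sample_discard_output_length(self):
        rng = np.random.default_rng(0)
        for n in (200, 257, 1024):
            x = rng.normal(size=(3, n))
            assert eg.avt_filter(x, FS).shape == (3, n)

    def test_rectifies_negative_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 500))
        out = eg.avt_filter(x, FS)
        assert np.all(out >= 0)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(210, 700))
    def test_output_bounded_by_rectified_input(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2, n)) * rng.uniform(0.1, 5)
        out = eg.avt_filter(x, FS)
        rect = np.abs(x)
        for c in range(2):
            assert out[c].min() >= rect[c].min() - 1e-12
            assert out[c].max() <= rect[c].max() + 1e-12

    @pytest.mark.parametrize("ff", [(0.8, 0.2), (0.5, 0.5)])
    def test_matches_bruteforce_reference(self, ff):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(2, 573))
        cfg = eg.AvtConfig(window_ms=200, stride_ms=10, ff1=ff[0], ff2=ff[1])
        np.testing.assert_array_equal(eg.avt_filter(x, FS, cfg), naive_avt(x, FS, cfg))

    def test_errors(self):
        with pytest.raises(ValueError):
            eg.avt_filter(np.empty((1, 0)), FS)
        with pytest.raises(ValueError):  # shorter than one window
            eg.avt_filter(np.ones((1, 100)), FS)
        with pytest.raises(ValueError):  # window shorter than two strides
            eg.avt_filter(np.ones((1, 500)), FS, eg.AvtConfig(window_ms=15, stride_ms=10))


class TestGlrRelabel:
    def _trial(self, seed=2, snr=3.0, n_movements=4, reps=2):
        p = eg.Protocol(n_movements=n_movements, n_repetitions=reps,
                        movement_duration_s=1.2, rest_duration_s=0.8, n_channels=4)
        s = eg.SubjectModel.random(n_movements, 4, seed=seed, snr=snr)
        return eg.generate_trial(p, s), p

    def test_aligned_labels_stay_within_one_grid_step(self):
        rec, _ = self._trial()
        refined = eg.glr_relabel(rec.signal, rec.true_labels, rec.sample_rate_hz)
        grid = int(30 / 1000 * rec.sample_rate_hz)
        t_on, r_on = burst_onsets(rec.true_labels), burst_onsets(refined)
        assert np.all(np.abs(r_on - t_on) <= grid)

    def test_recovers_known_onset_delay(self):
        """Stim onsets lag truth by 60-300 ms; refined onsets return to within
        one 30 ms grid step of the true onset."""
        rec, _ = self._trial(seed=5)
        refined = eg.glr_relabel(rec.signal, rec.stim_labels, rec.sample_rate_hz)
        err_ms = (burst_onsets(refined) - burst_onsets(rec.true_labels)) \
            / rec.sample_rate_hz * 1000
        assert np.all(np.abs(err_ms) <= 30)

    def test_matches_exhaustive_oracle_on_one_burst(self):
        """The returned boundaries equal a brute-force double-loop search of
        the same objective over the same grid."""
        rec, _ = self._trial(seed=8, n_movements=1, reps=1)
        cfg = eg.GlrConfig()
        refined = eg.glr_relabel(rec.signal, rec.stim_labels, rec.sample_rate_hz, cfg)
        (onset, offset, cls), = burst_runs(rec.stim_labels)

        fs = rec.sample_rate_hz
        rect = np.abs(rec.signal)
        grid = int(round(cfg.grid_ms / 1000 * fs))
        margin = int(round(cfg.search_margin_ms / 1000 * fs))
        min_move = int(round(cfg.min_movement_ms / 1000 * fs))
        n = rect.shape[1]
        ws, we = max(onset - margin, 0), min(offset + margin, n)
        var_floor = max(1e-12 * float(rect.max() - rect.min()) ** 2,
                        np.finfo(float).tiny)

        def seg_ll(i, j):
            if j <= i:
                return 0.0
            total = 0.0
            for ch in rect:
                seg = ch[i:j]
                var = max(seg.var(), var_floor)
                total += -0.5 * seg.size * (np.log(2 * np.pi * var) + 1)
            return total

        best, best_pair = -np.inf, None
        for t0 in range(onset - (margin // grid) * grid,
                        onset + (margin // grid) * grid + 1, grid):
            if not (ws <= t0 < we):
                continue
            for t1 in range(offset - (margin // grid) * grid,
                            offset + (margin // grid) * grid + 1, grid):
                if not (ws < t1 <= we) or t1 - t0 < max(min_move, 1):
                    continue
                ll = seg_ll(ws, t0) + seg_ll(t0, t1) + seg_ll(t1, we)
                if ll > best:
                    best, best_pair = ll, (t0, t1)

        runs = burst_runs(refined)
        assert len(runs) == 1
        assert (runs[0][0], runs[0][1]) == best_pair

    def test_preserves_class_ids_and_burst_count(self):
        rec, p = self._trial(seed=13)
        refined = eg.glr_relabel(rec.signal, rec.stim_labels, rec.sample_rate_hz)
        stim_runs = burst_runs(rec.stim_labels)
        ref_runs = burst_runs(refined)
        assert len(ref_runs) == len(stim_runs)
        assert [c for *_, c in ref_runs] == [c for *_, c in stim_runs]

    def test_all_rest_warns_and_returns_input(self):
        x = np.random.default_rng(0).normal(size=(2, 4000))
        labels = np.zeros(4000, dtype=int)
        with pytest.warns(UserWarning):
            out = eg.glr_relabel(x, labels, FS)
        assert np.array_equal(out, labels)

    def test_constant_signal_does_not_crash(self):
        """Degenerate zero-variance segments are floored, not -inf."""
        x = np.ones((1, 6000))
        labels = np.zeros(6000, dtype=int)
        labels[2000:4000] = 1
        refined = eg.glr_relabel(x, labels, 2000.0)
        assert set(np.unique(refined)) <= {0, 1}

    @pytest.mark.parametrize("kw", [dict(grid_ms=0), dict(grid_ms=50, search_margin_ms=20)])
    def test_config_invariants(self, kw):
        with pytest.raises(ValueError):
            eg.GlrConfig(**kw)


def test_find_bursts_run_length_encoding():
    labels = np.array([0, 0, 2, 2, 0, 3, 3, 3, 0, 0])
    assert _find_bursts(labels) == [(2, 4, 2), (5, 8, 3)]
    assert _find_bursts(np.zeros(5, int)) == []
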