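import numpy as np
import pandas as pd
import pytest

from boutloop import bouts as bt
from boutloop import reafference as rf

DT = rf.DT


def _recording(time, tail, grating=None, bout_flag=None):
    n = time.size
    grating = np.full(n, 10.0) if grating is None else grating
    bout_flag = np.zeros(n, dtype=np.int8) if bout_flag is None else bout_flag
    return rf.TailRecording(
        time=time, tail_angle=tail, grating_cmd=grating, grating_shown=grating,
        vigor=np.zeros(n), est_velocity=np.zeros(n), bout_flag=bout_flag,
        dt=float(time[1] - time[0]))


class TestPreprocess:
    def test_output_grid_and_zscore(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 3, 0.004)  # native 250 Hz
        raw = _recording(t, rng.normal(0, 0.3, t.size))
        rec = bt.preprocess_tail(raw)
        assert rec.dt == pytest.approx(0.005)
        assert np.allclose(np.diff(rec.time), 0.005)
        assert rec.tail_angle.mean() == pytest.approx(0.0, abs=1e-9)
        assert rec.tail_angle.std() == pytest.approx(1.0, abs=1e-9)

    def test_linear_interpolation_matches_hand_oracle(self):
        t = np.array([0.0, 0.01, 0.02])
        raw = _recording(t, np.array([0.0, 1.0, 0.0]))
        rec = bt.preprocess_tail(raw)
        # raw trace kept in radians: grid points 0, 5, 10, 15, 20 ms
        assert np.allclose(rec.tail_angle_raw, [0.0, 0.5, 1.0, 0.5, 0.0])

    def test_constant_trace_rejected(self):
        t = np.arange(0, 1, 0.005)
        with pytest.raises(ValueError):
            bt.preprocess_tail(_recording(t, np.full(t.size, 0.2)))


class TestFlicks:
    def test_constructed_extrema_match_bruteforce_scan(self):
        # 7 extrema at known positions
        x = np.zeros(100)
        peaks = {10: 0.5, 20: -0.4, 30: 0.45, 40: -0.3, 50: 0.2, 60: -0.5, 70: 0.4}
        for i, v in peaks.items():
            x[i] = v
        for a, b in zip(list(peaks) + [85], [0] + list(peaks)):
            pass
        # piecewise-linear between the peaks
        knots = [0] + list(peaks) + [99]
        vals = [0.0] + list(peaks.values()) + [0.0]
        x = np.interp(np.arange(100), knots, vals)
        ext = bt.local_extrema(x)
        assert list(ext) == list(peaks)
        flicks = bt.detect_flicks(x)
        # brute force: adjacent-extrema differences
        mags = np.abs(np.diff([peaks[i] for i in peaks]))
        assert np.allclose(np.sort(flicks["magnitude"]),
                           np.sort(mags[mags > 0.14]))

    def test_small_magnitude_flicks_rejected(self):
        t = np.arange(400) * DT
        x = 0.05 * np.sin(2 * np.pi * 25 * t)  # extrema differ by 0.10 rad
        assert bt.detect_flicks(x).empty

    def test_plateau_extrema_take_first_sample(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, 0.0, 1.0])
        ext = bt.local_extrema(x)
        assert 1 in ext and 4 in ext


class TestSegmentBouts:
    def _session(self):
        n = 4000
        t = np.arange(n) * DT
        tail = np.zeros(n)
        flag = np.zeros(n, dtype=np.int8)
        for on in (500, 1000, 1500):
            dur = 70
            flag[on : on + dur] = 1
            tt = np.arange(dur) * DT
            tail[on : on + dur] = 0.5 * np.cos(2 * np.pi * 25 * tt)
        return _recording(t, tail, bout_flag=flag)

    def test_bout_below_flick_threshold_discarded(self):
        rec = self._session()
        rec.tail_angle[1000:1070] *= 0.1  # extrema differ by ~0.1 rad only
        tab = bt.segment_bouts(rec)
        assert len(tab) == 2

    def test_all_filters_hold_on_survivors(self):
        rec = self._session()
        tab = bt.segment_bouts(rec)
        assert (tab["duration_ms"] >= bt.MIN_BOUT_MS).all()
        ib = tab["next_interbout_ms"].dropna()
        assert (ib >= bt.MIN_INTERBOUT_MS).all()
        fwd = rec.grating_cmd[tab["onset_idx"].to_numpy()]
        assert (fwd > 0).all()

    def test_bouts_outside_forward_grating_dropped(self):
        rec = self._session()
        rec.grating_cmd[:600] = 0.0  # first bout now in a static period
        tab = bt.segment_bouts(rec)
        assert len(tab) == 2
        assert tab["onset_idx"].min() >= 900

    def test_last_bout_in_trial_has_undefined_interbout(self):
        rec = self._session()
        tab = bt.segment_bouts(rec, trial_len_s=30.0)
        assert np.isnan(tab["next_interbout_ms"].iloc[-1])
        assert np.isfinite(tab["next_interbout_ms"].iloc[0])

    def test_segmentation_idempotent_on_own_output(self):
        rec = self._session()
        tab = bt.segment_bouts(rec)
        flag2 = np.zeros(rec.n_samples, dtype=np.int8)
        for row in tab.itertuples():
            flag2[int(row.onset_idx) : int(row.offset_idx)] = 1
        rec2 = _recording(rec.time, rec.tail_angle, bout_flag=flag2)
        tab2 = bt.segment_bouts(rec2)
        assert np.array_equal(tab2["onset_idx"].to_numpy(),
                              tab["onset_idx"].to_numpy())
        assert np.array_equal(tab2["offset_idx"].to_numpy(),
                              tab["offset_idx"].to_numpy())


class TestExcludeFish:
    def test_nine_zero_trials_kept(self):
        counts = [2] * 10 + [0] * 9 + [3] * 10
        assert bt.exclude_fish(counts) is True

    def test_ten_zero_trials_excluded(self):
        counts = [2] * 10 + [0] * 10 + [3] * 10
        assert bt.exclude_fish(counts) is False

    def test_random_vectors_match_runlength_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            counts = rng.integers(0, 2, 240)
            s = "".join(map(str, counts))
            assert bt.exclude_fish(counts) == ("0" * 10 not in s)


class TestBoutPower:
    def _rec_with_bout(self, tail, on, off):
        n = tail.size
        t = np.arange(n) * DT
        flag = np.zeros(n, dtype=np.int8)
        flag[on:off] = 1
        rec = _recording(t, tail, bout_flag=flag)
        rec.tail_angle_raw = tail
        table = pd.DataFrame({"onset_idx": [on], "offset_idx": [off]})
        return rec, table

    def test_flat_trace_gives_zero_profile(self):
        rec, table = self._rec_with_bout(np.zeros(1000), 300, 400)
        prof = bt.bout_power(rec, table)
        assert prof.shape == (1, bt.POWER_N_SAMPLES)
        assert np.allclose(prof, 0.0)

    def test_window_has_220_samples(self):
        assert bt.POWER_N_SAMPLES == 220
        assert int(round(1.1 / DT)) == 220

    def test_sinusoidal_bout_hand_oracle(self):
        n = 1000
        tail = np.full(n, 0.07)  # constant baseline
        on, off = 300, 400
        tt = np.arange(off - on) * DT
        tail[on:off] += 0.5 * np.sin(2 * np.pi * 25 * tt)
        rec, table = self._rec_with_bout(tail, on, off)
        prof = bt.bout_power(rec, table)[0]
        # pre-onset: baseline-subtracted constant -> exactly 0
        assert np.allclose(prof[:20], 0.0)
        # during bout: squared baseline-subtracted sinusoid
        assert np.allclose(prof[20:120],
                           (0.5 * np.sin(2 * np.pi * 25 * tt)) ** 2)
        # after offset: exactly 0 (zeroed, not baseline-shifted)
        assert np.allclose(prof[120:], 0.0)

    def test_bout_too_close_to_start_is_undefined(self):
        rec, table = self._rec_with_bout(np.zeros(1000), 10, 100)
        prof = bt.bout_power(rec, table)
        assert np.all(np.isnan(prof))


class TestSplitPower:
    def test_constant_profile_area_proportions(self):
        c = 0.3
        bal, rea = bt.split_power(np.full(220, c))
        # half-open window: ballistic covers 0.22 s, reactive 0.22-0.995 s
        assert bal == pytest.approx(0.22 * c)
        assert rea == pytest.approx(0.775 * c)

    def test_random_profiles_match_direct_integration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0, 1, 220)
            bal, rea = bt.split_power(p)
            t = (np.arange(220) - 20) * DT
            assert bal == pytest.approx(np.trapezoid(p[20:65], t[20:65]))
            assert rea == pytest.approx(np.trapezoid(p[64:], t[64:]))


class TestAdaptationMetrics:
    def _phases(self, n_ad=50, n_post=10):
        return np.array(["calibration"] * 10 + ["pre_adaptation"] * 10
                        + ["adaptation"] * n_ad + ["post_adaptation"] * n_post)

    def test_identical_durations_give_zero_metrics(self):
        phases = self._phases()
        m = bt.adaptation_metrics(np.full(phases.size, 400.0), phases)
        assert (m.acute_reaction, m.reduction_of_acute_reaction,
                m.after_effect) == (0.0, 0.0, 0.0)
        assert m.adapting is False

    def test_synthetic_schedule_hand_oracle(self):
        phases = self._phases(n_ad=50, n_post=10)
        v = np.full(phases.size, np.nan)
        v[phases == "pre_adaptation"] = 300.0
        ad = np.flatnonzero(phases == "adaptation")
        v[ad] = 330.0
        v[ad[:10]] = 420.0
        v[phases == "post_adaptation"] = 260.0
        m = bt.adaptation_metrics(v, phases)
        assert m.acute_reaction == pytest.approx(120.0)
        assert m.reduction_of_acute_reaction == pytest.approx(-90.0)
        assert m.after_effect == pytest.approx(-40.0)
        assert m.adapting is True

    def test_trials_without_first_bout_skipped(self):
        phases = self._phases()
        v = np.full(phases.size, 400.0)
        v[np.flatnonzero(phases == "pre_adaptation")[:5]] = np.nan
        m = bt.adaptation_metrics(v, phases)
        assert m.acute_reaction == 0.0

    def test_empty_block_gives_undefined_metric(self):
        phases = self._phases()
        v = np.full(phases.size, 400.0)
        v[phases == "pre_adaptation"] = np.nan
        m = bt.adaptation_metrics(v, phases)
        assert np.isnan(m.acute_reaction)
        assert np.isnan(m.after_effect)
        assert np.isfinite(m.reduction_of_acute_reaction)


class TestTimepointTest:
    def test_identical_distributions_rarely_significant(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(0, 1, (30, 220)) for k in "abc"}
        mask, pvals = bt.timepoint_condition_test(groups)
        # Bonferroni-corrected level: expect essentially no hits under null
        assert mask.sum() <= 2

    def test_shift_only_in_reactive_period_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, (40, 220))
        b = rng.normal(0, 0.1, (40, 220))
        b[:, 64:] += 5.0  # large shift after 220 ms post-onset only
        mask, _ = bt.timepoint_condition_test({"a": a, "b": b})
        assert not mask[:64].any()
        assert mask[64:].all()

    def test_bonferroni_divisor_is_220(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (10, 220))
        b = rng.normal(0, 1, (10, 220))
        mask, pvals = bt.timepoint_condition_test({"a": a, "b": b})
        assert np.array_equal(mask, pvals < 0.05 / 220)


class TestGroupCompare:
    def test_identical_groups_large_n_not_significant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 100)
        y = rng.normal(0, 1, 100)
        assert bt.group_compare(x, y) > 0.05

    def test_small_sample_exact_vs_enumeration_oracle(self):
        # all of one group larger: two-sided exact p = 2 / C(6,3) = 0.1
        x = [10.0, 11.0, 12.0]
        y = [1.0, 2.0, 3.0]
        assert bt.group_compare(x, y) == pytest.approx(2 / 20)
        assert bt.group_compare(x, y, alternative="greater") == pytest.approx(1 / 20)

    def test_fully_tied_data_warns_p_one(self):
        with pytest.warns(UserWarning):
            p = bt.group_compare([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
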