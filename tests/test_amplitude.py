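"""ROI amplitude statistic: oracle equivalence, missing rules, curve assembly."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_recording, make_subject
from pupilrecover.amplitude import (
    RoiConfig,
    average_eyes,
    build_table,
    extract_cycle,
    recovery_curve,
)
from pupilrecover.preprocess import CleaningConfig, clean
from pupilrecover.protocol import ReonsetEvent, reonset_times
from pupilrecover.synth import (
    amplitude_law,
    constriction_kernel,
    simulate_recording,
)

ROI = RoiConfig()


def brute_force_amplitude(rec, reonset, roi=ROI):
    """Independent scan over every sample in each ROI window."""
    vals_max, vals_min = [], []
    n_max = n_min = 0
    for t, d, v in zip(rec.t_ms, rec.diameter_mm, rec.valid):
        dt = t - reonset.time_ms
        if roi.max_window_ms[0] <= dt < roi.max_window_ms[1]:
            n_max += 1
            if v:
                vals_max.append(d)
        if roi.min_window_ms[0] <= dt < roi.min_window_ms[1]:
            n_min += 1
            if v:
                vals_min.append(d)
    if n_max == 0 or n_min == 0:
        return None
    if len(vals_max) < roi.min_valid_fraction * n_max:
        return None
    if len(vals_min) < roi.min_valid_fraction * n_min:
        return None
    return max(vals_max) - min(vals_min)


def event_at(t_ms=1000, dark_ms=500):
    return ReonsetEvent(time_ms=t_ms, preceding_dark_ms=dark_ms,
                        cycle_id="ramp_05", phase="ramp")


class TestExtractCycle:
    def test_constant_trace_zero_amplitude(self):
        rec = make_recording(np.full(400, 4.0))
        row = extract_cycle(rec, event_at())
        assert row.amplitude == 0.0
        assert not row.missing

    def test_noise_free_cycle_matches_closed_form_oracle(self, protocol, clean_subject):
        rec = simulate_recording(clean_subject, protocol)
        p = clean_subject.params
        for ev in [e for e in reonset_times(protocol) if e.phase == "ramp"][:10]:
            row = extract_cycle(rec, ev)
            amp = float(amplitude_law(ev.preceding_dark_ms, clean_subject))
            t_rel = np.arange(100, 200, 5.0) - 0.0
            g_max = constriction_kernel(t_rel, p.kernel_peak_ms).max()
            assert row.amplitude == pytest.approx(amp * g_max, abs=1e-9)

    def test_blink_over_min_window_gives_missing(self):
        d = np.full(400, 4.0)
        valid = np.ones(400, bool)
        # re-onset at 1000 ms, min ROI = samples 220..239
        valid[220:240] = False
        d[220:240] = np.nan
        rec = make_recording(d, valid=valid)
        row = extract_cycle(rec, event_at())
        assert row.missing and row.missing_reason == "roi_invalid"

    def test_out_of_span(self):
        rec = make_recording(np.full(100, 4.0))  # 0..495 ms
        row = extract_cycle(rec, event_at(t_ms=400))
        assert row.missing_reason == "out_of_span"

    def test_negative_amplitude_preserved(self):
        # trace rises after re-onset: amplitude < 0 must be kept as-is
        t = np.arange(400) * 5.0
        rec = make_recording(4.0 + 0.001 * t)
        row = extract_cycle(rec, event_at())
        assert row.amplitude < 0
        assert not row.missing

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        d = 4.0 + rng.normal(0, 0.3, n)
        valid = rng.random(n) > 0.1
        d[~valid] = np.nan
        rec = make_recording(d, valid=valid)
        ev = event_at(t_ms=int(rng.integers(0, 1800)))
        row = extract_cycle(rec, ev)
        expected = brute_force_amplitude(rec, ev)
        if expected is None:
            assert row.missing
        else:
            assert row.amplitude == expected  # bitwise

    def test_half_open_roi_boundaries(self):
        # minimum placed exactly at +200 ms must be excluded from the min ROI;
        # maximum exactly at +100 ms excluded from the max ROI
        d = np.full(400, 4.0)
        rec = make_recording(d)
        ev = event_at(t_ms=1000)
        i0 = 200  # sample at 1000 ms
        d[i0 + 20] = 6.0   # +100 ms -> min window, not max window
        d[i0 + 40] = 1.0   # +200 ms -> outside both
        rec = make_recording(d)
        row = extract_cycle(rec, ev)
        # d_max from [0,100): all 4.0; d_min from [100,200): min(4.0, ...)=4.0
        assert row.d_max_mm == 4.0
        assert row.d_min_mm == 4.0

    def test_shifting_reference_moves_membership_as_predicted(self):
        d = np.full(400, 4.0)
        d[220] = 2.0  # at 1100 ms
        rec = make_recording(d)
        # re-onset 1000 ms: 1100 is in [100,200) -> captured as min
        assert extract_cycle(rec, event_at(t_ms=1000)).d_min_mm == 2.0
        # re-onset 1005 ms: 1100-1005=95 -> in max window instead
        row = extract_cycle(rec, event_at(t_ms=1005))
        assert row.d_min_mm == 4.0
        assert row.d_max_mm == 4.0  # max window max is still 4.0


class TestBuildTable:
    def test_blink_free_subject_yields_50_ramp_rows(self, protocol, clean_subject):
        rec = clean(simulate_recording(clean_subject, protocol),
                    CleaningConfig(smooth_window_ms=0))
        tab = build_table([rec], protocol, [clean_subject])
        ramp = tab[tab.phase == "ramp"]
        assert len(ramp) == 50
        assert (ramp.missing_reason == "").all()
        assert sorted(ramp.dark_ms) == [100.0 * k for k in range(1, 51)]

    def test_small_cohort_row_count(self, protocol):
        subs = [make_subject(f"s{i}", "Control", seed=i,
                             noise_sd_mm=0, hippus_amp_mm=0, blink_rate_hz=0,
                             dark_gain_mm=0)
                for i in range(3)]
        recs = [simulate_recording(s, protocol) for s in subs]
        tab = build_table(recs, protocol, subs)
        assert len(tab[tab.phase == "ramp"]) == 3 * 50

    def test_empty_recording_list(self, protocol, clean_subject):
        tab = build_table([], protocol, [clean_subject])
        assert tab.empty

    def test_unknown_subject_is_join_error(self, protocol, clean_subject):
        rec = simulate_recording(clean_subject, protocol)
        other = make_subject("someone_else")
        with pytest.raises(KeyError, match=clean_subject.subject_id):
            build_table([rec], protocol, [other])

    def test_tail_and_repeat_rows_labelled(self, protocol, clean_subject):
        rec = simulate_recording(clean_subject, protocol)
        tab = build_table([rec], protocol, [clean_subject])
        assert set(tab.phase) == {"ramp", "tail", "repeat"}
        assert len(tab[tab.phase == "tail"]) == 3


class TestAverageEyes:
    def _two_eye_table(self, left_amp, right_amp, right_missing=""):
        rows = []
        for eye, amp, miss in [("left", left_amp, ""),
                               ("right", right_amp, right_missing)]:
            rows.append({
                "subject_id": "s1", "eye": eye, "group": "Control",
                "age_years": 70.0, "phase": "ramp", "cycle_id": "ramp_01",
                "dark_ms": 100.0, "d_max_mm": 5.0, "d_min_mm": 5.0 - amp,
                "amplitude": amp if miss == "" else np.nan,
                "missing_reason": miss,
            })
        return pd.DataFrame(rows)

    def test_mean_of_two_eyes(self):
        out = average_eyes(self._two_eye_table(0.4, 0.6))
        assert len(out) == 1
        assert out.amplitude.iloc[0] == pytest.approx(0.5)
        assert out.eye.iloc[0] == "both"

    def test_available_case_rule(self):
        out = average_eyes(self._two_eye_table(0.4, np.nan, "roi_invalid"))
        assert out.amplitude.iloc[0] == pytest.approx(0.4)
        assert out.missing_reason.iloc[0] == ""

    def test_single_eye_passthrough(self, protocol, clean_subject):
        rec = simulate_recording(clean_subject, protocol)
        tab = build_table([rec], protocol, [clean_subject])
        out = average_eyes(tab)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), tab.reset_index(drop=True)
        )

    def test_both_missing_stays_missing(self):
        df = self._two_eye_table(np.nan, np.nan)
        df["missing_reason"] = "roi_invalid"
        df["amplitude"] = np.nan
        out = average_eyes(df)
        assert out.missing_reason.iloc[0] == "roi_invalid"


class TestRecoveryCurve:
    def _table(self, subjects):
        rows = []
        for sid, group, amps in subjects:
            for k, a in enumerate(amps, start=1):
                rows.append({
                    "subject_id": sid, "eye": "left", "group": group,
                    "age_years": 70.0, "phase": "ramp",
                    "cycle_id": f"ramp_{k:02d}", "dark_ms": 100.0 * k,
                    "d_max_mm": 5.0, "d_min_mm": 5.0 - a, "amplitude": a,
                    "missing_reason": "",
                })
        return pd.DataFrame(rows)

    def test_single_subject_curve(self):
        amps = [0.1, 0.2, 0.3]
        curve = recovery_curve(self._table([("s1", "Control", amps)]), "Control")
        np.testing.assert_allclose(curve.mean_amplitude, amps)
        np.testing.assert_allclose(curve.sd, 0.0)

    def test_unknown_group(self):
        with pytest.raises(ValueError, match="unknown group"):
            recovery_curve(self._table([("s1", "Control", [0.1])]), "Martian")

    def test_missing_point_omitted(self):
        df = self._table([("s1", "Control", [0.1, 0.2])])
        df.loc[df.dark_ms == 200.0, "missing_reason"] = "roi_invalid"
        curve = recovery_curve(df, "Control")
        assert list(curve.dark_ms) == [100.0]

    def test_slower_group_below_at_every_duration(self, protocol):
        ctrl = make_subject("c1", "Control", noise_sd_mm=0, hippus_amp_mm=0,
                            blink_rate_hz=0, dark_gain_mm=0,
                            tau_recovery_ms=1800.0)
        amd = make_subject("a1", "AMD", noise_sd_mm=0, hippus_amp_mm=0,
                           blink_rate_hz=0, dark_gain_mm=0,
                           tau_recovery_ms=3600.0, amp_max_mm=1.2,
                           age_slope_mm_per_year=0.010)
        recs = [simulate_recording(s, protocol) for s in (ctrl, amd)]
        tab = build_table(recs, protocol, [ctrl, amd])
        c = recovery_curve(tab, "Control")
        a = recovery_curve(tab, "AMD")
        assert np.all(a.mean_amplitude.to_numpy() < c.mean_amplitude.to_numpy())

    def test_noise_free_curve_nondecreasing(self, protocol, clean_subject):
        rec = simulate_recording(clean_subject, protocol)
        tab = build_table([rec], protocol, [clean_subject])
        curve = recovery_curve(tab, "Control")
        assert np.all(np.diff(curve.mean_amplitude) >= -1e-12)
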