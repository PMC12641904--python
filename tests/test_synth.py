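"""Forward simulator: recovery law, trace synthesis, cohort, CSV round trips."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_recording, make_subject
from pupilrecover.protocol import reonset_times
from pupilrecover.synth import (
    CohortConfig,
    GroupParams,
    amplitude_law,
    constriction_kernel,
    default_group_params,
    read_recording,
    simulate_amplitude_table,
    simulate_cohort,
    simulate_model_form_table,
    simulate_recording,
    subjects_to_frame,
    write_recording,
)


class TestAmplitudeLaw:
    def test_zero_dark_zero_amplitude(self):
        s = make_subject()
        assert amplitude_law(0.0, s) == 0.0

    def test_one_time_constant(self):
        s = make_subject(amp_max_mm=1.0, age_slope_mm_per_year=0.0)
        tau = s.params.tau_recovery_ms
        assert amplitude_law(tau, s) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_saturates_at_asymptote(self):
        s = make_subject(amp_max_mm=1.0, age_slope_mm_per_year=0.0)
        assert amplitude_law(1e9, s) == pytest.approx(1.0)

    def test_negative_dark_rejected(self):
        with pytest.raises(ValueError):
            amplitude_law(-1.0, make_subject())

    def test_age_floor_at_zero(self):
        s = make_subject(age=200.0, amp_max_mm=0.5, age_slope_mm_per_year=0.1)
        assert amplitude_law(1e9, s) == 0.0

    @given(
        d1=st.floats(0, 1e5),
        d2=st.floats(0, 1e5),
        tau=st.floats(100, 10000),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_nondecreasing(self, d1, d2, tau):
        s = make_subject(tau_recovery_ms=tau)
        lo, hi = sorted([d1, d2])
        assert amplitude_law(lo, s) <= amplitude_law(hi, s) + 1e-15

    def test_slower_group_lies_below_at_all_ramp_durations(self):
        ctrl = make_subject(group="Control", tau_recovery_ms=1800.0)
        amd = make_subject(
            subject_id="amd_01", group="AMD", tau_recovery_ms=3600.0,
            amp_max_mm=ctrl.params.amp_max_mm,
            age_slope_mm_per_year=ctrl.params.age_slope_mm_per_year,
        )
        darks = 100.0 * np.arange(1, 51)
        assert np.all(amplitude_law(darks, amd) < amplitude_law(darks, ctrl))


class TestKernel:
    def test_shape(self):
        assert constriction_kernel(0.0, 150.0) == 0.0
        assert constriction_kernel(150.0, 150.0) == pytest.approx(1.0)
        t = np.linspace(0, 3000, 500)
        g = constriction_kernel(t, 150.0)
        assert g.max() <= 1.0 + 1e-12
        assert g[-1] < 1e-6


class TestSimulateRecording:
    def test_noise_free_trace_matches_closed_form(self, protocol, clean_subject):
        rec = simulate_recording(clean_subject, protocol)
        p = clean_subject.params
        t = rec.t_ms.astype(float)
        for ev in reonset_times(protocol)[:5]:
            sel_max = (t >= ev.time_ms) & (t < ev.time_ms + 100)
            sel_min = (t >= ev.time_ms + 100) & (t < ev.time_ms + 200)
            amp = float(amplitude_law(ev.preceding_dark_ms, clean_subject))
            # oracle: direct evaluation of D_pre - A(d) * g(t) on the grid
            g_max = constriction_kernel(t[sel_min] - ev.time_ms, p.kernel_peak_ms).max()
            assert rec.diameter_mm[sel_max].max() == pytest.approx(
                p.baseline_mm, abs=1e-9
            )
            assert rec.diameter_mm[sel_min].min() == pytest.approx(
                p.baseline_mm - amp * g_max, abs=1e-9
            )

    def test_sampling_grid_is_200hz(self, protocol, clean_subject):
        rec = simulate_recording(clean_subject, protocol)
        assert rec.sample_rate_hz == 200.0
        assert np.all(np.diff(rec.t_ms) == 5)
        assert rec.n_samples == protocol.total_duration_ms // 5

    def test_no_blinks_all_valid(self, protocol, clean_subject):
        rec = simulate_recording(clean_subject, protocol)
        assert rec.valid.all()
        assert np.all(rec.diameter_mm > 0)

    def test_same_seed_identical(self, protocol):
        s = make_subject(seed=42)
        r1 = simulate_recording(s, protocol)
        r2 = simulate_recording(s, protocol)
        assert r1.equals(r2)

    def test_blinks_marked_invalid_with_sentinel(self, protocol):
        s = make_subject(blink_rate_hz=0.5, seed=3)
        rec = simulate_recording(s, protocol)
        assert not rec.valid.all()
        assert np.isnan(rec.diameter_mm[~rec.valid]).all()
        assert not np.isnan(rec.diameter_mm[rec.valid]).any()

    def test_short_protocol_rejected(self, clean_subject):
        from pupilrecover.protocol import StimulusEpoch, StimulusProtocol

        p = StimulusProtocol(
            epochs=(StimulusEpoch(0, "ramp", "bright", 0, 3000, "c1"),)
        )
        with pytest.raises(ValueError):
            simulate_recording(clean_subject, p)


class TestCohort:
    def test_default_cohort_is_14_plus_14(self, protocol):
        subjects, recs = simulate_cohort(
            CohortConfig(seed=0), protocol, simulate_traces=False
        )
        assert len(subjects) == 28
        assert sum(s.group == "AMD" for s in subjects) == 14
        assert sum(s.group == "Control" for s in subjects) == 14
        assert recs == []

    def test_seed_determinism_bitwise_csv(self, protocol):
        frames = []
        for _ in range(2):
            subjects, _ = simulate_cohort(
                CohortConfig(seed=11), protocol, simulate_traces=False
            )
            buf = io.StringIO()
            subjects_to_frame(subjects).to_csv(buf, index=False)
            frames.append(buf.getvalue())
        assert frames[0] == frames[1]

    def test_control_only_cohort(self, protocol):
        subjects, _ = simulate_cohort(
            CohortConfig(n_amd=0, n_control=5, seed=0), protocol,
            simulate_traces=False,
        )
        assert all(s.group == "Control" for s in subjects)

    def test_between_subject_jitter_varies_parameters(self, protocol):
        subjects, _ = simulate_cohort(
            CohortConfig(seed=2), protocol, simulate_traces=False
        )
        taus = {s.params.tau_recovery_ms for s in subjects if s.group == "Control"}
        assert len(taus) > 1


class TestAmplitudeTableGenerators:
    def test_lawlevel_table_shape(self, protocol):
        tab = simulate_amplitude_table(CohortConfig(seed=1), protocol)
        assert len(tab) == 28 * 50
        assert set(tab["phase"]) == {"ramp"}
        assert sorted(tab["dark_ms"].unique()) == [100.0 * k for k in range(1, 51)]

    def test_model_form_table_recovers_known_means(self):
        rng = np.random.default_rng(5)
        tab = simulate_model_form_table(
            beta_intercept=0.3, beta_time=1e-4, beta_group=-0.1,
            noise_sd=1e-9, rng=rng,
        )
        amd = tab[tab.group == "AMD"]
        ctrl = tab[tab.group == "Control"]
        d = amd["dark_ms"].to_numpy()
        assert np.allclose(amd["amplitude"], 0.3 + 1e-4 * d - 0.1, atol=1e-6)
        assert np.allclose(
            ctrl["amplitude"], 0.3 + 1e-4 * ctrl["dark_ms"], atol=1e-6
        )


class TestRecordingIO:
    def test_round_trip_identity(self, tmp_path):
        rec = make_recording([4.0, 4.1, np.nan, 4.3, 4.25], subject_id="s9")
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        loaded = read_recording(path)
        assert loaded.equals(rec)

    def test_sentinel_written_as_empty_field(self, tmp_path):
        rec = make_recording([4.0, np.nan, 4.2])
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        lines = path.read_text().splitlines()
        assert lines[2].split(",")[3] == ""  # diameter field of invalid sample

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,eye,t_ms,diameter_mm,valid\n"
            "s,left,0,4.0,True\ns,left,10,4.0,True\ns,left,5,4.0,True\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_recording(path)

    def test_missing_valid_column_defaults_all_valid(self, tmp_path):
        path = tmp_path / "noval.csv"
        path.write_text(
            "subject_id,eye,t_ms,diameter_mm\ns,left,0,4.0\ns,left,5,4.1\n"
        )
        with pytest.warns(UserWarning, match="valid"):
            rec = read_recording(path)
        assert rec.valid.all()

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("subject_id,t_ms\ns,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_recording(path)


class TestConfigValidation:
    def test_bad_group_params(self):
        with pytest.raises(ValueError):
            GroupParams(tau_recovery_ms=-1, amp_max_mm=1, age_slope_mm_per_year=0)
        with pytest.raises(ValueError):
            GroupParams(tau_recovery_ms=1, amp_max_mm=1,
                        age_slope_mm_per_year=0, noise_sd_mm=-0.1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_amd=0, n_control=0)

    def test_default_group_conditions(self):
        gp = default_group_params()
        assert gp["AMD"].tau_recovery_ms > gp["Control"].tau_recovery_ms
        assert gp["AMD"].age_slope_mm_per_year < gp["Control"].age_slope_mm_per_year
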