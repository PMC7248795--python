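from datetime import date, timedelta

import numpy as np
import pytest

from stimtrack import (
    AdherenceStatus,
    BehaviorProfile,
    DetectorConfig,
    FailureMode,
    PatientTimeline,
    SessionRecord,
    StimulationProfile,
    detect_and_log,
    render_session_traces,
    run_check,
    simulate_cohort,
    simulate_patient,
    week_and_day,
)
from stimtrack.errors import ConfigurationError

FAST_STIM = StimulationProfile(
    contraction_duration=5.0,
    relaxation_duration=5.0,
    amplitude=40.0,
    ramp_time=1.0,
    baseline_noise_sd=0.0,
    sample_rate=10.0,
)


def deterministic_profile(**overrides) -> BehaviorProfile:
    base = dict(
        weekly_target=5,
        completion_prob_per_scheduled_day=1.0,
        overreport_prob=0.0,
        sync_prob=1.0,
        sync_latency_mean_days=0.0,
        session_minutes=3,
    )
    base.update(overrides)
    return BehaviorProfile(**base)


class TestSimulatePatient:
    def test_degenerate_probabilities_give_exact_counts(self):
        patient = simulate_patient(deterministic_profile(), weeks=1, seed=0)
        assert len(patient.true_sessions) == 5
        assert len(patient.self_report_dates) == 5
        assert len(patient.synced_sessions) == 5
        assert patient.device_log_count == 5

    def test_never_sync_patient_syncs_nothing(self):
        patient = simulate_patient(
            deterministic_profile(failure_mode=FailureMode.NEVER_SYNC),
            weeks=2,
            seed=0,
        )
        assert len(patient.true_sessions) == 10
        assert patient.synced_sessions == []

    def test_never_sync_downstream_is_noncompliant_with_reminders(self):
        patient = simulate_patient(
            deterministic_profile(failure_mode=FailureMode.NEVER_SYNC),
            weeks=2,
            seed=1,
        )
        timeline = PatientTimeline(patient.patient_id, patient.start_date)
        for record in patient.synced_sessions:
            timeline.add_session(record)
        for week in (1, 2):
            assert run_check(timeline, week, 3).reminder
            day7 = run_check(timeline, week, 7)
            assert day7.status is AdherenceStatus.NONCOMPLIANT
            assert day7.clinician_alert

    def test_spurious_mode_inflates_counter_only(self):
        patient = simulate_patient(
            deterministic_profile(failure_mode=FailureMode.SPURIOUS_DEVICE_COUNT),
            weeks=2,
            seed=0,
        )
        assert patient.device_log_count > len(patient.true_sessions)
        # behaviour itself is unaffected
        assert len(patient.true_sessions) == 10
        assert len(patient.synced_sessions) == 10

    def test_battery_abandon_truncates_sessions(self):
        full = simulate_patient(deterministic_profile(), weeks=2, seed=5)
        abandoned = simulate_patient(
            deterministic_profile(failure_mode=FailureMode.BATTERY_ABANDON),
            weeks=2,
            seed=5,
        )
        assert len(abandoned.true_sessions) < len(full.true_sessions)
        last = max(r.start_time for r in abandoned.true_sessions)
        cutoff_day = (last.date() - abandoned.start_date).days
        assert cutoff_day < 13  # stopped before the enrolment ended

    def test_overreport_rate_recovered_from_large_cohort(self):
        # 2000 simulated patient-weeks; estimator is a binomial proportion
        p = 0.12
        profile = deterministic_profile(overreport_prob=p)
        phantoms = 0
        true_total = 0
        for i in range(400):
            patient = simulate_patient(
                profile, weeks=5, seed=123, patient_index=i
            )
            true_total += len(patient.true_sessions)
            phantoms += len(patient.self_report_dates) - len(patient.true_sessions)
        estimate = phantoms / true_total
        sd = np.sqrt(p * (1 - p) / true_total)
        assert abs(estimate - p) <= 3 * sd

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            BehaviorProfile(overreport_prob=1.5)
        with pytest.raises(ConfigurationError):
            simulate_patient(BehaviorProfile(), weeks=0, seed=0)


class TestSimulateCohort:
    def test_ledger_has_one_row_per_patient(self):
        cohort = simulate_cohort([BehaviorProfile()] * 7, weeks=2, seed=0)
        ledger = cohort.ledger()
        assert len(ledger) == 7
        assert ledger["patient_id"].is_unique

    def test_identical_seed_identical_ledger(self):
        a = simulate_cohort([BehaviorProfile()] * 4, weeks=2, seed=9).ledger()
        b = simulate_cohort([BehaviorProfile()] * 4, weeks=2, seed=9).ledger()
        assert a.equals(b)

    def test_adding_a_patient_preserves_earlier_streams(self):
        small = simulate_cohort([BehaviorProfile()] * 3, weeks=2, seed=9)
        large = simulate_cohort([BehaviorProfile()] * 4, weeks=2, seed=9)
        for p_small, p_large in zip(small.patients, large.patients):
            assert p_small.true_sessions == p_large.true_sessions
            assert p_small.synced_sessions == p_large.synced_sessions

    def test_spurious_patient_flagged_in_ledger(self):
        cohort = simulate_cohort(
            [BehaviorProfile(),
             BehaviorProfile(failure_mode=FailureMode.SPURIOUS_DEVICE_COUNT)],
            weeks=2,
            seed=3,
        )
        flags = cohort.ledger()["flags"].tolist()
        assert flags == ["", "spurious_device"]


class TestRenderedTraces:
    def test_detector_recovers_session_count_exactly(self):
        patient = simulate_patient(deterministic_profile(), weeks=1, seed=2)
        traces = render_session_traces(patient, FAST_STIM)
        assert len(traces) == len(patient.true_sessions)
        config = DetectorConfig(
            on_threshold=10.0, off_threshold=5.0,
            session_gap_timeout=120.0, min_session_duration=60.0,
        )
        detected = [detect_and_log(trace, config) for trace in traces]
        assert all(len(found) == 1 for found in detected)
        for found, truth in zip(detected, patient.true_sessions):
            assert found[0].avg_peak_voltage == pytest.approx(
                truth.avg_peak_voltage
            )

    def test_patient_without_sessions_renders_nothing(self):
        profile = deterministic_profile(completion_prob_per_scheduled_day=0.0)
        patient = simulate_patient(profile, weeks=1, seed=0)
        assert render_session_traces(patient, FAST_STIM) == []

    def test_clock_drift_restamp_corrects_week_attribution(self):
        # 6 h/day gain: a late session on day 7 drifts into week 2
        profile = deterministic_profile(
            failure_mode=FailureMode.CLOCK_DRIFT,
            drift_seconds_per_day=6 * 3600.0,
        )
        patient = simulate_patient(profile, weeks=1, seed=11)
        start = date(2024, 1, 1)
        misattributed = 0
        for index, device_record in zip(
            patient.synced_indices, patient.synced_sessions
        ):
            truth = patient.true_sessions[index]
            true_week, _ = week_and_day(start, truth.start_time)
            drifted_week, _ = week_and_day(start, device_record.start_time)
            if drifted_week != true_week:
                misattributed += 1
            offset = patient.device_stamp_offset(truth)
            corrected = SessionRecord(
                device_record.start_time - offset,
                device_record.end_time - offset,
                device_record.avg_peak_voltage,
            )
            assert week_and_day(start, corrected.start_time) == (
                true_week,
                week_and_day(start, truth.start_time)[1],
            )
        assert misattributed >= 1  # drift actually flipped at least one week
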