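# Methods

This note documents the models, defaults and numerical choices behind
`stimtrack`, what the synthetic data do and do not emulate, and the known
limitations.

## Waveform model

NMES output is modelled at the envelope level: the rectified, divided
voltage the monitoring hardware samples, not the underlying biphasic
pulse train. Each contraction is a trapezoid — linear ramp of `ramp_time`
seconds to the plateau `amplitude`, plateau for the remainder of
`contraction_duration`, instantaneous release — followed by
`relaxation_duration` at zero. A session of duration *D* contains
`floor(D / cycle)` full cycles; the fractional remainder is silent so
cycle counts are exact by construction. Optional zero-mean Gaussian noise
(sd `baseline_noise_sd`) is added to every sample and clipped at 0,
because a rectified output cannot go negative.

Defaults: 10 s contraction / 10 s relaxation, 2 s ramp, 100 Hz sampling.
The real device's firmware sampling rate and duty-cycle timing are not
public; these are kit choices, fast enough to resolve multi-second cycles
and small enough for desk-scale tests. The generator is pure and seeded;
clock pathologies are injected by the simulator, never here.

## Session detector

Two thresholds rather than one: a session arms only at `on_threshold`
(default 10 device units) but is sustained and segmented at
`off_threshold` (default 5). Hysteresis prevents edge chatter, and
reusing `off_threshold` as the contraction-cycle boundary for the
average-peak-voltage statistic guarantees the detector and the intensity
measure agree on what a contraction is.

* `session_gap_timeout` = 120 s. Must exceed any plausible relaxation
  phase so intra-session rests never split a session; 120 s is an order
  of magnitude above the default 10 s relaxation.
* `min_session_duration` = 60 s, suppressing power-on blips.
* Session end is the last supra-threshold sample, not the end of the
  closing gap: the session ends when stimulation ends.

The detector is vectorised (run/gap analysis on boolean arrays) but is
specified by, and tested against, a per-sample reference scan that
implements the rule directly.

## Telemetry codec

Field layout `>QQd`: start and end time as big-endian unsigned 64-bit
milliseconds since the Unix epoch, average peak voltage as a 64-bit
float — exactly 24 bytes, lossless round trip at millisecond/IEEE-754
precision. The sync terminator is eight 0xFF bytes; that prefix decodes
to a year far beyond the validated timestamp range (capped at year 9999),
so it can never open a well-formed record. The 30-second connection
timeout is modelled as a boolean input (`timeout_elapsed`) to keep the
codec clock-free; on timeout the decoder salvages all complete records
and flags truncation. Upload follows retain-until-acknowledged semantics:
a failed sink call retains everything, and the server deduplicates on
(patient ID, start time), so double syncs are harmless. An optional
`restamp` hook rewrites timestamps at upload — the remedy for device
clock drift, replacing the device clock with receive-time-anchored
stamps.

## Adherence engine

Weeks are 1-based consecutive 7-day blocks from the patient start date
(`week = 1 + days//7`, `day = 1 + days%7`), in whole local calendar days
with no timezone handling (single-site semantics). Classification uses
synced sessions only — the server cannot observe unsynced behaviour —
attributed to weeks by session start time. Thresholds: > 4 compliant,
3–4 almost compliant, < 3 noncompliant. The day-3 check fires a reminder
iff days 1–3 contain no synced session; it is point-in-time and is not
retracted if the patient later completes the week. The day-7 check emits
the weekly status and raises a clinician alert iff noncompliant. Session
duration and intensity are reported but not enforced in adherence
counting; the only duration gate in the pipeline is the detector's
`min_session_duration`.

## Notification service

Each engine event type maps to a pool of message bodies; selection is
uniform via a seeded generator, so the whole messaging layer is
reproducible. All notifications, including after-session praise, route
through the hourly dispatcher for one consistent delivery semantics
(an immediate-send path for after-session messages would be equally
defensible; the queue-only design keeps exactly-once delivery trivially
auditable). Delivery latency is therefore bounded by one hour plus one
tick. Patients flagged as device-ID-reassociated keep receiving
notifications but their deliveries are marked `delivery-unknown` rather
than dropped, and such rows are treated as incomplete logs by reporting.

## Patient-behaviour simulator

Each patient schedules `weekly_target` (default 5) days uniformly per
week and completes each scheduled session with probability 0.9 —
pilot-scale behaviour of mostly adherent post-surgical patients enrolled
for one to two weeks. Sessions start uniformly between 08:00 and 21:00
and last `session_minutes` (default 60). Intensity is drawn per session
from N(36, 13²) device units, floored at 15 — the distribution matches
the large day-to-day variability of stimulation tolerance after knee
surgery, and the floor encodes that stimulation much weaker than that
produces no usable contraction envelope (it also keeps rendered traces
above the detector's on-threshold, preserving the end-to-end conservation
property).

Over-reporting: with probability `overreport_prob` (default 0.12) a
completed session spawns one phantom paper-log entry, so the expected
self-report/device ratio is exactly 1 + p and the configured rate is
recoverable from large cohorts as a binomial proportion. (An alternative
"phantom per scheduled day" mechanism would make the aggregate bias
depend on the completion rate; the per-session form keeps the parameter
directly interpretable as the observed 12–15% bias.)

Failure modes, one per observed deployment pathology: `never_sync`
(sessions happen, nothing uploads), `spurious_device_count`
(multiplicative 4–15× inflation of the device's internal counter only —
the field values of 34 and 135 sessions against single-digit real counts
had no evident mechanism, so only the observable is modelled),
`battery_abandon` (no sessions after a uniformly drawn cutoff day), and
`clock_drift` (device stamps gain `drift_seconds_per_day`, default
3600 s/day — deliberately exaggerated relative to a real RTC so the
failure is visible at two-week scale; the sync-time restamp corrects
week attribution).

Per-patient streams derive from `SeedSequence([cohort_seed, index])`, so
appending patients never perturbs earlier timelines.

What the simulator does **not** model: electrode/tissue impedance,
intensity trends with post-surgical edema, sub-cycle pulse structure,
multi-device usage, or correlated behaviour across patients. Passing
tests therefore demonstrate pipeline correctness under the stated
behavioural model, not validity of any clinical inference from real
patients.

## Reporting

Percentages are rounded to the nearest integer, half away from zero —
the convention consistent with every ledger ratio (55/73→75, 55/69→80,
40/48→83, 7/48→15). The spurious-counter rule flags
`device_logged > elapsed_days × 2`: no published rule exists, and a cap
of two sessions per day is generous against a one-per-day prescription
while still flagging both observed runaway counters over one-to-two-week
windows. Never-synced patients are excluded from the second self-report
capture figure; spurious rows from device-based figures; the notification
rate covers only rows with both expected and received counts present.
The bundled pilot ledger transcribes per-patient counts; two entries were
only published as two-patient aggregates (26/26 and 20/22) and are split
evenly / by the unique split consistent with the aggregate totals, as
annotated in the CSV. One aggregate figure (32/32 across four patients)
is not derivable from the per-patient breakdown and is deliberately not
represented.

## Pipeline and determinism

`run_demo` replays syncs and scheduled checks in chronological order so
point-in-time check semantics hold; checks run at 21:00 on days 3 and 7.
Everything — simulation, enrolment tokens, message selection — draws from
generators seeded from the single run seed, making re-runs byte-identical.
The default demo cohort is seven patients over two weeks (four typical,
one per failure mode), small enough to run in about a second at 100 Hz.
Statistical tests use 2,000 simulated patient-weeks (400 patients × 5
weeks) for parameter recovery and 1,000 randomised traces/records for
detector-oracle equivalence and codec round-trips.

## Known limitations

* Batch detection over complete traces; the streaming firmware behaviour
  is equivalent for these inputs but is not separately modelled.
* No transport layer: the uplink is an injectable in-memory sink, and
  "timeout" is an input flag rather than measured time.
* Calendar arithmetic ignores timezones and daylight-saving shifts.
* The clock-drift correction uses the offset measured at sync time, which
  over-corrects records synced late by up to the drift accumulated
  between session and sync; with the default drift and same-evening
  syncing this is bounded by a few hours and cannot cross a day boundary
  for daytime sessions.
* Intensity agreement between detector and patient perception is out of
  scope: the per-session statistic verifies device use, not dose.
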