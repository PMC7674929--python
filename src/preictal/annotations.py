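"""Seizure-event interval algebra.

Raw annotations (onset/termination seconds) are turned into *series* of
clustered seizures, *lead seizures* (the first seizure of each series), and a
disjoint labeling of the recording timeline into interictal / preictal /
postictal / ictal / unused periods for a chosen preictal length L.

Conventions
-----------
* Times are floating seconds from recording start; intervals are half-open
  ``[start, end)``.
* Consecutive seizures closer than the merge gap form one series.  The gap is
  measured onset-to-onset by default (``gap_reference="onset"``); ictal
  durations are minutes, so this differs negligibly from termination-to-onset,
  which is available as a switch.
* A time point is interictal iff it is farther than the interictal margin
  (default 3 h) from *every* lead onset, in both directions.
* Preictal = the L minutes ending exactly at a lead onset; postictal = the
  30 min following a series' last termination.  Time within the margin of a
  lead onset that is none of these is labeled ``unused`` and never sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SeizureEvent",
    "SeizureSeries",
    "PeriodLabeling",
    "ConfigurationError",
    "AnnotationError",
    "SUPPORTED_PREICTAL_LENGTHS_MIN",
    "merge_gap_for",
    "group_into_series",
    "derive_lead_onsets",
    "label_periods",
]

LABELS = ("interictal", "preictal", "postictal", "ictal", "unused")

#: Preictal lengths (minutes) the three-step protocol sweeps.
SUPPORTED_PREICTAL_LENGTHS_MIN = (1, 5, 10, 30, 60, 120)

INTERICTAL_MARGIN_S = 3 * 3600.0
POSTICTAL_LEN_S = 30 * 60.0


class ConfigurationError(ValueError):
    """An unsupported configuration value (e.g. preictal length)."""


class AnnotationError(ValueError):
    """Invalid seizure annotations (unordered, overlapping, out of range)."""


@dataclass(frozen=True, order=True)
class SeizureEvent:
    """One annotated seizure: ``[onset_s, termination_s)`` seconds."""

    onset_s: float
    termination_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.termination_s):
            raise AnnotationError(
                f"need 0 <= onset < termination, got [{self.onset_s}, {self.termination_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.termination_s - self.onset_s


@dataclass(frozen=True)
class SeizureSeries:
    """A maximal run of seizures whose consecutive gaps are below the merge gap."""

    events: tuple[SeizureEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise AnnotationError("a series must contain at least one event")
        _validate_events(self.events)

    @property
    def lead_onset(self) -> float:
        """Onset of the lead seizure (first event of the series)."""
        return self.events[0].onset_s

    @property
    def last_termination(self) -> float:
        return self.events[-1].termination_s


@dataclass
class PeriodLabeling:
    """Disjoint labeled intervals covering ``[0, duration_s)`` of a recording.

    ``flagged_leads`` are lead onsets whose preictal window was truncated
    below the configured minimum fraction of L; they stay in the labeling but
    epoch extraction should skip their preictal intervals.
    """

    preictal_length_min: float
    duration_s: float
    intervals: list[tuple[float, float, str]]
    lead_onsets: list[float] = field(default_factory=list)
    flagged_leads: list[float] = field(default_factory=list)

    def total(self, label: str) -> float:
        """Total seconds carrying `label`."""
        return sum(e - s for s, e, lab in self.intervals if lab == label)

    def with_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def validate(self, atol: float = 1e-6) -> None:
        """Assert the partition invariants: sorted, disjoint, exhaustive."""
        prev_end = 0.0
        for s, e, lab in self.intervals:
            if lab not in LABELS:
                raise AssertionError(f"unknown label {lab!r}")
            if s >= e:
                raise AssertionError(f"empty/negative interval [{s}, {e})")
            if abs(s - prev_end) > atol:
                raise AssertionError(f"gap or overlap at {prev_end} -> {s}")
            prev_end = e
        if abs(prev_end - self.duration_s) > atol:
            raise AssertionError(f"labeling ends at {prev_end}, duration {self.duration_s}")


def _validate_events(events) -> None:
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.onset_s:
            raise AnnotationError("events must be sorted by onset")
        if b.onset_s < a.termination_s:
            raise AnnotationError(
                f"overlapping events: [{a.onset_s}, {a.termination_s}) and onset {b.onset_s}"
            )


def merge_gap_for(preictal_length_min: float) -> float:
    """Merge gap (minutes) used to group seizures into series for a given L.

    The base rule clusters consecutive seizures within 1 h.  For the long
    preictal lengths the window widens so that a lead seizure's preictal and
    postictal periods fit between clusters: 1.5 h for L = 60 and 2.5 h for
    L = 120 (i.e. L + 30 min postictal).
    """
    if preictal_length_min not in SUPPORTED_PREICTAL_LENGTHS_MIN:
        raise ConfigurationError(
            f"unsupported preictal length {preictal_length_min} min; "
            f"supported: {SUPPORTED_PREICTAL_LENGTHS_MIN}"
        )
    if preictal_length_min <= 30:
        return 60.0
    return preictal_length_min + 30.0  # 90 for L=60, 150 for L=120


def group_into_series(
    events: list[SeizureEvent],
    gap_min: float,
    gap_reference: str = "onset",
) -> list[SeizureSeries]:
    """Group sorted, non-overlapping seizures into series by a linear scan.

    Two consecutive events belong to the same series iff the next onset is
    less than ``gap_min`` minutes after the reference point of the previous
    event (its onset by default, or its termination with
    ``gap_reference="termination"``).
    """
    if gap_reference not in ("onset", "termination"):
        raise ConfigurationError(f"gap_reference must be onset|termination, got {gap_reference!r}")
    _validate_events(events)
    if not events:
        return []
    gap_s = gap_min * 60.0
    groups: list[list[SeizureEvent]] = [[events[0]]]
    for ev in events[1:]:
        prev = groups[-1][-1]
        ref = prev.onset_s if gap_reference == "onset" else prev.termination_s
        if ev.onset_s - ref < gap_s:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    return [SeizureSeries(tuple(g)) for g in groups]


def derive_lead_onsets(series: list[SeizureSeries]) -> list[float]:
    """Lead-seizure onsets: the first onset of each series, strictly increasing."""
    onsets = [s.lead_onset for s in series]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise AnnotationError("series must be sorted with strictly increasing lead onsets")
    return onsets


def _carve(timeline: list[tuple[float, float, str | None]], start: float, end: float, label: str):
    """Assign `label` to the unassigned parts of [start, end) in the timeline."""
    out: list[tuple[float, float, str | None]] = []
    for s, e, lab in timeline:
        if lab is not None or e <= start or s >= end:
            out.append((s, e, lab))
            continue
        if s < start:
            out.append((s, start, None))
        out.append((max(s, start), min(e, end), label))
        if e > end:
            out.append((end, e, None))
    timeline[:] = out


def label_periods(
    events: list[SeizureEvent],
    preictal_length_min: float,
    recording_duration_s: float,
    *,
    interictal_margin_s: float = INTERICTAL_MARGIN_S,
    postictal_len_s: float = POSTICTAL_LEN_S,
    min_preictal_fraction: float = 0.5,
    gap_reference: str = "onset",
) -> PeriodLabeling:
    """Label the whole recording timeline for a given preictal length L.

    Priority when definitions overlap: ictal > postictal > preictal.  The
    remaining time is interictal when farther than ``interictal_margin_s``
    from every lead onset, else ``unused``.

    A lead seizure whose preictal window is clipped (by the recording start or
    by a preceding series' ictal/postictal time) below
    ``min_preictal_fraction * L`` is flagged, not dropped.
    """
    L_s = preictal_length_min * 60.0
    _validate_events(events)
    if events and events[-1].termination_s > recording_duration_s:
        raise AnnotationError("events extend beyond the recording duration")
    gap_min = merge_gap_for(preictal_length_min)
    series = group_into_series(events, gap_min, gap_reference=gap_reference)
    leads = derive_lead_onsets(series)

    timeline: list[tuple[float, float, str | None]] = [(0.0, float(recording_duration_s), None)]
    for ser in series:
        for ev in ser.events:
            _carve(timeline, ev.onset_s, ev.termination_s, "ictal")
    for ser in series:
        _carve(
            timeline,
            ser.last_termination,
            min(ser.last_termination + postictal_len_s, recording_duration_s),
            "postictal",
        )

    flagged: list[float] = []
    for ser in series:
        lead = ser.lead_onset
        start = max(lead - L_s, 0.0)
        # carve only what is still unassigned; earlier ictal/postictal win
        before = _unassigned_within(timeline, start, lead)
        _carve(timeline, start, lead, "preictal")
        if before < min_preictal_fraction * L_s:
            flagged.append(lead)

    # remaining time: interictal iff farther than the margin from every lead
    resolved: list[tuple[float, float, str]] = []
    for s, e, lab in timeline:
        if lab is not None:
            resolved.append((s, e, lab))
            continue
        pieces = [(s, e)]
        for lead in leads:
            lo, hi = lead - interictal_margin_s, lead + interictal_margin_s
            nxt: list[tuple[float, float]] = []
            for ps, pe in pieces:
                if pe <= lo or ps >= hi:
                    nxt.append((ps, pe))
                else:
                    if ps < lo:
                        nxt.append((ps, lo))
                    resolved.append((max(ps, lo), min(pe, hi), "unused"))
                    if pe > hi:
                        nxt.append((hi, pe))
            pieces = nxt
        resolved.extend((ps, pe, "interictal") for ps, pe in pieces)

    resolved.sort()
    merged: list[tuple[float, float, str]] = []
    for s, e, lab in resolved:
        if merged and merged[-1][2] == lab and abs(merged[-1][1] - s) < 1e-9:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))

    labeling = PeriodLabeling(
        preictal_length_min=preictal_length_min,
        duration_s=float(recording_duration_s),
        intervals=merged,
        lead_onsets=leads,
        flagged_leads=flagged,
    )
    labeling.validate()
    return labeling


def _unassigned_within(timeline, start: float, end: float) -> float:
    return sum(
        min(e, end) - max(s, start)
        for s, e, lab in timeline
        if lab is None and e > start and s < end
    )
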