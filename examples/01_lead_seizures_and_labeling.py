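"""Seizure-interval algebra: cluster seizures into series, find lead
seizures, and label a recording timeline for a chosen preictal length.

Seizures closer than 1 h (onset to onset) form one series whose first event
is the lead seizure — the prediction target.  For a preictal length L, the
L minutes before each lead onset are preictal, the 30 min after a series'
last termination are postictal, and only time farther than 3 h from every
lead onset counts as interictal.
"""

from preictal import SeizureEvent, group_into_series, label_periods, merge_gap_for

H, MIN = 3600.0, 60.0

# four seizures: a tight cluster of three around hour 5, one isolated at hour 14
events = [
    SeizureEvent(5 * H, 5 * H + 90),
    SeizureEvent(5 * H + 20 * MIN, 5 * H + 20 * MIN + 60),
    SeizureEvent(5 * H + 45 * MIN, 5 * H + 45 * MIN + 120),
    SeizureEvent(14 * H, 14 * H + 60),
]

for L in (30, 120):
    gap = merge_gap_for(L)
    series = group_into_series(events, gap)
    labeling = label_periods(events, L, recording_duration_s=20 * H)
    print(f"L = {L:>3} min  (merge gap {gap:.0f} min): "
          f"{len(series)} lead seizure(s) at {[s.lead_onset / H for s in series]} h")
    for label in ("interictal", "preictal", "postictal", "ictal", "unused"):
        print(f"   {label:<11}{labeling.total(label) / H:6.2f} h")

# The 20 h timeline is partitioned exactly; with the 1 h rule both groupings
# keep two lead seizures, and total preictal time is (number of leads) x L.
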