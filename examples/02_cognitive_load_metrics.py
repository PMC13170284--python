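"""Derive cognitive-load metrics from a raw audit-log event stream.

Shows the two worked examples the metric definitions are anchored to:
the looping sequence A,B,C,A,B,D (two loops) and a three-session
encounter split by the 10-minute inactivity timeout.
"""

import pandas as pd

import cogload as cl

# --- loop counting on a merged event sequence -------------------------
raw = [(t, 60.0) for t in "ABCABD"]
merged = cl.merge_consecutive(raw)
print(f"sequence A,B,C,A,B,D: loops={cl.count_loops(merged)}, "
      f"distinct={cl.count_distinct(merged)}")
# loops=2: one loop back to A and one back to B; distinct=4 unique types

# --- sessionization of a multi-segment encounter ----------------------
base = pd.Timestamp("2024-03-01 13:00:00")
rows = []
rows += [("prov1", "csn1", "ChartReview", base + pd.Timedelta(minutes=m)) for m in range(3)]
rows += [("prov1", "csn1", "Visit", base + pd.Timedelta(minutes=40 + 2 * k)) for k in range(15)]
rows += [("prov1", "csn1", "Notes", base + pd.Timedelta(hours=6, minutes=m)) for m in range(5)]
log = pd.DataFrame(
    {
        "provider_id": [r[0] for r in rows],
        "csn": [r[1] for r in rows],
        "event_type": [r[2] for r in rows],
        "timestamp": [r[3] for r in rows],
    }
)
encounters = cl.segment_and_time(log)
pe = encounters["csn1"]
load = cl.compute_cognitive_load(pe)
print(f"active segments: {len(pe.segments)}")
for s in pe.segments:
    print(f"  {s.start.time()} -> {s.end.time()}")
print(f"duration: {load.duration_minutes:.1f} min over {len(pe.segments)} segments")
print(f"avg dwell: {load.avg_event_seconds:.1f} s/event")
print()
print("Chart review, the visit, and after-hours notes become three disjoint")
print("active segments (gaps beyond the 10-minute timeout split them); the")
print("encounter duration is the sum of segment lengths, not wall-clock time.")
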