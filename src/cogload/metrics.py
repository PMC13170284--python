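"""Audit-log process mining: active segments and cognitive-load metrics.

Raw EHR audit logs record one timestamped row per (provider, encounter,
event type) interaction.  Work on a single encounter — identified by its
contact serial number (CSN) — is typically spread over several
non-contiguous sessions: chart review before the visit, the face-to-face
visit itself, and after-hours documentation.  This module reconstructs
those *active segments* from the raw event stream and derives four
encounter-level cognitive-load metrics per (provider, CSN) pair:

* ``loops`` — number of revisits to a previously opened event type,
* ``distinct_events`` — number of unique event types visited,
* ``duration_minutes`` — total active time summed over segments,
* ``avg_event_seconds`` — mean active time per merged event.

Sessionization uses a 10-minute inactivity timeout: each event's active
time is the gap to the provider's next event (in any encounter), capped at
the timeout; a gap beyond the timeout, or an intervening event for a
different encounter, closes the current segment.  Consecutive occurrences
of the same event type are merged into one event whose active time is the
run's sum, so that fine-grained logging of a single open screen does not
inflate the event count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import OrderingError, UndefinedMetricError

#: Default inactivity timeout, seconds.
DEFAULT_TIMEOUT = 600.0

#: Canonical audit-log column names.
AUDIT_COLUMNS = ["provider_id", "csn", "event_type", "timestamp"]

#: Canonical metric column names, in reporting order.
METRIC_COLUMNS = ["loops", "distinct_events", "duration_minutes", "avg_event_seconds"]


@dataclass(frozen=True)
class ActiveSegment:
    """A maximal run of one provider's uninterrupted work on one encounter."""

    provider_id: object
    csn: object
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def seconds(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class ProviderEncounter:
    """Merged event sequence and active segments for one (provider, CSN) pair.

    ``merged_events`` is an ordered list of ``(event_type, active_seconds)``
    tuples with no two consecutive entries sharing an event type.
    """

    provider_id: object
    csn: object
    merged_events: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    event_timestamps: list = field(default_factory=list)

    @property
    def total_active_seconds(self) -> float:
        return float(sum(s.seconds for s in self.segments))


@dataclass(frozen=True)
class CognitiveLoad:
    """The four encounter-level cognitive-load metrics."""

    loops: int
    distinct_events: int
    duration_minutes: float
    avg_event_seconds: float


def _as_event_frame(events) -> pd.DataFrame:
    """Normalise list-of-tuples or DataFrame input to an event frame."""
    if isinstance(events, pd.DataFrame):
        return events
    rows = []
    for item in events:
        etype, secs = item[0], float(item[1])
        rows.append({"event_type": etype, "active_seconds": secs})
    return pd.DataFrame(rows, columns=["event_type", "active_seconds"])


def merge_consecutive(events):
    """Collapse maximal runs of equal consecutive event types.

    Each run becomes a single event whose active time is the run's sum;
    order is otherwise preserved and the operation is idempotent.

    Parameters
    ----------
    events
        Either a list of ``(event_type, active_seconds)`` tuples or a
        DataFrame with columns ``event_type`` and ``active_seconds``
        (optionally ``timestamp``, which must be non-decreasing).

    Returns
    -------
    Same container kind as the input, merged.
    """
    as_frame = isinstance(events, pd.DataFrame)
    frame = _as_event_frame(events)
    if "timestamp" in frame.columns and len(frame) > 1:
        ts = pd.to_datetime(frame["timestamp"])
        if (ts.diff().dropna() < pd.Timedelta(0)).any():
            raise OrderingError("events must be chronologically ordered")
    if frame.empty:
        return frame.copy() if as_frame else []
    types = frame["event_type"].to_numpy()
    secs = frame["active_seconds"].to_numpy(dtype=float)
    new_run = np.ones(len(types), dtype=bool)
    new_run[1:] = types[1:] != types[:-1]
    run_id = np.cumsum(new_run) - 1
    starts = np.flatnonzero(new_run)
    merged_secs = np.bincount(run_id, weights=secs)
    merged_types = types[starts]
    if as_frame:
        out = pd.DataFrame(
            {"event_type": merged_types, "active_seconds": merged_secs}
        )
        if "timestamp" in frame.columns:
            out["timestamp"] = frame["timestamp"].to_numpy()[starts]
        return out
    return list(zip(merged_types.tolist(), merged_secs.tolist()))


def count_loops(merged_events) -> int:
    """Number of revisits: positions whose event type occurred earlier.

    On a merged sequence this equals ``len(sequence) - len(set(types))``;
    every revisit occurrence counts, e.g. A,B,C,A,B,D has two loops.
    """
    types = _merged_types(merged_events)
    return len(types) - len(set(types))


def count_distinct(merged_events) -> int:
    """Number of unique event types visited."""
    return len(set(_merged_types(merged_events)))


def _merged_types(merged_events):
    if isinstance(merged_events, pd.DataFrame):
        return merged_events["event_type"].tolist()
    return [e[0] for e in merged_events]


def segment_and_time(
    provider_events: pd.DataFrame,
    timeout: float = DEFAULT_TIMEOUT,
    assume_sorted: bool = False,
) -> dict:
    """Sessionize one provider's event stream into per-CSN encounters.

    Parameters
    ----------
    provider_events
        All audit-log rows for a single provider (any number of CSNs),
        with columns ``csn``, ``event_type``, ``timestamp``.
    timeout
        Inactivity timeout in seconds (default 600 = 10 minutes).
    assume_sorted
        If True, trust the input ordering; rows that step backwards in
        time are then dropped with a warning (clock skew).  Otherwise a
        stable sort by timestamp is applied first.

    Returns
    -------
    dict mapping csn -> :class:`ProviderEncounter`.
    """
    df = provider_events
    if df.empty:
        return {}
    provider_id = df["provider_id"].iloc[0] if "provider_id" in df.columns else None
    ts = pd.to_datetime(df["timestamp"])
    n_bad = int(ts.isna().sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} events with missing timestamps")
        keep = ~ts.isna()
        df, ts = df.loc[keep], ts.loc[keep]
    if assume_sorted:
        t = ts.to_numpy("datetime64[ns]").astype("int64") / 1e9
        bad = np.zeros(len(t), dtype=bool)
        last = -np.inf
        for i, v in enumerate(t):
            if v < last:
                bad[i] = True
            else:
                last = v
        if bad.any():
            warnings.warn(f"dropped {int(bad.sum())} out-of-order events (clock skew)")
            df, ts = df.loc[~bad], ts.loc[~bad]
    else:
        order = np.argsort(ts.to_numpy("datetime64[ns]"), kind="stable")
        df, ts = df.iloc[order], ts.iloc[order]
    if df.empty:
        return {}

    t = ts.to_numpy("datetime64[ns]").astype("int64") / 1e9
    csn = df["csn"].to_numpy()
    etype = df["event_type"].to_numpy()
    n = len(df)

    gap = np.empty(n)
    gap[:-1] = t[1:] - t[:-1]
    gap[-1] = np.inf
    active = np.minimum(gap, timeout)

    # A segment break occurs when the previous event belongs to a different
    # CSN or the gap from it exceeds the timeout.
    brk = np.ones(n, dtype=bool)
    brk[1:] = (csn[1:] != csn[:-1]) | (gap[:-1] > timeout)
    seg_id = np.cumsum(brk) - 1

    encounters: dict = {}
    for c in pd.unique(csn):
        idx = np.flatnonzero(csn == c)
        pe = ProviderEncounter(provider_id=provider_id, csn=c)
        # Active segments.
        for s in pd.unique(seg_id[idx]):
            sidx = idx[seg_id[idx] == s]
            start = pd.Timestamp(ts.iloc[sidx[0]])
            end = pd.Timestamp(ts.iloc[sidx[-1]]) + pd.Timedelta(
                seconds=float(active[sidx[-1]])
            )
            pe.segments.append(ActiveSegment(provider_id, c, start, end))
        # Merged events over the CSN's full chronological stream.
        stream = pd.DataFrame(
            {
                "event_type": etype[idx],
                "active_seconds": active[idx],
                "timestamp": ts.iloc[idx].to_numpy(),
            }
        )
        merged = merge_consecutive(stream)
        pe.merged_events = list(
            zip(merged["event_type"].tolist(), merged["active_seconds"].tolist())
        )
        pe.event_timestamps = list(merged["timestamp"])
        encounters[c] = pe
    return encounters


def compute_cognitive_load(pe: ProviderEncounter) -> CognitiveLoad:
    """Derive the four metrics from a sessionized provider-encounter."""
    n = len(pe.merged_events)
    if n == 0:
        raise UndefinedMetricError(
            f"provider {pe.provider_id!r} encounter {pe.csn!r} has no merged events"
        )
    total = pe.total_active_seconds
    distinct = count_distinct(pe.merged_events)
    return CognitiveLoad(
        loops=n - distinct,
        distinct_events=distinct,
        duration_minutes=total / 60.0,
        avg_event_seconds=total / n,
    )


def process_audit_log(
    audit_log: pd.DataFrame, timeout: float = DEFAULT_TIMEOUT
) -> pd.DataFrame:
    """Compute cognitive-load metrics for every (provider, CSN) pair.

    Parameters
    ----------
    audit_log
        Raw audit-log table with columns ``provider_id``, ``csn``,
        ``event_type``, ``timestamp``.
    timeout
        Inactivity timeout in seconds.

    Returns
    -------
    DataFrame with one row per provider-encounter pair: the four metrics
    plus ``total_active_seconds``, ``n_merged_events``, ``n_segments``,
    ``first_event_time`` and ``last_segment_end``.
    """
    missing = [c for c in AUDIT_COLUMNS if c not in audit_log.columns]
    if missing:
        raise KeyError(f"audit log is missing columns {missing}")
    rows = []
    for pid, group in audit_log.groupby("provider_id", sort=False):
        for c, pe in segment_and_time(group, timeout=timeout).items():
            load = compute_cognitive_load(pe)
            rows.append(
                {
                    "provider_id": pid,
                    "csn": c,
                    "loops": load.loops,
                    "distinct_events": load.distinct_events,
                    "duration_minutes": load.duration_minutes,
                    "avg_event_seconds": load.avg_event_seconds,
                    "total_active_seconds": pe.total_active_seconds,
                    "n_merged_events": len(pe.merged_events),
                    "n_segments": len(pe.segments),
                    "first_event_time": pe.segments[0].start,
                    "last_segment_end": pe.segments[-1].end,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "provider_id",
            "csn",
            *METRIC_COLUMNS,
            "total_active_seconds",
            "n_merged_events",
            "n_segments",
            "first_event_time",
            "last_segment_end",
        ],
    )


def pooled_encounter_streams(
    audit_log: pd.DataFrame, timeout: float = DEFAULT_TIMEOUT
) -> pd.DataFrame:
    """Pool every provider's merged events at the encounter level.

    The machine-learning stage works on one row per encounter rather than
    per provider-encounter pair, so all providers' merged events for a CSN
    are pooled into a single chronologically ordered stream.

    Returns
    -------
    DataFrame with columns ``csn``, ``provider_id``, ``event_type``,
    ``active_seconds``, ``timestamp``, sorted by (csn, timestamp).
    """
    rows = []
    for pid, group in audit_log.groupby("provider_id", sort=False):
        for c, pe in segment_and_time(group, timeout=timeout).items():
            for (etype, secs), ts in zip(pe.merged_events, pe.event_timestamps):
                rows.append(
                    {
                        "csn": c,
                        "provider_id": pid,
                        "event_type": etype,
                        "active_seconds": secs,
                        "timestamp": ts,
                    }
                )
    pooled = pd.DataFrame(
        rows, columns=["csn", "provider_id", "event_type", "active_seconds", "timestamp"]
    )
    if not pooled.empty:
        pooled = pooled.sort_values(["csn", "timestamp"], kind="stable").reset_index(
            drop=True
        )
    return pooled
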