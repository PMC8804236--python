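"""Head acceleration event (HAE) pruning and exposure counting.

Raw telemetry (HITS and xPatch sensors, pooled without cross-calibration)
is pruned to events whose timestamp falls inside a declared practice/game
activity window AND whose peak translational acceleration (PTA) is at
least 20 G.  Exposure is then summarized as cumulative counts

    nHAE(Th, j, k) = sum_p  u(PTA_p - Th)

over the pruned events of athlete *j* occurring before the cutoff time of
follow-up session *k* (In1, In2, Post1), for every threshold Th on a
5 G grid from 20 to 95 G.  ``u`` is the Heaviside step with u(0) = 1, so
an event exactly at the threshold counts.  Athletes with incomplete
telemetry are excluded from exposure analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: PTA threshold grid, in G.
DEFAULT_THRESHOLDS: tuple[int, ...] = tuple(range(20, 100, 5))

#: Pruning floor: events below this PTA are discarded.
MIN_PTA_G = 20.0

#: Follow-up sessions over which exposure accrues.
EXPOSURE_SESSIONS = ("In1", "In2", "Post1")

EVENT_COLUMNS = ("athlete_id", "timestamp", "pta_g", "window_id", "sensor")
WINDOW_COLUMNS = ("window_id", "start", "end")


@dataclass(frozen=True)
class PruningLog:
    """Bookkeeping for the pruning pass; the three removal/retention
    counts partition the raw events."""

    n_raw: int
    n_out_of_window: int
    n_below_threshold: int
    n_retained: int


def _parse_times(s: pd.Series) -> pd.Series:
    out = pd.to_datetime(s, errors="coerce")
    return out


def prune_events(
    events: pd.DataFrame,
    windows: pd.DataFrame,
) -> tuple[pd.DataFrame, PruningLog]:
    """Keep events inside a declared activity window with PTA >= 20 G.

    ``windows`` has columns window_id, start, end (optionally athlete_id
    for per-athlete schedules) and must be non-overlapping within its
    scope.  Window membership is decided from the event timestamp, not
    the recorded window_id; the retained frame's ``window_id`` is the
    matched window.  An event with a missing timestamp is an error.
    """
    ev = events.copy()
    for col in ("athlete_id", "timestamp", "pta_g"):
        if col not in ev.columns:
            raise ValueError(f"event table missing column {col!r}")
    ev["timestamp"] = _parse_times(ev["timestamp"])
    if ev["timestamp"].isna().any():
        bad = events.loc[ev["timestamp"].isna()].iloc[0]
        raise ValueError(f"event with missing/unparseable timestamp for athlete {bad['athlete_id']}")

    win = windows.copy()
    for col in WINDOW_COLUMNS:
        if col not in win.columns:
            raise ValueError(f"window table missing column {col!r}")
    win["start"] = _parse_times(win["start"])
    win["end"] = _parse_times(win["end"])
    if (win["end"] <= win["start"]).any():
        raise ValueError("activity window with end <= start")

    per_athlete = "athlete_id" in win.columns

    def match(sub_ev: pd.DataFrame, sub_win: pd.DataFrame) -> pd.Series:
        sw = sub_win.sort_values("start")
        starts = sw["start"].to_numpy()
        ends = sw["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("overlapping activity windows")
        t = sub_ev["timestamp"].to_numpy()
        idx = np.searchsorted(starts, t, side="right") - 1
        inside = (idx >= 0) & (t <= ends[np.clip(idx, 0, len(ends) - 1)])
        matched = pd.Series(pd.NA, index=sub_ev.index, dtype="object")
        matched[inside] = sw["window_id"].to_numpy()[idx[inside]]
        return matched

    if per_athlete:
        matched = pd.Series(pd.NA, index=ev.index, dtype="object")
        for athlete, sub in ev.groupby("athlete_id"):
            sub_win = win[win["athlete_id"] == athlete]
            if not sub_win.empty:
                matched.loc[sub.index] = match(sub, sub_win)
    else:
        matched = match(ev, win)

    in_window = matched.notna()
    above = ev["pta_g"].to_numpy() >= MIN_PTA_G
    keep = in_window.to_numpy() & above
    log = PruningLog(
        n_raw=len(ev),
        n_out_of_window=int((~in_window).sum()),
        n_below_threshold=int((in_window.to_numpy() & ~above).sum()),
        n_retained=int(keep.sum()),
    )
    out = ev.loc[keep].copy()
    out["window_id"] = matched[keep].to_numpy()
    return out.reset_index(drop=True), log


@dataclass
class ExposureMatrix:
    """Cumulative HAE counts per (athlete, follow-up session, threshold).

    ``counts`` is long-format with columns athlete_id, session,
    threshold_g, nhae.  ``complete`` flags telemetry completeness per
    athlete; incomplete athletes are dropped by
    :func:`exclude_incomplete` before any exposure analysis.
    """

    counts: pd.DataFrame
    thresholds: tuple[int, ...]
    sessions: tuple[str, ...]
    complete: dict[str, bool] = field(default_factory=dict)

    @property
    def athletes(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.counts["athlete_id"]))

    @property
    def n_athletes(self) -> int:
        return len(self.athletes)

    def wide(self, session: str, threshold: float) -> pd.Series:
        """nHAE per athlete at one (session, threshold), indexed by athlete."""
        sub = self.counts[
            (self.counts["session"] == session)
            & (self.counts["threshold_g"] == threshold)
        ]
        return sub.set_index("athlete_id")["nhae"]


def count_nhae(
    events: pd.DataFrame,
    session_cutoffs: Mapping[str, object],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    athletes: Iterable[str] | None = None,
    complete: Mapping[str, bool] | None = None,
) -> ExposureMatrix:
    """Build the exposure matrix from pruned events.

    ``session_cutoffs`` maps each follow-up session to its scan/cutoff
    time; events strictly before the cutoff accrue to the session.  The
    mapping's insertion order is the session order and the cutoff times
    must strictly increase along it.  ``athletes`` may list ids with no
    events (they get zero counts).
    """
    sessions = tuple(session_cutoffs.keys())
    cuts = pd.to_datetime(pd.Series([session_cutoffs[s] for s in sessions]))
    if not cuts.is_monotonic_increasing or cuts.duplicated().any():
        raise ValueError(f"session cutoffs must be strictly increasing in order {sessions}")

    ev = events.copy()
    ev["timestamp"] = _parse_times(ev["timestamp"])
    ids = list(pd.unique(ev["athlete_id"]))
    if athletes is not None:
        ids = list(dict.fromkeys(list(athletes) + ids))
    thresholds = tuple(thresholds)

    ev = ev.sort_values("timestamp")
    by_athlete = {
        a: (sub["timestamp"].to_numpy(), sub["pta_g"].to_numpy())
        for a, sub in ev.groupby("athlete_id")
    }

    records = []
    th_arr = np.asarray(thresholds, dtype=float)
    cut_arr = cuts.to_numpy()
    for a in ids:
        times, pta = by_athlete.get(a, (None, None))
        for s, cut in zip(sessions, cut_arr):
            if times is None:
                counts = np.zeros(len(th_arr), dtype=int)
            else:
                m = int(np.searchsorted(times, cut, side="left"))
                head = np.sort(pta[:m])
                # count of events with PTA >= Th (u(0) = 1)
                counts = m - np.searchsorted(head, th_arr, side="left")
            for th, c in zip(thresholds, counts):
                records.append((a, s, th, int(c)))
    counts_df = pd.DataFrame(records, columns=["athlete_id", "session", "threshold_g", "nhae"])
    comp = {a: True for a in ids}
    if complete:
        comp.update({a: bool(v) for a, v in complete.items() if a in comp})
    return ExposureMatrix(counts=counts_df, thresholds=thresholds, sessions=sessions, complete=comp)


def exclude_incomplete(
    matrix: ExposureMatrix, flags: Iterable[str] | None = None
) -> tuple[ExposureMatrix, list[str]]:
    """Drop athletes with incomplete telemetry from the exposure matrix.

    ``flags`` names the athletes to exclude; by default the matrix's own
    completeness flags are used.  Returns the reduced matrix and the list
    of excluded ids.  Flagging an unknown athlete is an error.
    """
    present = set(matrix.athletes)
    if flags is None:
        excluded = sorted(a for a, ok in matrix.complete.items() if not ok and a in present)
    else:
        excluded = sorted(set(flags))
        unknown = [a for a in excluded if a not in present]
        if unknown:
            raise ValueError(f"cannot exclude unknown athletes: {unknown}")
    keep = matrix.counts[~matrix.counts["athlete_id"].isin(excluded)].reset_index(drop=True)
    if keep.empty and excluded:
        warnings.warn("all athletes excluded from exposure matrix")
    complete = {a: v for a, v in matrix.complete.items() if a not in excluded}
    reduced = ExposureMatrix(
        counts=keep,
        thresholds=matrix.thresholds,
        sessions=matrix.sessions,
        complete=complete,
    )
    return reduced, excluded


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("athlete_id", "timestamp", "pta_g") if c not in df.columns]
    if missing:
        raise ValueError(f"event CSV missing columns: {missing}")
    return df


def write_exposure(matrix: ExposureMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, index=False)
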