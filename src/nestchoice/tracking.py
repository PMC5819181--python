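"""Home areas and dyadic associations from the antenna event log.

A female's *home area* is the set of nest boxes she entered for a cumulated
300 s or more during the 30 days before she gave birth; boxes entered for
less than 300 s in that window are not considered regularly entered.  A
*meeting* between two females is a maximal time interval during which both
are simultaneously inside the same nest box; *association time* is the total
duration of those meetings within the focal's 30-day window.

All timestamps are integer seconds; windows are half-open ``[t0, t1)`` so
the birth instant itself never contributes pre-birth association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DAY

#: cumulated in-window stay (seconds) below which a box is not "regular"
REGULAR_USE_THRESHOLD_S = 300


@dataclass
class HomeArea:
    female: int
    window: tuple[int, int]                 # [t0, t1)
    regular_boxes: frozenset[int]
    box_seconds: dict[int, int]             # all visited boxes, clipped
    box_visits: dict[int, int]

    @property
    def n_regular(self) -> int:
        return len(self.regular_boxes)


@dataclass
class DyadAssociation:
    pair: frozenset[int]
    n_meetings: int
    seconds: int
    per_box: dict[int, int] = field(default_factory=dict)


class EventIndex:
    """Per-individual sorted stay arrays for fast window queries."""

    def __init__(self, events: pd.DataFrame):
        self._stays: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        ev = events.sort_values("entry_s")
        for tag, grp in ev.groupby("tag"):
            self._stays[int(tag)] = (
                grp["box"].to_numpy(dtype=np.int64),
                grp["entry_s"].to_numpy(dtype=np.int64),
                grp["exit_s"].to_numpy(dtype=np.int64),
            )

    def stays(self, tag: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._stays.get(int(tag), (empty, empty, empty))

    @property
    def tags(self) -> list[int]:
        return list(self._stays)


def _as_index(events) -> EventIndex:
    return events if isinstance(events, EventIndex) else EventIndex(events)


def _clipped_arrays(idx: EventIndex, female: int, window: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t0, t1 = window
    box, ent, ext = idx.stays(female)
    keep = (ext > t0) & (ent < t1)
    return (box[keep], np.clip(ent[keep], t0, t1),
            np.clip(ext[keep], t0, t1))


def stays_in_window(events, female: int,
                    window: tuple[int, int]) -> pd.DataFrame:
    """Stays of ``female`` clipped to ``[t0, t1)``.

    A stay partially overlapping the window contributes only its in-window
    part.  Unknown females yield an empty result with a warning.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"malformed window {window}")
    idx = _as_index(events)
    if int(female) not in idx.tags:
        warnings.warn(f"female {female} has no events", stacklevel=2)
    box, ent, ext = _clipped_arrays(idx, female, window)
    return pd.DataFrame({"box": box, "entry_s": ent, "exit_s": ext})


def home_area(events, female: int, birth_ts: int,
              window_days: int = 30,
              min_seconds: int = REGULAR_USE_THRESHOLD_S) -> HomeArea:
    """Regular nest boxes in the ``window_days`` before ``birth_ts``."""
    window = (int(birth_ts) - window_days * DAY, int(birth_ts))
    st = stays_in_window(events, female, window)
    dur = st["exit_s"] - st["entry_s"]
    seconds = dur.groupby(st["box"]).sum()
    visits = st.groupby("box").size()
    regular = frozenset(int(b) for b, s in seconds.items() if s >= min_seconds)
    return HomeArea(female=int(female), window=window,
                    regular_boxes=regular,
                    box_seconds={int(b): int(s) for b, s in seconds.items()},
                    box_visits={int(b): int(v) for b, v in visits.items()})


def meetings(events, female_a: int, female_b: int,
             window: tuple[int, int]) -> DyadAssociation:
    """Maximal same-box co-presence intervals of a dyad within a window."""
    if int(female_a) == int(female_b):
        raise ValueError("self-association is undefined")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"malformed window {window}")
    idx = _as_index(events)
    segs = _overlap_segments(_clipped_arrays(idx, female_a, window),
                             _clipped_arrays(idx, female_b, window))
    merged = _merge_touching(segs)
    per_box: dict[int, int] = {}
    total = 0
    for box, s, e in merged:
        per_box[box] = per_box.get(box, 0) + (e - s)
        total += e - s
    return DyadAssociation(pair=frozenset((int(female_a), int(female_b))),
                           n_meetings=len(merged), seconds=int(total),
                           per_box=per_box)


def _overlap_segments(sa: tuple[np.ndarray, np.ndarray, np.ndarray],
                      sb: tuple[np.ndarray, np.ndarray, np.ndarray]
                      ) -> list[tuple[int, int, int]]:
    """Same-box overlap segments (box, start, end) of two sorted stay lists."""
    box_a, ent_a, ext_a = (arr.tolist() for arr in sa)
    box_b, ent_b, ext_b = (arr.tolist() for arr in sb)
    out: list[tuple[int, int, int]] = []
    i = j = 0
    na, nb = len(box_a), len(box_b)
    while i < na and j < nb:
        s = max(ent_a[i], ent_b[j])
        e = min(ext_a[i], ext_b[j])
        if s < e and box_a[i] == box_b[j]:
            out.append((box_a[i], s, e))
        # advance whichever stay ends first (ties: both are exhausted in turn)
        if ext_a[i] <= ext_b[j]:
            i += 1
        else:
            j += 1
    return out


def _merge_touching(segs: list[tuple[int, int, int]]
                    ) -> list[tuple[int, int, int]]:
    """Merge contiguous same-box segments into maximal meetings.

    Zero-length segments never arise (half-open overlap test), and a shared
    boundary instant in the same box means both mice were continuously
    co-present, so such segments merge.
    """
    merged: list[tuple[int, int, int]] = []
    for box, s, e in sorted(segs):
        if merged and merged[-1][0] == box and merged[-1][2] == s:
            merged[-1] = (box, merged[-1][1], e)
        else:
            merged.append((box, s, e))
    return merged


def association_matrix(events, focal_windows: dict[int, tuple[int, int]],
                       partners: dict[int, list[int]] | list[int] | None = None
                       ) -> pd.DataFrame:
    """Dyadic association of each focal with partner females.

    Each focal's association is computed over *her own* window (anchored to
    her birth date).  ``partners`` may be one list for every focal, a
    per-focal mapping, or ``None`` to use every tagged individual.  The
    output records the window used (provenance) alongside the symmetric
    meeting counts and association seconds.
    """
    idx = _as_index(events)
    rows = []
    for focal, window in focal_windows.items():
        if partners is None:
            others = [t for t in idx.tags if t != int(focal)]
        elif isinstance(partners, dict):
            others = [p for p in partners.get(focal, []) if p != focal]
        else:
            others = [p for p in partners if p != focal]
        for other in others:
            assoc = meetings(idx, focal, other, window)
            rows.append({
                "focal": int(focal), "other": int(other),
                "window_start_s": window[0], "window_end_s": window[1],
                "n_meetings": assoc.n_meetings,
                "association_s": assoc.seconds,
            })
    return pd.DataFrame(rows, columns=["focal", "other", "window_start_s",
                                       "window_end_s", "n_meetings",
                                       "association_s"])


def home_area_table(events, births: pd.DataFrame,
                    window_days: int = 30) -> pd.DataFrame:
    """One row per (mother, birth): regular-box count and total stay time."""
    idx = _as_index(events)
    rows = []
    for _, b in births.iterrows():
        ha = home_area(idx, int(b["mother"]), int(b["birth_day"]) * DAY,
                       window_days=window_days)
        rows.append({
            "mother": int(b["mother"]), "birth_day": int(b["birth_day"]),
            "n_regular_boxes": ha.n_regular,
            "regular_boxes": ";".join(map(str, sorted(ha.regular_boxes))),
            "total_stay_s": int(sum(ha.box_seconds.values())),
        })
    return pd.DataFrame(rows)
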