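"""Gap-tolerant nearest-neighbour linking and localization merging.

The same linking primitive serves two purposes: merging repeated
detections of one blinking fluorophore into a single localization
(small search radius, 1-2 dark frames allowed), and single-particle
tracking (larger radius).  Matching within each frame pair is resolved
globally greedily in ascending distance, which removes the input-order
dependence a per-localization loop would have; gap links are only
attempted for track heads that found no match at a smaller gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_io import UNASSIGNED, LocalizationTable

__all__ = ["LinkParams", "link_localizations", "merge_linked"]


@dataclass(frozen=True)
class LinkParams:
    """``max_jump_px``: maximum displacement between linked localizations;
    ``max_gap_frames``: allowed dark frames between them (0 means strictly
    consecutive frames)."""

    max_jump_px: float
    max_gap_frames: int = 0

    def __post_init__(self) -> None:
        if not self.max_jump_px > 0:
            raise ValueError("max_jump_px must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


def link_localizations(
    table: LocalizationTable, params: LinkParams, auto_sort: bool = False
) -> LocalizationTable:
    """Assign ``track_id`` by gap-tolerant nearest-neighbour linking.

    Frames are processed in order.  For a target frame t, heads ending at
    frame t-1 are matched first, then (for heads still unmatched) heads
    ending at t-2, ... down to t-1-max_gap.  Each frame-pair is matched
    greedily by ascending distance, ties broken by lower row index.  Every
    localization ends up in exactly one track; singletons get fresh ids;
    ids are consecutive integers from 0 in order of track start.
    """
    df = table.df
    if len(df) == 0:
        return table.copy()
    if not df["frame"].is_monotonic_increasing:
        if auto_sort:
            warnings.warn("input not sorted by frame; sorting", stacklevel=2)
            table = table.sorted_by_frame()
            df = table.df
        else:
            raise ValueError("localization table must be sorted by frame (or pass auto_sort=True)")

    frame = df["frame"].to_numpy()
    xy = df[["x", "y"]].to_numpy()
    n = len(df)
    track_of = np.full(n, UNASSIGNED, dtype=np.int64)
    head_row_of_track: dict[int, int] = {}  # track id -> row index of current head
    rows_by_frame: dict[int, np.ndarray] = {
        int(f): idx.to_numpy() for f, idx in df.groupby("frame").groups.items()
    }

    next_id = 0
    max_d2 = params.max_jump_px ** 2
    for t in sorted(rows_by_frame):
        targets = rows_by_frame[t]
        unclaimed = set(targets.tolist())
        for gap in range(0, params.max_gap_frames + 1):
            s = t - 1 - gap
            if s < 0 or not unclaimed:
                break
            if s not in rows_by_frame:
                continue
            heads = [r for r in rows_by_frame[s] if track_of[r] != UNASSIGNED
                     and head_row_of_track.get(track_of[r]) == r]
            if not heads:
                continue
            cand = np.array(sorted(unclaimed))
            if len(cand) == 0:
                continue
            heads_arr = np.array(heads)
            d2 = np.sum((xy[heads_arr][:, None, :] - xy[cand][None, :, :]) ** 2, axis=-1)
            hi, ci = np.nonzero(d2 <= max_d2)
            order = np.lexsort((cand[ci], heads_arr[hi], d2[hi, ci]))
            used_heads: set[int] = set()
            for k in order:
                hr = int(heads_arr[hi[k]])
                cr = int(cand[ci[k]])
                if hr in used_heads or cr not in unclaimed:
                    continue
                tid = int(track_of[hr])
                track_of[cr] = tid
                head_row_of_track[tid] = cr
                used_heads.add(hr)
                unclaimed.discard(cr)
        # remaining unclaimed rows start new tracks, in row order
        for r in sorted(unclaimed):
            track_of[r] = next_id
            head_row_of_track[next_id] = r
            next_id += 1

    out = table.copy()
    out.df["track_id"] = track_of
    return out


def merge_linked(
    table: LocalizationTable,
    exclude_ids: frozenset | set = frozenset(),
    max_jump_px: float | None = None,
) -> LocalizationTable:
    """Collapse each track to one localization.

    Merged position is the intensity-weighted mean, frame is the minimum
    frame, intensity the sum — so merging conserves total intensity and the
    merged position gains ~sqrt(n) precision.  Tracks in ``exclude_ids``
    (e.g. fiducial markers) pass through unchanged.
    """
    df = table.df
    if (df["track_id"] == UNASSIGNED).any():
        raise ValueError("all rows must have track_id assigned before merging")
    keep = df[df["track_id"].isin(exclude_ids)]
    todo = df[~df["track_id"].isin(exclude_ids)]

    rows = []
    for tid, g in todo.groupby("track_id", sort=True):
        w = g["intensity"].to_numpy()
        total = w.sum()
        if total <= 0:
            warnings.warn(f"track {tid} has zero total intensity; using unweighted mean", stacklevel=2)
            w = np.ones(len(g))
            total_w = len(g)
        else:
            total_w = total
        rows.append(
            {
                "frame": int(g["frame"].min()),
                "x": float((g["x"].to_numpy() * w).sum() / total_w),
                "y": float((g["y"].to_numpy() * w).sum() / total_w),
                "intensity": float(total),
                "track_id": int(tid),
                "channel": int(g["channel"].iloc[0]),
            }
        )
    merged = pd.DataFrame(rows, columns=["frame", "x", "y", "intensity", "track_id", "channel"])
    out_df = pd.concat([merged, keep], ignore_index=True).sort_values(
        ["frame", "track_id"], kind="stable"
    ).reset_index(drop=True)

    # High-density warning: many merges with large average steps suggest
    # different fluorophores were linked together.
    if max_jump_px is not None and len(todo):
        spans = todo.groupby("track_id")[["x", "y"]].agg(lambda s: s.max() - s.min())
        sizes = todo.groupby("track_id").size()
        multi = sizes > 1
        if multi.any():
            step = np.hypot(spans["x"][multi], spans["y"][multi]) / (sizes[multi] - 1)
            if (step > max_jump_px / 2).mean() > 0.05:
                warnings.warn(
                    "more than 5% of merged tracks average steps above max_jump_px/2; "
                    "possible high-density mis-linking",
                    stacklevel=2,
                )
    return replace(table, df=out_df)
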