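"""Gaze pipeline: from raw gaze samples to classified anticipation records.

The measure of interest is where gaze rests during inter-stimulus intervals
(ISIs), before the next target appears. The pipeline detects fixations with
a dispersion-threshold (I-DT) algorithm, assigns each fixation to the
nearest of the four diamond target regions, keeps the last fixated region
of each ISI (earlier fixations typically carry over from the previous
target), filters ISIs that lack a valid two-target prefix, and labels the
anticipated region both grammatically (ungrammatical = previous or
before-previous target's location) and semantically (Main / Interference /
Stuck / Alternative via the prefix table).

Coordinates are cm relative to screen center with y increasing upward;
pixel conversion from raw recordings lives in :mod:`osrt.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import PrefixTable, StimulusStream, diamond_layout

__all__ = [
    "detect_fixations",
    "assign_region",
    "extract_isi_anticipation",
    "classify_grammaticality",
    "classify_semantics",
    "filter_usable",
    "classify_isis",
]

FIXATION_COLUMNS = ["onset", "offset", "x", "y", "duration"]


def dispersion_threshold_cm(dispersion_deg: float, viewing_distance_cm: float) -> float:
    """On-screen extent (cm) subtended by a visual angle at a viewing distance."""
    return 2.0 * viewing_distance_cm * np.tan(np.deg2rad(dispersion_deg) / 2.0)


def detect_fixations(samples: pd.DataFrame,
                     dispersion_deg: float = 1.0,
                     min_duration_ms: float = 80.0,
                     viewing_distance_cm: float = 60.0) -> pd.DataFrame:
    """Dispersion-threshold (I-DT) fixation detection.

    A fixation is a maximal time window whose spatial dispersion
    ``(max x - min x) + (max y - min y)`` stays at or below the threshold
    (converted from degrees to cm at the viewing distance) and whose
    duration is at least ``min_duration_ms``. Windows are grown greedily
    from left to right, so fixations are non-overlapping and time-ordered.

    ``samples`` needs columns ``time_ms``, ``x``, ``y`` (cm, centered).
    Returns a frame with onset/offset times, centroid coordinates and
    duration; empty input yields an empty frame.
    """
    if len(samples) == 0:
        return pd.DataFrame(columns=FIXATION_COLUMNS)
    t = samples["time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample timestamps must be strictly increasing")
    # list buffers: tight loop over samples is much faster than ndarray indexing
    tl = t.tolist()
    xl = samples["x"].to_numpy(dtype=float).tolist()
    yl = samples["y"].to_numpy(dtype=float).tolist()
    thresh = dispersion_threshold_cm(dispersion_deg, viewing_distance_cm)

    n = len(tl)
    out: list[tuple[float, float, float, float, float]] = []
    i = 0
    while i < n:
        # grow the minimum-duration window
        j = i
        xmin = xmax = xl[i]
        ymin = ymax = yl[i]
        while j + 1 < n and tl[j + 1] - tl[i] < min_duration_ms:
            j += 1
            xv, yv = xl[j], yl[j]
            if xv < xmin: xmin = xv
            elif xv > xmax: xmax = xv
            if yv < ymin: ymin = yv
            elif yv > ymax: ymax = yv
        if j + 1 >= n and tl[j] - tl[i] < min_duration_ms:
            break
        if (xmax - xmin) + (ymax - ymin) > thresh:
            i += 1
            continue
        # extend while dispersion holds
        while j + 1 < n:
            xv, yv = xl[j + 1], yl[j + 1]
            nxmin = xv if xv < xmin else xmin
            nxmax = xv if xv > xmax else xmax
            nymin = yv if yv < ymin else ymin
            nymax = yv if yv > ymax else ymax
            if (nxmax - nxmin) + (nymax - nymin) > thresh:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        xs = xl[i:j + 1]
        ys = yl[i:j + 1]
        out.append((tl[i], tl[j], sum(xs) / len(xs), sum(ys) / len(ys), tl[j] - tl[i]))
        i = j + 1
    return pd.DataFrame(out, columns=FIXATION_COLUMNS)


def assign_region(x, y, layout: dict[int, tuple[float, float]] | None = None):
    """Assign points to the location whose center is nearest.

    For the centered diamond this reproduces the four triangular screen
    sectors around the targets. Exact ties resolve to the smallest location
    code (fixed priority 1 < 2 < 3 < 4). Accepts scalars or arrays.
    """
    if layout is None:
        layout = diamond_layout()
    codes = sorted(layout)
    cx = np.array([layout[c][0] for c in codes])
    cy = np.array([layout[c][1] for c in codes])
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d2 = (x[..., None] - cx) ** 2 + (y[..., None] - cy) ** 2
    idx = np.argmin(d2, axis=-1)  # argmin takes the first minimum: priority order
    result = np.asarray(codes)[idx]
    return result if result.ndim else int(result)


def extract_isi_anticipation(isi_fixations: pd.DataFrame,
                             layout: dict[int, tuple[float, float]] | None = None) -> int | None:
    """Anticipated region of one ISI: the last fixated region, or None.

    When several regions were fixated during an ISI the first fixation
    typically remains on the previous target (carryover), so only the last
    fixation — ordered by offset time — counts.
    """
    if len(isi_fixations) == 0:
        return None
    last = isi_fixations.loc[isi_fixations["offset"].idxmax()]
    return int(assign_region(last["x"], last["y"], layout))


def classify_grammaticality(region: int, prefix: tuple[int, int] | None) -> str:
    """Grammatical status of an anticipated region given the preceding pair.

    Ungrammatical iff the region is the previous or before-previous
    target's location; grammatical otherwise; undefined without a full
    prefix.
    """
    if prefix is None or prefix[0] is None or prefix[1] is None:
        return "undefined"
    return "ungrammatical" if region in tuple(prefix) else "grammatical"


def classify_semantics(region: int, prefix: tuple[int, int], table: PrefixTable) -> str:
    """Semantic label (main/interference/stuck/alternative) of a region."""
    prefix = (int(prefix[0]), int(prefix[1]))
    if prefix not in table:
        raise KeyError(f"prefix {prefix} not present in the semantics table")
    return table.label(prefix, int(region))


@dataclass(frozen=True)
class _ISIContext:
    trial: int            # 1-based index of the upcoming target
    block: int
    before_previous: int | None
    previous: int
    prefix_valid: bool    # full prefix present and within the task grammar


def _isi_contexts(stream: StimulusStream, table: PrefixTable) -> list[_ISIContext]:
    ctxs = []
    tgt = stream.targets
    blk = stream.block_index
    for t in range(1, len(tgt)):  # ISI precedes target t (0-based), anticipates tgt[t]
        prev = int(tgt[t - 1])
        bp = int(tgt[t - 2]) if t >= 2 else None
        valid = bp is not None and (bp, prev) in table
        ctxs.append(_ISIContext(trial=t + 1, block=int(blk[t]),
                                before_previous=bp, previous=prev,
                                prefix_valid=valid))
    return ctxs


def filter_usable(records: pd.DataFrame, stream: StimulusStream) -> pd.DataFrame:
    """Set usability flags on ISI anticipation records.

    An ISI is usable for four-way semantic labeling only when its two
    preceding targets form a prefix within the task grammar — which
    excludes the experiment's first ISI and block transitions that produce
    neighboring targets not appearing in the sequences — and a fixation was
    detected. ISIs with at least one preceding target stay eligible for
    Stuck-only labeling. Returns a copy with ``usable``, ``stuck_eligible``
    and ``exclusion_reason`` columns set.
    """
    records = records.copy()
    n_isi = len(stream.targets) - 1
    if len(records) != n_isi and not records["trial"].between(2, len(stream.targets)).all():
        raise ValueError("records are not aligned to the stimulus stream")
    no_fix = records["region"].isna()
    no_prefix = ~records["prefix_valid"].astype(bool)
    records["usable"] = ~(no_fix | no_prefix)
    records["stuck_eligible"] = ~no_fix  # one preceding target always exists
    reason = np.full(len(records), "", dtype=object)
    reason[no_prefix.to_numpy()] = "no-prefix"
    reason[no_fix.to_numpy()] = "no-fixation"
    records["exclusion_reason"] = reason
    return records


def classify_isis(gaze: pd.DataFrame, events: pd.DataFrame,
                  stream: StimulusStream, table: PrefixTable,
                  layout: dict[int, tuple[float, float]] | None = None,
                  dispersion_deg: float = 1.0, min_duration_ms: float = 80.0,
                  viewing_distance_cm: float = 60.0) -> pd.DataFrame:
    """Full pipeline: one classified anticipation record per ISI.

    ``gaze`` has columns (participant, time_ms, x, y) in centered cm;
    ``events`` has (participant, block, trial, target_loc, onset_ms,
    offset_ms). Fixations are detected per participant over the whole
    recording; each ISI window (previous target offset, next target onset]
    collects the fixations that overlap it (end after the window opens,
    begin before it closes), so a dwell that simply stays in place across
    the target's disappearance — the signature of Stuck anticipation —
    still counts as that ISI's fixation. Deterministic: identical inputs
    and settings yield identical record tables.
    """
    if layout is None:
        layout = diamond_layout()
    ctxs = _isi_contexts(stream, table)
    out_frames = []
    for pid, g in gaze.groupby("participant", sort=True):
        ev = events[events["participant"] == pid].sort_values("trial")
        fix = detect_fixations(g.sort_values("time_ms"), dispersion_deg,
                               min_duration_ms, viewing_distance_cm)
        fons = fix["onset"].to_numpy()
        foffs = fix["offset"].to_numpy()
        regions = (assign_region(fix["x"].to_numpy(), fix["y"].to_numpy(), layout)
                   if len(fix) else np.empty(0, dtype=int))
        onsets = ev["onset_ms"].to_numpy(dtype=float)
        offsets = ev["offset_ms"].to_numpy(dtype=float)
        n_trials = len(ev)
        rows = []
        for ctx in ctxs:
            t = ctx.trial - 1  # 0-based upcoming-target index
            if t >= n_trials:
                break
            lo, hi = offsets[t - 1], onsets[t]
            sel = (foffs > lo) & (fons <= hi)
            region: float | int = np.nan
            if sel.any():
                k = np.nonzero(sel)[0]
                region = int(regions[k[np.argmax(foffs[k])]])
            sem = gram = None
            if isinstance(region, int):
                prefix = ((ctx.before_previous, ctx.previous)
                          if ctx.before_previous is not None else None)
                gram = classify_grammaticality(region, prefix if ctx.prefix_valid else None)
                if ctx.prefix_valid:
                    sem = classify_semantics(region, prefix, table)
                elif region == ctx.previous:
                    sem = "stuck"   # stuck needs only one preceding target
                else:
                    sem = "unlabelable"
            rows.append({
                "participant": pid, "trial": ctx.trial, "block": ctx.block,
                "before_previous": ctx.before_previous, "previous": ctx.previous,
                "prefix_valid": ctx.prefix_valid, "region": region,
                "semantic": sem if sem is not None else "unlabelable",
                "grammatical": gram if gram is not None else "undefined",
                "target": int(stream.targets[t]),
                "correct": bool(isinstance(region, int)
                                and region == int(stream.targets[t])),
            })
        rec = pd.DataFrame(rows)
        out_frames.append(filter_usable(rec, stream))
    return pd.concat(out_frames, ignore_index=True) if out_frames else pd.DataFrame()
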