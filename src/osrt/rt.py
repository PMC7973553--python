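"""Reaction-time cleaning and summaries.

RT is the time from target onset to the correct keypress (arrow keys mapped
to the four locations). Trials with a wrong or absent response are removed.
Block-level RT is the mean of per-sequence (12-trial window) medians, and
RT can be re-grouped by the anticipation that preceded each trial, either
by semantic label or by anticipation correctness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CleanReport", "clean_rt", "block_rt_summary", "rt_by_anticipation",
           "trials_from_events"]

#: Default key-code -> location mapping: arrow keys coded by location number.
DEFAULT_KEY_MAP = {1: 1, 2: 2, 3: 3, 4: 4}

MAX_RT_MS = 3000.0  # target display cap


def trials_from_events(events: pd.DataFrame) -> pd.DataFrame:
    """Derive a TrialRT table from a trial-event table.

    RT is the keypress time minus target onset; trials without a keypress
    keep a missing key and RT.
    """
    t = events[["participant", "block", "trial", "target_loc", "key"]].copy()
    t["rt_ms"] = events["key_time_ms"] - events["onset_ms"]
    return t


@dataclass(frozen=True)
class CleanReport:
    n_total: int
    n_removed: int

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0


def clean_rt(trials: pd.DataFrame,
             key_map: dict | None = None) -> tuple[pd.DataFrame, CleanReport]:
    """Remove trials with an incorrect or absent keypress.

    ``trials`` needs columns (participant, block, trial, target_loc, key,
    rt_ms); ``key`` is missing/NaN when no key was pressed. Unmapped key
    codes raise ``ValueError`` listing the offenders.
    """
    if key_map is None:
        key_map = DEFAULT_KEY_MAP
    t = trials.copy()
    pressed = t["key"].notna()
    keys = t.loc[pressed, "key"]
    unmapped = sorted(set(keys) - set(key_map))
    if unmapped:
        raise ValueError(f"unmapped key codes: {unmapped}")
    correct = np.zeros(len(t), dtype=bool)
    idx = np.nonzero(pressed.to_numpy())[0]
    correct[idx] = (keys.map(key_map).to_numpy()
                    == t["target_loc"].to_numpy()[idx])
    cleaned = t[correct].copy()
    report = CleanReport(n_total=len(t), n_removed=int((~correct).sum()))
    return cleaned, report


def block_rt_summary(trials: pd.DataFrame, sequence_len: int = 12) -> pd.DataFrame:
    """Per participant x block: mean of per-sequence median RTs.

    Trials are windowed into consecutive ``sequence_len``-trial spans (one
    underlying sequence cycle each, and the same convention for RS streams);
    the window median is robust to slow outliers and the block value is the
    mean of its windows. Windows thinned by removed trials simply contribute
    the median of what remains; empty blocks yield missing values.
    """
    t = trials.copy()
    t["window"] = (t["trial"] - 1) // sequence_len
    med = (t.groupby(["participant", "block", "window"])["rt_ms"]
           .median().reset_index())
    out = (med.groupby(["participant", "block"])["rt_ms"]
           .mean().reset_index().rename(columns={"rt_ms": "rt_block_ms"}))
    return out


def rt_by_anticipation(trials: pd.DataFrame, records: pd.DataFrame,
                       grouping: str = "semantic",
                       interference_blocks: frozenset[int] = frozenset({7}),
                       aggregator: str = "median") -> pd.DataFrame:
    """RT summarized per participant x block x anticipation group.

    Joins each cleaned trial with the anticipation record of the ISI that
    preceded it (matching participant and trial). ``grouping="semantic"``
    keeps the four labels; ``grouping="correctness"`` maps labels per
    block: correct = Main outside the interference block(s) and
    Interference inside them; no-attempt = Stuck; incorrect = the remaining
    labeled attempts. Trials without a usable labeled ISI are excluded and
    counted in the ``n_unlabeled`` attribute of the result frame.
    """
    if grouping not in ("semantic", "correctness"):
        raise ValueError("grouping must be 'semantic' or 'correctness'")
    if aggregator not in ("median", "mean"):
        raise ValueError("aggregator must be 'median' or 'mean'")
    rec = records[records["usable"].astype(bool)][
        ["participant", "trial", "block", "semantic"]]
    merged = trials.merge(rec, on=["participant", "trial", "block"], how="left")
    n_unlabeled = int(merged["semantic"].isna().sum())
    merged = merged.dropna(subset=["semantic"])

    if grouping == "correctness":
        is_int = merged["block"].isin(interference_blocks)
        sem = merged["semantic"]
        group = np.select(
            [(sem == "main") & ~is_int, (sem == "interference") & is_int,
             sem == "stuck"],
            ["correct", "correct", "no-attempt"],
            default="incorrect",
        )
        merged["group"] = group
    else:
        merged["group"] = merged["semantic"]

    agg = getattr(merged.groupby(["participant", "block", "group"])["rt_ms"], aggregator)
    out = agg().reset_index().rename(columns={"rt_ms": "rt_ms_summary"})
    counts = (merged.groupby(["participant", "block", "group"])["rt_ms"]
              .size().reset_index(name="n_trials"))
    out = out.merge(counts, on=["participant", "block", "group"])
    out.attrs["n_unlabeled"] = n_unlabeled
    return out
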