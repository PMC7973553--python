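"""Synthetic O-SRT experiments from a latent multi-process learning model.

Each simulated participant carries three block-indexed learning curves that
factorize anticipation behavior the way the task dissociates it:

* ``p_attempt(b)`` — probability of making any anticipation attempt during
  an ISI (1 - p_attempt drives Stuck behavior: gaze stays on the previous
  target);
* ``p_grammar(b)`` — probability that an attempt respects the task grammar
  (avoids the previous and before-previous locations);
* ``p_sequence(b)`` — probability that a grammatical attempt targets the
  successor of the sequence governing the current block (vs. the other
  grammatical location).

From these the generator emits gaze samples (fixations at region centers
with Gaussian center scatter and uniform micro-jitter), trial events with a
keypress RT model, and a ground-truth table of every latent draw, so the
whole pipeline is testable without recorded data and parameter recovery can
be assessed. Task timing follows the experiment defaults: targets shown up
to 3000 ms or until keypress, 500 ms ISIs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import (SEQUENCE_A, SEQUENCE_B, PrefixTable, StimulusStream,
                   build_fs_stream, diamond_layout, semantic_table)
from .rsgen import generate_rs_stream

__all__ = ["SimulationParams", "simulate_participant", "simulate_cohort",
           "default_scenarios", "stream_for"]


@dataclass(frozen=True)
class SimulationParams:
    """Latent learning-curve and noise parameters for one participant.

    Curves are block-indexed probabilities (length = block count). Noise
    probabilities follow the observed data rates by default: 54.8% of ISIs
    fixate multiple regions, 91.6% of those start with a carryover fixation
    on the previous target region, 1.2% of ISIs have no fixation, 0.8% of
    trials get a wrong/absent response. RT parameters are in ms.
    """

    group: str = "FS"
    p_attempt: tuple[float, ...] = (0.60, 0.65, 0.70, 0.74, 0.77, 0.80, 0.80, 0.80)
    p_grammar: tuple[float, ...] = (0.60, 0.68, 0.74, 0.78, 0.82, 0.85, 0.85, 0.85)
    p_sequence: tuple[float, ...] = (0.52, 0.58, 0.63, 0.68, 0.72, 0.75, 0.62, 0.72)
    ungrammatical_stuck_ratio: float = 0.7   # previous vs before-previous location
    multi_region_prob: float = 0.548
    carryover_prob: float = 0.916
    no_fixation_prob: float = 0.012
    response_error_prob: float = 0.008
    rt_base_ms: float = 520.0
    rt_correct_advantage_ms: float = 80.0
    rt_incorrect_penalty_ms: float = 60.0
    rt_noise_sd_ms: float = 70.0
    rt_practice_decrement_ms: float = 12.0
    gaze_center_sd_cm: float = 0.3   # per-fixation Gaussian scatter of the centroid
    gaze_jitter_cm: float = 0.15     # per-sample uniform micro-jitter
    sample_rate_hz: float = 250.0
    isi_ms: float = 500.0
    max_target_ms: float = 3000.0

    def __post_init__(self) -> None:
        nb = len(self.p_attempt)
        if not (len(self.p_grammar) == len(self.p_sequence) == nb):
            raise ValueError("learning curves must share one length (the block count)")
        for name in ("p_attempt", "p_grammar", "p_sequence"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("ungrammatical_stuck_ratio", "multi_region_prob",
                     "carryover_prob", "no_fixation_prob", "response_error_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_blocks(self) -> int:
        return len(self.p_attempt)

    def noise_free(self) -> "SimulationParams":
        """Copy with every stochastic disturbance disabled (for round-trip
        identity checks); latent draws themselves stay stochastic."""
        return replace(self, no_fixation_prob=0.0, response_error_prob=0.0,
                       rt_noise_sd_ms=0.0, gaze_center_sd_cm=0.0)


def default_scenarios() -> dict[str, SimulationParams]:
    """Named presets spanning the qualitative behaviors of the task.

    ``fs-learner``: rising sequence knowledge and attempt rate over the six
    learning blocks, partial transfer to the interference block.
    ``rs-grammar-only``: grammar rises but sequence choice stays at chance
    (no governing sequence to learn).
    ``null``: all curves flat — no learning of any kind.
    """
    return {
        "fs-learner": SimulationParams(group="FS"),
        "rs-grammar-only": SimulationParams(
            group="RS",
            p_attempt=(0.62, 0.66, 0.69, 0.72, 0.74, 0.76),
            p_grammar=(0.60, 0.68, 0.74, 0.78, 0.82, 0.85),
            p_sequence=(0.5,) * 6,
        ),
        "null": SimulationParams(
            group="RS",
            p_attempt=(0.70,) * 6,
            p_grammar=(0.70,) * 6,
            p_sequence=(0.5,) * 6,
        ),
    }


def stream_for(params: SimulationParams, seed: int | None = None) -> StimulusStream:
    """The stimulus stream matching a parameter set's group and block count."""
    if params.group.upper() == "FS":
        if params.n_blocks != 8:
            raise ValueError("FS simulation requires 8-block learning curves")
        return build_fs_stream()
    return generate_rs_stream(n_blocks=params.n_blocks, seed=seed)


def _latent_draw(rng, params: SimulationParams, block: int, governing: str,
                 prefix: tuple[int, int] | None, previous: int,
                 table: PrefixTable) -> tuple[int, bool, str]:
    """One ISI's latent anticipation: (region, attempt, truth label)."""
    b = block - 1
    attempt = rng.random() < params.p_attempt[b]
    if not attempt:
        return previous, False, "stuck"
    if prefix is None or prefix not in table:
        # degenerate prefix (experiment onset / boundary repeat): any
        # non-repeat location; four-way truth label is undefined
        region = int(rng.choice([c for c in (1, 2, 3, 4) if c != previous]))
        return region, True, "unlabelable"
    sem = table[prefix]
    if rng.random() < params.p_grammar[b]:
        governed = sem.interference if governing == "interference" else sem.main
        other = sem.main if governing == "interference" else sem.interference
        region = governed if rng.random() < params.p_sequence[b] else other
    else:
        region = (sem.stuck if rng.random() < params.ungrammatical_stuck_ratio
                  else sem.alternative)
    return int(region), True, table.label(prefix, region)


def _fixation_samples(rng, params: SimulationParams, t0: float, t1: float,
                      center: tuple[float, float], noisy_center: bool,
                      out: list) -> None:
    dt = 1000.0 / params.sample_rate_hz
    n = int((t1 - t0) / dt)
    if n <= 0:
        return
    cx, cy = center
    if noisy_center and params.gaze_center_sd_cm > 0:
        cx += rng.normal(0, params.gaze_center_sd_cm)
        cy += rng.normal(0, params.gaze_center_sd_cm)
    times = t0 + dt * np.arange(n)
    j = params.gaze_jitter_cm
    xs = cx + rng.uniform(-j, j, n)
    ys = cy + rng.uniform(-j, j, n)
    out.append((times, xs, ys))


def simulate_participant(params: SimulationParams, stream: StimulusStream,
                         seed: int | None = None, participant: str = "p01",
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one participant: (gaze, events, ground-truth) tables.

    Gaze is in centered cm; events carry target onsets/offsets and
    keypresses; the truth table records every latent draw for the ISI
    preceding each trial (trial indices are 1-based; the first trial has no
    preceding ISI).
    """
    if len(stream.block_labels) != params.n_blocks:
        raise ValueError("stream block count does not match the learning curves")
    rng = np.random.default_rng(seed)
    table = semantic_table(SEQUENCE_A, SEQUENCE_B)
    layout = diamond_layout()
    targets = stream.targets
    blocks = stream.block_index
    n = len(targets)

    gaze_chunks: list = []
    events = []
    truth = []
    t_now = 0.0
    anticip_region: int | None = None   # region fixated last in the preceding ISI
    anticip_attempt = False

    for i in range(n):
        tgt = int(targets[i])
        blk = int(blocks[i])
        onset = t_now
        # --- response model
        correct_anticip = anticip_region == tgt
        rt = (params.rt_base_ms
              - params.rt_practice_decrement_ms * (blk - 1)
              + (-params.rt_correct_advantage_ms if correct_anticip
                 else params.rt_incorrect_penalty_ms if anticip_attempt else 0.0))
        if params.rt_noise_sd_ms > 0:
            rt += rng.normal(0, params.rt_noise_sd_ms)
        rt = float(np.clip(rt, 180.0, params.max_target_ms))
        if rng.random() < params.response_error_prob:
            if rng.random() < 0.5:
                key, key_time = int(rng.choice([c for c in (1, 2, 3, 4) if c != tgt])), onset + rt
                offset = onset + rt
            else:
                key, key_time = None, None
                offset = onset + params.max_target_ms
        else:
            key, key_time = tgt, onset + rt
            offset = onset + rt
        # fixation on the target during the trial
        _fixation_samples(rng, params, onset + 120.0, offset, layout[tgt],
                          noisy_center=True, out=gaze_chunks)
        events.append({"participant": participant, "block": blk, "trial": i + 1,
                       "target_loc": tgt, "onset_ms": onset, "offset_ms": offset,
                       "key": key, "key_time_ms": key_time})
        # --- ISI preceding trial i+1
        if i + 1 < n:
            next_onset = offset + params.isi_ms
            nxt_blk = int(blocks[i + 1])
            prev = tgt
            bp = int(targets[i - 1]) if i >= 1 else None
            prefix = (bp, prev) if bp is not None and bp != prev else None
            region, attempt, label = _latent_draw(
                rng, params, nxt_blk, stream.label_of_block(nxt_blk),
                prefix, prev, table)
            no_fix = rng.random() < params.no_fixation_prob
            if not no_fix:
                multi = (rng.random() < params.multi_region_prob
                         and region != prev)
                if multi:
                    first_region = (prev if rng.random() < params.carryover_prob
                                    else int(rng.choice([c for c in (1, 2, 3, 4)
                                                         if c not in (region,)])))
                    _fixation_samples(rng, params, offset + 40.0, offset + 230.0,
                                      layout[first_region], True, gaze_chunks)
                    _fixation_samples(rng, params, offset + 280.0, next_onset,
                                      layout[region], True, gaze_chunks)
                else:
                    _fixation_samples(rng, params, offset + 90.0, next_onset,
                                      layout[region], True, gaze_chunks)
            truth.append({"participant": participant, "trial": i + 2,
                          "block": nxt_blk, "attempt": attempt,
                          "label": "none" if no_fix else label,
                          "region": np.nan if no_fix else region,
                          "no_fixation": no_fix})
            anticip_region = None if no_fix else region
            anticip_attempt = attempt and not no_fix
            t_now = next_onset
        else:
            t_now = offset + params.isi_ms

    times = np.concatenate([c[0] for c in gaze_chunks])
    xs = np.concatenate([c[1] for c in gaze_chunks])
    ys = np.concatenate([c[2] for c in gaze_chunks])
    gaze = pd.DataFrame({"participant": participant, "time_ms": times,
                         "x": xs, "y": ys})
    return gaze, pd.DataFrame(events), pd.DataFrame(truth)


def _jitter_curve(curve, offset) -> tuple[float, ...]:
    return tuple(float(np.clip(c + offset, 0.02, 0.98)) for c in curve)


def simulate_cohort(n: int, params: SimulationParams | str = "fs-learner",
                    between_sd: float = 0.04, seed: int | None = None,
                    participant_prefix: str = "p", shared_stream: bool = True,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, StimulusStream]:
    """Simulate a cohort: (gaze, events, truth, stream).

    Participant heterogeneity adds one Gaussian offset per learning process
    per participant (SD ``between_sd`` on the probability scale), so
    cohorts contain attempt-driven as well as accuracy-driven learners.
    Independent participant seeds derive from the master seed. With
    ``shared_stream=False`` each RS participant gets a freshly generated
    stream (FS streams are fixed by the task).
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 participants")
    if between_sd < 0:
        raise ValueError("between_sd must be non-negative")
    if isinstance(params, str):
        params = default_scenarios()[params]
    master = np.random.SeedSequence(seed)
    stream_seed, *child_seqs = master.spawn(n + 1)
    stream = stream_for(params, seed=int(stream_seed.generate_state(1)[0] % 2**31))

    gaze_all, events_all, truth_all = [], [], []
    width = len(str(n))
    for idx, seq in enumerate(child_seqs, start=1):
        pid = f"{participant_prefix}{idx:0{width}d}"
        child_seed = int(seq.generate_state(1)[0] % 2**31)
        prng = np.random.default_rng(child_seed)
        p_i = replace(
            params,
            p_attempt=_jitter_curve(params.p_attempt, prng.normal(0, between_sd)),
            p_grammar=_jitter_curve(params.p_grammar, prng.normal(0, between_sd)),
            p_sequence=_jitter_curve(params.p_sequence, prng.normal(0, between_sd)),
        )
        stream_i = stream
        if not shared_stream and params.group.upper() != "FS":
            stream_i = stream_for(params, seed=child_seed + 1)
        g, e, t = simulate_participant(p_i, stream_i, seed=child_seed, participant=pid)
        gaze_all.append(g)
        events_all.append(e)
        truth_all.append(t)
    return (pd.concat(gaze_all, ignore_index=True),
            pd.concat(events_all, ignore_index=True),
            pd.concat(truth_all, ignore_index=True),
            stream)
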