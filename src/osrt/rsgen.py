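"""Pseudo-random (RS) stimulus streams that preserve the task grammar.

The RS condition replaces the fixed 12-element sequence with a constrained
pseudo-random target stream that keeps the statistical characteristics of
the fixed-sequence (FS) stream — no back-to-back repeats, near-uniform
location frequencies (~25% each), near-uniform permitted first-order
transitions (~33.3% each), reversal triplets x-y-x each near 1% of triplets
(~11.7% combined), remaining second-order continuations near-uniform
(~44.1% each) — while embedding no repeating sequence.

``stream_statistics`` audits any stream by exact counting;
``generate_rs_stream`` draws streams by deficit-weighted sequential
sampling with whole-stream rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .task import LOCATIONS, StimulusStream

__all__ = ["StreamStats", "StatTargets", "stream_statistics", "generate_rs_stream",
           "RSGenerationError"]

#: Conditional probability of a reversal continuation (x after x-y) that
#: reproduces the published RS reversal share of ~11.7% of triplets.
REVERSAL_SHARE_TARGET = 0.117

_PAIRS = [(a, b) for a, b in permutations(LOCATIONS, 2)]


@dataclass(frozen=True)
class StatTargets:
    """Audit acceptance rule for a generated stream.

    ``max_sd_*`` bound the empirical standard deviation within each
    statistic family, in percentage points; defaults are twice the
    published family SDs (0.3, 0.9, 0.1, 1.4). ``reversal_share`` and
    ``reversal_share_tol`` bound the combined reversal share (%).
    """

    max_sd_location: float = 0.6
    max_sd_transition: float = 1.8
    max_sd_reversal: float = 0.2
    max_sd_sot: float = 2.8
    reversal_share: float = 11.7
    reversal_share_tol: float = 1.5


@dataclass
class StreamStats:
    """Exact frequency audit of a target stream.

    Frequencies are percentages of the relevant denominators: locations of
    all targets, first-order transitions of transitions out of each
    location, reversal-triplet patterns of all consecutive triplets, and
    non-reversal second-order transitions of continuations of each ordered
    pair. ``periodic_period`` reports the smallest period p (searched up to
    ``max_period_check``) for which some window of length >= 3p is exactly
    p-periodic, or None.
    """

    location_pct: dict[int, float]
    transition_pct: dict[tuple[int, int], float]
    reversal_pct: dict[tuple[int, int], float]
    reversal_share: float
    sot_pct: dict[tuple[int, int, int], float]
    n_repeats: int
    n_targets: int
    periodic_period: int | None = None

    def family_summary(self) -> dict[str, tuple[float, float]]:
        """(mean, SD) per statistic family, in percent. SDs are population
        SDs across the family members, matching how the published M/SD
        summaries are stated."""
        fam = {
            "location": np.array(list(self.location_pct.values())),
            "transition": np.array(list(self.transition_pct.values())),
            "reversal": np.array(list(self.reversal_pct.values())),
            "sot": np.array(list(self.sot_pct.values())),
        }
        return {k: (float(v.mean()), float(v.std())) for k, v in fam.items()}


def _as_targets(stream) -> np.ndarray:
    if isinstance(stream, StimulusStream):
        return stream.targets
    return np.asarray(stream, dtype=np.int64)


def _periodicity_audit(t: np.ndarray, max_period: int) -> int | None:
    """Smallest p <= max_period with a run of >= 2p consecutive matches of
    t[i] == t[i-p] (equivalently: some window of length >= 3p is exactly
    p-periodic)."""
    n = len(t)
    for p in range(1, max_period + 1):
        if n < 3 * p:
            break
        eq = t[p:] == t[:-p]
        # longest run of True
        run = best = 0
        for v in eq:
            run = run + 1 if v else 0
            if run > best:
                best = run
                if best >= 2 * p:
                    break
        if best >= 2 * p:
            return p
    return None


def stream_statistics(stream, max_period_check: int = 24) -> StreamStats:
    """Audit a target stream by exact counting.

    Requires length >= 3 (at least one triplet).
    """
    t = _as_targets(stream)
    n = len(t)
    if n < 3:
        raise ValueError("stream must contain at least 3 targets")

    loc_counts = {loc: int(np.sum(t == loc)) for loc in LOCATIONS}
    location_pct = {loc: 100.0 * c / n for loc, c in loc_counts.items()}

    pair_counts = {p: 0 for p in _PAIRS}
    out_counts = {loc: 0 for loc in LOCATIONS}
    n_repeats = 0
    for a, b in zip(t[:-1], t[1:]):
        a, b = int(a), int(b)
        if a == b:
            n_repeats += 1
        else:
            pair_counts[(a, b)] += 1
        out_counts[a] += 1
    transition_pct = {
        p: (100.0 * c / out_counts[p[0]] if out_counts[p[0]] else 0.0)
        for p, c in pair_counts.items()
    }

    n_triplets = n - 2
    rev_counts = {p: 0 for p in _PAIRS}  # (x, y) stands for pattern x-y-x
    cont_counts: dict[tuple[int, int], int] = {p: 0 for p in _PAIRS}
    sot_counts: dict[tuple[int, int, int], int] = {
        (x, y, z): 0 for x, y in _PAIRS for z in LOCATIONS if z not in (x, y)
    }
    for x, y, z in zip(t[:-2], t[1:-1], t[2:]):
        x, y, z = int(x), int(y), int(z)
        if x == y or y == z:
            continue
        cont_counts[(x, y)] += 1
        if z == x:
            rev_counts[(x, y)] += 1
        else:
            sot_counts[(x, y, z)] += 1
    reversal_pct = {p: 100.0 * c / n_triplets for p, c in rev_counts.items()}
    reversal_share = float(sum(reversal_pct.values()))
    sot_pct = {
        trip: (100.0 * c / cont_counts[trip[:2]] if cont_counts[trip[:2]] else 0.0)
        for trip, c in sot_counts.items()
    }

    return StreamStats(
        location_pct=location_pct,
        transition_pct=transition_pct,
        reversal_pct=reversal_pct,
        reversal_share=reversal_share,
        sot_pct=sot_pct,
        n_repeats=n_repeats,
        n_targets=n,
        periodic_period=_periodicity_audit(t, max_period_check),
    )


class RSGenerationError(RuntimeError):
    """Raised when no stream satisfying the audit was found; carries the
    best-achieved statistics in ``best_stats``."""

    def __init__(self, msg: str, best_stats: StreamStats | None = None):
        super().__init__(msg)
        self.best_stats = best_stats


def _audit_ok(stats: StreamStats, targets: StatTargets) -> bool:
    fam = stats.family_summary()
    return (
        stats.n_repeats == 0
        and stats.periodic_period is None
        and fam["location"][1] <= targets.max_sd_location
        and fam["transition"][1] <= targets.max_sd_transition
        and fam["reversal"][1] <= targets.max_sd_reversal
        and fam["sot"][1] <= targets.max_sd_sot
        and abs(stats.reversal_share - targets.reversal_share) <= targets.reversal_share_tol
    )


def _draw_stream(n: int, rng: np.random.Generator, p_reversal: float,
                 gain: float, gain_soc: float = 30.0,
                 max_period_veto: int = 24) -> np.ndarray:
    """One sequential deficit-weighted draw of an n-target stream.

    Each next target is sampled from the three non-repeat candidates with
    base conditional probabilities (reversal ``p_reversal``, the two other
    continuations equal) multiplied by exponential corrections that shrink
    the running deficits of location, first-order-transition and
    second-order-continuation frequencies. Candidates that would extend an
    exactly-periodic window (period p <= ``max_period_veto``) to length 3p
    are vetoed so no repeating sequence inhabits the stream.
    """
    loc_target = 1.0 / 4
    trans_target = 1.0 / 3
    loc_counts = np.zeros(5)
    trans_counts = np.zeros((5, 5))
    out_counts = np.zeros(5)
    trip_counts = np.zeros((5, 5, 5))  # continuations z of ordered pair (x, y)
    cont_counts = np.zeros((5, 5))
    # run_len[p] = current count of consecutive positions i with s[i] == s[i-p]
    run_len = np.zeros(max_period_veto + 1, dtype=np.int64)

    stream = np.empty(n, dtype=np.int64)
    first = int(rng.integers(1, 5))
    stream[0] = first
    loc_counts[first] += 1
    second = int(rng.choice([c for c in LOCATIONS if c != first]))
    stream[1] = second
    loc_counts[second] += 1
    trans_counts[first, second] += 1
    out_counts[first] += 1
    run_len[1] = 0  # positions 0..1 differ by construction

    p_other = (1.0 - p_reversal) / 2
    for i in range(2, n):
        x, y = int(stream[i - 2]), int(stream[i - 1])
        cands = [c for c in LOCATIONS if c != y]
        max_p = min(max_period_veto, i)
        w = np.empty(3)
        vetoed = np.zeros(3, dtype=bool)
        for j, c in enumerate(cands):
            base = p_reversal if c == x else p_other
            loc_def = loc_target - loc_counts[c] / i
            trans_def = (trans_target - trans_counts[y, c] / out_counts[y]
                         if out_counts[y] > 0 else 0.0)
            cond_target = p_reversal if c == x else p_other
            soc_def = (cond_target - trip_counts[x, y, c] / cont_counts[x, y]
                       if cont_counts[x, y] > 0 else 0.0)
            w[j] = base * np.exp(gain * (loc_def + trans_def) + gain_soc * soc_def)
            for p in range(1, max_p + 1):
                if c == stream[i - p] and run_len[p] + 1 >= 2 * p:
                    vetoed[j] = True
                    break
        if not vetoed.all():
            w[vetoed] = 0.0
        w /= w.sum()
        c = cands[int(rng.choice(3, p=w))]
        stream[i] = c
        loc_counts[c] += 1
        trans_counts[y, c] += 1
        out_counts[y] += 1
        trip_counts[x, y, c] += 1
        cont_counts[x, y] += 1
        for p in range(1, max_p + 1):
            run_len[p] = run_len[p] + 1 if c == stream[i - p] else 0
    return stream


def generate_rs_stream(n_blocks: int = 6, block_len: int = 108,
                       seed: int | None = None,
                       targets: StatTargets | None = None,
                       max_period_check: int = 24,
                       max_retries: int = 50,
                       p_reversal: float = REVERSAL_SHARE_TARGET,
                       gain: float = 12.0, gain_soc: float = 30.0) -> StimulusStream:
    """Generate an RS stimulus stream matching the FS task's grammar.

    Draws streams by deficit-weighted sequential sampling and rejects any
    whole stream failing the audit (zero repeats, family SDs within
    ``targets``, combined reversal share near its goal, no embedded
    periodic window up to ``max_period_check``). Deterministic for a fixed
    seed; retries use incremented sub-seeds.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if targets is None:
        targets = StatTargets()
    n = n_blocks * block_len

    best: tuple[float, np.ndarray, StreamStats] | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(None if seed is None
                                    else (int(seed) + 10007 * attempt) % (2**31))
        t = _draw_stream(n, rng, p_reversal, gain, gain_soc, max_period_veto=max_period_check)
        stats = stream_statistics(t, max_period_check)
        if _audit_ok(stats, targets):
            block_index = np.repeat(np.arange(1, n_blocks + 1), block_len)
            return StimulusStream(targets=t, block_index=block_index,
                                  block_labels=("random",) * n_blocks)
        fam = stats.family_summary()
        score = sum(fam[k][1] / max(lim, 1e-9) for k, lim in (
            ("location", targets.max_sd_location),
            ("transition", targets.max_sd_transition),
            ("reversal", targets.max_sd_reversal),
            ("sot", targets.max_sd_sot)))
        if best is None or score < best[0]:
            best = (score, t, stats)
    raise RSGenerationError(
        f"no stream satisfied the audit after {max_retries} attempts",
        best_stats=None if best is None else best[2],
    )
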