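"""Second-order conditional (SOC) sequence structures for the O-SRT task.

The task presents targets at four screen locations arranged in a diamond
(1-down, 2-left, 3-right, 4-up). In the fixed-sequence (FS) condition the
target order follows a 12-element SOC sequence, read cyclically: every
location appears three times, no location repeats back-to-back, and every
ordered pair of distinct locations occurs exactly once per cycle, so the
upcoming target is fully determined by the two targets preceding it.

This module validates candidate SOC sequences, derives their pair-successor
maps, builds the 8-block FS stimulus stream, and enumerates the prefix
semantics table that assigns, for every ordered pair of preceding targets,
the four possible anticipation locations: the Main-sequence successor, the
Interference-sequence successor, the previous target's location ("Stuck"),
and the one remaining location ("Alternative").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LOCATIONS",
    "SEQUENCE_A",
    "SEQUENCE_B",
    "FS_START_OFFSETS",
    "diamond_layout",
    "SOCValidationReport",
    "validate_soc",
    "successor_map",
    "SemanticLocations",
    "PrefixTable",
    "semantic_table",
    "StimulusStream",
    "build_fs_stream",
    "EffectScores",
]

#: Location codes: 1-down, 2-left, 3-right, 4-up.
LOCATIONS: tuple[int, ...] = (1, 2, 3, 4)

#: The two SOC sequences used in the task.
SEQUENCE_A: tuple[int, ...] = (3, 4, 2, 3, 1, 2, 1, 4, 3, 2, 4, 1)
SEQUENCE_B: tuple[int, ...] = (3, 4, 1, 2, 4, 3, 1, 4, 2, 1, 3, 2)

#: 1-based within-sequence start position of each of the 8 FS blocks.
FS_START_OFFSETS: tuple[int, ...] = (1, 5, 10, 8, 4, 12, 1, 2)

SEQUENCE_LENGTH = 12
BLOCK_LENGTH = 108  # nine concatenated 12-element sequences per block


def diamond_layout(eccentricity_cm: float | None = None,
                   eccentricity_deg: float = 8.8,
                   viewing_distance_cm: float = 60.0) -> dict[int, tuple[float, float]]:
    """Centers of the four target locations, cm relative to screen center.

    The diamond places one location per cardinal direction at equal
    eccentricity (default 8.8 degrees of visual angle at 60 cm viewing
    distance). y increases upward.
    """
    if eccentricity_cm is None:
        eccentricity_cm = viewing_distance_cm * np.tan(np.deg2rad(eccentricity_deg))
    r = float(eccentricity_cm)
    return {1: (0.0, -r), 2: (-r, 0.0), 3: (r, 0.0), 4: (0.0, r)}


# ---------------------------------------------------------------------------
# SOC validation

@dataclass(frozen=True)
class SOCValidationReport:
    """Outcome of SOC-sequence validation.

    ``violations`` lists each broken rule; an empty list means the sequence
    is a valid second-order conditional sequence.
    """

    ok: bool
    violations: tuple[str, ...] = ()


def _check_alphabet(seq: Sequence[int]) -> tuple[int, ...]:
    seq = tuple(int(x) for x in seq)
    if len(seq) != SEQUENCE_LENGTH:
        raise ValueError(f"SOC sequence must have {SEQUENCE_LENGTH} elements, got {len(seq)}")
    bad = sorted({x for x in seq if x not in LOCATIONS})
    if bad:
        raise ValueError(f"location codes must be in {{1,2,3,4}}; found {bad}")
    return seq


def validate_soc(seq: Sequence[int]) -> SOCValidationReport:
    """Validate a candidate 12-element SOC sequence (read cyclically).

    Rules checked: each location appears exactly three times; no element
    equals its cyclic successor; each ordered pair of distinct locations
    appears exactly once as a cyclic bigram.

    Malformed input (wrong length, out-of-alphabet codes) raises
    ``ValueError``; rule violations are reported, not raised.
    """
    seq = _check_alphabet(seq)
    violations: list[str] = []

    counts = {loc: seq.count(loc) for loc in LOCATIONS}
    off = {loc: c for loc, c in counts.items() if c != 3}
    if off:
        violations.append(f"location frequency not counter-balanced (expect 3 each): {off}")

    repeats = [i for i in range(SEQUENCE_LENGTH) if seq[i] == seq[(i + 1) % SEQUENCE_LENGTH]]
    if repeats:
        violations.append(f"back-to-back repeats at cyclic positions {repeats}")

    bigrams = [(seq[i], seq[(i + 1) % SEQUENCE_LENGTH]) for i in range(SEQUENCE_LENGTH)]
    expected = {(a, b) for a in LOCATIONS for b in LOCATIONS if a != b}
    seen = set(bigrams)
    if len(bigrams) != len(seen) or seen != expected:
        missing = sorted(expected - seen)
        dupes = sorted({b for b in bigrams if bigrams.count(b) > 1})
        violations.append(
            "first-order transitions not counter-balanced: "
            f"missing pairs {missing}, duplicated pairs {dupes}"
        )

    return SOCValidationReport(ok=not violations, violations=tuple(violations))


def successor_map(seq: Sequence[int]) -> dict[tuple[int, int], int]:
    """Map each cyclic ordered pair of a SOC sequence to its unique successor.

    In a SOC sequence every bigram occurs once per cycle, so the map has
    exactly 12 entries and fully determines the next target from the two
    preceding ones.
    """
    seq = _check_alphabet(seq)
    out: dict[tuple[int, int], int] = {}
    for i in range(SEQUENCE_LENGTH):
        pair = (seq[i], seq[(i + 1) % SEQUENCE_LENGTH])
        nxt = seq[(i + 2) % SEQUENCE_LENGTH]
        if pair in out and out[pair] != nxt:
            raise ValueError(f"bigram {pair} has two successors ({out[pair]}, {nxt}); not SOC")
        out[pair] = nxt
    if len(out) != SEQUENCE_LENGTH:
        raise ValueError("sequence is not SOC: duplicated bigrams collapse the successor map")
    return out


# ---------------------------------------------------------------------------
# Prefix semantics

@dataclass(frozen=True)
class SemanticLocations:
    """The four anticipation locations available after one target-pair prefix."""

    main: int
    interference: int
    stuck: int
    alternative: int

    def as_dict(self) -> dict[str, int]:
        return {"main": self.main, "interference": self.interference,
                "stuck": self.stuck, "alternative": self.alternative}


@dataclass(frozen=True)
class PrefixTable:
    """Prefix -> semantic-location lookup for one Main/Interference assignment.

    Keys are ordered pairs ``(before_previous, previous)`` of distinct
    locations. For every prefix the four semantic locations are mutually
    distinct and jointly cover all four locations, so each fixated region
    receives exactly one label.
    """

    entries: Mapping[tuple[int, int], SemanticLocations]

    def __getitem__(self, prefix: tuple[int, int]) -> SemanticLocations:
        return self.entries[prefix]

    def __contains__(self, prefix: tuple[int, int]) -> bool:
        return tuple(prefix) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def label(self, prefix: tuple[int, int], region: int) -> str:
        """Semantic label of a fixated region given the preceding target pair."""
        sem = self.entries[tuple(prefix)]
        for name, loc in sem.as_dict().items():
            if loc == region:
                return name
        raise ValueError(f"region {region} is not a location code")

    def alternative_reversal_count(self) -> int:
        """Number of prefixes whose alternative location is the before-previous
        target, i.e. prefixes where the Alternative anticipation entails a
        gaze reversal. Computed by enumeration over the table."""
        return sum(1 for (bp, _), sem in self.entries.items() if sem.alternative == bp)


def semantic_table(main: Sequence[int] = SEQUENCE_A,
                   interference: Sequence[int] = SEQUENCE_B) -> PrefixTable:
    """Build the prefix semantics table from a Main/Interference sequence pair.

    For each of the 12 prefixes: the Main location is the Main sequence's
    successor, the Interference location the Interference sequence's
    successor, the Stuck location the previous target itself, and the
    Alternative location the one remaining.
    """
    for name, seq in (("main", main), ("interference", interference)):
        rep = validate_soc(seq)
        if not rep.ok:
            raise ValueError(f"{name} sequence is not SOC: {rep.violations}")
    smain = successor_map(main)
    sint = successor_map(interference)
    entries: dict[tuple[int, int], SemanticLocations] = {}
    for prefix, main_loc in smain.items():
        bp, prev = prefix
        int_loc = sint[prefix]
        taken = {main_loc, int_loc, prev}
        if len(taken) != 3:
            raise ValueError(
                f"prefix {prefix}: main ({main_loc}), interference ({int_loc}) and "
                f"stuck ({prev}) locations are not distinct; alternative undefined"
            )
        (alt,) = set(LOCATIONS) - taken
        entries[prefix] = SemanticLocations(main=main_loc, interference=int_loc,
                                            stuck=prev, alternative=alt)
    return PrefixTable(entries=entries)


# ---------------------------------------------------------------------------
# Stimulus stream

@dataclass
class StimulusStream:
    """Ordered target locations with block structure.

    ``targets`` holds location codes for the whole experiment; ``block_index``
    gives the 1-based block of each target; ``block_labels`` names the
    sequence governing each block (``main`` / ``interference`` / ``random``).
    ``boundary_flags`` marks targets whose transition from the preceding
    target crosses a block boundary; such transitions are not part of either
    sequence's grammar and downstream usability filtering consumes the flag.
    """

    targets: np.ndarray
    block_index: np.ndarray
    block_labels: tuple[str, ...]
    start_offsets: tuple[int, ...] | None = None
    boundary_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.int64)
        self.block_index = np.asarray(self.block_index, dtype=np.int64)
        if self.targets.shape != self.block_index.shape:
            raise ValueError("targets and block_index must have equal length")
        if self.boundary_flags is None:
            flags = np.zeros(len(self.targets), dtype=bool)
            flags[1:] = self.block_index[1:] != self.block_index[:-1]
            self.boundary_flags = flags

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def n_blocks(self) -> int:
        return len(self.block_labels)

    def block(self, b: int) -> np.ndarray:
        """Targets of 1-based block ``b``."""
        return self.targets[self.block_index == b]

    def label_of_block(self, b: int) -> str:
        return self.block_labels[b - 1]

    def repeat_count(self) -> int:
        """Number of back-to-back location repeats in the whole stream."""
        return int(np.sum(self.targets[1:] == self.targets[:-1]))


def build_fs_stream(main: Sequence[int] = SEQUENCE_A,
                    interference: Sequence[int] = SEQUENCE_B,
                    start_offsets: Iterable[int] = FS_START_OFFSETS) -> StimulusStream:
    """Construct the 8-block fixed-sequence stimulus stream.

    Blocks 1-6 and 8 are nine cyclic concatenations of the Main sequence,
    block 7 of the Interference sequence; each block takes 108 consecutive
    elements of the infinite cyclic repetition beginning at its 1-based
    start offset.
    """
    for name, seq in (("main", main), ("interference", interference)):
        rep = validate_soc(seq)
        if not rep.ok:
            raise ValueError(f"{name} sequence is not SOC: {rep.violations}")
    offsets = tuple(int(o) for o in start_offsets)
    if any(not 1 <= o <= SEQUENCE_LENGTH for o in offsets):
        raise ValueError(f"start offsets must be in 1..{SEQUENCE_LENGTH}, got {offsets}")
    main = tuple(main)
    interference = tuple(interference)

    targets: list[int] = []
    block_index: list[int] = []
    labels: list[str] = []
    n_blocks = len(offsets)
    for b, off in enumerate(offsets, start=1):
        seq = interference if (n_blocks == 8 and b == 7) else main
        labels.append("interference" if seq is interference else "main")
        for k in range(BLOCK_LENGTH):
            targets.append(seq[(off - 1 + k) % SEQUENCE_LENGTH])
            block_index.append(b)
    return StimulusStream(targets=np.array(targets), block_index=np.array(block_index),
                          block_labels=tuple(labels), start_offsets=offsets)


# ---------------------------------------------------------------------------
# Effect scores

@dataclass(frozen=True)
class EffectScores:
    """Block-contrast scores, all coded earlier-minus-later.

    learning = block 1 - block 6; interference = block 6 - block 7;
    recovery = block 7 - block 8. Units follow the underlying measure
    (% of ISIs or ms).
    """

    learning: float
    interference: float | None = None
    recovery: float | None = None
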