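"""Foreperiod-sequence paradigm: block designs, duration assignment, event timing.

The paradigm pairs two cued reaction-time trials into a "sequence": a warning
signal is followed, after a variable foreperiod (FP), by a target the subject
responds to.  The first and second foreperiods of a sequence (FP1, FP2) are
each drawn from a bimodal grid of durations between 0.4 and 2.0 s (0.1-s step,
1.2 s excluded).  Durations 0.4-1.1 s are "short" (S), 1.3-2.0 s "long" (L).
Four 50-sequence blocks vary the composition of the sequence types
LL/SS/LS/SL, which controls the conditional probability of FP2 given FP1
while keeping the unconditional short/long split at 50-50 everywhere.

All times are handled internally as integer centiseconds so that grid
membership and joins are exact; public frames expose seconds as floats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEQUENCE_TYPES = ("LL", "SS", "LS", "SL")

# Duration grid in centiseconds: 0.4..2.0 s step 0.1 s, 1.2 s excluded.
GRID_CS: tuple[int, ...] = tuple(c for c in range(40, 201, 10) if c != 120)
SHORT_CS: tuple[int, ...] = tuple(c for c in GRID_CS if c <= 110)
LONG_CS: tuple[int, ...] = tuple(c for c in GRID_CS if c >= 130)

#: Durations that receive exactly one trial per block and position category in
#: `actual` mode, keeping the foreperiod distribution nearly continuous.
PADDING_CS: tuple[int, ...] = (40, 50, 60, 100, 110, 130, 140, 190, 200)

#: The three durations around each mode of the bimodal design distribution;
#: in `actual` mode all non-padding trials land here.
DOMINANT_S_CS: tuple[int, ...] = (70, 80, 90)
DOMINANT_L_CS: tuple[int, ...] = (150, 160, 170)

# Smooth per-duration profile (`idealized` mode): discrete triangular counts
# over each 8-point category sub-grid, peaking at 0.8 s (S) and 1.6 s (L),
# 25 trials per category.
IDEALIZED_COUNTS: dict[str, dict[int, int]] = {
    "S": {40: 1, 50: 2, 60: 3, 70: 4, 80: 6, 90: 4, 100: 3, 110: 2},
    "L": {130: 2, 140: 3, 150: 4, 160: 6, 170: 4, 180: 3, 190: 2, 200: 1},
}

#: Sequence-type composition of the four blocks (50 sequences each).
BLOCK_COUNTS: dict[int, dict[str, int]] = {
    1: {"LL": 25, "SS": 25, "LS": 0, "SL": 0},
    2: {"LL": 0, "SS": 0, "LS": 25, "SL": 25},
    3: {"LL": 20, "SS": 20, "LS": 5, "SL": 5},
    4: {"LL": 5, "SS": 5, "LS": 20, "SL": 20},
}

WARNING_DURATION_CS = 10  # 0.1 s warning signal
TARGET_DURATION_CS = 10  # nominal target-signal duration used for scheduling
INTER_TRIAL_GAP_CS = 120  # 1.2 s between target offset (FP1) and warning (FP2)
#: Inter-sequence gap grid: 3.0-3.2 s in 0.05-s increments.
SEQUENCE_GAP_GRID_CS: tuple[int, ...] = tuple(range(300, 321, 5))

TRIAL_TABLE_COLUMNS = (
    "participant_id",
    "run",
    "block",
    "sequence",
    "position",
    "foreperiod_s",
    "fp1_context_s",
    "rt_s",
    "false_alarm",
)


def duration_category(duration_s: float) -> str:
    """Classify a foreperiod duration as short ('S') or long ('L')."""
    cs = int(round(float(duration_s) * 100))
    if cs in SHORT_CS:
        return "S"
    if cs in LONG_CS:
        return "L"
    raise ValueError(f"duration {duration_s} s is not on the foreperiod grid")


@dataclass(frozen=True)
class ForeperiodGrid:
    """The 16-duration foreperiod grid with its short/long partition."""

    durations_cs: tuple[int, ...] = GRID_CS

    @property
    def durations(self) -> np.ndarray:
        return np.asarray(self.durations_cs, dtype=float) / 100.0

    @property
    def short(self) -> np.ndarray:
        return np.asarray(SHORT_CS, dtype=float) / 100.0

    @property
    def long(self) -> np.ndarray:
        return np.asarray(LONG_CS, dtype=float) / 100.0


@dataclass(frozen=True)
class BlockDesign:
    block_id: int
    counts: Mapping[str, int]
    padding_durations: tuple[float, ...]

    @property
    def n_sequences(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SequenceTrial:
    """One two-foreperiod sequence; onsets in seconds from block start."""

    sequence_index: int
    fp1_cs: int
    fp2_cs: int
    warning1_onset: float | None = None
    target1_onset: float | None = None
    warning2_onset: float | None = None
    target2_onset: float | None = None
    inter_sequence_gap: float | None = None
    warning_duration: float = WARNING_DURATION_CS / 100.0
    target_duration: float = TARGET_DURATION_CS / 100.0

    @property
    def fp1(self) -> float:
        return self.fp1_cs / 100.0

    @property
    def fp2(self) -> float:
        return self.fp2_cs / 100.0

    @property
    def seq_type(self) -> str:
        return duration_category(self.fp1) + duration_category(self.fp2)


def build_block_design(block_id: int) -> BlockDesign:
    """Sequence-type composition and padding durations for one block."""
    if block_id not in BLOCK_COUNTS:
        raise ValueError(f"unknown block_id {block_id!r}; expected 1-4")
    padding = tuple(c / 100.0 for c in PADDING_CS)
    return BlockDesign(block_id, dict(BLOCK_COUNTS[block_id]), padding)


def _largest_remainder(weights: Sequence[int], total: int) -> list[int]:
    """Integer apportionment of `total` trials proportional to `weights`."""
    w = np.asarray(weights, dtype=float)
    quota = w / w.sum() * total
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def _category_multiset(category: str, n: int, mode: str, rng: np.random.Generator) -> list[int]:
    """Duration multiset (centiseconds) for `n` trials of one category."""
    grid = SHORT_CS if category == "S" else LONG_CS
    if mode == "idealized":
        profile = IDEALIZED_COUNTS[category]
        if n == 25:
            counts = [profile[d] for d in grid]
        else:
            counts = _largest_remainder([profile[d] for d in grid], n)
        out: list[int] = []
        for d, c in zip(grid, counts):
            out.extend([d] * c)
        return out
    if mode == "actual":
        padding = [d for d in PADDING_CS if d in grid]
        if n < len(padding):
            raise ValueError(
                f"{n} trials of category {category} cannot host the "
                f"{len(padding)} single-trial padding durations"
            )
        dominant = DOMINANT_S_CS if category == "S" else DOMINANT_L_CS
        remaining = n - len(padding)
        base, extra = divmod(remaining, len(dominant))
        counts = {d: base for d in dominant}
        for d in rng.choice(len(dominant), size=extra, replace=False):
            counts[dominant[d]] += 1
        out = list(padding)
        for d in dominant:
            out.extend([d] * counts[d])
        return out
    raise ValueError(f"unknown mode {mode!r}; expected 'idealized' or 'actual'")


def assign_durations(
    design: BlockDesign,
    mode: str = "actual",
    seed: int | np.random.Generator | None = None,
) -> list[SequenceTrial]:
    """Draw concrete FP1/FP2 durations for every sequence of a block.

    ``idealized`` reproduces the smooth triangular per-duration profile of the
    design distributions; ``actual`` emulates a sampled single-participant
    configuration in which nine padding durations appear exactly once per
    position category and the rest mass on the three durations around each
    peak.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq_types: list[str] = []
    for st in SEQUENCE_TYPES:
        seq_types.extend([st] * design.counts.get(st, 0))

    fps = np.zeros((len(seq_types), 2), dtype=int)
    for pos in (0, 1):
        for cat in ("S", "L"):
            idx = [i for i, st in enumerate(seq_types) if st[pos] == cat]
            if not idx:
                continue
            multiset = _category_multiset(cat, len(idx), mode, rng)
            rng.shuffle(multiset)
            fps[idx, pos] = multiset

    order = rng.permutation(len(seq_types))
    return [
        SequenceTrial(sequence_index=i + 1, fp1_cs=int(fps[j, 0]), fp2_cs=int(fps[j, 1]))
        for i, j in enumerate(order)
    ]


def schedule_timing(
    sequences: Sequence[SequenceTrial],
    seed: int | np.random.Generator | None = None,
) -> list[SequenceTrial]:
    """Assign warning/target onsets to an ordered list of sequences.

    Within a sequence the FP2 warning follows the FP1 target offset by 1.2 s;
    consecutive sequences are separated by a gap drawn uniformly from
    3.0-3.2 s in 0.05-s increments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[SequenceTrial] = []
    t = 0  # centiseconds from block start
    for seq in sequences:
        w1 = t
        t1 = w1 + seq.fp1_cs
        w2 = t1 + TARGET_DURATION_CS + INTER_TRIAL_GAP_CS
        t2 = w2 + seq.fp2_cs
        gap = int(rng.choice(SEQUENCE_GAP_GRID_CS))
        out.append(
            replace(
                seq,
                warning1_onset=w1 / 100.0,
                target1_onset=t1 / 100.0,
                warning2_onset=w2 / 100.0,
                target2_onset=t2 / 100.0,
                inter_sequence_gap=gap / 100.0,
            )
        )
        t = t2 + TARGET_DURATION_CS + gap
    return out


def generate_session(
    participant_id: int,
    seed: int | np.random.Generator | None = None,
    mode: str = "actual",
) -> pd.DataFrame:
    """Simulate one participant's full session as a trial table.

    Twelve runs: the four blocks in a fresh random order, repeated three
    times, yielding 600 FP1 and 600 FP2 rows.  Reaction times are left empty.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[tuple] = []
    run = 0
    for _repeat in range(3):
        for block_id in rng.permutation([1, 2, 3, 4]):
            run += 1
            design = build_block_design(int(block_id))
            sequences = schedule_timing(assign_durations(design, mode, rng), rng)
            for seq in sequences:
                rows.append(
                    (participant_id, run, int(block_id), seq.sequence_index,
                     "FP1", seq.fp1, np.nan, np.nan, False)
                )
                rows.append(
                    (participant_id, run, int(block_id), seq.sequence_index,
                     "FP2", seq.fp2, seq.fp1, np.nan, False)
                )
    return pd.DataFrame(rows, columns=list(TRIAL_TABLE_COLUMNS))


def generate_sessions(
    n_participants: int,
    seed: int | np.random.SeedSequence | None = None,
    mode: str = "actual",
) -> pd.DataFrame:
    """Concatenate independently seeded sessions for several participants."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    tables = [
        generate_session(pid + 1, np.random.default_rng(child), mode)
        for pid, child in enumerate(children)
    ]
    return pd.concat(tables, ignore_index=True)


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["false_alarm"] = df["false_alarm"].astype(bool)
    return df
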