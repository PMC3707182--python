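"""Finger-sequence task primitives.

Sequences are permutations of the digits 1-5 (thumb to little finger),
constrained so that no sequence contains an ascending or descending run of
more than three neighboring fingers (1-2-3 is allowed, 1-2-3-4 is not).
Force traces from the five-key response box are parsed into press events
with a 2.5 N press threshold and a 2.2 N release/interference threshold,
and per-trial movement times and the sequence-specific learning test are
computed from those events.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

N_FINGERS = 5
PRESS_THRESHOLD_N = 2.5
RELEASE_THRESHOLD_N = 2.2
DEFAULT_TRACE_HZ = 200.0

__all__ = [
    "SequenceSet",
    "ForceTrace",
    "PressEvent",
    "IncompleteTrialError",
    "is_valid_sequence",
    "all_valid_sequences",
    "generate_sequence_pool",
    "split_pool",
    "transitions",
    "transition_overlap",
    "detect_presses",
    "movement_time",
    "sequence_specific_test",
    "read_behavioral_table",
    "write_behavioral_table",
]


def is_valid_sequence(seq: Sequence[int]) -> bool:
    """Check the run constraint for one candidate sequence.

    A sequence is valid when it is a permutation of 1..5 and contains no
    ascending or descending sub-run of four or more neighboring digits.
    """
    if sorted(seq) != list(range(1, N_FINGERS + 1)):
        return False
    diffs = np.diff(np.asarray(seq))
    for step in (1, -1):
        run = 1
        for d in diffs:
            run = run + 1 if d == step else 1
            if run >= 4:  # four neighboring digits in a row
                return False
    return True


def all_valid_sequences() -> list[tuple[int, ...]]:
    """Enumerate every valid sequence (114 of the 120 permutations)."""
    return [
        p
        for p in itertools.permutations(range(1, N_FINGERS + 1))
        if is_valid_sequence(p)
    ]


@dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of distinct valid finger sequences."""

    sequences: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        for s in self.sequences:
            if not is_valid_sequence(s):
                raise ValueError(f"invalid sequence {s}")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("sequences within a set must be distinct")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def transition_set(self) -> set[tuple[int, int]]:
        """Distinct ordered digit transitions occurring anywhere in the set."""
        return {t for s in self.sequences for t in transitions(s)}


def transitions(seq: Sequence[int]) -> list[tuple[int, int]]:
    """The 4 ordered digit transitions of one five-press sequence."""
    return [(seq[i], seq[i + 1]) for i in range(len(seq) - 1)]


def generate_sequence_pool(n_sequences: int, rng_seed: int | None = None) -> SequenceSet:
    """Draw ``n_sequences`` distinct valid sequences uniformly at random."""
    valid = all_valid_sequences()
    if n_sequences > len(valid):
        raise ValueError(
            f"requested {n_sequences} sequences but only {len(valid)} valid "
            "permutations exist under the run constraint"
        )
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(valid), size=n_sequences, replace=False)
    return SequenceSet(tuple(valid[i] for i in idx))


def split_pool(pool: SequenceSet, n_groups: int, rng_seed: int | None = None) -> list[SequenceSet]:
    """Randomly partition a pool into ``n_groups`` equal-sized disjoint sets.

    The experimental design divides 12 sequences into three sets of four:
    trained, untrained test-only, and untrained scan-only.
    """
    if len(pool) % n_groups != 0:
        raise ValueError(f"pool of {len(pool)} not divisible into {n_groups} groups")
    per = len(pool) // n_groups
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(pool))
    seqs = pool.sequences
    return [
        SequenceSet(tuple(seqs[i] for i in order[g * per : (g + 1) * per]))
        for g in range(n_groups)
    ]


def transition_overlap(reference: SequenceSet, probe: SequenceSet) -> float:
    """Percentage of probe transitions also present anywhere in the reference.

    Each sequence contributes its 4 ordered transitions; a probe transition
    counts as shared when it occurs in any reference sequence, and repeated
    probe transitions are counted per occurrence.
    """
    if len(reference) == 0 or len(probe) == 0:
        raise ValueError("both sequence sets must be non-empty")
    ref = reference.transition_set()
    probe_transitions = [t for s in probe for t in transitions(s)]
    shared = sum(1 for t in probe_transitions if t in ref)
    return 100.0 * shared / len(probe_transitions)


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled 5-channel isometric force recording (Newtons)."""

    time: np.ndarray  # (n_samples,) seconds
    forces: np.ndarray  # (n_samples, 5) Newtons

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        if f.ndim != 2 or f.shape[1] != N_FINGERS:
            raise ValueError("forces must be (n_samples, 5)")
        if t.shape[0] != f.shape[0]:
            raise ValueError("time and forces length mismatch")
        if np.any(f < 0):
            raise ValueError("forces must be non-negative")
        if t.size > 1 and not np.allclose(np.diff(t), t[1] - t[0]):
            raise ValueError("sampling interval must be constant")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "forces", f)


@dataclass(frozen=True)
class PressEvent:
    finger: int  # digit 1-5
    onset: float  # seconds


class IncompleteTrialError(ValueError):
    """Raised when fewer than five presses were detected in a trial."""


def detect_presses(
    trace: ForceTrace,
    press_threshold: float = PRESS_THRESHOLD_N,
    other_threshold: float = RELEASE_THRESHOLD_N,
) -> list[PressEvent]:
    """Parse a force trace into ordered keypress events.

    A press is recognized at the first sample where one finger's force
    reaches ``press_threshold`` (>= 2.5 N) while every other finger is
    strictly below ``other_threshold`` (< 2.2 N); a finger that has pressed
    cannot trigger again until its force falls below ``other_threshold``.
    """
    if trace.time.size == 0:
        raise ValueError("empty force trace")
    f = trace.forces
    armed = np.ones(N_FINGERS, dtype=bool)
    events: list[PressEvent] = []
    for i in range(f.shape[0]):
        row = f[i]
        for finger in range(N_FINGERS):
            if not armed[finger] and row[finger] < other_threshold:
                armed[finger] = True
        for finger in range(N_FINGERS):
            if not armed[finger] or row[finger] < press_threshold:
                continue
            others = np.delete(row, finger)
            if np.all(others < other_threshold):
                events.append(PressEvent(finger + 1, float(trace.time[i])))
                armed[finger] = False
    return events


def movement_time(presses: Iterable[PressEvent]) -> float:
    """Movement time in ms: first press onset to fifth press onset."""
    onsets = [p.onset for p in presses]
    if len(onsets) < N_FINGERS:
        raise IncompleteTrialError(
            f"trial incomplete: {len(onsets)} of {N_FINGERS} presses detected"
        )
    return 1000.0 * (onsets[-1] - onsets[0])


def sequence_specific_test(pre_diff: np.ndarray, post_diff: np.ndarray):
    """Test for a sequence-specific advantage correcting for pre-test bias.

    Regresses the per-subject post-test MT difference (untrained - trained)
    on the pre-test difference and tests whether the intercept differs from
    zero: a positive intercept is a training advantage that is not explained
    by pre-existing differences between the sequence sets.

    Returns
    -------
    (intercept_ms, t_statistic, p_value) with n - 2 degrees of freedom.
    """
    x = np.asarray(pre_diff, dtype=float)
    y = np.asarray(post_diff, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pre_diff and post_diff must be matching 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept = float(fit.params[0])
    t_stat = float(fit.tvalues[0])
    p_val = float(fit.pvalues[0])
    if not np.isfinite(t_stat) and intercept == 0.0:
        t_stat, p_val = 0.0, 1.0  # exact fit through zero: no evidence either way
    return intercept, t_stat, p_val


# -- behavioral record I/O ---------------------------------------------------

BEHAVIOR_COLUMNS = [
    "subject",
    "run",
    "trial",
    "sequence",
    "condition",
    "MT_ms",
    "force_f1",
    "force_f2",
    "force_f3",
    "force_f4",
    "force_f5",
    "error",
]


def write_behavioral_table(records: pd.DataFrame, path) -> None:
    """Write per-trial behavioral records as a tab-separated table."""
    records.to_csv(path, sep="\t", index=False, columns=BEHAVIOR_COLUMNS)


def read_behavioral_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behavioral table missing columns: {sorted(missing)}")
    df["error"] = df["error"].astype(bool)
    return df
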