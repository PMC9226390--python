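"""Stimulus-sequence and trial-schedule generation for the audiovisual digit-span task.

A trial presents five black *target* digits interleaved with five dark-gray
*distractor* digits (blanks allowed as distractors).  Each target occupies its
own 1.25 s window; rhythmic conditions lock target onsets to the 0.8 Hz grid
and precede the sequence with five induction stimuli, non-rhythmic conditions
jitter onsets uniformly within the window.  Audio conditions co-present a
short tone with each target.  Thirty sequences are crossed with the four
conditions into a pseudo-randomized 120-trial session; a separate 108-trial
pre-test schedule feeds the audiovisual-dominance task.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Sentinel digit value for a blank distractor (an empty gray circle).
BLANK = 0

# timing/design constants (milliseconds)
STIM_MS = 200
INTERVAL_MS = 1250
ANSWER_WINDOW_MS = 7000
FIXATION_MS = 1000
N_TARGETS = 5
N_DISTRACTORS = 5
N_SEQUENCES = 30
N_INDUCTION = 5
N_TRIALS = 120
N_PRETEST = 108
N_PRETEST_PRACTICE = 12
TONE_HZ = 500
TONE_MS = 50
LEVEL_DB = 70


class DesignError(ValueError):
    """Raised when generation inputs are invalid or a retry cap is exhausted."""


@dataclass(frozen=True)
class Condition:
    """One of the four presentation conditions."""

    code: str
    audio_support: bool
    rhythmic: bool


CONDITIONS: tuple[Condition, ...] = (
    Condition("C_1-NoSupp", audio_support=False, rhythmic=False),
    Condition("C_2-VisRhythmSupp", audio_support=False, rhythmic=True),
    Condition("C_3-AudSupp", audio_support=True, rhythmic=False),
    Condition("C_4-AVRhythmSupp", audio_support=True, rhythmic=True),
)

CONDITION_BY_CODE = {c.code: c for c in CONDITIONS}


def condition(code: str) -> Condition:
    try:
        return CONDITION_BY_CODE[code]
    except KeyError:
        raise DesignError(f"unknown condition code: {code!r}") from None


@dataclass(frozen=True)
class TrialSequence:
    """Five targets plus five distractors arranged in gaps after each target.

    ``gaps[k]`` is the run of 0-2 distractor digits following target ``k``;
    gap lengths sum to five.  ``BLANK`` (0) is legal only inside gaps.
    """

    id: int
    targets: tuple[int, ...]
    gaps: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.targets) != N_TARGETS:
            raise DesignError(f"expected {N_TARGETS} targets, got {len(self.targets)}")
        if any(not 1 <= t <= 9 for t in self.targets):
            raise DesignError("targets must be digits 1..9 (no blanks)")
        if any(a == b for a, b in zip(self.targets, self.targets[1:])):
            raise DesignError("consecutive targets must differ")
        if len(self.gaps) != N_TARGETS:
            raise DesignError("one distractor run per target is required")
        if any(len(g) > 2 for g in self.gaps):
            raise DesignError("each distractor run holds at most two digits")
        n_distract = sum(len(g) for g in self.gaps)
        if n_distract != N_DISTRACTORS:
            raise DesignError(f"expected {N_DISTRACTORS} distractors, got {n_distract}")
        if any(not 0 <= d <= 9 for g in self.gaps for d in g):
            raise DesignError("distractors must be digits 1..9 or BLANK")

    @property
    def distractors(self) -> tuple[int, ...]:
        return tuple(d for g in self.gaps for d in g)

    @property
    def presented(self) -> tuple[int, ...]:
        """Full stimulus stream in presentation order (blanks included)."""
        out: list[int] = []
        for t, g in zip(self.targets, self.gaps):
            out.append(t)
            out.extend(g)
        return tuple(out)

    @property
    def presented_nonblank(self) -> tuple[int, ...]:
        """Presentation stream with blank distractors removed."""
        return tuple(d for d in self.presented if d != BLANK)


@dataclass(frozen=True)
class TrialSlot:
    order: int  # 1..120 rank within the session
    condition: Condition
    sequence_id: int


@dataclass(frozen=True)
class StimulusEvent:
    onset_ms: int
    duration_ms: int
    kind: str  # induction | target | distractor | fixation | answer_window
    digit: int | None
    has_tone: bool


@dataclass(frozen=True)
class StimulusTimeline:
    slot: TrialSlot
    events: tuple[StimulusEvent, ...]

    def of_kind(self, kind: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.kind == kind)


@dataclass(frozen=True)
class PretestSlot:
    index: int  # 1..108
    modality: str  # Au | Vi | AV
    obj: str  # A | B
    is_practice: bool


PRETEST_MODALITIES = ("Au", "Vi", "AV")
PRETEST_OBJECTS = ("A", "B")
PRETEST_TYPES = tuple(itertools.product(PRETEST_MODALITIES, PRETEST_OBJECTS))


# ---------------------------------------------------------------------------
# target-pattern exclusion


def _is_arithmetic(seq: Sequence[int]) -> bool:
    step = seq[1] - seq[0]
    return all(b - a == step for a, b in zip(seq, seq[1:]))


def _is_alternation(seq: Sequence[int]) -> bool:
    return (
        seq[0] != seq[1]
        and all(seq[i] == seq[i % 2] for i in range(len(seq)))
    )


def _is_tail_ladder(seq: Sequence[int]) -> bool:
    # e.g. 1-2468: the tail runs in a constant step whose direction agrees
    # with the first difference, reading as a recognizable ramp.
    tail = seq[1:]
    if not _is_arithmetic(tail):
        return False
    step = tail[1] - tail[0]
    if step == 0:
        return False
    return (seq[1] - seq[0] > 0) == (step > 0)


def is_recognizable_pattern(
    targets: Sequence[int], extra_blacklist: Iterable[Sequence[int]] = ()
) -> bool:
    """True if a five-target sequence reads as an obvious pattern.

    Excluded families: arithmetic progressions of any constant step (12345,
    97531), strict two-digit alternations (12121), constant-step ramps after
    the first digit (12468), plus any user-supplied blacklist entries.
    """
    targets = list(targets)
    if len(targets) != N_TARGETS:
        raise DesignError(f"pattern check requires {N_TARGETS} digits")
    if any(not 1 <= t <= 9 for t in targets):
        raise DesignError("pattern check requires digits 1..9")
    if _is_arithmetic(targets) or _is_alternation(targets) or _is_tail_ladder(targets):
        return True
    return any(list(b) == targets for b in extra_blacklist)


# ---------------------------------------------------------------------------
# sequence generation

# all ways to spread 5 distractors over 5 gaps of size <= 2
GAP_PROFILES: tuple[tuple[int, ...], ...] = tuple(
    p for p in itertools.product(range(3), repeat=N_TARGETS) if sum(p) == N_DISTRACTORS
)

_RETRY_CAP = 10_000


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _draw_targets(rng: np.random.Generator) -> tuple[int, ...]:
    out = [int(rng.integers(1, 10))]
    while len(out) < N_TARGETS:
        d = int(rng.integers(1, 10))
        if d != out[-1]:
            out.append(d)
    return tuple(out)


def generate_sequence(
    rng_seed,
    id: int,
    *,
    blank_probability: float = 0.1,
    extra_blacklist: Iterable[Sequence[int]] = (),
) -> TrialSequence:
    """Draw one trial sequence satisfying all structural constraints.

    Targets are rejection-sampled until no recognizable pattern remains;
    distractor counts per gap are uniform over the 51 admissible profiles and
    distractor values are uniform over {1..9, blank} (blank probability
    configurable, default 1/10).
    """
    rng = _as_rng(rng_seed)
    blacklist = [list(b) for b in extra_blacklist]
    for _ in range(_RETRY_CAP):
        targets = _draw_targets(rng)
        if not is_recognizable_pattern(targets, blacklist):
            break
    else:  # pragma: no cover - cap generous
        raise DesignError("target rejection-sampling cap exceeded")
    profile = GAP_PROFILES[int(rng.integers(len(GAP_PROFILES)))]
    gaps = []
    for g in profile:
        run = []
        for _ in range(g):
            if rng.random() < blank_probability:
                run.append(BLANK)
            else:
                run.append(int(rng.integers(1, 10)))
        gaps.append(tuple(run))
    return TrialSequence(id=id, targets=targets, gaps=tuple(gaps))


def generate_sequences(
    rng_seed, n: int = N_SEQUENCES, **kwargs
) -> list[TrialSequence]:
    """Draw ``n`` sequences with pairwise-distinct target tuples."""
    rng = _as_rng(rng_seed)
    seen: set[tuple[int, ...]] = set()
    out: list[TrialSequence] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > _RETRY_CAP:  # pragma: no cover
            raise DesignError("sequence-set generation cap exceeded")
        seq = generate_sequence(rng, id=len(out) + 1, **kwargs)
        if seq.targets in seen:
            continue
        seen.add(seq.targets)
        out.append(seq)
    return out


# ---------------------------------------------------------------------------
# session schedule


def build_schedule(
    sequences: Sequence[TrialSequence],
    rng_seed,
    *,
    min_sequence_gap: int = 3,
    max_restarts: int = 2000,
) -> list[TrialSlot]:
    """Pseudo-randomize the 30 sequences x 4 conditions into 120 slots.

    Constraints: every (sequence, condition) pair appears exactly once,
    adjacent slots differ in condition, and at least two other sequences
    intervene before a sequence id repeats (positional gap >= 3).  Built by a
    randomized greedy pass with restarts.  The full study uses 30 sequences
    (120 slots); smaller sequence sets are accepted for scaled-down runs.
    """
    if len(sequences) < min_sequence_gap:
        raise DesignError(
            f"need at least {min_sequence_gap} sequences, got {len(sequences)}"
        )
    rng = _as_rng(rng_seed)
    pairs = [(s.id, c) for s in sequences for c in CONDITIONS]
    for _ in range(max_restarts):
        remaining = list(pairs)
        slots: list[TrialSlot] = []
        ok = True
        while remaining:
            recent_seq = {s.sequence_id for s in slots[-(min_sequence_gap - 1):]}
            prev_cond = slots[-1].condition if slots else None
            feasible = [
                i
                for i, (sid, c) in enumerate(remaining)
                if sid not in recent_seq and c is not prev_cond
            ]
            if not feasible:
                ok = False
                break
            i = feasible[int(rng.integers(len(feasible)))]
            sid, c = remaining.pop(i)
            slots.append(TrialSlot(order=len(slots) + 1, condition=c, sequence_id=sid))
        if ok:
            return slots
    raise DesignError("schedule constraint satisfaction failed within restart cap")


# ---------------------------------------------------------------------------
# timelines


def _place_distractors(
    rng: np.random.Generator, start: int, end: int, digits: Sequence[int]
) -> list[tuple[int, int]]:
    """Place 200 ms distractors non-overlapping at random within [start, end)."""
    k = len(digits)
    if k == 0:
        return []
    slack = end - start - STIM_MS * k
    if slack < 0:
        raise AssertionError("distractor packing infeasible")
    offsets = np.sort(rng.integers(0, slack + 1, size=k))
    return [
        (start + int(offsets[i]) + STIM_MS * i, digits[i]) for i in range(k)
    ]


def render_timeline(
    trial: TrialSlot,
    sequence: TrialSequence,
    rng_seed,
    *,
    interval_ms: int = INTERVAL_MS,
    stim_ms: int = STIM_MS,
    answer_window_ms: int = ANSWER_WINDOW_MS,
    fixation_ms: int = FIXATION_MS,
) -> StimulusTimeline:
    """Lay out one trial's stimulus events on an integer-millisecond axis.

    Rhythmic conditions lock the five target onsets to an exact
    ``interval_ms`` grid preceded by five induction events on the same grid;
    non-rhythmic conditions jitter each target uniformly within its window,
    leaving room for that window's distractors.  Event intervals are
    half-open ``[onset, onset + duration)``.
    """
    if trial.sequence_id != sequence.id:
        raise DesignError("slot and sequence ids disagree")
    rng = _as_rng(rng_seed)
    cond = trial.condition
    events: list[StimulusEvent] = []
    events.append(StimulusEvent(0, fixation_ms, "fixation", None, False))
    base = fixation_ms
    if cond.rhythmic:
        for k in range(N_INDUCTION):
            events.append(
                StimulusEvent(
                    base + k * interval_ms,
                    stim_ms if not cond.audio_support else TONE_MS,
                    "induction",
                    None,
                    cond.audio_support,
                )
            )
        base += N_INDUCTION * interval_ms
    for k, (target, gap) in enumerate(zip(sequence.targets, sequence.gaps)):
        w0 = base + k * interval_ms
        w1 = w0 + interval_ms
        if cond.rhythmic:
            onset = w0
        else:
            latest = w1 - stim_ms * (1 + len(gap))
            onset = w0 + int(rng.integers(0, latest - w0 + 1))
        events.append(StimulusEvent(onset, stim_ms, "target", target, cond.audio_support))
        for d_onset, digit in _place_distractors(rng, onset + stim_ms, w1, gap):
            events.append(StimulusEvent(d_onset, stim_ms, "distractor", digit, False))
    seq_end = base + N_TARGETS * interval_ms
    events.append(StimulusEvent(seq_end, fixation_ms, "fixation", None, False))
    events.append(
        StimulusEvent(seq_end + fixation_ms, answer_window_ms, "answer_window", None, False)
    )
    events.sort(key=lambda e: (e.onset_ms, e.kind))
    return StimulusTimeline(slot=trial, events=tuple(events))


# ---------------------------------------------------------------------------
# pre-test schedule


def build_pretest_schedule(
    rng_seed, *, max_run: int = 4, max_restarts: int = 5000
) -> list[PretestSlot]:
    """Randomize the 108-trial dominance pre-test.

    First 12 slots are practice, two of each of the six (modality, object)
    stimulus types; the remaining 96 balance the types at 16 each (18 per
    type overall).  No more than ``max_run`` identical stimuli in a row.
    """
    rng = _as_rng(rng_seed)
    practice_pool = [t for t in PRETEST_TYPES for _ in range(2)]
    main_pool = [t for t in PRETEST_TYPES for _ in range((N_PRETEST - N_PRETEST_PRACTICE) // 6)]
    for _ in range(max_restarts):
        practice = list(rng.permutation(len(practice_pool)))
        main = list(rng.permutation(len(main_pool)))
        seq = [practice_pool[i] for i in practice] + [main_pool[i] for i in main]
        run, longest = 1, 1
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a == b else 1
            longest = max(longest, run)
        if longest <= max_run:
            return [
                PretestSlot(
                    index=i + 1,
                    modality=m,
                    obj=o,
                    is_practice=i < N_PRETEST_PRACTICE,
                )
                for i, (m, o) in enumerate(seq)
            ]
    raise DesignError("pre-test schedule constraint satisfaction failed")  # pragma: no cover
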