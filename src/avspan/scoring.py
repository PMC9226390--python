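"""Recall-accuracy scores for the digit-span task.

Three complementary outcome scores are computed for a recalled answer:

* **PerDigit** — fraction of positionally correct digits after inserting
  dummy digits into the shorter of (targets, answer) so as to maximize the
  number of matching positions; range [0, 1], 1 only for perfect recall.
* **Levenshtein** — unit-cost edit distance (insert/delete/substitute)
  between answer and targets; 0 only for perfect recall.
* **Distraction** — contrasts how much of the answer traces the full
  presented stream (targets plus distractors) versus the targets alone.
  Every consecutive answer triple is tested as a contiguous substring of
  each reference; the first two answer digits are tested as a prefix and the
  last two as a suffix.  The score is (stream matches − target matches)
  divided by answer length, so it falls in [−1, 1]: negative means recall
  was target-driven, positive means distractor-driven.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .design import BLANK, TrialSequence

DigitSeq = Sequence[int]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreBundle:
    per_digit: float
    levenshtein: int
    distraction: float


def parse_answer(text: str) -> tuple[int, ...]:
    """Normalize a transcript to the recalled digit string.

    Keeps digits 1-9 in order; whitespace and punctuation are dropped.  A
    '0' character cannot be a recalled stimulus (digits run 1-9) and is
    discarded with a warning.
    """
    out = []
    for ch in text:
        if ch in "123456789":
            out.append(int(ch))
        elif ch == "0":
            warnings.warn(f"dropping '0' from transcript {text!r}: digits run 1..9")
    return tuple(out)


def per_digit_score(targets: DigitSeq, answer: DigitSeq) -> float:
    """Positional-match fraction after optimal dummy insertion.

    Equal lengths compare position by position.  Otherwise exactly
    ``|longer| - |shorter|`` dummy digits (matching nothing) are inserted
    into the shorter sequence wherever they maximize the number of equal
    positions; the score is that maximum divided by the longer length.
    """
    targets, answer = list(targets), list(answer)
    if len(targets) == len(answer):
        if not targets:
            return 1.0
        return sum(a == b for a, b in zip(targets, answer)) / len(targets)
    short, long_ = sorted((targets, answer), key=len)
    if not short:
        return 0.0
    # Inserting dummies anywhere in `short` aligns its digits with any
    # order-preserving choice of |short| positions of `long_`; maximize
    # matches by DP over (i digits of short, j digits of long_ consumed).
    n, m = len(short), len(long_)
    NEG = float("-inf")
    best = [[NEG] * (m + 1) for _ in range(n + 1)]
    best[0][0] = 0
    for j in range(m):
        for i in range(min(j, n), -1, -1):
            cur = best[i][j]
            if cur == NEG:
                continue
            # long_[j] aligned with a dummy
            if (m - j - 1) >= (n - i):
                best[i][j + 1] = max(best[i][j + 1], cur)
            # long_[j] aligned with short[i]
            if i < n:
                best[i + 1][j + 1] = max(
                    best[i + 1][j + 1], cur + (short[i] == long_[j])
                )
    return best[n][m] / m


def levenshtein(a: DigitSeq, b: DigitSeq) -> int:
    """Unit-cost edit distance between two digit sequences."""
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _contains(haystack: DigitSeq, needle: DigitSeq) -> bool:
    n = len(needle)
    return any(
        list(haystack[i : i + n]) == list(needle)
        for i in range(len(haystack) - n + 1)
    )


def distraction_score(targets: DigitSeq, presented: DigitSeq, answer: DigitSeq) -> float:
    """Distractor-intrusion contrast in [-1, 1].

    ``presented`` is the full stimulus stream in presentation order with
    blanks removed.  Each of the answer's ``n - 2`` consecutive triples is
    tested as a contiguous substring of the targets and of the stream; the
    first two answer digits are additionally tested as a prefix of each, the
    last two as a suffix.  Returns (stream count − target count) / n.  A
    single-digit answer scores 0; for a two-digit answer the prefix and
    suffix pairs coincide but both are counted.
    """
    targets, presented, answer = list(targets), list(presented), list(answer)
    if not presented:
        raise ScoringError("presented stream must be non-empty")
    n = len(answer)
    if n == 0:
        return 0.0
    if n == 1:
        return 0.0
    count_t = count_f = 0
    for i in range(n - 2):
        tri = answer[i : i + 3]
        count_t += _contains(targets, tri)
        count_f += _contains(presented, tri)
    head, tail = answer[:2], answer[-2:]
    count_t += targets[:2] == head
    count_f += presented[:2] == head
    count_t += targets[-2:] == tail
    count_f += presented[-2:] == tail
    return (count_f - count_t) / n


def score_trial(sequence: TrialSequence, answer: DigitSeq) -> ScoreBundle:
    """Assemble the three outcome scores for one trial."""
    answer = tuple(answer)
    if any(d == BLANK for d in answer):
        raise ScoringError("answers cannot contain blanks")
    return ScoreBundle(
        per_digit=per_digit_score(sequence.targets, answer),
        levenshtein=levenshtein(sequence.targets, answer),
        distraction=distraction_score(
            sequence.targets, sequence.presented_nonblank, answer
        ),
    )
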