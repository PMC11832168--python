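"""Artificial speech streams with transitional-probability structure.

Streams are built from 36 tokens (6 syllables x 6 voices). A structured
stream concatenates three two-element units ("duplets") defined on one
feature only (phonemes or voices), so that transitional probabilities (TPs)
on that feature alternate between 1 within duplets and 0.5 across duplet
boundaries, while the other feature varies semi-randomly with uniform TPs
of 0.2. A random stream has uniform 0.2 TPs on both features.

"Semi-random" means two constraints on every element sequence: an element
never repeats immediately, and the alternation X Y X Y of two elements is
forbidden. At the structured level the element is the duplet; for the
unstructured feature the element is the feature id of each token.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

SYLLABLES = ("ki", "da", "pe", "tu", "bo", "ge")
VOICES = ("fr3", "fr1", "fr7", "fr2", "it4", "fr4")

N_IDS = 6
SYLLABLE_S = 0.25  #: duration of one consonant-vowel syllable, seconds
DUPLET_S = 0.5

#: default duplet inventories over feature ids. List B is the boundary
#: complement of list A: every B duplet straddles an A duplet boundary and
#: vice versa, so list A Words are list B Part-words.
DEFAULT_DUPLETS = {
    "A": ((2, 3), (0, 1), (4, 5)),  # petu, kida, boge (phoneme reading)
    "B": ((3, 0), (1, 4), (5, 2)),  # tuki, dabo, gepe
}


class Feature(str, Enum):
    phoneme = "phoneme"
    voice = "voice"


class Condition(str, Enum):
    random = "random"
    structured_long = "structured_long"
    structured_short = "structured_short"


@dataclass(frozen=True)
class Token:
    """One syllable-voice combination; 36 are possible."""

    syllable: int
    voice: int

    def __post_init__(self):
        if not (0 <= self.syllable < N_IDS and 0 <= self.voice < N_IDS):
            raise ValueError("syllable and voice ids must be in 0..5")

    def feature(self, feature: Feature | str) -> int:
        return self.syllable if Feature(feature) is Feature.phoneme else self.voice


@dataclass(frozen=True)
class Lexicon:
    """Three duplets over one feature, partitioning the six feature ids."""

    structured_feature: Feature
    duplets: tuple[tuple[int, int], ...]
    list_id: str = "A"

    def __post_init__(self):
        ids = [i for d in self.duplets for i in d]
        if len(self.duplets) != 3 or sorted(ids) != list(range(N_IDS)):
            raise ValueError("lexicon must hold 3 duplets partitioning ids 0..5")

    @property
    def words(self) -> tuple[tuple[int, int], ...]:
        return self.duplets

    @property
    def partwords(self) -> tuple[tuple[int, int], ...]:
        """All boundary pairs: second element of one duplet, first of another."""
        return tuple(
            (a[1], b[0]) for a in self.duplets for b in self.duplets if a != b
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "structured_feature": self.structured_feature.value,
                "duplets": [list(d) for d in self.duplets],
                "list_id": self.list_id,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Lexicon":
        obj = json.loads(text)
        return cls(
            Feature(obj["structured_feature"]),
            tuple(tuple(d) for d in obj["duplets"]),
            obj.get("list_id", "A"),
        )


@dataclass
class Stream:
    """A timed token sequence; one token every 0.25 s."""

    tokens: list[Token]
    condition: Condition
    lexicon: Lexicon | None = None
    onsets_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.onsets_s is None:
            self.onsets_s = SYLLABLE_S * np.arange(len(self.tokens))

    @property
    def duration_s(self) -> float:
        return SYLLABLE_S * len(self.tokens)

    def feature_ids(self, feature: Feature | str) -> np.ndarray:
        return np.array([t.feature(feature) for t in self.tokens], dtype=int)

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table, one row per token."""
        n = len(self.tokens)
        return pd.DataFrame(
            {
                "onset": self.onsets_s,
                "duration": np.full(n, SYLLABLE_S),
                "syllable": [SYLLABLES[t.syllable] for t in self.tokens],
                "voice": [VOICES[t.voice] for t in self.tokens],
                "syllable_id": [t.syllable for t in self.tokens],
                "voice_id": [t.voice for t in self.tokens],
                "duplet_id": np.arange(n) // 2,
                "condition": self.condition.value,
            }
        )


@dataclass
class TPMatrix:
    """First-order transition counts and row-normalised probabilities."""

    counts: np.ndarray
    probabilities: np.ndarray
    undefined_rows: np.ndarray

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(N_IDS, dtype=bool) & ~self.undefined_rows[:, None]
        return self.probabilities[mask]


@dataclass(frozen=True)
class TestItem:
    """An isolated duplet presented during the recognition test."""

    pair: tuple[Token, Token]
    item_type: str  # "word" | "partword"
    soa_s: float

    def __post_init__(self):
        if self.item_type not in ("word", "partword"):
            raise ValueError("item_type must be 'word' or 'partword'")
        if not (2.0 <= self.soa_s <= 2.3):
            raise ValueError("SOA must lie in [2.0, 2.3] s")


class GenerationError(RuntimeError):
    """Constrained sequence generation failed; constraints are never relaxed."""


def build_lexicon(
    structured_feature: Feature | str,
    list_id: str = "A",
    duplets: Sequence[Sequence[int]] | None = None,
) -> Lexicon:
    """Return the duplet lexicon for one familiarisation list.

    The shipped defaults put ``petu`` in list A; list B is the boundary
    complement of list A (its duplets are exactly list A's part-words),
    so acoustic content cannot distinguish Words from Part-words across
    lists. A custom partition may be supplied via ``duplets``.
    """
    if list_id not in ("A", "B"):
        raise ValueError("list_id must be 'A' or 'B'")
    if duplets is None:
        dups = DEFAULT_DUPLETS[list_id]
    else:
        dups = tuple(tuple(int(i) for i in d) for d in duplets)
    return Lexicon(Feature(structured_feature), dups, list_id)


def _legal(seq: list[int], candidate: int) -> bool:
    """No immediate repeat; no X Y X Y alternation."""
    if seq and candidate == seq[-1]:
        return False
    if len(seq) >= 3 and seq[-3] == seq[-1] and seq[-2] == candidate:
        return False
    return True


def _constrained_sequence(
    n: int,
    n_ids: int,
    rng: np.random.Generator,
    counts: list[int] | None = None,
    max_restarts: int = 100,
    backtrack_limit: int | None = None,
) -> list[int]:
    """Sample an id sequence under the no-repeat / no-ABAB constraints.

    With ``counts`` given, ids are drawn without replacement from that
    multiset (balanced duplet usage), proportionally to the remaining
    counts and with a majority-forcing rule (an id whose remaining count
    exceeds half the remaining slots must be placed whenever legal) so
    that the tail stays completable. Dead ends trigger systematic
    backtracking with per-position tried-sets; the per-attempt backtrack
    budget is bounded and exhausting all restarts raises GenerationError —
    constraints are never relaxed.
    """
    if backtrack_limit is None:
        backtrack_limit = max(1000, n)
    for _ in range(max_restarts):
        seq: list[int] = []
        remaining = list(counts) if counts is not None else None
        tried: list[set[int]] = [set()]  # tried[k]: ids already attempted at position k
        depth_used = 0
        while len(seq) < n:
            pos = len(seq)
            last = seq[-1] if pos else -1
            banned = seq[-2] if pos >= 3 and seq[-3] == seq[-1] else -1
            t = tried[pos]
            slots_left = n - pos
            if remaining is not None and slots_left > 3:
                # prune provably unfinishable states early: a depleted id
                # leaves only two ids, which the no-ABAB rule caps at three
                # more placements; a majority id beyond half the remaining
                # slots cannot be interleaved under no-repeat
                if min(remaining) == 0 or 2 * max(remaining) > slots_left + 1:
                    options = []
                    t = None
            if t is not None:
                options = [
                    i
                    for i in range(n_ids)
                    if i != last
                    and i != banned
                    and i not in t
                    and (remaining is None or remaining[i] > 0)
                ]
            if not options:
                if pos == 0 or depth_used >= backtrack_limit:
                    break  # restart from scratch
                depth_used += 1
                popped = seq.pop()
                if remaining is not None:
                    remaining[popped] += 1
                del tried[pos:]  # tried[pos-1] already contains `popped`
                continue
            if remaining is None:
                choice = options[int(rng.integers(len(options)))]
            else:
                slots_left = n - pos
                maj = max(options, key=remaining.__getitem__)
                if 2 * remaining[maj] > slots_left + 1:
                    choice = maj
                else:
                    total = sum(remaining[i] for i in options)
                    r = rng.random() * total
                    acc = 0.0
                    choice = options[-1]
                    for i in options:
                        acc += remaining[i]
                        if r < acc:
                            choice = i
                            break
            tried[pos].add(choice)
            tried.append(set())
            seq.append(choice)
            if remaining is not None:
                remaining[choice] -= 1
        if len(seq) == n:
            return seq
    raise GenerationError(
        f"could not generate a {n}-element constrained sequence "
        f"after {max_restarts} restarts"
    )


def generate_structured_stream(
    lexicon: Lexicon,
    n_duplets: int,
    seed: int | np.random.Generator,
    condition: Condition = Condition.structured_long,
) -> Stream:
    """Semi-random concatenation of the lexicon's duplets.

    The duplet sequence is drawn without replacement from a balanced
    multiset (each duplet ``n_duplets/3`` times, remainder spread at
    random), under the no-repeat and no-ABAB constraints at duplet level;
    the unstructured feature is an independent per-syllable id sequence
    under the same constraints. Within-duplet TP on the structured feature
    is 1 by construction, between-duplet TP converges to 0.5, and the
    unstructured feature's TPs converge to 0.2.
    """
    if n_duplets < 1:
        raise ValueError("n_duplets must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    base, extra = divmod(n_duplets, 3)
    counts = [base] * 3
    for i in rng.permutation(3)[:extra]:
        counts[i] += 1
    duplet_seq = _constrained_sequence(n_duplets, 3, rng, counts=counts)
    structured_ids = [i for d in duplet_seq for i in lexicon.duplets[d]]
    unstructured_ids = _constrained_sequence(2 * n_duplets, N_IDS, rng)
    tokens = _combine(lexicon.structured_feature, structured_ids, unstructured_ids)
    return Stream(tokens, condition, lexicon)


def generate_random_stream(
    n_tokens: int, seed: int | np.random.Generator
) -> Stream:
    """Random stream: both features semi-random, uniform TPs of 0.2."""
    if n_tokens < 2:
        raise ValueError("n_tokens must be >= 2")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    syl = _constrained_sequence(n_tokens, N_IDS, rng)
    voi = _constrained_sequence(n_tokens, N_IDS, rng)
    tokens = [Token(s, v) for s, v in zip(syl, voi)]
    return Stream(tokens, Condition.random)


def _combine(
    structured_feature: Feature, structured_ids: list[int], unstructured_ids: list[int]
) -> list[Token]:
    if structured_feature is Feature.phoneme:
        return [Token(s, v) for s, v in zip(structured_ids, unstructured_ids)]
    return [Token(s, v) for v, s in zip(structured_ids, unstructured_ids)]


def empirical_tp(stream: Stream, feature: Feature | str) -> TPMatrix:
    """Empirical transition matrix P(next id | current id) over one feature."""
    ids = stream.feature_ids(feature)
    if ids.size < 2:
        raise ValueError("stream must contain at least 2 tokens")
    counts = np.zeros((N_IDS, N_IDS), dtype=int)
    np.add.at(counts, (ids[:-1], ids[1:]), 1)
    row = counts.sum(axis=1)
    undefined = row == 0
    probs = np.divide(
        counts, np.where(undefined, 1, row)[:, None], dtype=float
    )
    return TPMatrix(counts, probs, undefined)


def make_test_block(
    lexicon: Lexicon, seed: int | np.random.Generator
) -> list[TestItem]:
    """One recognition block: 18 isolated duplets, 9 Words and 9 Part-words.

    Words repeat each lexicon duplet three times; Part-words cycle through
    the six boundary pairs (three drawn twice). The unstructured feature of
    each test token is resampled under the no-repeat constraint. Order is
    shuffled; SOAs are uniform on [2.0, 2.3] s.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    word_pairs = [d for d in lexicon.words for _ in range(3)]
    pw = list(lexicon.partwords)
    pw_pairs = pw + [pw[i] for i in rng.choice(len(pw), size=3, replace=False)]
    labelled = [("word", p) for p in word_pairs] + [("partword", p) for p in pw_pairs]
    order = rng.permutation(len(labelled))
    items = []
    for k in order:
        kind, pair = labelled[k]
        u = int(rng.integers(N_IDS))
        u2 = int(rng.choice([i for i in range(N_IDS) if i != u]))
        ids1, ids2 = (pair[0], u), (pair[1], u2)
        if lexicon.structured_feature is Feature.phoneme:
            toks = (Token(*ids1), Token(*ids2))
        else:
            toks = (Token(ids1[1], ids1[0]), Token(ids2[1], ids2[0]))
        soa = float(rng.uniform(2.0, 2.3))
        items.append(TestItem(toks, kind, soa))
    return items


def test_block_events(
    items: Sequence[TestItem], start_s: float = 0.0
) -> pd.DataFrame:
    """Events table for a test block: one row per item (duplet onset)."""
    onsets, rows = [], []
    t = start_s
    for it in items:
        onsets.append(t)
        rows.append(
            {
                "onset": t,
                "duration": DUPLET_S,
                "item_type": it.item_type,
                "syllables": "".join(SYLLABLES[tok.syllable] for tok in it.pair),
                "voices": "-".join(VOICES[tok.voice] for tok in it.pair),
                "soa": it.soa_s,
            }
        )
        t += it.soa_s
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# independent audit


def check_stream_constraints(stream: Stream) -> list[str]:
    """Brute-force scan for constraint violations; returns messages (empty if clean).

    Checks, for each feature, the no-repeat and no-ABAB rules at the level
    at which they apply: duplet identity for the structured feature of a
    structured stream, per-token feature id otherwise. Also audits the
    within-duplet TP=1 property against the lexicon.
    """
    problems: list[str] = []

    def scan(seq: Sequence[int], label: str) -> None:
        for i in range(1, len(seq)):
            if seq[i] == seq[i - 1]:
                problems.append(f"{label}: repeat at {i}")
        for i in range(3, len(seq)):
            if seq[i - 3] == seq[i - 1] and seq[i - 2] == seq[i]:
                problems.append(f"{label}: ABAB alternation ending at {i}")

    for feature in Feature:
        ids = stream.feature_ids(feature)
        if stream.lexicon is not None and feature is stream.lexicon.structured_feature:
            pair_to_duplet = {d: k for k, d in enumerate(stream.lexicon.duplets)}
            if len(ids) % 2:
                problems.append("structured stream has odd token count")
                continue
            duplets = []
            for i in range(0, len(ids), 2):
                d = (ids[i], ids[i + 1])
                if d not in pair_to_duplet:
                    problems.append(f"non-lexicon duplet {d} at token {i}")
                else:
                    duplets.append(pair_to_duplet[d])
            scan(duplets, f"{feature.value} duplets")
        else:
            scan(ids, f"{feature.value} ids")
    return problems
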