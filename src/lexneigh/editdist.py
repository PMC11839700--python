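"""Symbol tokenization and Levenshtein machinery.

Words are compared as sequences of atomic symbols: extended graphemes for
the orthographic dimension (a base character plus its combining marks, so
composed and decomposed spellings of the same accented letter are one
symbol) and phoneme tokens for the phonological dimension.  All distances
are unit-cost Levenshtein distances over those symbols; a transposition
counts as two edits.

Two words are *density neighbors* when their distance is exactly 1
(one substitution, addition, or deletion) and *substitution neighbors*
(Coltheart-style) when they have equal length and differ at exactly one
position.  A *phonographic neighbor* differs by one letter AND one phoneme
simultaneously.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping

ORTH = "orth"
PHON = "phon"
PG = "pg"

#: IPA primary/secondary stress marks and the syllable separator.
STRESS_MARKS = frozenset({"ˈ", "ˌ", "."})
#: Length marks that modify the preceding phoneme.
LENGTH_MARKS = frozenset({"ː", "ˑ"})
#: Tie bars joining two base symbols into one affricate/diphthong token.
TIE_BARS = frozenset({"͡", "͜"})


class TokenizationError(ValueError):
    """Raised when a string cannot be segmented into symbols."""


class DimensionMismatchError(ValueError):
    """Raised when sequences from different dimensions are compared."""


@dataclass(frozen=True)
class SymbolSeq:
    """An immutable sequence of opaque symbols tagged by dimension."""

    symbols: tuple[str, ...]
    dimension: str = ORTH

    def __post_init__(self) -> None:
        if not self.symbols:
            raise TokenizationError("a symbol sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "".join(self.symbols)


@dataclass(frozen=True)
class TokenizationPolicy:
    """How an IPA string is segmented into phoneme tokens.

    ``strip_marks`` are deleted outright (stress, syllable dots);
    ``attach_to_previous`` merge into the preceding base token (length
    marks; combining diacritics are always attached); ``join_pairs``
    makes a tie bar fuse its two base symbols into one token.
    """

    strip_marks: frozenset[str] = STRESS_MARKS
    attach_to_previous: frozenset[str] = LENGTH_MARKS
    join_pairs: bool = True


DEFAULT_IPA_POLICY = TokenizationPolicy()


def _is_combining(ch: str) -> bool:
    return unicodedata.combining(ch) != 0


def tokenize_orth(word: str) -> SymbolSeq:
    """Segment an orthographic form into extended graphemes.

    The string is NFC-normalized first, so ``"café"`` spelled with a
    combining accent and with a precomposed é tokenize identically; the
    token count is the word's letter length.
    """
    if not word:
        raise TokenizationError("cannot tokenize an empty word")
    word = unicodedata.normalize("NFC", word)
    tokens: list[str] = []
    for ch in word:
        if tokens and _is_combining(ch):
            tokens[-1] += ch
        else:
            tokens.append(ch)
    return SymbolSeq(tuple(tokens), ORTH)


def tokenize_ipa(ipa: str, policy: TokenizationPolicy = DEFAULT_IPA_POLICY) -> SymbolSeq:
    """Segment an IPA transcription into phoneme tokens.

    Stress marks are stripped; length marks and combining diacritics
    attach to the preceding base symbol; tie-barred pairs (t͡ʃ) form a
    single token when ``policy.join_pairs`` is set.
    """
    if not ipa:
        raise TokenizationError("cannot tokenize an empty transcription")
    tokens: list[str] = []
    join_next = False
    for ch in ipa:
        if ch in policy.strip_marks or ch.isspace():
            continue
        if ch in TIE_BARS:
            if policy.join_pairs and tokens:
                tokens[-1] += ch
                join_next = True
            continue
        if tokens and (ch in policy.attach_to_previous or _is_combining(ch) or join_next):
            tokens[-1] += ch
            join_next = False
        else:
            tokens.append(ch)
    if not tokens:
        raise TokenizationError(f"transcription {ipa!r} is empty after mark stripping")
    return SymbolSeq(tuple(tokens), PHON)


def _check_same_dimension(a: SymbolSeq, b: SymbolSeq) -> None:
    if a.dimension != b.dimension:
        raise DimensionMismatchError(
            f"cannot compare a {a.dimension!r} sequence with a {b.dimension!r} sequence"
        )


def levenshtein(a: SymbolSeq, b: SymbolSeq) -> int:
    """Unit-cost edit distance (substitution, addition, deletion)."""
    _check_same_dimension(a, b)
    return _lev(a.symbols, b.symbols)


def _lev(sa: tuple[str, ...], sb: tuple[str, ...]) -> int:
    # two-row DP; inner loop kept tight, it dominates whole-lexicon scans
    if sa == sb:
        return 0
    if len(sa) < len(sb):
        sa, sb = sb, sa
    if not sb:
        return len(sa)
    prev = list(range(len(sb) + 1))
    for i, ca in enumerate(sa, 1):
        cur = [i]
        append = cur.append
        prev_j = prev[0]
        for j, cb in enumerate(sb, 1):
            cost = prev_j if ca == cb else prev_j + 1
            prev_j = prev[j]
            d = prev_j + 1
            if d < cost:
                cost = d
            d = cur[j - 1] + 1
            if d < cost:
                cost = d
            append(cost)
        prev = cur
    return prev[-1]


def is_substitution_neighbor(a: SymbolSeq, b: SymbolSeq) -> bool:
    """True iff equal length and exactly one position differs."""
    _check_same_dimension(a, b)
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a.symbols, b.symbols)) == 1


def is_density_neighbor(a: SymbolSeq, b: SymbolSeq) -> bool:
    """True iff the edit distance is exactly 1."""
    return levenshtein(a, b) == 1


def is_phonographic_neighbor(
    orth_a: SymbolSeq, phon_a: SymbolSeq, orth_b: SymbolSeq, phon_b: SymbolSeq
) -> bool:
    """True iff the pair differs by exactly one letter AND one phoneme."""
    for seq in (phon_a, phon_b):
        if seq is None:
            raise ValueError("phonographic comparison requires both transcriptions")
    return levenshtein(orth_a, orth_b) == 1 and levenshtein(phon_a, phon_b) == 1


class NeighborIndex:
    """Deletion-variant index for fast retrieval of distance-1 entries.

    Every sequence is keyed by itself and by each of its one-symbol
    deletions; two sequences at distance <= 1 necessarily share a key.
    Shared keys can also arise at distance 2 (e.g. "abc"/"bca" share
    "bc"), so candidates are verified with the exact distance.
    """

    def __init__(self, seqs: Mapping[str, SymbolSeq]):
        self._seqs = dict(seqs)
        self._buckets: dict[tuple[str, ...], list[str]] = {}
        for form, seq in self._seqs.items():
            for variant in self._variants(seq.symbols):
                self._buckets.setdefault(variant, []).append(form)

    @staticmethod
    def _variants(symbols: tuple[str, ...]) -> Iterable[tuple[str, ...]]:
        yield symbols
        for i in range(len(symbols)):
            yield symbols[:i] + symbols[i + 1 :]

    def neighbors_of(self, target: SymbolSeq) -> set[str]:
        """Forms whose sequence is at edit distance exactly 1 from target."""
        candidates: set[str] = set()
        for variant in self._variants(target.symbols):
            candidates.update(self._buckets.get(variant, ()))
        tsym = target.symbols
        return {
            form
            for form in candidates
            if self._seqs[form].symbols != tsym and _lev(tsym, self._seqs[form].symbols) == 1
        }

    def identical_to(self, target: SymbolSeq) -> set[str]:
        """Forms whose sequence equals the target's (distance 0)."""
        tsym = target.symbols
        return {f for f in self._buckets.get(tsym, ()) if self._seqs[f].symbols == tsym}


def candidate_neighbors(target: SymbolSeq, seqs: Mapping[str, SymbolSeq]) -> set[str]:
    """All forms in ``seqs`` at edit distance exactly 1 from ``target``.

    Equivalent to a full pairwise Levenshtein scan but retrieved through
    a deletion-variant index.
    """
    return NeighborIndex(seqs).neighbors_of(target)
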