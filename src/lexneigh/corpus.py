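"""Five-step corpus cleaning and frequency transforms.

A raw frequency list becomes a reference lexicon by (1) dropping words
outside the target script, (2) dropping stopwords, (3) enforcing word
length limits, (4) dropping rare words below a per-million threshold,
and (5) capping the lexicon at the k most frequent types.  Per-million
frequencies always use the token total of the raw corpus as denominator:
filtering removes types, not corpus size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import LanguageConfig, Lexicon
from .editdist import tokenize_orth

#: Words rarer than this (occurrences per million tokens) are excluded.
DEFAULT_MIN_FPM = 0.34
#: Maximum lexicon size after cleaning.
DEFAULT_CAP = 30_000


@dataclass
class CleaningReport:
    """Word types removed at each cleaning step, plus the retained total."""

    input_types: int = 0
    removed_script: int = 0
    removed_stopword: int = 0
    removed_length: int = 0
    removed_frequency: int = 0
    removed_cap: int = 0
    retained: int = 0

    @property
    def total_removed(self) -> int:
        return (self.removed_script + self.removed_stopword + self.removed_length
                + self.removed_frequency + self.removed_cap)


def filter_script(lex: Lexicon, valid_chars: frozenset[str] | set[str]) -> tuple[Lexicon, int]:
    """Retain entries written entirely in the valid character set."""
    if not valid_chars:
        raise ValueError("valid_chars must be non-empty")
    valid = frozenset(valid_chars)
    kept = {w: e for w, e in lex.entries.items() if all(ch in valid for ch in w)}
    return lex.replace_entries(kept), len(lex) - len(kept)


def filter_stopwords(lex: Lexicon, stopwords: frozenset[str] | set[str]) -> tuple[Lexicon, int]:
    """Remove entries whose form appears in the stopword list."""
    stop = {s.lower() for s in stopwords}
    kept = {w: e for w, e in lex.entries.items() if w not in stop}
    return lex.replace_entries(kept), len(lex) - len(kept)


def filter_length(lex: Lexicon, min_len: int = 2, max_len: int = 25) -> tuple[Lexicon, int]:
    """Retain entries whose letter count lies in [min_len, max_len]."""
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    kept = {
        w: e for w, e in lex.entries.items()
        if min_len <= len(tokenize_orth(w)) <= max_len
    }
    return lex.replace_entries(kept), len(lex) - len(kept)


def compute_fpm(raw_freq: float, corpus_tokens: float) -> float:
    """Occurrences per million corpus tokens."""
    if corpus_tokens <= 0:
        raise ZeroDivisionError("corpus_tokens must be positive")
    if raw_freq < 0:
        raise ValueError("raw_freq must be non-negative")
    return raw_freq / corpus_tokens * 1_000_000


def compute_zipf(fpm: float) -> float:
    """Zipf value: log10 of the per-billion count, i.e. log10(fpm) + 3.

    Maps 0.001 fpm to 0 and 10,000 fpm to 7, so everyday vocabulary
    spans roughly 1 (very rare) to 7 (function words).  Undefined at
    fpm <= 0; no smoothing is applied.
    """
    if fpm <= 0:
        raise ValueError("Zipf is undefined for non-positive fpm")
    return math.log10(fpm) + 3.0


def filter_frequency(lex: Lexicon, min_fpm: float = DEFAULT_MIN_FPM) -> tuple[Lexicon, int]:
    """Retain entries at or above the per-million threshold.

    Only strictly rarer entries are excluded, so one at exactly the
    threshold stays; the comparison carries a tiny relative tolerance so
    a count that lands on the threshold up to float rounding (e.g.
    34 / 100M tokens vs 0.34) is treated as on the boundary, not below it.
    """
    missing = [w for w, e in lex.entries.items() if e.fpm is None]
    if missing:
        raise ValueError(f"fpm missing for {len(missing)} entries (e.g. {missing[0]!r})")
    cutoff = min_fpm - abs(min_fpm) * 1e-9
    kept = {w: e for w, e in lex.entries.items() if e.fpm >= cutoff}
    return lex.replace_entries(kept), len(lex) - len(kept)


def cap_top_k(lex: Lexicon, k: int = DEFAULT_CAP) -> tuple[Lexicon, int]:
    """Retain the k highest-raw-frequency entries.

    Boundary ties break by ascending lexicographic order of the form,
    so the result is deterministic across runs and platforms.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(lex) <= k:
        return lex.replace_entries(dict(lex.entries)), 0
    ranked = sorted(lex.entries.items(), key=lambda kv: (-(kv[1].raw_freq or 0.0), kv[0]))
    kept = dict(ranked[:k])
    return lex.replace_entries(kept), len(lex) - k


def build_database(
    raw: Lexicon,
    config: LanguageConfig | None = None,
    min_fpm: float = DEFAULT_MIN_FPM,
    k: int = DEFAULT_CAP,
) -> tuple[Lexicon, CleaningReport]:
    """Run the full cleaning pipeline and populate fpm/Zipf.

    Steps apply in fixed order: script -> stopwords -> length ->
    frequency threshold -> top-k cap.  The script step is skipped (zero
    removals) when the config supplies no character set.
    """
    config = config or raw.config
    report = CleaningReport(input_types=len(raw))

    tokens = raw.corpus_tokens
    if tokens is None:
        tokens = sum(e.raw_freq or 0.0 for e in raw)
    if tokens <= 0:
        raise ValueError("cannot build a database without a positive corpus token total")
    entries = {}
    for w, e in raw.entries.items():
        fpm = e.fpm if e.raw_freq is None else compute_fpm(e.raw_freq, tokens)
        zipf = compute_zipf(fpm) if fpm and fpm > 0 else None
        entries[w] = type(e)(word=w, ipa=e.ipa, raw_freq=e.raw_freq, fpm=fpm, zipf=zipf)
    lex = Lexicon(entries, corpus_tokens=tokens, config=config)

    if config.valid_chars:
        lex, report.removed_script = filter_script(lex, config.valid_chars)
    lex, report.removed_stopword = filter_stopwords(lex, config.stopwords)
    lex, report.removed_length = filter_length(lex, config.min_len, config.max_len)
    lex, report.removed_frequency = filter_frequency(lex, min_fpm)
    lex, report.removed_cap = cap_top_k(lex, k)
    report.retained = len(lex)
    return lex, report
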