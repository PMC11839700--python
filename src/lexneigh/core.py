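"""Domain types and table IO for lexicons, query lists, and measure output.

A :class:`Lexicon` is a keyed collection of word types with frequency
information (raw count, occurrences per million tokens, Zipf value) and
optional phonemic transcriptions.  Lookups are case-insensitive (forms
are lower-cased on ingest) but diacritic-sensitive: "café" and "cafe"
are distinct entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import pandas as pd

#: Intra-cell separator for serialized neighbor lists.
LIST_SEP = ";"

LINGUISTIC_FIELDS = ("num_letters", "num_phonemes", "IPA")
FREQUENCY_FIELDS = ("raw_freq", "freq_per_m", "zipf")
ORTH_FIELDS = (
    "orth_N", "orth_N_nbrs", "orth_density", "orth_density_nbrs",
    "OLD20", "OLD20_k", "orth_C", "orth_2hop_density",
    "orth_nbr_fpm_m", "orth_nbr_fpm_SD", "orth_nbr_fpm_higher_m", "orth_nbr_fpm_lower_m",
    "orth_nbr_zipf_m", "orth_nbr_zipf_SD", "orth_nbr_zipf_higher_m", "orth_nbr_zipf_lower_m",
)
PHON_FIELDS = (
    "phon_N", "phon_N_nbrs", "phon_density", "phon_density_nbrs",
    "PLD20", "PLD20_k", "phon_C", "phon_2hop_density",
    "phon_nbr_fpm_m", "phon_nbr_fpm_SD", "phon_nbr_fpm_higher_m", "phon_nbr_fpm_lower_m",
    "phon_nbr_zipf_m", "phon_nbr_zipf_SD", "phon_nbr_zipf_higher_m", "phon_nbr_zipf_lower_m",
)
PG_FIELDS = (
    "pg_N", "pg_N_nbrs", "pg_density", "pg_density_nbrs",
    "PGLD20", "PGLD20_k", "pg_C", "pg_2hop_density",
    "pg_nbr_fpm_m", "pg_nbr_fpm_SD", "pg_nbr_fpm_higher_m", "pg_nbr_fpm_lower_m",
    "pg_nbr_zipf_m", "pg_nbr_zipf_SD", "pg_nbr_zipf_higher_m", "pg_nbr_zipf_lower_m",
)
ALL_FIELDS = ("word",) + LINGUISTIC_FIELDS + FREQUENCY_FIELDS + ORTH_FIELDS + PHON_FIELDS + PG_FIELDS

#: Output fields holding neighbor-form lists.
LIST_FIELDS = frozenset(f for f in ALL_FIELDS if f.endswith("_nbrs"))


class ColumnError(ValueError):
    """A required column is missing or misnamed."""


class EmptyInputError(ValueError):
    """An input table contained no usable rows."""


@dataclass
class LanguageConfig:
    """Per-language settings for corpus cleaning and tokenization."""

    language_code: str = "und"
    valid_chars: frozenset[str] | None = None
    stopwords: frozenset[str] = frozenset()
    max_len: int = 25
    min_len: int = 2

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")


#: Language-specific maximum word lengths reported in lexical databases;
#: everything else falls back to a conservative default of 25.
MAX_LEN_BY_LANGUAGE = {"hi": 17, "en": 20, "fr": 20, "es": 20, "de": 27, "nl": 28}


def default_language_config(language_code: str = "und", **overrides) -> LanguageConfig:
    """Config with the documented per-language maximum length defaults."""
    max_len = overrides.pop("max_len", MAX_LEN_BY_LANGUAGE.get(language_code, 25))
    return LanguageConfig(language_code=language_code, max_len=max_len, **overrides)


@dataclass
class LexiconEntry:
    """One word type in the reference lexicon."""

    word: str
    ipa: str | None = None
    raw_freq: float | None = None
    fpm: float | None = None
    zipf: float | None = None


class Lexicon:
    """Mapping from orthographic form to :class:`LexiconEntry`.

    ``corpus_tokens`` is the token total of the source corpus and is the
    denominator for per-million frequencies; it is preserved through
    filtering so a cleaned subset keeps the original normalization.
    """

    def __init__(
        self,
        entries: Mapping[str, LexiconEntry] | Iterable[LexiconEntry],
        corpus_tokens: float | None = None,
        config: LanguageConfig | None = None,
    ):
        if isinstance(entries, Mapping):
            self.entries: dict[str, LexiconEntry] = dict(entries)
        else:
            self.entries = {e.word: e for e in entries}
        for form, entry in self.entries.items():
            if form != entry.word:
                raise ValueError(f"entry keyed {form!r} holds word {entry.word!r}")
            if entry.ipa is not None and not entry.ipa:
                raise ValueError(f"entry {form!r} has an empty transcription")
        self.corpus_tokens = corpus_tokens
        self.config = config or LanguageConfig()
        self._views: dict = {}  # per-dimension adjacency caches (see measures)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, form: str) -> bool:
        return form in self.entries

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries.values())

    def get(self, form: str) -> LexiconEntry | None:
        return self.entries.get(form)

    def replace_entries(self, entries: Mapping[str, LexiconEntry]) -> "Lexicon":
        """A new lexicon with the same corpus total and config."""
        return Lexicon(entries, corpus_tokens=self.corpus_tokens, config=self.config)

    def has_ipa(self) -> bool:
        return any(e.ipa for e in self)


class Query(NamedTuple):
    """One row of a query word list."""

    word: str
    ipa: str | None = None


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".csv":
            return pd.read_csv(path, dtype={"word": str})
        if suffix == ".tsv":
            return pd.read_csv(path, sep="\t", dtype={"word": str})
        if suffix in (".xlsx", ".xls"):
            return pd.read_excel(path, dtype={"word": str})
        if suffix == ".txt":
            # whitespace/tab separated with a header line, or bare one-word-per-line
            df = pd.read_csv(path, sep=r"\s+", dtype=str, engine="python")
            if "word" not in df.columns and len(df.columns) == 1:
                rows = [df.columns[0], *df.iloc[:, 0].tolist()]
                df = pd.DataFrame({"word": rows})
            return df
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path.name}: the input file is empty") from None
    raise ValueError(f"unsupported file format: {path.name!r} (use csv, tsv, txt, or xlsx)")


def _require_word_column(df: pd.DataFrame, path: Path | str) -> None:
    cols = {c.strip().lower(): c for c in df.columns}
    if "word" not in cols:
        raise ColumnError(
            f"{Path(path).name}: expected a column named 'word'; found {list(df.columns)!r}"
        )


def _clean_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def compute_zipf_or_none(fpm: float | None) -> float | None:
    if fpm is None or fpm <= 0:
        return None
    return math.log10(fpm) + 3.0


def read_corpus(path: str | Path, corpus_tokens: float | None = None,
                config: LanguageConfig | None = None) -> Lexicon:
    """Read a reference corpus table into a :class:`Lexicon`.

    The table must have a ``word`` column; optional columns are ``IPA``,
    ``frequency_1`` (raw count) and ``frequency_2`` (per-million).  Forms
    are lower-cased; duplicate rows merge by summing raw counts, with the
    first-seen transcription kept.  When raw counts are present and no
    ``corpus_tokens`` is given, the denominator defaults to their sum.
    """
    df = _read_table(path)
    _require_word_column(df, path)
    df.columns = [c.strip().lower() if c.strip().lower() == "word" else c.strip() for c in df.columns]
    if df.empty:
        raise EmptyInputError(f"{Path(path).name}: the input table is empty")

    colmap = {c.lower(): c for c in df.columns}
    raw_col = next((colmap[c] for c in ("frequency_1", "raw_freq", "frequency") if c in colmap), None)
    fpm_col = next((colmap[c] for c in ("frequency_2", "freq_per_m", "fpm") if c in colmap), None)
    ipa_col = colmap.get("ipa")

    entries: dict[str, LexiconEntry] = {}
    for _, row in df.iterrows():
        word = _clean_str(row["word"])
        if word is None:
            continue
        word = word.lower()
        raw = None
        if raw_col is not None and pd.notna(row[raw_col]):
            raw = float(row[raw_col])
        fpm = None
        if fpm_col is not None and pd.notna(row[fpm_col]):
            fpm = float(row[fpm_col])
        ipa = _clean_str(row[ipa_col]) if ipa_col is not None else None
        if word in entries:
            prior = entries[word]
            if raw is not None:
                prior.raw_freq = (prior.raw_freq or 0.0) + raw
            if prior.ipa is None:
                prior.ipa = ipa
            if prior.fpm is None:
                prior.fpm = fpm
        else:
            entries[word] = LexiconEntry(word=word, ipa=ipa, raw_freq=raw, fpm=fpm)
    if not entries:
        raise EmptyInputError(f"{Path(path).name}: no usable rows")

    if corpus_tokens is None:
        # an entry carrying both a raw count and a per-million value pins
        # down the source corpus total exactly
        for e in entries.values():
            if e.raw_freq and e.fpm:
                corpus_tokens = e.raw_freq / e.fpm * 1_000_000
                break
    if corpus_tokens is None:
        raw_total = sum(e.raw_freq for e in entries.values() if e.raw_freq is not None)
        if raw_total > 0:
            corpus_tokens = raw_total
    for e in entries.values():
        if e.fpm is None and e.raw_freq is not None and corpus_tokens:
            e.fpm = e.raw_freq / corpus_tokens * 1_000_000
        if e.zipf is None:
            e.zipf = compute_zipf_or_none(e.fpm)
    return Lexicon(entries, corpus_tokens=corpus_tokens, config=config)


def read_wordlist(path: str | Path) -> list[Query]:
    """Read a query word list (words or nonwords), preserving input order."""
    df = _read_table(path)
    _require_word_column(df, path)
    df.columns = [c.strip().lower() for c in df.columns]
    queries: list[Query] = []
    for _, row in df.iterrows():
        word = _clean_str(row["word"])
        if word is None:
            continue
        ipa = _clean_str(row["ipa"]) if "ipa" in df.columns else None
        queries.append(Query(word=word.lower(), ipa=ipa))
    if not queries:
        raise EmptyInputError(f"{Path(path).name}: the word list is empty")
    return queries


def write_measures(rows: list[Mapping], path: str | Path) -> None:
    """Write measure rows as UTF-8 CSV with the canonical column order.

    Neighbor lists are serialized into a single cell joined with ``;``;
    missing values become empty cells.
    """
    if not rows:
        raise ValueError("no measure rows to write")
    present = set()
    for row in rows:
        present.update(row.keys())
    columns = [f for f in ALL_FIELDS if f in present]
    columns += [c for c in sorted(present) if c not in ALL_FIELDS]
    records = []
    for row in rows:
        rec = {}
        for col in columns:
            value = row.get(col)
            if col in LIST_FIELDS and value is not None:
                value = LIST_SEP.join(value)
            rec[col] = value
        records.append(rec)
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False, encoding="utf-8")


def read_measures(path: str | Path) -> pd.DataFrame:
    """Read back a measures file, splitting neighbor-list cells."""
    df = pd.read_csv(path, encoding="utf-8")
    for col in df.columns:
        if col in LIST_FIELDS:
            df[col] = df[col].map(
                lambda v: v.split(LIST_SEP) if isinstance(v, str) and v else ([] if isinstance(v, str) else None)
            )
    return df
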