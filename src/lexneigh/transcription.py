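"""Pluggable word-to-IPA provisioning.

Phonological and phonographic measures need transcriptions, but no
grapheme-to-phoneme engine is bundled.  Instead, any object satisfying
:class:`Transcriber` can supply them: a lookup over the lexicon's own
IPA column, a per-letter substitution table (useful for synthetic
lexicons), or an adapter around an external engine such as eSpeak.
"""

from __future__ import annotations

from typing import Mapping, Protocol, runtime_checkable

from .core import Lexicon
from .editdist import tokenize_orth


@runtime_checkable
class Transcriber(Protocol):
    """Maps an orthographic form to an IPA string, or None when unknown."""

    language_code: str

    def transcribe(self, word: str) -> str | None: ...


class LookupTranscriber:
    """Transcribes in-lexicon forms from their stored IPA column."""

    def __init__(self, lex: Lexicon):
        self._table = {w: e.ipa for w, e in lex.entries.items() if e.ipa}
        if not self._table:
            raise ValueError("lexicon has no IPA transcriptions to look up")
        self.language_code = lex.config.language_code

    def transcribe(self, word: str) -> str | None:
        return self._table.get(word.lower())


class TableTranscriber:
    """Transcribes by per-letter substitution from a letter->phoneme table.

    Many-to-one mappings are allowed and create orthography/phonology
    divergence (homophones).  Words containing an unmapped letter return
    None rather than a partial transcription.
    """

    def __init__(self, mapping: Mapping[str, str], language_code: str = "und"):
        if not mapping:
            raise ValueError("the letter->phoneme table is empty")
        self._mapping = dict(mapping)
        self.language_code = language_code

    def transcribe(self, word: str) -> str | None:
        out = []
        for letter in tokenize_orth(word.lower()).symbols:
            phoneme = self._mapping.get(letter)
            if phoneme is None:
                return None
            out.append(phoneme)
        return "".join(out)


def lookup_transcriber(lex: Lexicon) -> LookupTranscriber:
    """Transcriber backed by the lexicon's own IPA column."""
    return LookupTranscriber(lex)


def table_transcriber(mapping: Mapping[str, str], language_code: str = "und") -> TableTranscriber:
    """Transcriber backed by a per-letter substitution table."""
    return TableTranscriber(mapping, language_code)
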