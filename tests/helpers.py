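"""Shared fixtures helpers and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms: edit
distance by naive recursion over first-symbol edits, neighbor retrieval
by full pairwise scan, network measures by explicit pair enumeration.
"""

from __future__ import annotations

import itertools
import math

from lexneigh import Lexicon, LexiconEntry, tokenize_ipa, tokenize_orth
from lexneigh.editdist import ORTH, PG, PHON, SymbolSeq


def lev_recursive(a: tuple, b: tuple) -> int:
    """Edit distance by exhaustive recursion over first-symbol edit choices."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    keep = lev_recursive(a[1:], b[1:]) + (0 if a[0] == b[0] else 1)
    delete = lev_recursive(a[1:], b) + 1
    insert = lev_recursive(a, b[1:]) + 1
    return min(keep, delete, insert)


def all_strings(alphabet: str, max_len: int) -> list[str]:
    """Every non-empty string over the alphabet up to max_len symbols."""
    return [
        "".join(p)
        for L in range(1, max_len + 1)
        for p in itertools.product(alphabet, repeat=L)
    ]


def pairwise_ld1_scan(target_seq: SymbolSeq, seqs: dict[str, SymbolSeq]) -> set[str]:
    """Brute-force set of forms at recursive-oracle distance exactly 1."""
    return {
        form
        for form, seq in seqs.items()
        if lev_recursive(target_seq.symbols, seq.symbols) == 1
    }


def make_lexicon(words, freqs=None, ipas=None, corpus_tokens=None) -> Lexicon:
    """Small hand-built lexicon; fpm/zipf populated when counts are given."""
    words = list(words)
    freqs = list(freqs) if freqs is not None else [None] * len(words)
    ipas = list(ipas) if ipas is not None else [None] * len(words)
    total = corpus_tokens
    if total is None and any(f is not None for f in freqs):
        total = sum(f for f in freqs if f is not None)
    entries = {}
    for w, f, ipa in zip(words, freqs, ipas):
        fpm = None if (f is None or not total) else f / total * 1_000_000
        zipf = None if (fpm is None or fpm <= 0) else math.log10(fpm) + 3
        entries[w] = LexiconEntry(word=w, ipa=ipa, raw_freq=f, fpm=fpm, zipf=zipf)
    return Lexicon(entries, corpus_tokens=total)


def graph_edges(lex: Lexicon, dim: str) -> set[frozenset]:
    """All unordered density-neighbor pairs among entries, by pairwise scan.

    Uses the DP distance (itself cross-validated against the recursive
    oracle) but never the deletion-variant index or the graph code under
    test.
    """
    from lexneigh.editdist import _lev

    forms = [w for w in lex.entries if dim == ORTH or lex.entries[w].ipa]
    orth = {w: tokenize_orth(w) for w in forms}
    phon = {w: tokenize_ipa(lex.entries[w].ipa) for w in forms if lex.entries[w].ipa}
    edges = set()
    for u, v in itertools.combinations(forms, 2):
        d_orth = _lev(orth[u].symbols, orth[v].symbols)
        if dim == ORTH:
            linked = d_orth == 1
        else:
            d_phon = _lev(phon[u].symbols, phon[v].symbols)
            linked = d_phon == 1 if dim == PHON else (d_orth == 1 and d_phon == 1)
        if linked:
            edges.add(frozenset((u, v)))
    return edges
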