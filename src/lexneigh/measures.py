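"""Per-dimension neighborhood measures for words and nonwords.

Given a target (in-lexicon word or ad-hoc nonword) and a reference
lexicon, this module computes, for each of the orthographic (``orth``),
phonological (``phon``) and phonographic (``pg``) dimensions:

* Coltheart's N — same-length entries differing by one substitution;
* neighborhood density — entries at unit edit distance (substitution,
  addition, or deletion), with the neighbor forms themselves;
* OLD20 / PLD20 / PGLD20 — mean distance to the 20 nearest entries;
* the clustering coefficient C = 2E / (k(k-1)) over the target's
  neighbors, where E counts neighbor pairs that are themselves neighbors;
* 2-hop density — cross-connection density between the target's 1-hop
  neighborhood and its distance-2 neighborhood;
* neighbor-frequency statistics on the fpm and Zipf scales.

A target never counts itself: entries at distance 0 (the form itself,
homographs, homophones) are excluded from every measure.  Phonographic
relations require unit distance in *both* channels simultaneously, and
the phonographic nearest-20 distance ranks pairs by
max(orthographic distance, phonological distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

from .core import (
    FREQUENCY_FIELDS,
    Lexicon,
    LexiconEntry,
    Query,
)
from .editdist import (
    ORTH,
    PG,
    PHON,
    NeighborIndex,
    SymbolSeq,
    _lev,
    tokenize_ipa,
    tokenize_orth,
)
from .transcription import Transcriber

DIMENSIONS = (ORTH, PHON, PG)
_PREFIX = {ORTH: "orth", PHON: "phon", PG: "pg"}
_LD_NAME = {ORTH: "OLD20", PHON: "PLD20", PG: "PGLD20"}


class TranscriptionMissingError(ValueError):
    """A phonological/phonographic measure was requested without IPA."""


@dataclass(frozen=True)
class Target:
    """A resolved query: tokenized form plus its lexicon entry, if any."""

    word: str
    orth: SymbolSeq
    phon: SymbolSeq | None
    entry: LexiconEntry | None


@dataclass(frozen=True)
class NeighborFreqStats:
    """Frequency statistics over a target's density neighbors."""

    scale: str
    mean: float | None
    sd: float | None
    higher_mean: float | None
    lower_mean: float | None


@dataclass(frozen=True)
class NeighborhoodProfile:
    """All measures for one target in one dimension."""

    dimension: str
    n_subst: int
    n_subst_neighbors: tuple[str, ...]
    density: int
    neighbors: tuple[str, ...]
    ld20: float | None
    ld20_k: int
    clustering_c: float | None
    two_hop_density: float | None
    fpm_stats: NeighborFreqStats
    zipf_stats: NeighborFreqStats


class DimensionView:
    """Tokenized sequences and distance-1 adjacency for one dimension.

    For ``orth`` every entry participates; for ``phon`` and ``pg`` only
    entries with a transcription do.  The phonographic relation is
    resolved by probing the orthographic deletion-variant index and
    verifying unit phonological distance on the candidates.
    """

    def __init__(self, lex: Lexicon, dim: str):
        if dim not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dim!r}")
        self.dim = dim
        self.lex = lex
        if dim == ORTH:
            self.orth_seqs = {w: tokenize_orth(w) for w in lex.entries}
            self.phon_seqs: dict[str, SymbolSeq] = {}
            self._index = NeighborIndex(self.orth_seqs)
        else:
            with_ipa = {w: e for w, e in lex.entries.items() if e.ipa}
            self.orth_seqs = {w: tokenize_orth(w) for w in with_ipa}
            self.phon_seqs = {w: tokenize_ipa(e.ipa) for w, e in with_ipa.items()}
            self._index = NeighborIndex(self.phon_seqs if dim == PHON else self.orth_seqs)
        self._entry_nbr_cache: dict[str, frozenset[str]] = {}

    @property
    def forms(self) -> Iterable[str]:
        return self.orth_seqs.keys()

    def __len__(self) -> int:
        return len(self.orth_seqs)

    def _seq_pair(self, form: str) -> tuple[SymbolSeq, SymbolSeq | None]:
        return self.orth_seqs[form], self.phon_seqs.get(form)

    def _is_zero(self, target: Target, form: str) -> bool:
        """Distance 0 in this dimension (self, homograph, or homophone)."""
        orth, phon = self._seq_pair(form)
        if self.dim == ORTH:
            return orth.symbols == target.orth.symbols
        if self.dim == PHON:
            return phon.symbols == target.phon.symbols
        return orth.symbols == target.orth.symbols and phon.symbols == target.phon.symbols

    def density_neighbors(self, target: Target) -> set[str]:
        """Forms at unit distance from the target in this dimension."""
        if self.dim == ORTH:
            return self._index.neighbors_of(target.orth)
        if target.phon is None:
            raise TranscriptionMissingError(
                f"{target.word!r}: the {self.dim!r} dimension requires a transcription"
            )
        if self.dim == PHON:
            return self._index.neighbors_of(target.phon)
        # pg: orthographic candidates, verified on the phonological channel
        tp = target.phon.symbols
        return {
            form
            for form in self._index.neighbors_of(target.orth)
            if _lev(tp, self.phon_seqs[form].symbols) == 1
        }

    def substitution_neighbors(self, target: Target) -> set[str]:
        """Density neighbors reachable by substitution only (equal lengths)."""
        nbrs = self.density_neighbors(target)
        if self.dim == ORTH:
            return {f for f in nbrs if len(self.orth_seqs[f]) == len(target.orth)}
        if self.dim == PHON:
            return {f for f in nbrs if len(self.phon_seqs[f]) == len(target.phon)}
        return {
            f for f in nbrs
            if len(self.orth_seqs[f]) == len(target.orth)
            and len(self.phon_seqs[f]) == len(target.phon)
        }

    def entry_neighbors(self, form: str) -> frozenset[str]:
        """Density neighbors of an in-view entry (edges of the word graph)."""
        cached = self._entry_nbr_cache.get(form)
        if cached is not None:
            return cached
        orth, phon = self._seq_pair(form)
        target = Target(word=form, orth=orth, phon=phon, entry=self.lex.get(form))
        nbrs = frozenset(self.density_neighbors(target))
        self._entry_nbr_cache[form] = nbrs
        return nbrs

    def distance(self, target: Target, form: str) -> int:
        """Distance from target to an entry; pg uses max over both channels."""
        orth, phon = self._seq_pair(form)
        if self.dim == ORTH:
            return _lev(target.orth.symbols, orth.symbols)
        if self.dim == PHON:
            return _lev(target.phon.symbols, phon.symbols)
        return max(
            _lev(target.orth.symbols, orth.symbols),
            _lev(target.phon.symbols, phon.symbols),
        )


def get_view(lex: Lexicon, dim: str) -> DimensionView:
    """Per-lexicon cached :class:`DimensionView`."""
    view = lex._views.get(dim)
    if view is None:
        view = DimensionView(lex, dim)
        lex._views[dim] = view
    return view


def resolve_target(
    lex: Lexicon,
    word: str,
    ipa: str | None = None,
    transcriber: Transcriber | None = None,
    need_phon: bool = False,
) -> Target:
    """Tokenize a query, pulling IPA from the query, lexicon, or transcriber."""
    word = word.lower()
    entry = lex.get(word)
    if ipa is None and entry is not None:
        ipa = entry.ipa
    if ipa is None and transcriber is not None:
        ipa = transcriber.transcribe(word)
    phon = tokenize_ipa(ipa) if ipa else None
    if need_phon and phon is None:
        raise TranscriptionMissingError(f"no transcription available for {word!r}")
    return Target(word=word, orth=tokenize_orth(word), phon=phon, entry=entry)


def _as_target(lex, target, dim, ipa, transcriber) -> Target:
    if isinstance(target, Target):
        return target
    return resolve_target(lex, target, ipa=ipa, transcriber=transcriber,
                          need_phon=dim in (PHON, PG))


def coltheart_n(target, lex: Lexicon, dim: str = ORTH, *, ipa: str | None = None,
                transcriber: Transcriber | None = None) -> tuple[int, list[str]]:
    """Count and list of one-substitution (same-length) neighbors."""
    t = _as_target(lex, target, dim, ipa, transcriber)
    nbrs = sorted(get_view(lex, dim).substitution_neighbors(t))
    return len(nbrs), nbrs


def density(target, lex: Lexicon, dim: str = ORTH, *, ipa: str | None = None,
            transcriber: Transcriber | None = None) -> tuple[int, list[str]]:
    """Count and list of unit-edit-distance neighbors."""
    t = _as_target(lex, target, dim, ipa, transcriber)
    nbrs = sorted(get_view(lex, dim).density_neighbors(t))
    return len(nbrs), nbrs


def ldist20(target, lex: Lexicon, dim: str = ORTH, k: int = 20, *,
            ipa: str | None = None,
            transcriber: Transcriber | None = None) -> tuple[float, int]:
    """Mean distance to the k nearest entries (distance-0 entries excluded).

    When fewer than k comparison entries exist, the mean runs over all of
    them and the count actually used is reported alongside.
    """
    t = _as_target(lex, target, dim, ipa, transcriber)
    view = get_view(lex, dim)
    distances = []
    for form in view.forms:
        d = view.distance(t, form)
        if d > 0:
            distances.append(d)
    if not distances:
        raise ValueError(f"no comparison entries for {t.word!r} in dimension {dim!r}")
    distances.sort()
    used = distances[: min(k, len(distances))]
    return sum(used) / len(used), len(used)


def clustering_coefficient(target, lex: Lexicon, dim: str = ORTH, *,
                           ipa: str | None = None,
                           transcriber: Transcriber | None = None) -> float | None:
    """C = 2E / (k(k-1)) over the target's density neighbors.

    E counts unordered neighbor pairs that are themselves density
    neighbors; undefined (None) when the target has fewer than two.
    """
    t = _as_target(lex, target, dim, ipa, transcriber)
    view = get_view(lex, dim)
    nbrs = sorted(view.density_neighbors(t))
    k = len(nbrs)
    if k < 2:
        return None
    edges = 0
    nbr_set = set(nbrs)
    for form in nbrs:
        edges += len(view.entry_neighbors(form) & nbr_set)
    edges //= 2  # each unordered pair seen from both ends
    return 2.0 * edges / (k * (k - 1))


def two_hop_density(target, lex: Lexicon, dim: str = ORTH, *,
                    ipa: str | None = None,
                    transcriber: Transcriber | None = None) -> float | None:
    """Cross-connection density between 1-hop and 2-hop neighborhoods.

    1-hop nodes are the target's density neighbors; 2-hop nodes are
    entries adjacent to at least one 1-hop node, excluding the target
    (and its distance-0 entries) and the 1-hop nodes themselves.
    Returns cross-edges / (|1-hop| * |2-hop|); None when either set is
    empty.
    """
    t = _as_target(lex, target, dim, ipa, transcriber)
    view = get_view(lex, dim)
    one_hop = view.density_neighbors(t)
    if not one_hop:
        return None
    two_hop: set[str] = set()
    for form in one_hop:
        two_hop.update(view.entry_neighbors(form))
    two_hop -= one_hop
    two_hop = {f for f in two_hop if not view._is_zero(t, f)}
    if not two_hop:
        return None
    cross = sum(len(view.entry_neighbors(form) & two_hop) for form in one_hop)
    return cross / (len(one_hop) * len(two_hop))


def neighbor_freq_stats(
    neighbors: Sequence[LexiconEntry],
    target_freq: float | None,
    scale: str = "zipf",
) -> NeighborFreqStats:
    """Mean/SD of neighbor frequencies plus strictly-higher/lower means.

    SD is the sample (n-1) standard deviation, undefined for a single
    neighbor.  Higher/lower means use strict inequality against the
    target's frequency; ties count in neither subset.  For nonword
    targets (no frequency) the split means are undefined.
    """
    attr = "fpm" if scale == "fpm" else "zipf"
    values = [getattr(e, attr) for e in neighbors if getattr(e, attr) is not None]
    if not values:
        return NeighborFreqStats(scale, None, None, None, None)
    m = mean(values)
    sd = stdev(values) if len(values) > 1 else None
    higher = lower = None
    if target_freq is not None:
        hi = [v for v in values if v > target_freq]
        lo = [v for v in values if v < target_freq]
        higher = mean(hi) if hi else None
        lower = mean(lo) if lo else None
    return NeighborFreqStats(scale, m, sd, higher, lower)


def dimension_profile(target: Target, lex: Lexicon, dim: str, k: int = 20) -> NeighborhoodProfile:
    """All measures for one target in one dimension."""
    view = get_view(lex, dim)
    nbr_forms = sorted(view.density_neighbors(target))
    subst = sorted(view.substitution_neighbors(target))
    try:
        ld, ld_k = ldist20(target, lex, dim, k=k)
    except ValueError:
        ld, ld_k = None, 0
    target_fpm = target.entry.fpm if target.entry else None
    target_zipf = target.entry.zipf if target.entry else None
    nbr_entries = [lex.entries[f] for f in nbr_forms]
    return NeighborhoodProfile(
        dimension=dim,
        n_subst=len(subst),
        n_subst_neighbors=tuple(subst),
        density=len(nbr_forms),
        neighbors=tuple(nbr_forms),
        ld20=ld,
        ld20_k=ld_k,
        clustering_c=clustering_coefficient(target, lex, dim),
        two_hop_density=two_hop_density(target, lex, dim),
        fpm_stats=neighbor_freq_stats(nbr_entries, target_fpm, "fpm"),
        zipf_stats=neighbor_freq_stats(nbr_entries, target_zipf, "zipf"),
    )


def _profile_fields(prefix: str, ld_name: str, p: NeighborhoodProfile) -> dict:
    return {
        f"{prefix}_N": p.n_subst,
        f"{prefix}_N_nbrs": list(p.n_subst_neighbors),
        f"{prefix}_density": p.density,
        f"{prefix}_density_nbrs": list(p.neighbors),
        ld_name: p.ld20,
        f"{ld_name}_k": p.ld20_k,
        f"{prefix}_C": p.clustering_c,
        f"{prefix}_2hop_density": p.two_hop_density,
        f"{prefix}_nbr_fpm_m": p.fpm_stats.mean,
        f"{prefix}_nbr_fpm_SD": p.fpm_stats.sd,
        f"{prefix}_nbr_fpm_higher_m": p.fpm_stats.higher_mean,
        f"{prefix}_nbr_fpm_lower_m": p.fpm_stats.lower_mean,
        f"{prefix}_nbr_zipf_m": p.zipf_stats.mean,
        f"{prefix}_nbr_zipf_SD": p.zipf_stats.sd,
        f"{prefix}_nbr_zipf_higher_m": p.zipf_stats.higher_mean,
        f"{prefix}_nbr_zipf_lower_m": p.zipf_stats.lower_mean,
    }


def profile(
    query: Query | str,
    lex: Lexicon,
    dims: Sequence[str] = DIMENSIONS,
    selected: set[str] | None = None,
    transcriber: Transcriber | None = None,
    k: int = 20,
) -> tuple[dict, list[str]]:
    """One output row for a word or nonword, plus per-row warnings.

    Fills the fields of the requested dimensions (all by default, or the
    subset named in ``selected``).  In-lexicon words also receive their
    raw/fpm/Zipf frequency fields; a missing transcription downgrades the
    phonological/phonographic dimensions to a warning instead of failing
    the row.
    """
    if isinstance(query, str):
        query = Query(word=query)
    warnings: list[str] = []
    need_phon = any(d in (PHON, PG) for d in dims)
    target = resolve_target(lex, query.word, ipa=query.ipa, transcriber=transcriber,
                            need_phon=False)
    row: dict = {"word": target.word, "num_letters": len(target.orth)}
    if target.phon is not None:
        row["num_phonemes"] = len(target.phon)
        row["IPA"] = str(target.phon)
    elif need_phon:
        warnings.append(
            f"{target.word!r}: no transcription available; "
            "phonological/phonographic measures left missing"
        )
    if target.entry is not None:
        row["raw_freq"] = target.entry.raw_freq
        row["freq_per_m"] = target.entry.fpm
        row["zipf"] = target.entry.zipf
    for dim in dims:
        if dim in (PHON, PG) and target.phon is None:
            continue
        try:
            p = dimension_profile(target, lex, dim, k=k)
        except TranscriptionMissingError as exc:
            warnings.append(str(exc))
            continue
        row.update(_profile_fields(_PREFIX[dim], _LD_NAME[dim], p))
    if selected is not None:
        keep = set(selected) | {"word"}
        row = {f: v for f, v in row.items() if f in keep}
    return row, warnings
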