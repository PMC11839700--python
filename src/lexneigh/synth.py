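"""Synthetic lexicons and behavioral tables with known structure.

The lexicon generator emulates a cleaned subtitle-style frequency list:
distinct word forms over a small alphabet, rank-law (Zipfian) raw
frequencies scaled to a corpus token total, and a letter-to-phoneme
table whose many-to-one mappings create orthography/phonology
divergence.  The behavioral generator produces response times that are
linear in Zipf frequency, word length, and one neighborhood measure,
plus Gaussian noise — the data-generating process the hierarchical
regression in :mod:`lexneigh.validation` is designed to recover.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LanguageConfig, Lexicon, LexiconEntry
from .corpus import compute_fpm, compute_zipf
from .transcription import TableTranscriber

#: Letter->phoneme table over the default 10-letter alphabet.  'c'->'k'
#: merges with no letter, but 'e'->'i' collides with 'i'->'i', so forms
#: differing only in e/i become homophones: phonological neighborhoods
#: diverge from orthographic ones.
DEFAULT_PHONEME_MAP = {
    "a": "æ", "b": "b", "c": "k", "d": "d", "e": "i",
    "f": "f", "g": "ɡ", "h": "h", "i": "i", "j": "ʒ",
}


@dataclass
class LexiconSpec:
    """Parameters of a synthetic frequency-ranked lexicon."""

    alphabet: tuple[str, ...] = tuple("abcdefghij")
    n_words: int = 1000
    length_range: tuple[int, int] = (2, 7)
    zipf_exponent: float = 1.0
    corpus_tokens: int = 1_000_000
    phoneme_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PHONEME_MAP))
    seed: int = 0


@dataclass
class BehavioralSpec:
    """Coefficients of the simulated response-time model.

    RT = intercept + beta_freq*zipf + beta_len*length
         + beta_measure*measure + N(0, noise_sd).
    Responses are modeled in standardized (z-score) units rather than
    milliseconds, so coefficients are effect sizes relative to a unit
    residual: the defaults encode the usual dominant facilitatory
    frequency effect and a smaller inhibitory length effect.  Accuracy
    is a logistic transform of the negated, standardized linear
    predictor (fast words are accurate words) plus clipped Gaussian
    noise.
    """

    intercept: float = 0.0
    beta_freq: float = -0.3
    beta_len: float = 0.15
    beta_measure: float = 0.0
    noise_sd: float = 1.0
    acc_slope: float = 1.0
    acc_noise_sd: float = 0.02
    seed: int = 0


def _capacity(alphabet_size: int, length_range: tuple[int, int]) -> int:
    lo, hi = length_range
    return sum(alphabet_size ** L for L in range(lo, hi + 1))


def generate_lexicon(spec: LexiconSpec) -> Lexicon:
    """Sample a distinct-form lexicon with rank-law frequencies.

    Frequency of the word at rank r is proportional to r**(-exponent),
    scaled so raw counts sum to approximately ``corpus_tokens`` (each
    word keeps at least one occurrence).  Fully determined by the seed.
    """
    lo, hi = spec.length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    cap = _capacity(len(spec.alphabet), spec.length_range)
    if spec.n_words > cap:
        raise ValueError(
            f"alphabet supports only {cap} distinct forms, {spec.n_words} requested"
        )
    rng = np.random.default_rng(spec.seed)
    forms: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(forms) < spec.n_words:
        length = int(rng.integers(lo, hi + 1))
        word = "".join(rng.choice(spec.alphabet, size=length))
        if word not in seen:
            seen.add(word)
            forms.append(word)
        attempts += 1
        if attempts > 200 * spec.n_words:
            # dense request relative to capacity: fall back to exhaustive pool
            pool = [
                "".join(p)
                for L in range(lo, hi + 1)
                for p in itertools.product(spec.alphabet, repeat=L)
                if "".join(p) not in seen
            ]
            extra = rng.choice(len(pool), size=spec.n_words - len(forms), replace=False)
            forms.extend(pool[i] for i in sorted(extra))
            break

    ranks = np.arange(1, spec.n_words + 1, dtype=float)
    weights = ranks ** (-spec.zipf_exponent)
    raw = np.maximum(1, np.rint(weights / weights.sum() * spec.corpus_tokens)).astype(int)

    transcriber = TableTranscriber(spec.phoneme_map) if spec.phoneme_map else None
    entries = {}
    for word, count in zip(forms, raw):
        fpm = compute_fpm(float(count), spec.corpus_tokens)
        entries[word] = LexiconEntry(
            word=word,
            ipa=transcriber.transcribe(word) if transcriber else None,
            raw_freq=float(count),
            fpm=fpm,
            zipf=compute_zipf(fpm),
        )
    config = LanguageConfig(language_code="syn", valid_chars=frozenset(spec.alphabet))
    return Lexicon(entries, corpus_tokens=spec.corpus_tokens, config=config)


def generate_behavioral(
    lex: Lexicon,
    measure_values: dict[str, float] | pd.Series,
    spec: BehavioralSpec,
    measure_name: str = "measure",
) -> pd.DataFrame:
    """Simulate per-word response times and accuracy.

    ``measure_values`` maps every word to its neighborhood-measure value;
    words missing from the lexicon or the mapping raise.  Columns:
    word, rt, accuracy, zipf, length, and the measure.
    """
    words = list(measure_values.keys() if isinstance(measure_values, dict) else measure_values.index)
    missing = [w for w in words if w not in lex.entries]
    if missing:
        raise ValueError(f"measure values supplied for non-lexicon words: {missing[:3]}")
    rng = np.random.default_rng(spec.seed)
    zipf = np.array([lex.entries[w].zipf for w in words], dtype=float)
    if np.isnan(zipf).any():
        raise ValueError("every word needs a Zipf value to simulate behavior")
    length = np.array([len(w) for w in words], dtype=float)
    meas = np.array([measure_values[w] for w in words], dtype=float)

    lp = spec.intercept + spec.beta_freq * zipf + spec.beta_len * length + spec.beta_measure * meas
    rt = lp + rng.normal(0.0, spec.noise_sd, size=len(words))

    sd = lp.std()
    z = (lp - lp.mean()) / sd if sd > 0 else np.zeros_like(lp)
    p = 1.0 / (1.0 + np.exp(spec.acc_slope * z - 2.0))  # slower predicted -> less accurate
    accuracy = np.clip(p + rng.normal(0.0, spec.acc_noise_sd, size=len(words)), 0.0, 1.0)

    return pd.DataFrame(
        {
            "word": words,
            "rt": rt,
            "accuracy": accuracy,
            "zipf": zipf,
            "length": length,
            measure_name: meas,
        }
    )
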