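"""Generative stochastic model of a three-level speech corpus.

Phoneme durations are lognormal, ``Y = exp(X)`` with Gaussian ``X``; a
word of ``n`` phonemes has duration ``Z = sum_i Y_i``; word types follow
a Zipf rank-frequency law and their mean durations grow logarithmically
with rank (the size-rank form), which makes Zipf, brevity and size-rank
jointly consistent in the generated data.  Breath groups are runs of
words separated by pauses longer than the segmentation threshold.

A coarsening operator degrades durations to a finite precision grid with
a lower-bound floor, emulating the resolution limits of real aligned
corpora (10 ms grid, 30 ms minimum observable duration).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import CorpusHierarchy
from .exceptions import ValidationError

__all__ = [
    "SynthSpec",
    "sample_phonemes",
    "compose_words",
    "coarsen",
    "generate_corpus",
    "vocabulary",
]


def _truncated_geometric(q: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1)
    p = (1.0 - q) ** (k - 1) * q
    return p / p.sum()


# phonemes per word: truncated geometric on 1..8 with mean ~3.7, matching the
# phoneme:word token ratio of a read-speech corpus; a stand-in for the unknown
# empirical distribution of a real corpus.
_DEFAULT_N_DIST = _truncated_geometric(0.144761, 8)
# words per breath group: truncated geometric on 1..20 with mean ~4.0
_DEFAULT_BG_DIST = _truncated_geometric(0.245608, 20)

#: 32 single-codepoint phoneme symbols (synthetic inventory)
_ALPHABET = "abcdefghijklmnopqrstuvwxyz" + "αβγδεζ"


def _normalize_dist(dist, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Accept a prob vector over 1..K or a (values, probs) pair."""
    if isinstance(dist, tuple) and len(dist) == 2:
        values = np.asarray(dist[0], dtype=int)
        probs = np.asarray(dist[1], dtype=float)
    else:
        probs = np.asarray(dist, dtype=float)
        values = np.arange(1, probs.size + 1)
    if values.size != probs.size or probs.size == 0:
        raise ValidationError(f"{name}: values and probabilities must align")
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValidationError(f"{name}: probabilities must be non-negative and sum to 1")
    if (values[probs > 0] < 1).any():
        raise ValidationError(f"{name}: support must be positive integers (no mass at 0)")
    return values, probs / probs.sum()


@dataclass
class SynthSpec:
    """Parameters of the generative model.

    mu, sigma
        Location/scale of the phoneme log-duration (log-seconds); the
        median phoneme duration is ``exp(mu)``.
    n_dist, bg_len_dist
        Distributions of phonemes-per-word and words-per-breath-group;
        either a probability vector over 1..K or a ``(values, probs)`` pair.
    zipf_alpha, brevity_lambda, vocab_size, ell_min
        Word-type structure: token probability ``p(r) ∝ r^-alpha`` and
        per-type mean duration ``ell_r = ell_min + (alpha/lambda)·log r``
        (seconds), over ``vocab_size`` types.
    precision, tau
        Coarsening grid (s) and lower-bound duration floor (s).
    seed
        Mandatory integer seed; all randomness flows through it.
    """

    seed: int
    mu: float = -3.0
    sigma: float = 0.6
    n_dist: object = field(default_factory=lambda: _DEFAULT_N_DIST.copy())
    zipf_alpha: float = 1.41
    brevity_lambda: float = 24.1
    vocab_size: int = 4000
    ell_min: float = 0.10
    bg_len_dist: object = field(default_factory=lambda: _DEFAULT_BG_DIST.copy())
    precision: float = 0.01
    tau: float = 0.03
    n_speakers: int = 4
    alphabet_size: int = 32
    bg_pause: float = 0.5

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.precision <= 0:
            raise ValidationError("precision must be > 0")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if self.vocab_size < 1:
            raise ValidationError("vocab_size must be >= 1")
        if self.brevity_lambda <= 0 or self.zipf_alpha <= 0:
            raise ValidationError("zipf_alpha and brevity_lambda must be > 0")
        if not 1 <= self.alphabet_size <= len(_ALPHABET):
            raise ValidationError(f"alphabet_size must be in 1..{len(_ALPHABET)}")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        _normalize_dist(self.n_dist, "n_dist")
        _normalize_dist(self.bg_len_dist, "bg_len_dist")

    # -- flat key=value (INI) serialization -------------------------------
    def to_config(self, path) -> None:
        cp = configparser.ConfigParser()
        d = {}
        for k in (
            "seed mu sigma zipf_alpha brevity_lambda vocab_size ell_min "
            "precision tau n_speakers alphabet_size bg_pause".split()
        ):
            v = getattr(self, k)
            d[k] = repr(float(v) if isinstance(v, float) else int(v))
        for k in ("n_dist", "bg_len_dist"):
            v, p = _normalize_dist(getattr(self, k), k)
            d[k + "_values"] = ",".join(str(x) for x in v)
            d[k + "_probs"] = ",".join(repr(float(x)) for x in p)
        cp["synth"] = d
        with open(path, "w", encoding="utf-8") as fh:
            cp.write(fh)

    @classmethod
    def from_config(cls, path) -> "SynthSpec":
        cp = configparser.ConfigParser()
        if not cp.read(path, encoding="utf-8") or "synth" not in cp:
            raise ValidationError(f"{path}: not a SynthSpec config (missing [synth])")
        s = cp["synth"]
        if "seed" not in s:
            raise ValidationError(f"{path}: seed is mandatory in config")
        kwargs = dict(
            seed=int(s["seed"]),
            mu=float(s["mu"]),
            sigma=float(s["sigma"]),
            zipf_alpha=float(s["zipf_alpha"]),
            brevity_lambda=float(s["brevity_lambda"]),
            vocab_size=int(s["vocab_size"]),
            ell_min=float(s["ell_min"]),
            precision=float(s["precision"]),
            tau=float(s["tau"]),
            n_speakers=int(s["n_speakers"]),
            alphabet_size=int(s["alphabet_size"]),
            bg_pause=float(s["bg_pause"]),
        )
        for k in ("n_dist", "bg_len_dist"):
            v = np.array([int(x) for x in s[k + "_values"].split(",")])
            p = np.array([float(x) for x in s[k + "_probs"].split(",")])
            kwargs[k] = (v, p)
        return cls(**kwargs)


def _rng(spec: SynthSpec, rng=None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(spec.seed)


def sample_phonemes(spec: SynthSpec, count: int, rng=None) -> np.ndarray:
    """Draw ``count`` i.i.d. phoneme durations ``Y = exp(X)``, X ~ N(mu, sigma^2)."""
    if count < 1:
        raise ValidationError("count must be >= 1")
    r = _rng(spec, rng)
    return np.exp(r.normal(spec.mu, spec.sigma, size=count))


@dataclass
class WordSample:
    """Word durations ``z`` with their phoneme parts (flat, ``word_index`` aligned)."""

    z: np.ndarray
    n: np.ndarray
    parts: np.ndarray
    word_index: np.ndarray

    def parts_of(self, i: int) -> np.ndarray:
        return self.parts[self.word_index == i]


def compose_words(
    spec: SynthSpec, count: int, rng=None, n_values: np.ndarray | None = None
) -> WordSample:
    """Draw word durations ``Z = sum_{i<=n} Y_i`` with ``n ~ n_dist``.

    ``n_values`` overrides the sampled phoneme counts (one per word).
    """
    if count < 1:
        raise ValidationError("count must be >= 1")
    r = _rng(spec, rng)
    if n_values is None:
        values, probs = _normalize_dist(spec.n_dist, "n_dist")
        n = r.choice(values, size=count, p=probs)
    else:
        n = np.asarray(n_values, dtype=int)
        if n.size != count or (n < 1).any():
            raise ValidationError("n_values must give a positive count per word")
    word_index = np.repeat(np.arange(count), n)
    parts = np.exp(r.normal(spec.mu, spec.sigma, size=int(n.sum())))
    z = np.bincount(word_index, weights=parts, minlength=count)
    return WordSample(z=z, n=n, parts=parts, word_index=word_index)


def coarsen(durations, precision: float, tau: float) -> np.ndarray:
    """Round durations to the nearest multiple of ``precision``, then floor at ``tau``.

    Idempotent whenever ``tau`` is a multiple of ``precision``.
    """
    if precision <= 0:
        raise ValidationError("precision must be > 0")
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    d = np.rint(np.asarray(durations, dtype=float) / precision) * precision
    return np.where(d < tau - 1e-12, tau, d)


def vocabulary(spec: SynthSpec, rng=None) -> pd.DataFrame:
    """Build the word-type table of the generative model.

    Columns: ``rank``, ``p`` (token probability ∝ rank^-alpha), ``ell``
    (target mean duration, size-rank form), ``n_ph`` (phoneme count),
    ``scale`` (per-type duration scale so that E[Z] = ell), ``label``.
    """
    r = _rng(spec, rng)
    ranks = np.arange(1, spec.vocab_size + 1)
    p = ranks.astype(float) ** -spec.zipf_alpha
    p /= p.sum()
    ell = spec.ell_min + (spec.zipf_alpha / spec.brevity_lambda) * np.log(ranks)
    mean_y = np.exp(spec.mu + spec.sigma**2 / 2)
    n_ph = np.maximum(1, np.rint(ell / mean_y)).astype(int)
    scale = ell / (n_ph * mean_y)

    alphabet = np.array(list(_ALPHABET[: spec.alphabet_size]))
    wts = 1.0 / np.arange(1, alphabet.size + 1)  # power-law symbol usage
    wts /= wts.sum()
    labels: list[str] = []
    seen: set[str] = set()
    for n in n_ph:
        lab = "".join(r.choice(alphabet, size=n, p=wts))
        tries = 0
        while lab in seen:
            tries += 1
            if tries <= 100:
                lab = "".join(r.choice(alphabet, size=n, p=wts))
            else:  # tiny alphabets: extend by one symbol until unique
                lab = lab + r.choice(alphabet, p=wts)
        seen.add(lab)
        labels.append(lab)
    return pd.DataFrame(
        {"rank": ranks, "p": p, "ell": ell, "n_ph": n_ph, "scale": scale, "label": labels}
    )


def generate_corpus(
    spec: SynthSpec, n_word_tokens: int, coarsened: bool = False
) -> CorpusHierarchy:
    """Generate a fully synthetic, valid :class:`CorpusHierarchy`.

    Word tokens are sampled i.i.d. from the Zipf law over the vocabulary;
    each token's duration is realized by concatenating its type's phoneme
    count of lognormal draws (scaled so the type mean duration follows the
    size-rank form); words are grouped into breath groups whose lengths
    follow ``bg_len_dist``, with inter-BG pauses of ``bg_pause`` seconds.
    With ``coarsened=True`` the phoneme parts are degraded by
    :func:`coarsen` before summing, so resolution artifacts propagate to
    the word and breath-group levels.
    """
    if n_word_tokens < 1:
        raise ValidationError("n_word_tokens must be >= 1")
    r = np.random.default_rng(spec.seed)
    vocab = vocabulary(spec, rng=r)

    counts = r.multinomial(n_word_tokens, vocab["p"].to_numpy())
    token_type = r.permutation(np.repeat(np.arange(spec.vocab_size), counts))

    # breath-group lengths, then speakers round-robin over BGs
    bg_values, bg_probs = _normalize_dist(spec.bg_len_dist, "bg_len_dist")
    mean_len = float((bg_values * bg_probs).sum())
    need = int(np.ceil(n_word_tokens / mean_len)) + 16
    lens = r.choice(bg_values, size=need, p=bg_probs)
    while lens.sum() < n_word_tokens:
        lens = np.concatenate([lens, r.choice(bg_values, size=need, p=bg_probs)])
    ends = np.cumsum(lens)
    n_bg = int(np.searchsorted(ends, n_word_tokens)) + 1
    lens = lens[:n_bg]
    lens[-1] -= int(ends[n_bg - 1] - n_word_tokens)
    bg_of_word = np.repeat(np.arange(n_bg), lens)
    spk_of_bg = np.array([f"s{(i % spec.n_speakers) + 1}" for i in range(n_bg)])
    spk_of_word = spk_of_bg[bg_of_word]

    # reorder words speaker-major (stream order preserved within speaker)
    order = np.argsort(spk_of_word, kind="stable")
    token_type = token_type[order]
    bg_of_word = bg_of_word[order]
    spk_of_word = spk_of_word[order]
    bg_of_word = pd.factorize(bg_of_word)[0]  # renumber in new order

    # realize durations: n_ph draws per token, scaled per type
    n_ph = vocab["n_ph"].to_numpy()
    scale = vocab["scale"].to_numpy()
    n_per = n_ph[token_type]
    total = int(n_per.sum())
    part_word = np.repeat(np.arange(n_word_tokens), n_per)
    parts = np.exp(r.normal(spec.mu, spec.sigma, size=total)) * scale[token_type][part_word]
    if coarsened:
        parts = coarsen(parts, spec.precision, spec.tau)
    z = np.bincount(part_word, weights=parts, minlength=n_word_tokens)

    # timestamps: contiguous within BG, bg_pause between BGs, per speaker
    last_of_bg = np.zeros(n_word_tokens, dtype=bool)
    last_of_bg[-1] = True
    last_of_bg[:-1] = bg_of_word[1:] != bg_of_word[:-1]
    advance = z + np.where(last_of_bg, spec.bg_pause, 0.0)
    word_start = np.empty(n_word_tokens)
    for spk in pd.unique(spk_of_word):
        m = spk_of_word == spk
        a = advance[m]
        word_start[m] = np.concatenate([[0.0], np.cumsum(a)[:-1]])
    word_end = word_start + z

    labels = vocab["label"].to_numpy()
    words = pd.DataFrame(
        {
            "speaker": spk_of_word,
            "label": labels[token_type],
            "start": word_start,
            "end": word_end,
            "t": z,
            "bg": bg_of_word,
        }
    )

    # phoneme tokens: contiguous inside their word
    c = np.cumsum(parts)
    first = np.concatenate([[0], np.cumsum(n_per)[:-1]])
    base = np.repeat(c[first] - parts[first], n_per)
    ph_end_rel = c - base
    ph_start = np.repeat(word_start, n_per) + ph_end_rel - parts
    ph_end = np.repeat(word_start, n_per) + ph_end_rel
    # phoneme labels: the type's symbol sequence
    label_chars = np.array(list("".join(labels)))
    type_off = np.concatenate([[0], np.cumsum(n_ph)[:-1]])
    pos_in_word = np.arange(total) - np.repeat(first, n_per)
    ph_labels = label_chars[type_off[token_type][part_word] + pos_in_word]
    phonemes = pd.DataFrame(
        {
            "speaker": np.repeat(spk_of_word, n_per),
            "label": ph_labels,
            "start": ph_start,
            "end": ph_end,
            "t": parts,
            "word": part_word,
        }
    )

    bg = words.groupby("bg").agg(
        speaker=("speaker", "first"), start=("start", "min"), end=("end", "max")
    )
    bg["t"] = bg["end"] - bg["start"]
    bg = bg.reset_index(drop=True)

    h = CorpusHierarchy(
        phonemes=phonemes, words=words, breath_groups=bg, pause_threshold=min(0.1, spec.bg_pause / 2)
    )
    h.validate()
    return h
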