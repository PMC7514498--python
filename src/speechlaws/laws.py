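"""The six linguistic-law analyses over a :class:`~speechlaws.corpus.CorpusHierarchy`.

Covered laws: lognormality of durations with Gaussian-collapse
diagnostics, Zipf's law for words (Yule family for phonemes),
Herdan-Heaps vocabulary growth in symbolic and physical units, the
brevity law with the optimal-coding exponent lambda_D, the size-rank law
ell ~ theta log r, and the Menzerath-Altmann law at both hierarchy
scales.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import CorpusHierarchy, normalize_label
from .exceptions import FitError, ValidationError
from .fitters import (
    ExponentialFit,
    LognormalFit,
    LoglogFit,
    MenzerathFit,
    PowerLawFit,
    YuleFit,
    fit_exponential,
    fit_loglog,
    fit_lognormal,
    fit_menzerath,
    fit_power_law,
    fit_yule,
)
from .synth import coarsen

__all__ = [
    "LognormalityResult",
    "ZipfResult",
    "HerdanResult",
    "BrevityResult",
    "SizeRankResult",
    "MenzerathResult",
    "analyze_lognormality",
    "analyze_zipf",
    "analyze_herdan",
    "analyze_brevity",
    "analyze_size_rank",
    "analyze_menzerath",
    "predicted_theta",
    "coarsened_durations",
    "rank_frequency_table",
]

_PUNCT = re.compile(r"[^\w]", flags=re.UNICODE)


# ---------------------------------------------------------------- lognormality


def coarsened_durations(h: CorpusHierarchy, precision: float, tau: float) -> dict[str, np.ndarray]:
    """Durations per level after coarsening at the lowest available level.

    Phoneme durations are coarsened directly; word durations are the sums
    of their coarsened phonemes and breath-group durations the sums of
    those words, so resolution artifacts propagate up the hierarchy.
    """
    out: dict[str, np.ndarray] = {}
    if not h.phonemes.empty:
        ph = coarsen(h.durations("phoneme"), precision, tau)
        out["phoneme"] = ph
        w = np.zeros(len(h.words))
        np.add.at(w, h.phonemes["word"].to_numpy(), ph)
    else:
        w = coarsen(h.durations("word"), precision, tau)
    out["word"] = w
    bg = np.zeros(len(h.breath_groups))
    np.add.at(bg, h.words["bg"].to_numpy(), w)
    out["breath_group"] = bg
    return out


@dataclass
class LognormalityResult:
    """Per-level lognormal fits; failures are isolated per level."""

    fits: dict[str, LognormalFit] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    coarsened_fits: dict[str, LognormalFit] | None = None


def analyze_lognormality(
    h: CorpusHierarchy, coarsening: tuple[float, float] | None = None
) -> LognormalityResult:
    """Fit the lognormality law per level; optional coarsening sensitivity.

    ``ks_to_gaussian`` of each fit measures how far the rescaled
    log-durations are from the N(0,1) collapse.  With
    ``coarsening=(precision, tau)`` the analysis is repeated on the
    coarsened corpus for a side-by-side comparison.
    """
    res = LognormalityResult()
    for level in ("phoneme", "word", "breath_group"):
        t = h.durations(level)
        if t.size == 0:
            res.errors[level] = "level absent"
            continue
        try:
            res.fits[level] = fit_lognormal(t)
        except FitError as exc:
            res.errors[level] = str(exc)
    if coarsening is not None:
        precision, tau = coarsening
        res.coarsened_fits = {}
        for level, t in coarsened_durations(h, precision, tau).items():
            try:
                res.coarsened_fits[level] = fit_lognormal(t)
            except FitError as exc:
                res.errors[f"{level} (coarsened)"] = str(exc)
    return res


# ---------------------------------------------------------------- Zipf


def rank_frequency_table(labels: pd.Series) -> pd.DataFrame:
    """Rank-frequency table with ties broken by first occurrence in the stream."""
    norm = labels.map(normalize_label)
    first = pd.Series(np.arange(norm.size), index=norm.to_numpy()).groupby(level=0).min()
    freq = norm.value_counts(sort=False)
    tab = pd.DataFrame({"label": freq.index, "freq": freq.to_numpy()})
    tab["first"] = tab["label"].map(first)
    tab = tab.sort_values(["freq", "first"], ascending=[False, True], kind="stable")
    tab = tab.drop(columns="first").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


@dataclass
class ZipfResult:
    """Rank-frequency tables and fits: power law for words, Yule for phonemes."""

    word_table: pd.DataFrame
    word_fit: PowerLawFit | None = None
    phoneme_table: pd.DataFrame | None = None
    phoneme_fit: YuleFit | None = None
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ranks(self) -> np.ndarray:
        return self.word_table["rank"].to_numpy()

    @property
    def freqs(self) -> np.ndarray:
        return self.word_table["freq"].to_numpy()


def analyze_zipf(h: CorpusHierarchy) -> ZipfResult:
    """Zipf's law for word frequencies; Yule rank-frequency fit for phonemes."""
    wtab = rank_frequency_table(h.words["label"])
    res = ZipfResult(word_table=wtab)
    try:
        res.word_fit = fit_power_law(wtab["freq"].to_numpy())
    except FitError as exc:
        res.errors["word"] = f"Zipf fit failed ({len(wtab)} word types): {exc}"
    if not h.phonemes.empty:
        ptab = rank_frequency_table(h.phonemes["label"])
        res.phoneme_table = ptab
        try:
            res.phoneme_fit = fit_yule(ptab["freq"].to_numpy())
        except FitError as exc:
            res.errors["phoneme"] = f"Yule fit failed ({len(ptab)} phoneme types): {exc}"
    return res


# ---------------------------------------------------------------- Herdan-Heaps


@dataclass
class HerdanResult:
    """Vocabulary growth curves per speaker-order permutation.

    ``beta`` is the mean V(L) ~ L^beta exponent (symbolic units),
    ``gamma`` the mean V(T) ~ T^gamma exponent (physical units).
    """

    curves: list[pd.DataFrame]
    fits_L: list[LoglogFit]
    fits_T: list[LoglogFit]
    beta: float
    gamma: float


def analyze_herdan(
    h: CorpusHierarchy, n_permutations: int | None = None, seed: int | None = None
) -> HerdanResult:
    """Walk the word stream in permuted speaker orders, accumulating V, L, T.

    For each permutation the tokens of each speaker stay in time order and
    speakers are concatenated in a random order; the growth exponents are
    fitted per curve by least squares on ~64 log-spaced checkpoints and
    averaged over permutations.
    """
    if h.words.empty:
        raise ValidationError("empty corpus")
    speakers = h.speakers()
    if n_permutations is None:
        n_permutations = min(100, math.factorial(len(speakers)))
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    groups = {s: h.words[h.words["speaker"] == s] for s in speakers}
    curves, fits_L, fits_T = [], [], []
    for _ in range(n_permutations):
        perm = rng.permutation(speakers)
        df = pd.concat([groups[s] for s in perm], ignore_index=True)
        norm = df["label"].map(normalize_label)
        new_type = (~norm.duplicated()).to_numpy()
        V = np.cumsum(new_type)
        L = np.arange(1, len(df) + 1)
        T = np.cumsum(df["t"].to_numpy())
        cp = np.unique(np.geomspace(1, len(df), 64).astype(int)) - 1
        curve = pd.DataFrame({"L": L[cp], "T": T[cp], "V": V[cp]})
        curves.append(curve)
        fits_L.append(fit_loglog(curve["L"], curve["V"]))
        fits_T.append(fit_loglog(curve["T"], curve["V"]))
    return HerdanResult(
        curves=curves,
        fits_L=fits_L,
        fits_T=fits_T,
        beta=float(np.mean([f.slope for f in fits_L])),
        gamma=float(np.mean([f.slope for f in fits_T])),
    )


# ---------------------------------------------------------------- brevity


def _char_count(label: str) -> int:
    """Unicode code points of the lowercased label, punctuation stripped."""
    return len(_PUNCT.sub("", normalize_label(label)))


@dataclass
class BrevityResult:
    """Per-type frequency/size table and exponential fits per unit system.

    For symbolic units, ``lambda_D`` quantifies distance from optimal
    non-singular coding over the D-ary alphabet: ell_i ~ -(1/lambda_D)
    log_D p_i, with lambda_D = 1 at optimality.
    """

    level: str
    table: pd.DataFrame
    fits: dict[str, ExponentialFit] = field(default_factory=dict)
    lambda_D: dict[str, float] = field(default_factory=dict)
    D: dict[str, int] = field(default_factory=dict)
    informative: dict[str, bool] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def analyze_brevity(
    h: CorpusHierarchy, level: str = "word", size_stat: str = "mean"
) -> BrevityResult:
    """Brevity law at the word or phoneme level, in every available unit system.

    Word sizes: mean (or median) token duration, phoneme count, character
    count.  Phoneme sizes: duration only.  Fits are least squares of log
    frequency against raw per-type sizes; Spearman's rho (average ranks
    for ties) flags whether the anticorrelation is informative.
    """
    if level not in ("word", "phoneme"):
        raise ValidationError(f"brevity level must be word or phoneme, not {level!r}")
    df = h.level_frame(level)
    if df.empty:
        raise ValidationError(f"corpus has no {level} tier")
    agg = {"mean": "mean", "median": "median"}[size_stat]
    norm = df["label"].map(normalize_label)
    tab = (
        pd.DataFrame({"label": norm, "t": df["t"]})
        .groupby("label", sort=False)
        .agg(freq=("t", "size"), duration=("t", agg))
        .reset_index()
    )
    if len(tab) < 10:
        raise ValidationError(f"need at least 10 {level} types, got {len(tab)}")
    tab["p"] = tab["freq"] / tab["freq"].sum()

    res = BrevityResult(level=level, table=tab)
    units: dict[str, np.ndarray] = {"duration": tab["duration"].to_numpy()}
    if level == "word":
        if not h.phonemes.empty:
            per_word = h.phonemes_per_word()
            nph = (
                pd.DataFrame({"label": norm, "nph": per_word[: len(df)]})
                .groupby("label", sort=False)["nph"]
                .mean()
            )
            tab["n_phonemes"] = tab["label"].map(nph)
            units["phonemes"] = tab["n_phonemes"].to_numpy()
            res.D["phonemes"] = int(h.phonemes["label"].map(normalize_label).nunique())
        chars = tab["label"].map(_char_count)
        if (chars > 0).all():
            tab["n_chars"] = chars
            units["characters"] = chars.to_numpy(dtype=float)
            res.D["characters"] = len({ch for lab in tab["label"] for ch in _PUNCT.sub("", lab)})
        else:
            res.errors["characters"] = "missing orthography: character units disabled"
            warnings.warn("missing orthography: character units disabled")

    p = tab["p"].to_numpy()
    for unit, sizes in units.items():
        try:
            fit = fit_exponential(sizes, tab["freq"].to_numpy())
        except FitError as exc:
            res.errors[unit] = str(exc)
            continue
        res.fits[unit] = fit
        res.informative[unit] = bool(np.isfinite(fit.spearman_p) and fit.spearman_p < 0.05)
        if unit in res.D:  # symbolic units: optimality exponent
            D = res.D[unit]
            l_star = -np.log(p) / np.log(D)
            slope = np.polyfit(l_star, sizes, 1)[0]
            lam_D = 1.0 / slope if slope != 0 else float("inf")
            if not 0 < lam_D <= 1:
                warnings.warn(
                    f"lambda_D={lam_D:.3f} outside (0, 1] for {unit}; reported anyway"
                )
            res.lambda_D[unit] = float(lam_D)
    return res


# ---------------------------------------------------------------- size-rank


def predicted_theta(alpha: float, lam: float) -> float:
    """Size-rank exponent implied by the Zipf and brevity fits: theta = alpha/lambda."""
    return alpha / lam


@dataclass
class SizeRankResult:
    """Fit of ell ~ theta·log r against the value implied by Zipf + brevity.

    ``formula_used`` records that theta is computed as the ratio
    alpha/lambda: the ratio reproduces the published exponents, whereas a
    literal product reading of "theta = alpha·lambda" does not.
    """

    theta: float
    intercept: float
    r2: float
    theta_predicted: float
    agreement: float
    unit: str
    n: int
    formula_used: str = "theta = alpha/lambda (ratio; a product reading is inconsistent)"


def analyze_size_rank(
    zipf: ZipfResult, brevity: BrevityResult, unit: str = "duration"
) -> SizeRankResult:
    """Size-rank law on raw per-type data, for the given unit system."""
    if unit not in brevity.fits:
        raise FitError(f"brevity has no fit for unit {unit!r}")
    if zipf.word_fit is None:
        raise FitError("zipf word fit unavailable")
    col = {"duration": "duration", "phonemes": "n_phonemes", "characters": "n_chars"}[unit]
    merged = zipf.word_table.merge(brevity.table[["label", col]], on="label", how="inner")
    if merged.empty:
        raise FitError("zipf and brevity tables share no types (different corpora?)")
    logr = np.log(merged["rank"].to_numpy(dtype=float))
    ell = merged[col].to_numpy(dtype=float)
    theta, intercept = np.polyfit(logr, ell, 1)
    resid = ell - (theta * logr + intercept)
    ss_tot = ((ell - ell.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    theta_pred = predicted_theta(zipf.word_fit.alpha, brevity.fits[unit].lambda_rate)
    return SizeRankResult(
        theta=float(theta),
        intercept=float(intercept),
        r2=float(r2),
        theta_predicted=float(theta_pred),
        agreement=float(abs(theta - theta_pred)),
        unit=unit,
        n=len(merged),
    )


# ---------------------------------------------------------------- Menzerath-Altmann


@dataclass
class MenzerathResult:
    """Raw construct-level (n, y) points and MAL fits per unit system."""

    scale_pair: str
    table: pd.DataFrame
    fits: dict[str, MenzerathFit] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def analyze_menzerath(h: CorpusHierarchy, scale_pair: str = "bg_words") -> MenzerathResult:
    """Menzerath-Altmann law for breath groups vs words or words vs phonemes.

    ``bg_words``: each breath group is one raw point, n = words in the BG
    and y = mean constituent size (word duration in seconds; phonemes or
    characters per word).  ``word_phonemes``: each word token is one
    point, n = phonemes in the word and y = mean phoneme duration.
    BG means average over word tokens, not types.
    """
    if scale_pair == "bg_words":
        n = h.words_per_bg().astype(float)
        bg_idx = h.words["bg"].to_numpy()
        table = pd.DataFrame({"n": n})
        dur = np.zeros(n.size)
        np.add.at(dur, bg_idx, h.words["t"].to_numpy())
        table["duration"] = dur / n
        if not h.phonemes.empty:
            nph = np.zeros(n.size)
            np.add.at(nph, bg_idx, h.phonemes_per_word().astype(float))
            table["phonemes"] = nph / n
        chars = h.words["label"].map(_char_count).to_numpy(dtype=float)
        if (chars > 0).all():
            cc = np.zeros(n.size)
            np.add.at(cc, bg_idx, chars)
            table["characters"] = cc / n
    elif scale_pair == "word_phonemes":
        if h.phonemes.empty:
            raise ValidationError("word_phonemes scale requires a phoneme tier")
        n = h.phonemes_per_word().astype(float)
        table = pd.DataFrame({"n": n, "duration": h.words["t"].to_numpy() / n})
    else:
        raise ValidationError(f"unknown scale_pair {scale_pair!r}")

    res = MenzerathResult(scale_pair=scale_pair, table=table)
    for unit in [c for c in table.columns if c != "n"]:
        try:
            res.fits[unit] = fit_menzerath(table["n"].to_numpy(), table[unit].to_numpy())
        except FitError as exc:
            res.errors[unit] = str(exc)
    return res
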