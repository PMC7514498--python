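"""Three-level data model for time-aligned speech corpora.

A corpus is a hierarchy of phonemes nested in words nested in breath
groups (BGs).  Phoneme and word tokens come from a forced alignment
(Praat TextGrid or the canonical TSV dialect); breath groups are derived
by segmenting each speaker's word stream at pauses of at least a
configurable duration.

Canonical TSV dialect: UTF-8, header ``speaker level label start end``,
times in seconds with at least three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .textgrid import read_textgrid, write_textgrid

#: linguistic levels, lowest first
LEVELS = ("phoneme", "word", "breath_group")

#: labels treated as silence/pause markers, not linguistic tokens
SILENCE_LABELS = frozenset({"", "sil", "sp", "spn", "pause", "#", "<p>", "<sil>"})

#: tolerance (s) for interval containment, absorbs aligner rounding
CONTAINMENT_TOL = 1e-3

#: default minimum pause (s) separating two breath groups
DEFAULT_PAUSE_THRESHOLD = 0.1

_TSV_COLUMNS = ["speaker", "level", "label", "start", "end"]


@dataclass(frozen=True)
class UnitToken:
    """One aligned linguistic unit with its time duration ``t = end - start``."""

    label: str
    level: str
    start: float
    end: float
    speaker: str

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}")
        if self.end < self.start:
            raise ValidationError(
                f"token {self.label!r}: end {self.end} < start {self.start}"
            )
        if self.level in ("phoneme", "word") and not self.label:
            raise ValidationError(f"{self.level} token at t={self.start} has empty label")

    @property
    def t(self) -> float:
        """Duration in seconds."""
        return self.end - self.start


def _as_frame(tokens, level: str) -> pd.DataFrame:
    """Normalize a token list / DataFrame to the internal frame layout."""
    if isinstance(tokens, pd.DataFrame):
        df = tokens.copy()
    else:
        df = pd.DataFrame(
            [(tok.speaker, tok.label, tok.start, tok.end) for tok in tokens],
            columns=["speaker", "label", "start", "end"],
        )
    missing = {"speaker", "label", "start", "end"} - set(df.columns)
    if missing:
        raise ValidationError(f"{level} frame is missing columns {sorted(missing)}")
    df = df.astype({"start": float, "end": float})
    if (df["end"] < df["start"]).any():
        bad = df.index[df["end"] < df["start"]][0]
        raise ValidationError(f"{level} token #{bad}: end precedes start")
    df["t"] = df["end"] - df["start"]
    df = df.sort_values(["speaker", "start"], kind="stable").reset_index(drop=True)
    return df


def _check_no_overlap(df: pd.DataFrame, level: str) -> None:
    for spk, grp in df.groupby("speaker", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        bad = np.nonzero(starts[1:] < ends[:-1] - CONTAINMENT_TOL)[0]
        if bad.size:
            i = bad[0]
            raise ValidationError(
                f"overlapping {level} intervals for speaker {spk!r} near "
                f"t={starts[i + 1]:.3f}"
            )


@dataclass
class CorpusHierarchy:
    """Aligned tokens at the three levels plus the containment maps.

    ``phonemes`` carries a ``word`` column (row index into ``words``);
    ``words`` carries a ``bg`` column (row index into ``breath_groups``).
    """

    phonemes: pd.DataFrame
    words: pd.DataFrame
    breath_groups: pd.DataFrame
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD

    def level_frame(self, level: str) -> pd.DataFrame:
        if level == "phoneme":
            return self.phonemes
        if level == "word":
            return self.words
        if level == "breath_group":
            return self.breath_groups
        raise ValidationError(f"unknown level {level!r}")

    def durations(self, level: str) -> np.ndarray:
        return self.level_frame(level)["t"].to_numpy()

    def n_tokens(self, level: str) -> int:
        return len(self.level_frame(level))

    def speakers(self) -> list[str]:
        return list(pd.unique(self.words["speaker"]))

    def phonemes_per_word(self) -> np.ndarray:
        """Number of phoneme tokens inside each word token (aligned corpora only)."""
        if self.phonemes.empty:
            raise ValidationError("corpus has no phoneme tier")
        counts = np.zeros(len(self.words), dtype=int)
        np.add.at(counts, self.phonemes["word"].to_numpy(), 1)
        return counts

    def words_per_bg(self) -> np.ndarray:
        counts = np.zeros(len(self.breath_groups), dtype=int)
        np.add.at(counts, self.words["bg"].to_numpy(), 1)
        return counts

    def iter_tokens(self, level: str) -> Iterator[UnitToken]:
        df = self.level_frame(level)
        for row in df.itertuples(index=False):
            yield UnitToken(
                label=getattr(row, "label", ""),
                level=level,
                start=row.start,
                end=row.end,
                speaker=row.speaker,
            )

    def validate(self) -> None:
        """Check structural invariants; raises :class:`ValidationError` on failure."""
        _check_no_overlap(self.words, "word")
        if not self.phonemes.empty:
            _check_no_overlap(self.phonemes, "phoneme")
            w = self.phonemes["word"].to_numpy()
            if w.min(initial=0) < 0 or (len(self.words) and w.max(initial=0) >= len(self.words)):
                raise ValidationError("phoneme→word map points outside the word table")
            if self.phonemes_per_word().sum() != len(self.phonemes):
                raise ValidationError("phoneme→word containment is not a partition")
        b = self.words["bg"].to_numpy()
        if len(b) and (b.min() < 0 or b.max() >= len(self.breath_groups)):
            raise ValidationError("word→BG map points outside the BG table")
        if self.words_per_bg().sum() != len(self.words):
            raise ValidationError("word→BG containment is not a partition")
        if (self.words_per_bg() == 0).any():
            raise ValidationError("empty breath group")


def segment_breath_groups(
    words,
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD,
    phonemes=None,
) -> CorpusHierarchy:
    """Build a hierarchy by splitting each speaker's word stream at pauses.

    A new breath group starts whenever the gap between consecutive words
    (``next.start - prev.end``) is at least ``pause_threshold`` seconds, or
    the speaker changes.  ``words`` (and optional ``phonemes``) may be
    token lists or frames with columns ``speaker label start end``.
    """
    if pause_threshold <= 0:
        raise ValidationError("pause_threshold must be > 0")
    wdf = _as_frame(words, "word")
    if wdf.empty:
        raise ValidationError("cannot segment an empty word list")
    _check_no_overlap(wdf, "word")

    new_bg = np.ones(len(wdf), dtype=bool)
    starts = wdf["start"].to_numpy()
    ends = wdf["end"].to_numpy()
    spk = wdf["speaker"].to_numpy()
    same_spk = spk[1:] == spk[:-1]
    gaps = starts[1:] - ends[:-1]
    if np.any(same_spk & (gaps < -CONTAINMENT_TOL)):
        i = int(np.nonzero(same_spk & (gaps < -CONTAINMENT_TOL))[0][0])
        raise ValidationError(
            f"words out of order / overlapping for speaker {spk[i]!r} near t={starts[i + 1]:.3f}"
        )
    new_bg[1:] = (~same_spk) | (gaps >= pause_threshold - 1e-9)
    bg_id = np.cumsum(new_bg) - 1
    wdf["bg"] = bg_id

    bg = wdf.groupby("bg").agg(
        speaker=("speaker", "first"), start=("start", "min"), end=("end", "max")
    )
    bg["t"] = bg["end"] - bg["start"]
    bg = bg.reset_index(drop=True)

    if phonemes is not None:
        pdf = _as_frame(phonemes, "phoneme")
        _check_no_overlap(pdf, "phoneme")
        pdf["word"] = _attach_phonemes(pdf, wdf)
    else:
        pdf = pd.DataFrame(columns=["speaker", "label", "start", "end", "t", "word"])

    h = CorpusHierarchy(phonemes=pdf, words=wdf, breath_groups=bg, pause_threshold=pause_threshold)
    h.validate()
    return h


def _attach_phonemes(pdf: pd.DataFrame, wdf: pd.DataFrame) -> np.ndarray:
    """Map each phoneme to the word whose interval contains it; orphans are errors."""
    word_idx = np.full(len(pdf), -1, dtype=int)
    orphans: list[str] = []
    for spk, grp in pdf.groupby("speaker", sort=False):
        wgrp = wdf[wdf["speaker"] == spk]
        if wgrp.empty:
            orphans += [f"{lab}@{s:.3f}" for lab, s in zip(grp["label"], grp["start"])]
            continue
        wstart = wgrp["start"].to_numpy()
        wend = wgrp["end"].to_numpy()
        widx = wgrp.index.to_numpy()
        pos = np.searchsorted(wstart, grp["start"].to_numpy() + CONTAINMENT_TOL, side="right") - 1
        for k, (i, ps, pe, lab) in enumerate(
            zip(grp.index, grp["start"], grp["end"], grp["label"])
        ):
            j = pos[k]
            if (
                j >= 0
                and ps >= wstart[j] - CONTAINMENT_TOL
                and pe <= wend[j] + CONTAINMENT_TOL
            ):
                word_idx[i] = widx[j]
            else:
                orphans.append(f"{lab}@{ps:.3f}")
    if orphans:
        shown = ", ".join(orphans[:10])
        raise ValidationError(
            f"{len(orphans)} phoneme(s) not contained in any word interval: {shown}"
        )
    return word_idx


def _drop_silence(df: pd.DataFrame) -> pd.DataFrame:
    keep = ~df["label"].astype(str).str.strip().str.lower().isin(SILENCE_LABELS)
    return df[keep].reset_index(drop=True)


def read_alignment(
    path,
    dialect: str = "tsv",
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD,
    tier_map: dict | None = None,
) -> CorpusHierarchy:
    """Read a time-aligned annotation file into a :class:`CorpusHierarchy`.

    ``dialect`` is ``"tsv"`` (canonical dialect, header
    ``speaker level label start end``) or ``"textgrid"``.  Silence/pause
    labels are excluded from the token lists but shape the breath-group
    segmentation through the gaps they leave behind.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    if dialect == "tsv":
        pdf, wdf = _read_tsv(path)
    elif dialect == "textgrid":
        pdf, wdf = _read_textgrid_levels(path, tier_map)
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    wdf = _drop_silence(wdf)
    pdf = _drop_silence(pdf)
    if wdf.empty:
        raise ValidationError(f"{path}: no word tokens after silence filtering")
    return segment_breath_groups(
        wdf, pause_threshold=pause_threshold, phonemes=pdf if not pdf.empty else None
    )


def _read_tsv(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"speaker": str, "label": str}, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: header is missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: file contains no tokens")
    try:
        df = df.astype({"start": float, "end": float})
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric start/end: {exc}") from exc
    bad = ~df["level"].isin(("phoneme", "word"))
    if bad.any():
        raise ParseError(
            f"{path}: line {df.index[bad][0] + 2}: unknown level {df['level'][bad].iloc[0]!r}"
        )
    pdf = df[df["level"] == "phoneme"][["speaker", "label", "start", "end"]]
    wdf = df[df["level"] == "word"][["speaker", "label", "start", "end"]]
    return pdf.reset_index(drop=True), wdf.reset_index(drop=True)


_TIER_ALIASES = {
    "phoneme": "phoneme", "phonemes": "phoneme", "phone": "phoneme", "phones": "phoneme",
    "word": "word", "words": "word",
}


def _read_textgrid_levels(path: Path, tier_map: dict | None):
    tiers = read_textgrid(path)
    rows = {"phoneme": [], "word": []}
    for name, intervals in tiers.items():
        key = name.strip().lower()
        speaker = "s1"
        if tier_map and name in tier_map:
            level = tier_map[name]
        elif key in _TIER_ALIASES:
            level = _TIER_ALIASES[key]
        elif "-" in key and key.rsplit("-", 1)[1] in _TIER_ALIASES:
            speaker, lev = key.rsplit("-", 1)
            level = _TIER_ALIASES[lev]
        else:
            continue
        for a, b, text in intervals:
            rows[level].append((speaker, text, a, b))
    if not rows["word"]:
        raise ParseError(f"{path}: no word tier found (tiers: {sorted(tiers)})")
    cols = ["speaker", "label", "start", "end"]
    return (pd.DataFrame(rows["phoneme"], columns=cols), pd.DataFrame(rows["word"], columns=cols))


def write_tsv(h: CorpusHierarchy, path) -> None:
    """Write phoneme and word tokens in the canonical TSV dialect.

    Breath groups are derived data and are re-segmented on read.
    """
    frames = []
    for level in ("phoneme", "word"):
        df = h.level_frame(level)
        if df.empty:
            continue
        out = df[["speaker", "label", "start", "end"]].copy()
        out.insert(1, "level", level)
        frames.append(out)
    allrows = pd.concat(frames, ignore_index=True)
    allrows = allrows.sort_values(["speaker", "start", "level"], kind="stable")
    allrows["start"] = allrows["start"].map(lambda v: f"{v:.6f}")
    allrows["end"] = allrows["end"].map(lambda v: f"{v:.6f}")
    allrows.to_csv(path, sep="\t", index=False)


def write_textgrid_file(h: CorpusHierarchy, path) -> None:
    """Write the hierarchy as a TextGrid, one phoneme/word tier pair per speaker."""
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    multi = len(h.speakers()) > 1
    for level in ("phoneme", "word"):
        df = h.level_frame(level)
        if df.empty:
            continue
        for spk, grp in df.groupby("speaker", sort=False):
            name = f"{spk}-{level}" if multi else level
            tiers[name] = list(zip(grp["start"], grp["end"], grp["label"]))
    write_textgrid(tiers, path)


@dataclass
class CorpusSummary:
    """Per-level token/type counts and median durations (seconds)."""

    counts: dict[str, int] = field(default_factory=dict)
    types: dict[str, int | None] = field(default_factory=dict)
    median_duration: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            if level in self.counts:
                rows.append(
                    {
                        "level": level,
                        "tokens": self.counts[level],
                        "types": self.types.get(level),
                        "median_duration_s": self.median_duration[level],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def normalize_label(label: str) -> str:
    """Type identity: case-folded exact label match (no lemmatization)."""
    return str(label).casefold()


def summarize(h: CorpusHierarchy) -> CorpusSummary:
    """Token counts, type counts (case-folded labels) and median durations per level."""
    if h.words.empty:
        raise ValidationError("cannot summarize an empty corpus")
    s = CorpusSummary()
    for level in LEVELS:
        df = h.level_frame(level)
        if df.empty:
            continue
        s.counts[level] = len(df)
        if "label" in df.columns and level != "breath_group":
            s.types[level] = df["label"].map(normalize_label).nunique()
        else:
            s.types[level] = None
        s.median_duration[level] = float(np.median(df["t"].to_numpy()))
    return s
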