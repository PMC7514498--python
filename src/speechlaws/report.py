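"""Pipeline orchestration: run the enabled analyses and emit a machine-readable report.

The report is the machine-readable twin of a per-corpus law summary
table: one flat record per (level, law, unit system) with parameter
estimates, goodness metrics and sample sizes, plus a wide table keyed by
(level, unit).  Identical (config, seed, inputs) produce byte-identical
reports; per-law failures are recorded without aborting the other laws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corpus import CorpusHierarchy, read_alignment, summarize
from .exceptions import SpeechLawsError
from .fitters import as_record
from .laws import (
    analyze_brevity,
    analyze_herdan,
    analyze_lognormality,
    analyze_menzerath,
    analyze_size_rank,
    analyze_zipf,
)
from .synth import SynthSpec, generate_corpus

ALL_LAWS = ("lognormality", "zipf", "herdan", "brevity", "size_rank", "menzerath")

log = logging.getLogger("speechlaws")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; hashed into the report."""

    seed: int
    input: str | None = None
    dialect: str = "tsv"
    synth: SynthSpec | None = None
    synth_tokens: int = 50_000
    pause_threshold: float = 0.1
    laws: tuple[str, ...] = ALL_LAWS
    permutations: int | None = None
    use_phonemes: bool = True
    coarsen: bool = False
    precision: float = 0.01
    tau: float = 0.03
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            sd = dataclasses.asdict(self.synth)
            for k, v in sd.items():
                if isinstance(v, np.ndarray):
                    sd[k] = v.tolist()
                elif isinstance(v, tuple):
                    sd[k] = [np.asarray(x).tolist() for x in v]
            d["synth"] = sd
        d["laws"] = list(self.laws)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LawReport:
    """Flat fit records plus run metadata; serializes losslessly to JSON."""

    rows: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"meta": self.meta, "rows": self.rows}, sort_keys=True, indent=1, default=float
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source) -> "LawReport":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else source
        obj = json.loads(text)
        return cls(rows=obj["rows"], meta=obj["meta"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_table(self) -> pd.DataFrame:
        """Wide law-summary table: one row per (level, unit), one column per law parameter."""
        keep = {
            "zipf": ("alpha",),
            "yule": ("a", "b"),
            "herdan": ("beta", "gamma"),
            "brevity": ("lambda_rate", "spearman_rho", "lambda_D"),
            "size_rank": ("theta", "theta_predicted"),
            "menzerath": ("a", "b", "c", "r2", "inversion_n"),
            "lognormality": ("mu", "sigma", "ks_to_gaussian"),
        }
        cells: dict[tuple, dict] = {}
        for row in self.rows:
            law = row.get("law")
            if law not in keep or "error" in row:
                continue
            key = (row.get("level", ""), row.get("unit", ""))
            cell = cells.setdefault(key, {})
            for p in keep[law]:
                if row.get(p) is not None:
                    cell[f"{law}.{p}"] = row[p]
        out = pd.DataFrame.from_dict(cells, orient="index").sort_index()
        out.index = pd.MultiIndex.from_tuples(out.index, names=["level", "unit"])
        return out.reset_index()

    def to_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _load_corpus(config: RunConfig) -> CorpusHierarchy:
    if config.input is not None:
        h = read_alignment(
            config.input, dialect=config.dialect, pause_threshold=config.pause_threshold
        )
    elif config.synth is not None:
        h = generate_corpus(config.synth, config.synth_tokens)
    else:
        raise SpeechLawsError("config needs either an input path or a SynthSpec")
    if not config.use_phonemes:
        h = CorpusHierarchy(
            phonemes=h.phonemes.iloc[0:0],
            words=h.words,
            breath_groups=h.breath_groups,
            pause_threshold=h.pause_threshold,
        )
    return h


def run_all(config: RunConfig, corpus: CorpusHierarchy | None = None) -> LawReport:
    """Execute every enabled law; failures are isolated per law.

    Returns the :class:`LawReport`; when ``config.out_dir`` is set, also
    writes ``report.json``, ``law_table.tsv``, ``summary.tsv`` and ``run.log``.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    handler = None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    try:
        report = _run_all(config, corpus)
    finally:
        if handler:
            log.removeHandler(handler)
            handler.close()
    if out_dir:
        report.to_json(out_dir / "report.json")
        report.to_tsv(out_dir / "law_table.tsv")
    return report


def _append_error(report: LawReport, law: str, exc: Exception, **tags) -> None:
    log.warning("%s failed: %s", law, exc)
    report.rows.append({"law": law, "error": str(exc), **tags})


def _run_all(config: RunConfig, corpus: CorpusHierarchy | None) -> LawReport:
    h = corpus if corpus is not None else _load_corpus(config)
    report = LawReport(
        meta={
            "software": "speechlaws",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "formulas": {
                "lognormality": "p(t; mu, sigma) lognormal; t' = (log t - <log t>)/sd(log t)",
                "zipf": "f(r) ~ r^-alpha (discrete MLE, KS-selected xmin)",
                "yule": "p(r) ~ r^-a · b^r (numerical MLE)",
                "herdan": "V(L) ~ L^beta, V(T) ~ T^gamma",
                "brevity": "f ~ exp(-lambda·ell); ell_i ~ -(1/lambda_D) log_D p_i",
                "size_rank": "ell ~ theta·log r with theta = alpha/lambda "
                             "(ratio form: the printed exponents satisfy alpha/lambda)",
                "menzerath": "y(n) = a·n^b·exp(-c·n)",
            },
        }
    )
    summary = summarize(h)
    for level, count in summary.counts.items():
        report.rows.append(
            {
                "law": "corpus_summary",
                "level": level,
                "tokens": count,
                "types": summary.types.get(level),
                "median_duration_s": summary.median_duration[level],
            }
        )
    log.info("corpus: %s", {k: int(v) for k, v in summary.counts.items()})

    zipf_res = brevity_res = None
    if "lognormality" in config.laws:
        res = analyze_lognormality(h, coarsening=(config.precision, config.tau) if config.coarsen else None)
        for level, fit in res.fits.items():
            report.rows.append(as_record(fit, law="lognormality", level=level, unit="duration"))
        if res.coarsened_fits:
            for level, fit in res.coarsened_fits.items():
                report.rows.append(
                    as_record(fit, law="lognormality_coarsened", level=level, unit="duration")
                )
        for level, err in res.errors.items():
            _append_error(report, "lognormality", SpeechLawsError(err), level=level)
    if "zipf" in config.laws:
        try:
            zipf_res = analyze_zipf(h)
            if zipf_res.word_fit:
                report.rows.append(as_record(zipf_res.word_fit, law="zipf", level="word", unit="rank"))
            if zipf_res.phoneme_fit:
                report.rows.append(
                    as_record(zipf_res.phoneme_fit, law="yule", level="phoneme", unit="rank")
                )
            for lvl, err in zipf_res.errors.items():
                _append_error(report, "zipf", SpeechLawsError(err), level=lvl)
        except SpeechLawsError as exc:
            _append_error(report, "zipf", exc)
    if "herdan" in config.laws:
        try:
            res = analyze_herdan(h, n_permutations=config.permutations, seed=config.seed)
            report.rows.append(
                {
                    "law": "herdan",
                    "level": "word",
                    "unit": "tokens|seconds",
                    "beta": res.beta,
                    "gamma": res.gamma,
                    "n_permutations": len(res.curves),
                    "n": int(res.curves[0]["L"].iloc[-1]),
                }
            )
        except SpeechLawsError as exc:
            _append_error(report, "herdan", exc)
    if "brevity" in config.laws:
        for level in ("word", "phoneme") if config.use_phonemes and not h.phonemes.empty else ("word",):
            try:
                res = analyze_brevity(h, level=level)
                if level == "word":
                    brevity_res = res
                for unit, fit in res.fits.items():
                    rec = as_record(fit, law="brevity", level=level, unit=unit)
                    rec["informative"] = res.informative.get(unit)
                    if unit in res.lambda_D:
                        rec["lambda_D"] = res.lambda_D[unit]
                        rec["D"] = res.D[unit]
                    report.rows.append(rec)
                for unit, err in res.errors.items():
                    _append_error(report, "brevity", SpeechLawsError(err), level=level, unit=unit)
            except SpeechLawsError as exc:
                _append_error(report, "brevity", exc, level=level)
    if "size_rank" in config.laws:
        if zipf_res is not None and brevity_res is not None:
            for unit in brevity_res.fits:
                try:
                    res = analyze_size_rank(zipf_res, brevity_res, unit=unit)
                    report.rows.append(
                        as_record(res, law="size_rank", level="word", unit=unit)
                    )
                except SpeechLawsError as exc:
                    _append_error(report, "size_rank", exc, unit=unit)
        else:
            _append_error(
                report, "size_rank", SpeechLawsError("requires zipf and brevity results")
            )
    if "menzerath" in config.laws:
        pairs = ["bg_words"]
        if config.use_phonemes and not h.phonemes.empty:
            pairs.append("word_phonemes")
        for pair in pairs:
            try:
                res = analyze_menzerath(h, scale_pair=pair)
                for unit, fit in res.fits.items():
                    report.rows.append(as_record(fit, law="menzerath", level=pair, unit=unit))
                for unit, err in res.errors.items():
                    _append_error(report, "menzerath", SpeechLawsError(err), level=pair, unit=unit)
            except SpeechLawsError as exc:
                _append_error(report, "menzerath", exc, level=pair)
    for row in report.rows:
        if "n" in row:
            log.info("fit %s/%s/%s n=%s", row.get("law"), row.get("level"), row.get("unit"), row["n"])
    return report


def simulate_coarsening(config: RunConfig, corpus: CorpusHierarchy | None = None) -> dict:
    """Lognormality before vs after coarsening: side-by-side KS distances and fits."""
    h = corpus if corpus is not None else _load_corpus(config)
    res = analyze_lognormality(h, coarsening=(config.precision, config.tau))
    out: dict = {
        "precision": config.precision,
        "tau": config.tau,
        "config_hash": config.config_hash(),
        "levels": {},
    }
    for level, fit in res.fits.items():
        entry = {"raw": dataclasses.asdict(fit)}
        if res.coarsened_fits and level in res.coarsened_fits:
            cfit = res.coarsened_fits[level]
            entry["coarsened"] = dataclasses.asdict(cfit)
            entry["ks_increase"] = cfit.ks_to_gaussian - fit.ks_to_gaussian
        out["levels"][level] = entry
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "coarsening_study.json").write_text(
            json.dumps(out, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
    return out
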