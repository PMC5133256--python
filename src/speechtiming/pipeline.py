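"""Per-language and corpus analysis orchestration.

``analyze_language`` chains interval extraction, the order-0 rhythm
metrics, the ideal-learner predictability score, and (optionally) the
ARMA model grid into a single report row; ``analyze_corpus`` adds the
cross-language aggregates.  Stage failures are recorded per field and
do not abort the rest of the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from speechtiming import arma as arma_mod
from speechtiming import learner as learner_mod
from speechtiming import metrics as metrics_mod
from speechtiming.annotations import AnnotationSequence
from speechtiming.series import extract_ini, log_ini, log_ratio, median_ini_ms

__all__ = [
    "AnalysisConfig",
    "LanguageReport",
    "CorpusReport",
    "analyze_language",
    "analyze_corpus",
    "aggregate_rows",
    "corpus_to_json",
    "corpus_from_json",
    "corpus_to_tsv",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-language pipeline."""

    run_arma: bool = True
    arma_max_p: int = 5
    arma_max_q: int = 5
    arma_max_d: int = 1
    arma_min_obs: int = 20
    akaike_threshold: float = 0.95
    with_exog: bool = True
    ks_on_log: bool = False  # KS D on raw durations by default
    min_learner_obs: int = 2


@dataclass
class LanguageReport:
    """One analysis row for a language (fields None when a stage failed)."""

    language_iso: str
    n_nuclei: int | None = None
    n_phrases: int | None = None
    median_ini_ms: float | None = None
    ks_d: float | None = None
    npvi: float | None = None
    lr_ini_mean: float | None = None
    lr_ini_variance: float | None = None
    lr_ini_variance_unbiased: float | None = None
    differential_entropy: float | None = None
    best_p: int | None = None
    best_q: int | None = None
    best_d: int | None = None
    akaike_set_size: int | None = None
    d1_weight_percent: float | None = None
    notes: dict[str, str] = field(default_factory=dict)


@dataclass
class CorpusReport:
    """Per-language rows plus cross-language aggregates."""

    rows: list[LanguageReport]
    spearman_d_npvi: float | None = None
    mean_entropy: float | None = None
    n_below_mean_entropy: int | None = None
    n_below_0_9: int | None = None
    max_entropy: float | None = None
    mean_variance: float | None = None
    nuclei_median: float | None = None
    nuclei_q1: float | None = None
    nuclei_q3: float | None = None


def analyze_language(
    seq: AnnotationSequence, config: AnalysisConfig | None = None
) -> LanguageReport:
    """Run the full per-language pipeline on one annotation sequence."""
    config = config or AnalysisConfig()
    report = LanguageReport(language_iso=seq.language_iso)
    try:
        s = extract_ini(seq)
    except Exception as exc:
        report.notes["extract"] = str(exc)
        return report
    report.n_nuclei = s.n_nuclei
    report.n_phrases = s.n_phrases
    try:
        report.median_ini_ms = median_ini_ms(s)
    except Exception as exc:
        report.notes["median"] = str(exc)

    y = log_ini(s)
    try:
        report.ks_d = metrics_mod.ks_normality_d(y if config.ks_on_log else s.d)
    except Exception as exc:
        report.notes["ks_d"] = str(exc)
    try:
        report.npvi = metrics_mod.npvi(s)
    except Exception as exc:
        report.notes["npvi"] = str(exc)

    r = log_ratio(s)
    try:
        post = learner_mod.fit_posterior(r)
        report.lr_ini_mean = post.mu_hat
        report.lr_ini_variance = post.sigma2_hat
        report.lr_ini_variance_unbiased = post.sigma2_unbiased
        pred = learner_mod.posterior_predictive(post)
        report.differential_entropy = learner_mod.differential_entropy(pred)
    except Exception as exc:
        report.notes["learner"] = str(exc)

    if config.run_arma:
        try:
            table = arma_mod.grid_search(
                y,
                s.i if config.with_exog else None,
                max_p=config.arma_max_p,
                max_q=config.arma_max_q,
                max_d=config.arma_max_d,
                with_exog=config.with_exog,
                threshold=config.akaike_threshold,
                min_obs=config.arma_min_obs,
            )
            report.best_p = table.best.spec.p
            report.best_q = table.best.spec.q
            report.best_d = table.best.spec.d
            report.akaike_set_size = len(table.akaike_set)
            report.d1_weight_percent = arma_mod.d1_weight_share(table)
        except Exception as exc:
            report.notes["arma"] = str(exc)
    return report


def aggregate_rows(rows: list[LanguageReport]) -> dict[str, float | int | None]:
    """Cross-language aggregates recomputable from the report rows.

    Entropy counts use strict inequality; quantiles use the
    linear-interpolation convention.
    """
    out: dict[str, float | int | None] = {
        "spearman_d_npvi": None,
        "mean_entropy": None,
        "n_below_mean_entropy": None,
        "n_below_0_9": None,
        "max_entropy": None,
        "mean_variance": None,
        "nuclei_median": None,
        "nuclei_q1": None,
        "nuclei_q3": None,
    }
    pairs = [
        (r.ks_d, r.npvi) for r in rows if r.ks_d is not None and r.npvi is not None
    ]
    if len(pairs) >= 3:
        ks, pv = zip(*pairs)
        try:
            out["spearman_d_npvi"] = metrics_mod.spearman(np.array(ks), np.array(pv))
        except metrics_mod.MetricError:
            pass
    ents = np.array(
        [r.differential_entropy for r in rows if r.differential_entropy is not None]
    )
    if len(ents):
        mean_ent = float(ents.mean())
        out["mean_entropy"] = mean_ent
        out["n_below_mean_entropy"] = int((ents < mean_ent).sum())
        out["n_below_0_9"] = int((ents < 0.9).sum())
        out["max_entropy"] = float(ents.max())
    variances = np.array(
        [r.lr_ini_variance for r in rows if r.lr_ini_variance is not None]
    )
    if len(variances):
        out["mean_variance"] = float(variances.mean())
    counts = np.array([r.n_nuclei for r in rows if r.n_nuclei is not None])
    if len(counts):
        out["nuclei_median"] = float(np.quantile(counts, 0.5))
        out["nuclei_q1"] = float(np.quantile(counts, 0.25))
        out["nuclei_q3"] = float(np.quantile(counts, 0.75))
    return out


def analyze_corpus(
    seqs: list[AnnotationSequence], config: AnalysisConfig | None = None
) -> CorpusReport:
    """Analyze every sequence and aggregate across languages."""
    rows = [analyze_language(seq, config) for seq in seqs]
    report = CorpusReport(rows=rows)
    for key, value in aggregate_rows(rows).items():
        setattr(report, key, value)
    return report


# ---------------------------------------------------------------------------
# Serialization: full-precision JSON plus a rounded TSV at report precision
# ---------------------------------------------------------------------------

_TSV_ROUNDING = {
    "median_ini_ms": 0,
    "ks_d": 3,
    "npvi": 1,
    "lr_ini_mean": 2,
    "lr_ini_variance": 2,
    "lr_ini_variance_unbiased": 2,
    "differential_entropy": 2,
    "d1_weight_percent": 2,
}


def _row_dict(row: LanguageReport) -> dict:
    d = dataclasses.asdict(row)
    return d


def corpus_to_json(report: CorpusReport, path: str | Path) -> None:
    payload = {
        "rows": [_row_dict(r) for r in report.rows],
        "aggregates": {
            k: getattr(report, k)
            for k in (
                "spearman_d_npvi",
                "mean_entropy",
                "n_below_mean_entropy",
                "n_below_0_9",
                "max_entropy",
                "mean_variance",
                "nuclei_median",
                "nuclei_q1",
                "nuclei_q3",
            )
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def corpus_from_json(path: str | Path) -> CorpusReport:
    payload = json.loads(Path(path).read_text())
    rows = [LanguageReport(**r) for r in payload["rows"]]
    report = CorpusReport(rows=rows)
    for k, v in payload["aggregates"].items():
        setattr(report, k, v)
    return report


def corpus_to_tsv(report: CorpusReport, path: str | Path) -> None:
    records = []
    for r in report.rows:
        d = _row_dict(r)
        d.pop("notes", None)
        for key, nd in _TSV_ROUNDING.items():
            if d.get(key) is not None:
                d[key] = round(d[key], nd)
        records.append(d)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
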