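"""Bundled per-language reference summary table.

``corpus_reference.tsv`` holds the published per-language summary values
for the 18-language IPA narrative corpus (descriptive counts, rhythm
metrics, ideal-learner scores, and ARMA model-comparison summaries).
It serves two purposes: desk-scale consistency checks of the corpus
aggregation code, and the default profile of the synthetic corpus
generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_table", "reference_reports"]


def load_reference_table() -> pd.DataFrame:
    """Load the bundled 18-row reference summary table."""
    ref = resources.files("speechtiming.data").joinpath("corpus_reference.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def reference_reports() -> list:
    """The reference rows as LanguageReport records (fields the table
    does not carry are left ``None``)."""
    from speechtiming.pipeline import LanguageReport

    df = load_reference_table()
    reports = []
    for row in df.itertuples(index=False):
        reports.append(
            LanguageReport(
                language_iso=row.iso,
                n_nuclei=int(row.n_nuclei),
                n_phrases=int(row.n_phrases),
                median_ini_ms=float(row.median_ini_ms),
                ks_d=float(row.ks_d),
                npvi=float(row.npvi),
                lr_ini_mean=float(row.lr_ini_mean),
                lr_ini_variance=float(row.lr_ini_variance),
                differential_entropy=float(row.differential_entropy),
                best_p=int(row.best_p),
                best_q=int(row.best_q),
                best_d=int(row.best_d),
                akaike_set_size=int(row.akaike_set_size),
                d1_weight_percent=float(row.d1_weight_percent),
            )
        )
    return reports
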