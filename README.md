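# speechtiming

Temporal predictability analysis of syllable-nucleus timing in speech.

Given point annotations of syllable nuclei (times, intensities, and
phrase/sentence break markers), the package quantifies how predictable
the timing of the next syllable is, at three levels of structure:

* **Order 0 — distributional metrics** (`speechtiming.metrics`): the
  normalized pairwise variability index (nPVI) computed on
  inter-nucleus intervals (INIs), the Kolmogorov–Smirnov distance to a
  moment-matched normal distribution, the D'Agostino–Pearson normality
  test, and Spearman rank correlation.
* **Order 1 — Bayesian ideal learner** (`speechtiming.learner`): a
  conjugate Normal–Inverse-χ² model of the log-ratios of adjacent INIs
  under an uninformative prior.  The Student-t posterior predictive for
  the next log-ratio is scored by its differential entropy (nats):
  lower entropy = higher predictability.
* **Higher order — ARMA multimodel inference** (`speechtiming.arma`):
  a 72-variant grid of ARMA(p, d, q) models (p, q ≤ 5, d ≤ 1) fitted to
  the NaN-masked log-INI series with the preceding intensity difference
  as exogenous regressor, compared via AICc, Akaike weights, the
  95 % Akaike set, and weights marginalized over d and q.

Supporting modules:

* `speechtiming.annotations` — Praat TextGrid (point tiers, long and
  short text form) and tab-separated `.out` annotation I/O, including
  the concatenated multi-language variant.
* `speechtiming.series` — INI extraction with break-masked missing
  values, log and log-ratio views.
* `speechtiming.synthetic` — synthetic corpus generator with recorded
  ground truth (iid log-normal or ARMA/ARIMA log-INI processes,
  intensity track, phrase-break placement); the bundled default profile
  mirrors the 18-language reference corpus.
* `speechtiming.agreement` — dynamic-time-warping alignment of two
  annotators' nucleus times and the squared-error separation check.
* `speechtiming.pipeline` — per-language and corpus reports with
  cross-language aggregates.
* `speechtiming.reference` — the bundled per-language reference
  summary table for the 18-language IPA narrative corpus.

## CLI

```sh
# analyze annotation files (TextGrid or .out) into a per-language report
speechtiming analyze data/*.out --out report.tsv             # full pipeline
speechtiming analyze data/*.TextGrid --tier nuclei --no-arma # fast subset

# generate a synthetic fixture corpus (default: 18-language profile)
speechtiming simulate --outdir fixtures --seed 7 --fmt both

# DTW agreement between two annotation files
speechtiming agree a.out b.out
```

`analyze` writes a rounded TSV plus a full-precision JSON companion.

## Python API sketch

```python
import speechtiming as st

seq = st.read_out_file("Language_iso_annotator.out", "iso", "AB")
s = st.extract_ini(seq)                  # durations + intensity diffs, NaN at breaks
print(st.npvi(s), st.ks_normality_d(s.d))

post = st.fit_posterior(st.log_ratio(s))
pred = st.posterior_predictive(post)     # Student-t for the next log-ratio
print(st.differential_entropy(pred))

table = st.grid_search(st.log_ini(s), s.i)   # 72 ARMA variants
print(table.best.spec, st.d1_weight_share(table))
```
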