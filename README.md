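# rxdivert

Drug-diversion surveillance analytics on consolidated multi-system hospital
medication-movement data.

Drug diversion — theft of controlled substances by healthcare workers — is
mostly detected late, by monthly cabinet usage reports or by a colleague
noticing impairment. The core difficulty is that no single IT system sees the
whole chain of custody: the wholesaler invoice, the pharmacy vault, the
dispensing cabinet, the medication administration record and the time clock
live in five different systems with five different medication-ID and username
spaces. `rxdivert` implements, as a tested and reusable pipeline, the
consolidated-data + supervised-learning approach to closing that gap:

1. **Ingestion** — parse the five extract dialects (EMR, ADC, IIS, WHL, ETC),
   map medications and clinician identities onto canonical spaces via a
   formulary and an identity cross-map (married/maiden username variants
   included), and normalize everything into one movement ledger. Nothing is
   silently dropped: malformed rows go to a reject report and unmapped IDs
   are retained with a null canonical ID, because outer-join semantics are
   the point — a dispense with no matching administration is the signal.
2. **Custody reconciliation** — one *custody episode* per cabinet dispense,
   linking the administrations, wastes, returns and transfers that settle it,
   with the unaccounted remainder
   `missing = dispensed − administered − wasted − returned − transferred`;
   wholesaler-to-vault and vault-to-cabinet shortfalls; and medication
   transactions timestamped outside the handling clinician's clocked shifts.
3. **Feature extraction** — 14 one-hot flags per transaction (late wasting /
   late administration past a 4-hour threshold, no administration, partial
   administration, partial waste/return, full wasting, bulk wasting,
   handoffs, incorrect order, incorrect medication, off-clock access,
   shipment and restock shortfalls, missing pain-score context).
4. **Risk scoring** — a weighted score per transaction, a nearest-rank
   98th-percentile threshold labeling the top tail *high risk*, and a
   classifier (logistic regression or random forest; stratified 60/40 split,
   minority oversampling in the training split only, stratified K-fold CV)
   trained to reproduce that labeling.
5. **Detection evaluation** — for each clinician on a known-incident roster,
   the earliest high-risk alert versus the date existing methods caught
   them, summarized per site as mean / median / min / max *improvement in
   detection time* (whole calendar days, rounded half-up).

Because real hospital data of this kind cannot be shared, the package ships a
first-class **synthetic hospital simulator**: ground-truthed extracts in all
five dialects with lawful clinician workflows, configurable benign
documentation noise, and injected diverter behavior profiles with known onset
dates — so every stage is testable against a known answer.

## Worked example

```
$ printf 'n_clinicians: 60\nn_diverters: 3\nbeds: 60\ndate_range: ["2024-01-01", "2024-03-31"]\n' > demo.yaml
$ rxdivert pipeline --out demo/ --seed 7 --config demo.yaml
transactions: 29298; episodes: 9903
classifier (held-out): accuracy 100.0% sensitivity 100.0% specificity 100.0%
diverters detected: 3/3; improvement mean 22 d, median 22 d
```

Reading the output: the simulated quarter produced 29,298 movement
transactions across the five systems, reconciled into 9,903 custody episodes.
The classifier reproduces the 98th-percentile heuristic labels perfectly on
the held-out 40% — expected here, since the flags fully determine the score.
All 3 injected diverters received at least one high-risk alert, on average 22
days before the roster's existing-method detection dates (the simulated
investigation lag). The same stages are available individually
(`rxdivert simulate / ingest / reconcile / train / classify / evaluate`) and
as library calls (`rxdivert.run_pipeline`).

Python API in one breath:

```python
from rxdivert import SimConfig, run_pipeline
result = run_pipeline(SimConfig(seed=7), "work/")
result.custody.episodes     # per-dispense custody + missing quantity
result.assessments          # per-transaction risk scores and alerts
result.aggregates.frame     # detection-time improvement summary
```

The package also bundles a 22-incident multi-site benchmark (published
detection dates, alert timestamps and improvement values) used to
regression-test the date arithmetic and aggregation:

```python
from rxdivert import benchmark_aggregates
benchmark_aggregates().frame
#       site  n_detected  mean  median  min  max
# 0        A           9   288     291   25  579
# 1        B           7    71      86    7  144
# 2        C           6    71      61   31  151
# 3  overall          22   160      74    7  579
```

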