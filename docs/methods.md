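# Methods

This note documents the models and procedures behind `rxdivert`, the
assumptions they make, the parameters that matter, and the design decisions
taken where the problem was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Hospital medication movements are recorded across five mutually independent
IT systems: the EMR (medication administration records and clinical context
such as pain assessments), automated dispensing cabinets (ADC: withdraw,
waste, return, transfer, restock), the internal inventory system (IIS:
wholesaler receipts into a narcotic vault, issues from vault to cabinets),
wholesaler invoices (WHL), and the employee time clock (ETC). Diversion can
happen at any hand-off along that chain, and most single-system reports
cannot see it. The pipeline therefore (a) consolidates the five extracts into
one normalized ledger, (b) reconciles chain of custody, (c) derives
transaction-level one-hot risk features, (d) labels and classifies the
high-risk tail, and (e) scores detection latency against a roster of
incidents found by existing methods.

## Normalization

Each extract dialect has its own delimiter, column names, timestamp
convention, medication-ID space and username space. Normalization maps
medications through a formulary cross-map (which also carries a unit factor:
wholesaler rows arrive in packages and are converted to each medication's
base unit — each, mg or mcg) and usernames through an identity cross-map
(married/maiden variants map two local usernames to one clinician). Two
policies are deliberate:

* **No silent drops.** Malformed rows (bad timestamp, negative or
  non-numeric quantity, unknown transaction code) go to a reject report with
  row number and reason; per file, parsed + rejected equals the raw row
  count. Unmapped medications or usernames keep their row with a null
  canonical ID and are counted in an unmapped report. Downstream logic uses
  outer-join semantics — an unmatched dispense *is* the signal — so mapping
  failures must never delete evidence.
* **Deterministic order.** The ledger sorts by (clinician, timestamp,
  transaction ID); same-minute ties break lexicographically on the ID.
  Duplicate transaction IDs are a hard error. Timestamps are minute
  resolution, naive local time (one hospital, one zone).

An optional `sso` flag treats usernames as already canonical, for hospitals
with single sign-on.

## Custody reconciliation

Every cabinet dispense opens one custody episode. Settling events
(administer, waste, return, transfer) attach by explicit cabinet reference
when the extract carries one; otherwise by the documented matching rule:
*same patient and canonical medication, dispense at or before the event,
within a 24-hour window; smallest nonnegative gap wins; equal gaps break
toward the smaller dispense ID*. The window is deliberately generous against
the 4-hour lateness threshold so that late settlements still reconcile.
Events that match nothing are emitted as orphans, never attached arbitrarily.
The rule is simple enough to check exhaustively: a brute-force matcher that
enumerates all feasible linkings and applies the same optimum is part of the
test suite and agrees on 200 random instances of ≤ 50 events.

Per episode, `missing = dispensed − administered − wasted − returned −
transferred`, computed in float64; quantities are small sums of at most a few
two-decimal values, so the conservation identity holds to well below the
1e-9 tolerance the tests assert. Negative missing quantity
(over-documentation) is retained and visible, not clamped — it is a charting
anomaly worth seeing. Multiple administrations may settle one dispense
(PCA and infusions give cumulative doses); patches settle with a single
administration. A linked event charting a different canonical medication
marks the episode as medication-mismatched; its quantity still counts toward
settlement so that the mismatch, not a phantom missing quantity, carries the
signal.

Supply reconciliation matches wholesaler shipments to vault receipts by
(invoice, medication) and vault issues to cabinet restocks by issue
reference; `shortfall = expected − observed`, with negative shortfalls
(overages) retained and flagged separately. Off-clock detection pairs
clock-ins with the next clock-out per clinician and flags medication
transactions outside every interval ± a 30-minute grace period (configurable;
the value is a policy choice, not a published constant), reporting minutes
beyond the grace boundary. Clinicians with medication activity but no clock
data are skipped and reported.

## Features

Fourteen binary flags per episode (timing / quantity / practice /
cross-system), listed in `rxdivert.FEATURE_ORDER`; the defining thresholds
live in `FeatureParams`:

* `late_*`: strictly more than `late_threshold_hours` (default 4 h) from
  dispense to the earliest linked waste or administration. Exactly 4 h is
  not late; the boundary is property-tested. Lateness is measured between
  charted event timestamps — the extracts carry no separate documentation
  time.
* `no_administration` is defined as *nothing settled at all* (no
  administration, waste or return; the full dose missing). A broader reading
  — "administered quantity zero" — would make the flag a superset of
  `full_wasting` and `partial_waste_return`; the disjoint partition
  (`no_administration` / `partial_waste_return` / `full_wasting` /
  `partial_administration`) keeps each flag attributable to exactly one
  behavior, which the ground-truth recovery tests require.
* `bulk_wasting`: the episode's waste belongs to a run of ≥ 3 wastes by the
  same clinician inside a 10-minute window (both numbers are invented
  defaults for a concept usually described qualitatively; config-exposed).
* `handoffs` is read as "more than one clinician touches the episode";
  `incorrect_order` as a custody-sequence violation (a settling event charted
  before its dispense). Both are declared interpretations of practice
  anomalies that have no standard operational definition; the alternative
  reading of "incorrect order" (against the prescription) is out of scope.
  Handoff episodes emit a secondary feature vector for the settling
  clinician, so both sides of a custody gap are scoreable.
* `pain_score_anomaly` is a deliberately simplified placeholder for clinical
  cross-checking: a PRN analgesic dispense with no pain score charted for
  that patient within ± 60 minutes. Real clinical context modeling (dose
  against pain trajectory) is out of scope.

Supply shortfalls emit their own feature vectors attributed to the
responsible technician. One-hot encoding is the identity on the flag columns
with a fixed, documented column order.

## Risk scoring and classification

The risk score is a weighted sum of flags. The default weights (5 for
whole-dose and supply discrepancies, 4 for off-clock/bulk/wrong-medication,
3 for partials, 2 for timing and sequence, 1 for handoffs and pain context)
encode an investigator's ordering of how directly each behavior maps to
diversion; since the operative threshold is a percentile of the resulting
scores, the weights shape ordering only, and they are fully configurable.

High-risk labeling uses the nearest-rank empirical percentile with the
"higher" convention (`numpy.quantile(..., method="higher")`): a transaction
is high iff its score ≥ the threshold, so 100 distinct scores at the 98th
percentile yield exactly 2 high labels, and degenerate all-equal scores label
everything high (ties at the threshold are never split). On heavily
zero-inflated score distributions the 98th percentile of *all* scores can
collapse to zero; `percentile_over="nonzero"` computes the threshold over
nonzero scores instead. Fewer than 50 scores is an error — a tail percentile
of a handful of values is noise.

Training reproduces the heuristic from the flags alone: stratified 60/40
split with a seeded shuffle, random-duplication oversampling of the minority
class to parity *in the training split only* (duplication, not synthetic
interpolation — the simplest method consistent with oversampling rare
high-risk transactions; provenance of every duplicate is tracked and the
tests assert none leaks into the held-out 40%), stratified 5-fold
cross-validation on the training data (K = 5 is a convention choice), final
metrics on the untouched held-out split. Logistic regression is the default
(fast, deterministic, and the labels are a linear threshold of the features);
random forest is available. Models serialize with joblib and reload to
bitwise-identical predictions. Single-class inputs are rejected with guidance
rather than silently fit.

## Detection-latency evaluation

For each roster incident, the earliest alert is the minimum timestamp among
the clinician's predicted-high transactions — emulating a daily feed in
which each day's data would have been scored as it arrived. *Improvement in
detection time* is the whole-calendar-day difference between the alert's
date and the existing-method detection date, ignoring time of day. One
auditable convention is used for every row rather than per-row fitting; on
the bundled 16 day-resolved benchmark incidents it reproduces 10 published
improvements exactly and the remainder within one day (those rows follow an
alert-time-of-day convention the published tables do not state). An alert on
or after the detection date yields improvement 0 with a `not_earlier` flag,
never a negative value. Month-resolution roster dates are accepted (first of
the month, annotated) and excluded from exact date-recomputation checks.
Aggregates report n / mean / median / min / max per site and overall, with
mean and median rounded half-up to whole days and the even-count median as
the midpoint of the two central values — the convention that reproduces all
published benchmark summary cells exactly.

## The synthetic hospital

The generator emulates the statistical structure the pipeline assumes, not a
clinical simulation. Defaults describe one desk-scale hospital: 200
clinicians (6 pharmacy technicians, the rest nursing), 90 days, 120 beds,
about 10⁵ movement transactions — two orders of magnitude below a multi-site
production dataset, chosen so the full pipeline runs in seconds; nothing in
the code depends on scale. Clinicians work fixed day/night 8 h or 12 h shift
patterns with tight clock punches; a seven-item formulary spans the five
dosage forms (oral solids in integer units; injections, infusions and PCA in
decimal mg/mcg, exercising partial-waste arithmetic); weekly wholesaler
shipments flow invoice → vault receipt → vault issue → cabinet restock with
stock conservation by construction. Lawful workflow is dispense → pain
assessment for PRN analgesics → administration within 45 minutes → witnessed
waste of any remainder, or unopened return. A patient is never re-dispensed
the same medication within 8 hours — a dosing-interval constraint that also
makes rule-based custody linkage provably unambiguous, since every lawful or
injected settle delay is under 8 hours.

Diverters carry a `BehaviorProfile`: an onset date plus per-opportunity
probabilities for thirteen behaviors (eleven dispense-level, two
supply-level; a profile with supply behaviors is hosted by a pharmacy
technician). No base rates for diverter behaviors exist in the literature;
the defaults (totaling 0.56 per dispense opportunity, full wasting the most
frequent) are the package's own choice and are fully config-exposed. Each
injection is constructed to set exactly its own flag among the injectable
behaviors, which is what makes per-feature sensitivity and specificity of
1.0 against ground-truth tags a testable property. Three generator choices
serve ground-truth cleanliness and are worth knowing when interpreting
results:

* benign documentation noise (lawful partial dosing, slow charting, missed
  pain scores — defaults 2% / 0.5% / 0.5%) applies to non-diverters only, so
  that no alert can precede a diverter's onset;
* handoff and witness partners are drawn from non-diverting nurses on shift;
* bulk-wasting bursts span distinct patients, as simultaneous leftovers
  would in practice.

What the generator does *not* emulate: patient clinical trajectories beyond
pain scores, pediatric dosing, multi-hospital federation, duplicate charting
across systems, clock-punch errors, and adversaries who adapt their behavior
to avoid the specific features. Consequently, passing tests show the
pipeline recovers planted structure under realistic formats and noise — not
that the feature set is sufficient against real, adaptive diverters; the
near-perfect classifier metrics on synthetic data say the classifier
reproduces the percentile heuristic, not that the heuristic finds all real
diversion.

## Numerical and degenerate-input conventions

Quantity comparisons use a 1e-9 absolute tolerance; timestamps are minute
resolution throughout. Determinism is a contract: one seeded RNG drives
generation (same config ⇒ byte-identical files), and the split, oversampling,
cross-validation and forest seeds all derive from the risk seed. Degenerate
inputs fail loudly: date ranges under one day, dosage-form mixes not summing
to 1, behavior rates outside [0, 1], non-functional cross-maps, mismatched
extract headers, duplicate transaction IDs, single-class training data, and
percentile requests on fewer than 50 scores are all errors, not warnings.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on constructed micro-fixtures and two 40-clinician
× 45-day worlds (one noisy, one noise-free). The acceptance script runs the
default 200 × 90 world (≈ 10⁵ transactions), a 60-clinician clean-world
control, a 12,000-score label-fraction check, and 200 random oracle
instances; end to end it completes in well under a minute on one CPU.
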