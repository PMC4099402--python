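# Methods

## Data model and cohort definition

A visit record carries 1–3 ordered ICD-9 codes (first = main reason for the
visit), a modality set over {CHM, ACUPUNCTURE, MASSAGE}, and, for CHM
visits, an itemized prescription. Codes are accepted dotted or undotted
("6254" ≡ "625.4") and stored dotted; normalization is idempotent. A CHM
product is either a herbal formula (HF, a fixed multi-herb concentrate) or a
single herb (SH), with a daily dose in grams of concentrated powder, a
duration in days and an administrations-per-day frequency. A duplicate
product within one prescription is rejected at read time: no aggregation
rule (sum doses? keep first?) is defensible without knowing whether split
dosing occurs in the source system, so the reader fails loudly instead of
guessing.

Cohort selection interprets "single diagnosis of the target condition"
strictly: the diagnosis list must equal `[target]`, not merely lead with it,
because the design intent is to exclude co-morbidity-influenced
prescriptions. Two denominators are kept on the cohort object: all
target-diagnosis visits (the denominator of the CHM modality share) and
retained CHM prescriptions N (the denominator of every prevalence). CHM
visits with an empty item list are excluded and logged. With a zero
denominator the modality share is reported as undefined (`None`), never 0.

## Statistics

Prevalence of a CHM (or unordered pair) is 100·instances/N where *instances*
counts prescriptions containing it — not grams, not patients. Percentages
are rounded half-up to one decimal, the convention of printed claims tables
(banker's rounding would turn e.g. 0.05 into 0.0). Mean dose and duration
are averaged over the prescriptions containing the product. Dosing frequency
is a prescription-level attribute; data with per-item disagreement are
resolved by the prescription's modal value (lowest value on a modal tie) and
logged. Pair members are ordered within a row by descending marginal
instances, then lexicographically; rows sort by pair instances descending
with the canonical order as tie-break, so output is deterministic.

The HF/SH composition of the top-k pair list (`combo_type_share`) reports
the full three-way HF-HF / HF-SH / SH-SH split summing to 100%; no single
headline share is privileged, since the choice of denominator for such a
headline is ambiguous.

## Association rule mining

Transactions are deduplicated prescription item sets; HF and SH share one
item universe (formula–formula pairs are meaningful and do occur). Support
of an itemset is count/n; confidence of A → B is support(A ∪ B)/support(A).
Mining is level-wise Apriori: level-k candidates join two frequent (k−1)-sets
sharing a (k−2)-prefix and are pruned unless every (k−1)-subset is frequent.
Counting uses a vertical bitset layout — each item maps to an integer
bitmask over transactions, and any candidate's count is the popcount of an
AND — so counting cost is independent of transaction length and the 20k×40
synthetic runs finish in well under a second.

Numerical choices:

* **Thresholds are inclusive (≥).** Defaults 0.01 support / 0.30 confidence.
  A strict inequality on floats makes the boundary case untestable and
  fragile; inclusiveness is stated in the config docs.
* `min_support = 0` is rejected (unbounded output) with a message suggesting
  a positive floor.
* `max_itemset_size` defaults to 3: pairs are the analytic target, triples
  are cheap and occasionally informative; pair-only output is one flag away.
* All outputs are canonically sorted (support, confidence, lexicographic
  itemset string) so identical inputs give byte-identical tables.

Rules are directional, but combinations are conventionally reported
unordered; `undirected_pairs` collapses directed rules on the same pair (a
pair is significant if *either* direction passed) and annotates both
directions' confidences, reconstructing the failed direction from the
itemset table. Both views — raw frequency-ranked pairs and rule-filtered
pairs — stay available, because the two rankings answer different questions
and need not agree (a dominant formula can head the frequency ranking while
failing the 30% confidence bar in the formula→herb direction).

## Co-prescription network

Nodes are the endpoints of the selected top-k pairs (k = 10 by default),
annotated with prevalence and type; edges carry co-occurrence counts; no
self-loops. The "core treatment" is not defined quantitatively in the
descriptive literature — networks are read visually — so a reproducible
criterion is adopted: the node maximizing weighted degree (sum of incident
edge counts), tie-broken by prevalence then identifier. On the published
top-10 pair table bundled in `herbnet.published` this criterion selects the
dominant formula (weighted degree 3,796 over 7 incident pairs), matching the
visually identified hub. The handshake identity (Σ weighted degrees = 2 Σ
edge counts) and order-invariance of the core are enforced by tests.
GraphML export preserves all attributes and round-trips exactly; the edge
list is a three-column convenience format. Note: the published pair table
contains one herb (Curcuma longa) whose marginal count falls below the
printed single-herb top ten; its node is annotated with the pair's
prevalence (1.8%), a published lower bound — this cannot affect core
identification.

## Synthetic claims generator

The generator emulates the structure the analysis assumes, with closed-form
ground truth:

* **Patients and visits.** Visits per patient ~ 1 + Poisson(mean − 1) with
  mean 2.5 (matching the visits-per-patient ratio of the emulated cohort);
  visit dates uniform over 1998–2011. A visit's primary diagnosis is the
  target code with probability 0.5; target visits carry a secondary
  distractor code with probability 0.10 (these fall to the sole-diagnosis
  filter); 3.4% of CHM target visits also receive acupuncture or massage,
  reproducing a ~96.6% CHM modality share.
* **Baskets.** Core/baseline items enter independently with configured
  marginal probabilities; each adjuvant rule (A, B, c) whose antecedent is in
  the marginal-pass basket adds B with probability c — one pass, in listed
  order, no chaining. Rule antecedents may not themselves be rule adjuvants
  (validated), which keeps every implied probability closed-form:
  P(B) = 1 − (1 − p_B)·Π(1 − p_A·c) and
  P(B | A) = 1 − (1 − p_B)·(1 − c)·Π_{other rules}(1 − p_{A'}·c'), with
  P(A ∩ B) = p_A · P(B | A) by construction.
* **Default calibration.** Five formulas (marginals 37.5% down to 7.2%), ten
  named single herbs whose implied marginals track the published prevalence
  ladder once the five formula→herb rules (conditional probabilities 0.35,
  0.26, 0.16, 0.11, 0.07) are folded in, one low-frequency herb, and a
  26-item adjuvant tail at 14.5% each, giving an expected prescription size
  of 5.41 items. Doses are normal truncated at zero (HF ≈ 3.9–4.9 g/day,
  SH ≈ 1.2–1.4 g/day, reproducing the formula/herb dose-scale gap); duration
  and frequency are drawn once per prescription, frequency weights
  {2: 2.6%, 3: 89%, 4: 8.4%}.
* **Empty baskets.** Independent inclusion leaves ~0.45% of target baskets
  empty; those visits are emitted as acupuncture-only (keeping the record
  invariant "items nonempty iff CHM modality"), so they stay in the
  target-visit denominator and leave the CHM cohort. Ground-truth
  probabilities are per sampled prescription; conditioning on nonemptiness
  biases marginal supports by ≈0.2% relative, far inside the 3-standard-error
  bands used in recovery tests.
* **Determinism.** One `numpy` Generator seeded from the config; fixed seed
  ⇒ byte-identical CSVs (tested).

What the generator does *not* emulate: demographics (age/sex), seasonality,
longitudinal treatment episodes, per-item duration/frequency variation, and
realistic distractor-diagnosis casemix. Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed independence
structure, not robustness to real-world confounding.

## Validation strategy and problem sizes

* Mining is checked for exact agreement against a brute-force
  subset-enumeration oracle (no pruning, no candidate generation) on 100
  random instances of ≤ 12 items and ≤ 200 transactions, plus
  hypothesis-driven property tests (downward closure, support ≤ confidence,
  threshold monotonicity).
* Parameter recovery runs at ~20,000 qualifying prescriptions (18,500
  patients): every planted marginal, pair and conditional probability must
  be matched within 3 binomial standard errors by the mining estimates.
* Cohort filtering is cross-checked against an independent row-level scan of
  the written CSVs.
* The published-count worked examples are exact arithmetic: every printed
  prevalence percentage must reproduce from its printed numerator and
  denominator, and the published top-10 pair network must return the
  dominant formula as core.

Headline data-dependent values of the emulated cohort that no synthetic run
can certify (e.g. the exact 5.4 mean items or 89.0% thrice-daily share) are
treated as generator calibration targets, reported by the acceptance script
for inspection rather than asserted as test expectations beyond their
sampling bands.

## Known limitations

* The sole-diagnosis rule means multi-diagnosis PMS prescriptions are
  invisible to the analysis; prevalence is conditional on the clean cohort.
* Rule significance uses raw thresholds only — no lift, leverage or
  statistical testing; top-pair tables and rule-filtered tables can differ
  by design.
* The weighted-degree core criterion is one defensible operationalization of
  "network hub"; other centralities are deliberately out of scope.
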