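# Methods

This note documents the models, parameter choices and numerical conventions
behind `herbmine`, and what the synthetic validation does and does not
demonstrate about real clinical data.

## Records, screening and standardization

A record is one patient visit. Screening is a pure conjunction of criteria,
each reported by id (`age`, `duration`, `das28_before`, `das28_after`,
`haq_before`, `haq_after`, `vas`, `alt`, `ast`, `wbc`, `consent`,
`tcm_treated`); a record with any missing score field fails with the single
id `incomplete_record`. Inequalities are implemented exactly as the protocol
states them: strict where it says "greater/less than" (DAS28 bounds, WBC
"equal to or less than 3.5×10⁹/L" excludes 3.5), inclusive where it says
"≥" (age bounds, duration, HAQ-DI before treatment).

Standardization is dictionary-driven and total: unknown terms pass through
unchanged (and are logged) rather than erroring, because no curated
dictionary is exhaustive against free-text entry. The dictionary is validated
for idempotence (mapping twice changes nothing). Two deliberate non-merges
are encoded by *absence* from the dictionary: herbs that are distinct drugs
despite a shared pharmacopeia entry (Chuanniuxi / Niuxigen) and different
parts of one plant (Jinyinhua / Rendongteng).

The multi-joint rule *replaces* regional pain terms with `Polyarthralgia`
when ≥ 2 distinct body regions are present, rather than adding it: regional
pains and multi-joint pain are disjoint categories with separate counts in
the downstream frequency tables, which only relabelling preserves.
`Joint pain of lower extremity` is the canonical spelling; the variant
`Lower extremity joint pain` maps to it.

## Synthetic generator

The generator is a latent-class Bernoulli mixture. Each case draws a class
`c` with weight `w_c`, then every vocabulary item `i` independently with
probability `p_{c,i}`. For itemset `I`, `P(I) = Σ_c w_c Π_{i∈I} p_{c,i}`,
giving closed-form support, confidence and lift for any rule
(`expected_rule_metrics`). The mixture was chosen over e.g. copula or Ising
models because it (a) yields these closed forms, and (b) mirrors the
clinical intuition of "syndrome patterns": subpopulations in which certain
symptoms co-occur and certain herbs are jointly favoured.

Defaults define the study conditions:

- **Scale**: 311 eligible cases, the study corpus size.
- **Marginals**: the 16 herbs at their published prescription rates
  (e.g. Jinyinhua 182/311) and the 18 high-frequency symptoms at theirs
  (e.g. Thready pulse 116/311).
- **Dependence**: two equal-weight classes (wind-damp/deficiency-type vs
  heat-type, assigned from the herbs' efficacy categories and the pain
  lexicon). An item's probability is `rate × 1.5` in its own class and
  `rate × 0.5` in the other, so marginals are preserved exactly while
  same-group pairs carry lift `(1.5² + 0.5²)/2 = 1.25` and cross-group pairs
  `0.75`. The factor 1.5 is the largest round value keeping every
  probability below 1 (max is Jinyinhua, 0.585 × 1.5 = 0.878).
- **Ineligible fraction**: 0 by default; when set, an ineligible case fails
  exactly one randomly chosen criterion, so screening tallies are checkable.

Clinical score fields are drawn uniformly inside the eligible region; they
carry no association with items or outcomes. A case drawing zero herbs or
zero symptoms is redrawn (bounded at 100 attempts). This conditioning
slightly perturbs the closed-form metrics; fixture configurations therefore
include independent filler items that keep the empty-draw probability below
a few percent (for the canonical planted pair — P = 0.9/0.1 across two equal
classes, closed form support 0.41 / confidence 0.82 / lift 1.64 — exact
enumeration under conditioning gives 0.4207 / 0.8238 / 1.6133, which is why
recovery tests use a ±0.1 band around the closed form).

What the generator does *not* emulate: dose/gram information, visit
sequences and within-patient correlation, score–prescription dependence,
free-text spelling noise, and the long tail of sub-10% items. Passing tests
therefore demonstrate correctness of the *computations* under a plausible
dependence structure, not robustness to real-world data entry.

## Frequency analyses

Counts are case-level incidences (an item counts once per case); rates
divide by the number of eligible cases N, the one denominator used
throughout. Tables sort by count descending, ties alphabetically. The
high-frequency filter is implemented as rate ≥ 10%: the lowest enrolled item
in the reference tables sits at 12.22%, so the boundary is unobserved, and
an inclusive cut avoids float-equality pathologies. Rates are proportions
internally and percentages (2 decimals) in output files.

Efficacy-category shares default to frequency weighting —
`share(c) = Σ_{herb∈c} count / Σ count × 100` — because the reference ring
chart's percentages are not multiples of 1/16; equal-weight ("count")
weighting is available by flag. The packaged monograph table assigns each of
the 16 herbs its pharmacopeia efficacy category; under frequency weighting
these assignments reproduce the reference shares to within rounding
(Heat-clearing 242/1399 = 17.3% → 17, Tonifying 20.9% → 21, Wind-dampness
dispelling 20.4% → 20, …).

The pain share is occurrence-weighted: each (case, symptom) pair counts
once; the pain lexicon is the three regional pain terms plus
`Polyarthralgia`.

## Rule mining

Frequent itemsets come from the classic level-wise search: size-k candidates
join frequent (k−1)-itemsets sharing a prefix and are pruned when any
(k−1)-subset is infrequent (support is anti-monotone). Support counting is
vectorised over a boolean transactions × items matrix. Rules of order 2
(1→1) and 3 (2→1) are generated from frequent itemsets of that size; since a
rule's support equals its itemset's support, mining at the support threshold
is complete by construction, and `brute_force_rules` (exhaustive enumeration,
guarded to small vocabularies) verifies this in tests.

Lift is the standard `confidence / support(RHS)`; 1 means independence.
All three cuts are inclusive (≥ 10% support, ≥ 50% confidence, ≥ 1.2 lift);
`min_count ≥ 1` additionally drops zero-co-occurrence artifacts (redundant
given support > 0, kept as an explicit knob). Pairwise herb rules are mined
over herb-only transactions; third-order rules over mixed herb+symptom
transactions with unrestricted RHS class, since both herb and symptom
consequents are of clinical interest. Output ordering is lift desc, support
desc, then names, and output files use the percent scale for support and
confidence. With `min_support = 0` the miner substitutes the smallest
representable support (1/2N) as the enumeration floor, which preserves every
rule with at least one co-occurrence.

## Clustering

Herbs with prescription count strictly > 50 (as the inclusion rule states
it) form a binary herbs × cases incidence matrix. Metric and linkage are not
dictated by the source analysis; the defaults are Euclidean distance with
complete linkage — the documented defaults of the standard hierarchical
clustering routines — with Jaccard distance and single/average linkage
selectable. Herbs are clustered over *cases* (co-prescription space), the
only reading under which the described 0/1 matrix is actually used.

The implementation keeps the merge sequence explicit: clusters are labelled
by their sorted leaf names, and among equidistant pairs the lexicographically
smallest is merged first, making the dendrogram invariant to input row
order. Heights are non-decreasing for all three supported linkages (they are
monotone; no inversions). `cut_groups(k)` removes the k−1 last (highest)
merges; group ids follow first-leaf order; default k = 3. Newick export is
ultrametric (leaf-to-node path = height/2) with `repr`-formatted branch
lengths so parsing recovers heights exactly; among equal-height merges the
reconstruction order is canonicalized by (height, cluster size, labels),
which can permute tied merges relative to the original sequence — topology
and heights are the preserved invariants.

## Pipeline and reproducibility

Stage order is fixed: load → screen/clean → frequency → classify/edges →
mine(order 2, herbs) → mine(order 3, both) → cluster → write. All
randomness flows from the configured seed through one `numpy` generator; no
global random state is touched. Output files fix float formatting (`%.6g` in
CSVs), so a configuration reproduces its bundle byte-identically. A stage
failure raises with the stage name; the bundle writer removes a directory it
created if writing fails, leaving no partial bundles.

Validation problem sizes were chosen to give tight statistical checks at
interactive runtimes: marginal-recovery tests at n = 1000 across 20 seeds
(4-standard-error bands), planted-rule recovery at n = 2000 across 20 seeds,
the independence null at n = 20000 across 20 seeds (expected false-rule
count ≪ 1), miner/oracle equivalence on 200 random databases of ≤ 12 items
and ≤ 60 transactions, and clustering/Newick checks on ≤ 10-leaf trees.

## Known limitations

- The pairwise herb analysis and the clustering both summarise the same
  binary co-prescription structure; neither adjusts for confounding by
  indication (a herb pair may co-occur because both respond to a third
  symptom).
- Only the order-2/order-3 rule shapes of the reference analysis are
  implemented; general k→m rules are out of scope.
- The eligibility screen assumes complete score fields; no imputation is
  attempted (incomplete records are excluded by design).
- Mining treats transactions as exchangeable; repeat visits by one patient
  would violate this silently.
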