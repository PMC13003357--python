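# Methods

This note documents the models and procedures implemented in `ahrqsar`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not show.

## Dose–response curation

Input records carry a compound's AhR EC25 (µM), cytotoxicity EC20 (µM),
purity, replicate EC25s and structural/identity flags. Exclusion rules
fire in a fixed order, and each excluded record gets exactly the first
matching reason, so the ledger partitions the input
(`kept + excluded = input`):

1. **purity** — unreported or < 90%;
2. **mixture/inorganic** — flag;
3. **EC25 band** — EC25 in (100, 1000] µM, a gray zone between the Low
   band and the inactive threshold that is never banded;
4. **cytotoxicity** — active compounds with EC20 < 3 × EC25 (strict
   inequality: EC20 exactly 3 × EC25 survives), inactive compounds with
   EC20 < 100 µM;
5. **undefined CAS** for inactive compounds;
6. **replicate inconsistency** for active compounds;
7. **atypical curve** — a manual, externally supplied flag; computed
   last because it encodes expert judgement, not a reproducible rule.

Potency bands are contiguous and half-open — High (0, 2.03], Medium
(2.03, 10], Low (10, 100] — so every admissible EC25 maps to exactly one
category. The printed convention "Low 11–100" leaves (10, 11) open;
(10, 100] closes the gap without moving any published boundary.

**Replicate consistency** has no standard quantitative definition; the
rule used here bands each replicate on the 4-category ladder (anything
above 100 µM, including the gray zone and no-effect, ranks as inactive)
and calls the set inconsistent when the bands are non-adjacent
(max rank − min rank > 1). This is a documented stand-in isolated in one
function (`replicate_consistency`), easy to swap.

**Duplicates** are reconciled by keeping the lowest-EC25 record
(conservative toward activity; absent EC25 counts as +∞, ties break by
input order); reconciled-away records are ledgered under
`duplicate_reconciled` to preserve the partition invariant. Duplicate
ids with conflicting metadata (mixture or defined-CAS flags) are
unreconcilable and raise an error naming the offenders.

## Predictor matrix

The models consume a precomputed compounds × predictors matrix mixing
continuous descriptors and binary fingerprint bits; descriptor
generation is deliberately external (any generator producing a numeric
table keyed by compound id plugs in). Filtering removes columns with any
missing value, then columns with variability below 1%. "Variability"
needs separate definitions per column kind: for binary bits, the
minority-state frequency; for continuous descriptors, a near-constant
test (range ≤ 1e-8 of scale) or fewer than 1% of values away from the
mode. Both read the 1% threshold as a frequency criterion, which is the
only interpretation covering both kinds; the continuous rule is
interpretive and flagged as such.

After an initial fit, predictors can be reselected by permutation
importance on the OOB samples (mean decrease in accuracy, negatives
clipped to zero), keeping those with relative importance ≥ 0.05 of the
top predictor.

Aromaticity for routing is delegated to RDKit's default perception
model; different toolkits perceive borderline systems differently, so
the choice is a configuration note: a compound with any aromatic ring is
`aromatic_ring`, else any ring `nonaromatic_ring`, else `acyclic`.

## Weighted random forest and OOB validation

Forests are ensembles of fully grown CART trees
(`sklearn.tree.DecisionTreeClassifier`) over bootstrap samples, with
`predictors_per_split` (default ⌊√p⌋) features tried per split and
`min_node_size` (default 1) minimum leaf size. The ensemble layer —
bootstrap drawing, OOB vote bookkeeping, class weighting — is
implemented in-package so that the OOB probability matrix and both
weighting modes are first-class:

- **split mode (default):** uniform bootstrap; category weights enter
  each tree's impurity criterion as sample weights.
- **bootstrap mode:** each record's bootstrap selection probability is
  proportional to its category weight.

Bootstrap-level weighting is the more literal reading of "weighted
random sampling", but at a 10:1 imbalance with active weight 10 it
places minority records in ≈ 99.8% of every tree's sample; over a
300-tree forest roughly half the actives then receive *zero* OOB votes
and the rest are voted by a couple of trees, collapsing the OOB estimate
for exactly the class the weights protect. Split-level weighting
preserves uniform OOB coverage and is therefore the default; the
bootstrap mode remains available and is where the
weight-monotonicity property (raising the active weight does not hurt
OOB sensitivity) genuinely operates — for fully grown trees, split-level
weights are close to inert because leaves are pure regardless.

Class probabilities are vote fractions: in prediction, over all trees;
in the OOB matrix, over the trees for which the compound was
out-of-bag. The two legitimately differ for training compounds and are
reported distinctly. Argmax ties break toward the less active category
(conservative activity claims; configurable by reordering categories).
Compounds never OOB are flagged (`oob_missing`), not silently imputed.

**Tuning** maximizes OOB binary WOA over a grid whose axes mirror the
tuned quantities (number of trees, predictors per split, terminal node
size, active-category weight), optionally refined by a Gaussian-process
surrogate (Matérn 5/2, expected improvement over a seeded candidate
pool). Exact published step sizes for the original search are not
available; the defaults here (trees 200/400, mtry ½√p/√p/2√p, node size
1/5, weight 1/5/10) are the package's own and are fully overridable.
Every configuration is evaluated with the same seed; ties resolve to the
smaller forest.

**Routing:** non-aromatic compounds are predicted by the all-compound
3-category model only; aromatic compounds additionally get the aromatic
4-category model, which sharpens precision at the high-potency end.

## Prioritization and applicability domain

The rule table (see `ahrqsar.prioritize`) is evaluated strictly
top-down, first match wins. A threshold is met when the category's own
probability crosses it — the argmax category need not be the rule's
category (a vector with Low 0.47 / Medium-High 0.45 / Inactive 0.08
earns priority 3 though its top class is Low). "Medium/Medium-High/High
≥ 0.4" is read as any listed category crossing 0.4, not their sum. Where
a rule row lists both models, a match by either triggers it. The
3-category priority-2 rule is textually identical to the priority-3 rule
above it and hence unreachable; it is retained for table fidelity.
Compounds matching no rule are NR and are excluded from downstream
mixture accounting.

One consequence worth knowing: the priority order is monotone in
probability mass shifted from Inactive toward High only across the
*reliable* levels. Draining P(Inactive) below 0.6 loses the priority-0
rule before any active rule can fire, so a vector can pass through NR on
its way from priority 0 to 3/4. This is a property of the rule table
itself, not of the implementation.

## REP and BEQ accounting

REP = EC25(TCDD)/EC25(compound), dimensionless on the molar scale only —
site concentrations given as ng/L are converted to nM with the molar
mass before summation. Category REPs anchor to representative EC25s of
32 / 5 / 2.5 / 0.5 µM for Low / Medium / Medium-High / High. The TCDD
reference EC25 itself is a required configuration value; the shipped
default (2.43e-3 × 8.39e-4 ≈ 2.0388e-6 µM) is *derived* from an
internally consistent measured EC25/REP pair, not published, and should
be overridden with an assay-specific value when available.

BEQ_chem = Σ cᵢ·REPᵢ under concentration addition; explained percent is
100 · BEQ_chem / BEQ_bio and is reported above 100% as-is. Compounds
predicted inactive contribute zero rather than erroring in batch mode.
Scenarios: *baseline* uses only pre-existing experimentally anchored
REPs; *scenario 1* adds category REPs for reliably predicted (non-NR)
actives; *scenario 2* replaces predictions with measured EC25s where
compounds were tested and removes compounds whose testing was confounded
by cytotoxicity (same logic as the curation factor-3 rule). When the two
routed models disagree on an aromatic compound's category, the category
of the priority-triggering model is used.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not real chemistry: category labels drawn with a 10:1 inactive:active
imbalance and active mix 0.648/0.242/0.110 (Low/Medium/High); EC25
log-uniform strictly inside the true category's band (so banding the
values recovers the labels exactly); 20 informative descriptors with a
class-conditional mean shift of `class_separation` (default 2) standard
deviations per ladder step plus 80 noise descriptors and 32 fingerprint
bits; ring classes at 95% aromatic among actives and 59% among
inactives. Site tables set BEQ_bio = true BEQ_chem × inflation
(default 4), making the true explained fraction exactly 100/inflation —
a double-entry bookkeeping oracle. All randomness flows from one seed
through named child streams (labels, EC values, descriptors, flags,
records, sites), so partial regeneration is stable.

What passing tests show — and do not. The synthetic descriptors are
independent Gaussians/Bernoullis with clean class shifts; real
descriptor matrices are heavily correlated, partly redundant and far
less separable, and real activity cliffs have no analogue here.
Recovery of sensitivity/specificity ≥ 0.85 on the separable preset
demonstrates that the estimator, weighting and OOB machinery are
correct, not that comparable accuracy is attainable on real screening
data. The pure-noise preset (separation 0) checks the opposite
calibration point: OOB WOA at chance (0.5) rather than optimistically
biased. Even on the separable preset the 3-category task is
substantially harder than the binary one (~25 Low training compounds
against ~500 inactives), mirroring the real observation that the Low
band is the weakest link.

## Numerical choices and degenerate inputs

- Metric denominators of zero yield NaN flagged absent (MCC additionally
  carries `mcc_defined`), never a silent 0.
- Probability vectors must sum to 1 within 1e-6 at the prioritizer;
  OOB vectors are exact vote fractions.
- Problem sizes in tests and the acceptance script (550-compound
  training sets, 300-tree forests, 10,000-vector rule-engine sweeps,
  1,000-record curation properties) were chosen as the smallest sizes at
  which the checked statistics are stable.
- Seeds are explicit everywhere; no global random state is touched.

## Known limitations

- Descriptor generation (Mordred/PaDEL/fingerprints) is out of scope by
  design; the matrix adapter assumes upstream QSAR-ready standardization.
- Dose–response curve fitting is not reimplemented; EC25/EC20 values are
  consumed as given.
- The Bayesian refinement is a light GP-EI loop, adequate for the small
  mixed-integer space but not a general-purpose optimizer.
- Passive-sampler uptake modelling and non-additive mixture effects
  (antagonism, synergy) are outside the concentration-addition model.
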