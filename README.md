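# ahrqsar

Multi-level QSAR prioritization of aryl hydrocarbon receptor (AhR)
agonists, for environmental toxicologists screening water contaminants
with effect-based methods. The package covers the full workflow around a
high-throughput AhR reporter dataset: curating dose–response records
with cytotoxicity-aware exclusion rules, filtering structural predictor
matrices, training class-weighted random forests whose out-of-bag (OOB)
class probabilities double as an applicability domain, mapping those
probabilities to testing priorities, and accounting for mixture effects
at monitoring sites by concentration addition.

## The model in brief

**Activity categories.** A compound's AhR potency is banded by its EC25
(µM, concentration inducing 25% of maximal reporter response):
High (0, 2.03], Medium (2.03, 10], Low (10, 100], Inactive above
1000 µM or no effect; EC25 values in (100, 1000] are excluded as
unclassifiable. Cytotoxic confounding is removed with the factor-3 rule:
an active compound is dropped when its cytotoxicity EC20 < 3 × EC25
(reporter activity that close to cell death cannot be attributed to
receptor agonism), and an AhR-inactive compound is dropped when it is
cytotoxic below 100 µM.

**Classification.** Random forests of CART trees with per-category class
weights handle the ~10:1 inactive:active imbalance. Each training
compound receives an OOB probability vector — the share of trees that
did not see it during training voting for each category — giving
unbiased internal validation without a held-out split. Performance is
summarized on the binary active/inactive collapse:

    WOA = (sensitivity + specificity) / 2
    MCC = (TA·TI − FA·FI) / √((TA+FA)(TA+FI)(TI+FA)(TI+FI))

plus OA, precision and NPV. Two models are routed in production: a
3-category model for all compounds and a 4-category model for aromatic
compounds (where actives concentrate and finer banding is supportable).

**Prioritization.** A fixed rule table maps probability vectors to
priorities 4 (potent, reliable) down to 0 (inactive); vectors matching no
rule are NR (not reliable) — the probability-based applicability domain.

**Mixture accounting.** A compound's relative effect potency is
REP = EC25(TCDD) / EC25(compound); predicted categories use
representative EC25s of 32 / 5 / 2.5 / 0.5 µM (Low / Medium /
Medium-High / High). Under concentration addition, the chemically
explained TCDD-equivalent at a site is BEQ_chem = Σ cᵢ·REPᵢ, compared
against the bioassay-measured BEQ_bio as an explained-effect percentage.

## Worked example

```bash
python examples/train_and_validate.py
```

prints (seed-fixed):

```
training set: 550 compounds, 41 active
OOB sensitivity : 0.854
OOB specificity : 1.000
OOB WOA         : 0.927
OOB MCC         : 0.919
```

Sensitivity is the fraction of truly active compounds recovered by
trees that never trained on them; specificity the same for inactives.
WOA averages the two, so the 10:1 inactive majority cannot inflate it.
The other scripts under `examples/` demonstrate curation, priority
assignment and site-level BEQ accounting, each printing a short
interpretation of its output.

The same workflow is scriptable from the shell:

```bash
ahrqsar simulate --seed 3 --n 250 --out-dir run/
ahrqsar curate --input run/dose_response.csv --scheme 3cat --out-dir run/
ahrqsar train --descriptors run/descriptors.csv --curated run/curated.csv \
        --out run/model.joblib
```

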