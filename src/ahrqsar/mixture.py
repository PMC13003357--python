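"""Relative effect potency (REP) and concentration-addition mixture accounting.

A compound's REP is the EC25 of the reference AhR agonist TCDD
(2,3,7,8-tetrachlorodibenzo-p-dioxin) divided by the compound's EC25 —
a dimensionless potency relative to TCDD on the molar scale.  For
compounds with only a predicted activity category, the REP is anchored to
a fixed representative EC25 per category (the geometric mean of curated
EC25 values in that category):

    Low 32 uM, Medium 5 uM, Medium-High 2.5 uM, High 0.5 uM.

Under concentration addition the chemically-explained bioanalytical
equivalent at a site is

    BEQ_chem = sum_i  c_i * REP_i        [nM TCDD equivalents]

and the explained effect fraction is 100 * BEQ_chem / BEQ_bio, where
BEQ_bio is the bioassay-measured TCDD-equivalent of the site extract.
Fractions above 100% are reported as-is.

The TCDD reference EC25 is a required configuration value; the shipped
default (~2.0388e-6 uM) is the value implied by internally consistent
measured EC25/REP pairs, derived rather than published — override it when
an assay-specific TCDD EC25 is available.

Three accounting scenarios: *baseline* uses only pre-existing
(experimentally anchored) REPs; *scenario 1* adds category REPs for
compounds with reliable (non-NR) active predictions; *scenario 2*
replaces predicted REPs with new experimental EC25s where compounds were
tested, and drops compounds whose testing was confounded by cytotoxicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .curation import ActivityCategory

__all__ = [
    "TCDD_EC25_DEFAULT_UM",
    "CATEGORY_BASIS_EC25_UM",
    "REPEntry",
    "SiteSample",
    "BEQResult",
    "category_rep",
    "rep_from_ec25",
    "beq_chem",
    "run_scenarios",
    "ng_per_l_to_nM",
]

#: Derived, not published: product of a measured compound EC25 and its
#: reported REP (2.43e-3 uM x 8.39e-4).
TCDD_EC25_DEFAULT_UM = 2.43e-3 * 8.39e-4

#: Representative EC25 (uM) per predicted activity category.
CATEGORY_BASIS_EC25_UM = {
    ActivityCategory.LOW: 32.0,
    ActivityCategory.MEDIUM: 5.0,
    ActivityCategory.MEDIUM_HIGH: 2.5,
    ActivityCategory.HIGH: 0.5,
}

CYTOTOXIC = "cytotoxic"


@dataclass
class REPEntry:
    compound_id: str
    rep: float
    source: str  # predicted_category | experimental | literature
    basis_ec25_uM: float
    category: ActivityCategory | None = None

    def __post_init__(self) -> None:
        if self.rep <= 0:
            raise ValueError("REP must be strictly positive")
        if self.basis_ec25_uM <= 0:
            raise ValueError("basis EC25 must be strictly positive")


@dataclass
class SiteSample:
    """One site x passive-sampler extract: molar compound concentrations
    (nM) and the bioassay-measured TCDD-equivalent (nM)."""

    site_id: str
    sampler: str  # HLB (polar) or SR (nonpolar)
    concentrations_nM: dict = field(default_factory=dict)
    beq_bio_nM: float | None = None

    def __post_init__(self) -> None:
        for cid, c in self.concentrations_nM.items():
            if c < 0:
                raise ValueError(f"negative concentration for {cid}")
        if self.beq_bio_nM is not None and self.beq_bio_nM <= 0:
            raise ValueError("beq_bio must be strictly positive when given")


@dataclass
class BEQResult:
    site_id: str
    sampler: str
    scenario: str
    beq_chem_nM: float
    explained_pct: float  # NaN when no beq_bio available
    n_contributing: int
    exclusions: list = field(default_factory=list)


def ng_per_l_to_nM(conc_ng_per_l: float, molar_mass_g_mol: float) -> float:
    """ng/L over g/mol is nmol/L = nM (REPs are dimensionless only on the
    molar scale, so mass concentrations must be converted first)."""
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be strictly positive")
    return conc_ng_per_l / molar_mass_g_mol


def rep_from_ec25(ec25_compound_uM: float, tcdd_ec25_uM: float = TCDD_EC25_DEFAULT_UM) -> float:
    """REP = EC25(TCDD) / EC25(compound); equipotent with TCDD gives 1."""
    if ec25_compound_uM <= 0 or tcdd_ec25_uM <= 0:
        raise ValueError("EC25 values must be strictly positive")
    return tcdd_ec25_uM / ec25_compound_uM


def category_rep(
    category: ActivityCategory | str,
    tcdd_ec25_uM: float = TCDD_EC25_DEFAULT_UM,
    compound_id: str = "",
) -> REPEntry:
    """REP for a predicted activity category via its representative EC25."""
    cat = category if isinstance(category, ActivityCategory) else ActivityCategory(category)
    basis = CATEGORY_BASIS_EC25_UM.get(cat)
    if basis is None:
        raise ValueError(f"no REP defined for category {cat.value!r}")
    return REPEntry(
        compound_id=compound_id,
        rep=rep_from_ec25(basis, tcdd_ec25_uM),
        source="predicted_category",
        basis_ec25_uM=basis,
        category=cat,
    )


def _rep_map(reps) -> dict:
    """Index REP entries by compound id; conflicting duplicates error."""
    out: dict[str, REPEntry] = {}
    for entry in reps:
        prev = out.get(entry.compound_id)
        if prev is not None and not math.isclose(prev.rep, entry.rep, rel_tol=1e-9):
            raise ValueError(
                f"conflicting REP entries for {entry.compound_id}: "
                f"{prev.rep} vs {entry.rep}"
            )
        out[entry.compound_id] = entry
    return out


def beq_chem(
    sample: SiteSample,
    reps,
    exclusions: set | None = None,
    scenario: str = "baseline",
) -> BEQResult:
    """Concentration-addition sum over compounds with a REP.

    Compounds without a REP entry (e.g. predicted inactive) contribute
    zero; excluded ids (NR, cytotoxic) are skipped and recorded.
    """
    exclusions = set(exclusions or ())
    rep_map = _rep_map(reps)
    total = 0.0
    contributing = 0
    skipped = []
    for cid, conc in sample.concentrations_nM.items():
        if cid in exclusions:
            skipped.append(cid)
            continue
        entry = rep_map.get(cid)
        if entry is None:
            continue
        contribution = conc * entry.rep
        total += contribution
        if contribution > 0:
            contributing += 1
    explained = (
        100.0 * total / sample.beq_bio_nM
        if sample.beq_bio_nM is not None
        else math.nan
    )
    return BEQResult(
        site_id=sample.site_id,
        sampler=sample.sampler,
        scenario=scenario,
        beq_chem_nM=total,
        explained_pct=explained,
        n_contributing=contributing,
        exclusions=sorted(skipped),
    )


def run_scenarios(
    samples,
    baseline_reps,
    predicted_categories: dict | None = None,
    priorities: dict | None = None,
    experimental_overrides: dict | None = None,
    tcdd_ec25_uM: float = TCDD_EC25_DEFAULT_UM,
) -> list[BEQResult]:
    """Baseline / scenario-1 / scenario-2 accounting per site and sampler.

    ``predicted_categories`` maps compound id to its predicted
    :class:`ActivityCategory`; ``priorities`` maps compound id to its
    priority label — compounds with label "NR" never receive a predicted
    REP.  ``experimental_overrides`` maps compound id to a measured EC25
    (uM) or the string ``"cytotoxic"``; cytotoxic compounds are removed
    from scenario 2 entirely, mirroring the curation logic.
    """
    predicted_categories = predicted_categories or {}
    priorities = priorities or {}
    experimental_overrides = experimental_overrides or {}

    baseline = list(baseline_reps)
    baseline_ids = {e.compound_id for e in baseline}

    predicted: list[REPEntry] = []
    for cid, cat in predicted_categories.items():
        if cid in baseline_ids:
            continue  # experimentally anchored REP takes precedence
        if str(priorities.get(cid, "")) == "NR":
            continue
        cat = cat if isinstance(cat, ActivityCategory) else ActivityCategory(cat)
        if cat in (ActivityCategory.INACTIVE, ActivityCategory.ACTIVE):
            continue  # inactive contributes zero; bare "Active" has no basis EC25
        predicted.append(category_rep(cat, tcdd_ec25_uM, compound_id=cid))

    cytotoxic_ids: set[str] = set()
    experimental: list[REPEntry] = []
    overridden: set[str] = set()
    for cid, value in experimental_overrides.items():
        if isinstance(value, str):
            if value != CYTOTOXIC:
                raise ValueError(
                    f"override for {cid} must be an EC25 or {CYTOTOXIC!r}"
                )
            cytotoxic_ids.add(cid)
            overridden.add(cid)
            continue
        experimental.append(
            REPEntry(
                compound_id=cid,
                rep=rep_from_ec25(float(value), tcdd_ec25_uM),
                source="experimental",
                basis_ec25_uM=float(value),
            )
        )
        overridden.add(cid)
    scenario2 = (
        [e for e in baseline if e.compound_id not in overridden]
        + experimental
        + [e for e in predicted if e.compound_id not in overridden]
    )

    results = []
    for sample in samples:
        results.append(beq_chem(sample, baseline, scenario="baseline"))
        results.append(
            beq_chem(sample, baseline + predicted, scenario="scenario1")
        )
        results.append(
            beq_chem(sample, scenario2, exclusions=cytotoxic_ids, scenario="scenario2")
        )
    return results
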