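"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates the shape of a curated high-throughput AhR
screening set: roughly ten inactive compounds per active one, active
EC25 values banded into Low/Medium/High with Table-like proportions,
class-informative continuous descriptors plus binary fingerprint bits,
and a predominantly aromatic active class.  It also emits site
concentration tables whose bioassay-equivalent is fixed by construction
(BEQ_bio = true BEQ_chem x inflation), so the explained-effect fraction
is known exactly.

Descriptors are abstract numeric columns, not real chemistry; an
optional mode attaches simple real SMILES (alkanes, cycloalkanes,
fused-aromatic cores) per ring class so structure parsing is exercised
end-to-end.  All randomness flows from one seed through named child
streams (labels, ec, descriptors, flags, records, sites — in that
order), so partial regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import (
    HIGH_UPPER_UM,
    INACTIVE_LOWER_UM,
    LOW_UPPER_UM,
    MEDIUM_UPPER_UM,
    ActivityCategory,
    DoseResponseRecord,
)
from .features import DESCRIPTOR, FINGERPRINT, DescriptorMatrix
from .mixture import TCDD_EC25_DEFAULT_UM, REPEntry, SiteSample, rep_from_ec25

__all__ = ["GeneratorConfig", "SyntheticCompounds", "SyntheticSites",
           "generate_compounds", "generate_sites"]

#: EC25 sampling windows (uM), strictly inside each band so banding the
#: generated values recovers the true label exactly.
_BAND_WINDOWS = {
    ActivityCategory.HIGH: (1.1e-4, HIGH_UPPER_UM * 0.99),
    ActivityCategory.MEDIUM: (HIGH_UPPER_UM * 1.02, MEDIUM_UPPER_UM * 0.99),
    ActivityCategory.LOW: (MEDIUM_UPPER_UM * 1.05, LOW_UPPER_UM * 0.99),
}

#: Simple SMILES pools per ring class (optional realistic mode).
_SMILES_POOLS = {
    "acyclic": ["CCCC", "CCCCCC", "CCO", "CC(C)CC", "CCCCCCCC", "CC(=O)OCC"],
    "nonaromatic_ring": ["C1CCCCC1", "C1CCCC1", "C1CCOC1", "C1CCCCCC1"],
    "aromatic_ring": [
        "c1ccccc1",
        "c1ccc2ccccc2c1",
        "c1ccc2cc3ccccc3cc2c1",
        "c1ccc2c(c1)ccc1ccccc12",
        "c1cc2ccc3cccc4ccc(c1)c2c34",
    ],
}


@dataclass
class GeneratorConfig:
    """Study-shaped defaults: 10:1 imbalance, Low/Medium/High mix
    0.648/0.242/0.110 among actives, 95% aromatic actives vs 59% aromatic
    inactives, 20 informative descriptors with a 2-sd class shift."""

    n_compounds: int = 550
    imbalance_ratio: float = 10.0
    category_mix: tuple = (0.648, 0.242, 0.110)  # Low, Medium, High
    n_informative: int = 20
    n_noise: int = 80
    n_fingerprint: int = 32
    class_separation: float = 2.0
    aromatic_frac_active: float = 0.95
    aromatic_frac_inactive: float = 0.59
    seed: int = 0
    emit_smiles: bool = False
    #: fraction of additional rule-tripping records per exclusion reason
    trip_fractions: dict = field(default_factory=dict)
    # site-table parameters
    site_count: int = 8
    sampler_types: tuple = ("HLB", "SR")
    concentration_range_nM: tuple = (0.01, 100.0)
    compounds_per_site: int = 25
    beq_inflation: float = 4.0
    tcdd_ec25_uM: float = TCDD_EC25_DEFAULT_UM

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if self.imbalance_ratio <= 0:
            raise ValueError("imbalance_ratio must be positive")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix proportions must sum to 1")
        if self.beq_inflation < 1:
            raise ValueError("beq_inflation must be >= 1")
        if min(self.n_informative, self.n_noise, self.n_fingerprint) < 0:
            raise ValueError("predictor counts must be non-negative")
        if self.n_informative + self.n_noise + self.n_fingerprint == 0:
            raise ValueError("at least one predictor column is required")


@dataclass
class SyntheticCompounds:
    records: list
    matrix: DescriptorMatrix
    labels: pd.Series  # true 4-category ActivityCategory per compound id
    ring_classes: pd.Series
    smiles: pd.Series | None = None


@dataclass
class SyntheticSites:
    samples: list
    true_reps: list  # REPEntry per active compound, from the true EC25
    bookkeeping: pd.DataFrame  # per site x sampler: true BEQ_chem, BEQ_bio


def _streams(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


_RANK = {
    ActivityCategory.INACTIVE: 0,
    ActivityCategory.LOW: 1,
    ActivityCategory.MEDIUM: 2,
    ActivityCategory.HIGH: 3,
}


def generate_compounds(cfg: GeneratorConfig) -> SyntheticCompounds:
    """Draw labels, EC values, descriptors, ring classes and records.

    EC25 values are log-uniform within the true category's band, so
    banding them recovers the labels exactly (round-trip property).
    Informative descriptors get a class-conditional mean shift of
    ``class_separation`` standard deviations per ladder step; noise
    columns are class-independent.  Optional ``trip_fractions`` append
    extra records each engineered to trip one named exclusion rule.
    """
    s_labels, s_ec, s_desc, s_flags, s_records, _ = _streams(cfg.seed, 6)

    p_active = 1.0 / (1.0 + cfg.imbalance_ratio)
    probs = [1.0 - p_active] + [p_active * m for m in cfg.category_mix]
    cat_pool = [
        ActivityCategory.INACTIVE,
        ActivityCategory.LOW,
        ActivityCategory.MEDIUM,
        ActivityCategory.HIGH,
    ]
    rng = np.random.default_rng(s_labels)
    draws = rng.choice(len(cat_pool), size=cfg.n_compounds, p=probs)
    labels = [cat_pool[i] for i in draws]
    ids = [f"SYN{i:05d}" for i in range(cfg.n_compounds)]

    rng = np.random.default_rng(s_ec)
    ec25 = []
    for cat in labels:
        if cat is ActivityCategory.INACTIVE:
            # mostly no effect up to assay maximum, some banded >1000 uM
            if rng.random() < 0.2:
                ec25.append(float(np.exp(rng.uniform(
                    np.log(INACTIVE_LOWER_UM * 1.1), np.log(INACTIVE_LOWER_UM * 5)
                ))))
            else:
                ec25.append(None)
        else:
            lo, hi = _BAND_WINDOWS[cat]
            ec25.append(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))

    rng = np.random.default_rng(s_desc)
    ranks = np.array([_RANK[c] for c in labels], dtype=float)
    cols = {}
    kinds = {}
    for j in range(cfg.n_informative):
        mu = cfg.class_separation * ranks
        cols[f"D_inf_{j:03d}"] = rng.normal(mu, 1.0)
        kinds[f"D_inf_{j:03d}"] = DESCRIPTOR
    for j in range(cfg.n_noise):
        cols[f"D_noise_{j:03d}"] = rng.normal(0.0, 1.0, size=cfg.n_compounds)
        kinds[f"D_noise_{j:03d}"] = DESCRIPTOR
    for j in range(cfg.n_fingerprint):
        if j % 2 == 0 and cfg.class_separation > 0:
            p_on = np.clip(0.15 + 0.15 * ranks, 0.01, 0.95)
        else:
            p_on = np.full(cfg.n_compounds, rng.uniform(0.1, 0.5))
        cols[f"FP_{j:03d}"] = (rng.random(cfg.n_compounds) < p_on).astype(float)
        kinds[f"FP_{j:03d}"] = FINGERPRINT
    matrix = DescriptorMatrix(
        pd.DataFrame(cols, index=ids), pd.Series(kinds)
    )

    rng = np.random.default_rng(s_flags)
    ring = []
    for cat in labels:
        p_arom = (
            cfg.aromatic_frac_active
            if cat is not ActivityCategory.INACTIVE
            else cfg.aromatic_frac_inactive
        )
        if rng.random() < p_arom:
            ring.append("aromatic_ring")
        elif rng.random() < 0.54:  # remaining mass split ~22:19 acyclic:ring
            ring.append("acyclic")
        else:
            ring.append("nonaromatic_ring")
    ring_classes = pd.Series(ring, index=ids, name="ring_class")

    rng = np.random.default_rng(s_records)
    records = []
    for cid, cat, ec in zip(ids, labels, ec25):
        records.append(
            DoseResponseRecord(
                compound_id=cid,
                purity_pct=float(rng.uniform(95, 100)),
                ec25_ahr_uM=ec,
                ec20_cyto_uM=None,
                replicate_ec25_uM=[ec] if (ec is not None and rng.random() < 0.2) else [],
            )
        )
    records.extend(_tripping_records(cfg, rng))

    smiles = None
    if cfg.emit_smiles:
        picks = [
            _SMILES_POOLS[r][int(rng.integers(len(_SMILES_POOLS[r])))]
            for r in ring
        ]
        smiles = pd.Series(picks, index=ids, name="smiles")

    return SyntheticCompounds(
        records=records,
        matrix=matrix,
        labels=pd.Series(labels, index=ids, name="activity_category"),
        ring_classes=ring_classes,
        smiles=smiles,
    )


def _tripping_records(cfg: GeneratorConfig, rng) -> list:
    """Extra records engineered to trip one exclusion rule each."""
    makers = {
        "purity": lambda i: DoseResponseRecord(
            f"TRIP_purity_{i}", purity_pct=float(rng.uniform(50, 89)), ec25_ahr_uM=5.0
        ),
        "mixture_inorganic": lambda i: DoseResponseRecord(
            f"TRIP_mix_{i}", purity_pct=99.0, ec25_ahr_uM=5.0,
            is_mixture_or_inorganic=True,
        ),
        "ec25_band_100_1000": lambda i: DoseResponseRecord(
            f"TRIP_band_{i}", purity_pct=99.0,
            ec25_ahr_uM=float(np.exp(rng.uniform(np.log(110), np.log(900)))),
        ),
        "cytotoxicity_factor3": lambda i: DoseResponseRecord(
            f"TRIP_cyto_{i}", purity_pct=99.0, ec25_ahr_uM=10.0, ec20_cyto_uM=25.0
        ),
        "inactive_cytotoxic": lambda i: DoseResponseRecord(
            f"TRIP_icyto_{i}", purity_pct=99.0, ec20_cyto_uM=float(rng.uniform(5, 90))
        ),
        "undefined_cas_inactive": lambda i: DoseResponseRecord(
            f"TRIP_cas_{i}", purity_pct=99.0, has_defined_cas=False
        ),
        "replicate_inconsistent": lambda i: DoseResponseRecord(
            f"TRIP_rep_{i}", purity_pct=99.0, ec25_ahr_uM=0.5,
            replicate_ec25_uM=[0.5, 50.0],
        ),
        "atypical_curve_manual": lambda i: DoseResponseRecord(
            f"TRIP_curve_{i}", purity_pct=99.0, ec25_ahr_uM=5.0, atypical_curve=True
        ),
    }
    out = []
    for reason, frac in cfg.trip_fractions.items():
        if reason not in makers:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        count = int(round(frac * cfg.n_compounds))
        out.extend(makers[reason](i) for i in range(count))
    return out


def generate_sites(
    cfg: GeneratorConfig, compounds: SyntheticCompounds
) -> SyntheticSites:
    """Site concentration tables with a known explained-effect fraction.

    Each site x sampler draws a compound subset with log-uniform molar
    concentrations; BEQ_bio is set to the true BEQ_chem (from the true
    EC25-derived REPs) times ``beq_inflation``, so recomputing explained
    percent must yield exactly 100 / inflation when all compounds carry
    their true REPs (double-entry bookkeeping oracle).
    """
    *_, s_sites = _streams(cfg.seed, 6)
    rng = np.random.default_rng(s_sites)

    ec_by_id = {
        rec.compound_id: rec.ec25_ahr_uM
        for rec in compounds.records
        if rec.compound_id in compounds.labels.index
    }
    true_reps = [
        REPEntry(
            compound_id=cid,
            rep=rep_from_ec25(ec, cfg.tcdd_ec25_uM),
            source="experimental",
            basis_ec25_uM=ec,
            category=compounds.labels[cid],
        )
        for cid, ec in ec_by_id.items()
        if ec is not None and ec <= LOW_UPPER_UM
    ]
    rep_lookup = {e.compound_id: e.rep for e in true_reps}

    ids = list(compounds.labels.index)
    lo, hi = cfg.concentration_range_nM
    samples, book = [], []
    for s in range(cfg.site_count):
        for sampler in cfg.sampler_types:
            k = min(cfg.compounds_per_site, len(ids))
            chosen = rng.choice(len(ids), size=k, replace=False)
            conc = {
                ids[i]: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                for i in chosen
            }
            true_beq = sum(
                c * rep_lookup.get(cid, 0.0) for cid, c in conc.items()
            )
            if true_beq <= 0:
                # guarantee at least one active contributor
                active_ids = list(rep_lookup)
                if not active_ids:
                    raise ValueError("no active compounds to build sites from")
                extra = active_ids[int(rng.integers(len(active_ids)))]
                conc[extra] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                true_beq = conc[extra] * rep_lookup[extra]
            beq_bio = true_beq * cfg.beq_inflation
            samples.append(
                SiteSample(
                    site_id=f"site{s + 1:02d}",
                    sampler=sampler,
                    concentrations_nM=conc,
                    beq_bio_nM=beq_bio,
                )
            )
            book.append(
                {
                    "site_id": f"site{s + 1:02d}",
                    "sampler": sampler,
                    "true_beq_chem_nM": true_beq,
                    "beq_bio_nM": beq_bio,
                    "true_explained_pct": 100.0 / cfg.beq_inflation,
                }
            )
    return SyntheticSites(
        samples=samples,
        true_reps=true_reps,
        bookkeeping=pd.DataFrame(book),
    )
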