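"""Dose-response curation for AhR agonism data.

Raw high-throughput dose-response records (AhR EC25, cytotoxicity EC20,
purity, replicate evidence) are filtered through a fixed sequence of
exclusion rules and the survivors are banded into potency categories.
Every input record is accounted for: it either survives curation or
receives exactly one primary exclusion reason (the first matching rule),
emitted as a ledger.

Potency bands (EC25 in uM), contiguous and half-open:

    High      (0, 2.03]
    Medium    (2.03, 10]
    Low       (10, 100]
    excluded  (100, 1000]   -- never banded; records here are removed
    Inactive  (1000, inf) or no effect observed up to the assay maximum

The 3-category scheme merges Medium and High into Medium-High; the
2-category scheme merges Low/Medium/High into Active.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "ActivityCategory",
    "ExclusionReason",
    "DoseResponseRecord",
    "ExclusionLedgerEntry",
    "CurationResult",
    "DuplicateIdError",
    "BandExclusionError",
    "SCHEMES",
    "assign_activity_category",
    "apply_cytotoxicity_rule",
    "replicate_consistency",
    "curate_dataset",
]

SCHEMES = ("2cat", "3cat", "4cat")

#: Band edges in uM.
HIGH_UPPER_UM = 2.03
MEDIUM_UPPER_UM = 10.0
LOW_UPPER_UM = 100.0
INACTIVE_LOWER_UM = 1000.0

#: Curation defaults.
PURITY_MIN_PCT = 90.0
CYTOTOX_FACTOR = 3.0
INACTIVE_CYTOTOX_LIMIT_UM = 100.0


class ActivityCategory(str, enum.Enum):
    """Banded AhR potency class.

    ``ACTIVE`` exists only under the 2-category scheme, where it is the
    union of Low, Medium and High.  ``MEDIUM_HIGH`` exists only under the
    3-category scheme (Medium and High merged).
    """

    INACTIVE = "Inactive"
    LOW = "Low"
    MEDIUM = "Medium"
    HIGH = "High"
    MEDIUM_HIGH = "Medium-High"
    ACTIVE = "Active"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Potency ladder used for tie-breaks and replicate adjacency.  Merged
#: categories sit at the rank of their most potent member boundary:
#: Medium-High spans Medium+High, Active spans everything active.
CATEGORY_RANK: dict[ActivityCategory, int] = {
    ActivityCategory.INACTIVE: 0,
    ActivityCategory.LOW: 1,
    ActivityCategory.ACTIVE: 1,
    ActivityCategory.MEDIUM: 2,
    ActivityCategory.MEDIUM_HIGH: 2,
    ActivityCategory.HIGH: 3,
}


class ExclusionReason(str, enum.Enum):
    PURITY = "purity"
    MIXTURE_INORGANIC = "mixture_inorganic"
    CYTOTOXICITY_FACTOR3 = "cytotoxicity_factor3"
    INACTIVE_CYTOTOXIC = "inactive_cytotoxic"
    EC25_BAND_100_1000 = "ec25_band_100_1000"
    UNDEFINED_CAS_INACTIVE = "undefined_cas_inactive"
    REPLICATE_INCONSISTENT = "replicate_inconsistent"
    ATYPICAL_CURVE_MANUAL = "atypical_curve_manual"
    #: Not an assay-quality exclusion: the record was a duplicate of a kept
    #: compound id and was reconciled away (lowest EC25 kept).
    DUPLICATE_RECONCILED = "duplicate_reconciled"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class BandExclusionError(ValueError):
    """EC25 falls in the unbandable (100, 1000] uM window."""


class DuplicateIdError(ValueError):
    """Same compound id carries contradictory metadata across records."""


def _check_positive(name: str, value: float | None) -> None:
    if value is None:
        return
    if math.isnan(value) or value <= 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class DoseResponseRecord:
    """One compound's dose-response evidence.

    ``ec25_ahr_uM`` absent means no AhR effect was observed up to the assay
    maximum; ``ec20_cyto_uM`` absent means no cytotoxicity observed.
    """

    compound_id: str
    purity_pct: float | None = None
    ec25_ahr_uM: float | None = None
    ec20_cyto_uM: float | None = None
    is_mixture_or_inorganic: bool = False
    replicate_ec25_uM: list[float] = field(default_factory=list)
    has_defined_cas: bool = True
    atypical_curve: bool = False

    def __post_init__(self) -> None:
        _check_positive("ec25_ahr_uM", self.ec25_ahr_uM)
        _check_positive("ec20_cyto_uM", self.ec20_cyto_uM)
        for r in self.replicate_ec25_uM:
            _check_positive("replicate_ec25_uM", r)
        if self.purity_pct is not None and not (0 <= self.purity_pct <= 100):
            raise ValueError(
                f"purity_pct must lie in [0, 100], got {self.purity_pct!r}"
            )

    @property
    def is_active(self) -> bool:
        """Active = a banded EC25 at or below the Low upper edge."""
        return self.ec25_ahr_uM is not None and self.ec25_ahr_uM <= LOW_UPPER_UM


@dataclass
class ExclusionLedgerEntry:
    compound_id: str
    reason: ExclusionReason
    detail: str = ""


@dataclass
class CurationResult:
    """Survivors with assigned categories plus the full exclusion ledger."""

    kept: pd.DataFrame
    ledger: list[ExclusionLedgerEntry]
    scheme: str

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"compound_id": e.compound_id, "reason": e.reason.value, "detail": e.detail}
                for e in self.ledger
            ],
            columns=["compound_id", "reason", "detail"],
        )

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.ledger:
            counts[e.reason.value] = counts.get(e.reason.value, 0) + 1
        return counts


def assign_activity_category(
    ec25_ahr_uM: float | None, scheme: str = "4cat"
) -> ActivityCategory:
    """Band an EC25 into the scheme's potency categories.

    Absent EC25 or EC25 > 1000 uM maps to Inactive.  Values in the
    (100, 1000] uM window are never banded: they raise
    :class:`BandExclusionError` and must be excluded upstream.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if ec25_ahr_uM is None or (
        isinstance(ec25_ahr_uM, float) and math.isnan(ec25_ahr_uM)
    ):
        return ActivityCategory.INACTIVE
    if ec25_ahr_uM <= 0:
        raise ValueError(f"EC25 must be strictly positive, got {ec25_ahr_uM!r}")
    if ec25_ahr_uM > INACTIVE_LOWER_UM:
        return ActivityCategory.INACTIVE
    if ec25_ahr_uM > LOW_UPPER_UM:
        raise BandExclusionError(
            f"EC25 {ec25_ahr_uM} uM lies in the excluded (100, 1000] window"
        )
    if scheme == "2cat":
        return ActivityCategory.ACTIVE
    if ec25_ahr_uM > MEDIUM_UPPER_UM:
        return ActivityCategory.LOW
    if scheme == "3cat":
        return ActivityCategory.MEDIUM_HIGH
    if ec25_ahr_uM > HIGH_UPPER_UM:
        return ActivityCategory.MEDIUM
    return ActivityCategory.HIGH


def apply_cytotoxicity_rule(
    ec25_ahr_uM: float | None,
    ec20_cyto_uM: float | None,
    factor: float = CYTOTOX_FACTOR,
    inactive_limit_uM: float = INACTIVE_CYTOTOX_LIMIT_UM,
) -> tuple[bool, ExclusionReason | None]:
    """Cytotoxicity-burst guard.

    An active compound is excluded when its cytotoxicity EC20 is less than
    ``factor`` (default 3) times its AhR EC25 -- reporter activation that
    close to cell death cannot be attributed to receptor agonism.  A
    compound inactive on AhR is excluded when it is cytotoxic below
    ``inactive_limit_uM`` (default 100 uM), because its inactivity could
    not be observed free of cytotoxicity.

    Returns ``(keep, reason)`` with ``reason`` None when kept.
    """
    _check_positive("ec25_ahr_uM", ec25_ahr_uM)
    _check_positive("ec20_cyto_uM", ec20_cyto_uM)
    if ec20_cyto_uM is None:
        return True, None
    if ec25_ahr_uM is not None:
        if ec20_cyto_uM < factor * ec25_ahr_uM:
            return False, ExclusionReason.CYTOTOXICITY_FACTOR3
        return True, None
    if ec20_cyto_uM < inactive_limit_uM:
        return False, ExclusionReason.INACTIVE_CYTOTOXIC
    return True, None


def _replicate_rank(ec25_uM: float) -> int:
    """Ladder rank of one replicate; anything above the Low band counts as
    the inactive rank (0), including the (100, 1000] window."""
    if ec25_uM > LOW_UPPER_UM:
        return 0
    return CATEGORY_RANK[assign_activity_category(ec25_uM, "4cat")]


def replicate_consistency(replicate_ec25_uM: list[float]) -> bool:
    """True when repeated measurements band into the same or adjacent
    potency categories.

    Empty or singleton replicate lists are trivially consistent.  The rule
    is a stand-in for the (undefined) notion of cross-experiment
    inconsistency: replicates two or more bands apart disagree about the
    compound's potency class, not merely about its exact EC25.
    """
    for r in replicate_ec25_uM:
        _check_positive("replicate_ec25_uM", r)
    if len(replicate_ec25_uM) < 2:
        return True
    ranks = [_replicate_rank(r) for r in replicate_ec25_uM]
    return max(ranks) - min(ranks) <= 1


def _first_exclusion(
    rec: DoseResponseRecord,
    purity_min: float,
    factor: float,
    inactive_limit: float,
) -> ExclusionLedgerEntry | None:
    """First matching rule in the fixed order, or None when kept."""
    if rec.purity_pct is None or rec.purity_pct < purity_min:
        detail = (
            "purity unreported"
            if rec.purity_pct is None
            else f"purity {rec.purity_pct}% < {purity_min}%"
        )
        return ExclusionLedgerEntry(rec.compound_id, ExclusionReason.PURITY, detail)
    if rec.is_mixture_or_inorganic:
        return ExclusionLedgerEntry(
            rec.compound_id, ExclusionReason.MIXTURE_INORGANIC, "mixture or inorganic"
        )
    if (
        rec.ec25_ahr_uM is not None
        and LOW_UPPER_UM < rec.ec25_ahr_uM <= INACTIVE_LOWER_UM
    ):
        return ExclusionLedgerEntry(
            rec.compound_id,
            ExclusionReason.EC25_BAND_100_1000,
            f"EC25 {rec.ec25_ahr_uM} uM in (100, 1000]",
        )
    keep, reason = apply_cytotoxicity_rule(
        rec.ec25_ahr_uM, rec.ec20_cyto_uM, factor, inactive_limit
    )
    if not keep:
        return ExclusionLedgerEntry(
            rec.compound_id,
            reason,
            f"EC20 {rec.ec20_cyto_uM} uM vs EC25 {rec.ec25_ahr_uM} uM",
        )
    if not rec.is_active and not rec.has_defined_cas:
        return ExclusionLedgerEntry(
            rec.compound_id,
            ExclusionReason.UNDEFINED_CAS_INACTIVE,
            "inactive with undefined CAS",
        )
    if rec.is_active and not replicate_consistency(rec.replicate_ec25_uM):
        return ExclusionLedgerEntry(
            rec.compound_id,
            ExclusionReason.REPLICATE_INCONSISTENT,
            f"replicates {rec.replicate_ec25_uM} band non-adjacently",
        )
    if rec.atypical_curve:
        return ExclusionLedgerEntry(
            rec.compound_id,
            ExclusionReason.ATYPICAL_CURVE_MANUAL,
            "flagged atypical curve shape",
        )
    return None


_KEPT_COLUMNS = [
    "compound_id",
    "purity_pct",
    "ec25_ahr_uM",
    "ec20_cyto_uM",
    "is_mixture_or_inorganic",
    "replicate_ec25_uM",
    "has_defined_cas",
    "atypical_curve",
    "activity_category",
]


def _check_duplicates(records: list[DoseResponseRecord]) -> None:
    by_id: dict[str, DoseResponseRecord] = {}
    offenders: list[str] = []
    for rec in records:
        prev = by_id.get(rec.compound_id)
        if prev is None:
            by_id[rec.compound_id] = rec
        elif (
            prev.is_mixture_or_inorganic != rec.is_mixture_or_inorganic
            or prev.has_defined_cas != rec.has_defined_cas
        ):
            offenders.append(rec.compound_id)
    if offenders:
        raise DuplicateIdError(
            "conflicting metadata across duplicate compound ids: "
            + ", ".join(sorted(set(offenders)))
        )


def curate_dataset(
    records: list[DoseResponseRecord],
    scheme: str = "4cat",
    purity_min: float = PURITY_MIN_PCT,
    cytotox_factor: float = CYTOTOX_FACTOR,
    inactive_cytotox_limit_uM: float = INACTIVE_CYTOTOX_LIMIT_UM,
) -> CurationResult:
    """Run the full exclusion pipeline and band the survivors.

    Rules fire in a fixed order (purity, mixture/inorganic, EC25 band,
    cytotoxicity, undefined-CAS inactive, replicate consistency, manual
    atypical-curve flag); each excluded record gets exactly the first
    matching reason.  Duplicate ids among the survivors are reconciled by
    keeping the lowest-EC25 record (conservative toward activity); the
    dropped duplicates are ledgered.  The partition invariant
    ``len(kept) + len(ledger) == len(records)`` always holds.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    _check_duplicates(records)

    ledger: list[ExclusionLedgerEntry] = []
    survivors: list[DoseResponseRecord] = []
    for rec in records:
        entry = _first_exclusion(
            rec, purity_min, cytotox_factor, inactive_cytotox_limit_uM
        )
        if entry is None:
            survivors.append(rec)
        else:
            ledger.append(entry)

    # duplicate reconciliation: lowest EC25 wins, ties by input order
    best: dict[str, DoseResponseRecord] = {}
    for rec in survivors:
        prev = best.get(rec.compound_id)
        if prev is None:
            best[rec.compound_id] = rec
            continue
        prev_ec = prev.ec25_ahr_uM if prev.ec25_ahr_uM is not None else math.inf
        cur_ec = rec.ec25_ahr_uM if rec.ec25_ahr_uM is not None else math.inf
        if cur_ec < prev_ec:
            ledger.append(
                ExclusionLedgerEntry(
                    prev.compound_id,
                    ExclusionReason.DUPLICATE_RECONCILED,
                    f"superseded by duplicate with EC25 {rec.ec25_ahr_uM} uM",
                )
            )
            best[rec.compound_id] = rec
        else:
            ledger.append(
                ExclusionLedgerEntry(
                    rec.compound_id,
                    ExclusionReason.DUPLICATE_RECONCILED,
                    f"kept duplicate with EC25 {prev.ec25_ahr_uM} uM",
                )
            )

    rows = []
    for rec in survivors:
        kept_rec = best.get(rec.compound_id)
        if kept_rec is not rec:
            continue
        rows.append(
            {
                "compound_id": rec.compound_id,
                "purity_pct": rec.purity_pct,
                "ec25_ahr_uM": rec.ec25_ahr_uM,
                "ec20_cyto_uM": rec.ec20_cyto_uM,
                "is_mixture_or_inorganic": rec.is_mixture_or_inorganic,
                "replicate_ec25_uM": list(rec.replicate_ec25_uM),
                "has_defined_cas": rec.has_defined_cas,
                "atypical_curve": rec.atypical_curve,
                "activity_category": assign_activity_category(rec.ec25_ahr_uM, scheme).value,
            }
        )
    kept = pd.DataFrame(rows, columns=_KEPT_COLUMNS)
    return CurationResult(kept=kept, ledger=ledger, scheme=scheme)


def records_from_frame(frame: pd.DataFrame) -> list[DoseResponseRecord]:
    """Rebuild records from a kept-survivors frame (or any frame with the
    record columns); used for idempotence checks and CSV round-trips."""
    records = []
    for _, row in frame.iterrows():
        records.append(
            DoseResponseRecord(
                compound_id=str(row["compound_id"]),
                purity_pct=_opt_float(row.get("purity_pct")),
                ec25_ahr_uM=_opt_float(row.get("ec25_ahr_uM")),
                ec20_cyto_uM=_opt_float(row.get("ec20_cyto_uM")),
                is_mixture_or_inorganic=bool(row.get("is_mixture_or_inorganic", False)),
                replicate_ec25_uM=list(row.get("replicate_ec25_uM", []) or []),
                has_defined_cas=bool(row.get("has_defined_cas", True)),
                atypical_curve=bool(row.get("atypical_curve", False)),
            )
        )
    return records


def _opt_float(value) -> float | None:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f
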