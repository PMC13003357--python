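"""Predictor-matrix assembly and filtering.

The models consume a precomputed compounds x predictors matrix mixing
continuous molecular descriptors and binary fingerprint bits.  Descriptor
generation itself (Mordred, PaDEL, PubChem keys, ...) is a pluggable
external step: any generator that yields a numeric table keyed by
compound id can be bolted on via :class:`DescriptorMatrix`.

Filtering drops columns with any missing value and columns with
variability below 1%: for a binary bit that is a minority-state frequency
below 1%, for a continuous descriptor a near-constant column or one with
fewer than 1% of values away from the mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "DescriptorMatrix",
    "ImportanceVector",
    "RING_CLASSES",
    "filter_predictors",
    "importance_reselect",
    "ring_classify",
    "classify_structures",
]

RING_CLASSES = ("acyclic", "nonaromatic_ring", "aromatic_ring")

FINGERPRINT = "fingerprint"
DESCRIPTOR = "descriptor"


@dataclass
class DescriptorMatrix:
    """Compounds x predictors grid with per-column provenance.

    ``values`` is indexed by compound id; ``kinds`` maps each column to
    ``"fingerprint"`` (binary) or ``"descriptor"`` (continuous).
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated predictor names: {dupes}")
        self.kinds = pd.Series(self.kinds).reindex(self.values.columns)
        if self.kinds.isna().any():
            missing = self.kinds.index[self.kinds.isna()].tolist()
            raise ValueError(f"predictors without a kind tag: {missing}")
        bad = set(self.kinds.unique()) - {FINGERPRINT, DESCRIPTOR}
        if bad:
            raise ValueError(f"unknown predictor kinds: {sorted(bad)}")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.values.columns)

    def subset_rows(self, compound_ids: list[str]) -> "DescriptorMatrix":
        missing = [c for c in compound_ids if c not in self.values.index]
        if missing:
            raise KeyError(f"compounds not in matrix: {missing}")
        return DescriptorMatrix(self.values.loc[compound_ids].copy(), self.kinds.copy())

    def subset(self, predictor_names: list[str]) -> "DescriptorMatrix":
        missing = [p for p in predictor_names if p not in self.values.columns]
        if missing:
            raise KeyError(f"predictors not in matrix: {missing}")
        return DescriptorMatrix(
            self.values[predictor_names].copy(), self.kinds[predictor_names].copy()
        )


def _low_variability(col: pd.Series, kind: str, min_frac: float) -> bool:
    n = len(col)
    if n == 0:
        return True
    if kind == FINGERPRINT:
        on = float((col != 0).sum())
        minority = min(on, n - on) / n
        return minority < min_frac
    vals = col.to_numpy(dtype=float)
    rng = np.ptp(vals)
    scale = max(1.0, float(np.abs(vals).max(initial=0.0)))
    if rng <= 1e-8 * scale:  # true constant up to float noise
        return True
    top = col.value_counts().iloc[0]
    return (n - top) / n < min_frac


def filter_predictors(
    matrix: DescriptorMatrix, min_variability: float = 0.01
) -> tuple[DescriptorMatrix, pd.DataFrame]:
    """Drop uninformative columns; report every removal with its cause.

    Columns with at least one missing value go first ("missing"), then
    columns whose variability is below ``min_variability`` ("low_variability").
    Raises if nothing survives.
    """
    if matrix.values.shape[1] == 0:
        raise ValueError("empty descriptor matrix")
    removed: list[dict[str, str]] = []
    keep: list[str] = []
    for name in matrix.predictor_names:
        col = matrix.values[name]
        if col.isna().any():
            removed.append({"predictor": name, "cause": "missing"})
            continue
        if _low_variability(col, matrix.kinds[name], min_variability):
            removed.append({"predictor": name, "cause": "low_variability"})
            continue
        keep.append(name)
    if not keep:
        raise ValueError("all predictors removed; matrix unusable")
    report = pd.DataFrame(removed, columns=["predictor", "cause"])
    return matrix.subset(keep), report


@dataclass
class ImportanceVector:
    """Per-predictor importance (misclassification-error based), with a
    relative view scaled so the most important predictor scores 1."""

    predictor_names: list[str]
    importance: np.ndarray

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if len(self.predictor_names) != len(self.importance):
            raise ValueError("names and importances differ in length")
        if (self.importance < 0).any():
            raise ValueError("importances must be non-negative")

    @property
    def relative(self) -> np.ndarray:
        top = self.importance.max(initial=0.0)
        if top == 0:
            return np.zeros_like(self.importance)
        return self.importance / top


def importance_reselect(
    importances: ImportanceVector, threshold_relative: float = 0.05
) -> list[str]:
    """Keep predictors whose importance is at least ``threshold_relative``
    of the top predictor's, preserving input order."""
    if not (0 < threshold_relative <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if len(importances.predictor_names) == 0:
        raise ValueError("empty importance vector")
    rel = importances.relative
    return [
        name
        for name, r in zip(importances.predictor_names, rel)
        if r >= threshold_relative
    ]


def ring_classify(smiles: str, compound_id: str | None = None) -> str:
    """Classify a structure as acyclic, nonaromatic_ring or aromatic_ring.

    Aromaticity follows the toolkit's default perception model; a
    structure with any aromatic atom in a ring is aromatic_ring, else any
    ring makes it nonaromatic_ring.
    """
    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    RDLogger.EnableLog("rdApp.error")
    if mol is None:
        ident = f" (compound {compound_id})" if compound_id else ""
        raise ValueError(f"unparseable structure{ident}: {smiles!r}")
    if any(atom.GetIsAromatic() for atom in mol.GetAtoms()):
        return "aromatic_ring"
    if mol.GetRingInfo().NumRings() > 0:
        return "nonaromatic_ring"
    return "acyclic"


def classify_structures(smiles_by_id: dict[str, str]) -> pd.Series:
    """Vectorised :func:`ring_classify` keyed by compound id."""
    return pd.Series(
        {cid: ring_classify(smi, cid) for cid, smi in smiles_by_id.items()},
        name="ring_class",
        dtype=object,
    )
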