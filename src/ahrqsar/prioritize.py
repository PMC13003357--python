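"""Rule-based compound prioritization with a probability applicability domain.

Each compound's class-probability vector(s) — from the all-compound
3-category model and, for aromatics, the aromatic 4-category model — are
matched against a fixed rule table.  Rules are evaluated strictly
top-down (priority 4 first); the first match wins.  A compound matching
no rule is NR (not reliable): its probability mass is too diffuse for the
prediction to be trusted, which operationally defines the models'
applicability domain.  NR compounds are excluded from downstream mixture
accounting.

Rule predicates (P(X) = class probability of category X):

    4   P(High) >= 0.5                              [aromatic 4-cat]
    4   P(Medium) >= 0.5 and P(Inactive) < 0.1      [aromatic 4-cat]
    4   P(Medium-High) >= 0.5 and P(Inactive) < 0.1 [all-compound 3-cat]
    3   P(Medium or High) >= 0.4 and P(Inactive) < 0.1      [aromatic 4-cat]
    3   P(Medium-High) >= 0.4 and P(Inactive) < 0.1 [all-compound 3-cat]
    2   P(Low) >= 0.6 and P(Inactive) < 0.1         [aromatic 4-cat]
    2   P(Medium-High) >= 0.4 and P(Inactive) < 0.1 [all-compound 3-cat]
    1   P(Low) >= 0.7                               [either model]
    0   P(Inactive) >= 0.6                          [either model]
    NR  no rule matched

A probability threshold is met when the category's own probability
crosses it; the top category by argmax need not be the rule's category.
The 3-category priority-2 rule is unreachable below the identical
priority-3 rule but is retained for table fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .curation import ActivityCategory
from .model import PredictionResult

__all__ = ["PriorityLevel", "RULES", "assign_priority", "prioritize_batch"]

M_ALL_3 = "M_ALL_3"
M_AROM_4 = "M_arom_4"

_I = ActivityCategory.INACTIVE
_L = ActivityCategory.LOW
_M = ActivityCategory.MEDIUM
_MH = ActivityCategory.MEDIUM_HIGH
_H = ActivityCategory.HIGH


@dataclass
class PriorityLevel:
    """Priority 4 (most potent, most reliable) down to 0 (inactive);
    ``value`` is None for NR."""

    value: int | None
    triggering_rule: str
    source_model: str

    @property
    def label(self) -> str:
        return "NR" if self.value is None else str(self.value)

    @property
    def is_reliable(self) -> bool:
        return self.value is not None


def _p(probs: dict, cat: ActivityCategory) -> float:
    return float(probs.get(cat, 0.0))


#: (priority, rule id, model tag, predicate) evaluated strictly in order.
RULES = [
    (4, "high_p50", M_AROM_4, lambda p: _p(p, _H) >= 0.5),
    (4, "medium_p50_inactive_lt10", M_AROM_4,
     lambda p: _p(p, _M) >= 0.5 and _p(p, _I) < 0.1),
    (4, "mediumhigh_p50_inactive_lt10", M_ALL_3,
     lambda p: _p(p, _MH) >= 0.5 and _p(p, _I) < 0.1),
    (3, "medium_or_high_p40_inactive_lt10", M_AROM_4,
     lambda p: max(_p(p, _M), _p(p, _H)) >= 0.4 and _p(p, _I) < 0.1),
    (3, "mediumhigh_p40_inactive_lt10", M_ALL_3,
     lambda p: _p(p, _MH) >= 0.4 and _p(p, _I) < 0.1),
    (2, "low_p60_inactive_lt10", M_AROM_4,
     lambda p: _p(p, _L) >= 0.6 and _p(p, _I) < 0.1),
    (2, "mediumhigh_p40_inactive_lt10", M_ALL_3,
     lambda p: _p(p, _MH) >= 0.4 and _p(p, _I) < 0.1),
    (1, "low_p70", M_AROM_4, lambda p: _p(p, _L) >= 0.7),
    (1, "low_p70", M_ALL_3, lambda p: _p(p, _L) >= 0.7),
    (0, "inactive_p60", M_AROM_4, lambda p: _p(p, _I) >= 0.6),
    (0, "inactive_p60", M_ALL_3, lambda p: _p(p, _I) >= 0.6),
]


def _check_normalized(result: PredictionResult) -> None:
    total = sum(result.probabilities.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(
            f"probability vector for {result.compound_id} sums to {total}, not 1"
        )


def assign_priority(
    results: dict, ring_class: str = "aromatic_ring"
) -> PriorityLevel:
    """Map one compound's model result(s) to a priority level.

    ``results`` maps model tag to :class:`PredictionResult`; aromatic
    compounds must supply both models, others only the 3-category model.
    """
    if not results:
        raise ValueError("no prediction results supplied")
    if ring_class == "aromatic_ring" and M_AROM_4 not in results:
        raise ValueError("aromatic compound requires the 4-category model result")
    for res in results.values():
        _check_normalized(res)
    for priority, rule_id, model_tag, pred in RULES:
        res = results.get(model_tag)
        if res is not None and pred(res.probabilities):
            return PriorityLevel(priority, rule_id, model_tag)
    return PriorityLevel(None, "no_rule_matched", "/".join(sorted(results)))


def prioritize_batch(
    results_by_compound: dict, ring_classes: pd.Series | dict
) -> tuple[pd.DataFrame, dict]:
    """Prioritize a batch; returns the per-compound table and tallies.

    ``results_by_compound`` maps compound id to {model tag: result}.
    Tallies count compounds per priority label and per predicted category
    (taken from the triggering model, or the 3-category model for NR).
    """
    rows = []
    for cid, results in results_by_compound.items():
        ring = (
            ring_classes.get(cid)
            if hasattr(ring_classes, "get")
            else ring_classes[cid]
        )
        level = assign_priority(results, ring)
        source = results.get(level.source_model) or results.get(M_ALL_3)
        rows.append(
            {
                "compound_id": cid,
                "priority": level.label,
                "triggering_rule": level.triggering_rule,
                "source_model": level.source_model,
                "predicted_category": (
                    source.predicted_category.value if source else ""
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "priority", "triggering_rule",
            "source_model", "predicted_category",
        ],
    )
    tallies = {
        "by_priority": table["priority"].value_counts().to_dict() if len(table) else {},
        "by_category": (
            table["predicted_category"].value_counts().to_dict() if len(table) else {}
        ),
    }
    return table, tallies
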