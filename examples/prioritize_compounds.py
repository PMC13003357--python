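"""Turn class-probability vectors into testing priorities.

Builds probability vectors for a few hypothetical compounds (aromatic
ones carry both the all-compound 3-category and the aromatic 4-category
result) and prints the priority each receives, including one NR
(not reliable) case that falls outside the applicability domain.
"""

from ahrqsar import ActivityCategory, PredictionResult, prioritize_batch

I, L, M, MH, H = (
    ActivityCategory.INACTIVE,
    ActivityCategory.LOW,
    ActivityCategory.MEDIUM,
    ActivityCategory.MEDIUM_HIGH,
    ActivityCategory.HIGH,
)


def res(cid, tag, probs):
    best = max(probs, key=lambda c: probs[c])
    return PredictionResult(cid, tag, probs, best)


predictions = {
    "pah-like": {
        "M_arom_4": res("pah-like", "M_arom_4", {I: 0.05, L: 0.10, M: 0.20, H: 0.65}),
        "M_ALL_3": res("pah-like", "M_ALL_3", {I: 0.05, L: 0.35, MH: 0.60}),
    },
    "borderline": {
        "M_arom_4": res("borderline", "M_arom_4", {I: 0.08, L: 0.47, M: 0.42, H: 0.03}),
        "M_ALL_3": res("borderline", "M_ALL_3", {I: 0.09, L: 0.46, MH: 0.45}),
    },
    "weak-polar": {
        "M_ALL_3": res("weak-polar", "M_ALL_3", {I: 0.20, L: 0.72, MH: 0.08}),
    },
    "clean-negative": {
        "M_ALL_3": res("clean-negative", "M_ALL_3", {I: 0.85, L: 0.10, MH: 0.05}),
    },
    "diffuse": {
        "M_ALL_3": res("diffuse", "M_ALL_3", {I: 0.40, L: 0.35, MH: 0.25}),
    },
}
ring = {
    "pah-like": "aromatic_ring", "borderline": "aromatic_ring",
    "weak-polar": "acyclic", "clean-negative": "nonaromatic_ring",
    "diffuse": "acyclic",
}

table, tallies = prioritize_batch(predictions, ring)
print(table.to_string(index=False))
print("\ntallies:", tallies["by_priority"])
print(
    "\nPriority 4 flags the most potent, most reliably predicted agonists "
    "for bioassay testing; NR marks probability vectors too diffuse to "
    "trust - the probability-based applicability domain in action."
)
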