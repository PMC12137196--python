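"""Behaviour vocabulary shared across the pipeline.

The four-category ethogram (resting, feeding, walking, running) is the label
space of the classifier. Rare behaviours seen during captive-bear video
annotation are excluded from training; walking and feeding are merged into a
single "feedwalking" state for wild-bear activity budgets because slow
berry-foraging locomotion confounds the two signatures.
"""

from __future__ import annotations

#: The four trainable behaviours, in the fixed class order used everywhere
#: (confusion-matrix axes, vote tie-breaking, serialized models).
CLASS_ORDER: tuple[str, ...] = ("feeding", "resting", "running", "walking")

BEHAVIORS: frozenset[str] = frozenset(CLASS_ORDER)

#: Rare behaviours dropped during training-set preparation.
EXCLUDED_RARE: tuple[str, ...] = (
    "playing",
    "fighting",
    "shaking",
    "scratching",
    "swimming",
    "tree rubbing",
    "drinking",
)

#: Merged walking-or-feeding state used for wild-bear analyses.
FEEDWALKING = "feedwalking"

#: Active (non-resting, non-running) states whose choice probability is
#: modulated by the diel profile in the simulator.
ACTIVE_STATES: frozenset[str] = frozenset({"feeding", "walking"})


def canonical(label: str) -> str:
    """Case- and whitespace-insensitive canonical form of a behaviour label."""
    return " ".join(str(label).strip().lower().split())
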