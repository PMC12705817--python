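"""Canonical item vocabularies.

EMA items follow the canonical reporting order of the study design this
package targets: 19 Likert items (1-7) plus the binary social-context item
``Being-Alone``.  Wellbeing items are stored reverse-coded ("Lacking-..."),
so that higher always means worse / more distressed.

SIPS items are the 19 interview items (positive P1-P5, negative N1-N6,
disorganization D1-D4, general G1-G4), each scored 0-6.
"""

from __future__ import annotations

# Canonical EMA item order; all matrices index by this order.
EMA_ITEMS: tuple[str, ...] = (
    "Lacking-Relaxation",
    "Feeling-Lonely",
    "Anxiety",
    "Lacking-Happiness",
    "Irritation",
    "Sensory-Issues",
    "Lacking-Excitement",
    "Sadness",
    "Lacking-Confidence",
    "Feeling-Rejected",
    "Feeling-Unsafe",
    "Confusing-Reality-with-Imagination",
    "Hallucinations",
    "Fatigue",
    "Lacking-Motivation",
    "Lacking-Physical-Activity",
    "Finding-Activity-Difficult",
    "Lacking-Enjoyment",
    "Lacking-Concentration",
    "Being-Alone",
)

#: The binary social-context item (0 = with others, 1 = alone).
BINARY_ITEM = "Being-Alone"

#: Likert items = all EMA items except the binary context flag.
LIKERT_ITEMS: tuple[str, ...] = tuple(i for i in EMA_ITEMS if i != BINARY_ITEM)

#: Positively-coded wellbeing column name -> stored reverse-coded name.
#: Ingest maps value r on the 1-7 scale to 8 - r under the reverse-coded name.
WELLBEING_REVERSE: dict[str, str] = {
    "Relaxation": "Lacking-Relaxation",
    "Happiness": "Lacking-Happiness",
    "Excitement": "Lacking-Excitement",
    "Confidence": "Lacking-Confidence",
    "Motivation": "Lacking-Motivation",
    "Physical-Activity": "Lacking-Physical-Activity",
    "Enjoyment": "Lacking-Enjoyment",
    "Concentration": "Lacking-Concentration",
}

#: Items whose high pole is psychological distress (upper embedding quadrants).
DISTRESS_ITEMS: tuple[str, ...] = (
    "Sadness",
    "Irritation",
    "Anxiety",
    "Feeling-Rejected",
)

#: Default axis-orientation anchor for the network embedding: the most
#: "cognitive" item is placed at negative x (left side of the layout).
COGNITIVE_ANCHOR = "Hallucinations"

# SIPS interview items, canonical order.
SIPS_ITEMS: tuple[str, ...] = (
    "P1", "P2", "P3", "P4", "P5",
    "N1", "N2", "N3", "N4", "N5", "N6",
    "D1", "D2", "D3", "D4",
    "G1", "G2", "G3", "G4",
)

#: SIPS positive-symptom items (load negatively on the valence dimension).
SIPS_POSITIVE: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5")
#: SIPS negative-symptom items (load positively on the valence dimension).
SIPS_NEGATIVE: tuple[str, ...] = ("N1", "N2", "N3", "N4", "N5", "N6")
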