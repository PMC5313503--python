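"""Static definition of the QuEDS instrument.

The QuEDS (qualitative-quantitative evaluation of depressive symptomatology)
is a 41-item dichotomous self-report questionnaire for major depressive
episodes.  Each item investigates one or more of 23 clinical criteria
("attributes") decomposed from the DSM-5 MDE criteria, Beck's hopelessness
triad, Seligman's learned helplessness, and literature symptoms of agitated
and inhibited depression.  This module holds the published item-attribute
map, the three-factor partition of the items, and the standardized factor
loadings used by the synthetic-respondent generator.
"""

from __future__ import annotations

# Attribute id -> (explanation, source of the criterion)
ATTRIBUTE_TABLE: dict[str, tuple[str, str]] = {
    "A1": ("Depressed mood", "DSM5"),
    "A2": ("Diminished interest and pleasure", "DSM5"),
    "A3": ("Decreased interest in sex", "DSM5"),
    "A4": ("Increase or loss of weight", "DSM5"),
    "A5": ("Gain or loss of appetite", "DSM5"),
    "A6": ("Insomnia or hypersomnia", "DSM5"),
    "A7": ("Agitation", "DSM5"),
    "A8": ("Psychomotor retardation", "DSM5"),
    "A9": ("Fatigue or energy loss", "DSM5"),
    "A10": ("Feelings of worthlessness (or Beck's negative view of self)", "DSM5"),
    "A11": ("Feelings of guilt", "DSM5"),
    "A12": ("Diminished ability to think and concentrate", "DSM5"),
    "A13": ("Indecision", "DSM5"),
    "A14": ("Recurrent thoughts of death", "DSM5"),
    "A15": ("Suicidal ideation or attempted suicide", "DSM5"),
    "A16": ("Beck's negative view of the world", "Beck"),
    "A17": ("Beck's negative expectation of the future", "Beck"),
    "A18": ("Seligman's learned helplessness", "Seligman"),
    "A19": ("Irritability", "literature"),
    "A20": ("Apathy", "literature"),
    "A21": ("Health concern", "literature"),
    "A22": ("Somatic disorders", "literature"),
    "A23": ("More positive mood in the evening", "literature"),
}

# Item id -> (prompt, attributes investigated).  This map is the clinical
# context: row i of the Boolean matrix is the indicator of item i's intent.
ITEM_TABLE: dict[int, tuple[str, tuple[str, ...]]] = {
    1: ("I feel that I don't have the same energy to have sex", ("A3", "A9")),
    2: ("I often wake up in the middle of the night and I can't asleep again", ("A6", "A7")),
    3: ("I feel like that my thinking is slowing down", ("A8", "A12")),
    4: ("I have sleeping problems", ("A6",)),
    5: ("I am stressed by feeling of guilt", ("A11",)),
    6: ("I am think the world is cruel and unhappy", ("A16",)),
    7: ("I keep crying very easily", ("A1", "A7", "A19")),
    8: ("I get irritated very easily", ("A19",)),
    9: ("I think my life is hell and I only deserve to feel bad", ("A1", "A11", "A16")),
    10: ("I fell incapable to face life's events", ("A18",)),
    11: ("I suffer of somatic disorders (e.g. headache stomach ache)", ("A22",)),
    12: ("I have lost interest in the future which doesn't save anything good for me", ("A2", "A17")),
    13: ("I am less interest in sex", ("A3", "A20")),
    14: ("I feel incapable and totally useless", ("A10", "A18")),
    15: ("I see the same unhappiness I have now in the future", ("A1", "A17")),
    16: ("My desire to eat is not the same", ("A5",)),
    17: ("I often feel like crying, but I cannot do it", ("A1", "A20")),
    18: ("I cannot have any interest and pleasure in people and things that before I was interested in", ("A2", "A20")),
    19: ("I thought to kill my self", ("A14", "A15")),
    20: ("Sometimes I think it would be better if I were dead", ("A14",)),
    21: ("I am really worried about my health", ("A21",)),
    22: ("My weight has had significant changes", ("A4",)),
    23: ("I've visibly lost (or gained) weight", ("A4",)),
    24: ("I am afraid of about everything that it will happen to me because I am not able to do anything", ("A17", "A18")),
    25: ("I feel like I don't have any more power over my empty and sad life", ("A1", "A16", "A18")),
    26: ("My appetite has changed", ("A5",)),
    27: ("To make choices is hard for me", ("A12", "A13", "A20")),
    28: ("I feel I'm slowing down in my daily routines", ("A8", "A9")),
    29: ("I feel helpless and inhibited facing my incapacity to concentrate", ("A12", "A20")),
    30: ("I feel too much on the other people that it would be better if I killed myself", ("A10", "A11", "A14")),
    31: ("I have not much energy and I feel tired", ("A9",)),
    32: ("I am disappointed of myself and the choices I made", ("A10", "A11")),
    33: ("I have problems in making decisions", ("A13",)),
    34: ("I feel sad", ("A1",)),
    35: ("My ability to think and memorize has been reduced", ("A8", "A9", "A12")),
    36: ("I don't have any interest and desire in doing anything", ("A2",)),
    37: ("I am agitated of the idea that this sadness won't ever leave me", ("A1", "A7", "A17")),
    38: ("I feel agitated", ("A7",)),
    39: ("I feel so tired and without any energy that I need help to wash myself and to get dressed", ("A8", "A9", "A18", "A20")),
    40: ("I am better in the evening more than in the morning", ("A23",)),
    41: ("I often feel like a loser", ("A10",)),
}

# Three-factor partition of the 41 items (cognitive / somatic / affective).
FACTOR_ITEMS: dict[str, frozenset[int]] = {
    "cognitive": frozenset({5, 6, 9, 10, 14, 19, 20, 21, 24, 25, 27, 30, 32, 33, 41}),
    "somatic": frozenset({1, 2, 3, 4, 11, 13, 16, 22, 23, 26, 28, 31, 35, 39}),
    "affective": frozenset({7, 8, 12, 15, 17, 18, 29, 34, 36, 37, 38, 40}),
}

# Standardized first-order loading of each item on its own factor.
FACTOR_LOADINGS: dict[int, float] = {
    # cognitive
    5: 0.59, 6: 0.37, 9: 0.50, 10: 0.42, 14: 0.72, 19: 0.32, 20: 0.62,
    21: 0.37, 24: 0.66, 25: 0.64, 27: 0.26, 30: 0.51, 32: 0.62, 33: 0.26,
    41: 0.76,
    # somatic
    1: 0.32, 2: 0.46, 3: 0.59, 4: 0.37, 11: 0.34, 13: 0.42, 16: 0.61,
    22: 0.39, 23: 0.36, 26: 0.42, 28: 0.71, 31: 0.55, 35: 0.54, 39: 0.39,
    # affective
    7: 0.36, 8: 0.39, 12: 0.49, 15: 0.45, 17: 0.45, 18: 0.62, 29: 0.38,
    34: 0.70, 36: 0.46, 37: 0.65, 38: 0.53, 40: 0.33,
}

# Loading of each first-order factor on the second-order depression factor.
SECOND_ORDER_LOADINGS: dict[str, float] = {
    "cognitive": 0.77,
    "somatic": 0.70,
    "affective": 0.91,
}

# Reported group moments of the total score (used as generator defaults).
NONCLINICAL_MEAN = 6.5
NONCLINICAL_SD = 6.0
CLINICAL_MEAN = 28.5
CLINICAL_SD = 6.5
RETEST_CORRELATION = 0.74
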