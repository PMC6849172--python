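"""Reference figures from the dual-corpus clinical term-mining benchmark.

The benchmark mined two licensed corpora — ``VetCN`` (first-opinion
veterinary consultation narratives, lowercased) and ``PMSB`` (PubMed
systematic-review titles/abstracts, case-preserving) — for 11 well-known
medical conditions, retrieved the top-20 cosine candidates per target
under CBOW and Skip-gram, and had domain experts assess short-form
detection, concept normalization (EXP-1: raw n-grams; EXP-2: short forms
expanded to long forms first) and the clinical validity of the resulting
concept pairs.  The corpora themselves are licensed and not
redistributable; what this module carries are the published summary
figures, which downstream evaluation arithmetic takes as input:

* the 11 target terms with their corpus frequencies and concept IDs;
* the short-form detector contingency counts;
* the per-target precision/recall/F percentages for both experiments;
* the micro-averaged P/R over the 613 unique candidate terms;
* the validation-precision group sizes and negative-pair counts.

Everything downstream (P/R/F arithmetic, macro/micro averaging,
significance testing, count recovery) is *computed* from these inputs by
:mod:`onehealthnlp.concept_mapping` and :mod:`onehealthnlp.short_forms`.
"""

from __future__ import annotations

from .short_forms import DetectorCounts

TARGET_TERMS: dict[str, dict] = {
    # target -> {cui, snomed, vetcn: (ngram, freq), pmsb: (ngram, freq)}
    "heart_failure": {
        "cui": "C0018801",
        "snomed": "84114007",
        "vetcn": ("heart_failure", 1292),
        "pmsb": ("heart_failure", 4615),
    },
    "asthma": {
        "cui": "C0004096",
        "snomed": "195967001",
        "vetcn": ("asthma", 1194),
        "pmsb": ("asthma", 8891),
    },
    "epilepsy": {
        "cui": "C0014544",
        "snomed": "84757009",
        "vetcn": ("epilepsy", 1164),
        "pmsb": ("epilepsy", 3521),
    },
    "glaucoma": {
        "cui": "C0017601",
        "snomed": "23986001",
        "vetcn": ("glaucoma", 1657),
        "pmsb": ("glaucoma", 1635),
    },
    "ckd": {
        "cui": "C1561643",
        "snomed": "709044004",
        "vetcn": ("ckd", 2698),
        "pmsb": ("CKD", 1550),  # PMSB keeps the original casing
    },
    "osteoarthritis": {
        "cui": "C0029408",
        "snomed": "396275006",
        "vetcn": ("osteoarthritis", 1765),
        "pmsb": ("osteoarthritis", 1991),
    },
    "anaemia": {
        "cui": "C0002871",
        "snomed": "271737000",
        "vetcn": ("anaemia", 1414),
        "pmsb": ("anaemia", 1154),
    },
    "arthritis": {
        "cui": "C0003864",
        "snomed": "3723001",
        "vetcn": ("arthritis", 8276),
        "pmsb": ("arthritis", 1023),
    },
    "diabetes": {
        "cui": "C0011849",
        "snomed": "73211009",
        "vetcn": ("diabetes", 3660),
        "pmsb": ("diabetes", 12846),
    },
    "hypertension": {
        "cui": "C0020538",
        "snomed": "38341003",
        "vetcn": ("hypertension", 1132),
        "pmsb": ("hypertension", 8365),
    },
    "obesity": {
        "cui": "C0028754",
        "snomed": "414916001",
        "vetcn": ("obesity", 1763),
        "pmsb": ("obesity", 10030),
    },
}

N_TARGETS = 11
N_ARCHITECTURES = 2  # CBOW, Skip-gram
N_DATASETS = 2  # VetCN, PMSB
TOP_K = 20
N_UNIQUE_CANDIDATES = 613  # unique candidate terms among the 880 pairs

# Short-form detector contingencies over the unique candidate terms:
# (correct SF, incorrectly flagged SF-I, missed SF-NF, correct NONE)
SF_DETECTOR_COUNTS: dict[str, DetectorCounts] = {
    "VetCN": DetectorCounts(57, 1, 14, 228),  # 300 unique terms
    "PMSB": DetectorCounts(75, 2, 0, 256),  # 333 unique terms
}

# Per-target normalization P/R/F (percent) for each dataset, architecture
# and experiment.  Rows are targets; each row holds four printed
# (P, R, F) triples: CBOW EXP-1, CBOW EXP-2, Skip-gram EXP-1,
# Skip-gram EXP-2.
NORMALIZATION_PRF: dict[str, dict[str, tuple[tuple[float, float, float], ...]]] = {
    "VetCN": {
        "anaemia": ((84.21, 94.12, 88.89), (95.00, 100.00, 97.44), (94.74, 94.74, 94.74), (95.00, 100.00, 97.44)),
        "arthritis": ((93.33, 73.68, 82.35), (100.00, 75.00, 85.71), (94.44, 89.47, 91.89), (100.00, 90.00, 94.74)),
        "asthma": ((100.00, 90.00, 94.74), (100.00, 95.00, 97.44), (89.47, 94.44, 91.89), (100.00, 100.00, 100.00)),
        "ckd": ((68.75, 73.33, 70.97), (100.00, 95.00, 97.44), (62.50, 71.43, 66.67), (100.00, 100.00, 100.00)),
        "diabetes": ((76.47, 81.25, 78.79), (100.00, 90.00, 94.74), (88.89, 88.89, 88.89), (94.74, 94.74, 94.74)),
        "epilepsy": ((100.00, 90.00, 94.74), (100.00, 95.00, 97.44), (100.00, 90.00, 94.74), (100.00, 95.00, 97.44)),
        "glaucoma": ((87.50, 77.78, 82.35), (94.74, 94.74, 94.74), (93.33, 73.68, 82.35), (94.74, 94.74, 94.74)),
        "heart_failure": ((73.68, 93.33, 82.35), (95.00, 100.00, 97.44), (84.21, 94.12, 88.89), (100.00, 100.00, 100.00)),
        "hypertension": ((71.43, 62.50, 66.67), (100.00, 95.00, 97.44), (72.22, 86.67, 78.79), (100.00, 100.00, 100.00)),
        "obesity": ((75.00, 100.00, 85.71), (85.00, 100.00, 91.89), (84.21, 94.12, 88.89), (89.47, 94.44, 91.89)),
        "osteoarthritis": ((94.74, 94.74, 94.74), (100.00, 95.00, 97.44), (85.00, 100.00, 91.89), (85.00, 100.00, 91.89)),
    },
    "PMSB": {
        "anaemia": ((90.00, 100.00, 94.74), (85.00, 100.00, 91.89), (84.21, 94.12, 88.89), (94.74, 94.74, 94.74)),
        "arthritis": ((88.89, 88.89, 88.89), (89.47, 94.44, 91.89), (100.00, 100.00, 100.00), (95.00, 100.00, 97.44)),
        "asthma": ((76.47, 81.25, 78.79), (72.22, 86.67, 78.79), (63.16, 92.31, 75.00), (68.42, 92.86, 78.79)),
        "CKD": ((100.00, 100.00, 100.00), (100.00, 100.00, 100.00), (90.00, 100.00, 94.74), (90.00, 100.00, 94.74)),
        "diabetes": ((63.16, 92.31, 75.00), (68.42, 92.86, 78.79), (75.00, 100.00, 85.71), (80.00, 100.00, 88.89)),
        "epilepsy": ((85.00, 100.00, 91.89), (95.00, 100.00, 97.44), (90.00, 100.00, 94.74), (95.00, 100.00, 97.44)),
        "glaucoma": ((90.00, 100.00, 94.74), (100.00, 100.00, 100.00), (84.21, 94.12, 88.89), (100.00, 100.00, 100.00)),
        "heart_failure": ((85.00, 100.00, 91.89), (90.00, 100.00, 94.74), (73.68, 93.33, 82.35), (90.00, 100.00, 94.74)),
        "hypertension": ((95.00, 100.00, 97.44), (100.00, 100.00, 100.00), (84.21, 94.12, 88.89), (95.00, 100.00, 97.44)),
        "obesity": ((100.00, 95.00, 97.44), (100.00, 100.00, 100.00), (94.74, 94.74, 94.74), (95.00, 100.00, 97.44)),
        "osteoarthritis": ((90.00, 100.00, 94.74), (100.00, 100.00, 100.00), (90.00, 100.00, 94.74), (100.00, 100.00, 100.00)),
    },
}

CONDITIONS = (
    ("VetCN", "CBOW", "EXP1", 0),
    ("VetCN", "CBOW", "EXP2", 1),
    ("VetCN", "SKIPGRAM", "EXP1", 2),
    ("VetCN", "SKIPGRAM", "EXP2", 3),
    ("PMSB", "CBOW", "EXP1", 0),
    ("PMSB", "CBOW", "EXP2", 1),
    ("PMSB", "SKIPGRAM", "EXP1", 2),
    ("PMSB", "SKIPGRAM", "EXP2", 3),
)

# Micro-averaged normalization P and R (percent) over the 613 unique
# candidate terms; the counts behind them are recoverable with
# concept_mapping.counts_from_prf.
MICRO_PR = {"EXP1": (84.68, 91.44), "EXP2": (92.41, 96.48)}

# Clinical validation of concept pairs: per (dataset, architecture) group
# of 220 term pairs, the number judged unrelated (the two negative labels).
VALIDATION_GROUPS: dict[tuple[str, str], tuple[int, int]] = {
    # (dataset, architecture) -> (group size, negative-labelled pairs)
    ("VetCN", "CBOW"): (220, 4),
    ("VetCN", "SKIPGRAM"): (220, 4),
    ("PMSB", "CBOW"): (220, 3),
    ("PMSB", "SKIPGRAM"): (220, 2),
}


def condition_values(metric: str) -> dict[tuple[str, str, str], list[float]]:
    """Per-(dataset, architecture, experiment) printed metric columns.

    ``metric`` is one of "P", "R", "F"; each column lists the 11
    per-target printed percentages in a fixed target order.
    """
    mi = {"P": 0, "R": 1, "F": 2}[metric]
    out: dict[tuple[str, str, str], list[float]] = {}
    for dataset, arch, exp, col in CONDITIONS:
        rows = NORMALIZATION_PRF[dataset]
        out[(dataset, arch, exp)] = [rows[t][col][mi] for t in rows]
    return out


def experiment_pairs(metric: str) -> tuple[list[float], list[float]]:
    """The 44 (EXP-1, EXP-2) value pairs for one metric.

    One pair per target x architecture x dataset, in a fixed order, for
    significance testing of the short-form-expansion effect.
    """
    cols = condition_values(metric)
    exp1: list[float] = []
    exp2: list[float] = []
    for dataset in ("VetCN", "PMSB"):
        for arch in ("CBOW", "SKIPGRAM"):
            exp1.extend(cols[(dataset, arch, "EXP1")])
            exp2.extend(cols[(dataset, arch, "EXP2")])
    return exp1, exp2
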