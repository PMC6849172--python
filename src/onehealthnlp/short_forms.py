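"""Short-form (abbreviation/acronym) detection, expansion and evaluation.

Clinical n-grams frequently contain short forms: measurement units
("mmHg"), acronyms ("HFpEF"), or cryptic lowercase abbreviations ("ckd").
The detector is a rule-based classifier over the "_"-separated tokens of
an n-gram, backed by two lexicons — a measurement-unit list and a ranked
common-word list (emulating a large general-English frequency list).  It
assigns one of four labels, in precedence order:

* ``SF_NU`` — a number together with a unit ("10_mg"); the n-gram is
  auto-mapped to the generic measurement concept (CUI C0242485);
* ``SF_U``  — a measurement unit ("mmHg"); auto-mapped to the
  unit-of-measure concept (CUI C1519795);
* ``SF``    — any other short-form token; expanded via a sense inventory;
* ``NONE``  — no short form found.

The rule set is intentionally simple and has two known error modes which
the evaluation labels name explicitly: a familiar all-lowercase word of
four or more letters used as an abbreviation ("echo" for
echocardiography) is missed (SF_NF), and an all-caps token that is not
clinically meaningful ("US") is flagged anyway (SF_I).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

UNIT_CUI = "C1519795"  # Unit of Measure
MEASUREMENT_CUI = "C0242485"  # Measurement

SF_U = "SF_U"
SF_NU = "SF_NU"
SF = "SF"
NONE = "NONE"

CORRECT_SF = "CORRECT_SF"
CORRECT_NONE = "CORRECT_NONE"
SF_I = "SF_I"  # flagged, but not clinically meaningful (false positive)
SF_NF = "SF_NF"  # meaningful short form not found (false negative)

_NUMBER_RE = re.compile(r"^\d+([.,]\d+)?$")
_LEADING_NUM_RE = re.compile(r"^[\d.,]+")
_LEADING_PUNCT_RE = re.compile(r"^[^\w]+|[^\w]+$")


class MisalignedGoldError(ValueError):
    """Predictions and gold labels cover different n-gram sets."""


class UndefinedMetricError(ZeroDivisionError):
    """A precision/recall denominator is zero."""


@dataclass(frozen=True)
class ShortFormLexicons:
    """Unit lexicon and ranked common-word list backing the detector."""

    units: frozenset[str]
    common_words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.units or not self.common_words:
            raise ValueError("both lexicons must be non-empty")
        object.__setattr__(
            self, "_units_folded", frozenset(u.lower() for u in self.units)
        )

    def is_unit(self, token: str) -> bool:
        """Exact match first, then case-insensitive ("g/dL" vs "g/dl")."""
        return token in self.units or token.lower() in self._units_folded

    def is_common(self, token: str, fold: bool = False) -> bool:
        return (token.lower() if fold else token) in self.common_words


@dataclass(frozen=True)
class SFRules:
    """Tunable thresholds of the rule set (defaults reproduce the
    documented behaviour including both error modes)."""

    max_lowercase_sf_len: int = 3  # all-lowercase tokens this short may be SFs
    min_caps_len: int = 2  # all-caps tokens this long are SF candidates
    fold_common_words: bool = False  # case-sensitive common-word lookup


@dataclass(frozen=True)
class SFAnnotation:
    label: str
    flagged_tokens: tuple[str, ...] = ()
    auto_cui: str | None = None

    def __post_init__(self) -> None:
        if self.label == NONE and self.flagged_tokens:
            raise ValueError("NONE label cannot carry flagged tokens")
        if self.label == SF_U and self.auto_cui != UNIT_CUI:
            raise ValueError("SF_U must map to the unit-of-measure concept")
        if self.label == SF_NU and self.auto_cui != MEASUREMENT_CUI:
            raise ValueError("SF_NU must map to the measurement concept")


def _strip(token: str) -> str:
    return _LEADING_PUNCT_RE.sub("", token)


def _is_number(token: str) -> bool:
    return bool(_NUMBER_RE.match(token))


def _fused_number_unit(token: str, lexicons: ShortFormLexicons) -> bool:
    """"10mg" — leading digits directly fused with a unit suffix."""
    m = _LEADING_NUM_RE.match(token)
    if not m or m.end() == len(token):
        return False
    return lexicons.is_unit(token[m.end() :])


def _is_sf_candidate(token: str, lexicons: ShortFormLexicons, rules: SFRules) -> bool:
    if not token or lexicons.is_common(token, fold=rules.fold_common_words):
        return False
    letters = [c for c in token if c.isalpha()]
    if not letters:
        return False
    n_upper = sum(1 for c in letters if c.isupper())
    has_digit = any(c.isdigit() for c in token)
    if n_upper >= 2:
        return True  # "HFpEF", "CRT", "mmHg"-like mixes
    if all(c.isupper() for c in letters) and len(letters) >= rules.min_caps_len:
        return True  # "US", "HF"
    if has_digit and letters:
        return True  # "Cox-2", "b12"
    if all(c.islower() for c in letters) and len(token) <= rules.max_lowercase_sf_len:
        return True  # "ckd", "bid" — but not "echo" (length 4, missed)
    return False


def detect_short_forms(
    ngram: str,
    lexicons: ShortFormLexicons,
    rules: SFRules = SFRules(),
) -> SFAnnotation:
    """Classify an n-gram's tokens; precedence SF_NU > SF_U > SF > NONE."""
    if not ngram:
        raise ValueError("empty n-gram")
    tokens = ngram.split("_")
    unit_tokens = [t for t in tokens if lexicons.is_unit(_strip(t))]
    number_tokens = [t for t in tokens if _is_number(_strip(t))]
    fused = [t for t in tokens if _fused_number_unit(_strip(t), lexicons)]

    if fused or (unit_tokens and number_tokens):
        flagged = tuple(dict.fromkeys(unit_tokens + number_tokens + fused))
        return SFAnnotation(SF_NU, flagged, MEASUREMENT_CUI)
    if unit_tokens:
        return SFAnnotation(SF_U, tuple(unit_tokens), UNIT_CUI)
    sf_tokens = tuple(
        t for t in tokens if _is_sf_candidate(_strip(t), lexicons, rules)
    )
    if sf_tokens:
        return SFAnnotation(SF, sf_tokens)
    return SFAnnotation(NONE)


def expand_short_forms(
    ngram: str,
    annotation: SFAnnotation,
    inventory: Mapping[str, Sequence[str]],
    overrides: Mapping[str, str] | None = None,
) -> str:
    """Replace each flagged SF token with its expansion.

    The rank-1 sense from ``inventory`` is used unless ``overrides`` names
    another sense for the token.  Tokens absent from the inventory are
    left in place with a warning.  Only ``SF``-labelled n-grams are
    expanded; unit/measurement n-grams keep their auto-assigned concept
    and everything else is returned unchanged.
    """
    if annotation.label != SF:
        return ngram
    overrides = overrides or {}
    tokens = ngram.split("_")
    flagged = set(annotation.flagged_tokens)
    out = []
    for tok in tokens:
        if tok not in flagged:
            out.append(tok)
            continue
        if tok in overrides:
            expansion = overrides[tok]
        elif tok in inventory and inventory[tok]:
            expansion = inventory[tok][0]
        else:
            warnings.warn(f"no sense-inventory entry for short form {tok!r}")
            out.append(tok)
            continue
        # multi-token n-grams must stay whitespace-free
        out.append(expansion.replace(" ", "_") if len(tokens) > 1 else expansion)
    return "_".join(out)


@dataclass(frozen=True)
class DetectorCounts:
    """Contingency of the detector against expert gold judgements."""

    correct_sf: int  # gold meaningful SF, detector flagged it (TP role)
    sf_incorrect: int  # flagged, gold says not meaningful (FP role)
    sf_not_found: int  # gold meaningful SF missed (FN role)
    correct_none: int  # gold no SF, detector silent (TN role)

    @property
    def total(self) -> int:
        return self.correct_sf + self.sf_incorrect + self.sf_not_found + self.correct_none


def assess_detector(
    predictions: Mapping[str, SFAnnotation],
    gold_has_sf: Mapping[str, bool],
) -> DetectorCounts:
    """Compare detector output with gold has-a-meaningful-SF judgements."""
    if set(predictions) != set(gold_has_sf):
        only_pred = sorted(set(predictions) - set(gold_has_sf))
        only_gold = sorted(set(gold_has_sf) - set(predictions))
        raise MisalignedGoldError(
            f"prediction/gold n-gram sets differ; only in predictions: "
            f"{only_pred}; only in gold: {only_gold}"
        )
    tp = fp = fn = tn = 0
    for ngram, ann in predictions.items():
        flagged = ann.label != NONE
        if gold_has_sf[ngram]:
            if flagged:
                tp += 1
            else:
                fn += 1
        else:
            if flagged:
                fp += 1
            else:
                tn += 1
    return DetectorCounts(tp, fp, fn, tn)


def verdict(predicted: SFAnnotation, gold_has_sf: bool) -> str:
    flagged = predicted.label != NONE
    if gold_has_sf:
        return CORRECT_SF if flagged else SF_NF
    return SF_I if flagged else CORRECT_NONE


SF_SIDE = "SF_SIDE"
NONE_SIDE = "NONE_SIDE"


def detector_prf(
    counts: DetectorCounts, mode: str = SF_SIDE
) -> tuple[float, float, float]:
    """Precision/recall/F (percent, 2 dp) for either side of the detector.

    ``SF_SIDE`` measures the ability to find n-grams WITH a clinically
    meaningful short form (TP=correct SF, FP=incorrectly flagged,
    FN=missed).  ``NONE_SIDE`` swaps the roles: TP=correct NONE,
    FN=incorrectly flagged, FP=missed.  F is computed from the counts,
    2TP/(2TP+FP+FN), not from the rounded P and R.
    """
    if mode == SF_SIDE:
        tp, fp, fn = counts.correct_sf, counts.sf_incorrect, counts.sf_not_found
    elif mode == NONE_SIDE:
        tp, fp, fn = counts.correct_none, counts.sf_not_found, counts.sf_incorrect
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if tp + fp == 0 or tp + fn == 0:
        raise UndefinedMetricError(
            f"undefined metric for counts tp={tp} fp={fp} fn={fn}"
        )
    p = 100.0 * tp / (tp + fp)
    r = 100.0 * tp / (tp + fn)
    f = 100.0 * 2 * tp / (2 * tp + fp + fn)
    return round(p, 2), round(r, 2), round(f, 2)


# ---------------------------------------------------------------------------
# lexicon / inventory IO (one term per line; TSV short<TAB>long<TAB>rank)


def read_term_list(path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def read_sense_inventory(path) -> dict[str, list[str]]:
    entries: dict[str, list[tuple[int, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            short, long_form, rank = line.split("\t")
            entries.setdefault(short, []).append((int(rank), long_form))
    return {
        short: [lf for _, lf in sorted(ranked)] for short, ranked in entries.items()
    }


def write_annotations(
    annotations: Mapping[str, SFAnnotation],
    expansions: Mapping[str, str],
    path,
) -> None:
    """Annotation TSV: ngram, label, flagged tokens (';'-joined), auto CUI,
    expanded form."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ngram\tlabel\tflagged_tokens\tauto_cui\texpanded_form\n")
        for ngram in sorted(annotations):
            ann = annotations[ngram]
            fh.write(
                "\t".join(
                    [
                        ngram,
                        ann.label,
                        ";".join(ann.flagged_tokens),
                        ann.auto_cui or "",
                        expansions.get(ngram, ngram),
                    ]
                )
                + "\n"
            )
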