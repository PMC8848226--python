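"""Scorers for the study's clinical instruments.

* SEQ — Suitability Evaluation Questionnaire for virtual rehabilitation:
  13 scored Likert items (1–5) plus an unscored open-ended question;
  items Q7–Q10, Q12 and Q13 are negatively keyed and reverse-scored, so
  the total ranges from 13 (worst) to 65 (best suitability).
* NDI — Neck Disability Index: 10 items, each 0–5; the raw total (max
  50) is also expressed as a percentage of the maximum.
* MMSE — Mini-Mental State Examination (adapted 35-point version):
  severity brackets by score and an age-dependent screening cutoff
  (24 for geriatric respondents aged 65+, 29 otherwise).
* VAS — visual analogue pain scale, 0–10; values above 3 flag poor
  pain control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "SeqResponse",
    "NdiResponse",
    "MmseRecord",
    "VasValue",
    "SEQ_REVERSE_ITEMS",
    "score_seq",
    "score_ndi",
    "mmse_classify",
    "validate_vas",
]

#: 1-based ids of the negatively keyed SEQ items (scored as 6 − raw).
SEQ_REVERSE_ITEMS = frozenset({7, 8, 9, 10, 12, 13})

EDUCATION_LEVELS = ("elementary", "standard", "university")

#: MMSE severity brackets, inclusive score ranges on the 35-point scale.
MMSE_BRACKETS = (
    (30, 35, "normal"),
    (24, 29, "borderline"),
    (19, 23, "mild"),
    (14, 18, "moderate"),
    (0, 13, "severe"),
)


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, name: str) -> list[int]:
    items = list(items)
    if len(items) != n:
        raise ValueError(f"{name} requires exactly {n} items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not float(v).is_integer() or not lo <= int(v) <= hi:
            raise ValueError(
                f"{name} item {i} must be an integer in [{lo}, {hi}], got {v!r}"
            )
    return [int(v) for v in items]


@dataclass(frozen=True)
class SeqResponse:
    """The 13 scored SEQ items (Q1–Q13), raw values 1–5 each.

    The open-ended question is kept verbatim and never scored.
    """

    items: Sequence[int]
    open_comment: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", _check_items(self.items, 13, 1, 5, "SEQ"))


@dataclass(frozen=True)
class NdiResponse:
    """The 10 NDI items, each 0 (no disability) to 5 (worst)."""

    items: Sequence[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", _check_items(self.items, 10, 0, 5, "NDI"))


@dataclass(frozen=True)
class MmseRecord:
    """An MMSE administration: score on the 35-point scale, age, education."""

    score: int
    age: float
    education_level: str = "standard"

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 35:
            raise ValueError(f"MMSE score must lie in [0, 35], got {self.score}")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.education_level not in EDUCATION_LEVELS:
            raise ValueError(f"education_level must be one of {EDUCATION_LEVELS}")


@dataclass(frozen=True)
class VasValue:
    """A validated 0–10 pain rating; ``poor_control`` flags values above 3."""

    value: float
    poor_control: bool


def score_seq(r: SeqResponse) -> int:
    """Total SEQ score in [13, 65]; higher means better suitability.

    Positively keyed items contribute their raw value; the negatively
    keyed items (Q7–Q10, Q12, Q13 — the difficulty/discomfort block)
    contribute the standard Likert reversal ``6 − raw``.
    """
    total = 0
    for qid, raw in enumerate(r.items, start=1):
        total += (6 - raw) if qid in SEQ_REVERSE_ITEMS else raw
    return total


def score_ndi(r: NdiResponse) -> dict[str, float]:
    """NDI raw total (0–50) and its percentage of the maximum score."""
    raw = sum(r.items)
    return {"raw": raw, "percent": 100.0 * raw / 50.0}


def mmse_classify(rec: MmseRecord) -> dict[str, object]:
    """Severity bracket and age-dependent screening cutoff.

    Returns ``bracket`` (normal/borderline/mild/moderate/severe),
    ``cutoff`` (24 for respondents aged 65 and over, 29 for younger
    adults) and ``below_cutoff``.
    """
    bracket = next(name for lo, hi, name in MMSE_BRACKETS if lo <= rec.score <= hi)
    cutoff = 24 if rec.age >= 65 else 29
    return {
        "bracket": bracket,
        "cutoff": cutoff,
        "below_cutoff": rec.score < cutoff,
    }


def validate_vas(v: float) -> VasValue:
    """Validate a 0–10 pain rating; ratings above 3 indicate poor pain control."""
    v = float(v)
    if not 0.0 <= v <= 10.0:
        raise ValueError(f"VAS must lie in [0, 10], got {v}")
    return VasValue(value=v, poor_control=v > 3.0)
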