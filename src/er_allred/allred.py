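"""Allred scoring of a slide from its stain-class composition.

The Allred system grades estrogen-receptor expression as the sum of two
sub-scores. The proportion score bins the percentage p of positively
stained cells (DAB-brown: weak, moderate, or strong) over all cells:

    p = 0        -> 0
    0 < p < 1    -> 1
    1 <= p <= 10 -> 2
    10 < p <= 33 -> 3
    33 < p <= 66 -> 4
    p > 66       -> 5

The intensity score reflects the staining strength of most positive cells:
0 when no positive cells are present, otherwise 1/2/3 according to whether
weak, moderate, or strong is the largest positive class (ties go to the
stronger class). The total lies in {0, 2, ..., 8}; a total of 1 cannot
occur because the two sub-scores are zero together. Totals of 3 and above
support a hormonal-therapy recommendation; 0 and 2 do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "SlideSummary",
    "AllredResult",
    "proportion_score",
    "intensity_score",
    "allred",
    "score_components",
    "treatment",
]

#: slides below this positivity (percent) are flagged in reports: spurious
#: sub-0.1% detections are a known failure mode on truly ER-negative slides
LOW_POSITIVITY_PCT = 0.1


@dataclass(frozen=True)
class SlideSummary:
    """Per-slide class totals; counts or percentages, in N/W/M/S order."""

    n_negative: float
    n_weak: float
    n_moderate: float
    n_strong: float

    def __post_init__(self):
        if min(self.n_negative, self.n_weak, self.n_moderate, self.n_strong) < 0:
            raise ValueError("class totals must be >= 0")

    @classmethod
    def from_cells(cls, cells: Sequence) -> "SlideSummary":
        counts = {"N": 0, "W": 0, "M": 0, "S": 0}
        for c in cells:
            if c.label not in counts:
                raise ValueError(f"cell without a valid stain class: {c!r}")
            counts[c.label] += 1
        return cls(counts["N"], counts["W"], counts["M"], counts["S"])

    @property
    def total(self) -> float:
        return self.n_negative + self.n_weak + self.n_moderate + self.n_strong

    @property
    def positive_pct(self) -> float:
        """ER status: 100 * (W + M + S) / total."""
        if self.total == 0:
            raise ValueError("slide with no cells is not scorable")
        return 100.0 * (self.n_weak + self.n_moderate + self.n_strong) / self.total


def proportion_score(p: float) -> int:
    """Proportion sub-score (0-5) from the positive-cell percentage."""
    if not 0 <= p <= 100:
        raise ValueError(f"positive percentage must be in [0, 100], got {p}")
    if p == 0:
        return 0
    if p < 1:
        return 1
    if p <= 10:
        return 2
    if p <= 33:
        return 3
    if p <= 66:
        return 4
    return 5


def intensity_score(strong: float, moderate: float, weak: float) -> int:
    """Intensity sub-score (0-3) from the majority positive class.

    Arguments may be counts or percentages; only their ordering matters.
    Ties break toward the stronger class.
    """
    if min(strong, moderate, weak) < 0:
        raise ValueError("class totals must be >= 0")
    if strong == moderate == weak == 0:
        return 0
    if strong >= moderate and strong >= weak:
        return 3
    if moderate >= weak:
        return 2
    return 1


@dataclass(frozen=True)
class AllredResult:
    """Proportion + intensity sub-scores, their sum, and the treatment flag."""

    proportion_score: int
    intensity_score: int
    total: int
    actionable: bool
    low_positivity: bool = False

    def __post_init__(self):
        if self.total != self.proportion_score + self.intensity_score:
            raise ValueError("total must equal proportion + intensity score")
        if self.total == 1:
            raise ValueError("an Allred score of 1 is not a possible outcome")
        if (self.proportion_score == 0) != (self.intensity_score == 0):
            raise ValueError("proportion and intensity scores are zero together")


def score_components(p: float, strong: float, moderate: float, weak: float
                     ) -> AllredResult:
    """Allred result from an ER percentage plus the positive-class breakdown."""
    ps = proportion_score(p)
    i = intensity_score(strong, moderate, weak)
    if ps > 0 and i == 0:
        raise ValueError(
            "positive percentage with an all-zero positive class breakdown")
    if ps == 0:
        i = 0
    total = ps + i
    return AllredResult(ps, i, total, actionable=treatment(total),
                        low_positivity=0 < p < LOW_POSITIVITY_PCT)


def allred(summary: SlideSummary) -> AllredResult:
    """Allred result for a slide summary (total count must be positive)."""
    p = summary.positive_pct  # raises on an empty slide
    return score_components(p, summary.n_strong, summary.n_moderate, summary.n_weak)


def treatment(score: int) -> bool:
    """Hormonal-therapy recommendation: True for Allred scores of 3 to 8."""
    if score == 1:
        raise ValueError("an Allred score of 1 is not a possible outcome")
    if score not in (0, 2, 3, 4, 5, 6, 7, 8):
        raise ValueError(f"Allred score must be in {{0, 2..8}}, got {score}")
    return score >= 3
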