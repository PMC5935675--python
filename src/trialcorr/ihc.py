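"""pSTAT3 IHC T-scoring, eligibility, and the screening funnel.

The T-score is an additive semi-quantitative score in the Allred style:
an intensity component (0-3) plus a proportion component (0-5) binned from
the percent of stained cells. Interpretation anchors: total 0 (and the
otherwise-unreachable 1-2) negative; 3-4 weak/equivocal; 5-6 moderate;
7-8 high. Eligibility defaults to moderate-or-high, i.e. total >= 5.
Bin edges and the eligibility threshold are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

NEGATIVE = "negative"
WEAK = "weak/equivocal"
MODERATE = "moderate"
HIGH = "high"

CATEGORIES = (NEGATIVE, WEAK, MODERATE, HIGH)

#: Upper edges of the >0 proportion bins (percent positive), Allred style:
#: score 1: (0,1], 2: (1,10], 3: (10,33], 4: (33,66], 5: (66,100].
DEFAULT_PROPORTION_EDGES = (1.0, 10.0, 33.0, 66.0)

DEFAULT_ELIGIBILITY_THRESHOLD = 5


@dataclass(frozen=True)
class TScore:
    intensity_score: int
    proportion_score: int
    total: int
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class ScreeningFunnel:
    n_consented: int
    n_with_result: int
    n_high_moderate: int
    n_weak: int
    n_negative: int

    def __post_init__(self):
        if self.n_with_result != (self.n_high_moderate + self.n_weak
                                  + self.n_negative):
            raise ValueError("category counts must sum to n_with_result")
        if self.n_with_result > self.n_consented:
            raise ValueError("n_with_result cannot exceed n_consented")

    @property
    def positive_fraction(self) -> float | None:
        """Moderate-or-high share of scored samples; None if none scored."""
        if self.n_with_result == 0:
            return None
        return self.n_high_moderate / self.n_with_result

    @property
    def positive_percent(self) -> float | None:
        """Positive fraction as a percent at one-decimal display precision."""
        frac = self.positive_fraction
        return None if frac is None else round(100.0 * frac, 1)


def proportion_score(percent_positive: float,
                     edges=DEFAULT_PROPORTION_EDGES) -> int:
    """Bin percent-positive into the 0-5 proportion component."""
    if not (0.0 <= percent_positive <= 100.0):
        raise ValueError("percent_positive must be in [0, 100]")
    if percent_positive == 0.0:
        return 0
    for score, upper in enumerate(edges, start=1):
        if percent_positive <= upper:
            return score
    return len(edges) + 1


def category_for_total(total: int) -> str:
    """Interpretation anchors on the additive total."""
    if total >= 7:
        return HIGH
    if total >= 5:
        return MODERATE
    if total >= 3:
        return WEAK
    return NEGATIVE


def tscore(percent_positive: float, intensity: int,
           edges=DEFAULT_PROPORTION_EDGES) -> TScore:
    """Compute the additive T-score from percent stained and intensity.

    If either component is 0 the total is 0 (no staining); a nonzero
    percent with intensity 0 is contradictory and collapses to 0 with a
    warning.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be an integer in 0..3")
    p_score = proportion_score(percent_positive, edges)
    if intensity == 0 and p_score > 0:
        warnings.warn(
            "percent_positive > 0 with intensity 0 is contradictory; "
            "scoring as total 0 (negative)", stacklevel=2)
    if intensity == 0 or p_score == 0:
        return TScore(intensity_score=intensity, proportion_score=p_score,
                      total=0, category=NEGATIVE)
    total = intensity + p_score
    return TScore(intensity_score=intensity, proportion_score=p_score,
                  total=total, category=category_for_total(total))


def is_eligible(t: TScore,
                threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD) -> bool:
    """Trial eligibility: moderate-or-high staining (total >= 5 by default)."""
    return t.total >= threshold


def funnel_summary(results: list[TScore], n_consented: int) -> ScreeningFunnel:
    """Tabulate scored samples into the screening funnel."""
    if len(results) > n_consented:
        raise ValueError("more results than consented patients")
    n_hm = sum(1 for t in results if t.category in (MODERATE, HIGH))
    n_weak = sum(1 for t in results if t.category == WEAK)
    n_neg = sum(1 for t in results if t.category == NEGATIVE)
    return ScreeningFunnel(n_consented=n_consented,
                           n_with_result=len(results),
                           n_high_moderate=n_hm,
                           n_weak=n_weak,
                           n_negative=n_neg)


def score_table(df: pd.DataFrame,
                edges=DEFAULT_PROPORTION_EDGES,
                threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD) -> pd.DataFrame:
    """Score a CSV-shaped table (sample_id, percent_positive, intensity).

    Returns one row per sample with score components, category and
    eligibility.
    """
    required = {"sample_id", "percent_positive", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        t = tscore(float(rec.percent_positive), int(rec.intensity), edges)
        rows.append({
            "sample_id": rec.sample_id,
            "proportion_score": t.proportion_score,
            "intensity_score": t.intensity_score,
            "total": t.total,
            "category": t.category,
            "eligible": is_eligible(t, threshold),
        })
    return pd.DataFrame(rows)
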