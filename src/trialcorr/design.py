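"""Exact operating characteristics of a two-stage single-arm binomial design.

The design enrols ``n1`` patients, continues to a total of ``n_total`` only
if at least ``r1`` responses are seen in stage 1, and declares the agent
worthy of further study if at least ``r`` responses are seen overall.
Responses observed in stage 1 count toward the total. All probabilities are
computed by exact summation over stage-1 outcomes times binomial tail
probabilities for stage 2 — no Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps

CONTINUE = "continue"
STOP_EARLY = "stop_early"
WORTHY = "worthy"
NOT_WORTHY = "not_worthy"


@dataclass(frozen=True)
class TwoStageDesign:
    """Decision rules (n1, r1, n_total, r) with design hypotheses (p0, p1)."""

    n1: int
    r1: int
    n_total: int
    r: int
    p0: float = 0.05
    p1: float = 0.20

    def __post_init__(self):
        if not (0 < self.n1 <= self.n_total):
            raise ValueError("require 0 < n1 <= n_total")
        if not (0 <= self.r1 <= self.n1):
            raise ValueError("require 0 <= r1 <= n1")
        if not (self.r1 <= self.r <= self.n_total):
            raise ValueError("require r1 <= r <= n_total")
        if not (0.0 <= self.p0 < self.p1 <= 1.0):
            raise ValueError("require 0 <= p0 < p1 <= 1")

    @property
    def n2(self) -> int:
        return self.n_total - self.n1


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Exact error rates and accrual profile under the null."""

    alpha: float       # P(worthy | p0)
    power: float       # P(worthy | p1)
    pet0: float        # P(stop at stage 1 | p0)
    expected_n0: float  # E[sample size | p0]

    def __post_init__(self):
        for name in ("alpha", "power", "pet0"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {v}")


def reject_probability(design: TwoStageDesign, p: float) -> float:
    """P(declare worthy) at true response probability ``p``.

    Sum over stage-1 response counts x1 = r1..n1 of
    Binom(x1; n1, p) * P(X2 >= max(0, r - x1)), X2 ~ Binom(n2, p).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    total = 0.0
    for x1 in range(design.r1, design.n1 + 1):
        need = design.r - x1
        tail = 1.0 if need <= 0 else float(sps.binom.sf(need - 1, design.n2, p))
        total += float(sps.binom.pmf(x1, design.n1, p)) * tail
    return min(total, 1.0)


def early_termination_probability(design: TwoStageDesign, p: float) -> float:
    """P(X1 < r1) at true response probability ``p``."""
    if design.r1 == 0:
        return 0.0
    return float(sps.binom.cdf(design.r1 - 1, design.n1, p))


def expected_sample_size(design: TwoStageDesign, p: float) -> float:
    """n1 + (1 - PET(p)) * n2."""
    pet = early_termination_probability(design, p)
    return design.n1 + (1.0 - pet) * design.n2


def operating_characteristics(design: TwoStageDesign) -> OperatingCharacteristics:
    """Exact (alpha, power, PET under p0, expected N under p0)."""
    return OperatingCharacteristics(
        alpha=reject_probability(design, design.p0),
        power=reject_probability(design, design.p1),
        pet0=early_termination_probability(design, design.p0),
        expected_n0=expected_sample_size(design, design.p0),
    )


def interim_decision(x1: int, design: TwoStageDesign) -> str:
    """``continue`` iff at least r1 responses among the first n1 patients."""
    if not (0 <= x1 <= design.n1):
        raise ValueError(f"x1 must be in [0, {design.n1}]")
    return CONTINUE if x1 >= design.r1 else STOP_EARLY


def final_decision(x_total: int, design: TwoStageDesign,
                   x1: int | None = None) -> str:
    """``worthy`` iff the stage-1 gate passed and x_total >= r.

    If ``x1`` is omitted the stage-1 gate is assumed to have passed (the
    trial reached a final analysis at all).
    """
    if not (0 <= x_total <= design.n_total):
        raise ValueError(f"x_total must be in [0, {design.n_total}]")
    if x1 is not None:
        if x1 > x_total:
            raise ValueError("stage-1 responses cannot exceed the total")
        if interim_decision(x1, design) == STOP_EARLY:
            return NOT_WORTHY
    return WORTHY if x_total >= design.r else NOT_WORTHY
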