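"""Clinical endpoint summaries: response rates, Kaplan-Meier, AE tables.

Best-response categories follow RECIST-style labels (CR/PR/SD/PD/NE).
Unevaluable patients stay in the efficacy denominator. Display percentages
use round-half-to-even at integer precision while exact fractions are
retained on the result objects. Kaplan-Meier medians and their 95% CIs come
from the product-limit estimator with the log-log (exponential Greenwood)
confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
CBR_SD_WEEKS = 24.0


@dataclass(frozen=True)
class TrialCohort:
    """Patient-level endpoint data plus long-format adverse events.

    ``patients`` columns: patient_id, best_response, sd_duration_weeks,
    pfs_months, pfs_event, os_months, os_event.
    ``ae`` columns: patient_id, ae_name, grade (1-4; one row per episode).
    """

    patients: pd.DataFrame
    ae: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["patient_id", "ae_name", "grade"]))

    def __post_init__(self):
        bad = set(self.patients["best_response"]) - set(RESPONSE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown best_response values: {sorted(bad)}")
        if len(self.ae) and not self.ae["grade"].isin([1, 2, 3, 4]).all():
            raise ValueError("AE grades must be integers in 1..4")
        for col in ("pfs_months", "os_months"):
            if col in self.patients and (self.patients[col] <= 0).any():
                raise ValueError(f"{col} must be positive")


def _display_pct(fraction: float) -> int:
    """Integer percent, round half to even (Python banker's rounding)."""
    return int(round(100.0 * fraction))


@dataclass(frozen=True)
class ResponseSummary:
    n: int
    counts: dict
    orr: float           # (CR+PR)/n
    sd_rate: float       # SD/n regardless of duration
    cbr: float           # (CR+PR+SD>24wk)/n

    @property
    def orr_pct(self) -> int:
        return _display_pct(self.orr)

    @property
    def sd_pct(self) -> int:
        return _display_pct(self.sd_rate)

    @property
    def cbr_pct(self) -> int:
        return _display_pct(self.cbr)


def response_summary(cohort: TrialCohort,
                     cbr_sd_weeks: float = CBR_SD_WEEKS) -> ResponseSummary:
    """Objective response, stable-disease and clinical-benefit rates.

    Clinical benefit counts CR, PR, and SD lasting strictly longer than
    ``cbr_sd_weeks`` weeks. All treated patients (including NE) are in the
    denominator.
    """
    df = cohort.patients
    if df.empty:
        raise ValueError("empty cohort")
    n = len(df)
    counts = {c: int((df["best_response"] == c).sum())
              for c in RESPONSE_CATEGORIES}
    orr = (counts["CR"] + counts["PR"]) / n
    sd_rate = counts["SD"] / n
    durable_sd = int(((df["best_response"] == "SD")
                      & (df.get("sd_duration_weeks", np.nan) > cbr_sd_weeks)
                      ).sum())
    cbr = (counts["CR"] + counts["PR"] + durable_sd) / n
    return ResponseSummary(n=n, counts=counts, orr=orr, sd_rate=sd_rate,
                           cbr=cbr)


@dataclass(frozen=True)
class KMEstimate:
    median: float | None
    ci_low: float | None
    ci_high: float | None
    n: int
    n_events: int

    @property
    def defined(self) -> bool:
        return self.median is not None


def km_estimate(times, events, alpha: float = 0.05) -> KMEstimate:
    """Product-limit median with a log-log transformed 95% CI.

    The median is the first time the survival curve drops to <= 0.5; if the
    curve never reaches 0.5 (e.g. everything censored) the estimate is
    undefined and ``median`` is None. CI bounds that are never crossed are
    reported as None.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)
    med = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(v) for v in np.asarray(ci).ravel()[:2])

    def _finite(v):
        return None if not np.isfinite(v) else v

    return KMEstimate(median=_finite(med), ci_low=_finite(lo),
                      ci_high=_finite(hi), n=int(times.size),
                      n_events=int(events.sum()))


def survival_function(times, events) -> pd.DataFrame:
    """The fitted step function (time, survival) for plotting/round-trips."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def ae_table(cohort: TrialCohort, min_incidence: float = 0.10
             ) -> pd.DataFrame:
    """Worst-grade-per-patient AE table with incidence/severity filtering.

    One output row per adverse event: counts in grade columns g1..g4 (each
    patient counted once, at their maximum grade), total count and display
    percent. Rows are kept when incidence >= ``min_incidence`` or any
    patient reached grade >= 3.
    """
    n = len(cohort.patients)
    if n == 0:
        raise ValueError("empty cohort")
    if cohort.ae.empty:
        return pd.DataFrame(columns=["ae_name", "g1", "g2", "g3", "g4",
                                     "total", "pct"])
    worst = (cohort.ae.groupby(["ae_name", "patient_id"])["grade"].max()
             .reset_index())
    rows = []
    for ae_name, grp in worst.groupby("ae_name"):
        gcounts = {f"g{g}": int((grp["grade"] == g).sum()) for g in (1, 2, 3, 4)}
        total = int(len(grp))
        row = {"ae_name": ae_name, **gcounts, "total": total,
               "pct": _display_pct(total / n)}
        if total / n >= min_incidence or gcounts["g3"] or gcounts["g4"]:
            rows.append(row)
    out = pd.DataFrame(rows, columns=["ae_name", "g1", "g2", "g3", "g4",
                                      "total", "pct"])
    return out.sort_values("ae_name").reset_index(drop=True)
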