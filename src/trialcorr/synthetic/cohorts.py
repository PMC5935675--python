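"""Synthetic single-arm cohorts: best response, survival, adverse events.

Responses are Bernoulli; progression-free and overall survival are
exponential with the requested medians; censoring is an independent
exponential race calibrated so the marginal censoring probability equals
``censor_rate``. Adverse-event worst grades are sampled per patient from a
per-AE categorical profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trialcorr.endpoints import TrialCohort

RESPONSES = ("CR", "PR", "SD", "PD", "NE")

#: Default worst-grade probabilities (grades 1..4); remainder = no event.
DEFAULT_AE_PROFILE = {
    "Fatigue": (0.30, 0.18, 0.02, 0.0),
    "Anemia": (0.10, 0.10, 0.08, 0.0),
    "Nausea": (0.12, 0.05, 0.0, 0.0),
}


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 21
    response_prob: float = 0.05
    sd_prob: float = 0.15          # P(SD | no objective response)
    ne_prob: float = 0.05          # P(unevaluable), drawn independently
    median_pfs: float = 1.2        # months
    median_os: float = 4.5         # months
    censor_rate: float = 0.1
    sd_duration_mean_weeks: float = 16.0
    ae_profile: dict = field(default_factory=lambda: dict(DEFAULT_AE_PROFILE))
    seed: int = 0

    def __post_init__(self):
        for name in ("response_prob", "sd_prob", "ne_prob", "censor_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.median_pfs <= 0 or self.median_os <= 0:
            raise ValueError("medians must be positive")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, grades in self.ae_profile.items():
            g = np.asarray(grades, dtype=float)
            if g.shape != (4,) or (g < 0).any() or g.sum() > 1 + 1e-9:
                raise ValueError(f"bad grade profile for {name!r}")


def _censored_exponential(rng: np.random.Generator, n: int, median: float,
                          censor_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Observed times and event flags for an exponential/censoring race."""
    lam = math.log(2.0) / median
    t = rng.exponential(1.0 / lam, n)
    if censor_rate <= 0.0:
        return t, np.ones(n, dtype=bool)
    if censor_rate >= 1.0:
        return t, np.zeros(n, dtype=bool)
    lam_c = lam * censor_rate / (1.0 - censor_rate)
    c = rng.exponential(1.0 / lam_c, n)
    return np.minimum(t, c), t <= c


def generate_cohort(spec: CohortSpec) -> TrialCohort:
    """Draw a patient table plus long-format AE table from the spec."""
    seqs = np.random.SeedSequence(spec.seed).spawn(4)
    rng_resp, rng_pfs, rng_os, rng_ae = (
        np.random.Generator(np.random.PCG64(s)) for s in seqs)
    n = spec.n_patients

    responder = rng_resp.random(n) < spec.response_prob
    sd = (~responder) & (rng_resp.random(n) < spec.sd_prob)
    ne = rng_resp.random(n) < spec.ne_prob
    best = np.where(ne, "NE",
                    np.where(responder, "PR", np.where(sd, "SD", "PD")))
    sd_weeks = np.where(
        best == "SD",
        rng_resp.exponential(spec.sd_duration_mean_weeks, n), np.nan)

    pfs, pfs_event = _censored_exponential(rng_pfs, n, spec.median_pfs,
                                           spec.censor_rate)
    os_, os_event = _censored_exponential(rng_os, n, spec.median_os,
                                          spec.censor_rate)

    patients = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "best_response": best,
        "sd_duration_weeks": sd_weeks,
        "pfs_months": pfs,
        "pfs_event": pfs_event,
        "os_months": os_,
        "os_event": os_event,
    })

    ae_rows = []
    for ae_name, grades in spec.ae_profile.items():
        g = np.asarray(grades, dtype=float)
        probs = np.concatenate([[1.0 - g.sum()], g])
        draws = rng_ae.choice(5, size=n, p=probs)  # 0 = no event
        for i, grade in enumerate(draws):
            if grade > 0:
                ae_rows.append({"patient_id": patients.patient_id[i],
                                "ae_name": ae_name, "grade": int(grade)})
    ae = pd.DataFrame(ae_rows, columns=["patient_id", "ae_name", "grade"])
    return TrialCohort(patients=patients, ae=ae)
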