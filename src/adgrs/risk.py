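"""Relative-to-absolute risk conversion for covariate profiles.

An odds ratio per 0.1 score units and a baseline probability determine the
probability at any other score value: convert the baseline to odds,
multiply by ``OR^(Δ/0.1)``, convert back.  Equal percentage-point risk
differences can therefore coexist with very different odds ratios when
baseline risks differ — the arithmetic this module makes explicit.

``shift_probability``/``risk_difference`` work directly from printed
numbers (no fitted model needed); ``predict_from_fit`` serves the
model-based route on synthetic or user data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

from .estimation import AGE_CENTER, YEAR_CENTER, FitResult


@dataclass(frozen=True)
class RiskProfile:
    """Covariate profile at which to evaluate absolute risk."""

    race: str = "NHW"
    sex: str = "male"
    age: float = 70.0
    grs: float = 0.10
    wave_year: int = 2006
    baseline_probability: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.grs < 1.0:
            raise ValueError("grs must be a probability-scale score in (0, 1)")
        if self.baseline_probability is not None and not (
            0.0 < self.baseline_probability < 1.0
        ):
            raise ValueError("baseline_probability must be in (0, 1)")


def shift_probability(
    baseline: float, or_per_unit: float, delta_exposure: float, *, scale: float = 0.1
) -> float:
    """Probability after shifting exposure by ``delta_exposure``.

    ``or_per_unit`` is the odds ratio per ``scale`` exposure units, so the
    odds multiply by ``or_per_unit ** (delta_exposure / scale)``.
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError("baseline must be in (0, 1)")
    if or_per_unit <= 0.0:
        raise ValueError("odds ratio must be positive")
    odds = baseline / (1.0 - baseline) * or_per_unit ** (delta_exposure / scale)
    return odds / (1.0 + odds)


def risk_difference(
    baseline: float, or_per_unit: float, delta_exposure: float, *, scale: float = 0.1
) -> float:
    """Percentage-point change in probability for the same shift."""
    return 100.0 * (
        shift_probability(baseline, or_per_unit, delta_exposure, scale=scale) - baseline
    )


def predict_from_fit(fit: FitResult, profile: RiskProfile | Mapping[str, object]) -> float:
    """Inverse-logit of the fitted linear predictor at a covariate profile.

    Only defined for the binomial family; raises if the fit involves a
    covariate the profile cannot supply.
    """
    if fit.family != "binomial":
        raise ValueError("absolute-risk prediction needs a logistic fit")
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if isinstance(profile, RiskProfile):
        prof = {
            "race": profile.race,
            "sex": profile.sex,
            "age": profile.age,
            "wave_year": profile.wave_year,
            fit.spec.exposure: profile.grs,
        }
    else:
        prof = dict(profile)
    x = []
    for term in fit.params.index:
        if term == "const":
            x.append(1.0)
        elif term == "age_c":
            x.append(float(prof["age"]) - AGE_CENTER)
        elif term == "year_c":
            x.append(float(prof["wave_year"]) - YEAR_CENTER)
        elif term == "male":
            x.append(1.0 if prof["sex"] == "male" else 0.0)
        elif term == "black":
            x.append(1.0 if prof["race"] == "NHB" else 0.0)
        elif term == "age65":
            x.append(1.0 if float(prof["age"]) >= 65.0 else 0.0)
        elif term in prof:
            x.append(float(prof[term]))
        elif ":" in term:
            left, right = term.split(":", 1)
            parts = []
            for piece in (left, right):
                if piece == "black":
                    parts.append(1.0 if prof["race"] == "NHB" else 0.0)
                elif piece == "male":
                    parts.append(1.0 if prof["sex"] == "male" else 0.0)
                elif piece == "age65":
                    parts.append(1.0 if float(prof["age"]) >= 65.0 else 0.0)
                elif piece in prof:
                    parts.append(float(prof[piece]))
                else:
                    raise KeyError(f"profile cannot supply model term {term!r}")
            x.append(parts[0] * parts[1])
        else:
            raise KeyError(f"profile cannot supply model term {term!r}")
    lp = float(np.dot(np.asarray(x), fit.params.to_numpy()))
    return float(expit(lp))


def worked_example(
    baseline_pct: float, or_per_01: float, grs_from: float = 0.100, grs_to: float = 0.137
) -> dict[str, float]:
    """Absolute-risk shift for one profile, on the printed (percent) scale.

    Returns the shifted probability (percent, 2 dp convention) and the risk
    difference in percentage points (1 dp convention), unrounded.
    """
    base = baseline_pct / 100.0
    delta = grs_to - grs_from
    shifted = shift_probability(base, or_per_01, delta)
    return {
        "baseline_pct": baseline_pct,
        "shifted_pct": 100.0 * shifted,
        "risk_difference_pp": risk_difference(base, or_per_01, delta),
    }
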