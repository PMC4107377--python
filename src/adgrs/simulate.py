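"""Synthetic HRS-style cohorts for exercising the full analysis pipeline.

The generator emulates the statistical structure the downstream models
assume: a two-race (NHW/NHB) panel of up to three biennial waves
(2006/2008/2010), Hardy–Weinberg genotypes at the score loci with
race-specific allele frequencies calibrated so the mean probability-scale
risk score matches observed race-specific means, a dementia outcome whose
log odds is linear in the risk score (with race-specific slopes) plus age,
sex and calendar-year terms, a continuous memory score standardized by the
first-wave standard deviation, and absorbing death plus transient
nonresponse dropout.

Loci are simulated in linkage equilibrium, and mortality is independent of
genotype by default; both are simplifications relative to real cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .grs import GrsConfig, compute_grs
from .io import APOE_SNPS, CohortPanel, GenotypeMatrix, WeightTable, WAVE_YEARS

RACES = ("NHW", "NHB")

#: Starting allele frequencies for the calibration search.  The APOE
#: ε4-defining allele uses the cohort's printed race-specific frequencies;
#: the other loci start from typical population frequencies and all loci
#: are then moved together by the calibration shift.
DEFAULT_BASE_FREQS: dict[str, dict[str, float]] = {
    "rs429358": {"NHW": 0.285, "NHB": 0.415},
    "rs744373": {"NHW": 0.29, "NHB": 0.29},
    "rs11136000": {"NHW": 0.38, "NHB": 0.38},
    "rs3764650": {"NHW": 0.10, "NHB": 0.10},
    "rs3818361": {"NHW": 0.20, "NHB": 0.20},
    "rs3851179": {"NHW": 0.35, "NHB": 0.35},
    "rs610932": {"NHW": 0.42, "NHB": 0.42},
    "rs3865444": {"NHW": 0.30, "NHB": 0.30},
    "rs670139": {"NHW": 0.40, "NHB": 0.40},
    "rs9349407": {"NHW": 0.27, "NHB": 0.27},
}

#: Frequency of the ε2-defining rs7412-T allele (carries no score weight;
#: simulated so that strict APOE haplotyping is exercised end to end).
RS7412_FREQ = {"NHW": 0.075, "NHB": 0.11}

FREQ_BOUNDS = (0.01, 0.99)


def _race_dict(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {r: float(value[r]) for r in RACES}
    return {r: float(value) for r in RACES}


@dataclass
class SimulationParams:
    """Generative settings; the defaults emulate the source cohort.

    Sample composition (size, race mix, age and sex distributions), mean
    risk-score targets, and the race-specific genetic effects on dementia
    (odds ratio per 0.1 score units) and memory (SD units per 0.1) follow
    the cohort's published descriptive and model tables.  ``outcome_mode``
    selects a Bernoulli dementia outcome (``"binary"``, cleanly identified
    for parameter recovery) or a logit-normal fractional probability score
    (``"fractional"``).
    """

    n_persons: int = 10444
    prop_nhb: float = 1015 / 7690
    seed: int = 0
    # genotypes
    allele_freq: dict[str, dict[str, float]] | None = None  # [race][locus]
    target_mean_grs: dict[str, float] = field(
        default_factory=lambda: {"NHW": 0.092, "NHB": 0.122}
    )
    prevalence: float = 0.10
    # demographics (first wave)
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"NHW": 74.0, "NHB": 71.63}
    )
    age_sd: dict[str, float] = field(default_factory=lambda: {"NHW": 7.08, "NHB": 6.62})
    age_bounds: tuple[float, float] = (50.0, 95.0)
    prop_male: dict[str, float] = field(
        default_factory=lambda: {"NHW": 0.433, "NHB": 0.377}
    )
    # dementia outcome model (log odds linear in score, age, sex, year)
    or_per_01_grs: dict[str, float] = field(
        default_factory=lambda: {"NHW": 2.22, "NHB": 1.33}
    )
    baseline_dementia_prob: dict[str, float] = field(
        default_factory=lambda: {"NHW": 0.011, "NHB": 0.033}
    )
    dementia_age_log_or: float = 0.11  # per year, roughly doubling every 6 years
    dementia_male_log_or: float = -0.05
    dementia_year_log_or: float = 0.02  # per calendar year
    outcome_mode: str = "binary"
    fractional_sigma: float = 0.5
    # memory outcome model (raw scale; the panel stores the standardized score)
    beta_memory_per_01_grs: dict[str, float] = field(
        default_factory=lambda: {"NHW": -0.07, "NHB": -0.01}
    )
    race_main_effect_memory: float = -0.49
    memory_intercept: float = 1.0
    memory_age_slope: float = -0.027  # per year
    memory_male_effect: float = -0.08
    memory_year_slope: float = -0.01
    memory_noise_sd: float = 0.95
    # panel attrition (per wave-to-wave transition)
    wave_death_rate: float = 0.034
    wave_nonresponse_rate: float = 0.022

    def __post_init__(self) -> None:
        if self.n_persons < 10:
            raise ValueError("n_persons must be at least 10")
        if not 0.0 <= self.prop_nhb <= 1.0:
            raise ValueError("prop_nhb must be a proportion")
        for name in ("wave_death_rate", "wave_nonresponse_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.outcome_mode not in ("binary", "fractional"):
            raise ValueError("outcome_mode must be 'binary' or 'fractional'")
        for attr in (
            "target_mean_grs",
            "age_mean",
            "age_sd",
            "prop_male",
            "or_per_01_grs",
            "baseline_dementia_prob",
            "beta_memory_per_01_grs",
        ):
            setattr(self, attr, _race_dict(getattr(self, attr)))
        if self.allele_freq is not None:
            for race, freqs in self.allele_freq.items():
                for locus, f in freqs.items():
                    if not 0.0 < f < 1.0:
                        raise ValueError(
                            f"allele frequency for {locus} ({race}) must be in (0, 1)"
                        )


@dataclass
class SyntheticStudy:
    """A simulated cohort: genotypes, phenotype panel, and generative truth."""

    genotypes: GenotypeMatrix
    panel: CohortPanel
    truth: SimulationParams
    allele_freqs: dict[str, dict[str, float]]
    memory_scale: float  # first-wave SD the memory score was divided by


# ---------------------------------------------------------------------------
# allele-frequency calibration
# ---------------------------------------------------------------------------


def population_mean_grs(
    freqs: Mapping[str, float], weights: WeightTable, prevalence: float = 0.10
) -> float:
    """Exact mean probability-scale score under Hardy–Weinberg sampling.

    Enumerates the joint dosage distribution over the score loci (3^L
    atoms, assuming linkage equilibrium) rather than relying on Monte
    Carlo, so calibration targets are hit deterministically.
    """
    vals = np.zeros(1)
    probs = np.ones(1)
    for locus in weights.locus_ids:
        f = freqs[locus]
        beta = weights.betas[locus]
        pmf = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        vals = (vals[:, None] + beta * np.arange(3)[None, :]).ravel()
        probs = (probs[:, None] * pmf[None, :]).ravel()
    return float(np.sum(expit(vals + math.log(prevalence)) * probs))


_CALIBRATION_CACHE: dict[tuple, dict[str, float]] = {}


def calibrate_allele_freqs(
    weights: WeightTable,
    target_mean_grs: float,
    *,
    base_freqs: Mapping[str, float] | None = None,
    race: str = "NHW",
    prevalence: float = 0.10,
) -> dict[str, float]:
    """Find allele frequencies whose population mean score hits a target.

    A single shift ``δ`` is applied to every locus on the logit-frequency
    scale, signed by the direction of risk (frequencies of risk-increasing
    alleles move up together, of protective alleles down), which makes the
    population mean score strictly monotone in ``δ``; the root is then
    bracketed and solved with Brent's method.  Frequencies are confined to
    [0.01, 0.99]; a target outside the achievable range raises with the
    range reported.
    """
    if not any(w.beta > 0 for w in weights.weights):
        raise ValueError("calibration needs at least one positive-beta locus")
    if base_freqs is None:
        base_freqs = {
            l: DEFAULT_BASE_FREQS.get(l, {r: 0.30 for r in RACES})[race]
            for l in weights.locus_ids
        }
    key = (
        tuple((w.locus_id, w.beta) for w in weights.weights),
        tuple(sorted(base_freqs.items())),
        round(target_mean_grs, 12),
        round(prevalence, 12),
    )
    if key in _CALIBRATION_CACHE:
        return dict(_CALIBRATION_CACHE[key])

    lo, hi = FREQ_BOUNDS
    signs = {l: float(np.sign(weights.betas[l])) for l in weights.locus_ids}

    def shifted(delta: float) -> dict[str, float]:
        out = {}
        for l in weights.locus_ids:
            s = signs[l]
            if s == 0.0:
                out[l] = base_freqs[l]
            else:
                out[l] = float(expit(logit(base_freqs[l]) + s * delta))
        return out

    # admissible delta range keeping every shifted frequency inside bounds
    d_lo, d_hi = -np.inf, np.inf
    for l in weights.locus_ids:
        if signs[l] == 0.0:
            continue
        room_up = logit(hi) - logit(base_freqs[l])  # frequency rising
        room_dn = logit(base_freqs[l]) - logit(lo)  # frequency falling
        if signs[l] > 0:
            d_hi = min(d_hi, room_up)
            d_lo = max(d_lo, -room_dn)
        else:
            d_hi = min(d_hi, room_dn)
            d_lo = max(d_lo, -room_up)

    def objective(delta: float) -> float:
        return population_mean_grs(shifted(delta), weights, prevalence) - target_mean_grs

    f_lo, f_hi = objective(d_lo), objective(d_hi)
    if not (f_lo <= 0.0 <= f_hi):
        raise ValueError(
            f"target mean GRS {target_mean_grs} unreachable; achievable range is "
            f"[{f_lo + target_mean_grs:.4f}, {f_hi + target_mean_grs:.4f}]"
        )
    delta = brentq(objective, d_lo, d_hi, xtol=1e-12)
    result = shifted(delta)
    _CALIBRATION_CACHE[key] = dict(result)
    return result


def _resolve_freqs(
    params: SimulationParams, weights: WeightTable
) -> dict[str, dict[str, float]]:
    if params.allele_freq is not None:
        return {r: dict(params.allele_freq[r]) for r in params.allele_freq}
    return {
        race: calibrate_allele_freqs(
            weights,
            params.target_mean_grs[race],
            race=race,
            prevalence=params.prevalence,
        )
        for race in RACES
    }


# ---------------------------------------------------------------------------
# genotypes and demographics
# ---------------------------------------------------------------------------


def _draw_demographics(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_persons
    person_id = [f"P{i:06d}" for i in range(n)]
    race = np.where(rng.random(n) < params.prop_nhb, "NHB", "NHW")
    male = np.zeros(n, dtype=bool)
    age = np.zeros(n)
    for r in RACES:
        mask = race == r
        male[mask] = rng.random(mask.sum()) < params.prop_male[r]
        a, b = params.age_bounds
        mu, sd = params.age_mean[r], params.age_sd[r]
        age[mask] = truncnorm.rvs(
            (a - mu) / sd, (b - mu) / sd, loc=mu, scale=sd,
            size=mask.sum(), random_state=rng,
        )
    return pd.DataFrame(
        {"person_id": person_id, "race": race, "male": male, "age0": age}
    ).set_index("person_id")


def simulate_genotypes(
    params: SimulationParams,
    weights: WeightTable,
    demographics: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw Hardy–Weinberg dosages, binomial(2, f) per locus and person.

    rs7412 is appended (zero score weight) so that APOE haplotyping and
    VCF export can be exercised on the simulated data.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if demographics is None:
        demographics = _draw_demographics(params, rng)
    freqs = _resolve_freqs(params, weights)
    loci = list(weights.locus_ids)
    race = demographics["race"].to_numpy()
    n = len(demographics)
    dosage = np.zeros((n, len(loci)))
    for j, locus in enumerate(loci):
        p = np.array([freqs[r][locus] for r in race])
        dosage[:, j] = rng.binomial(2, p)
    df = pd.DataFrame(dosage, index=demographics.index, columns=loci)
    if "rs7412" not in df.columns:
        p = np.array([RS7412_FREQ[r] for r in race])
        df["rs7412"] = rng.binomial(2, p).astype(float)
    return GenotypeMatrix(dosages=df)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


def simulate_panel(
    params: SimulationParams,
    genotypes: GenotypeMatrix,
    weights: WeightTable,
    demographics: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[CohortPanel, float]:
    """Generate the person-wave panel given genotypes and demographics.

    Every person is observed at the first wave (the cohort includes only
    respondents who contributed at least one assessment); at later waves
    death strikes at ``wave_death_rate`` (absorbing) and nonresponse at
    ``wave_nonresponse_rate`` (transient).  Dementia probabilities exist
    only for observed person-waves aged 65+; the memory score for all
    observed person-waves, standardized by its first-wave SD.

    Returns the panel and the first-wave SD used for standardization.
    """
    grs = compute_grs(
        genotypes, weights, GrsConfig(prevalence=params.prevalence)
    )["probability"]
    n = len(demographics)
    race = demographics["race"].to_numpy()
    male = demographics["male"].to_numpy().astype(float)
    age0 = demographics["age0"].to_numpy()
    g = grs.reindex(demographics.index).to_numpy()

    slope_dem = np.array(
        [math.log(params.or_per_01_grs[r]) / 0.1 for r in race]
    )
    alpha_dem = np.array(
        [logit(params.baseline_dementia_prob[r]) for r in race]
    ) - slope_dem * 0.1
    slope_mem = np.array([params.beta_memory_per_01_grs[r] / 0.1 for r in race])
    black = (race == "NHB").astype(float)

    dead = np.zeros(n, dtype=bool)
    rows = []
    for t, year in enumerate(WAVE_YEARS):
        age = age0 + 2.0 * t
        if t > 0:
            dead |= rng.random(n) < params.wave_death_rate
            nonresp = (~dead) & (rng.random(n) < params.wave_nonresponse_rate)
        else:
            nonresp = np.zeros(n, dtype=bool)
        observed = ~(dead | nonresp)

        lp = (
            alpha_dem
            + slope_dem * g
            + params.dementia_age_log_or * (age - 70.0)
            + params.dementia_male_log_or * male
            + params.dementia_year_log_or * (year - WAVE_YEARS[0])
        )
        p_dem = expit(lp)
        if params.outcome_mode == "binary":
            dem = rng.binomial(1, p_dem).astype(float)
        else:
            noise = rng.normal(0.0, params.fractional_sigma, size=n)
            dem = expit(lp + noise)
        dem = np.where(observed & (age >= 65.0), dem, np.nan)

        mem = (
            params.memory_intercept
            + slope_mem * g
            + params.race_main_effect_memory * black
            + params.memory_age_slope * (age - 70.0)
            + params.memory_male_effect * male
            + params.memory_year_slope * (year - WAVE_YEARS[0])
            + rng.normal(0.0, params.memory_noise_sd, size=n)
        )
        mem = np.where(observed, mem, np.nan)

        status = np.where(dead, "dead", np.where(nonresp, "nonresponse", "observed"))
        rows.append(
            pd.DataFrame(
                {
                    "person_id": demographics.index,
                    "wave_year": year,
                    "race": race,
                    "sex": np.where(male == 1.0, "male", "female"),
                    "age": age,
                    "dementia_prob": dem,
                    "memory_score": mem,
                    "status": status,
                }
            )
        )
    panel = pd.concat(rows, ignore_index=True)
    first = panel["wave_year"] == WAVE_YEARS[0]
    scale = float(panel.loc[first, "memory_score"].std(ddof=1))
    panel["memory_score"] = panel["memory_score"] / scale
    return CohortPanel(data=panel), scale


def simulate_study(
    params: SimulationParams, weights: WeightTable | None = None
) -> SyntheticStudy:
    """Draw a complete synthetic study from a single seed.

    Orchestrates demographics → calibrated genotypes → phenotype panel.
    Identical ``SimulationParams`` (including ``seed``) give bit-identical
    output.
    """
    if weights is None:
        from .io import default_weight_table

        weights = default_weight_table()
    rng = np.random.default_rng(params.seed)
    demographics = _draw_demographics(params, rng)
    freqs = _resolve_freqs(params, weights)
    frozen = replace(params, allele_freq=freqs)
    genotypes = simulate_genotypes(frozen, weights, demographics, rng)
    panel, scale = simulate_panel(frozen, genotypes, weights, demographics, rng)
    return SyntheticStudy(
        genotypes=genotypes,
        panel=panel,
        truth=frozen,
        allele_freqs=freqs,
        memory_scale=scale,
    )
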