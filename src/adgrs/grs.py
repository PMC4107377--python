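"""Probability-scale genetic risk scores for dementia.

The score family is built in three steps for each person *i*:

1. a weighted allele sum ``s_i = Σ_j d_ij β_j`` over the score loci, where
   ``d_ij`` is the effect-allele dosage and ``β_j`` the per-allele log odds
   ratio from an external meta-analysis;
2. odds ``q_i = π · exp(s_i)``, anchoring the score at an assumed disease
   prevalence ``π`` (0.10 for dementia in the source cohort);
3. probability ``p_i = q_i / (1 + q_i)``.

``p_i`` is interpretable as the probability of dementia predicted by the
score loci alone.  Dropping the APOE loci from the sum yields the
APOE-excluded variant of the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, WeightTable


@dataclass(frozen=True)
class GrsConfig:
    """Configuration of the odds→probability transform and locus exclusions.

    Parameters
    ----------
    prevalence
        Assumed disease prevalence anchoring the odds scale, in (0, 1).
    excluded_locus_ids
        Loci removed from the weighted sum before scoring (e.g. the APOE
        SNPs for the APOE-excluded score variant).
    missing_policy
        ``"mean"`` imputes a missing dosage with the locus mean over
        non-missing persons (keeps panels balanced); ``"drop"`` scores the
        person as indeterminate if any included locus is missing.
    """

    prevalence: float = 0.10
    excluded_locus_ids: frozenset[str] = field(default_factory=frozenset)
    missing_policy: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.missing_policy not in ("mean", "drop"):
            raise ValueError("missing_policy must be 'mean' or 'drop'")


def weighted_allele_sum(
    genotypes: GenotypeMatrix, weights: WeightTable, config: GrsConfig = GrsConfig()
) -> pd.DataFrame:
    """Per-person ``Σ_j d_ij β_j`` over the included score loci.

    Returns a frame indexed by person with columns ``weighted_sum`` and
    ``n_loci_used`` (count of loci contributing a non-imputed dosage).
    Persons missing every included locus get a NaN sum.
    """
    excluded = set(config.excluded_locus_ids)
    unknown = excluded - set(weights.locus_ids)
    if unknown:
        raise KeyError(f"excluded loci not in weight table: {sorted(unknown)}")
    loci = [l for l in weights.locus_ids if l not in excluded]
    betas = weights.betas.loc[loci]
    dos = genotypes.dosages.reindex(columns=loci).astype(float)

    observed = dos.notna()
    n_used = observed.sum(axis=1).astype(int)
    if config.missing_policy == "mean":
        filled = dos.fillna(dos.mean(axis=0, skipna=True))
    else:
        filled = dos.where(observed.all(axis=1), np.nan)
    sums = filled @ betas
    # a person (or a whole locus) with no data at all stays indeterminate
    sums[n_used == 0] = np.nan
    return pd.DataFrame({"weighted_sum": sums, "n_loci_used": n_used})


def grs_probability(weighted_sum, prevalence: float = 0.10):
    """Odds→probability transform ``π·e^s / (1 + π·e^s)``, vectorised.

    Evaluated on the log scale (``expit(s + ln π)``) so it is stable for
    sums far out in either tail.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    s = np.asarray(weighted_sum, dtype=float)
    if np.isinf(s).any():
        raise ValueError("weighted sum must be finite")
    from scipy.special import expit

    # odds = π·e^s, so p = expit(s + ln π)
    out = expit(s + math.log(prevalence))
    if np.ndim(weighted_sum) == 0:
        return float(out)
    return out


def invert_grs_probability(probability, prevalence: float = 0.10):
    """Recover the weighted sum from a probability-scale score."""
    p = np.asarray(probability, dtype=float)
    s = np.log(p / (1.0 - p)) - math.log(prevalence)
    if np.ndim(probability) == 0:
        return float(s)
    return s


def compute_grs(
    genotypes: GenotypeMatrix, weights: WeightTable, config: GrsConfig = GrsConfig()
) -> pd.DataFrame:
    """Score every person: weighted sum, odds, probability-scale score.

    With ``config.excluded_locus_ids`` set to the APOE SNPs this computes
    the APOE-excluded score variant.
    """
    out = weighted_allele_sum(genotypes, weights, config)
    out["odds"] = config.prevalence * np.exp(out["weighted_sum"])
    out["probability"] = grs_probability(
        out["weighted_sum"].to_numpy(), config.prevalence
    )
    out.index.name = "person_id"
    return out[["weighted_sum", "odds", "probability", "n_loci_used"]]


@dataclass(frozen=True)
class ApoeStatus:
    """APOE ε4 carrier call; ``None`` fields mean indeterminate."""

    e4_allele_count: int | None
    e4_carrier: bool | None


def apoe_e4_status(
    rs429358_dosage: float, rs7412_dosage: float | None = None, *, strict: bool = False
) -> ApoeStatus:
    """Call ε4 carriage from unphased dosages of the two APOE SNPs.

    The ε4 haplotype carries the rs429358-C allele, ε2 the rs7412-T allele.
    The ε4 count therefore equals the rs429358-C dosage — except that the
    unphased double heterozygote (one C at rs429358, one T at rs7412) is
    consistent with both ε2/ε4 and ε1/ε3 haplotype pairs.  Under
    ``strict=True`` that genotype is returned indeterminate; by default it
    is resolved as ε2/ε4, the overwhelmingly more common configuration.
    """
    if rs429358_dosage is None or (
        isinstance(rs429358_dosage, float) and math.isnan(rs429358_dosage)
    ):
        return ApoeStatus(None, None)
    d = int(rs429358_dosage)
    if d not in (0, 1, 2):
        raise ValueError("rs429358 dosage must be 0, 1 or 2")
    if strict and d == 1:
        if rs7412_dosage is None or (
            isinstance(rs7412_dosage, float) and math.isnan(rs7412_dosage)
        ):
            return ApoeStatus(None, None)
        if int(rs7412_dosage) == 1:
            return ApoeStatus(None, None)
    return ApoeStatus(e4_allele_count=d, e4_carrier=d >= 1)


def quintile_bins(values) -> np.ndarray:
    """Assign sample-quintile bins 1..5; tied values share the lower bin.

    Requires at least five values with some variation; an all-equal input
    is degenerate (no cut-points exist) and raises.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 5:
        raise ValueError("need at least 5 values to form quintiles")
    if np.isnan(v).any():
        raise ValueError("quintile input contains missing values")
    if np.all(v == v[0]):
        raise ValueError("all values equal: quintiles undefined")
    order = np.argsort(v, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = np.arange(n) * 5 // n + 1
    # ties share the lower bin
    low = pd.Series(bins).groupby(pd.Series(v)).transform("min").to_numpy()
    return low
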