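"""Auditable sample-exclusion cascades (CONSORT-style accounting).

A cascade applies an ordered list of exclusion rules to a panel of
person-wave observations.  Rules are disjoint by construction: an
observation is counted against the first rule it fails.  Each stage
reports how many observations it removed, the percentage of the cascade's
starting total (recomputed from integers, one decimal), and how many
remain; the final survivors define the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .io import CohortPanel


@dataclass(frozen=True)
class ExclusionRule:
    """One exclusion step.

    ``query`` is a pandas query expression selecting the observations to
    REMOVE (e.g. ``"age < 65"`` or ``"status == 'dead'"``); alternatively
    ``predicate`` is a callable mapping the frame to a boolean removal
    mask.  ``scope='person'`` removes every observation of any person with
    at least one flagged row.
    """

    name: str
    query: str | None = None
    predicate: Callable[[pd.DataFrame], pd.Series] | None = None
    scope: str = "obs"

    def __post_init__(self) -> None:
        if (self.query is None) == (self.predicate is None):
            raise ValueError("give exactly one of query or predicate")
        if self.scope not in ("obs", "person"):
            raise ValueError("scope must be 'obs' or 'person'")

    def mask(self, df: pd.DataFrame) -> pd.Series:
        if self.query is not None:
            try:
                removed = df.eval(self.query)
            except pd.errors.UndefinedVariableError as exc:
                raise KeyError(f"rule {self.name!r}: {exc}") from exc
        else:
            removed = self.predicate(df)
        removed = pd.Series(removed, index=df.index).fillna(False).astype(bool)
        if self.scope == "person":
            flagged = df.loc[removed, "person_id"].unique()
            removed = df["person_id"].isin(flagged)
        return removed


@dataclass(frozen=True)
class ExclusionStage:
    """Accounting for one cascade stage; percentages recompute from counts."""

    stage_name: str
    n_removed: int
    n_remaining: int
    denominator: int

    @property
    def pct_removed(self) -> float:
        return round(100.0 * self.n_removed / self.denominator, 1)


def cascade_counts(
    n_initial: int, removals: Sequence[tuple[str, int]]
) -> list[ExclusionStage]:
    """Build a cascade report from printed stage counts (exact integers)."""
    if n_initial < 0 or any(n < 0 for _, n in removals):
        raise ValueError("counts must be non-negative integers")
    stages = []
    remaining = int(n_initial)
    for name, n in removals:
        n = int(n)
        if n > remaining:
            raise ValueError(f"stage {name!r} removes {n} from only {remaining}")
        remaining -= n
        stages.append(
            ExclusionStage(
                stage_name=name,
                n_removed=n,
                n_remaining=remaining,
                denominator=int(n_initial),
            )
        )
    return stages


def run_exclusion_cascade(
    panel: CohortPanel | pd.DataFrame, rules: Sequence[ExclusionRule]
) -> tuple[list[ExclusionStage], pd.DataFrame]:
    """Apply rules sequentially and account for every removed observation.

    Returns the per-stage report plus the surviving analysis set.  The sum
    of stage removals and final survivors equals the starting count
    exactly.
    """
    df = panel.data if isinstance(panel, CohortPanel) else panel
    df = df.reset_index(drop=True)
    n_initial = len(df)
    stages = []
    for rule in rules:
        removed = rule.mask(df)
        n_removed = int(removed.sum())
        df = df.loc[~removed]
        stages.append(
            ExclusionStage(
                stage_name=rule.name,
                n_removed=n_removed,
                n_remaining=len(df),
                denominator=n_initial,
            )
        )
    return stages, df


def retention_pct(n_kept: int, n_initial: int) -> float:
    """Share of the source sample retained, printed to one decimal."""
    if n_initial <= 0:
        raise ValueError("initial count must be positive")
    return round(100.0 * n_kept / n_initial, 1)


def report_frame(stages: Sequence[ExclusionStage]) -> pd.DataFrame:
    """Stage report as a stable-column CSV-ready frame."""
    return pd.DataFrame(
        {
            "stage": [s.stage_name for s in stages],
            "n_removed": [s.n_removed for s in stages],
            "pct_removed": [s.pct_removed for s in stages],
            "n_remaining": [s.n_remaining for s in stages],
        }
    )


#: The standard dementia-sample cascade: under-65 observations, outcome
#: nonresponse, then death by the interview wave.
DEMENTIA_SAMPLE_RULES = (
    ExclusionRule(name="under_65", query="age < 65"),
    ExclusionRule(name="nonresponse", query="status == 'nonresponse'"),
    ExclusionRule(name="died", query="status == 'dead'"),
)
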