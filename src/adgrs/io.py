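"""Readers, writers and validation for weights, genotypes and phenotype panels.

Three exchange formats are supported:

* **weight table** — delimited text with one row per risk locus giving the
  effect allele and the per-allele log odds ratio (or the odds ratio itself,
  from which the log is taken);
* **genotypes** — either a VCF with GT calls or a "dosage TSV" (persons as
  rows, rsID header, values 0/1/2 with ``NA`` for missing, already counted
  with respect to the effect allele);
* **phenotype panel** — long-format delimited text, one row per person-wave.

VCF genotypes are harmonised to each locus's effect allele: the effect
allele is matched against REF, ALT, or their reverse complements (a strand
flip).  Palindromic A/T and C/G sites are strand-ambiguous and are excluded
by default, the conservative convention in polygenic-score pipelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Calendar years of the assessment waves the panel schema expects.
WAVE_YEARS = (2006, 2008, 2010)

#: SNPs jointly defining the APOE epsilon haplotypes.  rs429358-C defines
#: the risk (ε4) arm, rs7412-T the protective (ε2) arm.
APOE_SNPS = ("rs429358", "rs7412")

PANEL_COLUMNS = [
    "person_id",
    "wave_year",
    "race",
    "sex",
    "age",
    "dementia_prob",
    "memory_score",
    "status",
]


class FormatError(ValueError):
    """Raised when an input file violates the schema it claims to follow."""


# ---------------------------------------------------------------------------
# weight tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskWeight:
    """One risk locus: effect allele and per-allele natural-log odds ratio."""

    locus_id: str
    effect_allele: str
    beta: float
    source_or: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise FormatError(
                f"{self.locus_id}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if not math.isfinite(self.beta):
            raise FormatError(f"{self.locus_id}: beta must be finite")
        if self.source_or is not None:
            if self.source_or <= 0:
                raise FormatError(f"{self.locus_id}: odds ratio must be positive")
            if abs(self.beta - math.log(self.source_or)) > 1e-9:
                raise FormatError(
                    f"{self.locus_id}: beta={self.beta} inconsistent with ln(OR)="
                    f"{math.log(self.source_or)}"
                )


@dataclass(frozen=True)
class WeightTable:
    """Ordered collection of risk-locus weights, with APOE loci flagged."""

    weights: tuple[RiskWeight, ...]
    apoe_locus_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = [w.locus_id for w in self.weights]
        dupes = {x for x in ids if ids.count(x) > 1}
        if dupes:
            raise FormatError(f"duplicate locus ids in weight table: {sorted(dupes)}")
        extra = self.apoe_locus_ids - set(ids)
        if extra:
            raise FormatError(f"apoe_locus_ids not present in table: {sorted(extra)}")

    @property
    def locus_ids(self) -> list[str]:
        return [w.locus_id for w in self.weights]

    @property
    def betas(self) -> pd.Series:
        return pd.Series(
            {w.locus_id: w.beta for w in self.weights}, name="beta", dtype=float
        )

    @property
    def effect_alleles(self) -> dict[str, str]:
        return {w.locus_id: w.effect_allele for w in self.weights}

    def drop(self, locus_ids: Iterable[str]) -> "WeightTable":
        """Return a table without the given loci (for e.g. the no-APOE score)."""
        drop = set(locus_ids)
        unknown = drop - set(self.locus_ids)
        if unknown:
            raise KeyError(f"cannot drop unknown loci: {sorted(unknown)}")
        return WeightTable(
            weights=tuple(w for w in self.weights if w.locus_id not in drop),
            apoe_locus_ids=self.apoe_locus_ids - drop,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "effect_allele": [w.effect_allele for w in self.weights],
                "beta": [w.beta for w in self.weights],
                "source_or": [w.source_or for w in self.weights],
                "is_apoe": [w.locus_id in self.apoe_locus_ids for w in self.weights],
            }
        )


def _pick_column(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    lower = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    return None


def read_weight_table(path: str | Path) -> WeightTable:
    """Read a delimited weight table.

    The header must name a locus column, an effect-allele column, and at
    least one of a ``beta`` (log odds ratio) or ``or`` (odds ratio) column.
    When only the odds ratio is given, ``beta = ln(OR)``.  An optional
    boolean ``is_apoe`` column flags the APOE loci; absent that, loci named
    rs429358 / rs7412 are flagged automatically.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    locus_col = _pick_column(df.columns, ["locus_id", "locus", "rsid", "snp", "marker"])
    allele_col = _pick_column(
        df.columns, ["effect_allele", "allele", "risk_allele", "ea", "a1"]
    )
    beta_col = _pick_column(df.columns, ["beta", "log_or", "lnor", "b"])
    or_col = _pick_column(df.columns, ["source_or", "or", "odds_ratio"])
    apoe_col = _pick_column(df.columns, ["is_apoe", "apoe"])
    if locus_col is None or allele_col is None:
        raise FormatError(
            f"weight table must name locus and effect-allele columns; got {list(df.columns)}"
        )
    if beta_col is None and or_col is None:
        raise FormatError("weight table must provide a beta or an OR column")

    weights = []
    apoe_ids = set()
    for _, row in df.iterrows():
        locus = str(row[locus_col]).strip()
        allele = str(row[allele_col]).strip().upper()
        source_or = None
        if or_col is not None and pd.notna(row[or_col]):
            source_or = float(row[or_col])
        if beta_col is not None and pd.notna(row[beta_col]):
            beta = float(row[beta_col])
        elif source_or is not None:
            beta = math.log(source_or)
        else:
            raise FormatError(f"{locus}: neither beta nor OR given")
        weights.append(RiskWeight(locus, allele, beta, source_or))
        if apoe_col is not None:
            if bool(row[apoe_col]):
                apoe_ids.add(locus)
        elif locus in APOE_SNPS:
            apoe_ids.add(locus)
    return WeightTable(weights=tuple(weights), apoe_locus_ids=frozenset(apoe_ids))


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def default_weight_table() -> WeightTable:
    """The 10-locus table shipped with the package.

    Effect sizes approximate the AlzGene meta-analysis rankings circa
    January 2013 (APOE plus the nine loci BIN1, CLU, ABCA7, CR1, PICALM,
    MS4A6A, CD33, MS4A4E, CD2AP).  They are stand-in values for testing and
    simulation; replace the file with your own weights for real analyses.
    """
    ref = resources.files("adgrs").joinpath("data/alzgene_weights_2013.tsv")
    with resources.as_file(ref) as p:
        return read_weight_table(p)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages: persons in rows, loci in columns, NaN = missing."""

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise FormatError(f"dosages must be 0/1/2 or missing; found {bad}")

    @property
    def person_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.dosages.columns)


@dataclass
class HarmonizationReport:
    """Per-locus record of how the file's alleles mapped onto effect alleles.

    ``action`` is one of ``match_alt``/``match_ref`` (direct match),
    ``flip_alt``/``flip_ref`` (reverse-complement strand flip),
    ``palindromic_excluded``, ``unresolvable`` or ``absent``.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["locus_id", "effect_allele", "ref", "alt", "action"]
        )
    )

    def add(self, locus: str, effect: str, ref: str | None, alt: str | None, action: str):
        self.records.loc[len(self.records)] = [locus, effect, ref, alt, action]

    @property
    def unresolved(self) -> list[str]:
        mask = self.records["action"].isin(
            ["unresolvable", "palindromic_excluded", "absent"]
        )
        return list(self.records.loc[mask, "locus_id"])


def _is_palindromic(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "T"}, {"C", "G"})


def classify_alleles(
    effect: str, ref: str, alt: str, *, allow_palindromic: bool = False
) -> str:
    """Decide how to count the effect allele at a biallelic REF/ALT site."""
    if _is_palindromic(ref, alt) and not allow_palindromic:
        return "palindromic_excluded"
    if effect == alt:
        return "match_alt"
    if effect == ref:
        return "match_ref"
    if COMPLEMENT[effect] == alt:
        return "flip_alt"
    if COMPLEMENT[effect] == ref:
        return "flip_ref"
    return "unresolvable"


def read_genotypes(
    path: str | Path,
    table: WeightTable,
    dialect: str = "vcf",
    *,
    extra_loci: Mapping[str, str] | None = None,
    allow_palindromic: bool = False,
) -> tuple[GenotypeMatrix, HarmonizationReport]:
    """Read genotypes and express them as effect-allele dosages.

    ``extra_loci`` maps additional rsIDs to the allele to count (used for
    rs7412 when it carries no score weight but is needed for APOE ε4
    haplotyping).  Loci absent from the file come back all-missing.
    """
    wanted = dict(table.effect_alleles)
    if extra_loci:
        for locus, allele in extra_loci.items():
            wanted.setdefault(locus, allele.upper())
    if dialect == "vcf":
        return _read_vcf(path, wanted, allow_palindromic=allow_palindromic)
    if dialect == "dosage_tsv":
        return _read_dosage_tsv(path, wanted)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_vcf(
    path: str | Path, wanted: dict[str, str], *, allow_palindromic: bool
) -> tuple[GenotypeMatrix, HarmonizationReport]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data = pd.DataFrame(np.nan, index=samples, columns=list(wanted), dtype=float)
    report = HarmonizationReport()
    seen: set[str] = set()
    for variant in vcf:
        locus = variant.ID
        if locus not in wanted or locus in seen:
            continue
        seen.add(locus)
        effect = wanted[locus]
        ref, alts = variant.REF.upper(), [a.upper() for a in variant.ALT]
        if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1:
            report.add(locus, effect, ref, ",".join(alts), "unresolvable")
            continue
        alt = alts[0]
        action = classify_alleles(effect, ref, alt, allow_palindromic=allow_palindromic)
        report.add(locus, effect, ref, alt, action)
        if action in ("palindromic_excluded", "unresolvable"):
            if action == "palindromic_excluded":
                logger.warning("excluding palindromic site %s (%s/%s)", locus, ref, alt)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        alt_count = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        if action in ("match_alt", "flip_alt"):
            data[locus] = alt_count
        else:  # the effect allele sits on the REF side
            data[locus] = 2.0 - alt_count
    for locus in wanted:
        if locus not in seen:
            report.add(locus, wanted[locus], None, None, "absent")
    return GenotypeMatrix(dosages=data), report


def _read_dosage_tsv(
    path: str | Path, wanted: dict[str, str]
) -> tuple[GenotypeMatrix, HarmonizationReport]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    report = HarmonizationReport()
    data = pd.DataFrame(np.nan, index=df.index, columns=list(wanted), dtype=float)
    for locus in wanted:
        if locus in df.columns:
            data[locus] = df[locus].astype(float)
            report.add(locus, wanted[locus], None, None, "match_alt")
        else:
            report.add(locus, wanted[locus], None, None, "absent")
    return GenotypeMatrix(dosages=data), report


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    out = genotypes.dosages.copy()
    out.index.name = "person_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def write_vcf(
    genotypes: GenotypeMatrix,
    alleles: Mapping[str, tuple[str, str]],
    path: str | Path,
) -> None:
    """Write hard-call genotypes as a minimal single-chromosome VCF.

    ``alleles`` maps locus id to (REF, ALT); dosages are counts of ALT.
    Positions are synthetic (loci are identified by ID, not coordinate).
    """
    samples = genotypes.person_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for pos, locus in enumerate(genotypes.locus_ids, start=1):
            ref, alt = alleles[locus]
            calls = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[locus].to_numpy(dtype=float)
            ]
            fh.write(
                f"1\t{pos}\t{locus}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# phenotype panel
# ---------------------------------------------------------------------------


@dataclass
class CohortPanel:
    """Long-format person-wave records with demographics and outcomes.

    One row per person per wave; ``dementia_prob`` is only defined for
    respondents aged 65 or older; death is absorbing across waves.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = validate_panel(self.data)

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)


def validate_panel(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"panel is missing columns: {sorted(missing)}")
    df = df[PANEL_COLUMNS].copy()
    df["person_id"] = df["person_id"].astype(str)
    df["wave_year"] = df["wave_year"].astype(int)
    for col in ("age", "dementia_prob", "memory_score"):
        df[col] = df[col].astype(float)

    if df.duplicated(["person_id", "wave_year"]).any():
        dupes = df.loc[df.duplicated(["person_id", "wave_year"]), "person_id"].unique()
        raise FormatError(f"duplicate person-wave rows for persons {list(dupes)[:5]}")
    bad_years = set(df["wave_year"]) - set(WAVE_YEARS)
    if bad_years:
        raise FormatError(f"wave_year outside {WAVE_YEARS}: {sorted(bad_years)}")
    if (df["age"] < 50).any():
        raise FormatError("panel contains ages below 50")
    bad_race = set(df["race"]) - {"NHW", "NHB"}
    if bad_race:
        raise FormatError(f"unknown race codes: {sorted(bad_race)}")
    bad_sex = set(df["sex"]) - {"male", "female"}
    if bad_sex:
        raise FormatError(f"unknown sex codes: {sorted(bad_sex)}")
    bad_status = set(df["status"]) - {"observed", "nonresponse", "dead"}
    if bad_status:
        raise FormatError(f"unknown status codes: {sorted(bad_status)}")

    dp = df["dementia_prob"]
    if ((dp < 0) | (dp > 1)).any():
        raise FormatError("dementia_prob outside [0, 1]")

    # death is absorbing: once dead, all later waves must also be dead
    df = df.sort_values(["person_id", "wave_year"], kind="stable").reset_index(drop=True)
    dead = df["status"].eq("dead")
    ever_dead = dead.groupby(df["person_id"]).cummax()
    if (ever_dead & ~dead).any():
        raise FormatError("death must be absorbing across waves")
    return df


def read_panel(path: str | Path) -> CohortPanel:
    """Read a long-format panel, rejecting under-65 dementia scores.

    Rows carrying a dementia probability for a respondent younger than 65
    violate the outcome's definition; they are dropped with a logged count
    rather than failing the whole file.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    violation = df["dementia_prob"].notna() & (df["age"] < 65)
    if violation.any():
        logger.warning(
            "rejected %d rows with dementia_prob recorded before age 65",
            int(violation.sum()),
        )
        df = df.loc[~violation]
    return CohortPanel(data=df)


def write_panel(panel: CohortPanel, path: str | Path) -> None:
    panel.data.to_csv(path, index=False, float_format="%.17g")
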