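"""WHO/CDC bioassay record filtering and resistance classification.

Mortality at a diagnostic dose is banded into susceptible / possible
resistance / resistant following standard WHO and CDC interpretation:
WHO tube or bottle assays call >=98% mortality susceptible, 90-<98%
possible resistance, <90% resistant; CDC bottle assays use a 97%
susceptibility cut-off.  Thresholds are configuration, not constants,
since guideline editions differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BioassayRecord",
    "AssayThresholds",
    "DEFAULT_THRESHOLDS",
    "filter_records",
    "classify_mortality",
    "classify_and_summarize",
]

ALLOWED_ASSAYS = ("WHO_tube", "WHO_bottle", "CDC_bottle")
INSECTICIDE_CLASSES = ("pyrethroid", "organophosphate", "organochlorine", "carbamate")
CATEGORIES = ("susceptible", "possible", "resistant")


@dataclass(frozen=True)
class BioassayRecord:
    country: str
    insecticide: str
    insecticide_class: str
    assay: str
    mortality: float
    year: int
    species: str = "Aedes aegypti"
    method_note: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.mortality <= 100):
            raise ValueError(f"mortality {self.mortality} outside 0-100")


@dataclass(frozen=True)
class AssayThresholds:
    """(susceptible_min, possible_min): mortality >= susceptible_min is
    susceptible, >= possible_min possible resistance, below resistant."""

    susceptible_min: float
    possible_min: float = 90.0


DEFAULT_THRESHOLDS: dict[str, AssayThresholds] = {
    "WHO_tube": AssayThresholds(98.0),
    "WHO_bottle": AssayThresholds(98.0),
    "CDC_bottle": AssayThresholds(97.0),
}


def read_bioassay_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"country", "insecticide", "insecticide_class", "assay", "mortality", "year", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bioassay CSV missing columns: {sorted(missing)}")
    return df


def filter_records(
    df: pd.DataFrame,
    species: str = "Aedes aegypti",
    min_year_exclusive: int = 2000,
    allowed_assays: tuple[str, ...] = ALLOWED_ASSAYS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain post-2000 target-species records from accepted bioassays.

    PCR/RT-PCR-only determinations (marked in ``method_note``) are
    excluded — they genotype rather than phenotype.  Returns the
    filtered frame plus exclusion counts by reason.
    """
    df = df.copy()
    reasons: dict[str, int] = {}
    mort = pd.to_numeric(df["mortality"], errors="coerce")
    bad_mort = mort.isna() | (mort < 0) | (mort > 100)
    reasons["unparseable_mortality"] = int(bad_mort.sum())
    df, mort = df[~bad_mort], mort[~bad_mort]
    df["mortality"] = mort

    wrong_species = df["species"].str.strip().str.lower() != species.lower()
    reasons["wrong_species"] = int(wrong_species.sum())
    df = df[~wrong_species]

    too_old = pd.to_numeric(df["year"], errors="coerce").fillna(0) <= min_year_exclusive
    reasons["year_at_or_before_cutoff"] = int(too_old.sum())
    df = df[~too_old]

    bad_assay = ~df["assay"].isin(allowed_assays)
    reasons["disallowed_assay"] = int(bad_assay.sum())
    df = df[~bad_assay]

    if "method_note" in df.columns:
        pcr = df["method_note"].fillna("").str.contains("PCR", case=False)
        reasons["pcr_only"] = int(pcr.sum())
        df = df[~pcr]
    for reason, n in reasons.items():
        if n:
            logger.info("bioassay filter: excluded %d records (%s)", n, reason)
    return df.reset_index(drop=True), reasons


def classify_mortality(
    mortality: float,
    assay: str,
    thresholds: dict[str, AssayThresholds] = DEFAULT_THRESHOLDS,
) -> str:
    th = thresholds.get(assay)
    if th is None:
        raise KeyError(f"unknown assay type {assay!r}")
    if mortality >= th.susceptible_min:
        return "susceptible"
    if mortality >= th.possible_min:
        return "possible"
    return "resistant"


def classify_and_summarize(
    df: pd.DataFrame,
    thresholds: dict[str, AssayThresholds] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per (country, insecticide class) counts and proportions by category.

    Records with unrecognised assay types are skipped with a warning.
    Proportions in each cell sum to 1.
    """
    known = df["assay"].isin(thresholds)
    if (~known).any():
        logger.warning("skipping %d records with unknown assay types", int((~known).sum()))
        df = df[known]
    if df.empty:
        return pd.DataFrame(
            columns=["country", "insecticide_class", "n",
                     "n_susceptible", "n_possible", "n_resistant",
                     "pct_susceptible", "pct_possible", "pct_resistant"]
        )
    df = df.copy()
    df["category"] = [
        classify_mortality(m, a, thresholds) for m, a in zip(df["mortality"], df["assay"])
    ]
    rows = []
    for (country, iclass), grp in df.groupby(["country", "insecticide_class"], sort=True):
        n = len(grp)
        counts = grp["category"].value_counts()
        row = {"country": country, "insecticide_class": iclass, "n": n}
        for cat in CATEGORIES:
            row[f"n_{cat}"] = int(counts.get(cat, 0))
            row[f"pct_{cat}"] = 100.0 * counts.get(cat, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)
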