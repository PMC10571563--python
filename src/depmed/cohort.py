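"""Participant-level cohort tables: reading, validation, encoding, descriptives.

The cohort is one row per participant: survival outcome (days from diagnosis
to death or last contact, vital status), mediators (3-level SEER/FIGO stage,
binary debulking status), census-tract deprivation-index exposures, candidate
modifiers (age, BMI, income category, smoking, physical-activity guideline
adherence) and the census-tract identifier that groups the contextual random
effect.
"""

from __future__ import annotations

import decimal
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EXPOSURE_NAMES = ("URB", "MOB", "SES", "MICA", "ADI", "YOST", "POV", "CDI")

STAGE_LEVELS = ("localized", "regional", "distant")
DEBULK_LEVELS = ("optimal", "suboptimal")
SMOKING_LEVELS = ("never", "ever")
PAGA_LEVELS = ("yes", "no")
INCOME_LEVELS = ("<10k", "10-25k", "25-50k", "50-75k", "75-100k", ">100k")

#: modifiers eligible for Gibbs variable selection, with their kind
MODIFIERS = {
    "age_dx": "continuous",
    "bmi": "continuous",
    "income_cat": "categorical",
    "smoking": "categorical",
    "paga": "categorical",
}

#: reference level per categorical modifier (omitted from the design matrix)
MODIFIER_REFERENCE = {
    "income_cat": "<10k",
    "smoking": "never",
    "paga": "yes",
}

_MODIFIER_LEVELS = {
    "income_cat": INCOME_LEVELS,
    "smoking": SMOKING_LEVELS,
    "paga": PAGA_LEVELS,
}

MANDATORY_COLUMNS = ("participant_id", "time_days", "event", "stage", "tract_id")


class SchemaError(ValueError):
    """A mandatory column is absent or the schema map is malformed."""


class CohortValidationError(ValueError):
    """One or more rows violate cohort invariants; message names the rows."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("cohort validation failed:\n" + "\n".join(problems))


@dataclass
class ExposureSpec:
    """Which deprivation index is the exposure and how it is scaled.

    ``direction`` records whether large values mean more deprivation
    (POV, CDI, MICA, ADI) or higher area-level SES (YOST, URB, MOB, SES);
    it only annotates reports, it never flips the data.
    """

    name: str
    direction: str = "high_is_deprivation"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("high_is_deprivation", "high_is_ses"):
            raise ValueError(f"unknown direction {self.direction!r}")


#: conventional direction of each index
EXPOSURE_DIRECTIONS = {
    "URB": "high_is_ses",
    "MOB": "high_is_ses",
    "SES": "high_is_ses",
    "YOST": "high_is_ses",
    "MICA": "high_is_deprivation",
    "ADI": "high_is_deprivation",
    "POV": "high_is_deprivation",
    "CDI": "high_is_deprivation",
}


def exposure_spec(name: str, standardize: bool = True) -> ExposureSpec:
    """ExposureSpec with the conventional direction for a known index."""
    return ExposureSpec(
        name=name,
        direction=EXPOSURE_DIRECTIONS.get(name, "high_is_deprivation"),
        standardize=standardize,
    )


@dataclass
class CohortTable:
    """A validated participant-level table.

    Wraps a DataFrame with canonical column names; construction through
    :func:`validate_cohort` guarantees the invariants (positive follow-up,
    binary events, known category labels, non-empty tract ids).
    """

    df: pd.DataFrame
    exposures: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.df)


def _check_categories(series: pd.Series, levels: tuple[str, ...], colname: str,
                      problems: list[str]) -> None:
    bad = series.dropna()[~series.dropna().isin(levels)]
    for idx in bad.index:
        problems.append(f"row {idx}: {colname}={series[idx]!r} not in {levels}")


def validate_cohort(df: pd.DataFrame) -> CohortTable:
    """Validate a canonical-column DataFrame into a CohortTable.

    Raises :class:`SchemaError` for missing mandatory columns and
    :class:`CohortValidationError` with row-indexed diagnostics otherwise.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    df = df.copy()
    problems: list[str] = []

    time = pd.to_numeric(df["time_days"], errors="coerce")
    for idx in df.index[time.isna() | (time <= 0)]:
        problems.append(f"row {idx}: time_days={df.loc[idx, 'time_days']!r} must be a positive number")
    df["time_days"] = time

    event = pd.to_numeric(df["event"], errors="coerce")
    for idx in df.index[~event.isin([0, 1])]:
        problems.append(f"row {idx}: event={df.loc[idx, 'event']!r} must be 0 or 1")
    df["event"] = event

    tract = df["tract_id"].astype(str)
    for idx in df.index[(tract.str.len() == 0) | df["tract_id"].isna()]:
        problems.append(f"row {idx}: tract_id must be non-empty")

    _check_categories(df["stage"], STAGE_LEVELS, "stage", problems)
    for col, levels in (("debulk", DEBULK_LEVELS), ("smoking", SMOKING_LEVELS),
                        ("paga", PAGA_LEVELS), ("income_cat", INCOME_LEVELS)):
        if col in df.columns:
            _check_categories(df[col], levels, col, problems)

    exposures = tuple(c for c in EXPOSURE_NAMES if c in df.columns)
    for name in exposures:
        vals = pd.to_numeric(df[name], errors="coerce")
        nonfinite = df.index[df[name].notna() & ~np.isfinite(vals)]
        for idx in nonfinite:
            problems.append(f"row {idx}: exposure {name}={df.loc[idx, name]!r} is not finite")
        df[name] = vals

    if problems:
        raise CohortValidationError(problems)
    df["event"] = df["event"].astype(int)
    return CohortTable(df=df, exposures=exposures)


def read_cohort(path, schema=None) -> CohortTable:
    """Read a delimited cohort file (CSV/TSV by extension) and validate it.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.
    schema : dict or str or Path, optional
        Map from file column names to canonical CohortTable field names,
        given directly or as a YAML/JSON file path.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "tract_id": str})
    if schema is not None:
        if not isinstance(schema, dict):
            with open(schema) as fh:
                schema = yaml.safe_load(fh)
        if not isinstance(schema, dict):
            raise SchemaError("schema must be a mapping of file columns to cohort fields")
        df = df.rename(columns=schema)
    return validate_cohort(df)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort back to delimited text in the same dialect read_cohort reads."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cohort.df.to_csv(path, sep=sep, index=False)


def standardize_exposure(cohort: CohortTable, spec: ExposureSpec) -> np.ndarray:
    """Return the exposure column as a float vector, z-scored if requested.

    Standardization uses the mean and SD over non-missing entries (ddof=1);
    missing entries stay NaN. Hazard ratios downstream are then per one SD
    of the index.
    """
    if spec.name not in cohort.df.columns:
        raise SchemaError(f"exposure column {spec.name!r} not in cohort")
    x = cohort.df[spec.name].to_numpy(dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError(f"exposure {spec.name!r} needs >=2 non-missing values")
    if not spec.standardize:
        return x
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError(f"exposure {spec.name!r} has zero variance")
    return (x - obs.mean()) / sd


def _pct(count: int, denom: int) -> float:
    """Percent of non-missing denominator, round-half-up to one decimal."""
    if denom == 0:
        return float("nan")
    frac = decimal.Decimal(count) / decimal.Decimal(denom) * 100
    return float(frac.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


_CATEGORICAL_SUMMARY = {
    "event": {0: "alive", 1: "deceased"},
    "stage": None,
    "debulk": None,
    "income_cat": None,
    "smoking": None,
    "paga": None,
    "site": None,
}

_CONTINUOUS_SUMMARY = ("time_days", "age_dx", "bmi") + tuple(EXPOSURE_NAMES)


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Descriptive table: n / percent per categorical level, mean (SD) per continuous.

    Percentages use the non-missing denominator and one round-half-up decimal,
    so they reproduce published descriptive tables exactly from the raw counts.
    Missing entries are reported as an ``NA`` row with a count but no percent.
    """
    df = cohort.df
    rows = []
    for col in _CONTINUOUS_SUMMARY:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        if vals.empty:
            continue
        rows.append({"variable": col, "level": "", "n": int(vals.size),
                     "percent": np.nan, "mean": vals.mean(), "sd": vals.std(ddof=1)})
    for col, relabel in _CATEGORICAL_SUMMARY.items():
        if col not in df.columns:
            continue
        series = df[col]
        if relabel is not None:
            series = series.map(relabel)
        nonmiss = series.dropna()
        denom = int(nonmiss.size)
        levels = _MODIFIER_LEVELS.get(col)
        if levels is None:
            if col == "stage":
                levels = STAGE_LEVELS
            elif col == "debulk":
                levels = DEBULK_LEVELS
            elif col == "event":
                levels = ("alive", "deceased")
            else:
                levels = tuple(sorted(nonmiss.unique()))
        for level in levels:
            count = int((nonmiss == level).sum())
            rows.append({"variable": col, "level": level, "n": count,
                         "percent": _pct(count, denom), "mean": np.nan, "sd": np.nan})
        n_missing = int(series.isna().sum())
        if n_missing:
            rows.append({"variable": col, "level": "NA", "n": n_missing,
                         "percent": np.nan, "mean": np.nan, "sd": np.nan})
    return pd.DataFrame(rows)


def encode_modifiers(cohort: CohortTable,
                     modifiers: tuple[str, ...] = tuple(MODIFIERS)) -> tuple[pd.DataFrame, list[dict]]:
    """Design matrix for the candidate modifiers.

    Continuous modifiers (age, BMI) are centered; their sporadic missing
    values are mean-imputed with a logged warning. Categorical modifiers are
    dummy-coded against a declared reference level (never smoker, PAGA=yes,
    lowest income); missing categorical values get an explicit ``_missing``
    indicator column rather than dropping the row.

    Returns the design DataFrame and per-column metadata dicts with keys
    ``column``, ``modifier``, ``kind`` and (for dummies) ``level``.
    """
    df = cohort.df
    cols: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    for mod in modifiers:
        kind = MODIFIERS.get(mod)
        if kind is None:
            raise ValueError(f"unknown modifier {mod!r}")
        if mod not in df.columns:
            raise SchemaError(f"modifier column {mod!r} not in cohort")
        if kind == "continuous":
            x = pd.to_numeric(df[mod], errors="coerce").to_numpy(dtype=float)
            n_miss = int(np.isnan(x).sum())
            if n_miss:
                logger.warning("modifier %s: mean-imputing %d missing values", mod, n_miss)
                warnings.warn(f"modifier {mod}: mean-imputing {n_miss} missing values",
                              stacklevel=2)
                x = np.where(np.isnan(x), np.nanmean(x), x)
            cols[mod] = x - x.mean()
            meta.append({"column": mod, "modifier": mod, "kind": "continuous"})
        else:
            levels = _MODIFIER_LEVELS[mod]
            ref = MODIFIER_REFERENCE[mod]
            series = df[mod]
            unknown = series.dropna()[~series.dropna().isin(levels)]
            if not unknown.empty:
                raise ValueError(f"modifier {mod}: unknown label(s) {sorted(unknown.unique())}")
            for level in levels:
                if level == ref:
                    continue
                name = f"{mod}_{level}"
                cols[name] = (series == level).to_numpy(dtype=float)
                meta.append({"column": name, "modifier": mod, "kind": "dummy",
                             "level": level, "reference": ref})
            if series.isna().any():
                name = f"{mod}_missing"
                cols[name] = series.isna().to_numpy(dtype=float)
                meta.append({"column": name, "modifier": mod, "kind": "missing_indicator"})
    return pd.DataFrame(cols, index=df.index), meta
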