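"""Cohort data model and delimited-table I/O.

The canonical in-memory container is a pandas DataFrame with one row per
participant and canonical column names:

* demographics/covariates: ``id, age, sex, race, education, marital,
  employment, smoking, bmi_category, cohort, weight_2yr``
* 24-h recall nutrients: ``nut_<name>_<unit>`` (e.g. ``nut_protein_g``,
  ``nut_sodium_mg``), with total energy in ``nut_energy_kcal``
* food-pattern equivalents: ``fpe_<component>_<unit>`` (cup/oz equivalents
  per day)
* Mediterranean-diet food groups: ``mds_<group>_g`` (grams/day)
* labs and exam measures: ``lab_<name>``, ``exam_<name>``
* self-reported health items: ``sr_<name>``
* mortality follow-up: ``time_years``, ``event`` (1 = died, 0 = censored)

Typed per-participant record views (dataclasses) are provided for callers
that prefer objects over rows; all scoring operates on the DataFrame.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dietfrail.errors import ConfigurationError, DomainError

SEXES = ("male", "female")
RACES = ("non-Hispanic white", "non-Hispanic black", "Hispanic", "other")
EDUCATION_LEVELS = (
    "less than high school",
    "high school",
    "some college/associate",
    "college graduate or higher",
)
MARITAL_LEVELS = ("married", "widowed", "divorced or separated", "never married")
EMPLOYMENT_LEVELS = ("working", "non-working")
SMOKING_LEVELS = ("never", "former", "current")
BMI_CATEGORIES = ("<18.5", "18.5-24.9", "25.0-29.9", ">=30.0")

#: columns every cohort table must carry before scoring
REQUIRED_COLUMNS = ("id", "age", "sex", "weight_2yr", "nut_energy_kcal")

#: prefixes whose values must be non-negative amounts
AMOUNT_PREFIXES = ("nut_", "fpe_", "mds_")


@dataclasses.dataclass
class ParticipantRecord:
    """Demographics, covariates and sampling weight for one subject."""

    id: str
    age: float
    sex: str
    race: str | None = None
    education: str | None = None
    marital: str | None = None
    employment: str | None = None
    smoking: str | None = None
    bmi_category: str | None = None
    cohort: str | None = None
    weight_2yr: float = 1.0


@dataclasses.dataclass
class NutrientIntake:
    """Named nutrient amounts plus total energy from one 24-h recall."""

    energy_kcal: float
    amounts: dict[str, float]


@dataclasses.dataclass
class FoodPatternIntake:
    """Food-pattern-equivalent and MDS food-group amounts (native units)."""

    amounts: dict[str, float]


@dataclasses.dataclass
class LabExamPanel:
    """Nutrition-related blood tests and anthropometrics; values may be NaN."""

    values: dict[str, float]


@dataclasses.dataclass
class FollowUp:
    """Survival time (years since exam) and event indicator."""

    time: float
    event: int
    window_cap: float = 8.0


def iter_records(
    df: pd.DataFrame,
) -> Iterator[tuple[ParticipantRecord, NutrientIntake, FoodPatternIntake, LabExamPanel, FollowUp | None]]:
    """Yield typed record views of the cohort DataFrame, row by row."""
    demo_fields = [f.name for f in dataclasses.fields(ParticipantRecord)]
    for _, row in df.iterrows():
        demo = {k: row[k] for k in demo_fields if k in row.index}
        nut = {
            c.removeprefix("nut_"): row[c]
            for c in df.columns
            if c.startswith("nut_") and c != "nut_energy_kcal"
        }
        fpe = {
            c: row[c] for c in df.columns if c.startswith(("fpe_", "mds_"))
        }
        lab = {
            c: row[c] for c in df.columns if c.startswith(("lab_", "exam_"))
        }
        fu = None
        if "time_years" in row.index and "event" in row.index:
            fu = FollowUp(time=row["time_years"], event=int(row["event"]))
        yield (
            ParticipantRecord(**demo),
            NutrientIntake(energy_kcal=row["nut_energy_kcal"], amounts=nut),
            FoodPatternIntake(amounts=fpe),
            LabExamPanel(values=lab),
            fu,
        )


# ---------------------------------------------------------------------------
# reading / writing


class RowError:
    """One rejected row: its 0-based position and the reason."""

    def __init__(self, row: int, message: str) -> None:
        self.row = row
        self.message = message

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RowError(row={self.row}, message={self.message!r})"


def load_schema(path: str | Path) -> dict:
    """Load a column-mapping schema: ``{canonical: {source: col, scale: f}}``."""
    with open(path, "r", encoding="utf-8") as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, Mapping) or "columns" not in schema:
        raise ConfigurationError("schema must be a mapping with a 'columns' key")
    return dict(schema)


def read_cohort(
    path: str | Path,
    schema: Mapping | None = None,
    sep: str = ",",
) -> tuple[pd.DataFrame, list[RowError]]:
    """Read a delimited cohort table into canonical columns.

    Parameters
    ----------
    path
        UTF-8 delimited file, one row per participant.
    schema
        Optional column mapping, ``{"columns": {canonical: {"source": name,
        "scale": factor}}}``; unit conversion is multiplication by ``scale``.
        When omitted the file is assumed to already use canonical names and
        units.
    sep
        Field delimiter.

    Returns
    -------
    (DataFrame, list of RowError)
        Typed records, with rows that fail validation removed and reported
        by 0-based data-row number.

    Raises
    ------
    ConfigurationError
        If a mandatory column is absent from the file (or from the schema
        mapping).
    """
    raw = pd.read_csv(path, sep=sep, dtype={"id": str})
    if schema is not None:
        mapping = schema["columns"]
        rename = {}
        scales = {}
        for canonical, spec in mapping.items():
            if isinstance(spec, str):
                src, scale = spec, 1.0
            else:
                src, scale = spec["source"], float(spec.get("scale", 1.0))
            if src not in raw.columns:
                raise ConfigurationError(
                    f"schema maps {canonical!r} to missing source column {src!r}"
                )
            rename[src] = canonical
            if scale != 1.0:
                scales[canonical] = scale
        raw = raw.rename(columns=rename)
        for canonical, scale in scales.items():
            raw[canonical] = pd.to_numeric(raw[canonical], errors="coerce") * scale

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"mandatory column(s) missing: {', '.join(missing)}")

    errors: list[RowError] = []
    numeric_cols = [
        c
        for c in raw.columns
        if c.startswith(AMOUNT_PREFIXES + ("lab_", "exam_"))
        or c in ("age", "weight_2yr", "time_years", "event")
    ]
    for c in numeric_cols:
        coerced = pd.to_numeric(raw[c], errors="coerce")
        bad = raw[c].notna() & coerced.isna()
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(RowError(int(i), f"column {c!r}: unparseable value {raw[c].iloc[i]!r}"))
        raw[c] = coerced

    drop = pd.Series(False, index=raw.index)
    for c in raw.columns:
        if c.startswith(AMOUNT_PREFIXES):
            neg = raw[c] < 0
            for i in np.flatnonzero(neg.to_numpy()):
                errors.append(
                    RowError(int(i), f"column {c!r}: negative amount {raw[c].iloc[i]}")
                )
            drop |= neg
    bad_rows = {e.row for e in errors}
    drop |= raw.index.isin(bad_rows)

    df = raw.loc[~drop].reset_index(drop=True)
    return df, errors


def write_cohort(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a cohort table; floats at full precision so reads round-trip."""
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# exclusions and weights

#: criterion name -> column(s) that must be non-missing (and, for dietary
#: data, positive energy)
EXCLUSION_ORDER = ("dietary_data", "frailty_evaluable", "mortality_linked")


def apply_exclusions(
    df: pd.DataFrame,
    required: Sequence[str] = ("frailty_evaluable", "mortality_linked"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop participants failing inclusion criteria, in a fixed order.

    Criteria are applied sequentially (dietary data, then frailty, then
    mortality linkage), so the ledger counts are disjoint and sum to
    ``len(input) - len(output)``.

    Returns the analytic cohort and an ordered exclusion ledger
    ``{criterion: n_removed}``.
    """
    ledger: dict[str, int] = {}
    out = df
    for criterion in EXCLUSION_ORDER:
        if criterion not in required:
            continue
        if criterion == "dietary_data":
            ok = out["nut_energy_kcal"].notna() & (out["nut_energy_kcal"] > 0)
        elif criterion == "frailty_evaluable":
            ok = out["frailty_index"].notna() if "frailty_index" in out.columns else pd.Series(True, index=out.index)
        elif criterion == "mortality_linked":
            if "time_years" in out.columns and "event" in out.columns:
                ok = out["time_years"].notna() & out["event"].notna()
            else:
                ok = pd.Series(False, index=out.index)
        ledger[criterion] = int((~ok).sum())
        out = out.loc[ok]
    return out.reset_index(drop=True), ledger


def six_year_weight(weight_2yr, n_cycles: int = 3):
    """Pool per-cycle sampling weights across survey cycles.

    Combining ``n_cycles`` 2-year cycles divides each 2-year weight by the
    number of cycles (default 3, i.e. 6-year weights from three 2-year
    cycles).
    """
    if n_cycles <= 0:
        raise DomainError(f"n_cycles must be >= 1, got {n_cycles}")
    return np.asarray(weight_2yr) / n_cycles if np.ndim(weight_2yr) else weight_2yr / n_cycles


# ---------------------------------------------------------------------------
# derived columns

#: energy yielded per gram of macronutrient (Atwater factors)
KCAL_PER_G = {"protein": 4.0, "carbohydrate": 4.0, "fat": 9.0, "alcohol": 7.0}


def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with derived columns the scores consume.

    Computes (only when inputs exist and the target is absent):

    * ``nut_energy_per_kg`` = energy / body weight (kcal/kg/day)
    * ``nut_protein_per_kg`` = protein / body weight (g/kg/day)
    * ``nut_sat_fat_pct_energy`` = saturated fat as % of energy
    * ``mufa_sfa_ratio`` = monounsaturated : saturated fat ratio
      (NaN where both are 0; +inf where only SFA is 0)
    * ``bmi_category`` from ``exam_bmi``
    """
    out = df.copy()
    e = out["nut_energy_kcal"] if "nut_energy_kcal" in out.columns else None

    if "nut_energy_per_kg" not in out.columns and e is not None and "exam_weight_kg" in out.columns:
        out["nut_energy_per_kg"] = e / out["exam_weight_kg"]
    if (
        "nut_protein_per_kg" not in out.columns
        and "nut_protein_g" in out.columns
        and "exam_weight_kg" in out.columns
    ):
        out["nut_protein_per_kg"] = out["nut_protein_g"] / out["exam_weight_kg"]
    if (
        "nut_sat_fat_pct_energy" not in out.columns
        and "nut_saturated_fat_g" in out.columns
        and e is not None
    ):
        out["nut_sat_fat_pct_energy"] = out["nut_saturated_fat_g"] * KCAL_PER_G["fat"] * 100.0 / e
    if (
        "mufa_sfa_ratio" not in out.columns
        and "nut_mufa_g" in out.columns
        and "nut_saturated_fat_g" in out.columns
    ):
        mufa = out["nut_mufa_g"].to_numpy(dtype=float)
        sfa = out["nut_saturated_fat_g"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mufa / sfa
        ratio[(sfa == 0) & (mufa == 0)] = np.nan
        out["mufa_sfa_ratio"] = ratio
    if "bmi_category" not in out.columns and "exam_bmi" in out.columns:
        out["bmi_category"] = pd.cut(
            out["exam_bmi"],
            bins=[-np.inf, 18.5, 25.0, 30.0, np.inf],
            labels=BMI_CATEGORIES,
            right=False,
        ).astype(object)
    return out
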