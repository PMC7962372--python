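"""Energy-density Dietary Inflammatory Index (E-DII).

The E-DII weighs a diet's nutrient profile by literature-derived
inflammatory effect scores. Each dietary parameter is expressed as a
density per 1000 kcal, standardised against a reference distribution of
densities (mean, SD), converted to a centred percentile, and multiplied by
the parameter's effect score:

    density  = 1000 * amount / energy_kcal
    z        = (density - ref_mean) / ref_sd
    centred  = 2 * Phi(z) - 1                  # in (-1, 1)
    total    = sum over parameters of centred * effect_score

Higher totals indicate a more pro-inflammatory dietary intake.

The packaged default reference table is SYNTHETIC: the licensed global
intake database behind the published index is not public, so the shipped
table carries plausible per-1000-kcal means/SDs with literature-sign effect
scores. Supply the licensed table (same CSV layout) for real analyses; the
table's checksum is exposed so runs can record which table produced scores.
"""

from __future__ import annotations

import dataclasses
import hashlib
from collections.abc import Mapping
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from dietfrail.errors import ConfigurationError, DomainError

#: E-DII parameter name -> canonical cohort column holding the daily amount
PARAMETER_COLUMNS = {
    "protein": "nut_protein_g",
    "carbohydrate": "nut_carbohydrate_g",
    "total_fat": "nut_total_fat_g",
    "saturated_fat": "nut_saturated_fat_g",
    "mufa": "nut_mufa_g",
    "pufa": "nut_pufa_g",
    "omega3": "nut_omega3_g",
    "omega6": "nut_omega6_g",
    "cholesterol": "nut_cholesterol_mg",
    "fiber": "nut_fiber_g",
    "vitamin_a": "nut_vitamin_a_mcg",
    "vitamin_b1": "nut_vitamin_b1_mg",
    "vitamin_b2": "nut_vitamin_b2_mg",
    "vitamin_b3": "nut_vitamin_b3_mg",
    "vitamin_b6": "nut_vitamin_b6_mg",
    "vitamin_b12": "nut_vitamin_b12_mcg",
    "vitamin_c": "nut_vitamin_c_mg",
    "vitamin_d": "nut_vitamin_d_mcg",
    "vitamin_e": "nut_vitamin_e_mg",
    "folate": "nut_folate_mcg",
    "beta_carotene": "nut_beta_carotene_mcg",
    "iron": "nut_iron_mg",
    "magnesium": "nut_magnesium_mg",
    "selenium": "nut_selenium_mcg",
    "zinc": "nut_zinc_mg",
    "caffeine": "nut_caffeine_mg",
    "alcohol": "nut_alcohol_g",
}


@dataclasses.dataclass
class EdiiReferenceTable:
    """Per-parameter reference density mean, SD and inflammatory effect score."""

    table: pd.DataFrame
    source: str = "synthetic-default"

    def __post_init__(self) -> None:
        required = {"parameter", "ref_mean", "ref_sd", "effect_score"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"reference table missing columns: {sorted(missing)}")
        if self.table["parameter"].duplicated().any():
            dupes = self.table.loc[self.table["parameter"].duplicated(), "parameter"].tolist()
            raise ConfigurationError(f"duplicate reference parameters: {dupes}")
        if (self.table["ref_sd"] <= 0).any():
            bad = self.table.loc[self.table["ref_sd"] <= 0, "parameter"].tolist()
            raise ConfigurationError(f"ref_sd must be > 0; offending parameters: {bad}")
        self.table = self.table.set_index("parameter", drop=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EdiiReferenceTable":
        return cls(pd.read_csv(path), source=str(path))

    @classmethod
    def default(cls) -> "EdiiReferenceTable":
        """The packaged synthetic reference table (27 available parameters)."""
        ref = resources.files("dietfrail") / "config" / "edii_reference_synthetic.csv"
        with ref.open("rb") as fh:
            data = fh.read()
        tab = cls(pd.read_csv(ref.open("r", encoding="utf-8")), source="synthetic-default")
        tab._checksum = hashlib.sha256(data).hexdigest()
        return tab

    @property
    def checksum(self) -> str:
        """SHA-256 of the canonical CSV serialisation of the table."""
        if getattr(self, "_checksum", None) is None:
            payload = self.table.reset_index(drop=True).to_csv(index=False).encode()
            self._checksum = hashlib.sha256(payload).hexdigest()
        return self._checksum

    @property
    def parameters(self) -> list[str]:
        return list(self.table["parameter"])


@dataclasses.dataclass
class EdiiResult:
    """Total score plus per-parameter contributions for one intake."""

    total: float
    per_parameter: dict[str, float]
    n_parameters_used: int


def energy_density(amount, energy_kcal):
    """Express a daily amount as a density per 1000 kcal.

    Raises DomainError if any energy value is non-positive.
    """
    e = np.asarray(energy_kcal, dtype=float)
    if np.any(e <= 0):
        raise DomainError("energy_kcal must be > 0 for density-based scoring")
    return np.asarray(amount, dtype=float) * 1000.0 / e


def compute_edii(
    data: pd.DataFrame | Mapping,
    ref: EdiiReferenceTable | None = None,
    missing: str = "skip",
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Compute the E-DII for every row of a cohort table.

    Parameters
    ----------
    data
        Cohort DataFrame (canonical columns) or a single record mapping.
    ref
        Reference table; defaults to the packaged synthetic table.
    missing
        ``"skip"`` scores over the parameters present (missing parameters
        are skipped and counted out of ``n_parameters_used``);
        ``"reference_mean"`` treats a missing density as sitting at the
        reference mean, contributing zero.
    columns
        Override of the parameter -> column mapping.

    Returns
    -------
    DataFrame with ``edii`` (the total), ``edii_n_parameters`` and one
    ``edii_c_<parameter>`` contribution column per reference parameter.
    """
    if missing not in ("skip", "reference_mean"):
        raise DomainError(f"missing must be 'skip' or 'reference_mean', got {missing!r}")
    if ref is None:
        ref = EdiiReferenceTable.default()
    colmap = dict(PARAMETER_COLUMNS if columns is None else columns)

    single = not isinstance(data, pd.DataFrame)
    df = pd.DataFrame([data]) if single else data
    if "nut_energy_kcal" not in df.columns:
        raise DomainError("cohort table lacks 'nut_energy_kcal'")
    energy = pd.to_numeric(df["nut_energy_kcal"], errors="coerce").to_numpy(dtype=float)
    if np.any(~(energy > 0)):
        raise DomainError("energy_kcal must be > 0 for every record entering the E-DII")

    usable = [p for p in ref.parameters if colmap.get(p) in df.columns]
    if not usable:
        raise DomainError("no reference parameter is present in the intake table")

    total = np.zeros(len(df))
    n_used = np.zeros(len(df), dtype=int)
    contribs: dict[str, np.ndarray] = {}
    for p in usable:
        row = ref.table.loc[p]
        amount = pd.to_numeric(df[colmap[p]], errors="coerce").to_numpy(dtype=float)
        density = amount * 1000.0 / energy
        z = (density - float(row["ref_mean"])) / float(row["ref_sd"])
        centred = 2.0 * norm.cdf(z) - 1.0
        contrib = centred * float(row["effect_score"])
        present = ~np.isnan(contrib)
        if missing == "reference_mean":
            contrib = np.where(present, contrib, 0.0)
            n_used += 1
        else:
            contrib = np.where(present, contrib, np.nan)
            n_used += present
        total += np.nan_to_num(contrib)
        contribs[f"edii_c_{p}"] = contrib

    out = pd.DataFrame({"edii": total, "edii_n_parameters": n_used}, index=df.index)
    for k, v in contribs.items():
        out[k] = v
    return out


def edii_record(record: Mapping, ref: EdiiReferenceTable | None = None, **kw) -> EdiiResult:
    """Score one record, returning an :class:`EdiiResult`."""
    row = compute_edii(record, ref=ref, **kw).iloc[0]
    per = {
        k.removeprefix("edii_c_"): float(v)
        for k, v in row.items()
        if k.startswith("edii_c_") and not pd.isna(v)
    }
    return EdiiResult(
        total=float(row["edii"]),
        per_parameter=per,
        n_parameters_used=int(row["edii_n_parameters"]),
    )
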