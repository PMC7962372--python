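"""Healthy Eating Index-2015 (HEI-2015).

Thirteen components score adherence to the Dietary Guidelines for Americans
on a 0-100 scale. Nine adequacy components (total fruits, whole fruits,
total vegetables, greens and beans, whole grains, dairy, total protein
foods, seafood and plant proteins, fatty-acid ratio) reward higher intake;
four moderation components (refined grains, sodium, added sugars, saturated
fats) reward lower intake. Each component is scored by piecewise-linear
interpolation of its density between two standards, flat outside them:

    adequacy:   points = max_points * clamp((d - s_min) / (s_max - s_min), 0, 1)
    moderation: points = max_points * clamp((s_min - d) / (s_min - s_max), 0, 1)

where d is the component density (amount x 1000 / energy for cup/oz
equivalents and sodium, percent of energy for added sugars and saturated
fat, and (MUFA+PUFA)/SFA for the fatty-acid component). A higher total
reflects healthier eating.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dietfrail.errors import ConfigurationError, DomainError

BASES = ("density_per_1000kcal", "percent_energy", "ratio")


@dataclasses.dataclass(frozen=True)
class HeiComponentStandard:
    """Scoring standard for one HEI-2015 component."""

    name: str
    kind: str  # adequacy | moderation
    max_points: float
    basis: str
    standard_for_max: float
    standard_for_min: float
    column: str | None = None
    scale: float = 1.0  # unit conversion applied to the raw amount
    kcal_per_g: float | None = None  # for percent_energy components

    def __post_init__(self) -> None:
        if self.kind not in ("adequacy", "moderation"):
            raise ConfigurationError(f"{self.name}: kind must be adequacy|moderation")
        if self.basis not in BASES:
            raise ConfigurationError(f"{self.name}: basis must be one of {BASES}")
        if self.kind == "adequacy" and not self.standard_for_max > self.standard_for_min:
            raise ConfigurationError(f"{self.name}: adequacy needs standard_for_max > standard_for_min")
        if self.kind == "moderation" and not self.standard_for_min > self.standard_for_max:
            raise ConfigurationError(f"{self.name}: moderation needs standard_for_min > standard_for_max")
        if self.basis == "percent_energy" and self.kcal_per_g is None:
            raise ConfigurationError(f"{self.name}: percent_energy basis needs kcal_per_g")


def default_standards() -> list[HeiComponentStandard]:
    """The packaged 13 HEI-2015 component standards."""
    ref = resources.files("dietfrail") / "config" / "hei2015.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return [HeiComponentStandard(**c) for c in cfg["components"]]


def load_standards(path: str | Path) -> list[HeiComponentStandard]:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return [HeiComponentStandard(**c) for c in cfg["components"]]


def component_points(density, standard: HeiComponentStandard):
    """Piecewise-linear points for one component given its density.

    Negative densities are a domain error; NaN densities propagate.
    """
    d = np.asarray(density, dtype=float)
    if np.any(d[~np.isnan(d)] < 0):
        raise DomainError(f"{standard.name}: negative density")
    smax, smin = standard.standard_for_max, standard.standard_for_min
    if standard.kind == "adequacy":
        frac = (d - smin) / (smax - smin)
    else:
        frac = (smin - d) / (smin - smax)
    return standard.max_points * np.clip(frac, 0.0, 1.0)


def _density(df: pd.DataFrame, std: HeiComponentStandard, energy: np.ndarray) -> np.ndarray:
    if std.basis == "ratio":
        # fatty-acid ratio (MUFA + PUFA) / SFA, with documented limits:
        # SFA = 0 with unsaturated fat present -> max points; 0/0 -> 0 points.
        mufa = pd.to_numeric(df.get("nut_mufa_g"), errors="coerce").to_numpy(dtype=float)
        pufa = pd.to_numeric(df.get("nut_pufa_g"), errors="coerce").to_numpy(dtype=float)
        sfa = pd.to_numeric(df.get("nut_saturated_fat_g"), errors="coerce").to_numpy(dtype=float)
        unsat = mufa + pufa
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = unsat / sfa
        ratio = np.where((sfa == 0) & (unsat > 0), np.inf, ratio)
        ratio = np.where((sfa == 0) & (unsat == 0), 0.0, ratio)
        return ratio
    if std.column not in df.columns:
        return np.full(len(df), np.nan)
    amount = pd.to_numeric(df[std.column], errors="coerce").to_numpy(dtype=float) * std.scale
    if std.basis == "percent_energy":
        return amount * std.kcal_per_g * 100.0 / energy
    return amount * 1000.0 / energy


def compute_hei2015(
    data: pd.DataFrame | Mapping,
    standards: list[HeiComponentStandard] | None = None,
    missing: str = "propagate",
) -> pd.DataFrame:
    """Score the HEI-2015 for every row of a cohort table.

    Parameters
    ----------
    data
        Cohort DataFrame (canonical columns) or single record mapping.
    standards
        The 13 component standards; packaged defaults when omitted.
    missing
        ``"propagate"`` (default) makes the total NaN when any component
        amount is missing; ``"zero_intake"`` treats a missing amount as zero
        consumption (0 adequacy points, full moderation points).

    Returns a DataFrame with ``hei_total`` and per-component ``hei_<name>``
    columns.
    """
    if missing not in ("propagate", "zero_intake"):
        raise DomainError(f"missing must be 'propagate' or 'zero_intake', got {missing!r}")
    if standards is None:
        standards = default_standards()
    if len(standards) != 13:
        raise ConfigurationError(f"HEI-2015 requires 13 component standards, got {len(standards)}")

    single = not isinstance(data, pd.DataFrame)
    df = pd.DataFrame([data]) if single else data
    energy = pd.to_numeric(df["nut_energy_kcal"], errors="coerce").to_numpy(dtype=float)
    if np.any(~(energy > 0)):
        raise DomainError("energy_kcal must be > 0 for every record entering the HEI-2015")

    out = pd.DataFrame(index=df.index)
    total = np.zeros(len(df))
    for std in standards:
        d = _density(df, std, energy)
        if missing == "zero_intake":
            d = np.where(np.isnan(d), 0.0, d)
        pts = component_points(d, std)
        out[f"hei_{std.name}"] = pts
        total = total + pts
    out.insert(0, "hei_total", total)
    return out
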