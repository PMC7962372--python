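"""Mediterranean Diet Score (MDS) and DASH nutrient-adherence score.

MDS (0-10): ten binary components scored against cohort medians. One point
for intake at or above the cohort median of each favourable component
(non-refined cereals, legumes, fruits and nuts, vegetables excluding
potatoes, fish, and the MUFA:SFA ratio); one point for intake below the
median of each unfavourable component (red meat and products, poultry,
dairy products); and one point for alcohol inside a sex-specific moderate
band (14-28 g/day for women, 28-70 g/day for men, bounds inclusive).
Medians come from the analytic sample being scored, unweighted by default.

DASH (0-9, half-point steps): nine nutrient targets (protein, fiber,
magnesium, calcium, potassium, total fat, saturated fat, cholesterol,
sodium), each compared on an energy-adjusted basis (per 1000 kcal or % of
energy). Meeting the goal scores 1; meeting the midpoint between the goal
and the DASH-trial control diet scores 0.5; neither scores 0.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dietfrail.cohort import add_derived_columns
from dietfrail.errors import ConfigurationError, DomainError

#: favourable MDS components (point for value >= cohort median)
MDS_FAVORABLE = {
    "non_refined_cereals": "mds_non_refined_cereals_g",
    "legumes": "mds_legumes_g",
    "fruits_and_nuts": "mds_fruits_nuts_g",
    "vegetables": "mds_vegetables_g",  # potatoes already excluded upstream
    "fish": "mds_fish_g",  # shrimp, clams, and fish
    "mufa_sfa_ratio": "mufa_sfa_ratio",
}

#: unfavourable MDS components (point for value < cohort median)
MDS_UNFAVORABLE = {
    "red_meat": "mds_red_meat_g",
    "poultry": "mds_poultry_g",
    "dairy": "mds_dairy_g",
}

#: moderate-alcohol band in g/day, inclusive at both ends
ALCOHOL_BANDS = {"female": (14.0, 28.0), "male": (28.0, 70.0)}


def weighted_median(values, weights) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half
    the total weight."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = ~np.isnan(v)
    v, w = v[keep], w[keep]
    if v.size == 0:
        raise DomainError("weighted_median of an empty sample")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


@dataclasses.dataclass
class MdsMedianSet:
    """Analytic-sample medians for the nine food components and the
    MUFA:SFA ratio."""

    medians: dict[str, float]
    weighted: bool = False

    def __post_init__(self) -> None:
        expected = set(MDS_FAVORABLE) | set(MDS_UNFAVORABLE)
        missing = expected - set(self.medians)
        if missing:
            raise ConfigurationError(f"median set missing components: {sorted(missing)}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"weighted": self.weighted, "medians": self.medians}, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MdsMedianSet":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(medians={k: float(v) for k, v in cfg["medians"].items()},
                   weighted=bool(cfg.get("weighted", False)))


def compute_mds_medians(df: pd.DataFrame, weights=None) -> MdsMedianSet:
    """Component medians on the analytic sample (optionally survey-weighted)."""
    if len(df) == 0:
        raise DomainError("cannot compute medians on an empty cohort")
    df = add_derived_columns(df)
    medians: dict[str, float] = {}
    for comp, col in {**MDS_FAVORABLE, **MDS_UNFAVORABLE}.items():
        if col not in df.columns:
            raise ConfigurationError(f"cohort lacks column {col!r} for MDS component {comp!r}")
        if weights is None:
            medians[comp] = float(df[col].median())
        else:
            medians[comp] = weighted_median(df[col], weights)
    return MdsMedianSet(medians=medians, weighted=weights is not None)


def compute_mds(
    data: pd.DataFrame | Mapping,
    medians: MdsMedianSet,
) -> pd.DataFrame:
    """MDS (0-10) per row: favourable >= median, unfavourable < median,
    alcohol inside the sex band. Returns ``mds`` plus per-component 0/1
    indicator columns ``mds_pt_<component>``."""
    single = not isinstance(data, pd.DataFrame)
    df = pd.DataFrame([data]) if single else data
    df = add_derived_columns(df)
    if "sex" not in df.columns:
        raise DomainError("MDS requires a 'sex' column for the alcohol band")
    unknown = set(df["sex"].dropna().unique()) - set(ALCOHOL_BANDS)
    if unknown:
        raise DomainError(f"unknown sex value(s): {sorted(unknown)}")

    out = pd.DataFrame(index=df.index)
    total = np.zeros(len(df))
    for comp, col in MDS_FAVORABLE.items():
        pts = (pd.to_numeric(df[col], errors="coerce") >= medians.medians[comp]).astype(int)
        out[f"mds_pt_{comp}"] = pts
        total += pts
    for comp, col in MDS_UNFAVORABLE.items():
        pts = (pd.to_numeric(df[col], errors="coerce") < medians.medians[comp]).astype(int)
        out[f"mds_pt_{comp}"] = pts
        total += pts

    alcohol_raw = df["nut_alcohol_g"] if "nut_alcohol_g" in df.columns else pd.Series(np.nan, index=df.index)
    alcohol = pd.to_numeric(alcohol_raw, errors="coerce")
    lo = df["sex"].map({s: b[0] for s, b in ALCOHOL_BANDS.items()})
    hi = df["sex"].map({s: b[1] for s, b in ALCOHOL_BANDS.items()})
    pts = ((alcohol >= lo) & (alcohol <= hi)).astype(int)
    out["mds_pt_alcohol"] = pts
    total += pts

    out.insert(0, "mds", total.astype(int))
    return out


# ---------------------------------------------------------------------------
# DASH


@dataclasses.dataclass(frozen=True)
class DashTarget:
    """Goal and control-diet value for one DASH nutrient."""

    nutrient: str
    column: str
    basis: str  # density_per_1000kcal | percent_energy
    direction: str  # at-least | at-most
    goal: float
    control: float
    kcal_per_g: float | None = None

    def __post_init__(self) -> None:
        if self.basis not in ("density_per_1000kcal", "percent_energy"):
            raise ConfigurationError(f"{self.nutrient}: bad basis {self.basis!r}")
        if self.direction not in ("at-least", "at-most"):
            raise ConfigurationError(f"{self.nutrient}: bad direction {self.direction!r}")
        if self.goal == self.control:
            raise ConfigurationError(f"{self.nutrient}: goal must differ from control")
        if self.basis == "percent_energy" and self.kcal_per_g is None:
            raise ConfigurationError(f"{self.nutrient}: percent_energy basis needs kcal_per_g")

    @property
    def intermediate(self) -> float:
        """Midpoint between the goal and the control-diet value."""
        return 0.5 * (self.goal + self.control)


def default_dash_targets() -> list[DashTarget]:
    """The packaged nine DASH nutrient targets."""
    ref = resources.files("dietfrail") / "config" / "dash.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return [DashTarget(**t) for t in cfg["targets"]]


def load_dash_targets(path: str | Path) -> list[DashTarget]:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return [DashTarget(**t) for t in cfg["targets"]]


def compute_dash(
    data: pd.DataFrame | Mapping,
    targets: list[DashTarget] | None = None,
) -> pd.DataFrame:
    """DASH score (0-9 in half-point steps) per row.

    Returns ``dash`` plus per-nutrient point columns ``dash_pt_<nutrient>``.
    Missing nutrient values make that component (and the total) NaN.
    """
    if targets is None:
        targets = default_dash_targets()
    if len(targets) != 9:
        raise ConfigurationError(f"DASH requires nine targets, got {len(targets)}")

    single = not isinstance(data, pd.DataFrame)
    df = pd.DataFrame([data]) if single else data
    energy = pd.to_numeric(df["nut_energy_kcal"], errors="coerce").to_numpy(dtype=float)
    if np.any(~(energy > 0)):
        raise DomainError("energy_kcal must be > 0 for every record entering the DASH score")

    out = pd.DataFrame(index=df.index)
    total = np.zeros(len(df))
    for t in targets:
        raw = df[t.column] if t.column in df.columns else pd.Series(np.nan, index=df.index)
        amount = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        if t.basis == "percent_energy":
            value = amount * t.kcal_per_g * 100.0 / energy
        else:
            value = amount * 1000.0 / energy
        if t.direction == "at-least":
            pts = np.where(value >= t.goal, 1.0, np.where(value >= t.intermediate, 0.5, 0.0))
        else:
            pts = np.where(value <= t.goal, 1.0, np.where(value <= t.intermediate, 0.5, 0.0))
        pts = np.where(np.isnan(value), np.nan, pts)
        out[f"dash_pt_{t.nutrient}"] = pts
        total = total + pts
    out.insert(0, "dash", total)
    return out
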