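"""Deficit-accumulation indices.

A deficit-accumulation index maps a participant's raw measurements through a
set of item rules, each yielding a deficit score in [0, 1], and reports

    index = (sum of item deficit scores) / (number of items assessed),

so values lie in [0, 1] and a higher value means more accumulated deficits.
The engine is instantiated here as the 31-item Nutrition Index (18 nutrient
intakes, 3 anthropometrics, 10 nutrition-related blood tests; higher = worse
nutritional status) and the 36-item frailty index (self-report health,
vital signs, laboratory tests; higher = frailer). The two default item sets
share no source measurement, so nutritional status never leaks into the
frailty measure.

Item rules (see the packaged YAML configs):

``threshold``
    deficit when the value is below (``direction: low``) or above
    (``direction: high``) a cut-off; the cut-off may be sex-specific
    (``{male: x, female: y}``).
``band``
    deficit when the value falls outside ``[low, high]`` (bounds healthy).
``categories``
    explicit mapping from coded values to deficit scores, supporting graded
    items (e.g. 0 / 0.5 / 1 for self-rated health).
``interval``
    graded score by ordered breakpoints: ``breaks`` of length k partition
    the line into k+1 segments scored by ``scores``.
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

VALID_SOURCES = ("nutrient", "lab", "exam", "self_report")
RULE_TYPES = ("threshold", "band", "categories", "interval")


def _resolve_cutoff(cutoff, sex: pd.Series | None, n: int) -> np.ndarray:
    """Broadcast a scalar or per-sex cut-off to an array of length n."""
    if isinstance(cutoff, Mapping):
        if sex is None:
            raise DomainError("sex-specific cut-off requires a 'sex' column")
        return sex.map({k: float(v) for k, v in cutoff.items()}).to_numpy(dtype=float)
    return np.full(n, float(cutoff))


@dataclasses.dataclass(frozen=True)
class DeficitItem:
    """One index item: a named rule over one source column."""

    name: str
    source: str
    column: str
    rule: dict

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ConfigurationError(
                f"item {self.name!r}: source must be one of {VALID_SOURCES}, got {self.source!r}"
            )
        rtype = self.rule.get("type")
        if rtype not in RULE_TYPES:
            raise ConfigurationError(f"item {self.name!r}: unknown rule type {rtype!r}")
        if rtype == "interval":
            breaks, scores = self.rule["breaks"], self.rule["scores"]
            if len(scores) != len(breaks) + 1:
                raise ConfigurationError(
                    f"item {self.name!r}: interval rule needs len(scores) == len(breaks)+1"
                )
            if any(not 0 <= s <= 1 for s in scores):
                raise ConfigurationError(f"item {self.name!r}: scores must lie in [0,1]")
        if rtype == "categories":
            if any(not 0 <= s <= 1 for s in self.rule["mapping"].values()):
                raise ConfigurationError(f"item {self.name!r}: scores must lie in [0,1]")

    def score(self, values: pd.Series, sex: pd.Series | None = None) -> pd.Series:
        """Vectorised deficit score in [0, 1]; NaN where the value is missing."""
        rule = self.rule
        rtype = rule["type"]
        if rtype == "categories":
            mapping = {float(k): float(v) for k, v in rule["mapping"].items()}
            out = pd.to_numeric(values, errors="coerce").map(mapping)
            return out.astype(float)

        v = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
        out = np.full(v.shape, np.nan)
        present = ~np.isnan(v)
        if rtype == "threshold":
            cut = _resolve_cutoff(rule["cutoff"], sex, len(v))
            if rule["direction"] == "low":
                out[present] = (v[present] < cut[present]).astype(float)
            elif rule["direction"] == "high":
                out[present] = (v[present] > cut[present]).astype(float)
            else:
                raise ConfigurationError(
                    f"item {self.name!r}: threshold direction must be 'low' or 'high'"
                )
        elif rtype == "band":
            lo, hi = float(rule["low"]), float(rule["high"])
            out[present] = ((v[present] < lo) | (v[present] > hi)).astype(float)
        elif rtype == "interval":
            breaks = np.asarray(rule["breaks"], dtype=float)
            scores = np.asarray(rule["scores"], dtype=float)
            out[present] = scores[np.searchsorted(breaks, v[present], side="right")]
        return pd.Series(out, index=values.index)

    def example_value(self, deficit: bool, sex: str = "female") -> float:
        """A deterministic raw value that does (or does not) trigger the item.

        Used to build fixture records; the generator draws random values by
        the same regions.
        """
        rule = self.rule
        rtype = rule["type"]
        if rtype == "threshold":
            cut = rule["cutoff"]
            cut = float(cut[sex]) if isinstance(cut, Mapping) else float(cut)
            lowish = cut * 0.5 if cut > 0 else cut - 1.0
            highish = cut * 1.5 if cut > 0 else cut * 0.5 + 1.0
            if rule["direction"] == "low":
                return lowish if deficit else highish
            return highish if deficit else lowish
        if rtype == "band":
            lo, hi = float(rule["low"]), float(rule["high"])
            if deficit:
                return hi + 0.25 * (hi - lo)
            return 0.5 * (lo + hi)
        if rtype == "categories":
            mapping = {float(k): float(v) for k, v in rule["mapping"].items()}
            target = max(mapping, key=mapping.get) if deficit else min(mapping, key=mapping.get)
            return float(target)
        # interval: first segment scoring 1 (deficit) / 0 (healthy)
        breaks = list(rule["breaks"])
        scores = list(rule["scores"])
        want = max(scores) if deficit else min(scores)
        seg = scores.index(want)
        edges = [breaks[0] - 1.0] + [
            (breaks[i - 1] + breaks[i]) / 2 if 0 < i < len(breaks) else None for i in range(len(breaks))
        ]
        if seg == 0:
            return breaks[0] - 1.0
        if seg == len(breaks):
            return breaks[-1] + 1.0
        return (breaks[seg - 1] + breaks[seg]) / 2


@dataclasses.dataclass
class DeficitScore:
    """Scored index for one participant."""

    value: float
    n_deficits: float
    n_assessed: int


@dataclasses.dataclass
class DeficitDefinitionSet:
    """Ordered, validated collection of deficit items."""

    name: str
    items: list[DeficitItem]
    expected_count: int
    min_nonmissing_fraction: float = 0.8

    def __post_init__(self) -> None:
        if len(self.items) != self.expected_count:
            raise ConfigurationError(
                f"{self.name}: expected {self.expected_count} items, got {len(self.items)}"
            )
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"{self.name}: duplicate item names {dupes}")
        if not 0 < self.min_nonmissing_fraction <= 1:
            raise ConfigurationError("min_nonmissing_fraction must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeficitDefinitionSet":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "DeficitDefinitionSet":
        items = [
            DeficitItem(
                name=it["name"], source=it["source"], column=it["column"], rule=dict(it["rule"])
            )
            for it in cfg["items"]
        ]
        return cls(
            name=cfg["name"],
            items=items,
            expected_count=int(cfg["expected_count"]),
            min_nonmissing_fraction=float(cfg.get("min_nonmissing_fraction", 0.8)),
        )

    @classmethod
    def default_nutrition_index(cls) -> "DeficitDefinitionSet":
        """The packaged 31-item Nutrition Index."""
        return cls.from_dict(_load_packaged("nutrition_index.yaml"))

    @classmethod
    def default_frailty_index(cls) -> "DeficitDefinitionSet":
        """The packaged 36-item frailty index."""
        return cls.from_dict(_load_packaged("frailty_index.yaml"))


def _load_packaged(filename: str) -> dict:
    ref = resources.files("dietfrail") / "config" / filename
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def score_deficit_index(
    data: pd.DataFrame | Mapping,
    defs: DeficitDefinitionSet,
) -> pd.DataFrame:
    """Score a deficit-accumulation index for every row of ``data``.

    Returns a DataFrame with columns ``value`` (the index, or NaN when fewer
    than ``min_nonmissing_fraction`` of items are assessed), ``n_deficits``
    (sum of item deficit scores) and ``n_assessed``.

    Derived nutrient columns (per-kg intakes, % saturated fat) are computed
    on the fly when their inputs are present.
    """
    single = not isinstance(data, pd.DataFrame)
    df = pd.DataFrame([data]) if single else data
    if "nut_energy_kcal" in df.columns:
        df = add_derived_columns(df)
    sex = df["sex"] if "sex" in df.columns else None

    n = len(df)
    scores = np.zeros(n)
    assessed = np.zeros(n, dtype=int)
    for item in defs.items:
        if item.column in df.columns:
            s = item.score(df[item.column], sex)
        else:
            s = pd.Series(np.nan, index=df.index)
        present = s.notna().to_numpy()
        assessed += present
        scores[present] += s.to_numpy(dtype=float)[present]

    min_assessed = defs.min_nonmissing_fraction * defs.expected_count
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(assessed >= min_assessed, scores / np.maximum(assessed, 1), np.nan)
    value = np.where(assessed == 0, np.nan, value)
    return pd.DataFrame(
        {"value": value, "n_deficits": scores, "n_assessed": assessed}, index=df.index
    )


def score_record(record: Mapping, defs: DeficitDefinitionSet) -> DeficitScore:
    """Score one participant given a mapping of column -> raw value."""
    row = score_deficit_index(record, defs).iloc[0]
    return DeficitScore(
        value=float(row["value"]),
        n_deficits=float(row["n_deficits"]),
        n_assessed=int(row["n_assessed"]),
    )


def split_nutrition_index(
    defs_full: DeficitDefinitionSet,
) -> tuple[DeficitDefinitionSet, DeficitDefinitionSet]:
    """Partition the Nutrition Index into its nutrient and lab/exam halves.

    The nutrient sub-index keeps the 18 intake items; the lab/exam sub-index
    keeps the 3 anthropometric and 10 blood-test items.
    """
    nutrient_items, labexam_items = [], []
    for item in defs_full.items:
        if item.source == "nutrient":
            nutrient_items.append(item)
        elif item.source in ("lab", "exam"):
            labexam_items.append(item)
        else:
            raise ConfigurationError(
                f"item {item.name!r} has source {item.source!r}; cannot assign to a sub-index"
            )
    frac = defs_full.min_nonmissing_fraction
    return (
        DeficitDefinitionSet(
            name=f"{defs_full.name}_nutrient",
            items=nutrient_items,
            expected_count=len(nutrient_items),
            min_nonmissing_fraction=frac,
        ),
        DeficitDefinitionSet(
            name=f"{defs_full.name}_labexam",
            items=labexam_items,
            expected_count=len(labexam_items),
            min_nonmissing_fraction=frac,
        ),
    )


def validate_frailty_independence(
    fi_defs: DeficitDefinitionSet, ni_defs: DeficitDefinitionSet
) -> list[str]:
    """Source columns shared between the frailty and nutrition item sets.

    An empty list certifies that no frailty item draws on dietary intake or
    nutritional-status measurements; the default configurations satisfy
    this.
    """
    fi_cols = {it.column for it in fi_defs.items}
    ni_cols = {it.column for it in ni_defs.items}
    return sorted(fi_cols & ni_cols)


def all_deficit_record(defs: DeficitDefinitionSet, sex: str = "female") -> dict:
    """A fixture record in which every item of ``defs`` scores a full deficit."""
    rec: dict = {"sex": sex}
    for item in defs.items:
        rec[item.column] = item.example_value(deficit=True, sex=sex)
    return rec


def no_deficit_record(defs: DeficitDefinitionSet, sex: str = "female") -> dict:
    """A fixture record in which every item of ``defs`` scores zero."""
    rec: dict = {"sex": sex}
    for item in defs.items:
        rec[item.column] = item.example_value(deficit=False, sex=sex)
    return rec
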