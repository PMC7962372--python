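"""Independent reference implementations used to cross-check the package.

These deliberately use plain-python / textbook-formula routes rather than
the package's vectorised code paths.
"""

import numpy as np

from dietfrail.deficits import DeficitDefinitionSet


def brute_force_deficit_score(row: dict, defs: DeficitDefinitionSet):
    """Per-record deficit recount by direct rule interpretation.

    Returns (value, n_deficits, n_assessed); value is NaN below the
    completeness threshold.
    """
    deficits = 0.0
    assessed = 0
    sex = row.get("sex")
    for item in defs.items:
        v = row.get(item.column)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        rule = item.rule
        if rule["type"] == "threshold":
            cut = rule["cutoff"]
            if isinstance(cut, dict):
                cut = cut[sex]
            hit = v < cut if rule["direction"] == "low" else v > cut
            s = 1.0 if hit else 0.0
        elif rule["type"] == "band":
            s = 1.0 if (v < rule["low"] or v > rule["high"]) else 0.0
        elif rule["type"] == "categories":
            mapping = {float(k): float(x) for k, x in rule["mapping"].items()}
            if float(v) not in mapping:
                continue
            s = mapping[float(v)]
        else:
            raise NotImplementedError(rule["type"])
        deficits += s
        assessed += 1
    if assessed < defs.min_nonmissing_fraction * defs.expected_count:
        return np.nan, deficits, assessed
    return deficits / assessed, deficits, assessed


def pearson_r(x, y) -> float:
    """Product-moment correlation by the explicit sums formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd = x - x.mean()
    yd = y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))


def vif_from_r(r: float) -> float:
    """Variance inflation factor between two exposures: 1 / (1 - r^2)."""
    return 1.0 / (1.0 - r**2)


def enumeration_weighted_median(values, weights) -> float:
    """Smallest candidate value whose cumulative weight reaches half the
    total, found by scanning every candidate."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    half = weights.sum() / 2.0
    for v in sorted(values):
        if weights[values <= v].sum() >= half:
            return float(v)
    raise AssertionError("unreachable")
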