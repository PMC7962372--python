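"""Assemble all per-participant scores into one table.

Adds to a cohort table: the Nutrition Index and its nutrient / lab-exam
sub-indices, the 36-item frailty index, E-DII, HEI-2015, MDS (with medians
computed on the analytic sample) and DASH.
"""

from __future__ import annotations

import pandas as pd

from dietfrail.deficits import (
    DeficitDefinitionSet,
    score_deficit_index,
    split_nutrition_index,
)
from dietfrail.edii import EdiiReferenceTable, compute_edii
from dietfrail.hei import compute_hei2015, default_standards
from dietfrail.patterns import MdsMedianSet, compute_dash, compute_mds, compute_mds_medians

SCORE_COLUMNS = (
    "nutrition_index",
    "ni_nutrient",
    "ni_labexam",
    "frailty_index",
    "edii",
    "hei2015",
    "mds",
    "dash",
)


def score_all(
    df: pd.DataFrame,
    ni_defs: DeficitDefinitionSet | None = None,
    fi_defs: DeficitDefinitionSet | None = None,
    edii_ref: EdiiReferenceTable | None = None,
    hei_standards=None,
    dash_targets=None,
    mds_medians: MdsMedianSet | None = None,
    mds_weights=None,
) -> pd.DataFrame:
    """Return a copy of ``df`` with all eight score columns appended.

    MDS medians default to the (unweighted) medians of the sample being
    scored; pass ``mds_medians`` to reuse medians across runs.
    """
    ni_defs = ni_defs or DeficitDefinitionSet.default_nutrition_index()
    fi_defs = fi_defs or DeficitDefinitionSet.default_frailty_index()
    ni_nut_defs, ni_lab_defs = split_nutrition_index(ni_defs)

    out = df.copy()
    out["nutrition_index"] = score_deficit_index(df, ni_defs)["value"]
    out["ni_nutrient"] = score_deficit_index(df, ni_nut_defs)["value"]
    out["ni_labexam"] = score_deficit_index(df, ni_lab_defs)["value"]
    out["frailty_index"] = score_deficit_index(df, fi_defs)["value"]
    out["edii"] = compute_edii(df, ref=edii_ref)["edii"]
    out["hei2015"] = compute_hei2015(df, standards=hei_standards or default_standards())["hei_total"]
    medians = mds_medians or compute_mds_medians(df, weights=mds_weights)
    out["mds"] = compute_mds(df, medians)["mds"]
    out["dash"] = compute_dash(df, targets=dash_targets)["dash"]
    return out
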