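"""Association stage: diet scores vs frailty (polynomial OLS) and mortality
(Cox proportional hazards), with correlations, pairwise-score models and
interaction tests.

Modelled after statsmodels: a Model object is built from a scored cohort
DataFrame and ``fit()`` returns a Results object carrying estimates, 95%
confidence intervals, p-values, diagnostics and a ``summary()`` table.

Polynomial exposure handling follows the convention of reporting the
highest-order model whose highest-order term is statistically significant:
the linear model is fitted first, then the squared term is added (a line
with one bend), then the cubic (two bends); the selected model is the
highest-degree one whose top term has p < alpha, falling back to linear.
Exposure values are unit-scaled (deficit indices per 0.1 point, HEI-2015
per 10 points, others per point) and mean-centred before powering to tame
collinearity among the polynomial terms.

Survey weights enter OLS as weighted least squares (with
heteroscedasticity-robust variance) and Cox models as case weights with
robust sandwich variance; full survey-design (strata/PSU) variance
estimation is out of scope.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from dietfrail.errors import DomainError, ValidationError

#: covariates adjusted for in every model (the "basic" set)
BASIC_COVARIATES = (
    "age",
    "sex",
    "race",
    "education",
    "marital",
    "employment",
    "smoking",
    "bmi_category",
    "cohort",
)

#: per-score unit of the reported coefficients / hazard ratios
UNIT_SCALES = {
    "nutrition_index": 0.1,
    "ni_nutrient": 0.1,
    "ni_labexam": 0.1,
    "frailty_index": 0.1,
    "hei2015": 10.0,
    "edii": 1.0,
    "mds": 1.0,
    "dash": 1.0,
}


def standardized_beta(b: float, sd_exposure: float, sd_outcome: float) -> float:
    """Standardise a regression coefficient: b * SD(exposure) / SD(outcome)."""
    if sd_outcome <= 0:
        raise DomainError("sd_outcome must be > 0")
    return b * sd_exposure / sd_outcome


def score_correlations(
    df: pd.DataFrame, scores: Sequence[str] | None = None, weights=None
) -> pd.DataFrame:
    """Pairwise Pearson correlations among score columns.

    With ``weights``, weighted Pearson correlations are computed. Scores
    with zero variance yield NaN entries and a warning.
    """
    cols = list(scores) if scores is not None else [c for c in df.columns]
    data = df[cols].apply(pd.to_numeric, errors="coerce")
    if data.shape[1] < 2:
        raise DomainError("need at least two scores")
    cc = data.dropna()
    if len(cc) < 3:
        raise DomainError("need at least three complete rows")

    if weights is None:
        w = np.ones(len(cc))
    else:
        w = np.asarray(weights, dtype=float)[data.notna().all(axis=1).to_numpy()]
    X = cc.to_numpy(dtype=float)
    wsum = w.sum()
    mean = (w[:, None] * X).sum(axis=0) / wsum
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc / wsum
    sd = np.sqrt(np.diag(cov))
    flagged = [cols[i] for i in np.flatnonzero(sd == 0)]
    if flagged:
        warnings.warn(f"zero-variance score(s), correlations undefined: {flagged}")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _encode_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric columns pass through; categoricals become treatment dummies."""
    X = pd.DataFrame(index=df.index)
    for c in covariates:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            X[c] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        culprits = constant or list(X.columns)
        raise ValidationError(f"design matrix is rank deficient; collinear column(s): {culprits}")


def _exposure_terms(
    x: pd.Series, name: str, scale: float, degree: int, center: bool
) -> pd.DataFrame:
    xs = x.astype(float) / scale
    if center:
        xs = xs - xs.mean()
    out = pd.DataFrame(index=x.index)
    for d in range(1, degree + 1):
        out[name if d == 1 else f"{name}^{d}"] = xs**d
    return out


def _resolve_weights(df: pd.DataFrame, weights) -> np.ndarray | None:
    if weights is None:
        return None
    if isinstance(weights, str):
        if weights in ("six-year", "six_year"):
            from dietfrail.cohort import six_year_weight

            return six_year_weight(df["weight_2yr"].to_numpy(dtype=float))
        return df[weights].to_numpy(dtype=float)
    return np.asarray(weights, dtype=float)


def _auto_energy(exposures: Sequence[str], extra: Sequence[str]) -> bool:
    # energy enters as a covariate when MDS is modelled without the
    # Nutrition Index (the NI is itself energy-adjusted)
    return "mds" in exposures and "nutrition_index" not in extra and not (
        set(exposures) & {"nutrition_index", "ni_nutrient", "ni_labexam"}
    )


# ---------------------------------------------------------------------------
# frailty outcome: polynomial weighted least squares


@dataclasses.dataclass
class OlsTermTable:
    """Per-term estimates for the selected model."""

    table: pd.DataFrame


class FrailtyRegressionResults:
    """Estimates from the selected polynomial OLS model of frailty."""

    def __init__(self, model, selected_degree, sm_results, params, degree_pvalues):
        self.model = model
        self.selected_degree = selected_degree
        self.sm_results = sm_results
        #: DataFrame (term x coef, ci_low, ci_high, pvalue, std_beta)
        self.params = params
        #: p-value of the highest-order term at each candidate degree
        self.degree_pvalues = degree_pvalues
        self.n_obs = int(sm_results.nobs)

    def summary(self) -> str:
        head = (
            f"Frailty OLS: outcome={self.model.outcome}, "
            f"exposure={self.model.exposures} (unit scale {self.model.unit_scales}), "
            f"selected degree={self.selected_degree}, n={self.n_obs}"
        )
        return head + "\n" + self.params.to_string(float_format=lambda v: f"{v: .6g}")


class FrailtyModel:
    """Polynomial OLS of the frailty index on one or more diet scores.

    Parameters
    ----------
    data
        Scored cohort table (one row per participant).
    exposure
        Score column name, or a sequence of names for joint models.
    outcome
        Outcome column, default ``frailty_index``.
    covariates
        Adjustment set; defaults to the basic covariates present in
        ``data``. Categorical covariates are dummy-coded.
    degree_max
        Highest polynomial degree tried for each exposure (1-3).
    weights
        ``None``, an array of case weights, a column name, or
        ``"six-year"`` to pool the 2-year survey weights over 3 cycles.
    alpha
        Significance level of the degree-selection rule.
    unit_scale
        Override of the per-score unit scaling.
    add_energy
        Force energy (kcal) into the covariates; by default it is added
        exactly when MDS is modelled without the Nutrition Index.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure,
        outcome: str = "frailty_index",
        covariates: Sequence[str] | None = None,
        extra_covariates: Sequence[str] = (),
        degree_max: int = 3,
        weights=None,
        alpha: float = 0.05,
        unit_scale=None,
        add_energy: bool | None = None,
        center: bool = True,
    ) -> None:
        if degree_max not in (1, 2, 3):
            raise DomainError("degree_max must be 1, 2 or 3")
        self.data = data
        self.exposures = [exposure] if isinstance(exposure, str) else list(exposure)
        if not self.exposures:
            raise DomainError("at least one exposure is required")
        self.outcome = outcome
        if covariates is None:
            covariates = [c for c in BASIC_COVARIATES if c in data.columns]
        self.covariates = list(covariates)
        self.extra_covariates = list(extra_covariates)
        self.degree_max = degree_max
        self.weights = weights
        self.alpha = alpha
        if unit_scale is None:
            self.unit_scales = {e: UNIT_SCALES.get(e, 1.0) for e in self.exposures}
        elif np.isscalar(unit_scale):
            self.unit_scales = {e: float(unit_scale) for e in self.exposures}
        else:
            self.unit_scales = dict(unit_scale)
        if add_energy is None:
            add_energy = _auto_energy(self.exposures, self.extra_covariates)
        self.add_energy = add_energy
        self.center = center

    # -- internal -----------------------------------------------------------

    def _complete_cases(self) -> tuple[pd.DataFrame, np.ndarray | None]:
        cols = [self.outcome, *self.exposures, *self.covariates, *self.extra_covariates]
        if self.add_energy:
            cols.append("nut_energy_kcal")
        df = self.data[list(dict.fromkeys(cols))].copy()
        w = _resolve_weights(self.data, self.weights)
        keep = df.notna().all(axis=1)
        df = df.loc[keep]
        if w is not None:
            w = w[keep.to_numpy()]
        return df, w

    def _design(self, df: pd.DataFrame, degrees: dict[str, int]) -> pd.DataFrame:
        parts = [
            _exposure_terms(df[e], e, self.unit_scales[e], degrees[e], self.center)
            for e in self.exposures
        ]
        cov_cols = self.covariates + self.extra_covariates
        if self.add_energy:
            cov_cols = cov_cols + ["nut_energy_kcal"]
        if cov_cols:
            parts.append(_encode_covariates(df, cov_cols))
        return pd.concat(parts, axis=1)

    def fit(self) -> FrailtyRegressionResults:
        df, w = self._complete_cases()
        primary = self.exposures[0]
        n_params_max = 1 + self.degree_max * len(self.exposures) + len(self.covariates) + 8
        if len(df) < n_params_max:
            raise DomainError(f"too few complete cases ({len(df)}) to fit the model")
        y = df[self.outcome].astype(float)

        degree_pvalues: dict[int, float] = {}
        fits: dict[int, object] = {}
        for deg in range(1, self.degree_max + 1):
            degrees = {e: (deg if e == primary else 1) for e in self.exposures}
            X = self._design(df, degrees)
            _check_rank(X)
            Xc = sm.add_constant(X.astype(float), has_constant="add")
            if w is None:
                res = sm.OLS(y, Xc).fit()
            else:
                res = sm.WLS(y, Xc, weights=w).fit(cov_type="HC1")
            fits[deg] = (res, X)
            top = primary if deg == 1 else f"{primary}^{deg}"
            degree_pvalues[deg] = float(res.pvalues[top])

        selected = 1
        for deg in range(self.degree_max, 0, -1):
            if degree_pvalues[deg] < self.alpha:
                selected = deg
                break
        res, X = fits[selected]

        sd_y = float(y.std(ddof=1))
        rows = []
        exp_terms = [
            t
            for t in X.columns
            if t in self.exposures or any(t.startswith(f"{e}^") for e in self.exposures)
        ]
        ci = res.conf_int()
        for term in exp_terms:
            b = float(res.params[term])
            rows.append(
                {
                    "term": term,
                    "coef": b,
                    "ci_low": float(ci.loc[term, 0]),
                    "ci_high": float(ci.loc[term, 1]),
                    "pvalue": float(res.pvalues[term]),
                    "std_beta": standardized_beta(b, float(X[term].std(ddof=1)), sd_y),
                }
            )
        params = pd.DataFrame(rows).set_index("term")
        return FrailtyRegressionResults(self, selected, res, params, degree_pvalues)


def fit_polynomial_ols(data: pd.DataFrame, exposure, **kwargs) -> FrailtyRegressionResults:
    """Convenience wrapper: build a :class:`FrailtyModel` and fit it."""
    return FrailtyModel(data, exposure, **kwargs).fit()


# ---------------------------------------------------------------------------
# mortality outcome: Cox proportional hazards


class MortalityResults:
    """Hazard ratios from the selected Cox model."""

    def __init__(self, model, selected_degree, fitter, params, degree_pvalues, n_obs, n_events):
        self.model = model
        self.selected_degree = selected_degree
        self.fitter = fitter  # the underlying lifelines CoxPHFitter
        #: DataFrame (term x coef, hr, hr_ci_low, hr_ci_high, pvalue)
        self.params = params
        self.degree_pvalues = degree_pvalues
        self.n_obs = n_obs
        self.n_events = n_events

    def summary(self) -> str:
        head = (
            f"Cox PH: window={self.model.window}y, exposure={self.model.exposures} "
            f"(unit scale {self.model.unit_scales}), selected degree={self.selected_degree}, "
            f"n={self.n_obs}, events={self.n_events}"
        )
        return head + "\n" + self.params.to_string(float_format=lambda v: f"{v: .6g}")


class MortalityModel:
    """Cox proportional-hazards model of 3- or 8-year mortality.

    Follow-up is administratively right-censored at ``window`` years before
    fitting. Ties are handled by lifelines' Efron approximation. The model
    is adjusted for the basic covariates plus, optionally, the continuous
    frailty index (``include_frailty``, default on) and the Nutrition Index
    (``include_ni``).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure,
        window: float = 8.0,
        covariates: Sequence[str] | None = None,
        include_frailty: bool = True,
        include_ni: bool = False,
        extra_covariates: Sequence[str] = (),
        degree_max: int = 3,
        weights=None,
        alpha: float = 0.05,
        unit_scale=None,
        add_energy: bool | None = None,
        center: bool = True,
        duration_col: str = "time_years",
        event_col: str = "event",
    ) -> None:
        if degree_max not in (1, 2, 3):
            raise DomainError("degree_max must be 1, 2 or 3")
        self.data = data
        self.exposures = [exposure] if isinstance(exposure, str) else list(exposure)
        if not self.exposures:
            raise DomainError("at least one exposure is required")
        self.window = float(window)
        if covariates is None:
            covariates = [c for c in BASIC_COVARIATES if c in data.columns]
        self.covariates = list(covariates)
        self.extra_covariates = list(extra_covariates)
        if include_frailty and "frailty_index" in data.columns:
            if "frailty_index" not in self.extra_covariates:
                self.extra_covariates.append("frailty_index")
        if include_ni:
            if "nutrition_index" not in self.extra_covariates:
                self.extra_covariates.append("nutrition_index")
        self.degree_max = degree_max
        self.weights = weights
        self.alpha = alpha
        if unit_scale is None:
            self.unit_scales = {e: UNIT_SCALES.get(e, 1.0) for e in self.exposures}
        elif np.isscalar(unit_scale):
            self.unit_scales = {e: float(unit_scale) for e in self.exposures}
        else:
            self.unit_scales = dict(unit_scale)
        if add_energy is None:
            add_energy = _auto_energy(self.exposures, self.extra_covariates)
        self.add_energy = add_energy
        self.center = center
        self.duration_col = duration_col
        self.event_col = event_col

    def _complete_cases(self) -> tuple[pd.DataFrame, np.ndarray | None]:
        cols = [
            self.duration_col,
            self.event_col,
            *self.exposures,
            *self.covariates,
            *self.extra_covariates,
        ]
        if self.add_energy:
            cols.append("nut_energy_kcal")
        df = self.data[list(dict.fromkeys(cols))].copy()
        w = _resolve_weights(self.data, self.weights)
        keep = df.notna().all(axis=1)
        df = df.loc[keep]
        if w is not None:
            w = w[keep.to_numpy()]
        return df, w

    def _cap_window(self, df: pd.DataFrame) -> pd.DataFrame:
        t = df[self.duration_col].astype(float)
        e = df[self.event_col].astype(int)
        capped = df.copy()
        capped[self.event_col] = np.where(t <= self.window, e, 0)
        capped[self.duration_col] = np.minimum(t, self.window)
        return capped

    def fit(self) -> MortalityResults:
        df, w = self._complete_cases()
        df = self._cap_window(df)
        n_events = int(df[self.event_col].sum())
        if n_events < 1:
            raise DomainError("no events remain after window capping")

        primary = self.exposures[0]
        degree_pvalues: dict[int, float] = {}
        fits: dict[int, CoxPHFitter] = {}
        for deg in range(1, self.degree_max + 1):
            degrees = {e: (deg if e == primary else 1) for e in self.exposures}
            parts = [
                _exposure_terms(df[e], e, self.unit_scales[e], degrees[e], self.center)
                for e in self.exposures
            ]
            cov_cols = self.covariates + self.extra_covariates
            if self.add_energy:
                cov_cols = cov_cols + ["nut_energy_kcal"]
            if cov_cols:
                parts.append(_encode_covariates(df, cov_cols))
            X = pd.concat(parts, axis=1)
            _check_rank(X)
            frame = X.copy()
            frame[self.duration_col] = df[self.duration_col].to_numpy()
            frame[self.event_col] = df[self.event_col].to_numpy()
            kwargs = {}
            if w is not None:
                frame["_w"] = w
                kwargs = {"weights_col": "_w", "robust": True}
            cph = CoxPHFitter()
            cph.fit(frame, duration_col=self.duration_col, event_col=self.event_col, **kwargs)
            fits[deg] = cph
            top = primary if deg == 1 else f"{primary}^{deg}"
            degree_pvalues[deg] = float(cph.summary.loc[top, "p"])

        selected = 1
        for deg in range(self.degree_max, 0, -1):
            if degree_pvalues[deg] < self.alpha:
                selected = deg
                break
        cph = fits[selected]

        summ = cph.summary
        exp_terms = [
            t
            for t in summ.index
            if t in self.exposures or any(str(t).startswith(f"{e}^") for e in self.exposures)
        ]
        rows = []
        for term in exp_terms:
            rows.append(
                {
                    "term": term,
                    "coef": float(summ.loc[term, "coef"]),
                    "hr": float(summ.loc[term, "exp(coef)"]),
                    "hr_ci_low": float(summ.loc[term, "exp(coef) lower 95%"]),
                    "hr_ci_high": float(summ.loc[term, "exp(coef) upper 95%"]),
                    "pvalue": float(summ.loc[term, "p"]),
                }
            )
        params = pd.DataFrame(rows).set_index("term")
        return MortalityResults(self, selected, cph, params, degree_pvalues, len(df), n_events)


def fit_cox(data: pd.DataFrame, exposure, **kwargs) -> MortalityResults:
    """Convenience wrapper: build a :class:`MortalityModel` and fit it."""
    return MortalityModel(data, exposure, **kwargs).fit()


# ---------------------------------------------------------------------------
# pairwise score models and interaction tests


@dataclasses.dataclass
class PairwiseResult:
    """Joint two-score model plus multicollinearity diagnostics."""

    results: FrailtyRegressionResults | MortalityResults
    vif: dict[str, float]
    warning: str | None = None


def pairwise_score_models(
    data: pd.DataFrame,
    score_a: str,
    score_b: str,
    outcome: str = "frailty",
    vif_threshold: float = 10.0,
    **kwargs,
) -> PairwiseResult:
    """Fit a joint model with two diet scores and report per-exposure VIFs.

    The variance inflation factor between the two exposures is
    1 / (1 - r^2) of one regressed on the other; a warning is attached when
    it exceeds ``vif_threshold``.
    """
    if score_a == score_b:
        raise DomainError("the two scores must differ")
    cc = data[[score_a, score_b]].dropna()
    r = float(np.corrcoef(cc[score_a], cc[score_b])[0, 1])
    vif = 1.0 / (1.0 - r**2) if abs(r) < 1 else np.inf
    vifs = {score_a: vif, score_b: vif}
    warning = None
    if vif > vif_threshold:
        warning = f"VIF {vif:.1f} exceeds {vif_threshold}; estimates may be unstable"
        warnings.warn(warning)

    if outcome == "frailty":
        res = FrailtyModel(data, [score_a, score_b], **kwargs).fit()
    elif outcome == "mortality":
        res = MortalityModel(data, [score_a, score_b], **kwargs).fit()
    else:
        raise DomainError(f"outcome must be 'frailty' or 'mortality', got {outcome!r}")
    return PairwiseResult(results=res, vif=vifs, warning=warning)


def _moderator_values(df: pd.DataFrame, moderator: str) -> pd.Series:
    if moderator == "sex":
        return df["sex"].map({"male": 0.0, "female": 1.0}).astype(float)
    if moderator == "age":
        return df["age"].astype(float)
    if moderator == "frailty":
        return df["frailty_index"].astype(float)
    raise DomainError(f"unsupported moderator {moderator!r}")


def interaction_tests(
    data: pd.DataFrame,
    exposure: str,
    moderators: Sequence[str],
    outcome: str = "frailty",
    covariates: Sequence[str] | None = None,
    weights=None,
    window: float = 8.0,
    unit_scale=None,
) -> dict[str, float]:
    """Wald p-value of the highest-order score x moderator interaction.

    For the frailty outcome the moderators are drawn from {age, sex}
    (score x age x sex is the 3-way term); for mortality, frailty may be
    added (score x age x sex x frailty, a 4-way term). All lower-order
    product terms are included alongside the main effects.

    Returns ``{term_name: p}`` for the single highest-order product term.
    """
    mods = list(moderators)
    if not mods:
        raise DomainError("moderators must be non-empty")
    scale = UNIT_SCALES.get(exposure, 1.0) if unit_scale is None else float(unit_scale)

    if covariates is None:
        covariates = [c for c in BASIC_COVARIATES if c in data.columns]
    covariates = list(covariates)

    need = [exposure, *covariates]
    if outcome == "frailty":
        need.append("frailty_index")
    if outcome == "mortality":
        need += ["time_years", "event"]
    if "frailty" in mods or outcome == "mortality":
        need.append("frailty_index")
    df = data[list(dict.fromkeys([c for c in need if c in data.columns]))].dropna()

    x = df[exposure].astype(float) / scale
    x = x - x.mean()
    modvals = {m: _moderator_values(df, m) for m in mods}
    for m in mods:
        modvals[m] = modvals[m] - modvals[m].mean()

    X = pd.DataFrame(index=df.index)
    X[exposure] = x
    # all product terms of the exposure with non-empty moderator subsets,
    # plus products among moderators, so the top term is a proper interaction
    from itertools import combinations

    for k in range(2, len(mods) + 1):
        for combo in combinations(mods, k):
            X["*".join(combo)] = np.prod([modvals[m] for m in combo], axis=0)
    top_term = None
    for k in range(1, len(mods) + 1):
        for combo in combinations(mods, k):
            name = f"{exposure}*" + "*".join(combo)
            X[name] = x * np.prod([modvals[m] for m in combo], axis=0)
            top_term = name
    cov_cols = [c for c in covariates if c in df.columns]
    if "frailty" in mods:
        cov_cols = [c for c in cov_cols if c != "frailty_index"]
        X["frailty_index"] = modvals["frailty"]
    elif outcome == "mortality" and "frailty_index" in df.columns:
        X["frailty_index"] = df["frailty_index"].astype(float)
    if cov_cols:
        X = pd.concat([X, _encode_covariates(df, cov_cols)], axis=1)
    X = X.loc[:, ~X.columns.duplicated()]

    w = _resolve_weights(df, weights) if weights is not None else None
    if outcome == "frailty":
        y = df["frailty_index"].astype(float)
        Xc = sm.add_constant(X.astype(float), has_constant="add")
        res = sm.OLS(y, Xc).fit() if w is None else sm.WLS(y, Xc, weights=w).fit(cov_type="HC1")
        p = float(res.pvalues[top_term])
    elif outcome == "mortality":
        frame = X.astype(float).copy()
        frame["time_years"] = df["time_years"].to_numpy(dtype=float)
        frame["event"] = df["event"].to_numpy(dtype=int)
        frame["time_years"] = np.minimum(frame["time_years"], window)
        frame["event"] = np.where(df["time_years"].to_numpy(dtype=float) <= window, frame["event"], 0)
        kwargs = {}
        if w is not None:
            frame["_w"] = w
            kwargs = {"weights_col": "_w", "robust": True}
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="time_years", event_col="event", **kwargs)
        p = float(cph.summary.loc[top_term, "p"])
    else:
        raise DomainError(f"outcome must be 'frailty' or 'mortality', got {outcome!r}")
    return {top_term: p}
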