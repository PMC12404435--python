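"""At-vessel survival (AVS) analysis of longline observer records.

Workflow mirroring standard practice for haul-back survival studies:
recode damaged animals as dead, screen covariate collinearity, centre and
scale covariates, fit a candidate set of mixed-effects logistic models with
a calendar-year random intercept, rank by AIC/Akaike weight, screen
AIC-competitive models for informative parameters (85% Wald CIs excluding
zero), and evaluate the selected model by leave-one-out cross-validated AUC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

from . import fixtures
from .mixedlogit import MixedLogit, MixedLogitResults
from .simulate import COVARIATES

__all__ = [
    "TERM_COLUMNS", "ScalingSpec", "ModelSpec", "AVSFit",
    "recode_fates", "screen_collinearity", "scale_covariates",
    "fit_mixed_logistic", "fit_region_model", "fit_sex_model",
    "candidate_model_set", "rank_models", "akaike_weights",
    "informative_parameters", "select_inference_model", "predict_avs",
    "loocv_auc", "auc_score", "records_from_counts",
]

#: Model-formula symbols -> record columns. HD is a synonym for FD
#: (estimated maximum hook/fishing depth) appearing only in interactions.
TERM_COLUMNS = {
    "FL": "fl_cm",
    "ML": "mainline_km",
    "SST": "sst_c",
    "ST": "soak_h",
    "FD": "hook_depth_m",
    "HD": "hook_depth_m",
    "LL": "leader_m",
}

_FATE_CODES = {"alive": 1, "a": 1, "1": 1, "dead": 0, "d": 0, "0": 0,
               "damaged": 0}


def recode_fates(fates) -> pd.Series:
    """Recode haul-back fate labels to binary survival (1 alive, 0 dead).

    Animals recorded as damaged (injured by predation before haul-back) are
    scored dead. Accepts labels {alive, dead, damaged} case-insensitively,
    and 0/1 codes, which pass through.
    """
    s = pd.Series(fates)
    coded = s.astype("string").str.strip().str.lower().map(_FATE_CODES)
    bad = s[coded.isna() & s.notna()]
    if len(bad) or s.isna().any():
        rows = list(s.index[coded.isna()])
        raise ValueError(f"unrecognised fate labels at rows {rows[:20]}")
    return coded.astype(int)


def screen_collinearity(records: pd.DataFrame,
                        threshold: float = 0.70) -> pd.DataFrame:
    """Pairwise Pearson correlations among the six covariates.

    Returns a tidy frame (var1, var2, r, flagged); pairs with |r| above
    the threshold are flagged. A constant covariate yields an undefined
    (NaN) correlation, reported but never flagged.
    """
    cols = [c for c in COVARIATES if c in records.columns]
    if len(records.dropna(subset=cols)) < 3:
        raise ValueError("need at least 3 complete records")
    corr = records[cols].corr()
    rows = []
    for a, b in itertools.combinations(cols, 2):
        r = corr.loc[a, b]
        rows.append((a, b, r, bool(np.abs(r) > threshold)
                     if np.isfinite(r) else False))
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "flagged"])


@dataclass(frozen=True)
class ScalingSpec:
    """Per-covariate centring/scaling constants (sample mean and SD)."""

    means: pd.Series
    sds: pd.Series

    def apply(self, records: pd.DataFrame) -> pd.DataFrame:
        out = records.copy()
        for c in self.means.index:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out

    def invert(self, records: pd.DataFrame) -> pd.DataFrame:
        out = records.copy()
        for c in self.means.index:
            out[c] = out[c] * self.sds[c] + self.means[c]
        return out


def scale_covariates(records: pd.DataFrame,
                     columns=COVARIATES) -> tuple[pd.DataFrame, ScalingSpec]:
    """Centre and scale covariates to mean 0, sample SD 1.

    The scaling spec is retained on the fitted model so that predictions
    can be made from covariates on their natural scales.
    """
    cols = [c for c in columns if c in records.columns]
    means = records[cols].mean()
    sds = records[cols].std(ddof=1)
    zero = sds.index[(sds == 0) | sds.isna()]
    if len(zero):
        raise ValueError(f"zero-variance covariates: {list(zero)}")
    spec = ScalingSpec(means=means, sds=sds)
    return spec.apply(records), spec


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure (plus the year intercept).

    ``terms`` are formula symbols (``FL``, ``SST*ST``, ...); the intercept
    and the year random effect are implicit. ``K`` counts the intercept,
    the slopes and the random-intercept variance.
    """

    terms: tuple[str, ...]
    group: str = "year"

    @property
    def K(self) -> int:
        return len(self.terms) + 2

    @property
    def formula(self) -> str:
        return " + ".join(self.terms) if self.terms else "Null"

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        formula = formula.strip()
        if formula.lower() in ("null", "1", ""):
            return cls(terms=())
        return cls(terms=tuple(t.strip() for t in formula.split("+")))

    def required_columns(self) -> list[str]:
        cols = []
        for term in self.terms:
            for sym in term.split("*"):
                col = TERM_COLUMNS[sym.strip()]
                if col not in cols:
                    cols.append(col)
        return cols

    def design_matrix(self, scaled: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame({"intercept": np.ones(len(scaled))},
                         index=scaled.index)
        for term in self.terms:
            syms = [s.strip() for s in term.split("*")]
            col = scaled[TERM_COLUMNS[syms[0]]].to_numpy(dtype=float)
            for sym in syms[1:]:
                col = col * scaled[TERM_COLUMNS[sym]].to_numpy(dtype=float)
            X[term] = col
        return X


@dataclass
class AVSFit:
    """A fitted AVS model: spec, mixed-logit results and scaling constants."""

    spec: ModelSpec
    results: MixedLogitResults
    scaling: ScalingSpec | None = None

    @property
    def aic(self) -> float:
        return self.results.aic

    @property
    def converged(self) -> bool:
        return self.results.converged

    def summary(self) -> str:
        return f"AVS model: {self.spec.formula}\n" + self.results.summary()


def fit_mixed_logistic(spec: ModelSpec, records: pd.DataFrame,
                       scaling: ScalingSpec | None = None) -> AVSFit:
    """Fit one candidate model on (already scaled) complete-case records.

    With a single year level the model degrades to a fixed-effects logistic
    regression (variance pinned at 0) with a warning.
    """
    X = spec.design_matrix(records)
    y = records["fate"].to_numpy(dtype=float)
    groups = records[spec.group].to_numpy()
    model = MixedLogit(y, X, groups)
    if model.n_groups < 2:
        warnings.warn("single grouping level: fitting fixed-effects "
                      "logistic (random-intercept variance fixed at 0)",
                      UserWarning, stacklevel=2)
        res = model.fit(sigma_fixed=0.0)
    else:
        res = model.fit()
    return AVSFit(spec=spec, results=res, scaling=scaling)


def _categorical_fit(records: pd.DataFrame, column: str,
                     reference: str) -> tuple[AVSFit, list[str]]:
    levels = [lv for lv in pd.unique(records[column]) if pd.notna(lv)]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from "
                         f"{column}")
    others = [lv for lv in levels if lv != reference]
    X = pd.DataFrame({"intercept": np.ones(len(records))},
                     index=records.index)
    for lv in others:
        X[f"{column}[{lv}]"] = (records[column] == lv).astype(float)
    y = records["fate"].to_numpy(dtype=float)
    groups = records["year"].to_numpy()
    model = MixedLogit(y, X, groups)
    if model.n_groups < 2:
        warnings.warn("single grouping level: fitting fixed-effects "
                      "logistic", UserWarning, stacklevel=2)
        res = model.fit(sigma_fixed=0.0)
    else:
        res = model.fit()
    spec = ModelSpec(terms=tuple(f"{column}[{lv}]" for lv in others))
    return AVSFit(spec=spec, results=res), others


def fit_region_model(records: pd.DataFrame,
                     reference: str = "GOM") -> tuple[AVSFit, pd.DataFrame]:
    """Region as a categorical fixed effect plus year random intercept.

    Returns the fit and a per-region table of estimated AVS (inverse-logit
    of the fixed-effect linear predictor at random intercept 0) with 95%
    Wald confidence intervals. A region with a single fate class yields an
    unbounded interval.
    """
    fit, others = _categorical_fit(records, "region", reference)
    res = fit.results
    params = res.params
    cov = res.cov_params
    names = list(params.index)
    rows = []
    z95 = norm.ppf(0.975)
    for region in [reference] + others:
        v = np.zeros(len(names))
        v[names.index("intercept")] = 1.0
        if region != reference:
            v[names.index(f"region[{region}]")] = 1.0
        eta = float(v @ params.to_numpy())
        se = float(np.sqrt(v @ cov[:len(names), :len(names)] @ v))
        rows.append((region, expit(eta), expit(eta - z95 * se),
                     expit(eta + z95 * se)))
    table = pd.DataFrame(rows, columns=["region", "avs", "ci_lower",
                                        "ci_upper"])
    return fit, table


def fit_sex_model(records: pd.DataFrame, reference: str = "F") -> AVSFit:
    """Sex as a categorical fixed effect (reference female) plus year
    random intercept, on records with known sex. Sex-biased survival is
    judged by the 95% CI of the sex coefficient crossing zero."""
    known = records.dropna(subset=["sex"])
    fit, _ = _categorical_fit(known, "sex", reference)
    return fit


def candidate_model_set() -> list[ModelSpec]:
    """The published 35-model candidate set (including the null model)."""
    table = fixtures.model_selection_table()
    specs = [ModelSpec.from_formula(f) for f in table["formula"]]
    for spec, k in zip(specs, table["K"]):
        assert spec.K == int(k), f"K mismatch for {spec.formula}"
    return specs


def akaike_weights(aic: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (dAIC, weights): d_i = AIC_i - min AIC and
    w_i = exp(-d_i/2) / sum_j exp(-d_j/2)."""
    aic = np.asarray(aic, dtype=float)
    delta = aic - np.min(aic)
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def rank_models(fits: list[AVSFit]) -> pd.DataFrame:
    """AIC ranking of candidate fits.

    Non-converged fits carry AIC = +inf and weight 0. Ties in dAIC break
    by smaller K, then by specification order.
    """
    aics = np.array([f.aic for f in fits])
    if not np.isfinite(aics).any():
        raise ValueError("no converged candidate models")
    finite = np.where(np.isfinite(aics), aics, np.inf)
    delta = finite - finite.min()
    w = np.where(np.isfinite(delta), np.exp(-np.where(np.isfinite(delta),
                                                      delta, 0) / 2), 0.0)
    w = w / w.sum()
    table = pd.DataFrame({
        "formula": [f.spec.formula for f in fits],
        "K": [f.spec.K for f in fits],
        "AIC": aics,
        "dAIC": delta,
        "weight": w,
        "fit_index": np.arange(len(fits)),
    })
    return table.sort_values(["dAIC", "K", "fit_index"],
                             kind="stable").reset_index(drop=True)


def informative_parameters(fit: AVSFit, level: float = 0.85) -> pd.Series:
    """Flag each non-intercept term whose Wald CI at ``level`` excludes 0."""
    z = norm.ppf((1.0 + level) / 2.0)
    res = fit.results
    flags = {}
    for name in res.params.index:
        if name == "intercept":
            continue
        lo = res.params[name] - z * res.bse[name]
        hi = res.params[name] + z * res.bse[name]
        flags[name] = bool(lo > 0 or hi < 0)
    return pd.Series(flags, dtype=bool)


def select_inference_model(ranking: pd.DataFrame, fits: list[AVSFit],
                           level: float = 0.85) -> AVSFit:
    """Pick the inference model among AIC-competitive candidates.

    Among models with dAIC <= 2 (in ranking order) return the first whose
    every fixed-effect term is informative at the given level; if none
    qualifies, fall back to the overall lowest-AIC model with a warning.
    """
    if not len(ranking):
        raise ValueError("empty ranking")
    competitive = ranking[ranking["dAIC"] <= 2.0]
    for _, row in competitive.iterrows():
        fit = fits[int(row["fit_index"])]
        flags = informative_parameters(fit, level=level)
        if flags.all():
            return fit
    warnings.warn("no AIC-competitive model has all parameters informative;"
                  " falling back to the lowest-AIC model", UserWarning,
                  stacklevel=2)
    return fits[int(ranking.iloc[0]["fit_index"])]


def predict_avs(fit: AVSFit, covariates: dict[str, float] | pd.DataFrame
                ) -> np.ndarray:
    """Predict AVS probability from covariates on their natural scales.

    Applies the stored scaling, evaluates the fixed-effect linear predictor
    at random intercept 0 and inverse-logit transforms it.
    """
    if fit.scaling is None:
        raise ValueError("fit carries no scaling spec; cannot accept "
                         "natural-scale covariates")
    if isinstance(covariates, dict):
        covariates = pd.DataFrame({k: np.atleast_1d(v)
                                   for k, v in covariates.items()})
    needed = fit.spec.required_columns()
    missing = [c for c in needed if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    scaled = covariates.copy()
    for c in needed:
        scaled[c] = (scaled[c] - fit.scaling.means[c]) / fit.scaling.sds[c]
    X = fit.spec.design_matrix(scaled)
    return fit.results.predict(X.to_numpy())


def auc_score(y: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by the Mann-Whitney rank statistic, ties counted 0.5."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one fate class present")
    r = rankdata(scores)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def loocv_auc(spec: ModelSpec, records: pd.DataFrame, folds: int | None = None,
              seed: int = 0) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validated AUC for one model specification.

    Each record is held out in turn, the model refit on the remainder and
    the held-out record scored; AUC is computed from the out-of-sample
    scores by the rank statistic. ``records`` must already be scaled. For
    large inputs an explicit k-fold mode may be requested via ``folds``.
    """
    y = records["fate"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one fate class present")
    n = len(records)
    if folds is None:
        assignment = np.arange(n)
        n_folds = n
    else:
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(np.arange(n) % folds)
        n_folds = folds
    scores = np.empty(n)
    idx = np.arange(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for fold in range(n_folds):
            hold = assignment == fold
            train = records.iloc[idx[~hold]]
            fit = fit_mixed_logistic(spec, train)
            X = spec.design_matrix(records.iloc[idx[hold]])
            scores[hold] = fit.results.predict(X.to_numpy())
    return auc_score(y, scores), scores


def fit_candidate_set(records: pd.DataFrame,
                      specs: list[ModelSpec] | None = None
                      ) -> tuple[list[AVSFit], pd.DataFrame, ScalingSpec]:
    """Complete-case filter, scale, fit every candidate model and rank.

    Returns (fits, ranking table, scaling spec). Incomplete records (any
    missing covariate) are dropped before scaling, mirroring the
    complete-case convention of observer-data covariate analyses.
    """
    specs = specs if specs is not None else candidate_model_set()
    needed = sorted({c for s in specs for c in s.required_columns()})
    complete = records.dropna(subset=needed + ["fate", "year"])
    scaled, scaling = scale_covariates(complete, columns=needed)
    fits = [fit_mixed_logistic(spec, scaled, scaling) for spec in specs]
    return fits, rank_models(fits), scaling


def records_from_counts(counts: pd.DataFrame, category: str,
                        year: int = 0) -> pd.DataFrame:
    """Expand an alive/dead count table to record-level data.

    Useful for refitting categorical models from published contingency
    tables; all records share one pseudo-year.
    """
    rows = []
    for _, row in counts.iterrows():
        rows.append(pd.DataFrame({
            category: row[category],
            "fate": [1] * int(row["alive"]) + [0] * int(row["dead"]),
            "year": year,
        }))
    return pd.concat(rows, ignore_index=True)
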