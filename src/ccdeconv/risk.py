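"""Cox-based metachronous-metastasis risk modelling and benchmarking.

Implements the survival-analysis stage around a compact gene-expression
signature: building the modelling table (follow-up filter, z-scoring,
one-hot encoding), a univariate Cox screen with FDR control, repeated
k-fold cross-validation of a fixed multivariate signature, nested
cross-validation with L1-penalized (LASSO) Cox feature selection, and
tertile risk stratification with a log-rank test.

Endpoint convention: ``event = 1`` is metachronous metastasis; indolent
patients are right-censored at last follow-up.  Only patients with at
least 100 days of follow-up enter the table.  Cox partial likelihoods use
the Efron approximation for ties throughout (the lifelines default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375
MIN_FOLLOWUP_DAYS = 100.0
DEFAULT_TARGET_SENSITIVITY = 0.878
SIGNATURE_5G = ("FKBP15", "SLC31A1", "CPT2", "PATJ", "CALR")


@dataclass
class RiskFeatureTable:
    """Modelling-ready survival table.

    ``data`` holds time_months, event and the encoded but *unscaled*
    features (cross-validation re-fits scaling on training folds only);
    ``scaling`` stores the full-table mean/sd per continuous feature for
    scoring held-out data outside CV; ``reference_levels`` records the
    dropped level of each one-hot-encoded categorical.
    """

    data: pd.DataFrame
    continuous: list[str]
    scaling: pd.DataFrame
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time_months", "event")]

    def scaled(self) -> pd.DataFrame:
        out = self.data.copy()
        for col in self.continuous:
            out[col] = (out[col] - self.scaling.loc[col, "mean"]) / self.scaling.loc[col, "sd"]
        return out


@dataclass
class CVReport:
    """Cross-validation metrics per fold/repeat with aggregate summaries."""

    per_fold: pd.DataFrame
    per_repeat: pd.DataFrame
    summary: pd.DataFrame  # index metric, columns mean/sd
    selection_frequency: pd.Series | None = None


def build_feature_table(
    features: pd.DataFrame,
    annotation: pd.DataFrame,
    min_followup_days: float = MIN_FOLLOWUP_DAYS,
) -> RiskFeatureTable:
    """Filter, encode and summarize features for survival modelling.

    Parameters
    ----------
    features
        Samples x features; numeric columns are treated as continuous,
        object/category columns are one-hot encoded with the first level
        (alphabetical) as the recorded, dropped reference.
    annotation
        Must provide ``time_months`` and ``event`` per sample.  Samples
        with follow-up under ``min_followup_days`` or any missing value
        are excluded (counts logged).
    """
    if not {"time_months", "event"} <= set(annotation.columns):
        raise ValueError("annotation must provide time_months and event")
    shared = features.index.intersection(annotation.index)
    df = features.loc[shared].copy()
    df["time_months"] = annotation.loc[shared, "time_months"]
    df["event"] = annotation.loc[shared, "event"]

    n0 = len(df)
    df = df[df["time_months"] * DAYS_PER_MONTH >= min_followup_days]
    n_short = n0 - len(df)
    df = df.dropna()
    n_missing = n0 - n_short - len(df)
    if n_short or n_missing:
        logger.info("build_feature_table: excluded %d samples (<%g days follow-up), "
                    "%d with missing values", n_short, min_followup_days, n_missing)
    if df.empty:
        raise ValueError("all samples excluded by the follow-up/missing-value filters")

    reference_levels: dict[str, str] = {}
    encoded = {}
    continuous: list[str] = []
    for col in features.columns:
        if col not in df.columns:
            continue
        if pd.api.types.is_numeric_dtype(df[col]):
            continuous.append(col)
            encoded[col] = df[col].astype(float)
        else:
            levels = sorted(df[col].astype(str).unique())
            reference_levels[col] = levels[0]
            for lvl in levels[1:]:
                encoded[f"{col}={lvl}"] = (df[col].astype(str) == lvl).astype(float)
    table = pd.DataFrame(encoded, index=df.index)
    table["time_months"] = df["time_months"].astype(float)
    table["event"] = df["event"].astype(int)

    scaling = pd.DataFrame(
        {"mean": table[continuous].mean(), "sd": table[continuous].std(ddof=0)}
    )
    degenerate = scaling.index[scaling["sd"] == 0]
    if len(degenerate):
        logger.warning("build_feature_table: %d constant continuous features", len(degenerate))
        scaling.loc[degenerate, "sd"] = 1.0
    return RiskFeatureTable(table, continuous, scaling, reference_levels)


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df[covariates + ["time_months", "event"]],
            duration_col="time_months", event_col="event")
    return cph


def _oof_scores(cph: CoxPHFitter, train: pd.DataFrame, test: pd.DataFrame,
                covariates: list[str]) -> np.ndarray:
    """Held-out linear predictors, standardized by the training-set predictor
    distribution so scores pooled across folds are on one scale (the linear
    predictor of a Cox fit has an arbitrary per-fold location)."""
    lp_train = cph.predict_log_partial_hazard(train[covariates]).to_numpy()
    lp_test = cph.predict_log_partial_hazard(test[covariates]).to_numpy()
    sd = lp_train.std()
    return (lp_test - lp_train.mean()) / (sd if sd > 0 else 1.0)


def univariate_cox_screen(table: RiskFeatureTable) -> pd.DataFrame:
    """One proportional-hazards fit per feature, BH-corrected, ranked by p.

    Continuous features are standardized so hazard ratios are per 1 SD;
    one-hot indicators give the hazard vs the recorded reference level.
    Non-converging fits are flagged, not fatal.
    """
    from .de import bh_adjust

    df = table.scaled()
    if df["event"].sum() < 1:
        raise ValueError("no events in feature table")
    rows = []
    for feat in table.features:
        try:
            cph = _fit_cox(df, [feat])
            s = cph.summary.loc[feat]
            rows.append((feat, s["coef"], s["exp(coef)"], s["p"], True))
        except Exception as exc:  # noqa: BLE001 - convergence failures are data-dependent
            logger.warning("univariate_cox_screen: %r did not converge: %s", feat, exc)
            rows.append((feat, np.nan, np.nan, np.nan, False))
    out = pd.DataFrame(rows, columns=["feature", "coef", "hr", "p", "converged"])
    out = out.set_index("feature")
    ok = out["p"].notna()
    out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"])
    return out.sort_values("p")


def _scale_train_test(
    train: pd.DataFrame, test: pd.DataFrame, continuous: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    train, test = train.copy(), test.copy()
    for col in continuous:
        mu, sd = train[col].mean(), train[col].std(ddof=0)
        sd = sd if sd > 0 else 1.0
        train[col] = (train[col] - mu) / sd
        test[col] = (test[col] - mu) / sd
    return train, test


def specificity_at_sensitivity(
    y_true: np.ndarray, scores: np.ndarray, target_sensitivity: float
) -> tuple[float, float]:
    """(sensitivity, specificity) at the smallest score threshold whose
    sensitivity reaches the target, on the given scores."""
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    idx = np.flatnonzero(tpr >= target_sensitivity)
    if idx.size == 0:  # only reachable when no positive exists
        return float("nan"), float("nan")
    i = idx[0]
    return float(tpr[i]), float(1.0 - fpr[i])


def _stratified_folds(
    events: np.ndarray, k: int, rng: np.random.Generator, max_retries: int = 20
):
    """Event-stratified k-fold index pairs; folds without events are redrawn."""
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        folds = list(skf.split(np.zeros_like(events), events))
        if all(events[test].sum() > 0 for _, test in folds):
            if attempt:
                logger.info("fold draw retried %d time(s) to ensure events per fold", attempt)
            return folds
    raise ValueError("could not draw folds with at least one event each")


def repeated_cv_evaluate(
    table: RiskFeatureTable,
    signature: list[str] | tuple[str, ...],
    k: int = 5,
    repeats: int = 100,
    target_sensitivity: float = DEFAULT_TARGET_SENSITIVITY,
    seed: int = 0,
) -> CVReport:
    """Repeated k-fold cross-validation of a fixed multivariate Cox signature.

    Per repeat, samples are split into ``k`` event-stratified folds; a
    multivariate Cox model is fit on k-1 folds (feature scaling refit on
    the training folds only) and linear risk scores computed on the held-out
    fold.  AUC (event vs censored), sensitivity and
    specificity-at-target-sensitivity are computed on the repeat's pooled
    out-of-fold scores; c-index is per fold on held-out data; AIC and the
    likelihood-ratio p-value describe the training fits.
    """
    signature = list(signature)
    missing = [g for g in signature if g not in table.features]
    if missing:
        raise ValueError(f"signature features absent from table: {missing}")
    if k < 2:
        raise ValueError("k must be >= 2")
    data = table.data
    events = data["event"].to_numpy()
    rng = np.random.default_rng(seed)

    fold_rows, repeat_rows = [], []
    for rep in range(repeats):
        folds = _stratified_folds(events, k, rng)
        oof_scores = np.full(len(data), np.nan)
        for fold_i, (train_idx, test_idx) in enumerate(folds):
            train, test = data.iloc[train_idx], data.iloc[test_idx]
            train, test = _scale_train_test(train, test,
                                            [c for c in table.continuous if c in signature])
            cph = _fit_cox(train, signature)
            lp = _oof_scores(cph, train, test, signature)
            oof_scores[test_idx] = lp
            cidx = concordance_index(test["time_months"], -lp, test["event"])
            fold_rows.append({
                "repeat": rep, "fold": fold_i,
                "c_index": cidx,
                "aic": cph.AIC_partial_,
                "lr_p": cph.log_likelihood_ratio_test().p_value,
            })
        auc = roc_auc_score(events, oof_scores)
        sens, spec = specificity_at_sensitivity(events, oof_scores, target_sensitivity)
        repeat_rows.append({"repeat": rep, "auc": auc, "sensitivity": sens,
                            "specificity_at_sensitivity": spec})

    per_fold = pd.DataFrame(fold_rows)
    per_repeat = pd.DataFrame(repeat_rows)
    metrics = {
        "auc": per_repeat["auc"],
        "sensitivity": per_repeat["sensitivity"],
        "specificity_at_sensitivity": per_repeat["specificity_at_sensitivity"],
        "c_index": per_fold["c_index"],
        "aic": per_fold["aic"],
        "lr_p": per_fold["lr_p"],
    }
    summary = pd.DataFrame(
        {"mean": {m: v.mean() for m, v in metrics.items()},
         "sd": {m: v.std(ddof=1) for m, v in metrics.items()}}
    )
    return CVReport(per_fold, per_repeat, summary)


def _select_features_coxnet(
    train: pd.DataFrame, features: list[str], inner_k: int, rng: np.random.Generator
) -> list[str]:
    """LASSO-Cox feature selection with the penalty chosen by inner CV."""
    x = train[features].to_numpy(dtype=float)
    y = Surv.from_arrays(train["event"].to_numpy(dtype=bool),
                         train["time_months"].to_numpy(dtype=float))
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=30, alpha_min_ratio=0.01)
    try:
        path.fit(x, y)
    except Exception as exc:  # noqa: BLE001
        logger.warning("coxnet path fit failed (%s); selecting no features", exc)
        return []
    alphas = path.alphas_
    events = train["event"].to_numpy()
    folds = _stratified_folds(events, inner_k, rng)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for tr, va in folds:
        try:
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
            m.fit(x[tr], y[tr])
        except Exception:  # noqa: BLE001 - inner refit may fail on tiny folds
            continue
        for ai, alpha in enumerate(alphas):
            try:
                lp = m.predict(x[va], alpha=alpha)
                scores[ai] += concordance_index(train["time_months"].to_numpy()[va],
                                                -lp, events[va])
                counts[ai] += 1
            except Exception:  # noqa: BLE001
                continue
    valid = counts > 0
    if not valid.any():
        return []
    best_alpha = alphas[np.flatnonzero(valid)[np.argmax(scores[valid] / counts[valid])]]
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[best_alpha])
    with warnings.catch_warnings():
        # an empty selection at a strong penalty is a legitimate outcome here
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        final.fit(x, y)
    coefs = final.coef_[:, 0]
    return [f for f, c in zip(features, coefs) if c != 0]


def nested_cv_lasso(
    table: RiskFeatureTable,
    k: int = 5,
    repeats: int = 10,
    inner_k: int = 3,
    target_sensitivity: float = DEFAULT_TARGET_SENSITIVITY,
    seed: int = 0,
) -> CVReport:
    """Nested cross-validation with per-fold LASSO-Cox feature selection.

    Within each outer training set, an L1-penalized Cox model (penalty
    chosen by inner ``inner_k``-fold CV on concordance) selects features;
    an unpenalized Cox model refit on the selected features scores the
    outer test fold.  Selection frequencies are aggregated across all
    outer folds and repeats.  A fold with an empty selection contributes a
    constant (uninformative) score, recorded as AUC 0.5.
    """
    data = table.data
    if len(data) < 2 * k:
        raise ValueError("need at least 2*k samples for nested CV")
    features = table.features
    events = data["event"].to_numpy()
    rng = np.random.default_rng(seed)
    selection_counts = pd.Series(0, index=features, dtype=float)
    n_selection_rounds = 0

    fold_rows, repeat_rows = [], []
    for rep in range(repeats):
        folds = _stratified_folds(events, k, rng)
        oof_scores = np.zeros(len(data))
        for fold_i, (train_idx, test_idx) in enumerate(folds):
            train, test = data.iloc[train_idx], data.iloc[test_idx]
            train, test = _scale_train_test(train, test, table.continuous)
            selected = _select_features_coxnet(train, features, inner_k, rng)
            selection_counts[selected] += 1
            n_selection_rounds += 1
            if selected:
                cph = _fit_cox(train, selected)
                lp = _oof_scores(cph, train, test, selected)
            else:
                logger.info("nested_cv_lasso: empty selection in repeat %d fold %d", rep, fold_i)
                lp = np.zeros(len(test))
            oof_scores[test_idx] = lp
            fold_rows.append({"repeat": rep, "fold": fold_i, "n_selected": len(selected)})
        auc = roc_auc_score(events, oof_scores)
        sens, spec = specificity_at_sensitivity(events, oof_scores, target_sensitivity)
        repeat_rows.append({"repeat": rep, "auc": auc, "sensitivity": sens,
                            "specificity_at_sensitivity": spec})

    per_repeat = pd.DataFrame(repeat_rows)
    summary = pd.DataFrame({
        "mean": {"auc": per_repeat["auc"].mean()},
        "sd": {"auc": per_repeat["auc"].std(ddof=1)},
    })
    freq = selection_counts / max(n_selection_rounds, 1)
    return CVReport(pd.DataFrame(fold_rows), per_repeat, summary,
                    selection_frequency=freq.sort_values(ascending=False))


def tertile_logrank(
    scores: pd.Series, survival: pd.DataFrame
) -> tuple[pd.Series, float, float, pd.DataFrame]:
    """Stratify samples into risk-score tertiles and run a 3-group log-rank test.

    Tertile boundaries are the 1/3 and 2/3 score quantiles (linear
    interpolation); samples at a boundary value go to the lower group,
    which is deterministic (boundary ties are logged).  Returns the group
    assignment (low/medium/high), the log-rank chi-square, its p-value and
    a number-at-risk table over a 12-month grid.
    """
    scores = scores.sort_index()
    if scores.nunique() < 3:
        raise ValueError("need at least 3 distinct score values for tertiles")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    if (scores == q1).any() or (scores == q2).any():
        logger.info("tertile_logrank: ties at a tertile boundary assigned to the lower group")
    groups = pd.Series(
        np.where(scores <= q1, "low", np.where(scores <= q2, "medium", "high")),
        index=scores.index, name="risk_group",
    )
    surv = survival.loc[scores.index]
    res = multivariate_logrank_test(surv["time_months"], groups, surv["event"])

    grid = np.arange(0, surv["time_months"].max() + 12, 12)
    at_risk = pd.DataFrame(
        {g: [(surv.loc[groups == g, "time_months"] >= t).sum() for t in grid]
         for g in ("low", "medium", "high")},
        index=pd.Index(grid, name="time_months"),
    )
    return groups, float(res.test_statistic), float(res.p_value), at_risk
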