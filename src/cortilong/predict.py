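"""Individual-level conversion prediction from percent thickness change.

Logistic regression predicts conversion among CHR subjects (controls are
excluded) from the left-ROI percent-change statistic plus covariates. Four
nested predictor sets are compared:

    full        pc + age + age^2 + sex + scanner
    pc_scanner  pc + scanner
    pc_only     pc
    demo_only   age + age^2 + sex

Classification accuracy is the in-sample area under the ROC curve (AUC),
with a nonparametric case-resampling bootstrap (subjects resampled with
replacement, model refit, AUC recomputed per replicate) providing a
percentile 95% confidence interval. AUC equals the Mann-Whitney concordance
probability (ties counted 1/2), so any strictly monotone transform of the
model scores — fitted probability or linear predictor — gives the same AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "PREDICTOR_SETS",
    "PredictionModel",
    "ROCResult",
    "prediction_frame",
    "fit_logistic",
    "roc_auc",
    "bootstrap_auc_ci",
    "compare_predictor_sets",
]

PREDICTOR_SETS = ("full", "pc_scanner", "pc_only", "demo_only")


@dataclass
class PredictionModel:
    predictor_set: str
    columns: list[str]
    params: np.ndarray
    bse: np.ndarray
    fitted_prob: np.ndarray
    subject_ids: np.ndarray
    labels: np.ndarray
    separation: bool = False


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_replicates: int = 0
    n_skipped: int = 0
    seed: int | None = None
    degenerate: bool = False
    bootstrap_auc: np.ndarray | None = field(default=None, repr=False)

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tpr

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


def prediction_frame(pc_table: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per CHR subject with pc, covariates and the conversion flag."""
    first = (cohort.sort_values(["subject_id", "months_from_baseline"],
                                kind="stable")
             .groupby("subject_id", sort=True).first())
    df = pc_table.merge(
        first[["age_first_scan", "sex", "scanner", "converted"]],
        left_on="subject_id", right_index=True, how="left")
    df = df[df["group"].isin(["CHR-NC", "CHR-C"])].reset_index(drop=True)
    df["converted"] = df["converted"].astype(int)
    return df


def _design(df: pd.DataFrame, predictor_set: str):
    if predictor_set not in PREDICTOR_SETS:
        raise ValueError(f"unknown predictor set {predictor_set!r}")
    age = df["age_first_scan"].to_numpy(float)
    age_c = age - age.mean()
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    if predictor_set != "demo_only":
        cols["pc"] = df["pc"].to_numpy(float)
    if predictor_set in ("full", "demo_only"):
        cols["age"] = age_c
        cols["age2"] = age_c ** 2
        cols["sex_M"] = (df["sex"].astype(str) == "M").astype(float).to_numpy()
    if predictor_set in ("full", "pc_scanner"):
        for s in np.sort(df["scanner"].astype(str).unique())[1:]:
            cols[f"scanner_{s}"] = (df["scanner"].astype(str) == s
                                    ).astype(float).to_numpy()
    return np.column_stack(list(cols.values())), list(cols)


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Indices of a maximal linearly independent column subset (greedy, in
    the original column order)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(X).max())) \
                == len(keep) + 1:
            keep.append(j)
    return keep


def fit_logistic(
    pc_table: pd.DataFrame,
    cohort: pd.DataFrame,
    predictor_set: str = "full",
) -> PredictionModel:
    """Maximum-likelihood logistic fit of conversion on the predictor set.

    Deterministic Newton optimisation started at zero. Perfect or
    quasi-perfect separation is detected and flagged (coefficients are still
    reported, with a warning). Rejects single-class outcomes.
    """
    import statsmodels.api as sm

    df = prediction_frame(pc_table, cohort)
    y = df["converted"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("conversion outcome has a single class")
    X, names = _design(df, predictor_set)
    # degenerate predictors (e.g. a constant pc duplicating the intercept)
    # are dropped from the fit and reported with a zero coefficient
    keep = _independent_columns(X)
    dropped = [n for i, n in enumerate(names) if i not in keep]
    if dropped:
        warnings.warn(f"dropping linearly dependent predictors {dropped}",
                      RuntimeWarning, stacklevel=2)
    Xf = X[:, keep]
    separation = False
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, Xf).fit(method="newton", disp=0, maxiter=100)
        except Exception:
            # fall back to a damped optimiser when Newton breaks down under
            # separation; results are still flagged
            separation = True
            fit = sm.Logit(y, Xf).fit(method="bfgs", disp=0, maxiter=500)
        for w in wlist:
            if "separation" in str(w.message).lower() \
                    or "Maximum Likelihood optimization failed" in str(w.message):
                separation = True
        with np.errstate(over="ignore"):
            prob = np.asarray(fit.predict(Xf))
    if separation:
        warnings.warn("(quasi-)separation detected in logistic fit; "
                      "coefficients are unreliable", RuntimeWarning,
                      stacklevel=2)
    params = np.zeros(len(names))
    bse = np.full(len(names), np.nan)
    params[keep] = np.asarray(fit.params)
    bse[keep] = np.asarray(fit.bse)
    eps = 1e-12
    return PredictionModel(
        predictor_set=predictor_set, columns=names,
        params=params, bse=bse,
        fitted_prob=np.clip(prob, eps, 1 - eps),
        subject_ids=df["subject_id"].to_numpy(), labels=y,
        separation=separation,
    )


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC curve and AUC.

    The ROC is traced over all distinct score thresholds, AUC by the
    trapezoidal rule; with ties this equals the Mann-Whitney concordance
    count (ties 1/2) divided by n1*n0. Endpoints are exactly (0,0) and
    (1,1). Rejects one-class label vectors.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr,
                     auc=float(roc_auc_score(labels, scores)))


def bootstrap_auc_ci(
    pc_table: pd.DataFrame,
    cohort: pd.DataFrame,
    predictor_set: str = "full",
    replicates: int = 10_000,
    seed: int = 0,
    stratified: bool = False,
) -> ROCResult:
    """In-sample AUC with a case-resampling bootstrap percentile 95% CI.

    Subjects are resampled with replacement (optionally stratified by
    outcome class), the logistic model is refit on each resample and its
    in-sample AUC recorded; the CI is the 2.5/97.5 percentile of the
    replicate distribution. Replicates whose resample contains a single
    outcome class cannot produce an AUC and are skipped (counted); more
    than 20% skipped aborts with a diagnostic. Deterministic given ``seed``.
    """
    import statsmodels.api as sm

    model = fit_logistic(pc_table, cohort, predictor_set)
    base = roc_auc(model.fitted_prob, model.labels)
    df = prediction_frame(pc_table, cohort)
    y = df["converted"].to_numpy()
    X, _ = _design(df, predictor_set)
    X = X[:, _independent_columns(X)]
    n = len(df)
    rng = np.random.default_rng(seed)
    aucs = []
    skipped = 0
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    for _ in range(replicates):
        if stratified:
            idx = np.concatenate([rng.choice(pos, pos.size, replace=True),
                                  rng.choice(neg, neg.size, replace=True)])
        else:
            idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            skipped += 1
            continue
        Xb = X[idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yb, Xb).fit(method="newton", disp=0, maxiter=50)
                pb = np.asarray(fit.predict(Xb))
            if not np.isfinite(pb).all():
                skipped += 1
                continue
            aucs.append(roc_auc_score(yb, pb))
        except Exception:
            skipped += 1
    if skipped > 0.2 * replicates:
        raise ValueError(
            f"{skipped}/{replicates} bootstrap replicates were degenerate "
            "(outcome class too rare for case resampling)")
    aucs = np.asarray(aucs)
    degenerate = aucs.size < 2
    if aucs.size == 0:
        lo = hi = base.auc
    elif degenerate:
        lo = hi = float(aucs[0])
        warnings.warn("single usable bootstrap replicate; CI is degenerate",
                      RuntimeWarning, stacklevel=2)
    else:
        lo, hi = np.percentile(aucs, [2.5, 97.5])
    return ROCResult(fpr=base.fpr, tpr=base.tpr, thresholds=base.thresholds,
                     auc=base.auc, ci_low=float(lo), ci_high=float(hi),
                     n_replicates=int(aucs.size), n_skipped=skipped,
                     seed=seed, degenerate=degenerate, bootstrap_auc=aucs)


def compare_predictor_sets(
    pc_table: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """In-sample AUC for the four nested predictor sets on the same
    subjects, ordered by descending AUC."""
    rows = []
    for ps in PREDICTOR_SETS:
        model = fit_logistic(pc_table, cohort, ps)
        rows.append({"predictor_set": ps,
                     "auc": roc_auc(model.fitted_prob, model.labels).auc,
                     "n": model.labels.size,
                     "separation": model.separation})
    return (pd.DataFrame(rows)
            .sort_values("auc", ascending=False, kind="stable")
            .reset_index(drop=True))
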