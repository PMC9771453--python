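"""Cognitive age prediction and the Cognitive Maturity Index (CMI).

Chronological age (years) is regressed on the four standardized latent
factor scores with elastic-net regularization (alpha = 0 ridge, 0.5 elastic
net, 1 lasso) over a log-spaced lambda path.  Hyperparameters are chosen by
leave-one-out cross-validation within a training split that keeps every wave
of a participant on the same side; the held-out split provides the reported
R^2 and mean absolute error.  The CMI of a person-wave is the gap between
model-predicted cognitive age and chronological age; by default a positive
CMI marks cognitive maturity in advance of the sample age norm.

Cross-validation detail: the leave-out unit is the *participant* (all of
their waves leave together) to avoid within-person leakage; row-level
folds are available via ``loocv_unit='row'``.  For ridge the fold errors are
computed with the exact closed-form block hat-matrix identity, holding the
penalty fixed on the absolute scale across folds; for alpha > 0 each fold is
refit explicitly along the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import enet_path

MONTHS_PER_YEAR = 12.0

DEFAULT_CMI_COVARIATES = (
    "bmi",
    "pds",
    "bas_d",
    "iq",
    "dusi_substance_use",
    "dusi_health_risk",
    "dusi_violence_risk",
    "ses",
    "bis",
    "bas_fs",
    "bas_rr",
)


@dataclass(frozen=True)
class AgeModelConfig:
    alphas: tuple[float, ...] = (0.0, 0.5, 1.0)
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    split_fraction: float = 0.5
    loocv_unit: str = "participant"
    seed: int = 0

    def __post_init__(self):
        if any(not (0.0 <= a <= 1.0) for a in self.alphas):
            raise ValueError("alpha values must lie in [0, 1]")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.loocv_unit not in ("participant", "row"):
            raise ValueError("loocv_unit must be 'participant' or 'row'")


@dataclass
class AgeModelFit:
    alpha: float
    lam: float
    coef: pd.Series  # on the (train-)standardized predictor scale
    intercept: float
    columns: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    cv_curve: pd.DataFrame  # alpha, lambda, cv_mse, cv_r2
    train_participants: list
    test_participants: list
    test_r2: float
    test_mae_months: float
    test_n: int
    train_n: int


def _ridge_solve(Xs: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """Minimize ||y - b0 - Xs b||^2 + penalty * ||b||^2 (intercept free)."""
    n, k = Xs.shape
    X1 = np.column_stack([np.ones(n), Xs])
    A = np.diag(np.concatenate([[0.0], np.full(k, penalty)]))
    return np.linalg.solve(X1.T @ X1 + A, X1.T @ y)


def ridge_loocv_mse(
    Xs: np.ndarray, y: np.ndarray, lam: float, groups: np.ndarray
) -> float:
    """Exact leave-one-group-out CV mean squared error for ridge.

    The penalty matrix is held fixed at n_train * lam (glmnet's objective
    scaled to the absolute level of the full training sample), for which the
    block hat-matrix identity e_g = (I - H_gg)^-1 r_g is exact.
    """
    n, k = Xs.shape
    X1 = np.column_stack([np.ones(n), Xs])
    A = np.diag(np.concatenate([[0.0], np.full(k, n * lam)]))
    Sinv = np.linalg.inv(X1.T @ X1 + A)
    beta = Sinv @ (X1.T @ y)
    resid = y - X1 @ beta
    sse = 0.0
    for g in np.unique(groups):
        ix = np.flatnonzero(groups == g)
        Hgg = X1[ix] @ Sinv @ X1[ix].T
        e = np.linalg.solve(np.eye(len(ix)) - Hgg, resid[ix])
        sse += float(e @ e)
    return sse / n


def _enet_loocv_mse(
    Xs: np.ndarray, y: np.ndarray, alpha: float, lambdas: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Explicit leave-one-group-out refits along the lambda path (alpha > 0)."""
    n = len(y)
    sse = np.zeros(len(lambdas))
    for g in np.unique(groups):
        test = groups == g
        Xtr, ytr = Xs[~test], y[~test]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        _, coefs, _ = enet_path(Xtr - xm, ytr - ym, l1_ratio=alpha, alphas=lambdas)
        pred = (Xs[test] - xm) @ coefs + ym  # (n_test, n_lambda)
        sse += ((y[test, None] - pred) ** 2).sum(axis=0)
    return sse / n


def _lambda_path(Xs: np.ndarray, y: np.ndarray, alpha: float, cfg: AgeModelConfig) -> np.ndarray:
    yc = y - y.mean()
    a = max(alpha, 1e-3)  # ridge surrogate for the path endpoint
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / (len(y) * a))
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def split_participants(ids: np.ndarray, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random participant-level split; every wave of a participant stays on
    one side."""
    uniq = np.unique(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    n_train = int(round(fraction * len(uniq)))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def fit_regularized_age_model(
    scores: pd.DataFrame, ages: pd.Series, config: AgeModelConfig | None = None
) -> AgeModelFit:
    """Select (alpha, lambda) by grouped LOOCV on the training split, refit,
    and evaluate on the held-out split.

    ``scores`` must be indexed by (participant_id, wave); rows with any
    missing score are dropped.  Selection follows the minimum lambda at the
    highest cross-validated R^2.
    """
    config = config or AgeModelConfig()
    d = scores.copy()
    d["__age"] = ages
    d = d.dropna()
    cols = [c for c in scores.columns]
    pid = d.index.get_level_values(0).to_numpy()

    train_ids, test_ids = split_participants(pid, config.split_fraction, config.seed)
    tr = np.isin(pid, train_ids)
    te = ~tr
    if tr.sum() < 20:
        raise ValueError(f"training split has {int(tr.sum())} person-waves; need >= 20")
    y_tr = d.loc[tr, "__age"].to_numpy(dtype=float)
    y_te = d.loc[te, "__age"].to_numpy(dtype=float)
    for name, yy in (("train", y_tr), ("test", y_te)):
        if len(yy) == 0 or np.var(yy) == 0:
            raise ValueError(f"degenerate age variance in {name} split")

    X = d[cols].to_numpy(dtype=float)
    xm = X[tr].mean(axis=0)
    xs = X[tr].std(ddof=1, axis=0)
    if np.any(xs == 0):
        raise ValueError("a predictor is constant on the training split")
    Xs = (X - xm) / xs

    groups = pid[tr] if config.loocv_unit == "participant" else np.arange(int(tr.sum()))
    var_tr = float(np.var(y_tr, ddof=1))

    records = []
    for alpha in config.alphas:
        lambdas = _lambda_path(Xs[tr], y_tr, alpha, config)
        if alpha == 0.0:
            mses = np.array([ridge_loocv_mse(Xs[tr], y_tr, lam, groups) for lam in lambdas])
        else:
            mses = _enet_loocv_mse(Xs[tr], y_tr, alpha, lambdas, groups)
        for lam, mse in zip(lambdas, mses):
            records.append({"alpha": alpha, "lambda": lam, "cv_mse": mse, "cv_r2": 1.0 - mse / var_tr})
    cv_curve = pd.DataFrame(records)

    best_r2 = cv_curve["cv_r2"].max()
    at_best = cv_curve[cv_curve["cv_r2"] >= best_r2 - 1e-12]
    row = at_best.loc[at_best["lambda"].idxmin()]  # minimum lambda at the highest R^2
    alpha_hat, lam_hat = float(row["alpha"]), float(row["lambda"])

    if alpha_hat == 0.0:
        b = _ridge_solve(Xs[tr], y_tr, len(y_tr) * lam_hat)
        intercept, coef = float(b[0]), b[1:]
    else:
        xm2, ym2 = Xs[tr].mean(axis=0), y_tr.mean()
        _, coefs, _ = enet_path(
            Xs[tr] - xm2, y_tr - ym2, l1_ratio=alpha_hat, alphas=[lam_hat])
        coef = coefs[:, 0]
        intercept = float(ym2 - xm2 @ coef)

    pred_te = intercept + Xs[te] @ coef
    err = y_te - pred_te
    test_r2 = float(1.0 - np.mean(err**2) / np.var(y_te, ddof=1))
    test_mae_months = float(np.mean(np.abs(err)) * MONTHS_PER_YEAR)

    return AgeModelFit(
        alpha=alpha_hat,
        lam=lam_hat,
        coef=pd.Series(coef, index=cols),
        intercept=intercept,
        columns=cols,
        feature_means=xm,
        feature_sds=xs,
        cv_curve=cv_curve,
        train_participants=list(train_ids),
        test_participants=list(test_ids),
        test_r2=test_r2,
        test_mae_months=test_mae_months,
        test_n=int(te.sum()),
        train_n=int(tr.sum()),
    )


def predict_age(fit: AgeModelFit, scores: pd.DataFrame) -> pd.Series:
    """Predicted cognitive age (years) for each person-wave with complete
    scores; standardization uses the training-split moments."""
    if list(scores.columns) != fit.columns:
        raise ValueError(f"score columns {list(scores.columns)} do not match training columns {fit.columns}")
    X = scores.to_numpy(dtype=float)
    Xs = (X - fit.feature_means) / fit.feature_sds
    pred = fit.intercept + Xs @ fit.coef.to_numpy()
    pred[np.isnan(X).any(axis=1)] = np.nan
    return pd.Series(pred, index=scores.index, name="predicted_age")


@dataclass
class CMITable:
    table: pd.DataFrame  # observed_age, predicted_age, cmi
    sign_convention: str
    correlations: pd.DataFrame | None = None
    note: str = field(
        default="Pearson correlations over person-waves; repeated measures per participant "
        "are not adjusted for (clustering caveat)."
    )


def compute_cmi(
    predicted: pd.Series, observed: pd.Series, sign_convention: str = "predicted_minus_observed"
) -> CMITable:
    """CMI per person-wave.

    ``predicted_minus_observed`` (default): positive CMI = cognitively
    advanced relative to the sample growth curve.
    ``observed_minus_predicted``: the reversed subtraction order.
    """
    if sign_convention not in ("predicted_minus_observed", "observed_minus_predicted"):
        raise ValueError("unknown sign_convention")
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed must align")
    gap = predicted - observed
    if sign_convention == "observed_minus_predicted":
        gap = -gap
    table = pd.DataFrame(
        {"observed_age": observed, "predicted_age": predicted, "cmi": gap}
    )
    return CMITable(table=table, sign_convention=sign_convention)


def correlate_cmi(
    cmi: CMITable, cohort: pd.DataFrame, covariates: tuple[str, ...] = DEFAULT_CMI_COVARIATES
) -> pd.DataFrame:
    """Pearson r (two-sided p) between CMI and each covariate over
    person-waves.  Constant covariates are reported with missing r."""
    cohort_ix = cohort.set_index(["participant_id", "wave"]) if "participant_id" in cohort.columns else cohort
    rows = []
    for cov in covariates:
        if cov not in cohort_ix.columns:
            rows.append({"covariate": cov, "r": np.nan, "p": np.nan, "n": 0})
            continue
        joined = pd.concat([cmi.table["cmi"], cohort_ix[cov].astype(float)], axis=1, join="inner").dropna()
        if len(joined) < 3 or joined[cov].std() == 0:
            rows.append({"covariate": cov, "r": np.nan, "p": np.nan, "n": len(joined)})
            continue
        r, p = pearsonr(joined["cmi"], joined[cov])
        rows.append({"covariate": cov, "r": float(r), "p": float(p), "n": len(joined)})
    out = pd.DataFrame(rows)
    cmi.correlations = out
    return out
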