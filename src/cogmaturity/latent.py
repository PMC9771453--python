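"""Confirmatory factor analysis and structural equation models by FIML.

The measurement model is x = mu + Lambda eta + eps with eta ~ N(0, Psi),
eps ~ N(0, Theta); Theta is diagonal plus explicitly freed residual
covariances.  Factors are identified by fixing their (disturbance) variances
to one — the "standardized factors" convention — leaving every loading free.
The structural extension replaces Psi by (I - B)^-1 Phi (I - B)^-T for a
matrix B of directed, acyclic regression paths between factors.

Estimation maximizes the full-information maximum-likelihood (FIML)
casewise objective: rows are grouped by missingness pattern and each pattern
contributes the multivariate-normal log-likelihood of its observed
sub-vector.  No imputation is performed.  The analytic gradient is used with
L-BFGS-B; residual and disturbance variances are optimized on the log scale
with a floor at 1e-6 (Heywood cases hit the boundary and raise a warning),
and factor correlations pass through tanh to stay inside (-1, 1).

Model chi-square is measured against the saturated multivariate-normal model
(fitted by EM when data are incomplete) and the usual incremental indices
(RMSEA, CFI, TLI) are referenced against the null model with all loadings
fixed to zero and free indicator variances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2, norm

from .scoring import IndicatorMatrix

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-6
_TANH_BOUND = 6.0


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementSpec:
    """Loading pattern and free residual covariances of a measurement model.

    ``loadings`` maps each factor to its indicator list; no indicator may load
    on two factors.  Factor variances are fixed to 1 (standardized factors).
    """

    loadings: dict[str, tuple[str, ...]]
    residual_covariances: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        seen: set[str] = set()
        for fac, inds in self.loadings.items():
            if len(inds) == 0:
                raise ValueError(f"factor {fac!r} has no indicators")
            if len(inds) < 2:
                warnings.warn(f"factor {fac!r} has a single indicator; identification relies on "
                              "its fixed unit variance", stacklevel=2)
            for ind in inds:
                if ind in seen:
                    raise ValueError(f"indicator {ind!r} loads on two factors")
                seen.add(ind)
        for a, b in self.residual_covariances:
            if a not in seen or b not in seen:
                raise ValueError(f"residual covariance ({a!r}, {b!r}) names unknown indicators")
            if a == b:
                raise ValueError("residual covariance must involve two distinct indicators")

    @property
    def factors(self) -> list[str]:
        return list(self.loadings)

    @property
    def indicators(self) -> list[str]:
        return [i for inds in self.loadings.values() for i in inds]

    def to_dict(self) -> dict:
        return {
            "loadings": {f: list(v) for f, v in self.loadings.items()},
            "residual_covariances": [list(p) for p in self.residual_covariances],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementSpec":
        return cls(
            loadings={f: tuple(v) for f, v in d["loadings"].items()},
            residual_covariances=tuple(tuple(p) for p in d.get("residual_covariances", [])),
        )


def ads_measurement_spec() -> MeasurementSpec:
    """The four-factor battery measurement model used throughout the package."""
    return MeasurementSpec(
        loadings={
            "ICLF": ("cpt_dprime", "cpt_lnbeta", "cpt_hit_rt_sd", "cpt_fa_rt_sd", "bis"),
            "RRLF": ("wof_p_high_risk", "wof_rt_high", "wof_rt_low", "wof_winnings", "td_auc"),
            "ENLF": ("efr_neg_acc", "efr_neg_rt", "efr_neg_rt_sd"),
            "EPLF": ("efr_pos_acc", "efr_pos_rt", "efr_pos_rt_sd"),
        },
        residual_covariances=(
            ("cpt_dprime", "cpt_lnbeta"),
            ("cpt_dprime", "cpt_hit_rt_sd"),
            ("wof_p_high_risk", "wof_rt_high"),
            ("wof_rt_low", "wof_rt_high"),
            ("efr_neg_rt", "efr_pos_rt"),
            ("efr_neg_acc", "efr_pos_acc"),
        ),
    )


DEFAULT_STRUCTURAL_PATHS: tuple[tuple[str, str], ...] = (
    ("ICLF", "RRLF"),
    ("ICLF", "ENLF"),
    ("ICLF", "EPLF"),
)
DEFAULT_DISTURBANCE_COVARIANCES: tuple[tuple[str, str], ...] = (("ENLF", "EPLF"),)


# ---------------------------------------------------------------------------
# Internal parameterization
# ---------------------------------------------------------------------------

class _Structure:
    """Maps the flat parameter vector to (mu, Lambda, Theta, Psi_eta)."""

    def __init__(
        self,
        spec: MeasurementSpec,
        paths: tuple[tuple[str, str], ...] = (),
        disturbance_covariances: tuple[tuple[str, str], ...] = (),
    ):
        self.spec = spec
        self.indicators = spec.indicators
        self.factors = spec.factors
        self.p = len(self.indicators)
        self.m = len(self.factors)
        self._ind_ix = {v: i for i, v in enumerate(self.indicators)}
        self._fac_ix = {v: i for i, v in enumerate(self.factors)}

        self.load_pos = [
            (self._ind_ix[ind], self._fac_ix[fac])
            for fac, inds in spec.loadings.items()
            for ind in inds
        ]
        self.theta_pairs = [
            (self._ind_ix[a], self._ind_ix[b]) for a, b in spec.residual_covariances
        ]

        self.paths = [(self._fac_ix[s], self._fac_ix[d]) for s, d in paths]
        targets = {d for _, d in self.paths}
        self.endo = sorted(targets)
        self.exo = [k for k in range(self.m) if k not in targets]
        if any(s in targets and (d, s) in [(a, b) for a, b in self.paths] for s, d in self.paths):
            raise ValueError("structural paths must be acyclic")
        self.exo_pairs = [
            (a, b) for i, a in enumerate(self.exo) for b in self.exo[i + 1:]
        ]
        self.dist_pairs = []
        for a, b in disturbance_covariances:
            ka, kb = self._fac_ix[a], self._fac_ix[b]
            if ka in self.exo and kb in self.exo:
                continue  # already covered by exogenous correlations
            self.dist_pairs.append((ka, kb))

        # slices into the parameter vector
        n = 0
        self.sl_mu = slice(n, n + self.p); n += self.p
        self.sl_load = slice(n, n + len(self.load_pos)); n += len(self.load_pos)
        self.sl_logtheta = slice(n, n + self.p); n += self.p
        self.sl_thpair = slice(n, n + len(self.theta_pairs)); n += len(self.theta_pairs)
        self.sl_path = slice(n, n + len(self.paths)); n += len(self.paths)
        self.sl_exocorr = slice(n, n + len(self.exo_pairs)); n += len(self.exo_pairs)
        # endogenous disturbance variances are FIXED to 1 (standardized-latent
        # identification): with free loadings, a free disturbance variance
        # would leave the endogenous factor's scale unidentified.
        self.sl_distcov = slice(n, n + len(self.dist_pairs)); n += len(self.dist_pairs)
        self.n_params = n

    @property
    def n_free_structural(self) -> int:
        """Free parameters excluding means (enter the df count)."""
        return self.n_params - self.p

    def bounds(self) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = [(None, None)] * self.n_params
        for i in range(*self.sl_logtheta.indices(self.n_params)):
            b[i] = (np.log(_VAR_FLOOR), None)
        for i in range(*self.sl_exocorr.indices(self.n_params)):
            b[i] = (-_TANH_BOUND, _TANH_BOUND)
        return b

    def build(self, theta: np.ndarray):
        p, m = self.p, self.m
        mu = theta[self.sl_mu]
        Lam = np.zeros((p, m))
        for val, (i, k) in zip(theta[self.sl_load], self.load_pos):
            Lam[i, k] = val
        Theta = np.diag(np.exp(theta[self.sl_logtheta]))
        for val, (i, j) in zip(theta[self.sl_thpair], self.theta_pairs):
            Theta[i, j] = Theta[j, i] = val

        B = np.zeros((m, m))
        for val, (s, d) in zip(theta[self.sl_path], self.paths):
            B[d, s] = val
        Phi = np.eye(m)
        for val, (a, b) in zip(theta[self.sl_exocorr], self.exo_pairs):
            Phi[a, b] = Phi[b, a] = np.tanh(val)
        for val, (a, b) in zip(theta[self.sl_distcov], self.dist_pairs):
            Phi[a, b] = Phi[b, a] = val

        if self.paths:
            A = np.linalg.inv(np.eye(m) - B)
            Psi = A @ Phi @ A.T
        else:
            A = np.eye(m)
            Psi = Phi
        return mu, Lam, Theta, Psi, B, Phi, A

    def grad_to_theta(
        self, theta, G, g_mu, Lam, Theta, Psi, Phi, A
    ) -> np.ndarray:
        """Chain rule from (dL/dSigma = G, dL/dmu = g_mu) to the flat vector."""
        g = np.zeros(self.n_params)
        g[self.sl_mu] = g_mu
        GL = 2.0 * G @ Lam @ Psi
        g[self.sl_load] = [GL[i, k] for i, k in self.load_pos]
        g[self.sl_logtheta] = np.diag(G) * np.diag(Theta)
        g[self.sl_thpair] = [2.0 * G[i, j] for i, j in self.theta_pairs]

        M = Lam.T @ G @ Lam
        if self.paths:
            gB = A.T @ (2.0 * M @ A @ Phi) @ A.T
            g[self.sl_path] = [gB[d, s] for s, d in self.paths]
            H = A.T @ M @ A
        else:
            H = M
        u = theta[self.sl_exocorr]
        g[self.sl_exocorr] = [
            2.0 * H[a, b] * (1.0 - np.tanh(ui) ** 2) for ui, (a, b) in zip(u, self.exo_pairs)
        ]
        g[self.sl_distcov] = [2.0 * H[a, b] for a, b in self.dist_pairs]
        return g


# ---------------------------------------------------------------------------
# Pattern-wise likelihood machinery
# ---------------------------------------------------------------------------

def _prepare_patterns(X: np.ndarray):
    """Group rows by missingness pattern; precompute count, mean, scatter."""
    obs = ~np.isnan(X)
    keep = obs.any(axis=1)
    X, obs = X[keep], obs[keep]
    out = []
    _, inverse = np.unique(obs, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = X[inverse == g]
        o = np.flatnonzero(obs[inverse == g][0])
        sub = rows[:, o]
        xbar = sub.mean(axis=0)
        d = sub - xbar
        out.append((o, len(sub), xbar, d.T @ d))
    return out, int(keep.sum())


def _fiml_negloglik_grad(theta, struct: _Structure, patterns):
    mu, Lam, Theta, Psi, B, Phi, A = struct.build(theta)
    Sigma = Lam @ Psi @ Lam.T + Theta
    p = struct.p
    ll = 0.0
    G = np.zeros((p, p))
    g_mu = np.zeros(p)
    for o, n_g, xbar, C in patterns:
        So = Sigma[np.ix_(o, o)]
        try:
            cf = cho_factor(So, lower=True)
        except LinAlgError:
            return 1e15, np.zeros(struct.n_params)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Sinv = cho_solve(cf, np.eye(len(o)))
        d = xbar - mu[o]
        Ag = C / n_g + np.outer(d, d)
        ll += -0.5 * n_g * (len(o) * _LOG2PI + logdet + np.sum(Sinv * Ag))
        Go = 0.5 * n_g * (Sinv @ Ag @ Sinv - Sinv)
        G[np.ix_(o, o)] += Go
        g_mu[o] += n_g * (Sinv @ d)
    grad = struct.grad_to_theta(theta, G, g_mu, Lam, Theta, Psi, Phi, A)
    return -ll, -grad


def fiml_loglik(theta, struct: _Structure, data: np.ndarray) -> float:
    """FIML log-likelihood of a parameter vector on raw data (NaN = missing)."""
    patterns, _ = _prepare_patterns(np.asarray(data, dtype=float))
    f, _ = _fiml_negloglik_grad(np.asarray(theta, dtype=float), struct, patterns)
    return -f


def mvn_loglik(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Ordinary complete-data multivariate-normal log-likelihood."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cf = cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    D = X - mu
    quad = np.sum(D * cho_solve(cf, D.T).T)
    return float(-0.5 * (n * (p * _LOG2PI + logdet) + quad))


def fit_saturated_mvn(X: np.ndarray, max_iter: int = 500, tol: float = 1e-8):
    """Saturated (unstructured) MVN fit under missing data, via EM.

    Returns (mu, Sigma, loglik).  With complete data this reduces to the
    sample mean and ML covariance in one step.
    """
    X = np.asarray(X, dtype=float)
    obs = ~np.isnan(X)
    X = X[obs.any(axis=1)]
    obs = ~np.isnan(X)
    n, p = X.shape
    if obs.all():
        mu = X.mean(axis=0)
        Sigma = (X - mu).T @ (X - mu) / n
        return mu, Sigma, mvn_loglik(X, mu, Sigma)

    mu = np.nanmean(X, axis=0)
    Sigma = np.diag(np.nanvar(X, axis=0)) + 1e-3 * np.eye(p)
    patterns, _ = _prepare_patterns(X)
    # regroup raw rows per pattern for the E step
    groups = []
    obs_mask = ~np.isnan(X)
    _, inverse = np.unique(obs_mask, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = X[inverse == g]
        o = np.flatnonzero(obs_mask[inverse == g][0])
        groups.append((o, rows[:, o]))

    last = -np.inf
    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        ll = 0.0
        for o, sub in groups:
            mi = np.setdiff1d(np.arange(p), o)
            So = Sigma[np.ix_(o, o)]
            cf = cho_factor(So, lower=True)
            Sinv = cho_solve(cf, np.eye(len(o)))
            d = sub - mu[o]
            ll += -0.5 * (
                len(sub) * (len(o) * _LOG2PI + 2.0 * np.sum(np.log(np.diag(cf[0]))))
                + np.sum(d * (d @ Sinv))
            )
            full = np.zeros((len(sub), p))
            full[:, o] = sub
            if mi.size:
                Smo = Sigma[np.ix_(mi, o)]
                cond = mu[mi] + d @ (Smo @ Sinv).T
                full[:, mi] = cond
                Vm = Sigma[np.ix_(mi, mi)] - Smo @ Sinv @ Smo.T
                s2[np.ix_(mi, mi)] += len(sub) * Vm
            s1 += full.sum(axis=0)
            s2 += full.T @ full
        mu = s1 / n
        Sigma = s2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        if abs(ll - last) < tol * (abs(ll) + 1.0):
            last = ll
            break
        last = ll
    return mu, Sigma, float(last)


def _null_model_loglik(X: np.ndarray) -> tuple[float, int]:
    """Null model: zero loadings/covariances, free per-indicator mean and
    variance.  FIML factorizes column-wise; ML closed form."""
    X = np.asarray(X, dtype=float)
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[~np.isnan(x)]
        v = np.mean((x - x.mean()) ** 2)
        ll += -0.5 * len(x) * (_LOG2PI + np.log(v) + 1.0)
    return float(ll), 2 * X.shape[1]


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def compute_fit_indices(chi2: float, df: int, chi2_null: float, df_null: int, n: int) -> dict:
    """RMSEA (with the close-fit p-value at eps0 = 0.05), CFI and TLI.

    With df = 0 the indices are undefined and reported as NaN.
    """
    out: dict[str, float] = {"chi2": chi2, "df": df, "chi2_null": chi2_null, "df_null": df_null, "n": n}
    out["p_value"] = float(chi2_dist.sf(chi2, df)) if df > 0 else np.nan
    if df > 0 and n > 1:
        out["rmsea"] = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        out["rmsea_pclose"] = float(ncx2.sf(chi2, df, 0.05**2 * df * (n - 1)))
    else:
        out["rmsea"] = np.nan
        out["rmsea_pclose"] = np.nan
    d_model = max(chi2 - df, 0.0)
    d_null = max(chi2_null - df_null, 0.0)
    denom = max(d_null, d_model)
    out["cfi"] = float(1.0 - (d_model / denom if denom > 0 else 0.0))
    if df > 0 and df_null > 0 and chi2_null / df_null != 1.0:
        out["tli"] = float(((chi2_null / df_null) - (chi2 / df)) / ((chi2_null / df_null) - 1.0))
    else:
        out["tli"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Fitted model container
# ---------------------------------------------------------------------------

@dataclass
class FittedLatentModel:
    spec: MeasurementSpec
    kind: str  # "cfa" or "sem"
    indicators: list[str]
    factors: list[str]
    theta: np.ndarray
    mu: np.ndarray
    Lambda: np.ndarray
    Theta: np.ndarray
    Psi: np.ndarray  # implied factor covariance (Psi_eta for SEM)
    Sigma: np.ndarray
    loglik: float
    n_obs: int
    n_params: int
    fit: dict
    loadings: pd.DataFrame
    residual_variances: pd.DataFrame
    residual_covariances: pd.DataFrame
    paths: pd.DataFrame
    converged: bool
    n_iter: int
    message: str
    heywood: bool = False
    se_available: bool = False
    score_method: str = "regression"

    def parameter_table(self) -> pd.DataFrame:
        """Flat estimate / std.error / z / p table mirroring the loading-table
        layout, plus residual covariances and structural paths."""
        frames = []
        for df_, kind in (
            (self.loadings, "loading"),
            (self.residual_covariances, "residual_covariance"),
            (self.paths, "path"),
        ):
            if len(df_):
                d = df_.copy()
                d.insert(0, "type", kind)
                frames.append(d)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "spec": self.spec.to_dict(),
            "indicators": self.indicators,
            "factors": self.factors,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "fit": {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in self.fit.items()},
            "converged": self.converged,
            "heywood": self.heywood,
            "score_method": self.score_method,
            "loadings": self.loadings.to_dict(orient="records"),
            "residual_variances": self.residual_variances.to_dict(orient="records"),
            "residual_covariances": self.residual_covariances.to_dict(orient="records"),
            "paths": self.paths.to_dict(orient="records"),
            "factor_covariance": self.Psi.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, IndicatorMatrix):
        return data.values
    return data


def _start_values(struct: _Structure, X: np.ndarray) -> np.ndarray:
    theta = np.zeros(struct.n_params)
    mu0 = np.nanmean(X, axis=0)
    var0 = np.nanvar(X, axis=0, ddof=1)
    theta[struct.sl_mu] = mu0
    sds = np.sqrt(var0)

    lam0 = np.zeros(len(struct.load_pos))
    resid0 = var0.copy()
    for k, fac in enumerate(struct.factors):
        cols = [i for i, kk in struct.load_pos if kk == k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
            comp = np.nanmean((X[:, cols] - mu0[cols]) / sds[cols], axis=1)
        for pos, (i, kk) in enumerate(struct.load_pos):
            if kk != k:
                continue
            x = X[:, i]
            m = ~np.isnan(x) & ~np.isnan(comp)
            r = 0.0
            if m.sum() > 3 and np.std(comp[m]) > 0 and np.std(x[m]) > 0:
                r = float(np.corrcoef(x[m], comp[m])[0, 1])
            r = float(np.clip(r, -0.9, 0.9))
            lam0[pos] = r * sds[i]
            resid0[i] = max(var0[i] * (1.0 - r**2), 0.05 * var0[i])
    theta[struct.sl_load] = lam0
    theta[struct.sl_logtheta] = np.log(np.maximum(resid0, _VAR_FLOOR * 10))
    return theta


class ConvergenceError(RuntimeError):
    pass


def _fit(
    struct: _Structure,
    data,
    kind: str,
    compute_se: bool = True,
    max_iter: int = 500,
) -> FittedLatentModel:
    frame = _as_frame(data)
    missing_cols = [c for c in struct.indicators if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"data is missing indicator columns: {missing_cols}")
    X = frame[struct.indicators].to_numpy(dtype=float)
    patterns, n_obs = _prepare_patterns(X)
    if n_obs < 5 * struct.n_free_structural:
        warnings.warn(
            f"only {n_obs} rows for {struct.n_free_structural} free parameters "
            "(< 5 rows per parameter); estimates may be unstable",
            stacklevel=2,
        )

    theta0 = _start_values(struct, X)
    res = minimize(
        _fiml_negloglik_grad,
        theta0,
        args=(struct, patterns),
        jac=True,
        method="L-BFGS-B",
        bounds=struct.bounds(),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7, "maxfun": 20 * max_iter},
    )
    if not res.success and res.fun >= 1e14:
        raise ConvergenceError(f"FIML optimization failed: {res.message}")
    theta = _align_factor_signs(struct, res.x)
    mu, Lam, Theta, Psi, B, Phi, A = struct.build(theta)
    Sigma = Lam @ Psi @ Lam.T + Theta
    loglik = -res.fun

    heywood = bool(np.any(theta[struct.sl_logtheta] <= np.log(_VAR_FLOOR) + 1e-9))
    if heywood:
        warnings.warn("Heywood case: residual variance at the 1e-6 boundary", stacklevel=2)

    # chi-square vs saturated, fit indices vs the zero-loading null
    _, _, ll_sat = fit_saturated_mvn(X)
    ll_null, null_params = _null_model_loglik(X)
    p = struct.p
    sat_structural = p * (p + 1) // 2
    df = sat_structural - struct.n_free_structural
    df_null = sat_structural - p
    chi2 = max(2.0 * (ll_sat - loglik), 0.0)
    chi2_null = max(2.0 * (ll_sat - ll_null), 0.0)
    fit = compute_fit_indices(chi2, df, chi2_null, df_null, n_obs)
    fit["loglik"] = loglik
    fit["loglik_saturated"] = ll_sat
    fit["loglik_null"] = ll_null

    se = np.full(struct.n_params, np.nan)
    se_ok = False
    if compute_se:
        try:
            H = _observed_information(struct, patterns, theta)
            cov = np.linalg.pinv(H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
            se_ok = True
        except Exception:  # pragma: no cover - singular information
            pass

    ind_sd = np.sqrt(np.diag(Sigma))
    fac_sd = np.sqrt(np.diag(Psi))
    load_rows = []
    lam_se = se[struct.sl_load]
    for (i, k), est, s in zip(struct.load_pos, theta[struct.sl_load], lam_se):
        z = est / s if (se_ok and s > 0) else np.nan
        load_rows.append(
            {
                "factor": struct.factors[k],
                "indicator": struct.indicators[i],
                "estimate": est,
                "std_estimate": est * fac_sd[k] / ind_sd[i],
                "se": s,
                "z": z,
                "p": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            }
        )
    loadings = pd.DataFrame(load_rows)

    th = np.exp(theta[struct.sl_logtheta])
    th_se = se[struct.sl_logtheta] * th  # delta method from the log scale
    residual_variances = pd.DataFrame(
        {"indicator": struct.indicators, "estimate": th, "se": th_se}
    )

    rc_rows = []
    for (i, j), est, s in zip(struct.theta_pairs, theta[struct.sl_thpair], se[struct.sl_thpair]):
        z = est / s if (se_ok and s > 0) else np.nan
        rc_rows.append(
            {
                "indicator_1": struct.indicators[i],
                "indicator_2": struct.indicators[j],
                "estimate": est,
                "std_estimate": est / (ind_sd[i] * ind_sd[j]),
                "se": s,
                "z": z,
                "p": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            }
        )
    residual_covariances = pd.DataFrame(
        rc_rows, columns=["indicator_1", "indicator_2", "estimate", "std_estimate", "se", "z", "p"]
    )

    path_rows = []
    for (s_ix, d_ix), est, s in zip(struct.paths, theta[struct.sl_path], se[struct.sl_path]):
        z = est / s if (se_ok and s > 0) else np.nan
        path_rows.append(
            {
                "source": struct.factors[s_ix],
                "target": struct.factors[d_ix],
                "estimate": est,
                "std_estimate": est * fac_sd[s_ix] / fac_sd[d_ix],
                "se": s,
                "z": z,
                "p": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            }
        )
    paths = pd.DataFrame(
        path_rows, columns=["source", "target", "estimate", "std_estimate", "se", "z", "p"]
    )

    return FittedLatentModel(
        spec=struct.spec,
        kind=kind,
        indicators=list(struct.indicators),
        factors=list(struct.factors),
        theta=theta,
        mu=mu,
        Lambda=Lam,
        Theta=Theta,
        Psi=Psi,
        Sigma=Sigma,
        loglik=loglik,
        n_obs=n_obs,
        n_params=struct.n_params,
        fit=fit,
        loadings=loadings,
        residual_variances=residual_variances,
        residual_covariances=residual_covariances,
        paths=paths,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        heywood=heywood,
        se_available=se_ok,
    )


def _align_factor_signs(struct: _Structure, theta: np.ndarray) -> np.ndarray:
    """Resolve the sign indeterminacy of each factor: flip so the first
    indicator of every factor loads positively.  The likelihood is invariant
    under these reflections (tanh is odd, so correlation parameters just
    change sign)."""
    theta = theta.copy()
    s = np.ones(struct.m)
    anchor = {}
    for k, fac in enumerate(struct.factors):
        anchor[k] = struct._ind_ix[struct.spec.loadings[fac][0]]
    lam = theta[struct.sl_load].copy()
    for pos, (i, k) in enumerate(struct.load_pos):
        if i == anchor[k] and lam[pos] < 0:
            s[k] = -1.0
    for pos, (i, k) in enumerate(struct.load_pos):
        lam[pos] *= s[k]
    theta[struct.sl_load] = lam
    theta[struct.sl_path] = [
        v * s[src] * s[dst] for v, (src, dst) in zip(theta[struct.sl_path], struct.paths)
    ]
    theta[struct.sl_exocorr] = [
        v * s[a] * s[b] for v, (a, b) in zip(theta[struct.sl_exocorr], struct.exo_pairs)
    ]
    theta[struct.sl_distcov] = [
        v * s[a] * s[b] for v, (a, b) in zip(theta[struct.sl_distcov], struct.dist_pairs)
    ]
    return theta


def _observed_information(struct: _Structure, patterns, theta: np.ndarray) -> np.ndarray:
    """Observed information: central finite differences of the analytic
    gradient of the negative log-likelihood."""
    n = struct.n_params
    H = np.zeros((n, n))
    for i in range(n):
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = _fiml_negloglik_grad(tp, struct, patterns)
        _, gm = _fiml_negloglik_grad(tm, struct, patterns)
        H[:, i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def fit_cfa(spec: MeasurementSpec, data, compute_se: bool = True, max_iter: int = 500) -> FittedLatentModel:
    """Fit a confirmatory factor model by FIML with standardized factors.

    ``data`` is an :class:`IndicatorMatrix` or a DataFrame with NaN marking
    missing entries.  All pairwise factor covariances are free.
    """
    struct = _Structure(spec)
    return _fit(struct, data, kind="cfa", compute_se=compute_se, max_iter=max_iter)


def fit_sem(
    spec: MeasurementSpec,
    data,
    paths: tuple[tuple[str, str], ...] = DEFAULT_STRUCTURAL_PATHS,
    disturbance_covariances: tuple[tuple[str, str], ...] = DEFAULT_DISTURBANCE_COVARIANCES,
    compute_se: bool = True,
    max_iter: int = 500,
) -> FittedLatentModel:
    """Fit the structural model: directed paths between factors, exogenous
    factor variances fixed at 1, endogenous disturbance variances free."""
    struct = _Structure(spec, paths=tuple(paths), disturbance_covariances=tuple(disturbance_covariances))
    return _fit(struct, data, kind="sem", compute_se=compute_se, max_iter=max_iter)


# ---------------------------------------------------------------------------
# Factor scores
# ---------------------------------------------------------------------------

@dataclass
class FactorScores:
    scores: pd.DataFrame
    method: str
    n_missing: dict[str, int]


def extract_factor_scores(
    fitted: FittedLatentModel,
    data,
    method: str = "regression",
    standardize: bool = True,
) -> FactorScores:
    """Factor scores under the fitted model's implied moments.

    ``regression`` scores are the conditional means
    E[eta | x_obs] = Psi Lambda_o' Sigma_o^-1 (x_obs - mu_o), computed per
    missingness pattern; ``bartlett`` scores are the GLS estimator
    (Lambda_o' Theta_o^-1 Lambda_o)^-1 Lambda_o' Theta_o^-1 (x_obs - mu_o).
    A factor with no observed indicator for a person-wave gets a missing
    score.  Columns are z-standardized when ``standardize`` is True.
    """
    if method not in ("regression", "bartlett"):
        raise ValueError("method must be 'regression' or 'bartlett'")
    frame = _as_frame(data)
    X = frame[fitted.indicators].to_numpy(dtype=float)
    n, p = X.shape
    m = len(fitted.factors)
    out = np.full((n, m), np.nan)

    fac_of_col = np.empty(p, dtype=int)
    for k, fac in enumerate(fitted.factors):
        for ind in fitted.spec.loadings[fac]:
            fac_of_col[fitted.indicators.index(ind)] = k

    obs = ~np.isnan(X)
    _, inverse = np.unique(obs, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = np.flatnonzero(inverse == g)
        o = np.flatnonzero(obs[rows[0]])
        if o.size == 0:
            continue
        Lo = fitted.Lambda[o]
        d = X[np.ix_(rows, o)] - fitted.mu[o]
        if method == "regression":
            So = fitted.Sigma[np.ix_(o, o)]
            W = fitted.Psi @ Lo.T @ np.linalg.inv(So)
        else:
            To_inv = np.linalg.inv(fitted.Theta[np.ix_(o, o)])
            W = np.linalg.pinv(Lo.T @ To_inv @ Lo) @ Lo.T @ To_inv
        f = d @ W.T
        # a factor with no observed indicator in this pattern stays missing
        have = np.unique(fac_of_col[o])
        cols = np.isin(np.arange(m), have)
        out[np.ix_(rows, np.flatnonzero(cols))] = f[:, cols]

    scores = pd.DataFrame(out, index=frame.index, columns=fitted.factors)
    n_missing = {f: int(scores[f].isna().sum()) for f in fitted.factors}
    if standardize:
        for c in scores.columns:
            sd = scores[c].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"factor score column {c!r} has zero variance")
            scores[c] = (scores[c] - scores[c].mean()) / sd
    return FactorScores(scores=scores, method=method, n_missing=n_missing)


def score_covariate_association(scores: pd.Series, covariate: pd.Series) -> dict:
    """Simple-regression association between a factor score and a covariate
    (score-on-covariate OLS), tagged with its method for reporting."""
    d = pd.concat([scores, covariate], axis=1).dropna()
    y = d.iloc[:, 0].to_numpy(dtype=float)
    x = d.iloc[:, 1].to_numpy(dtype=float)
    n = len(d)
    if n < 3 or np.std(x) == 0:
        return {"estimate": np.nan, "se": np.nan, "z": np.nan, "p": np.nan, "n": n, "method": "score_on_covariate"}
    xc = x - x.mean()
    b = float(np.sum(xc * y) / np.sum(xc**2))
    resid = y - y.mean() - b * xc
    s2 = float(np.sum(resid**2) / (n - 2))
    se = float(np.sqrt(s2 / np.sum(xc**2)))
    z = b / se if se > 0 else np.nan
    return {
        "estimate": b,
        "se": se,
        "z": z,
        "p": float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        "n": n,
        "method": "score_on_covariate",
    }
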