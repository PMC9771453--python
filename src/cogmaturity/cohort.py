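"""Synthetic longitudinal cohort with known latent cognitive growth.

The generator emulates a three-wave adolescent study (default N = 141,
wave-one ages 11.1-14.0 years, ~1.6-year inter-wave gaps).  Four latent
cognitive factors drive task performance:

* ``ICLF`` — inhibitory control (CPT + BIS indicators),
* ``RRLF`` — risk/reward processing (WOF + delay discounting),
* ``ENLF`` — negative-emotion face recognition,
* ``EPLF`` — positive-emotion face recognition.

Each factor follows a linear growth curve in *effective age* = chronological
age + a per-person maturity offset (the planted ground truth the Cognitive
Maturity Index is meant to recover), plus a person-level random intercept and
wave-level noise.  Factor values are pushed through a loading pattern to
per-indicator targets, which parameterize the trial-level task simulators in
:mod:`cogmaturity.tasks`.  Cumulative WOF winnings are *emergent* rather than
calibrated: risky choices carry a lower net expected payoff under the task's
payoff rules, so the negative coupling with risk propensity arises from the
accounting itself.

Ground truth (factor values, maturity offsets) is returned as a separate
sidecar table and never appears among the observable columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import tasks
from ._utils import RTSpec

FACTORS = ("ICLF", "RRLF", "ENLF", "EPLF")

#: indicator -> (factor, generating loading).  Signs and magnitudes follow the
#: measurement models this package is designed to estimate.
DEFAULT_LOADINGS: dict[str, tuple[str, float]] = {
    "cpt_dprime": ("ICLF", 0.650),
    "cpt_lnbeta": ("ICLF", -0.503),
    "cpt_hit_rt_sd": ("ICLF", -0.913),
    "cpt_fa_rt_sd": ("ICLF", -0.371),
    "bis": ("ICLF", 0.193),
    "wof_p_high_risk": ("RRLF", 0.703),
    "wof_rt_high": ("RRLF", 0.158),
    "wof_rt_low": ("RRLF", 0.433),
    "wof_winnings": ("RRLF", -0.899),  # emergent; sign realized via payoff rules
    "td_auc": ("RRLF", -0.127),
    "efr_neg_acc": ("ENLF", 0.164),
    "efr_neg_rt": ("ENLF", -0.451),
    "efr_neg_rt_sd": ("ENLF", -0.302),
    "efr_pos_acc": ("EPLF", 0.173),
    "efr_pos_rt": ("EPLF", 0.310),
    "efr_pos_rt_sd": ("EPLF", 0.235),
}

INDICATORS = tuple(DEFAULT_LOADINGS)

#: indicator -> (native-scale mean, SD) used to map standardized targets into
#: task-native parameters, with clipping bounds keeping parameters valid.
_NATIVE_SCALE: dict[str, tuple[float, float, float, float]] = {
    # name: (mean, sd, lo, hi)
    "cpt_dprime": (2.2, 0.6, 0.5, 4.5),
    "cpt_lnbeta": (0.0, 0.45, -1.5, 1.5),
    "cpt_hit_rt_sd": (150.0, 40.0, 30.0, 320.0),
    "cpt_fa_rt_sd": (150.0, 40.0, 30.0, 320.0),
    "bis": (20.1, 3.3, 7.0, 28.0),
    "wof_p_high_risk": (0.45, 0.15, 0.02, 0.98),
    "wof_rt_high": (1250.0, 250.0, 450.0, 2600.0),
    "wof_rt_low": (1350.0, 250.0, 450.0, 2600.0),
    "td_auc": (0.55, 0.18, 0.03, 0.99),
    "efr_neg_acc": (0.78, 0.09, 0.10, 0.995),
    "efr_neg_rt": (1900.0, 350.0, 700.0, 3800.0),
    "efr_neg_rt_sd": (500.0, 120.0, 60.0, 1200.0),
    "efr_pos_acc": (0.93, 0.05, 0.10, 0.999),
    "efr_pos_rt": (1500.0, 300.0, 650.0, 3500.0),
    "efr_pos_rt_sd": (420.0, 110.0, 60.0, 1100.0),
}

TASKS = ("cpt", "wof", "efr", "td")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the synthetic cohort."""

    n_participants: int = 141
    n_waves: int = 3
    wave1_age_range: tuple[float, float] = (11.1, 14.0)
    inter_wave_gap_mean_sd: tuple[float, float] = (1.6, 0.3)
    dropout_rate_per_wave: float = 0.08
    indicator_missing_rate: float = 0.05
    lie_gt6_rate: float = 0.16
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        lo, hi = self.wave1_age_range
        if not lo < hi:
            raise ValueError("wave1_age_range must satisfy lower < upper")
        for name in ("dropout_rate_per_wave", "indicator_missing_rate", "lie_gt6_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")


@dataclass(frozen=True)
class LatentGrowthSpec:
    """Ground-truth growth model for the four latent factors.

    ``age_slopes`` are standardized effects: the factor changes by that many
    (approximate) factor-SD units per SD of pooled effective age.
    ``maturity_offset_sd`` (years) scales the planted per-person offsets that
    define individual cognitive maturity relative to the age norm.
    """

    age_slopes: dict[str, float] = field(
        default_factory=lambda: {"ICLF": 0.72, "RRLF": -0.22, "ENLF": 0.35, "EPLF": -0.16}
    )
    intercepts: dict[str, float] = field(default_factory=lambda: {f: 0.0 for f in FACTORS})
    person_intercept_sd: float = 0.3
    factor_residual_sd: float = 0.5
    maturity_offset_sd: float = 1.0
    loadings: dict[str, tuple[str, float]] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    indicator_residual_sd: dict[str, float] | None = None
    residual_covariances: dict[tuple[str, str], float] = field(default_factory=dict)
    structural_paths: dict[tuple[str, str], float] = field(default_factory=dict)
    covariate_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    #: covariate -> coefficient linking the standardized maturity offset to the
    #: covariate on its native scale (drives the CMI covariate correlations).
    maturity_covariate_coupling: dict[str, float] = field(
        default_factory=lambda: {
            "bmi": -1.2,
            "pds": -0.15,
            "bas_d": -0.5,
            "iq": 4.0,
            "dusi_substance_use": -0.8,
            "dusi_health_risk": -0.8,
            "dusi_violence_risk": -0.8,
        }
    )

    def __post_init__(self):
        seen: dict[str, str] = {}
        for ind, (fac, _) in self.loadings.items():
            if fac not in FACTORS:
                raise ValueError(f"unknown factor {fac!r} for indicator {ind!r}")
            if ind in seen:
                raise ValueError(f"indicator {ind!r} assigned to two factors")
            seen[ind] = fac
        if self.person_intercept_sd < 0 or self.factor_residual_sd < 0 or self.maturity_offset_sd < 0:
            raise ValueError("SD parameters must be non-negative")

    def residual_sd_for(self, indicator: str) -> float:
        if self.indicator_residual_sd and indicator in self.indicator_residual_sd:
            return self.indicator_residual_sd[indicator]
        lam = self.loadings[indicator][1]
        return float(np.sqrt(max(0.1, 1.0 - lam**2)))


def ads_growth_spec() -> LatentGrowthSpec:
    """Default growth spec: reported age slopes, moderate noise."""
    return LatentGrowthSpec()


def strong_signal_growth_spec() -> LatentGrowthSpec:
    """Reliability-ceiling validation regime for end-to-end recovery tests.

    Keeps the reported effect directions (ICLF +, RRLF -, ENLF +, EPLF -) but
    places every factor at unit slope with minimal trait/wave noise and all
    loadings near the reliability ceiling of their tasks, so that planted
    per-person maturity offsets dominate measurement error.  Chosen from a
    noise-budget calculation over the fixed task designs (27 CPT lures, 10
    happiness trials, ...); see docs/methods.md.
    """
    return replace(
        LatentGrowthSpec(),
        age_slopes={"ICLF": 1.0, "RRLF": -1.0, "ENLF": 1.0, "EPLF": -1.0},
        person_intercept_sd=0.05,
        factor_residual_sd=0.1,
        loadings={ind: (fac, float(np.copysign(0.95, lam))) for ind, (fac, lam) in DEFAULT_LOADINGS.items()},
        indicator_residual_sd={ind: 0.15 for ind in DEFAULT_LOADINGS},
        maturity_offset_sd=0.7,
    )


@dataclass
class CohortBundle:
    """Observable cohort table + per-session trial tables + hidden truth."""

    cohort: pd.DataFrame
    trials: dict[tuple[str, int], dict[str, pd.DataFrame]]
    truth: pd.DataFrame
    config: CohortConfig
    growth: LatentGrowthSpec


def _zcol(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def generate_cohort(config: CohortConfig, growth: LatentGrowthSpec | None = None) -> CohortBundle:
    """Generate the full cohort bundle, reproducibly from ``config.seed``."""
    growth = growth or ads_growth_spec()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    pids = np.array([f"P{i:03d}" for i in range(n)])
    female = rng.random(n) < 0.536
    age1 = rng.uniform(*config.wave1_age_range, size=n)
    gap_mu, gap_sd = config.inter_wave_gap_mean_sd
    gaps = np.clip(rng.normal(gap_mu, gap_sd, size=(n, max(config.n_waves - 1, 1))), 0.8, None)
    ages = np.column_stack([age1] + [age1 + gaps[:, : w + 1].sum(axis=1) for w in range(config.n_waves - 1)])

    # Monotone dropout: a participant seen at wave w survived every earlier gate.
    present = np.ones((n, config.n_waves), dtype=bool)
    for w in range(1, config.n_waves):
        present[:, w] = present[:, w - 1] & (rng.random(n) >= config.dropout_rate_per_wave)

    delta = rng.normal(0.0, growth.maturity_offset_sd, size=n)  # planted maturity offsets (years)
    delta_z = delta / growth.maturity_offset_sd if growth.maturity_offset_sd > 0 else np.zeros(n)
    b = rng.normal(0.0, growth.person_intercept_sd, size=(n, len(FACTORS)))

    # Stable person-level covariates
    income = rng.lognormal(mean=np.log(90_000.0), sigma=0.6, size=n)
    educ1 = np.clip(rng.normal(16.0, 2.2, size=n), 8, 24)
    educ2 = np.clip(rng.normal(15.5, 2.4, size=n), 8, 24)
    ses = 0.5 * (_zcol(income) + _zcol(0.5 * (educ1 + educ2)))
    cpl = growth.maturity_covariate_coupling
    iq = rng.normal(110.0, 13.0, size=n) + cpl.get("iq", 0.0) * delta_z
    lie = np.where(
        rng.random(n) < config.lie_gt6_rate,
        rng.integers(7, 11, size=n),
        rng.integers(0, 7, size=n),
    )

    eff_age = ages + delta[:, None]
    pooled = ages[present] if present.any() else ages
    age_mu, age_sd = float(pooled.mean()), float(pooled.std(ddof=1))
    z_eff = (eff_age - age_mu) / age_sd

    # Wave-level covariates
    bmi = (
        21.0
        + 0.68 * (ages - 12.7)
        + cpl.get("bmi", 0.0) * delta_z[:, None]
        + rng.normal(0.0, 4.0, size=ages.shape)
    )
    bmi = np.clip(bmi, 13.5, 48.0)
    pds = np.clip(
        1.0
        + 0.45 * (ages - 10.0)
        + 0.4 * female[:, None]
        + cpl.get("pds", 0.0) * delta_z[:, None]
        + rng.normal(0.0, 0.35, size=ages.shape),
        1.0,
        4.0,
    )
    bas_d = np.clip(
        np.round(10.0 + 0.3 * (ages - 12.7) + cpl.get("bas_d", 0.0) * delta_z[:, None] + rng.normal(0, 2.4, ages.shape)),
        4,
        16,
    ).astype(int)
    bas_fs = np.clip(np.round(rng.normal(11.3, 2.3, ages.shape)), 4, 16).astype(int)
    bas_rr = np.clip(np.round(rng.normal(17.6, 1.8, ages.shape)), 12, 20).astype(int)
    dusi = {}
    for scale in ("dusi_substance_use", "dusi_health_risk", "dusi_violence_risk"):
        dusi[scale] = np.clip(
            np.round(2.0 + 0.55 * (ages - 12.7) + cpl.get(scale, 0.0) * delta_z[:, None] + rng.normal(0, 1.8, ages.shape)),
            0,
            12,
        ).astype(int)

    cov_z = {
        "SES": _zcol(ses)[:, None] * np.ones_like(ages),
        "PDS": (pds - pds.mean()) / pds.std(ddof=1),
        "BMI": (bmi - bmi.mean()) / bmi.std(ddof=1),
        "sex": female[:, None].astype(float) * np.ones_like(ages),
    }

    # Latent factor values per person-wave
    fvals = {}
    for j, fac in enumerate(FACTORS):
        f = (
            growth.intercepts.get(fac, 0.0)
            + growth.age_slopes.get(fac, 0.0) * z_eff
            + b[:, j][:, None]
            + rng.normal(0.0, growth.factor_residual_sd, size=ages.shape)
        )
        for (cov, cfac), coef in growth.covariate_effects.items():
            if cfac == fac and cov in cov_z:
                f = f + coef * cov_z[cov]
        fvals[fac] = f
    for (src, dst), coef in growth.structural_paths.items():
        fvals[dst] = fvals[dst] + coef * fvals[src]

    # Indicator targets (standardized scale), with optional residual covariance
    inds = list(growth.loadings)
    resid_cov = np.diag([growth.residual_sd_for(i) ** 2 for i in inds])
    for (a, bb), c in growth.residual_covariances.items():
        ia, ib = inds.index(a), inds.index(bb)
        resid_cov[ia, ib] = resid_cov[ib, ia] = c
    chol = np.linalg.cholesky(resid_cov + 1e-12 * np.eye(len(inds)))

    targets = {}  # indicator -> (n, n_waves) native-scale targets
    zt = {}
    eps = rng.standard_normal(size=(n, config.n_waves, len(inds))) @ chol.T
    for k, ind in enumerate(inds):
        fac, lam = growth.loadings[ind]
        zt[ind] = lam * fvals[fac] + eps[:, :, k]
    for ind in inds:
        if ind == "wof_winnings":
            continue  # emergent from the payoff ledger
        mu, sd, lo, hi = _NATIVE_SCALE[ind]
        targets[ind] = np.clip(mu + sd * zt[ind], lo, hi)

    task_missing = rng.random((n, config.n_waves, len(TASKS))) < config.indicator_missing_rate

    cohort_rows = []
    truth_rows = []
    trials: dict[tuple[str, int], dict[str, pd.DataFrame]] = {}
    for i in range(n):
        for w in range(config.n_waves):
            if not present[i, w]:
                continue
            cohort_rows.append(
                {
                    "participant_id": pids[i],
                    "wave": w + 1,
                    "age": round(float(ages[i, w]), 4),
                    "sex": "female" if female[i] else "male",
                    "bmi": round(float(bmi[i, w]), 2),
                    "pds": round(float(pds[i, w]), 2),
                    "income": round(float(income[i]), 2),
                    "educ_years_p1": round(float(educ1[i]), 1),
                    "educ_years_p2": round(float(educ2[i]), 1),
                    "ses": round(float(ses[i]), 4),
                    "iq": round(float(iq[i]), 1),
                    "bis": int(round(targets["bis"][i, w])),
                    "bas_d": int(bas_d[i, w]),
                    "bas_fs": int(bas_fs[i, w]),
                    "bas_rr": int(bas_rr[i, w]),
                    "dusi_lie": int(lie[i]),
                    "dusi_substance_use": int(dusi["dusi_substance_use"][i, w]),
                    "dusi_health_risk": int(dusi["dusi_health_risk"][i, w]),
                    "dusi_violence_risk": int(dusi["dusi_violence_risk"][i, w]),
                }
            )
            truth_rows.append(
                {
                    "participant_id": pids[i],
                    "wave": w + 1,
                    "maturity_offset": float(delta[i]),
                    "effective_age": float(eff_age[i, w]),
                    **{f: float(fvals[f][i, w]) for f in FACTORS},
                }
            )
            session: dict[str, pd.DataFrame] = {}
            if not task_missing[i, w, 0]:
                session["cpt"] = tasks.generate_cpt_session(
                    float(targets["cpt_dprime"][i, w]),
                    float(targets["cpt_lnbeta"][i, w]),
                    tasks.CPTRTParams(
                        hit=RTSpec(420.0, float(targets["cpt_hit_rt_sd"][i, w])),
                        false_alarm=RTSpec(380.0, float(targets["cpt_fa_rt_sd"][i, w])),
                    ),
                    rng=rng,
                )
            if not task_missing[i, w, 1]:
                session["wof"] = tasks.generate_wof_session(
                    float(targets["wof_p_high_risk"][i, w]),
                    tasks.WOFRTParams(
                        high=RTSpec(float(targets["wof_rt_high"][i, w]), 350.0),
                        low=RTSpec(float(targets["wof_rt_low"][i, w]), 350.0),
                    ),
                    rng=rng,
                )
            if not task_missing[i, w, 2]:
                session["efr"] = tasks.generate_efr_session(
                    float(targets["efr_neg_acc"][i, w]),
                    float(targets["efr_pos_acc"][i, w]),
                    tasks.EFRRTParams(
                        negative=RTSpec(float(targets["efr_neg_rt"][i, w]), float(targets["efr_neg_rt_sd"][i, w])),
                        positive=RTSpec(float(targets["efr_pos_rt"][i, w]), float(targets["efr_pos_rt_sd"][i, w])),
                    ),
                    rng=rng,
                )
            if not task_missing[i, w, 3]:
                k = tasks.hyperbolic_k_for_auc(float(targets["td_auc"][i, w]))
                session["td"] = tasks.generate_td_session(
                    tasks.hyperbolic_profile(k), choice_noise_sd=0.4, rng=rng
                )
            trials[(pids[i], w + 1)] = session

    cohort = pd.DataFrame(cohort_rows)
    truth = pd.DataFrame(truth_rows)
    return CohortBundle(cohort=cohort, trials=trials, truth=truth, config=config, growth=growth)
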