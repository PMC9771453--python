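"""Score trial tables into the indicator variables of the latent models.

Implements signal-detection scoring for the CPT (d' and the log likelihood-
ratio criterion ln beta), choice/RT/winnings summaries for the wheel-of-
fortune task, block accuracy and RT summaries for emotional face recognition,
indifference-point estimation and trapezoidal AUC for delay discounting, the
income/education SES composite, the Lie-scale exclusion rule, and assembly of
the standardized indicator matrix consumed by the CFA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from . import tasks
from .cohort import INDICATORS, CohortBundle

WOF_ANTICIPATORY_MS = 200.0
LIE_EXCLUSION_THRESHOLD = 6  # strict: Lie > 6 excluded, Lie = 6 retained


# ---------------------------------------------------------------------------
# CPT / signal detection theory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDTSummary:
    hit_rate: float
    fa_rate: float
    d_prime: float
    ln_beta: float
    hit_rt_mean: float
    hit_rt_sd: float
    fa_rt_sd: float
    n_targets: int
    n_lures: int


def adjusted_rate(k: int, n: int) -> float:
    """Proportion k/n with extreme rates 0 and 1 pulled in to 1/(2n) and
    1 - 1/(2n), so the normal quantile stays finite."""
    if n <= 0:
        raise ValueError("rate undefined for zero trials")
    r = k / n
    if r <= 0.0:
        return 1.0 / (2 * n)
    if r >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def score_cpt(trials: pd.DataFrame) -> SDTSummary:
    """Score a CPT trial table into SDT and RT-variability indicators.

    d' = z(H) - z(F); ln beta = 0.5 * (z(F)^2 - z(H)^2), with z the standard
    normal quantile of the (extreme-adjusted) hit and false-alarm rates.
    RT statistics are over responded trials only.
    """
    is_lure = trials["stimulus"].to_numpy() == "lure"
    responded = trials["responded"].to_numpy().astype(bool)
    n_targets = int((~is_lure).sum())
    n_lures = int(is_lure.sum())
    if n_targets == 0 or n_lures == 0:
        raise ValueError("CPT scoring requires at least one target and one lure")

    hits = int((responded & ~is_lure).sum())
    fas = int((responded & is_lure).sum())
    h = adjusted_rate(hits, n_targets)
    f = adjusted_rate(fas, n_lures)
    z_h, z_f = norm.ppf(h), norm.ppf(f)

    rt = trials["rt_ms"].to_numpy(dtype=float)
    hit_rt = rt[responded & ~is_lure]
    fa_rt = rt[responded & is_lure]
    return SDTSummary(
        hit_rate=h,
        fa_rate=f,
        d_prime=float(z_h - z_f),
        ln_beta=float(0.5 * (z_f**2 - z_h**2)),
        hit_rt_mean=float(np.mean(hit_rt)) if hit_rt.size else np.nan,
        hit_rt_sd=float(np.std(hit_rt, ddof=1)) if hit_rt.size > 1 else np.nan,
        fa_rt_sd=float(np.std(fa_rt, ddof=1)) if fa_rt.size > 1 else np.nan,
        n_targets=n_targets,
        n_lures=n_lures,
    )


# ---------------------------------------------------------------------------
# Wheel of fortune
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WOFSummary:
    p_high_risk: float
    rt_high_mean: float
    rt_low_mean: float
    cumulative_winnings: float
    n_valid: int
    n_anticipatory: int
    n_timeout: int


def score_wof(trials: pd.DataFrame) -> WOFSummary:
    """Score a WOF table.  Anticipatory (< 200 ms) and timeout trials are
    dropped from choice/RT metrics; winnings are the final balances of the
    runs summed, computed from the *full* payoff ledger (timeouts included).
    """
    choice = trials["choice"].to_numpy()
    rt = trials["rt_ms"].to_numpy(dtype=float)
    timeout = choice == "timeout"
    anticipatory = ~timeout & (rt < WOF_ANTICIPATORY_MS)
    valid = ~timeout & ~anticipatory
    if not valid.any():
        raise ValueError("all WOF trials excluded (timeout/anticipatory)")

    high = valid & (choice == "high_risk")
    low = valid & (choice == "low_risk")
    winnings = float(
        trials.groupby("run")["payoff"].sum().sum()
    )  # runs reset to $0, so summing final balances == total payoff
    return WOFSummary(
        p_high_risk=float(high.sum() / valid.sum()),
        rt_high_mean=float(rt[high].mean()) if high.any() else np.nan,
        rt_low_mean=float(rt[low].mean()) if low.any() else np.nan,
        cumulative_winnings=winnings,
        n_valid=int(valid.sum()),
        n_anticipatory=int(anticipatory.sum()),
        n_timeout=int(timeout.sum()),
    )


# ---------------------------------------------------------------------------
# Emotional face recognition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EFRSummary:
    neg_accuracy: float
    pos_accuracy: float
    neg_rt_mean: float
    neg_rt_sd: float
    pos_rt_mean: float
    pos_rt_sd: float


def score_efr(trials: pd.DataFrame) -> EFRSummary:
    """Score an EFR table: the negative block pools disgust/anger/sadness/fear,
    the positive block is happiness only.  RT statistics are over all trials in
    a block (correct and incorrect)."""
    true = trials["true_emotion"].to_numpy()
    present = set(true)
    missing = set(tasks.EFR_EMOTIONS) - present
    if missing:
        raise ValueError(f"EFR table missing emotion categories: {sorted(missing)}")
    chosen = trials["chosen_emotion"].to_numpy()
    rt = trials["rt_ms"].to_numpy(dtype=float)

    neg = np.isin(true, list(tasks.EFR_NEGATIVE))
    pos = true == "happiness"
    correct = chosen == true
    return EFRSummary(
        neg_accuracy=float(correct[neg].mean()),
        pos_accuracy=float(correct[pos].mean()),
        neg_rt_mean=float(rt[neg].mean()),
        neg_rt_sd=float(np.std(rt[neg], ddof=1)),
        pos_rt_mean=float(rt[pos].mean()),
        pos_rt_sd=float(np.std(rt[pos], ddof=1)),
    )


# ---------------------------------------------------------------------------
# Delay discounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TDSummary:
    indifference_points: dict[str, float]
    auc: float
    inconsistent_delays: tuple[str, ...] = field(default_factory=tuple)


def _logistic_midpoint(amounts: np.ndarray, took_now: np.ndarray) -> float:
    """Midpoint (P(immediate) = 0.5) of a 2-parameter logistic choice fit."""

    def nll(theta):
        b0, b1 = theta
        eta = b0 + b1 * amounts
        return float(np.sum(np.logaddexp(0.0, eta)) - np.sum(eta[took_now]))

    res = minimize(nll, x0=np.array([-1.0, 0.5]), method="Nelder-Mead")
    b0, b1 = res.x
    if abs(b1) < 1e-9:
        return 0.5 * (tasks.TD_MIN_IMMEDIATE + tasks.TD_DELAYED_AMOUNT)
    return float(-b0 / b1)


def estimate_indifference_points(choices: pd.DataFrame) -> tuple[dict[str, float], list[str]]:
    """Per delay, the midpoint between the largest immediate amount rejected
    and the smallest accepted (monotone-threshold summary), clipped to
    [$0.50, $10].  Non-monotone response series fall back to a logistic-fit
    midpoint and are flagged."""
    points: dict[str, float] = {}
    flagged: list[str] = []
    for label in tasks.TD_DELAY_LABELS:
        sub = choices[choices["delay_label"] == label]
        if len(sub) == 0:
            raise ValueError(f"no choices at delay {label!r}")
        amounts = sub["immediate_amount"].to_numpy(dtype=float)
        now = sub["choice"].to_numpy() == "immediate"
        accepted = amounts[now]
        rejected = amounts[~now]
        if accepted.size == 0:
            ip = tasks.TD_DELAYED_AMOUNT  # delayed always preferred: value undiminished
        elif rejected.size == 0:
            ip = tasks.TD_MIN_IMMEDIATE
        elif rejected.max() < accepted.min():
            ip = 0.5 * (rejected.max() + accepted.min())
        else:
            ip = _logistic_midpoint(amounts, now)
            flagged.append(label)
        points[label] = float(np.clip(ip, tasks.TD_MIN_IMMEDIATE, tasks.TD_DELAYED_AMOUNT))
    return points, flagged


def compute_td_auc(points: dict[str, float]) -> float:
    """Trapezoidal AUC of the normalized indifference curve.

    Delays are annualized (days / 365, with 1 mo = 30 d and 6 mo = 182.5 d)
    and values normalized by the $10 delayed reward, so the statistic lies in
    [0, 1]; a zero-delay point (subjective value 1) anchors the curve if the
    curve does not already include one.
    """
    labels = list(points)
    days = np.array(
        [tasks.TD_DELAY_DAYS[d] if d in tasks.TD_DELAY_DAYS else float(d) for d in labels],
        dtype=float,
    )
    order = np.argsort(days)
    days = days[order]
    if np.any(np.diff(days) <= 0):
        raise ValueError("delays must be strictly increasing (no duplicates)")
    vals = np.array([points[labels[i]] for i in order], dtype=float) / tasks.TD_DELAYED_AMOUNT
    t = days / 365.0
    if t[0] > 0.0:
        t = np.concatenate([[0.0], t])
        vals = np.concatenate([[1.0], vals])
    return float(np.trapezoid(vals, t))


def score_td(choices: pd.DataFrame) -> TDSummary:
    points, flagged = estimate_indifference_points(choices)
    return TDSummary(indifference_points=points, auc=compute_td_auc(points), inconsistent_delays=tuple(flagged))


# ---------------------------------------------------------------------------
# SES composite and exclusions
# ---------------------------------------------------------------------------

def compute_ses(
    income: pd.Series, educ_years_p1: pd.Series, educ_years_p2: pd.Series
) -> pd.Series:
    """SES composite: average of z(income) and z(mean parental education).

    z-scores are over the supplied cohort-level distributions.  If one
    component is missing the other is used alone; both missing propagates NaN.
    """
    def z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("cannot z-score a constant component")
        return (s - s.mean()) / sd

    educ = pd.concat([educ_years_p1, educ_years_p2], axis=1).mean(axis=1)
    z_inc, z_edu = z(income.astype(float)), z(educ.astype(float))
    return pd.concat([z_inc, z_edu], axis=1).mean(axis=1)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every wave of any participant with DUSI-R Lie > 6 (strict).

    Returns (retained cohort, exclusion log with participant and reason).
    """
    lie = cohort.groupby("participant_id")["dusi_lie"].max()
    excluded = lie[lie > LIE_EXCLUSION_THRESHOLD]
    log = pd.DataFrame(
        {
            "participant_id": excluded.index,
            "reason": [f"dusi_lie={v} > {LIE_EXCLUSION_THRESHOLD}" for v in excluded.to_numpy()],
        }
    )
    retained = cohort[~cohort["participant_id"].isin(excluded.index)].reset_index(drop=True)
    return retained, log


# ---------------------------------------------------------------------------
# Indicator matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class IndicatorMatrix:
    """Person-wave x indicator matrix, z-standardized per column.

    ``values`` holds NaN where an indicator is missing; ``mask`` is True at
    observed entries.  Rows are indexed by (participant_id, wave).
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


def score_bundle(bundle: CohortBundle) -> pd.DataFrame:
    """Score every session of a cohort bundle into raw (unstandardized)
    indicators, one row per person-wave present in the cohort table."""
    rows = []
    for _, rec in bundle.cohort.iterrows():
        key = (rec["participant_id"], rec["wave"])
        session = bundle.trials.get(key, {})
        row: dict[str, float] = {"participant_id": key[0], "wave": key[1]}
        row["bis"] = rec["bis"]
        if "cpt" in session:
            s = score_cpt(session["cpt"])
            row.update(
                cpt_dprime=s.d_prime, cpt_lnbeta=s.ln_beta, cpt_hit_rt_sd=s.hit_rt_sd, cpt_fa_rt_sd=s.fa_rt_sd
            )
        if "wof" in session:
            s = score_wof(session["wof"])
            row.update(
                wof_p_high_risk=s.p_high_risk,
                wof_rt_high=s.rt_high_mean,
                wof_rt_low=s.rt_low_mean,
                wof_winnings=s.cumulative_winnings,
            )
        if "efr" in session:
            s = score_efr(session["efr"])
            row.update(
                efr_neg_acc=s.neg_accuracy,
                efr_neg_rt=s.neg_rt_mean,
                efr_neg_rt_sd=s.neg_rt_sd,
                efr_pos_acc=s.pos_accuracy,
                efr_pos_rt=s.pos_rt_mean,
                efr_pos_rt_sd=s.pos_rt_sd,
            )
        if "td" in session:
            row["td_auc"] = score_td(session["td"]).auc
        rows.append(row)
    raw = pd.DataFrame(rows).set_index(["participant_id", "wave"])
    return raw.reindex(columns=list(INDICATORS))


def build_indicator_matrix(raw_indicators: pd.DataFrame) -> IndicatorMatrix:
    """z-standardize each indicator column over all retained person-waves.

    Missing entries stay missing (masked, never imputed).  A column with zero
    variance over its observed entries raises, naming the column.
    """
    values = raw_indicators.astype(float).copy()
    for col in values.columns:
        x = values[col]
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"indicator column {col!r} has zero variance (or too few observations)")
        values[col] = (x - x.mean()) / sd
    return IndicatorMatrix(values=values, mask=values.notna())
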