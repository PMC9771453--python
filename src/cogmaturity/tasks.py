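"""Trial-level generators for the four neurocognitive tasks.

Each generator emits one session as a tidy :class:`pandas.DataFrame` whose
summary statistics, when scored with :mod:`cogmaturity.scoring`, recover the
generator's targets up to sampling error:

* CPT — go/no-go continuous performance task: 5 blocks x 30 letters (150
  trials, 27 "Q" lures); hit and false-alarm probabilities are obtained by
  analytically inverting the signal-detection equations for a target
  (d', ln beta) pair.
* WOF — wheel-of-fortune gambling task: 90 trials over 3 runs with 10:90 and
  30:70 probability splits whose *winning* expected values are equal by
  construction; a losing spin forfeits the selected amount and a timeout
  forfeits the higher amount.
* EFR — emotional face recognition: 70 trials, 10 per emotion label.
* TD — delay discounting: an adjusting-amount staircase per delay against a
  fixed $10 delayed reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._utils import RTSpec, draw_rts

# Task design constants
CPT_N_BLOCKS = 5
CPT_TRIALS_PER_BLOCK = 30
CPT_N_TRIALS = CPT_N_BLOCKS * CPT_TRIALS_PER_BLOCK
CPT_N_LURES = 27

WOF_N_TRIALS = 90
WOF_N_RUNS = 3
WOF_TIMEOUT_MS = 3000.0

EFR_EMOTIONS = ("happiness", "surprise", "sadness", "anger", "disgust", "fear", "neutral")
EFR_NEGATIVE = frozenset({"disgust", "anger", "sadness", "fear"})
EFR_TRIALS_PER_EMOTION = 10
EFR_N_TRIALS = EFR_TRIALS_PER_EMOTION * len(EFR_EMOTIONS)

TD_DELAY_LABELS = ("0d", "1d", "2d", "10d", "1mo", "6mo", "1yr")
TD_DELAY_DAYS = {"0d": 0.0, "1d": 1.0, "2d": 2.0, "10d": 10.0, "1mo": 30.0, "6mo": 182.5, "1yr": 365.0}
TD_DELAYED_AMOUNT = 10.0
TD_MIN_IMMEDIATE = 0.50


def sdt_rates_from_targets(d_prime: float, ln_beta: float) -> tuple[float, float]:
    """Invert the SDT equations: return (hit, false-alarm) probabilities.

    Solves d' = z(H) - z(F) and ln(beta) = 0.5 * (z(F)^2 - z(H)^2) for the two
    normal quantiles.  With d' = 0 the likelihood-ratio criterion beta is 1
    identically, so ln_beta must also be 0.
    """
    if not (np.isfinite(d_prime) and np.isfinite(ln_beta)):
        raise ValueError("d_prime and ln_beta must be finite")
    if d_prime == 0.0:
        if ln_beta != 0.0:
            raise ValueError("with d_prime = 0, ln_beta = 0 is the only consistent target")
        z_hit = z_fa = 0.0
    else:
        s = -ln_beta / d_prime  # (z_hit + z_fa) / 2
        z_hit = d_prime / 2.0 + s
        z_fa = -d_prime / 2.0 + s
    return float(norm.cdf(z_hit)), float(norm.cdf(z_fa))


@dataclass(frozen=True)
class CPTRTParams:
    hit: RTSpec = field(default_factory=lambda: RTSpec(420.0, 120.0))
    false_alarm: RTSpec = field(default_factory=lambda: RTSpec(380.0, 120.0))


def generate_cpt_session(
    target_dprime: float,
    target_lnbeta: float,
    rt_params: CPTRTParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one 150-trial CPT session hitting (d', ln beta) in expectation."""
    rng = np.random.default_rng() if rng is None else rng
    rt_params = rt_params or CPTRTParams()
    p_hit, p_fa = sdt_rates_from_targets(target_dprime, target_lnbeta)

    stimulus = np.array(["target"] * CPT_N_TRIALS, dtype=object)
    lure_idx = rng.choice(CPT_N_TRIALS, size=CPT_N_LURES, replace=False)
    stimulus[lure_idx] = "lure"

    letters = rng.choice([c for c in "ABCDEFGHIJKLMNOPRSTUVWXYZ"], size=CPT_N_TRIALS)
    letters = letters.astype(object)
    letters[lure_idx] = "Q"

    is_lure = stimulus == "lure"
    p_respond = np.where(is_lure, p_fa, p_hit)
    responded = rng.random(CPT_N_TRIALS) < p_respond

    rt = np.full(CPT_N_TRIALS, np.nan)
    hit_mask = responded & ~is_lure
    fa_mask = responded & is_lure
    rt[hit_mask] = draw_rts(rt_params.hit, int(hit_mask.sum()), rng)
    rt[fa_mask] = draw_rts(rt_params.false_alarm, int(fa_mask.sum()), rng)

    return pd.DataFrame(
        {
            "trial": np.arange(CPT_N_TRIALS),
            "block": np.arange(CPT_N_TRIALS) // CPT_TRIALS_PER_BLOCK,
            "letter": letters,
            "stimulus": stimulus,
            "responded": responded,
            "rt_ms": rt,
        }
    )


@dataclass(frozen=True)
class WOFRTParams:
    high: RTSpec = field(default_factory=lambda: RTSpec(1250.0, 350.0))
    low: RTSpec = field(default_factory=lambda: RTSpec(1350.0, 350.0))


# (low win prob, low amounts) and matched high = low * p_low / p_high keeps
# the winning-side expected value identical across risk levels.
_WOF_DESIGNS = {
    "10:90": {"p_high": 0.10, "p_low": 0.90, "low_amounts": (1, 2), "ratio": 9},
    "30:70": {"p_high": 0.30, "p_low": 0.70, "low_amounts": (3, 6, 9), "ratio": 7 / 3},
}


def generate_wof_session(
    p_high_risk: float,
    rt_params: WOFRTParams | None = None,
    timeout_rate: float = 0.02,
    anticipatory_rate: float = 0.02,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one 90-trial wheel-of-fortune session.

    ``p_high_risk`` is the probability of choosing the risky side on any
    non-timeout trial.  The 10:90 split occurs 32-42 times and the 30:70
    split 48-58 times, uniformly within those design bounds.
    """
    for name, p in (("p_high_risk", p_high_risk), ("timeout_rate", timeout_rate), ("anticipatory_rate", anticipatory_rate)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    rt_params = rt_params or WOFRTParams()

    n_1090 = int(rng.integers(32, 43))
    splits = np.array(["10:90"] * n_1090 + ["30:70"] * (WOF_N_TRIALS - n_1090), dtype=object)
    rng.shuffle(splits)

    low_amt = np.empty(WOF_N_TRIALS)
    high_amt = np.empty(WOF_N_TRIALS)
    p_win_high = np.empty(WOF_N_TRIALS)
    p_win_low = np.empty(WOF_N_TRIALS)
    for split, d in _WOF_DESIGNS.items():
        m = splits == split
        lows = rng.choice(d["low_amounts"], size=int(m.sum()))
        low_amt[m] = lows
        high_amt[m] = lows * d["ratio"]
        p_win_high[m] = d["p_high"]
        p_win_low[m] = d["p_low"]

    u = rng.random(WOF_N_TRIALS)
    timeout = u < timeout_rate
    high = ~timeout & (rng.random(WOF_N_TRIALS) < p_high_risk)
    choice = np.where(timeout, "timeout", np.where(high, "high_risk", "low_risk")).astype(object)

    p_win = np.where(high, p_win_high, p_win_low)
    won = (~timeout) & (rng.random(WOF_N_TRIALS) < p_win)
    selected = np.where(high, high_amt, low_amt)
    payoff = np.where(timeout, -high_amt, np.where(won, selected, -selected))

    rt = np.where(high, draw_rts(rt_params.high, WOF_N_TRIALS, rng), draw_rts(rt_params.low, WOF_N_TRIALS, rng))
    anticip = (~timeout) & (rng.random(WOF_N_TRIALS) < anticipatory_rate)
    rt[anticip] = rng.uniform(50.0, 199.0, size=int(anticip.sum()))
    rt[timeout] = WOF_TIMEOUT_MS

    run = np.arange(WOF_N_TRIALS) // (WOF_N_TRIALS // WOF_N_RUNS)
    cumulative = np.concatenate([np.cumsum(payoff[run == r]) for r in range(WOF_N_RUNS)])

    return pd.DataFrame(
        {
            "trial": np.arange(WOF_N_TRIALS),
            "run": run,
            "split": splits,
            "low_amount": low_amt,
            "high_amount": high_amt,
            "choice": choice,
            "rt_ms": rt,
            "win": np.where(won, "yes", "no"),
            "payoff": payoff,
            "cumulative_winnings": cumulative,
        }
    )


@dataclass(frozen=True)
class EFRRTParams:
    negative: RTSpec = field(default_factory=lambda: RTSpec(1900.0, 500.0))
    positive: RTSpec = field(default_factory=lambda: RTSpec(1500.0, 420.0))
    other: RTSpec = field(default_factory=lambda: RTSpec(1800.0, 480.0))


def generate_efr_session(
    neg_acc: float,
    pos_acc: float,
    rt_params: EFRRTParams | None = None,
    other_acc: float = 0.85,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one 70-trial emotion-labeling session (10 trials per emotion).

    Errors are distributed uniformly over the six incorrect labels.
    """
    for name, p in (("neg_acc", neg_acc), ("pos_acc", pos_acc), ("other_acc", other_acc)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    rt_params = rt_params or EFRRTParams()

    true = np.repeat(np.array(EFR_EMOTIONS, dtype=object), EFR_TRIALS_PER_EMOTION)
    rng.shuffle(true)

    acc = np.where(
        np.isin(true, list(EFR_NEGATIVE)), neg_acc, np.where(true == "happiness", pos_acc, other_acc)
    )
    correct = rng.random(EFR_N_TRIALS) < acc
    chosen = true.copy()
    for i in np.flatnonzero(~correct):
        others = [e for e in EFR_EMOTIONS if e != true[i]]
        chosen[i] = others[int(rng.integers(len(others)))]

    rt = np.empty(EFR_N_TRIALS)
    neg_mask = np.isin(true, list(EFR_NEGATIVE))
    pos_mask = true == "happiness"
    oth_mask = ~(neg_mask | pos_mask)
    rt[neg_mask] = draw_rts(rt_params.negative, int(neg_mask.sum()), rng)
    rt[pos_mask] = draw_rts(rt_params.positive, int(pos_mask.sum()), rng)
    rt[oth_mask] = draw_rts(rt_params.other, int(oth_mask.sum()), rng)

    return pd.DataFrame(
        {"trial": np.arange(EFR_N_TRIALS), "true_emotion": true, "chosen_emotion": chosen, "rt_ms": rt}
    )


def generate_td_session(
    true_discount_profile: dict[str, float],
    choice_noise_sd: float = 0.0,
    n_trials_per_delay: int = 6,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate an adjusting-amount staircase against a $10 delayed reward.

    ``true_discount_profile`` maps each delay label to the responder's
    subjective present value of $10 at that delay, in (0, 10].  On each trial
    the responder takes the immediate amount iff it exceeds that value plus
    Gaussian choice noise; the offered amount then steps down (after an
    immediate choice) or up (after a delayed choice) with halving step sizes.
    """
    rng = np.random.default_rng() if rng is None else rng
    for label in TD_DELAY_LABELS:
        if label not in true_discount_profile:
            raise ValueError(f"discount profile missing delay {label!r}")
        v = true_discount_profile[label]
        if not (0.0 < v <= TD_DELAYED_AMOUNT):
            raise ValueError(f"subjective value at {label!r} must be in (0, {TD_DELAYED_AMOUNT}]")

    rows = []
    t = 0
    for label in TD_DELAY_LABELS:
        v = true_discount_profile[label]
        amount = 5.0
        step = 2.5
        for _ in range(n_trials_per_delay):
            offered = float(np.clip(round(amount, 2), TD_MIN_IMMEDIATE, TD_DELAYED_AMOUNT))
            noise = rng.normal(0.0, choice_noise_sd) if choice_noise_sd > 0 else 0.0
            take_now = offered > v + noise
            rows.append((t, label, offered, TD_DELAYED_AMOUNT, "immediate" if take_now else "delayed"))
            amount = amount - step if take_now else amount + step
            step /= 2.0
            t += 1
    return pd.DataFrame(rows, columns=["trial", "delay_label", "immediate_amount", "delayed_amount", "choice"])


def hyperbolic_profile(k: float) -> dict[str, float]:
    """Subjective values of $10 under hyperbolic discounting v = A / (1 + k*t),
    with t the delay annualized (days / 365)."""
    if k < 0:
        raise ValueError("discount rate k must be >= 0")
    return {
        label: TD_DELAYED_AMOUNT / (1.0 + k * TD_DELAY_DAYS[label] / 365.0) for label in TD_DELAY_LABELS
    }


def hyperbolic_k_for_auc(target_auc: float) -> float:
    """Find the hyperbolic rate k whose normalized discount curve has the
    requested trapezoidal AUC (monotone in k; solved by bisection)."""
    if not (0.0 < target_auc <= 1.0):
        raise ValueError("target_auc must be in (0, 1]")
    t = np.array([TD_DELAY_DAYS[d] for d in TD_DELAY_LABELS]) / 365.0

    def auc_of(k: float) -> float:
        v = 1.0 / (1.0 + k * t)
        return float(np.trapezoid(v, t))

    if target_auc >= auc_of(0.0) - 1e-12:
        return 0.0
    lo, hi = 0.0, 1.0
    while auc_of(hi) > target_auc:
        hi *= 2.0
        if hi > 1e9:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if auc_of(mid) > target_auc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
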