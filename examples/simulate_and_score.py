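"""Generate one synthetic task session per task and score it.

Shows the round trip the whole package is built on: a trial-level simulator
parameterized by target summary statistics, and a scorer that recovers them.
"""

import numpy as np

from cogmaturity import scoring, tasks

rng = np.random.default_rng(7)

cpt = tasks.generate_cpt_session(target_dprime=2.0, target_lnbeta=0.0, rng=rng)
s = scoring.score_cpt(cpt)
print(f"CPT: {len(cpt)} trials, {(cpt.stimulus == 'lure').sum()} lures")
print(f"  scored d' = {s.d_prime:.3f} (target 2.0), ln(beta) = {s.ln_beta:.3f} (target 0.0)")
mean_d = np.mean(
    [scoring.score_cpt(tasks.generate_cpt_session(2.0, 0.0, rng=rng)).d_prime for _ in range(100)]
)
print(f"  mean scored d' over 100 sessions = {mean_d:.3f}: single-session scatter is "
      "binomial noise on 123 targets / 27 lures, not bias")

wof = tasks.generate_wof_session(p_high_risk=0.6, rng=rng)
w = scoring.score_wof(wof)
print(f"WOF: P(high risk) = {w.p_high_risk:.2f}, cumulative winnings = ${w.cumulative_winnings:.0f}")
print("  risky choices carry negative net expected payoff, so winnings fall as risk rises")

profile = tasks.hyperbolic_profile(k=2.0)
td = tasks.generate_td_session(profile, choice_noise_sd=0.3, rng=rng)
t = scoring.score_td(td)
true_auc = scoring.compute_td_auc(profile)
print(f"TD: scored AUC = {t.auc:.3f} (generating curve AUC = {true_auc:.3f})")
print("  AUC near 1 = patient responder, near 0 = steep discounter")
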