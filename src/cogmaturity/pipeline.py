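"""Reproducible end-to-end pipeline: simulate -> score -> fit-latent -> fit-age -> report.

A single master seed fans out to a named substream per stage, so inserting a
new stage never perturbs the draws of existing ones.  All tabular outputs are
CSV, model objects are JSON, and the run manifest records seeds, stage
counts and a SHA-256 checksum for every file written.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import latent, maturity, scoring
from ._utils import stage_seed


@dataclass(frozen=True)
class PipelineConfig:
    cohort: cohort_mod.CohortConfig = field(default_factory=cohort_mod.CohortConfig)
    growth: cohort_mod.LatentGrowthSpec = field(default_factory=cohort_mod.ads_growth_spec)
    age_model: maturity.AgeModelConfig = field(default_factory=maturity.AgeModelConfig)
    sign_convention: str = "predicted_minus_observed"
    seed: int = 0
    write_trials: bool = False
    compute_se: bool = True
    fit_structural: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        g = d["growth"]
        for key in ("residual_covariances", "structural_paths", "covariate_effects"):
            g[key] = {"|".join(k): v for k, v in g[key].items()}
        g["loadings"] = {ind: list(v) for ind, v in g["loadings"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        g = dict(d.get("growth", {}))
        for key in ("residual_covariances", "structural_paths", "covariate_effects"):
            if key in g:
                g[key] = {tuple(k.split("|")): v for k, v in g[key].items()}
        if "loadings" in g:
            g["loadings"] = {ind: tuple(v) for ind, v in g["loadings"].items()}
        cc = d.get("cohort", {})
        for key in ("wave1_age_range", "inter_wave_gap_mean_sd"):
            if key in cc:
                cc[key] = tuple(cc[key])
        am = dict(d.get("age_model", {}))
        if "alphas" in am:
            am["alphas"] = tuple(am["alphas"])
        return cls(
            cohort=cohort_mod.CohortConfig(**cc),
            growth=cohort_mod.LatentGrowthSpec(**g),
            age_model=maturity.AgeModelConfig(**am),
            sign_convention=d.get("sign_convention", "predicted_minus_observed"),
            seed=d.get("seed", 0),
            write_trials=d.get("write_trials", False),
            compute_se=d.get("compute_se", True),
            fit_structural=d.get("fit_structural", True),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


DATA_DICTIONARY = {
    "cohort.csv": {
        "participant_id": "participant identifier",
        "wave": "assessment wave (1-based)",
        "age": "chronological age at assessment, years",
        "sex": "female/male",
        "bmi": "body-mass index, kg/m^2",
        "pds": "pubertal development score (1-4)",
        "income": "household income, $/year",
        "educ_years_p1": "parent/guardian 1 education, years",
        "educ_years_p2": "parent/guardian 2 education, years",
        "ses": "socioeconomic composite, z-units (mean of income and education z-scores)",
        "iq": "composite IQ",
        "bis": "behavioral inhibition scale score",
        "bas_d": "behavioral activation: drive",
        "bas_fs": "behavioral activation: fun-seeking",
        "bas_rr": "behavioral activation: reward responsiveness",
        "dusi_lie": "DUSI-R Lie validity scale (participants with Lie > 6 are excluded)",
        "dusi_substance_use": "DUSI-R substance-use problem scale",
        "dusi_health_risk": "DUSI-R health-risk problem scale",
        "dusi_violence_risk": "DUSI-R violence-risk problem scale",
    },
    "indicators.csv": {
        "cpt_dprime": "CPT target-lure discriminability d'",
        "cpt_lnbeta": "CPT log response-bias criterion ln(beta)",
        "cpt_hit_rt_sd": "CPT hit reaction-time SD, ms",
        "cpt_fa_rt_sd": "CPT false-alarm reaction-time SD, ms",
        "bis": "behavioral inhibition scale score",
        "wof_p_high_risk": "WOF probability of high-risk choices (valid trials)",
        "wof_rt_high": "WOF mean RT on high-risk choices, ms",
        "wof_rt_low": "WOF mean RT on low-risk choices, ms",
        "wof_winnings": "WOF cumulative winnings over runs, $",
        "td_auc": "delay-discounting area under the normalized indifference curve",
        "efr_neg_acc": "EFR negative-emotion accuracy (disgust/anger/sadness/fear)",
        "efr_neg_rt": "EFR negative-emotion mean RT, ms",
        "efr_neg_rt_sd": "EFR negative-emotion RT SD, ms",
        "efr_pos_acc": "EFR happiness accuracy",
        "efr_pos_rt": "EFR happiness mean RT, ms",
        "efr_pos_rt_sd": "EFR happiness RT SD, ms",
    },
}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis and write all artifacts under ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).  Any stage
    failure raises :class:`StageError`; partial outputs are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    stage = "simulate"
    t0 = time.time()
    try:
        seed = int(stage_seed(config.seed, stage).generate_state(1)[0] % (2**31))
        bundle = cohort_mod.generate_cohort(replace(config.cohort, seed=seed), config.growth)
        emit("cohort.csv", lambda p: _write_csv(bundle.cohort, p, index=False))
        emit("ground_truth.json", lambda p: p.write_text(bundle.truth.to_json(orient="records", indent=2)))
        if config.write_trials:
            tdir = outdir / "trials"
            tdir.mkdir(exist_ok=True)
            for (pid, wave), session in bundle.trials.items():
                for task, df in session.items():
                    path = tdir / f"{pid}_{wave}_{task}.csv"
                    _write_csv(df, path, index=False)
                    written.append(path)
        manifest["stages"][stage] = {
            "seed": seed,
            "n_participants": int(bundle.cohort["participant_id"].nunique()),
            "n_person_waves": int(len(bundle.cohort)),
            "seconds": round(time.time() - t0, 3),
        }
        log(f"[simulate] {len(bundle.cohort)} person-waves")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "score"
    t0 = time.time()
    try:
        retained, exclusion_log = scoring.apply_exclusions(bundle.cohort)
        raw = scoring.score_bundle(
            cohort_mod.CohortBundle(retained, bundle.trials, bundle.truth, bundle.config, bundle.growth)
        )
        matrix = scoring.build_indicator_matrix(raw)
        emit("indicators.csv", lambda p: _write_csv(matrix.values, p, index=True))
        emit("indicator_mask.json", lambda p: p.write_text(json.dumps(
            {"columns": matrix.columns, "observed": matrix.mask.to_numpy().astype(int).tolist()})))
        emit("exclusions.tsv", lambda p: exclusion_log.to_csv(p, sep="\t", index=False))
        n_masked = int((~matrix.mask.to_numpy()).sum())
        manifest["stages"][stage] = {
            "n_excluded_participants": int(len(exclusion_log)),
            "n_retained_person_waves": int(len(matrix.values)),
            "n_masked_entries": n_masked,
            "seconds": round(time.time() - t0, 3),
        }
        log(f"[score] excluded {len(exclusion_log)} participants (Lie > 6); {n_masked} masked entries")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "fit-latent"
    t0 = time.time()
    try:
        spec = latent.ads_measurement_spec()
        cfa = latent.fit_cfa(spec, matrix, compute_se=config.compute_se)
        emit("cfa_model.json", lambda p: cfa.to_json(p))
        emit("cfa_parameters.csv", lambda p: _write_csv(cfa.parameter_table(), p, index=False))
        sem = None
        if config.fit_structural:
            sem = latent.fit_sem(spec, matrix, compute_se=config.compute_se)
            emit("sem_model.json", lambda p: sem.to_json(p))
            emit("sem_parameters.csv", lambda p: _write_csv(sem.parameter_table(), p, index=False))
        fscores = latent.extract_factor_scores(cfa, matrix)
        emit("factor_scores.csv", lambda p: _write_csv(fscores.scores, p, index=True))
        manifest["stages"][stage] = {
            "cfa_converged": cfa.converged,
            "cfa_chi2": round(cfa.fit["chi2"], 4),
            "cfa_df": cfa.fit["df"],
            "cfa_cfi": round(cfa.fit["cfi"], 4),
            "cfa_rmsea": round(cfa.fit["rmsea"], 4),
            "sem_converged": (sem.converged if sem is not None else None),
            "n_scored_person_waves": int(len(fscores.scores)),
            "seconds": round(time.time() - t0, 3),
        }
        log(f"[fit-latent] CFA chi2={cfa.fit['chi2']:.2f} df={cfa.fit['df']} CFI={cfa.fit['cfi']:.3f}")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "fit-age"
    t0 = time.time()
    try:
        ages = retained.set_index(["participant_id", "wave"])["age"]
        am_seed = int(stage_seed(config.seed, stage).generate_state(1)[0] % (2**31))
        am_cfg = replace(config.age_model, seed=am_seed)
        fit = maturity.fit_regularized_age_model(fscores.scores, ages, am_cfg)
        complete = fscores.scores.dropna()
        pred = maturity.predict_age(fit, complete)
        cmi = maturity.compute_cmi(pred, ages.loc[complete.index], config.sign_convention)
        corr = maturity.correlate_cmi(cmi, retained)
        emit("age_model.json", lambda p: p.write_text(json.dumps(
            {
                "alpha": fit.alpha,
                "lambda": fit.lam,
                "coefficients": fit.coef.to_dict(),
                "intercept": fit.intercept,
                "test_r2": fit.test_r2,
                "test_mae_months": fit.test_mae_months,
                "train_n": fit.train_n,
                "test_n": fit.test_n,
                "sign_convention": config.sign_convention,
            },
            indent=2,
        )))
        emit("cmi.csv", lambda p: _write_csv(cmi.table, p, index=True))
        emit("cmi_correlations.tsv", lambda p: corr.to_csv(p, sep="\t", index=False))
        emit("predicted_vs_observed.csv", lambda p: _write_csv(
            cmi.table[["observed_age", "predicted_age"]], p, index=True))
        manifest["stages"][stage] = {
            "seed": am_seed,
            "alpha": fit.alpha,
            "lambda": round(fit.lam, 6),
            "test_r2": round(fit.test_r2, 4),
            "test_mae_months": round(fit.test_mae_months, 3),
            "n_predicted": int(len(cmi.table)),
            "seconds": round(time.time() - t0, 3),
        }
        log(f"[fit-age] alpha={fit.alpha} lambda={fit.lam:.4g} test R2={fit.test_r2:.3f} "
            f"MAE={fit.test_mae_months:.2f} months")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "report"
    t0 = time.time()
    try:
        emit("data_dictionary.json", lambda p: p.write_text(json.dumps(DATA_DICTIONARY, indent=2)))
        emit("report.md", lambda p: p.write_text(_render_report(manifest, cfa, sem, fit, cmi, corr)))
        emit("run.log", lambda p: p.write_text("\n".join(log_lines) + "\n"))
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    generated = manifest["stages"]["simulate"]["n_person_waves"]
    excluded_rows = generated - manifest["stages"]["score"]["n_retained_person_waves"]
    manifest["counts"] = {
        "generated_person_waves": generated,
        "excluded_person_waves": excluded_rows,
        "retained_person_waves": manifest["stages"]["score"]["n_retained_person_waves"],
        "masked_entries": manifest["stages"]["score"]["n_masked_entries"],
    }
    for path in written:
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _render_report(manifest, cfa, sem, fit, cmi, corr) -> str:
    lines = ["# Cognitive maturity pipeline report", ""]
    lines += [f"Master seed: {manifest['seed']}", ""]
    lines += ["## Measurement model (CFA)", ""]
    lines.append(cfa.loadings.round(4).to_string(index=False))
    f = cfa.fit
    lines += ["", f"chi2 = {f['chi2']:.3f} (df = {f['df']}, p = {f['p_value']:.3f}); "
              f"RMSEA = {f['rmsea']:.4f}, CFI = {f['cfi']:.4f}, TLI = {f['tli']:.4f}", ""]
    if sem is not None:
        lines += ["## Structural paths", ""]
        lines.append(sem.paths.round(4).to_string(index=False))
        lines.append("")
    lines += ["## Age prediction", "",
              f"alpha = {fit.alpha}, lambda = {fit.lam:.4g}; held-out R^2 = {fit.test_r2:.3f}, "
              f"MAE = {fit.test_mae_months:.2f} months (n = {fit.test_n})", ""]
    lines += ["## CMI covariate correlations", ""]
    lines.append(corr.round(4).to_string(index=False))
    lines += ["", f"CMI sign convention: {cmi.sign_convention}", ""]
    return "\n".join(lines)


def make_fixtures(scale: str, outdir, seed: int = 20260) -> dict:
    """Write a deterministic fixture bundle: ``tiny`` (n=12, for unit tests)
    or ``demo`` (n=141, the full study design)."""
    if scale == "tiny":
        cfg = PipelineConfig(
            cohort=cohort_mod.CohortConfig(n_participants=12, dropout_rate_per_wave=0.0,
                                           indicator_missing_rate=0.0, lie_gt6_rate=0.0),
            seed=seed,
            write_trials=True,
            compute_se=False,
            fit_structural=False,
        )
        bundle = cohort_mod.generate_cohort(replace(cfg.cohort, seed=seed), cfg.growth)
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_csv(bundle.cohort, outdir / "cohort.csv", index=False)
        (outdir / "ground_truth.json").write_text(bundle.truth.to_json(orient="records", indent=2))
        tdir = outdir / "trials"
        tdir.mkdir(exist_ok=True)
        n_files = 0
        for (pid, wave), session in bundle.trials.items():
            for task, df in session.items():
                _write_csv(df, tdir / f"{pid}_{wave}_{task}.csv", index=False)
                n_files += 1
        return {"scale": scale, "n_participants": 12, "n_trial_files": n_files, "outdir": str(outdir)}
    if scale == "demo":
        cfg = PipelineConfig(seed=seed)
        manifest = run_pipeline(cfg, outdir)
        return {"scale": scale, "outdir": str(outdir), "manifest": manifest}
    raise ValueError("scale must be 'tiny' or 'demo'")
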