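"""End-to-end pipeline: simulate/load -> QC -> harmonize -> prune -> score ->
PCA -> stratify -> model -> ROC, bundled into a reproducible report directory.

Event orientation throughout: the "positive" outcome is nonresponse /
nonremission (the clinically adverse state the GRS is meant to flag);
response and remission are their complements.  Stratification p-values are
flagged at 0.05; regression model comparisons at the multiplicity-adjusted
0.025.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SimulationConfig, simulate_cohort
from .models import REGRESSION_ALPHA, compare_models, fit_linear, fit_logistic, point_biserial, pearson_corr
from .popstruct import compute_pcs, flag_outliers, grs_normality
from .published import REFERENCE_MARGINS, REFERENCE_ROWS
from .roc import roc_curve, youden
from .scoring import compute_grs, harmonize_weights, prune_ld, qc_variants
from .stratify import decile_report, odds_ratio, reconstruct_table, round_half_up
from . import io as pio

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "verify_table2"]

ENDPOINTS = ("nonresponse", "nonremission")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Exactly one of ``simulation`` (a :class:`SimulationConfig` block) or the
    three input paths must be supplied.
    """

    outdir: str = "psygrs_run"
    seed: int = 2026
    simulation: SimulationConfig | None = None
    vcf_path: str | None = None
    weights_path: str | None = None
    phenotypes_path: str | None = None
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    endpoints: tuple[str, ...] = ENDPOINTS
    covariates: tuple[str, ...] = ("age", "sex", "treatment_arm", "severity")
    pc_counts: tuple[int, ...] = (0, 2, 10)
    scoring_mode: str = "mean_per_allele"
    maf_min: float = 0.05
    call_rate_min: float = 0.98
    hwe_p_min: float = 1e-6
    p_max: float = 5.0e-6
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.5

    def __post_init__(self) -> None:
        paths = (self.vcf_path, self.weights_path, self.phenotypes_path)
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.simulation is not None and some_paths:
            raise ValueError("supply either a simulation block or input paths, not both")
        if self.simulation is None and not have_paths:
            raise ValueError("supply a simulation block or all three input paths")
        bad = set(self.endpoints) - set(ENDPOINTS)
        if bad:
            raise ValueError(f"unknown endpoints: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None,
            **{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()},
        )
        return cfg

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _design_matrix(pheno: pd.DataFrame, covariates: tuple[str, ...], grs_z: np.ndarray | None,
                   pc_scores: np.ndarray | None, n_pcs: int) -> pd.DataFrame:
    X = pd.DataFrame(index=pheno.index)
    for cov in covariates:
        if cov == "treatment_arm":
            X["arm_combo"] = (pheno["treatment_arm"] == "venlafaxine_quetiapine").astype(float)
        else:
            X[cov] = pd.to_numeric(pheno[cov])
    if n_pcs and pc_scores is not None:
        for c in range(n_pcs):
            X[f"PC{c + 1}"] = pc_scores[:, c]
    if grs_z is not None:
        X["grs"] = grs_z
    return X


def _tsv_header(fh, config_hash: str) -> None:
    fh.write(f"# psygrs {__version__} config_hash={config_hash}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Returns the manifest (also written to ``manifest.json``).  Rerunning with
    an identical config reproduces the bundle bit for bit.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "stages": [],
        "files": [],
    }

    def emit_json(name: str, payload: dict) -> None:
        payload = {"config_hash": chash, **payload}
        (outdir / name).write_text(json.dumps(payload, indent=2, default=float))
        manifest["files"].append(name)

    def stage(name: str):
        manifest["stages"].append(name)

    # --- inputs -----------------------------------------------------------
    stage("input")
    try:
        if config.simulation is not None:
            sim = config.simulation
            genotypes, weights_table, phenotypes = simulate_cohort(sim)
            pio.write_vcf(genotypes, outdir / "genotypes.vcf", header_comment=f"config_hash={chash}")
            pio.write_weights_tsv(weights_table, outdir / "weights.tsv")
            pio.write_phenotypes_csv(phenotypes, outdir / "phenotypes.csv")
            manifest["files"] += ["genotypes.vcf", "weights.tsv", "phenotypes.csv"]
        else:
            genotypes = pio.read_vcf(config.vcf_path)
            weights_table = pio.read_weights_tsv(config.weights_path)
            phenotypes = pio.read_phenotypes_csv(config.phenotypes_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", "E_INPUT", str(exc)) from exc

    # --- QC ---------------------------------------------------------------
    stage("qc")
    try:
        genotypes_qc, qc_summary = qc_variants(
            genotypes, config.maf_min, config.call_rate_min, config.hwe_p_min, return_summary=True
        )
        emit_json("qc_summary.json", qc_summary)
    except Exception as exc:
        raise PipelineError("qc", "E_QC", str(exc)) from exc

    # --- harmonize + prune + score ---------------------------------------
    stage("score")
    try:
        weights = harmonize_weights(weights_table, genotypes_qc, p_max=config.p_max)
        emit_json("harmonization_report.json", weights.report)
        pruned = prune_ld(genotypes_qc, weights, config.prune_window, config.prune_step, config.prune_r2)
        with (outdir / "pruned_weights.tsv").open("w") as fh:
            _tsv_header(fh, chash)
            pruned.table.to_csv(fh, sep="\t", index=False)
        manifest["files"].append("pruned_weights.tsv")
        scores = compute_grs(genotypes_qc, pruned, mode=config.scoring_mode)
        with (outdir / "scores.tsv").open("w") as fh:
            _tsv_header(fh, chash)
            pd.DataFrame({"individual_id": genotypes_qc.samples, "grs": scores.values}).to_csv(
                fh, sep="\t", index=False
            )
        manifest["files"].append("scores.tsv")
        emit_json(
            "score_summary.json",
            {
                "n_variants": scores.n_variants,
                "mode": scores.mode,
                "median": float(np.nanmedian(scores.values)),
                "min": float(np.nanmin(scores.values)),
                "max": float(np.nanmax(scores.values)),
                "normality": grs_normality(scores.values),
            },
        )
    except Exception as exc:
        raise PipelineError("score", "E_SCORE", str(exc)) from exc

    # --- PCA --------------------------------------------------------------
    stage("pca")
    try:
        k = min(max(config.pc_counts, default=2), genotypes_qc.n_individuals - 1, genotypes_qc.n_variants)
        k = max(k, 2)
        pcs = flag_outliers(compute_pcs(genotypes_qc, k=k))
        with (outdir / "pcs.tsv").open("w") as fh:
            _tsv_header(fh, chash)
            df = pd.DataFrame(pcs.scores, columns=[f"PC{i + 1}" for i in range(pcs.k)])
            df.insert(0, "individual_id", genotypes_qc.samples)
            df["population_outlier"] = pcs.outlier_flags.astype(int)
            df.to_csv(fh, sep="\t", index=False)
        manifest["files"].append("pcs.tsv")
        with (outdir / "pc_pairs.tsv").open("w") as fh:  # PC1-PC3 scatter data
            _tsv_header(fh, chash)
            df.iloc[:, : min(4, df.shape[1])].to_csv(fh, sep="\t", index=False)
        manifest["files"].append("pc_pairs.tsv")
        emit_json(
            "pca_summary.json",
            {
                "explained_variance": [float(v) for v in pcs.explained_variance],
                "n_outliers": int(pcs.outlier_flags.sum()),
            },
        )
    except Exception as exc:
        raise PipelineError("pca", "E_PCA", str(exc)) from exc

    # --- stratification ---------------------------------------------------
    stage("stratify")
    try:
        strat_payload = {}
        for endpoint in config.endpoints:
            rows = decile_report(scores, phenotypes[endpoint].to_numpy(dtype=float), config.fractions)
            strat_payload[endpoint] = [
                {
                    "fraction": r.top_fraction,
                    "k_top": r.k_top,
                    "table": r.table.cells,
                    "ppv": r.ppv,
                    "npv": r.npv,
                    "accuracy": r.accuracy,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "odds_ratio": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "significant_0.05": bool(r.p_value < 0.05) if np.isfinite(r.p_value) else False,
                    "correction_applied": r.correction_applied,
                }
                for r in rows
            ]
            with (outdir / f"stratification_{endpoint}.tsv").open("w") as fh:
                _tsv_header(fh, chash)
                pd.DataFrame(strat_payload[endpoint]).to_csv(fh, sep="\t", index=False)
            manifest["files"].append(f"stratification_{endpoint}.tsv")
        emit_json("stratification.json", strat_payload)
    except Exception as exc:
        raise PipelineError("stratify", "E_STRAT", str(exc)) from exc

    # --- models + ROC -----------------------------------------------------
    stage("model")
    try:
        pc_scores = pcs.scores
        grs_z = scores.standardized()
        models_payload: dict = {}
        roc_payload: dict = {}
        for endpoint in config.endpoints:
            y = phenotypes[endpoint].to_numpy(dtype=float)
            per_pc = {}
            for n_pcs in config.pc_counts:
                n_pcs_eff = min(n_pcs, pc_scores.shape[1])
                base = fit_logistic(y, _design_matrix(phenotypes, config.covariates, None, pc_scores, n_pcs_eff))
                ext = fit_logistic(y, _design_matrix(phenotypes, config.covariates, grs_z, pc_scores, n_pcs_eff))
                cmp_ = compare_models(base, ext)
                per_pc[str(n_pcs)] = {
                    "base": _fit_summary(base),
                    "with_grs": _fit_summary(ext),
                    "comparison": asdict(cmp_),
                }
                if n_pcs == 0:
                    ok = ~np.isnan(y)
                    Xb = _design_matrix(phenotypes, config.covariates, None, None, 0).loc[ok]
                    Xe = _design_matrix(phenotypes, config.covariates, grs_z, None, 0).loc[ok]
                    import statsmodels.api as sm

                    pb = sm.Logit(y[ok], sm.add_constant(Xb)).fit(disp=False).predict()
                    pe = sm.Logit(y[ok], sm.add_constant(Xe)).fit(disp=False).predict()
                    rb, re_ = roc_curve(pb, y[ok]), roc_curve(pe, y[ok])
                    roc_payload[endpoint] = {
                        "note": "in-sample AUC: probabilities from models fitted on the same data",
                        "auc_base": rb.auc,
                        "auc_with_grs": re_.auc,
                        "auc_pct_change": 100.0 * (re_.auc - rb.auc) / rb.auc,
                        "youden_base": youden(rb),
                        "youden_with_grs": youden(re_),
                    }
                    for label, rc in (("base", rb), ("with_grs", re_)):
                        fname = f"roc_{endpoint}_{label}.tsv"
                        with (outdir / fname).open("w") as fh:
                            _tsv_header(fh, chash)
                            pd.DataFrame(
                                [(p.threshold, p.sensitivity, p.specificity) for p in rc.points],
                                columns=["threshold", "sensitivity", "specificity"],
                            ).to_csv(fh, sep="\t", index=False)
                        manifest["files"].append(fname)
            models_payload[endpoint] = per_pc
        # linear model for adequate-trial count (no treatment-arm covariate:
        # the trial count predates randomization)
        covs = tuple(c for c in config.covariates if c != "treatment_arm")
        y_tr = phenotypes["n_adequate_trials"].to_numpy(dtype=float)
        base = fit_linear(y_tr, _design_matrix(phenotypes, covs, None, None, 0))
        ext = fit_linear(y_tr, _design_matrix(phenotypes, covs, grs_z, None, 0))
        models_payload["n_adequate_trials"] = {
            "base": _fit_summary(base),
            "with_grs": _fit_summary(ext),
            "comparison": asdict(compare_models(base, ext)),
        }
        corr = {
            "nonresponse": asdict(point_biserial(phenotypes["nonresponse"].to_numpy(dtype=float), scores.values)),
            "nonremission": asdict(point_biserial(phenotypes["nonremission"].to_numpy(dtype=float), scores.values)),
            "n_adequate_trials": asdict(pearson_corr(y_tr, scores.values)),
        }
        emit_json("models.json", {"alpha": REGRESSION_ALPHA, "models": models_payload, "correlations": corr})
        emit_json("roc_summary.json", roc_payload)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("model", "E_MODEL", str(exc)) from exc

    manifest["files"].sort()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _fit_summary(fit) -> dict:
    out = {
        "kind": fit.kind,
        "n_used": fit.n_used,
        "model_p": fit.model_p,
        "coefficients": {k: float(v) for k, v in fit.params["coef"].items()},
        "p_values": {k: float(v) for k, v in fit.params["p"].items()},
    }
    if fit.kind == "linear":
        out["r_squared"] = fit.r_squared
        out["adjusted_r_squared"] = fit.adjusted_r_squared
    else:
        out["mcfadden"] = fit.mcfadden
        out["mcfadden_adjusted"] = fit.mcfadden_adjusted
        out["nagelkerke"] = fit.nagelkerke
    return out


def verify_table2() -> dict:
    """Check the odds-ratio machinery against the published stratification rows.

    For every reconstructible published row the rounded printed summaries are
    inverted to the unique integer 2x2 table and the recomputed OR, CI bounds
    and p-value are compared with the printed values at printed precision.
    The two top-10% rows are reported as excluded (known inconsistency in the
    printed summaries), never as passes.
    """
    report = {"rows": [], "n_pass": 0, "n_fail": 0, "n_excluded": 0}
    for row in REFERENCE_ROWS:
        margins = REFERENCE_MARGINS[row.endpoint]
        entry = {"endpoint": row.endpoint, "fraction": row.fraction}
        if not row.reconstructible:
            entry["status"] = "EXCLUDED"
            entry["note"] = (
                "printed summaries are internally inconsistent; no integer table "
                "with the stated margins reproduces them"
            )
            report["n_excluded"] += 1
            report["rows"].append(entry)
            continue
        table = reconstruct_table(
            row.ppv,
            row.accuracy if row.use_accuracy else None,
            n=margins["n"],
            n_events=margins["n_events"],
            fraction=row.fraction,
        )
        orr = odds_ratio(table)
        checks = {
            "odds_ratio": (round_half_up(orr.odds_ratio, 2), row.odds_ratio),
            "ci_low": (round_half_up(orr.ci_low, 2), row.ci_low),
            "ci_high": (round_half_up(orr.ci_high, 2), row.ci_high),
            "p_value": (round_half_up(orr.p_value, row.p_decimals), row.p_value),
        }
        ok = all(got == want for got, want in checks.values())
        entry.update(
            status="PASS" if ok else "FAIL",
            table=table.cells,
            computed={k: v[0] for k, v in checks.items()},
            printed={k: v[1] for k, v in checks.items()},
        )
        report["n_pass" if ok else "n_fail"] += 1
        report["rows"].append(entry)
    return report
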