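"""End-to-end study orchestration.

``run_study`` chains simulate → validate → QC → score → normalize →
classify → clinical endpoints → concordance → survival (→ establishment)
and emits a flat, machine-readable report.  Every number in the report is
computed by the public module operations on the intermediate tables; the
run is deterministic given the configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical_endpoints import DECREASE, derive_patient_responses, responses_frame
from .concordance_stats import (
    ContingencyTable,
    diagnostic_performance,
    empirical_roc,
    pearson_r,
)
from .errors import OdrsError
from .plate_model import ScreenConfig, dumps_plate_table, validate_layout
from .response_metrics import SENSITIVE, normalize_metrics, score_screen
from .screen_qc import qc_gate
from .survival_analysis import firth_cox, kaplan_meier, log_rank
from .synthetic_data import (
    FOCAL_REGIMEN,
    CohortTruth,
    generate_establishment_cohort,
    generate_screen_cohort,
)

logger = logging.getLogger(__name__)


class StageError(OdrsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_pdos": 23,
    "noise_cv": 0.08,
    "screen": {},
    "cohort_truth": {},
    "establishment": {"enabled": True, "n": 205},
}


def _round_floats(obj, sig: int = 10):
    """Recursively round floats to `sig` significant digits for diffability."""
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return repr(obj)
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def _log_stage(stage: str, n_in: int, n_out: int, note: str = "") -> None:
    logger.info("stage=%s n_in=%d n_out=%d %s", stage, n_in, n_out, note)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **raw}
    cfg["establishment"] = {**DEFAULT_CONFIG["establishment"], **cfg.get("establishment", {})}
    return cfg


def _concordance_block(
    scores: np.ndarray, sensitive: np.ndarray, pct_change: np.ndarray
) -> dict:
    decrease = pct_change < 0
    table = ContingencyTable.from_calls(sensitive, decrease)
    perf = diagnostic_performance(table)
    roc = empirical_roc(scores, decrease.astype(int))
    r, p = pearson_r(scores, pct_change)
    return {
        "table": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "ppv": perf.ppv,
        "ppv_ci": list(perf.ppv_ci),
        "npv": perf.npv,
        "npv_ci": list(perf.npv_ci),
        "auroc": roc["auroc"],
        "auroc_ci": list(roc["auroc_ci"]),
        "pearson_r": r,
        "pearson_p": p,
        "n": perf.n,
    }


def _survival_block(sdf: pd.DataFrame) -> dict:
    fit = firth_cox(sdf["time_months"], sdf["event"], sdf["norm_gr_auc"], scale=0.1)
    sens = sdf[sdf["sensitivity_class"] == SENSITIVE]
    res = sdf[sdf["sensitivity_class"] != SENSITIVE]
    block = {
        "firth_hr_per_0.1": fit.hr,
        "firth_ci": list(fit.ci),
        "firth_wald_p": fit.wald_p,
        "firth_converged": fit.converged,
        "n": int(len(sdf)),
        "n_events": int(sdf["event"].sum()),
    }
    if len(sens) and len(res):
        km_s = kaplan_meier(sens["time_months"], sens["event"])
        km_r = kaplan_meier(res["time_months"], res["event"])
        chi2, p = log_rank(
            sens["time_months"], sens["event"], res["time_months"], res["event"]
        )
        block.update(
            {
                "median_sensitive": km_s["median"],
                "median_resistant": km_r["median"],
                "logrank_chi2": chi2,
                "logrank_p": p,
            }
        )
    return block


def run_study(config=None, seed: int | None = None, out_dir=None) -> dict:
    """Run the full synthetic study and return the report dictionary.

    `config` is a YAML path or dict (see DEFAULT_CONFIG); `seed` overrides
    the configured seed; `out_dir`, when given, receives report.json plus
    TSV sidecars (metrics, QC, responses, survival).
    """
    cfg = load_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    screen_cfg = ScreenConfig.from_dict(cfg.get("screen", {}))
    cohort_truth = CohortTruth(**cfg.get("cohort_truth", {}))

    sim = generate_screen_cohort(
        n_pdos=cfg["n_pdos"],
        cohort_truth=cohort_truth,
        cfg=screen_cfg,
        noise_cv=cfg["noise_cv"],
        seed=cfg["seed"],
    )
    checksums = {
        p: hashlib.sha256(dumps_plate_table(w).encode()).hexdigest()[:16]
        for p, w in sim["plates"].items()
    }
    _log_stage("simulate", cfg["n_pdos"], sum(len(w) for w in sim["plates"].values()))

    # validate + QC + score
    all_metrics = []
    qc_rows = []
    for pdo_id, wells in sim["plates"].items():
        violations = validate_layout(wells, screen_cfg)
        if violations:
            raise StageError("validate", f"{pdo_id}: {violations[0]}")
        reports, included = qc_gate(wells, screen_cfg, pdo_id)
        qc_rows.extend(r.__dict__ for r in reports)
        all_metrics.extend(score_screen(wells, screen_cfg, pdo_id, included_bio_reps=included))
    _log_stage("qc+score", len(sim["plates"]), len(all_metrics))

    if not all_metrics:
        raise StageError("score", "no screens passed quality gates; nothing to score")
    normalized = normalize_metrics(all_metrics, screen_cfg)
    metrics_df = pd.DataFrame([m.__dict__ for m in normalized])

    focal = metrics_df[metrics_df["drug"] == FOCAL_REGIMEN].set_index("pdo_id")
    if focal.empty:
        raise StageError("concordance", f"no QC-passed screens for {FOCAL_REGIMEN}")

    responses = derive_patient_responses(sim["clinical"])
    resp_df = responses_frame(responses).set_index("patient_id")
    joined = focal.join(resp_df, how="inner")
    if joined.empty:
        raise StageError("concordance", "no patients with both screen and response data")
    _log_stage("endpoints", len(resp_df), len(joined))

    sensitive = (joined["sensitivity_class"] == SENSITIVE).to_numpy()
    scores = joined["norm_gr_auc"].to_numpy(dtype=float)
    concordance = {
        "targets": _concordance_block(
            scores, sensitive, joined["pct_change_targets"].to_numpy(dtype=float)
        ),
        "biopsied": _concordance_block(
            scores, sensitive, joined["pct_change_biopsied"].to_numpy(dtype=float)
        ),
    }

    surv = sim["survival"].merge(
        focal[["norm_gr_auc", "sensitivity_class"]],
        left_on="patient_id",
        right_index=True,
    )
    survival = {
        endpoint: _survival_block(surv[surv["endpoint"] == endpoint])
        for endpoint in ("pfs", "os")
    }
    _log_stage("survival", len(surv), len(survival))

    report = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items() if k != "screen"},
        "seed": cfg["seed"],
        "input_checksums": checksums,
        "n_pdos": cfg["n_pdos"],
        "mean_z_prime": float(
            np.mean([r["z_prime"] for r in qc_rows if r["z_prime"] is not None])
        ),
        "n_screens_scored": int(len(metrics_df)),
        "concordance": concordance,
        "survival": survival,
    }

    est_cfg = cfg["establishment"]
    if est_cfg.get("enabled", True):
        from .establishment_model import fit_establishment_model
        from .synthetic_data import DEFAULT_PERIOD_KNOTS

        cohort = generate_establishment_cohort(est_cfg["n"], seed=cfg["seed"])
        fit = fit_establishment_model(cohort, knots=DEFAULT_PERIOD_KNOTS)
        report["establishment"] = {
            "n": int(len(cohort)),
            "success_rate_pct": float(100.0 * cohort["success"].mean()),
            "selected_terms": list(fit.selected_terms),
            "aic": fit.aic,
            "auroc": fit.auroc,
            "auroc_ci": list(fit.auroc_ci),
            "max_vif": max(fit.vif.values()) if fit.vif else None,
            "prob_summary": fit.prob_summary,
        }
        _log_stage("establishment", est_cfg["n"], len(fit.selected_terms))

    report = _round_floats(report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        metrics_df.to_csv(out / "metrics.tsv", sep="\t", index=False)
        pd.DataFrame(qc_rows).to_csv(out / "qc.tsv", sep="\t", index=False)
        responses_frame(responses).to_csv(out / "responses.tsv", sep="\t", index=False)
        surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    return report


def main(argv: Sequence[str] | None = None) -> int:  # pragma: no cover - thin shim
    import argparse

    ap = argparse.ArgumentParser(description="run the synthetic screening study")
    ap.add_argument("--config", default=None)
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--out-dir", default=None)
    args = ap.parse_args(argv)
    try:
        run_study(args.config, seed=args.seed, out_dir=args.out_dir)
    except OdrsError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
    return 0
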