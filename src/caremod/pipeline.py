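"""End-to-end orchestration of the analysis stages.

``run_all`` executes, in dependency order: calcium simulation ->
feature extraction -> per-response mixed fits with letter displays;
expression simulation -> QC -> dual-platform DE -> concordance ->
reversal -> selectivity summary; qPCR simulation -> ddCt analysis.
All randomness is funnelled through one integer seed; identical
config + seed yields an identical report payload.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, grouping, mixed, qc, qpcr, reversal
from .features import FEATURE_NAMES, extract_features
from .panel import load_panel
from .simulate import (
    CalciumSimConfig,
    ExprSimConfig,
    QpcrSimConfig,
    simulate_calcium,
    simulate_expression_pair,
    simulate_qpcr,
)


@dataclass
class RunConfig:
    """Top-level configuration for a full pipeline run."""

    seed: int = 0
    alpha: float = 0.05
    alpha2: float = 0.10
    fdr: float = 0.05
    calcium: CalciumSimConfig = field(default_factory=CalciumSimConfig)
    expression: ExprSimConfig = field(default_factory=ExprSimConfig)
    qpcr: QpcrSimConfig = field(default_factory=QpcrSimConfig)
    responses: tuple[str, ...] = tuple(FEATURE_NAMES)
    baseline_mode: str = "combined"

    def validate(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.alpha2 < 1 and 0 < self.fdr < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.alpha >= self.alpha2:
            raise ValueError("alpha must be < alpha2")
        self.calcium.validate()
        self.expression.validate()
        self.qpcr.validate()

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        cfg = cls()
        for key in ("seed", "alpha", "alpha2", "fdr", "baseline_mode"):
            if key in payload:
                setattr(cfg, key, payload[key])
        if "responses" in payload:
            cfg.responses = tuple(payload["responses"])
        for section, klass in (
            ("calcium", CalciumSimConfig),
            ("expression", ExprSimConfig),
            ("qpcr", QpcrSimConfig),
        ):
            if section in payload:
                setattr(cfg, section, klass(**payload[section]))
        # derive per-module seeds from the top-level one
        cfg.calcium.seed = cfg.seed
        cfg.expression.seed = cfg.seed + 1
        cfg.qpcr.seed = cfg.seed + 2
        return cfg


def run_calcium_stage(config: RunConfig) -> dict:
    """Simulate traces, extract features, fit and letter every response."""
    traces, truth = simulate_calcium(config.calcium)
    extraction = extract_features(traces, config.calcium.protocol())
    features = extraction.features
    letters = {}
    contrasts = {}
    for response in config.responses:
        spec = mixed.ModelSpec(response=response, random=("day", "coverslip"))
        fit = mixed.fit_condition_model(features, spec)
        disp, ctr, _ = grouping.letter_display(fit, alpha=config.alpha)
        letters[response] = dict(zip(disp["condition"], disp["letters"]))
        contrasts[response] = ctr
    return {
        "traces": traces,
        "features": features,
        "truth": truth,
        "letters": letters,
        "contrasts": contrasts,
        "n_rejects": int(len(extraction.rejects)),
    }


def run_expression_stage(config: RunConfig) -> dict:
    """Simulate paired platforms, run QC, DE, concordance and reversal."""
    matrix_a, matrix_b, sheet, truth = simulate_expression_pair(config.expression)
    panel = load_panel()
    qc_out = qc.qc_report(matrix_a, sheet, seed=config.seed)
    tables_a, _, report_a = diffexpr.run_de(matrix_a, sheet, panel=panel, fdr=config.fdr)
    tables_b, _, report_b = diffexpr.run_de(matrix_b, sheet, panel=panel, fdr=config.fdr)

    cancer_calls = reversal.call_cross_platform_de(
        tables_a["line"][["q", "logFC"]],
        tables_b["line"][["q", "logFC"]],
        alpha1=config.alpha,
        alpha2=config.alpha2,
    )
    if config.baseline_mode == "combined":
        baseline: pd.DataFrame = cancer_calls
    else:
        baseline = tables_a["line"][["q", "logFC"]]
    reversals = reversal.classify_reversal(
        baseline,
        tables_a["treatment_HT29"][["q", "logFC"]],
        alpha=config.fdr,
        baseline_mode=config.baseline_mode,
    )
    selectivity = reversal.summarize_selectivity(
        tables_a["treatment_NCM460"],
        tables_a["treatment_HT29"],
        panel,
        reversals=reversals,
        alpha=config.fdr,
    )
    return {
        "matrix_a": matrix_a,
        "matrix_b": matrix_b,
        "sheet": sheet,
        "truth": truth,
        "qc": qc_out,
        "tables_a": tables_a,
        "tables_b": tables_b,
        "cancer_calls": cancer_calls,
        "reversals": reversals,
        "selectivity": selectivity,
        "de_reports": {"a": report_a, "b": report_b},
    }


def run_qpcr_stage(config: RunConfig) -> dict:
    """Simulate Ct tables and run the ddCt comparison."""
    ct = simulate_qpcr(config.qpcr)
    test, calib = config.qpcr.groups
    result = qpcr.analyze_qpcr(ct, test_group=test, calibrator_group=calib)
    return {"ct_table": ct, "result": result}


def run_all(config: RunConfig | dict) -> dict:
    """Execute all stages; a stage failure halts with the stage named."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    config.validate()
    report: dict = {"seed": config.seed, "stages": {}}
    t0 = time.time()
    stages = (
        ("calcium", run_calcium_stage),
        ("expression", run_expression_stage),
        ("qpcr", run_qpcr_stage),
    )
    outputs: dict = {}
    for name, fn in stages:
        start = time.time()
        try:
            outputs[name] = fn(config)
        except Exception as exc:
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            report["runtime_s"] = time.time() - t0
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {
            "status": "ok",
            "elapsed_s": round(time.time() - start, 3),
        }
    report["letters"] = outputs["calcium"]["letters"]
    report["selectivity"] = outputs["expression"]["selectivity"]
    report["reversed_genes"] = sorted(
        outputs["expression"]["reversals"]
        .index[outputs["expression"]["reversals"]["reversed"]]
        .tolist()
    )
    report["qpcr_log2_fold"] = (
        outputs["qpcr"]["result"].table["log2_fold"].round(6).to_dict()
    )
    report["runtime_s"] = round(time.time() - t0, 3)
    report["_outputs"] = outputs  # in-memory artefacts, not serialised
    return report


def serialise_report(report: dict, path: str | Path) -> None:
    payload = {k: v for k, v in report.items() if k != "_outputs"}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
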