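"""End-to-end orchestration: score, prepare, validate, report.

``run_validation`` wires the modules together: load the model and input
CSVs, score the questionnaire, summarise the dietary records, apply the
eligibility filters, and quantify discriminative accuracy per protein
threshold and probability cut-off. The report is returned as a plain dict
(JSON-serialisable) and, when an output directory is configured, written
as ``report.json``, ``metrics.csv``, ``roc_points.csv`` and
``exclusions.csv``.

Formatting follows the conventions of screening-validation reports:
percentages rounded to 1 decimal (half away from zero), probabilities to
2 decimals; all underlying values are carried at full precision in the
JSON.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from pro55 import dietary, diagnostics, screener
from pro55.errors import DegenerateDataError

DEFAULT_THRESHOLDS = (1.0, 0.8)
DEFAULT_CUTOFFS = (0.3, 0.5, 0.7)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables).

    Plain ``round`` rounds half to even; report tables round 0.05 -> 0.1.
    """
    x = float(x)
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(x: float, ndigits: int = 1) -> float:
    """Proportion -> percentage with report rounding; NaN passes through."""
    return round_half_up(100.0 * x, ndigits)


class RunConfig(BaseModel):
    """Paths and analysis settings for one validation run."""

    model_config = ConfigDict(frozen=True)

    model_path: Optional[str] = None  # None -> bundled synthetic stand-in model
    participants_path: str
    responses_path: str
    dietary_path: str
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    ci_method: str = "clopper_pearson"
    ci_level: float = Field(default=0.95, gt=0, lt=1)
    auc_ci_method: str = "delong"
    output_dir: Optional[str] = None
    seed: int = 0

    @field_validator("thresholds", "cutoffs")
    @classmethod
    def _nonempty(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) == 0:
            raise ValueError("thresholds and cutoffs must be nonempty")
        if any(x <= 0 for x in v):
            raise ValueError("thresholds and cutoffs must be positive")
        return v


def _describe(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    return {"mean": float(np.mean(values)), "sd": float(np.std(values, ddof=1))}


def validate_scores(
    scores: np.ndarray,
    protein_per_kg_abw: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    ci_method: str = "clopper_pearson",
    ci_level: float = 0.95,
    auc_ci_method: str = "delong",
) -> dict:
    """Diagnostic-accuracy report for aligned score/reference arrays.

    One block per protein threshold: prevalence, ROC operating points, AUC
    with CI, the Youden cut-off, and per probability cut-off the confusion
    table and the four accuracy metrics with CIs.
    """
    scores = np.asarray(scores, dtype=float)
    intake = np.asarray(protein_per_kg_abw, dtype=float)
    out: dict = {"n": int(scores.size), "thresholds": {}}
    for thr in thresholds:
        labels = intake < thr
        n_pos = int(labels.sum())
        if n_pos == 0 or n_pos == labels.size:
            raise DegenerateDataError(
                f"threshold {thr}: all participants on one side of the reference"
            )
        roc = diagnostics.roc_with_ci(
            scores, labels, level=ci_level, method=auc_ci_method
        )
        block = {
            "threshold": float(thr),
            "n_low_intake": n_pos,
            "n_adequate": int(labels.size - n_pos),
            "prevalence": n_pos / labels.size,
            "prevalence_pct": as_percent(n_pos / labels.size),
            "auc": roc.auc,
            "auc_ci": [roc.auc_ci_low, roc.auc_ci_high],
            "auc_ci_method": auc_ci_method,
            "youden_cutoff": roc.youden_cutoff,
            "youden_sensitivity": roc.youden_sens,
            "youden_specificity": roc.youden_spec,
            "roc_points": [
                {"cutoff": c, "tpr": t, "fpr": f}
                for c, t, f in roc.operating_points
            ],
            "cutoffs": {},
        }
        for cut in cutoffs:
            table = diagnostics.confusion_at_cutoff(scores, labels, cut, threshold=thr)
            metrics = diagnostics.accuracy_metrics(
                table, ci_method=ci_method, level=ci_level
            )
            block["cutoffs"][f"{cut:g}"] = {
                "cutoff": float(cut),
                "confusion": {
                    "tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn
                },
                "metrics": {
                    name: {
                        "estimate": m.estimate,
                        "percent": as_percent(m.estimate),
                        "ci_low": m.ci_low,
                        "ci_high": m.ci_high,
                        "ci_low_pct": as_percent(m.ci_low),
                        "ci_high_pct": as_percent(m.ci_high),
                        "k": m.k,
                        "n": m.n,
                        "ci_method": m.ci_method,
                    }
                    for name, m in metrics.items()
                },
            }
        out["thresholds"][f"{thr:g}"] = block
    return out


def run_validation(config: RunConfig) -> dict:
    """Run the full score -> prepare -> validate pipeline from CSV inputs."""
    model = (
        screener.load_model(config.model_path)
        if config.model_path
        else screener.load_default_model()
    )
    participants = pd.read_csv(config.participants_path, dtype={"participant_id": str})
    responses = pd.read_csv(config.responses_path, dtype=str)
    days = pd.read_csv(config.dietary_path, dtype={"participant_id": str})

    scored = screener.score_participants(model, responses, participants)
    summaries = dietary.summarize_records(days, participants)
    included, exclusion_log = dietary.apply_eligibility(participants, summaries, scored)

    cohort = (
        included[["participant_id", "age", "sex"]]
        .merge(scored, on="participant_id")
        .merge(summaries, on="participant_id")
    )
    report: dict = {
        "model": model.metadata,
        "flow": {
            "n_read": int(len(participants)),
            "n_excluded": int(len(exclusion_log)),
            "n_included": int(len(cohort)),
            "exclusion_counts": exclusion_log["reason"].value_counts().to_dict(),
        },
        "descriptives": {
            "age": _describe(cohort["age"]),
            "pct_female": as_percent((cohort["sex"] == "female").mean()),
            "bmi": _describe(cohort["bmi"]),
            "energy_kcal": _describe(cohort["mean_energy"]),
            "protein_g": _describe(cohort["mean_protein"]),
            "protein_per_kg_abw": _describe(cohort["protein_per_kg_abw"]),
            "energy_pct_protein": _describe(cohort["energy_pct_protein"]),
            "energy_pct_fat": _describe(cohort["energy_pct_fat"]),
            "energy_pct_carb": _describe(cohort["energy_pct_carb"]),
            "predicted_probability_median": float(
                np.median(cohort["predicted_probability"])
            ),
            "predicted_probability_iqr": [
                float(np.percentile(cohort["predicted_probability"], 25)),
                float(np.percentile(cohort["predicted_probability"], 75)),
            ],
        },
    }
    report.update(
        validate_scores(
            cohort["predicted_probability"].to_numpy(),
            cohort["protein_per_kg_abw"].to_numpy(),
            thresholds=config.thresholds,
            cutoffs=config.cutoffs,
            ci_method=config.ci_method,
            ci_level=config.ci_level,
            auc_ci_method=config.auc_ci_method,
        )
    )

    if config.output_dir:
        write_report(report, exclusion_log, Path(config.output_dir))
    return report


def metrics_frame(report: dict) -> pd.DataFrame:
    """Flatten the report into one row per threshold x cutoff x metric."""
    rows = []
    for thr_key, block in report["thresholds"].items():
        for cut_key, cell in block["cutoffs"].items():
            for name, m in cell["metrics"].items():
                rows.append(
                    {
                        "threshold": block["threshold"],
                        "cutoff": cell["cutoff"],
                        "metric": name,
                        "percent": m["percent"],
                        "ci_low_pct": m["ci_low_pct"],
                        "ci_high_pct": m["ci_high_pct"],
                        "k": m["k"],
                        "n": m["n"],
                    }
                )
    return pd.DataFrame(rows)


def roc_points_frame(report: dict) -> pd.DataFrame:
    rows = []
    for thr_key, block in report["thresholds"].items():
        for pt in block["roc_points"]:
            rows.append({"threshold": block["threshold"], **pt})
    return pd.DataFrame(rows)


def write_report(report: dict, exclusion_log: pd.DataFrame, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, allow_nan=True)
    metrics_frame(report).to_csv(outdir / "metrics.csv", index=False)
    roc_points_frame(report).to_csv(outdir / "roc_points.csv", index=False)
    exclusion_log.to_csv(outdir / "exclusions.csv", index=False)


def render_text_report(report: dict) -> str:
    """Human-readable summary mirroring the tabular report layout."""
    lines = [
        f"Included participants: {report['n']}",
    ]
    if "flow" in report:
        flow = report["flow"]
        lines.insert(0, f"Read {flow['n_read']}, excluded {flow['n_excluded']} "
                        f"({flow['exclusion_counts']}), included {flow['n_included']}.")
    for thr_key, block in report["thresholds"].items():
        lines.append("")
        lines.append(
            f"Reference: protein intake < {block['threshold']:g} g/kg aBW/d "
            f"(prevalence {block['prevalence_pct']}%, "
            f"n={block['n_low_intake']}/{block['n_low_intake'] + block['n_adequate']})"
        )
        lines.append(
            f"  AUC {as_percent(block['auc'])}% "
            f"(95%CI {as_percent(block['auc_ci'][0])}-{as_percent(block['auc_ci'][1])})"
        )
        lines.append(
            f"  Best trade-off cut-off {round_half_up(block['youden_cutoff'], 2):.2f}: "
            f"sensitivity {as_percent(block['youden_sensitivity'])}%, "
            f"specificity {as_percent(block['youden_specificity'])}%"
        )
        for cut_key, cell in block["cutoffs"].items():
            m = cell["metrics"]
            lines.append(
                f"  cut-off >{cell['cutoff']:g}: "
                + ", ".join(
                    f"{name} {m[name]['percent']}% "
                    f"({m[name]['ci_low_pct']}-{m[name]['ci_high_pct']})"
                    for name in ("sensitivity", "specificity", "ppv", "npv")
                )
            )
    return "\n".join(lines)
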