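"""End-to-end per-sex analysis: transforms -> factorial screen -> the five
pairwise diagnostic models, with report rendering.

The five default comparisons discriminate (1) AD vs controls among
non-diabetics, (2) T2DM vs controls among non-AD subjects, (3) AD without
T2DM vs T2DM without AD, and the comorbid group against (4) AD-only and
(5) T2DM-only subjects.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

from .ancova import fit_transforms, screen_all_variables, screen_table
from .cohort import CohortTable, read_cohort, split_by_sex
from .evaluate import EvalReport, evaluate_in_sample, explained_variability_percent
from .opls import OplsConfig, OplsError, OplsModel, fit_opls

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = (
    ("A+D-", "A-D-"),
    ("A-D+", "A-D-"),
    ("A+D-", "A-D+"),
    ("A+D+", "A+D-"),
    ("A+D+", "A-D+"),
)


@dataclass
class PipelineConfig:
    input: str | CohortTable = ""
    sexes: tuple[str, ...] = ("F", "M")
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    seed: int = 0
    output_dir: str | None = None
    steroids_only: bool = False
    opls: OplsConfig = field(default_factory=OplsConfig)


@dataclass
class ModelReport:
    sex: str
    case: str
    control: str
    model: OplsModel | None
    evaluation: EvalReport | None
    error: str | None = None


def _predictor_universe(table: CohortTable, steroids_only: bool) -> list[str]:
    names = []
    for spec in table.spec:
        if spec.name not in table.df.columns:
            continue
        if steroids_only and spec.block not in ("steroid", "shbg"):
            continue
        names.append(spec.name)
    return names


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Run the whole pipeline; returns a result bundle (dict).

    Per-model failures are recorded in the bundle, not raised.  The
    manifest (seed, config, input hash, effective n) makes a rerun with
    the same seed reproduce the bundle.
    """
    if isinstance(cfg.input, CohortTable):
        table = cfg.input
        input_hash = "in-memory"
    else:
        table = read_cohort(cfg.input)
        input_hash = hashlib.sha256(
            pathlib.Path(cfg.input).read_bytes()).hexdigest()

    women, men = split_by_sex(table)
    by_sex = {"F": women, "M": men}
    bundle: dict = {
        "manifest": {
            "seed": cfg.seed, "input_hash": input_hash,
            "sexes": list(cfg.sexes),
            "pairs": [list(p) for p in cfg.pairs],
            "steroids_only": cfg.steroids_only,
        },
        "screens": {}, "models": [],
    }
    opls_cfg = OplsConfig(**{**vars(cfg.opls), "seed": cfg.seed})

    for sex in cfg.sexes:
        sub = by_sex[sex]
        if len(sub) == 0:
            continue
        transforms = fit_transforms(sub)
        results, pairs, failures = screen_all_variables(sub, transforms)
        bundle["screens"][sex] = {
            "table": screen_table(results, pairs).to_dict(orient="records"),
            "failures": failures,
        }
        universe = _predictor_universe(sub, cfg.steroids_only)
        for case, control in cfg.pairs:
            report = ModelReport(sex=sex, case=case, control=control,
                                 model=None, evaluation=None)
            try:
                model = fit_opls(sub, (case, control), universe,
                                 transforms, opls_cfg)
                report.model = model
                report.evaluation = evaluate_in_sample(model)
            except (OplsError, ValueError) as exc:
                report.error = str(exc)
                logger.warning("model %s vs %s (%s) failed: %s",
                               case, control, sex, exc)
            bundle["models"].append(report)

    if cfg.output_dir:
        _write_bundle(bundle, cfg.output_dir)
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable Markdown report mirroring the published model tables."""
    lines = ["# Steroidome discriminant analysis", ""]
    for report in bundle["models"]:
        title = f"{report.case} vs {report.control} ({report.sex})"
        lines.append(f"## {title}")
        if report.error:
            lines.append(f"model failed: {report.error}")
            lines.append("")
            continue
        model, ev = report.model, report.evaluation
        if not model.predictor_stats:
            lines.append("no relevant predictors")
            lines.append("")
            continue
        lines.append("| Variable | Loading (R) | t | VIP | |")
        lines.append("|---|---|---|---|---|")
        for s in model.predictor_stats:
            lines.append(
                f"| {s.predictor} | {s.R:.3f} | {s.t_statistic:.2f} | "
                f"{s.vip:.2f} | {s.significance} |")
        lines.append("")
        lines.append(
            f"Explained variability: {ev.r2y_percent:.1f}% "
            f"({ev.q2_percent:.1f}% after cross-validation)")
        lines.append(ev.footer())
        lines.append("")
    return "\n".join(lines)


def _write_bundle(bundle: dict, output_dir: str) -> None:
    out = pathlib.Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    serializable = {
        "manifest": bundle["manifest"],
        "screens": bundle["screens"],
        "models": [
            {
                "sex": r.sex, "case": r.case, "control": r.control,
                "error": r.error,
                "model": json.loads(r.model.to_json()) if r.model else None,
                "evaluation": r.evaluation.to_dict() if r.evaluation else None,
            }
            for r in bundle["models"]
        ],
    }
    text = json.dumps(serializable, indent=1, sort_keys=True)
    (out / "bundle.json").write_text(text)
    (out / "report.md").write_text(render_report(bundle))
    digest = hashlib.sha256(text.encode()).hexdigest()
    manifest = dict(bundle["manifest"], bundle_sha256=digest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def bundle_hash(bundle: dict) -> str:
    """Deterministic digest of a bundle's serialized content."""
    serializable = {
        "manifest": bundle["manifest"],
        "models": [
            {"sex": r.sex, "case": r.case, "control": r.control,
             "error": r.error,
             "model": json.loads(r.model.to_json()) if r.model else None}
            for r in bundle["models"]
        ],
    }
    return hashlib.sha256(
        json.dumps(serializable, sort_keys=True).encode()).hexdigest()
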