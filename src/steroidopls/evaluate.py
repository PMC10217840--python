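"""Diagnostic evaluation: confusion counts, sensitivity/specificity with
unclipped Wald 95% intervals, and explained-variability reporting.

The Wald interval p +/- 1.96*sqrt(p(1-p)/n) is deliberately NOT clipped to
[0, 1]; near-perfect classifiers therefore report bounds slightly outside
the unit interval, matching the convention of the reference tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .opls import OplsModel, Prediction

Z975 = 1.96


@dataclass(frozen=True)
class EvalReport:
    n_cases: int
    n_controls: int
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: tuple[float, float, float]   # (point, low, high)
    specificity: tuple[float, float, float]
    r2y_percent: float
    q2_percent: float

    def footer(self) -> str:
        """One-line summary formatted like the published table footers."""
        def fmt(t):
            point, low, high = (round(v, 3) for v in t)
            def s(v):
                return f"{v:g}"
            return f"{s(point)} ({s(low)}, {s(high)})"
        return (f"Sensitivity = {fmt(self.sensitivity)}, "
                f"Specificity = {fmt(self.specificity)}")

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": list(self.sensitivity),
            "specificity": list(self.specificity),
            "r2y_percent": self.r2y_percent, "q2_percent": self.q2_percent,
        }


def sens_spec_ci(k: int, n: int) -> tuple[float, float, float]:
    """Proportion k/n with its unclipped Wald 95% CI."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    point = k / n
    half = Z975 * np.sqrt(point * (1.0 - point) / n)
    return point, point - half, point + half


def explained_variability_percent(r: float) -> float:
    """Explained variability (%) implied by a dependent-variable loading R."""
    if abs(r) > 1:
        raise ValueError(f"|R| must be <= 1, got {r}")
    return 100.0 * r * r


def evaluate(model: OplsModel, predictions: list[Prediction],
             truth: dict[str, int]) -> EvalReport:
    """Confusion-at-0.5 summary of predictions against true labels.

    ``truth`` maps subject_id -> 1 (case) / 0 (control).  A probability of
    exactly 0.5 counts as a negative call (documented tie-break).
    """
    missing = [p.subject_id for p in predictions if p.subject_id not in truth]
    if missing:
        raise ValueError(f"no truth label for subject(s) {missing[:5]}")
    labels = np.array([truth[p.subject_id] for p in predictions])
    if labels.min() == labels.max():
        raise ValueError("both classes must be present in the truth labels")
    calls = np.array([p.probability > 0.5 for p in predictions])
    cases, controls = labels == 1, labels == 0
    tp = int((calls & cases).sum())
    fn = int((~calls & cases).sum())
    fp = int((calls & controls).sum())
    tn = int((~calls & controls).sum())
    return EvalReport(
        n_cases=int(cases.sum()), n_controls=int(controls.sum()),
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens_spec_ci(tp, tp + fn),
        specificity=sens_spec_ci(tn, tn + fp),
        r2y_percent=100.0 * model.r2y, q2_percent=100.0 * model.q2)


def evaluate_in_sample(model: OplsModel) -> EvalReport:
    """Evaluate the model on its own training subjects."""
    from .opls import Prediction  # local alias for clarity
    a, slope = model.calibration
    llr = np.clip(a + slope * model.t_p, -model.llr_cap, model.llr_cap)
    prob = 1.0 / (1.0 + np.exp(-llr))
    y01 = model.y + model.y_mean
    preds = [Prediction(sid, float(t), float(l), float(p), int(p > 0.5))
             for sid, t, l, p in zip(model.subject_ids, model.t_p, llr, prob)]
    truth = {sid: int(round(v))
             for sid, v in zip(model.subject_ids, y01)}
    return evaluate(model, preds, truth)
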