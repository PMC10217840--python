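"""Synthetic cohort generation calibrated to printed group statistics.

The study's raw per-subject data are not deposited, so the pipeline is
exercised on synthetic cohorts that reproduce the published structure:

* the four diagnostic cells at their published per-sex sizes,
* per-variable, per-group Gaussians on a transformed scale whose
  retransformed means and 95% CIs match the published group summaries,
* a single latent class axis shared by all variables of a subject, whose
  per-variable weights mirror the published discriminant-model component
  loadings, giving the cross-variable correlation the discriminant stage
  needs to be testable.

Within-group dispersion is recovered from the printed CI of each group
mean: on the transformed scale SD = h * sqrt(n) / t_{0.975, n-1} where h
is the CI half-width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GROUPS, CohortTable, default_variables
from .transform import TransformFit, apply_transform, invert_transform

_PACKAGED = {"F": "calibration_women.json", "M": "calibration_men.json"}


class CalibrationError(ValueError):
    """Raised when a calibration file is structurally invalid."""


def _hint_fit(transform: str, variable: str = "") -> TransformFit:
    if transform == "log":
        return TransformFit(variable, 0.0, 0.0, float("nan"), 0)
    if transform == "identity":
        return TransformFit(variable, 1.0, 0.0, float("nan"), 0)
    raise CalibrationError(f"unknown transform hint {transform!r}")


@dataclass(frozen=True)
class CalibrationTable:
    """Machine-readable transcription of published group statistics.

    ``variables`` maps name -> {"transform": hint, "cells": {group: [low,
    mean, high]}}; ``models`` maps a "case vs control" key to the class
    axis (per-variable loadings R and the dependent-variable loading).
    """

    sex: str
    groups: dict[str, int]
    variables: dict[str, dict]
    models: dict[str, dict] = field(default_factory=dict)

    def transform_fit(self, variable: str) -> TransformFit:
        return _hint_fit(self.variables[variable]["transform"], variable)

    def cell(self, variable: str, group: str) -> tuple[float, float, float]:
        low, mean, high = self.variables[variable]["cells"][group]
        return float(low), float(mean), float(high)

    def group_sd(self, variable: str, group: str) -> float:
        low, mean, high = self.cell(variable, group)
        return derive_sd_from_ci(mean, low, high, self.groups[group],
                                 self.transform_fit(variable))

    def group_mean_transformed(self, variable: str, group: str) -> float:
        _, mean, _ = self.cell(variable, group)
        return float(apply_transform(self.transform_fit(variable), mean))


def _validate_calibration(cal: CalibrationTable) -> None:
    missing = set(GROUPS) - set(cal.groups)
    if missing:
        raise CalibrationError(f"missing group(s) {sorted(missing)}")
    if any(n <= 0 for n in cal.groups.values()):
        raise CalibrationError("group sizes must be positive")
    for name, entry in cal.variables.items():
        _hint_fit(entry["transform"], name)
        for g in GROUPS:
            if g not in entry["cells"]:
                raise CalibrationError(f"{name}: missing group {g}")
            low, mean, high = entry["cells"][g]
            if not (low < mean < high):
                raise CalibrationError(
                    f"{name} / {g}: CI must satisfy low < mean < high, "
                    f"got ({low}, {mean}, {high})")
    for key, model in cal.models.items():
        for role in ("case", "control"):
            if model[role] not in GROUPS:
                raise CalibrationError(f"model {key}: bad group {model[role]}")
        for vn, r in model["loadings"].items():
            if vn not in cal.variables:
                raise CalibrationError(f"model {key}: unknown variable {vn}")
            if not -1.0 <= r <= 1.0:
                raise CalibrationError(f"model {key}: loading {vn}={r}")


def load_calibration(source) -> CalibrationTable:
    """Load a calibration from a JSON path, or ``"F"``/``"M"`` for the
    packaged per-sex files."""
    if source in _PACKAGED:
        text = resources.files("steroidopls.data").joinpath(
            _PACKAGED[source]).read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    raw = json.loads(text)
    cal = CalibrationTable(sex=raw["sex"], groups=dict(raw["groups"]),
                           variables=raw["variables"],
                           models=raw.get("models", {}))
    _validate_calibration(cal)
    return cal


def derive_sd_from_ci(mean: float, low: float, high: float, n: int,
                      transform: TransformFit) -> float:
    """Within-group SD on the transformed scale implied by a printed CI."""
    if not (low < mean < high):
        raise CalibrationError(f"need low < mean < high, got "
                               f"({low}, {mean}, {high})")
    if n < 2:
        raise CalibrationError("n must be >= 2")
    g_low = apply_transform(transform, low)
    g_high = apply_transform(transform, high)
    h = (g_high - g_low) / 2.0
    return float(h * np.sqrt(n) / stats.t.ppf(0.975, n - 1))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator.

    seed fixed => byte-identical output.  ``multiplier`` scales every group
    size; ``class_axis_strength`` scales the published loadings into the
    latent-axis weights b_j; ``noise_df`` switches the transformed-scale
    noise from Gaussian to a (variance-standardised) Student t for
    robustness experiments.
    """

    seed: int = 0
    multiplier: int = 1
    class_axis_strength: float = 1.0
    model: str | None = None
    noise_df: float | None = None


def sample_cohort(cal: CalibrationTable,
                  config: GeneratorConfig = GeneratorConfig()) -> CohortTable:
    """Draw a synthetic cohort from a calibration table.

    For subject i of group k and variable j the transformed-scale value is

        z_ij = mu_jk + sigma_jk * (b_j * u_i + sqrt(1 - b_j^2) * eps_ij)

    with u_i ~ N(0,1) the subject's latent class-axis position, eps white
    noise, and b_j = class_axis_strength * R_j taken from the configured
    model's loadings (0 for variables the model does not list).  Values are
    then back-transformed to original units.
    """
    rng = np.random.default_rng(config.seed)
    model_key = config.model
    if model_key is None and cal.models:
        model_key = next(iter(cal.models))
    loadings = (cal.models[model_key]["loadings"]
                if model_key and cal.models else {})

    var_names = [v for v in cal.variables if v != "age"]
    b = np.array([config.class_axis_strength * loadings.get(v, 0.0)
                  for v in var_names])
    if np.any(np.abs(b) > 1.0):
        raise CalibrationError(
            "class_axis_strength scales a loading outside [-1, 1]")

    frames = []
    offset = 0
    for group in GROUPS:
        n = cal.groups[group] * config.multiplier
        u = rng.standard_normal(n)
        if config.noise_df is not None:
            scale = np.sqrt((config.noise_df - 2.0) / config.noise_df)
            eps = rng.standard_t(config.noise_df,
                                 size=(n, len(var_names))) * scale
        else:
            eps = rng.standard_normal((n, len(var_names)))
        data = {}
        if "age" in cal.variables:
            mu = cal.group_mean_transformed("age", group)
            sd = cal.group_sd("age", group)
            fit = cal.transform_fit("age")
            z = mu + sd * rng.standard_normal(n)
            data["age"] = np.maximum(invert_transform(fit, z), 18.0)
        for j, name in enumerate(var_names):
            mu = cal.group_mean_transformed(name, group)
            sd = cal.group_sd(name, group)
            fit = cal.transform_fit(name)
            z = mu + sd * (b[j] * u + np.sqrt(1.0 - b[j] ** 2) * eps[:, j])
            data[name] = invert_transform(fit, z)
        frame = pd.DataFrame(data)
        frame.insert(0, "age", frame.pop("age"))
        frame.insert(0, "group", group)
        frame.insert(0, "sex", cal.sex)
        frame.insert(0, "subject_id",
                     [f"{cal.sex}{offset + i + 1:05d}" for i in range(n)])
        frames.append(frame)
        offset += n

    df = pd.concat(frames, ignore_index=True)
    spec = default_variables()
    known = {s.name for s in spec}
    # calibrations may carry variables outside the packaged dictionary
    # (e.g. constructed test calibrations): declare them ad hoc
    from .cohort import VariableSpec
    for name in cal.variables:
        if name not in known and name != "age":
            spec.append(VariableSpec(
                name=name, label=name, unit="", block="synthetic",
                assay="synthetic", positive_only=False,
                transform=cal.variables[name]["transform"]))
    return CohortTable(df, spec)


def retransformed_mean(values, transform: TransformFit) -> float:
    """Mean on the transformed scale mapped back to original units."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    return float(invert_transform(transform,
                                  float(np.mean(apply_transform(transform, x)))))
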