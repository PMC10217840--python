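"""Age-adjusted two-factor ANCOVA screen with Bonferroni pairwise tests.

Each transformed variable is modelled as

    y ~ AD + T2DM + AD:T2DM + age

with AD and T2DM the binary diagnosis factors (sum-to-zero coding) and age
a centred covariate; factor F-tests are Type III (marginal) sums of
squares, appropriate for the unbalanced factorial.  Adjusted (least-
squares) group means are evaluated at the sample mean age and mapped back
to original units with their 95% CIs.  Age itself is screened with the
same factorial model without the covariate.  The six pairwise group
contrasts are tested on the transformed scale at a Bonferroni-corrected
per-test level alpha/6.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.anova import anova_lm

from .cohort import GROUPS, CohortTable, decompose_group
from .transform import TransformFit, apply_transform, fit_lambda, retransform_interval

logger = logging.getLogger(__name__)

N_PAIRS = 6
FAMILY_ALPHA = 0.05
# ordering convention of the published "Multiple Comparisons" column
PAIR_ORDER = ("A-D-", "A-D+", "A+D-", "A+D+")


class AncovaError(ValueError):
    pass


@dataclass
class AncovaResult:
    """Per-variable factorial screen result.

    ``adjusted_means`` maps group label -> (low, mean, high) on the
    original scale.
    """

    variable: str
    n_used: int
    F_AD: float
    F_T2DM: float
    F_interaction: float
    p_AD: float
    p_T2DM: float
    p_interaction: float
    adjusted_means: dict[str, tuple[float, float, float]]
    age_adjusted: bool
    transform: TransformFit
    _fit: object = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable, "n_used": self.n_used,
            "F": {"AD": self.F_AD, "T2DM": self.F_T2DM,
                  "interaction": self.F_interaction},
            "p": {"AD": self.p_AD, "T2DM": self.p_T2DM,
                  "interaction": self.p_interaction},
            "adjusted_means": {g: list(v)
                               for g, v in self.adjusted_means.items()},
            "age_adjusted": self.age_adjusted,
            "transform": self.transform.to_dict(),
        }


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    direction: str          # "<" or ">": group_a vs group_b
    significant: bool
    p_value: float

    def __str__(self) -> str:
        return f"{self.group_a} {self.direction} {self.group_b}"


def _model_frame(table: CohortTable, variable: str,
                 fit: TransformFit) -> pd.DataFrame:
    df = table.df
    y_raw = pd.to_numeric(df[variable], errors="coerce")
    keep = y_raw.notna() & df["age"].notna()
    sub = df.loc[keep, ["group", "ad", "t2dm", "age"]].copy()
    sub["y"] = apply_transform(fit, y_raw[keep].to_numpy())
    for g in GROUPS:
        if not (sub["group"] == g).any():
            raise AncovaError(
                f"{variable}: group cell {g} has no usable subjects")
    sub["age_c"] = sub["age"] - sub["age"].mean()
    return sub


def fit_two_factor_ancova(table: CohortTable, variable: str,
                          transforms: dict[str, TransformFit],
                          ) -> AncovaResult:
    """Fit the AD x T2DM (+ age) linear model for one variable.

    Complete-case per model: a subject is dropped only if it misses this
    variable (or age).  Returns Type III F/p for both factors and the
    interaction plus retransformed adjusted group means with 95% CIs.
    """
    fit_t = transforms[variable]
    data = _model_frame(table, variable, fit_t)
    # age itself is screened without the covariate; a constant age column
    # carries no information and would make the design singular
    age_adjusted = variable != "age" and data["age"].nunique() > 1
    formula = "y ~ C(ad, Sum) * C(t2dm, Sum)"
    if age_adjusted:
        formula += " + age_c"
    res = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise AncovaError(f"{variable}: singular design matrix")
    table3 = anova_lm(res, typ=3)

    def row(key: str) -> tuple[float, float]:
        return (float(table3.loc[key, "F"]), float(table3.loc[key, "PR(>F)"]))

    F_ad, p_ad = row("C(ad, Sum)")
    F_dm, p_dm = row("C(t2dm, Sum)")
    F_int, p_int = row("C(ad, Sum):C(t2dm, Sum)")

    adjusted: dict[str, tuple[float, float, float]] = {}
    for g in GROUPS:
        ad, dm = decompose_group(g)
        new = pd.DataFrame({"ad": [ad], "t2dm": [dm], "age_c": [0.0]})
        pred = res.get_prediction(new).summary_frame(alpha=0.05)
        center = float(pred["mean"].iloc[0])
        half = center - float(pred["mean_ci_lower"].iloc[0])
        adjusted[g] = retransform_interval(fit_t, center, half)

    return AncovaResult(
        variable=variable, n_used=len(data),
        F_AD=F_ad, F_T2DM=F_dm, F_interaction=F_int,
        p_AD=p_ad, p_T2DM=p_dm, p_interaction=p_int,
        adjusted_means=adjusted, age_adjusted=age_adjusted,
        transform=fit_t, _fit=res,
    )


def bonferroni_pairs(result: AncovaResult,
                     alpha: float = FAMILY_ALPHA) -> list[PairwiseComparison]:
    """All six pairwise contrasts of age-adjusted group means.

    Contrasts are formed on the transformed scale from the fitted model
    (model residual variance, adjusted-mean difference SEs) and each is
    tested at the Bonferroni per-test level alpha/6.
    """
    res = result._fit
    if res is None:
        raise AncovaError("result does not carry a fitted model")
    design_info = res.model.data.design_info

    def design_row(group: str) -> np.ndarray:
        ad, dm = decompose_group(group)
        new = pd.DataFrame({"ad": [ad], "t2dm": [dm], "age_c": [0.0]})
        (mat,) = build_design_matrices([design_info], new)
        return np.asarray(mat)[0]

    rows = {g: design_row(g) for g in GROUPS}
    out = []
    per_test = alpha / N_PAIRS
    for a, b in itertools.combinations(PAIR_ORDER, 2):
        tt = res.t_test(rows[a] - rows[b])
        p = float(tt.pvalue)
        mean_a = result.adjusted_means[a][1]
        mean_b = result.adjusted_means[b][1]
        out.append(PairwiseComparison(
            group_a=a, group_b=b,
            direction="<" if mean_a < mean_b else ">",
            significant=p < per_test, p_value=p))
    return out


def fit_transforms(table: CohortTable,
                   variables: list[str] | None = None,
                   ) -> dict[str, TransformFit]:
    """Fit one Box-Cox transform per variable on the (per-sex) pooled data."""
    if variables is None:
        variables = table.variable_names
    out = {}
    for name in variables:
        values = pd.to_numeric(table.df[name], errors="coerce").dropna()
        out[name] = fit_lambda(values.to_numpy(), variable=name)
    return out


def screen_all_variables(table: CohortTable,
                         transforms: dict[str, TransformFit] | None = None,
                         ) -> tuple[list[AncovaResult],
                                    dict[str, list[PairwiseComparison]],
                                    dict[str, str]]:
    """Run the factorial screen over every declared variable.

    Returns (results, pairwise-by-variable, failures).  Per-variable
    failures are collected, not fatal; ordering follows the data
    dictionary.
    """
    if transforms is None:
        transforms = fit_transforms(table)
    results, pairs, failures = [], {}, {}
    for name in table.variable_names:
        if name not in transforms:
            continue
        try:
            r = fit_two_factor_ancova(table, name, transforms)
            results.append(r)
            pairs[name] = bonferroni_pairs(r)
        except (AncovaError, ValueError) as exc:
            failures[name] = str(exc)
            logger.warning("screen: %s failed: %s", name, exc)
    return results, pairs, failures


def screen_table(results: list[AncovaResult],
                 pairs: dict[str, list[PairwiseComparison]]) -> pd.DataFrame:
    """Wide summary mirroring the published screen layout."""
    rows = []
    for r in results:
        row = {"variable": r.variable, "n": r.n_used,
               "F_AD": r.F_AD, "p_AD": r.p_AD,
               "F_T2DM": r.F_T2DM, "p_T2DM": r.p_T2DM,
               "F_interaction": r.F_interaction,
               "p_interaction": r.p_interaction}
        for g in GROUPS:
            low, mid, high = r.adjusted_means[g]
            row[g] = f"{mid:.3g} ({low:.3g}, {high:.3g})"
        row["multiple_comparisons"] = ", ".join(
            str(c) for c in pairs.get(r.variable, []) if c.significant)
        rows.append(row)
    return pd.DataFrame(rows)
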