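import warnings

import numpy as np
import pytest

from steroidopls import (CalibrationTable, GeneratorConfig, load_calibration,
                         sample_cohort)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def women_cal():
    return load_calibration("F")


@pytest.fixture(scope="session")
def men_cal():
    return load_calibration("M")


@pytest.fixture(scope="session")
def women_cohort(women_cal):
    """One women cohort at the published group sizes (fixed seed)."""
    return sample_cohort(women_cal, GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def hint_transforms(women_cal):
    """The generating (calibration-hint) transforms, keyed by variable."""
    return {v: women_cal.transform_fit(v) for v in women_cal.variables}


def make_two_group_calibration(loadings, sd=0.3, delta=0.5, n=40,
                               base=10.0):
    """Synthetic calibration with a known class axis for recovery tests.

    The case group's transformed mean is offset from the control's by
    delta * R_j, so group separation and the latent-axis loading agree in
    sign by construction.  Only the first two groups carry subjects worth
    modelling; the remaining cells exist to satisfy the schema.
    """
    variables = {}
    t_crit = 2.0
    for j, r in enumerate(loadings):
        cells = {}
        for g, mu in (("A-D-", base), ("A+D-", base + delta * r),
                      ("A-D+", base), ("A+D+", base)):
            h = t_crit * sd / np.sqrt(n)
            cells[g] = [mu - h, mu, mu + h]
        variables[f"v{j}"] = {"transform": "identity", "cells": cells}
    # plausible elderly ages so the schema validates
    variables["age"] = {"transform": "identity",
                        "cells": {g: [68.0, 70.0, 72.0]
                                  for g in ("A-D-", "A+D-", "A-D+", "A+D+")}}
    models = {"A+D- vs A-D-": {
        "case": "A+D-", "control": "A-D-", "llr_loading": 0.8,
        "loadings": {f"v{j}": r for j, r in enumerate(loadings)},
    }}
    return CalibrationTable(sex="F",
                            groups={"A-D-": n, "A+D-": n, "A-D+": 5,
                                    "A+D+": 5},
                            variables=variables, models=models)
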