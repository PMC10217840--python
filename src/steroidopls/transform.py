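"""Box-Cox power transformation to near-Gaussianity.

Every metric variable in the cohort is mapped to a scale on which its
distribution is approximately Gaussian before any linear modelling; group
summaries computed on that scale are mapped back to original units
("retransformed means").  The family is the one-parameter Box-Cox power

    y = ((x + c)^lambda - 1) / lambda      (lambda != 0)
    y = ln(x + c)                          (lambda == 0)

with an automatic shift ``c`` that makes all inputs strictly positive, and
``lambda`` chosen by maximising the Box-Cox profile log-likelihood over
lambda in [-3, 3].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

LAMBDA_RANGE = (-3.0, 3.0)
_GOLDEN_TOL = 1e-4
_MIN_N = 10


@dataclass(frozen=True)
class TransformFit:
    """Fitted power-transformation parameters for one variable.

    Attributes
    ----------
    variable : str
        Variable name (informational).
    lam : float
        Power exponent; 0 means natural log.
    shift : float
        Additive offset applied before powering so inputs are positive.
    criterion_value : float
        Attained Box-Cox profile log-likelihood at ``lam``.
    n_used : int
        Number of finite observations the fit used.
    """

    variable: str
    lam: float
    shift: float
    criterion_value: float
    n_used: int

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TransformFit":
        return cls(**d)


def identity_fit(variable: str = "") -> TransformFit:
    """A no-op transform (lambda=1, shift=0): y = x - 1."""
    return TransformFit(variable, 1.0, 0.0, float("nan"), 0)


def log_fit(variable: str = "") -> TransformFit:
    """A pure log transform (lambda=0, shift=0)."""
    return TransformFit(variable, 0.0, 0.0, float("nan"), 0)


def boxcox_loglik(lam: float, x: np.ndarray) -> float:
    """Box-Cox profile log-likelihood of shifted-positive data ``x``."""
    return float(stats.boxcox_llf(lam, x))


def fit_lambda(values, variable: str = "") -> TransformFit:
    """Fit the Box-Cox exponent by profile maximum likelihood.

    The search is a coarse grid over [-3, 3] followed by golden-section
    refinement of the best bracket to 1e-4; deterministic for fixed input.

    Raises
    ------
    ValueError
        If fewer than 10 finite values are supplied or the sample is
        constant ("degenerate variable").
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < _MIN_N:
        raise ValueError(
            f"need at least {_MIN_N} finite values to fit a power "
            f"transform, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate variable {variable!r}: all values equal")

    xmin = x.min()
    shift = 0.0 if xmin > 0 else 1e-6 - xmin
    xs = x + shift

    lo, hi = LAMBDA_RANGE
    grid = np.linspace(lo, hi, 121)
    ll = np.array([boxcox_loglik(l, xs) for l in grid])
    k = int(np.argmax(ll))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]

    # golden-section maximisation on [a, b]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = boxcox_loglik(c, xs), boxcox_loglik(d, xs)
    while (b - a) > _GOLDEN_TOL:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = boxcox_loglik(c, xs)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = boxcox_loglik(d, xs)
    lam = float((a + b) / 2.0)
    return TransformFit(variable, lam, float(shift),
                        boxcox_loglik(lam, xs), int(x.size))


def apply_transform(fit: TransformFit, values):
    """Forward Box-Cox transform; continuous in lambda at 0."""
    x = np.asarray(values, dtype=float)
    xs = x + fit.shift
    if fit.lam == 1.0:          # affine case: defined on all reals
        out = xs - 1.0
        return out if out.ndim else float(out)
    bad = xs <= 0
    if np.any(bad & np.isfinite(xs)):
        offender = float(x[np.nonzero(bad & np.isfinite(xs))[0][0]])
        raise ValueError(
            f"value {offender} is non-positive after shift {fit.shift}; "
            f"outside the transform domain"
        )
    if abs(fit.lam) < 1e-12:
        out = np.log(xs)
    else:
        # expm1(lam*log x)/lam: keeps precision for |lam*log x| far from 0
        out = np.expm1(fit.lam * np.log(xs)) / fit.lam
    return out if out.ndim else float(out)


def invert_transform(fit: TransformFit, y):
    """Exact inverse of :func:`apply_transform`."""
    yv = np.asarray(y, dtype=float)
    if fit.lam == 1.0:
        out = yv + 1.0 - fit.shift
    elif abs(fit.lam) < 1e-12:
        out = np.exp(yv) - fit.shift
    else:
        ly = fit.lam * yv
        if np.any((ly <= -1.0) & np.isfinite(ly)):
            raise ValueError(
                f"transformed value out of inverse domain for lambda={fit.lam}"
            )
        out = np.exp(np.log1p(ly) / fit.lam) - fit.shift
    return out if out.ndim else float(out)


def retransform_interval(fit: TransformFit, center: float,
                         half_width: float) -> tuple[float, float, float]:
    """Map a transformed-scale interval back to original units.

    Returns (low, mid, high) on the original scale.  The inverse is
    strictly monotone, so low <= mid <= high.
    """
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    low = invert_transform(fit, center - half_width)
    mid = invert_transform(fit, center)
    high = invert_transform(fit, center + half_width)
    return float(low), float(mid), float(high)
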