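"""Orthogonal projections to latent structures (OPLS) binary discriminator.

The variability of the standardized predictor matrix X is split into a
single component predictive of the class and K components orthogonal to
it:

    X = T_p P_p' + T_0 P_0' + E        Y = T_p b + F

For a binary outcome there is one predictive component; its weight vector
is w = X'y / ||X'y|| and each orthogonal component is extracted from the
current X-loading by removing its projection on w (Trygg-Wold O-PLS).
The pipeline around the decomposition follows the published 8-step
procedure: Hotelling T2 homogeneity screening of the subjects, iterative
elimination of predictors with VIP below threshold, per-predictor loadings
expressed as correlations with the predictive component (with jackknife
t-statistics over cross-validation folds), and a likelihood-ratio
calibration that converts the predictive score into the logarithm of the
ratio p/(1-p) for the presence of pathology, hence into a probability.

Explained variability is R2Y = corr(y, t_p)^2; its cross-validated
counterpart Q2 = 1 - PRESS/SS uses stratified 7-fold CV by default.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .cohort import CohortTable
from .transform import TransformFit, apply_transform

logger = logging.getLogger(__name__)


class OplsError(ValueError):
    pass


@dataclass(frozen=True)
class OplsConfig:
    """Fitting knobs; all defaults are conventional SIMCA-style choices."""

    n_orth: int | None = None        # None = choose by cross-validated Q2
    max_orth: int = 5
    q2_tol: float = 0.01             # required Q2 gain per orthogonal comp
    vip_threshold: float = 1.0
    vip_guard: float = 0.1           # keep VIPs within guard of threshold
    n_folds: int = 7
    seed: int = 0
    llr_cap: float = 15.0
    hotelling_alpha: float = 0.05
    hotelling_screen: bool = True
    prune: bool = True


@dataclass(frozen=True)
class PredictorStats:
    predictor: str
    component_loading: float   # loading as correlation with t_p
    t_statistic: float         # jackknife t of the loading
    R: float                   # identical to component_loading by convention
    vip: float
    significance: str          # "**" p<0.01, "*" p<0.05, "" otherwise


@dataclass(frozen=True)
class Prediction:
    subject_id: str
    t_p_score: float
    llr: float
    probability: float
    predicted_class: int


@dataclass
class OplsModel:
    predictors: list[str]
    case: str
    control: str
    x_mean: np.ndarray
    x_std: np.ndarray
    w: np.ndarray                       # predictive weights, unit norm
    p_p: np.ndarray                     # predictive X-loading
    w_orth: np.ndarray                  # (p, K)
    p_orth: np.ndarray                  # (p, K)
    t_p: np.ndarray
    t_orth: np.ndarray                  # (n, K)
    b: float                            # y-side slope on t_p
    y: np.ndarray                       # centred 0/1 coding
    y_mean: float
    E: np.ndarray
    F_resid: np.ndarray
    r2y: float
    q2: float
    n_orth: int
    calibration: tuple[float, float]    # (intercept, slope): t_p -> LLR
    llr_cap: float
    transforms: dict[str, TransformFit]
    subject_ids: list[str]
    excluded_subjects: list[str] = field(default_factory=list)
    dropped_predictors: list[str] = field(default_factory=list)
    predictor_stats: list[PredictorStats] = field(default_factory=list)
    config: OplsConfig = field(default_factory=OplsConfig)

    @property
    def informative(self) -> bool:
        return self.q2 > 0

    def to_json(self) -> str:
        return json.dumps({
            "case": self.case, "control": self.control,
            "predictors": self.predictors,
            "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
            "w": self.w.tolist(), "p_p": self.p_p.tolist(),
            "w_orth": self.w_orth.tolist(), "p_orth": self.p_orth.tolist(),
            "b": self.b, "y_mean": self.y_mean,
            "r2y": self.r2y, "q2": self.q2, "n_orth": self.n_orth,
            "calibration": list(self.calibration), "llr_cap": self.llr_cap,
            "transforms": {k: v.to_dict() for k, v in self.transforms.items()},
            "excluded_subjects": self.excluded_subjects,
            "dropped_predictors": self.dropped_predictors,
            "seed": self.config.seed,
            "stats": [vars(s) for s in self.predictor_stats],
        }, indent=1)


# ---------------------------------------------------------------- core

def _core_fit(X: np.ndarray, y: np.ndarray, n_orth: int):
    """O-PLS decomposition of standardized X against centred y.

    Returns (w, p_p, w_orth, p_orth, t_p, t_orth, b, E, F_resid).
    """
    n, p = X.shape
    cov = X.T @ y
    norm = np.linalg.norm(cov)
    if norm == 0:
        raise OplsError("predictors carry no covariance with the outcome")
    w = cov / norm
    Xc = X.copy()
    w_os, p_os, t_os = [], [], []
    for _ in range(n_orth):
        t = Xc @ w
        p_load = Xc.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        nw = np.linalg.norm(w_o)
        if nw < 1e-12:
            break
        w_o /= nw
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
    t_p = Xc @ w
    p_p = Xc.T @ t_p / (t_p @ t_p)
    b = float(y @ t_p / (t_p @ t_p))
    E = Xc - np.outer(t_p, p_p)
    F_resid = y - b * t_p
    k = len(w_os)
    w_orth = np.column_stack(w_os) if k else np.zeros((p, 0))
    p_orth = np.column_stack(p_os) if k else np.zeros((p, 0))
    t_orth = np.column_stack(t_os) if k else np.zeros((X.shape[0], 0))
    return w, p_p, w_orth, p_orth, t_p, t_orth, b, E, F_resid


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    return (X - mean) / std, mean, std


def _project(X_new: np.ndarray, w, w_orth, p_orth) -> np.ndarray:
    """Predictive score of new standardized rows after orthogonal removal."""
    Xc = X_new.copy()
    for k in range(w_orth.shape[1]):
        t_o = Xc @ w_orth[:, k]
        Xc = Xc - np.outer(t_o, p_orth[:, k])
    return Xc @ w


# ------------------------------------------------------- cross-validation

def _fold_assignment(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Seeded stratified round-robin fold labels; never empties a class."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    n_eff = n_folds
    min_class = min(int((y == 1).sum()), int((y == 0).sum()))
    if min_class < n_folds:
        n_eff = max(2, min_class)
        warnings.warn(
            f"reducing CV folds from {n_folds} to {n_eff}: "
            f"smallest class has {min_class} subjects", stacklevel=2)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_eff
    return folds


def cross_validate(X: np.ndarray, y01: np.ndarray, n_orth: int,
                   n_folds: int = 7, seed: int = 0):
    """Stratified K-fold CV of the OPLS fit.

    Returns (q2, per-fold loading matrix R (folds x p), fold labels).
    Q2 = 1 - PRESS/SS on the 0/1-coded outcome; loadings per training
    fold feed the jackknife SEs of the full-fit loadings.
    """
    folds = _fold_assignment(y01, n_folds, seed)
    n_eff = folds.max() + 1
    press = 0.0
    fold_loadings = []
    for f in range(n_eff):
        tr, te = folds != f, folds == f
        Xtr, mean, std = _standardize(X[tr])
        ok = std > 0
        if not np.all(ok):
            Xtr = Xtr[:, ok]
        ytr = y01[tr].astype(float)
        ybar = ytr.mean()
        w, p_p, w_o, p_o, t_p, t_o, b, _, _ = _core_fit(
            Xtr, ytr - ybar, n_orth)
        Xte = (X[te] - mean) / np.where(std > 0, std, 1.0)
        if not np.all(ok):
            Xte = Xte[:, ok]
        t_new = _project(Xte, w, w_o, p_o)
        press += float(np.sum((y01[te] - (ybar + b * t_new)) ** 2))
        r = np.full(X.shape[1], np.nan)
        sd_t = t_p.std(ddof=1)
        r[ok] = Xtr.T @ (t_p - t_p.mean()) / (
            (len(t_p) - 1) * Xtr.std(axis=0, ddof=1) * sd_t)
        fold_loadings.append(r)
    ss = float(np.sum((y01 - y01.mean()) ** 2))
    q2 = 1.0 - press / ss
    return q2, np.array(fold_loadings), folds


def choose_orthogonal_components(X: np.ndarray, y01: np.ndarray,
                                 config: OplsConfig = OplsConfig()) -> int:
    """Add orthogonal components while cross-validated Q2 keeps improving.

    Starts at K=0 and accepts K+1 only if Q2 gains more than
    ``config.q2_tol``; K is capped at min(n-2, p-1, max_orth).
    """
    n, p = X.shape
    cap = max(0, min(n - 2, p - 1, config.max_orth))
    if not np.isfinite(config.q2_tol):
        return 0
    best_k = 0
    q2_prev, _, _ = cross_validate(X, y01, 0, config.n_folds, config.seed)
    for k in range(1, cap + 1):
        q2_k, _, _ = cross_validate(X, y01, k, config.n_folds, config.seed)
        if q2_k > q2_prev + config.q2_tol:
            best_k, q2_prev = k, q2_k
        else:
            break
    return best_k


# ------------------------------------------------------------- statistics

def compute_vip(model: "OplsModel") -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt(p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a); with one
    predictive component of unit-norm weights this is sqrt(p)*|w_j|, and
    mean(VIP^2) = 1 over the retained predictors.
    """
    p = len(model.predictors)
    ssy = model.b ** 2 * float(model.t_p @ model.t_p)  # SS_Y of component
    wnorm = model.w / np.linalg.norm(model.w)
    return np.sqrt(p * ssy * wnorm ** 2 / ssy)


def hotelling_t2(scores: np.ndarray, alpha: float = 0.05):
    """Hotelling T2 outlier flags against the F-based tolerance ellipse.

    T2_i = (s_i - mean)' S^{-1} (s_i - mean); the 100(1-alpha)% limit is
    d(n-1)(n+1)/(n(n-d)) * F_{1-alpha}(d, n-d).  Returns (flags, t2,
    limit).
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    if s.shape[0] < s.shape[1] and s.shape[1] > 2:  # passed as (d, n)?
        raise OplsError("scores must be (n_subjects, n_dims)")
    n, d = s.shape
    if n < d + 2:
        raise OplsError(f"need at least d+2={d + 2} subjects, got {n}")
    centred = s - s.mean(axis=0)
    cov = np.cov(centred, rowvar=False, ddof=1).reshape(d, d)
    if np.linalg.matrix_rank(cov) < d:
        raise OplsError("singular score covariance")
    t2 = np.einsum("ij,jk,ik->i", centred, np.linalg.inv(cov), centred)
    limit = (d * (n - 1) * (n + 1)) / (n * (n - d)) * stats.f.ppf(
        1.0 - alpha, d, n - d)
    return t2 > limit, t2, float(limit)


# ------------------------------------------------------------ assembling

def _build_matrix(table: CohortTable, case: str, control: str,
                  predictors: list[str],
                  transforms: dict[str, TransformFit]):
    df = table.df[table.df["group"].isin([case, control])]
    cols = {}
    for name in predictors:
        cols[name] = pd.to_numeric(df[name], errors="coerce")
    frame = pd.DataFrame(cols, index=df.index)
    keep = frame.notna().all(axis=1)
    frame, sub = frame[keep], df[keep]
    X = np.column_stack([
        apply_transform(transforms[name], frame[name].to_numpy())
        for name in predictors])
    y01 = (sub["group"] == case).to_numpy().astype(float)
    ids = sub["subject_id"].tolist()
    return X, y01, ids


def fit_opls(table: CohortTable, group_pair: tuple[str, str],
             predictors: list[str],
             transforms: dict[str, TransformFit],
             config: OplsConfig = OplsConfig()) -> OplsModel:
    """Fit the full OPLS discriminant pipeline for one pair of groups.

    ``group_pair`` is (case, control); the outcome is coded 1 for case.
    Steps: complete-case assembly, zero-variance drop, Hotelling
    homogeneity screen (once), orthogonal-component count by CV, VIP
    pruning to convergence, final fit with loadings-as-correlations,
    jackknife t-statistics and logistic LLR calibration.
    """
    case, control = group_pair
    X, y01, ids = _build_matrix(table, case, control, list(predictors),
                                transforms)
    n_case, n_ctrl = int(y01.sum()), int((1 - y01).sum())
    if n_case < 3 or n_ctrl < 3:
        raise OplsError(
            f"need >= 3 subjects per class, got case={n_case}, "
            f"control={n_ctrl}")

    predictors = list(predictors)
    std0 = X.std(axis=0, ddof=1)
    dropped = [p for p, s in zip(predictors, std0) if s == 0]
    if dropped:
        logger.warning("dropping zero-variance predictor(s): %s", dropped)
        keep = std0 > 0
        X = X[:, keep]
        predictors = [p for p, k in zip(predictors, keep) if k]
    if not predictors:
        raise OplsError("no usable predictors")

    # homogeneity screen on the leading principal plane of X
    excluded: list[str] = []
    if config.hotelling_screen and X.shape[0] > 4:
        Z, _, _ = _standardize(X)
        d = min(2, Z.shape[1])
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        scores = Z @ vt[:d].T
        try:
            flags, _, _ = hotelling_t2(scores, config.hotelling_alpha)
        except OplsError:
            flags = np.zeros(len(ids), dtype=bool)
        keep_mask = ~flags
        if keep_mask.sum() >= 6 and y01[keep_mask].sum() >= 3 \
                and (1 - y01[keep_mask]).sum() >= 3:
            excluded = [i for i, f in zip(ids, flags) if f]
            if excluded:
                logger.info("Hotelling screen excluded %d subject(s)",
                            len(excluded))
            X, y01 = X[keep_mask], y01[keep_mask]
            ids = [i for i, f in zip(ids, flags) if not f]

    if config.n_orth is None:
        n_orth = choose_orthogonal_components(X, y01, config)
    else:
        n_orth = config.n_orth

    model = _assemble(X, y01, ids, predictors, case, control, n_orth,
                      transforms, config, excluded, dropped)
    if config.prune:
        model = prune_predictors(model, table, config.vip_threshold)
    return model


def _assemble(X, y01, ids, predictors, case, control, n_orth, transforms,
              config, excluded, dropped) -> OplsModel:
    Z, mean, std = _standardize(X)
    y = y01 - y01.mean()
    w, p_p, w_o, p_o, t_p, t_o, b, E, F_resid = _core_fit(Z, y, n_orth)
    r2y = float(np.corrcoef(y, t_p)[0, 1] ** 2)
    q2, fold_loadings, _ = cross_validate(X, y01, n_orth, config.n_folds,
                                          config.seed)
    calibration = _calibrate_llr(t_p, y01, config.llr_cap)

    model = OplsModel(
        predictors=predictors, case=case, control=control,
        x_mean=mean, x_std=std, w=w, p_p=p_p, w_orth=w_o, p_orth=p_o,
        t_p=t_p, t_orth=t_o, b=b, y=y, y_mean=float(y01.mean()),
        E=E, F_resid=F_resid, r2y=r2y, q2=q2, n_orth=n_orth,
        calibration=calibration, llr_cap=config.llr_cap,
        transforms={p: transforms[p] for p in predictors},
        subject_ids=list(ids), excluded_subjects=list(excluded),
        dropped_predictors=list(dropped), config=config)
    model.predictor_stats = _predictor_stats(model, Z, fold_loadings)
    return model


def _predictor_stats(model: OplsModel, Z: np.ndarray,
                     fold_loadings: np.ndarray) -> list[PredictorStats]:
    t_p = model.t_p
    tc = t_p - t_p.mean()
    r_full = Z.T @ tc / ((len(t_p) - 1)
                         * Z.std(axis=0, ddof=1) * t_p.std(ddof=1))
    vips = compute_vip(model)
    m = fold_loadings.shape[0]
    theta = np.nan_to_num(fold_loadings, nan=0.0)
    se = np.sqrt((m - 1) / m * np.sum((theta - theta.mean(axis=0)) ** 2,
                                      axis=0))
    out = []
    for j, name in enumerate(model.predictors):
        t_stat = r_full[j] / se[j] if se[j] > 0 else np.inf * np.sign(
            r_full[j] if r_full[j] != 0 else 1)
        p_val = 2 * stats.t.sf(abs(t_stat), m - 1) if np.isfinite(t_stat) \
            else 0.0
        marks = "**" if p_val < 0.01 else ("*" if p_val < 0.05 else "")
        out.append(PredictorStats(
            predictor=name, component_loading=float(r_full[j]),
            t_statistic=float(t_stat), R=float(r_full[j]),
            vip=float(vips[j]), significance=marks))
    return out


def prune_predictors(model: OplsModel, table: CohortTable,
                     threshold: float = 1.0) -> OplsModel:
    """Iteratively drop predictors with VIP below threshold and refit.

    Stops when every survivor reaches the threshold, or when a refit would
    cost more than ``q2_tol`` of Q2 (the previous model is kept), or
    raises once nothing survives.  A small guard band below the threshold
    is tolerated so that sampling noise around VIP = 1 in a set of equally
    informative predictors does not trigger spurious elimination.
    """
    if threshold <= 0:
        return model
    config = model.config
    cut = threshold - config.vip_guard
    cfg_noprune = OplsConfig(**{**vars(config), "prune": False,
                                "hotelling_screen": False})
    current = model
    while True:
        vips = compute_vip(current)
        survivors = [p for p, v in zip(current.predictors, vips)
                     if v >= cut]
        if not survivors:
            raise OplsError("no relevant predictors survive VIP pruning")
        if len(survivors) == len(current.predictors):
            return current
        sub = table.subset([current.case, current.control])
        refit = fit_opls(sub, (current.case, current.control), survivors,
                         current.transforms | model.transforms,
                         cfg_noprune)
        if refit.q2 < current.q2 - config.q2_tol:
            logger.info("pruning stopped: Q2 would drop %.3f -> %.3f",
                        current.q2, refit.q2)
            return current
        current = refit


# ------------------------------------------------------------- prediction

def _calibrate_llr(t_p: np.ndarray, y01: np.ndarray,
                   llr_cap: float = 15.0) -> tuple[float, float]:
    """Univariate logistic fit of class on the predictive score.

    Under complete separation the likelihood-ratio slope diverges; the
    calibration then pivots on the separating midpoint with a slope that
    puts the training subject nearest the boundary exactly at the cap.
    """
    lo, hi = t_p[y01 == 0], t_p[y01 == 1]
    if lo.max() < hi.min() or hi.max() < lo.min():
        sign = 1.0 if lo.max() < hi.min() else -1.0
        a, b = (lo.max(), hi.min()) if sign > 0 else (hi.max(), lo.min())
        mid = (a + b) / 2.0
        gap = max((b - a) / 2.0, 1e-12)
        slope = sign * llr_cap / gap
        return float(-slope * mid), float(slope)
    lr = LogisticRegression(C=1e8, solver="lbfgs", max_iter=10_000)
    lr.fit(t_p.reshape(-1, 1), y01.astype(int))
    return float(lr.intercept_[0]), float(lr.coef_[0, 0])


def predict_llr(model: OplsModel, subjects) -> list[Prediction]:
    """Predict LLR and pathology probability for new subjects.

    ``subjects`` is a CohortTable or DataFrame carrying every model
    predictor.  The probability is the logistic map of the capped LLR;
    class is called positive iff probability > 0.5 (ties negative).
    """
    df = subjects.df if isinstance(subjects, CohortTable) else subjects
    missing = [p for p in model.predictors if p not in df.columns]
    if missing:
        raise OplsError(f"missing predictor(s): {missing}")
    X = np.column_stack([
        apply_transform(model.transforms[p],
                        pd.to_numeric(df[p], errors="coerce").to_numpy())
        for p in model.predictors])
    if np.isnan(X).any():
        raise OplsError("missing predictor values in prediction input")
    Z = (X - model.x_mean) / model.x_std
    t_new = _project(Z, model.w, model.w_orth, model.p_orth)
    a, slope = model.calibration
    llr = np.clip(a + slope * t_new, -model.llr_cap, model.llr_cap)
    prob = 1.0 / (1.0 + np.exp(-llr))
    ids = (df["subject_id"].tolist() if "subject_id" in df.columns
           else [str(i) for i in range(len(df))])
    return [Prediction(subject_id=i, t_p_score=float(t),
                       llr=float(l), probability=float(p),
                       predicted_class=int(p > 0.5))
            for i, t, l, p in zip(ids, t_new, llr, prob)]
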