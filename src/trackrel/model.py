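"""Domain-adapted logistic reliability model for tracked frames.

The model is ``P(reliable) = sigmoid(b0 + b1 x1 + ... + b4 x4 + b5 DI +
b6 DI*x1 + ... + b9 DI*x4)`` fitted by minimizing the sample-weighted
cross-entropy plus a regularization penalty (L1, L2 or elastic net),
with the intercept unpenalized.  Two optimizers honor the same loss: a
deterministic proximal-gradient scheme with momentum (FISTA) and a
seeded stochastic proximal gradient with iterate averaging.

Evaluation follows a fixed-specificity protocol: on each training fold
the probability cutoff is the smallest one whose training specificity
reaches 95% (chosen per domain), fold cutoffs are averaged into the
final operating threshold, and sensitivity/specificity/AUC are reported
at that operating point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.metrics import roc_auc_score, roc_curve

from .config import LrHyper, WeightScheme
from .features import (
    DESIGN_COLUMNS,
    ScalerState,
    apply_scalers,
    assign_weights,
    build_design_matrix,
    fit_scalers,
)

__all__ = [
    "LrFit",
    "ModelFit",
    "ConfusionReport",
    "sigmoid",
    "loss_value",
    "fit_weighted_lr",
    "predict_proba",
    "select_threshold",
    "average_fold_thresholds",
    "evaluate",
    "evaluate_model",
    "loo_cv",
    "sweep_weights_and_hyper",
    "run_modality_study",
    "mcnemar_exact",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _penalty_split(hyper: LrHyper) -> Tuple[float, float]:
    """(l1 strength, smooth l2 strength) of ``lam * R``."""
    if hyper.penalty == "l1":
        return hyper.lam, 0.0
    if hyper.penalty == "l2":
        return 0.0, hyper.lam
    return hyper.lam * hyper.l1_ratio, hyper.lam * (1.0 - hyper.l1_ratio)


def loss_value(theta: np.ndarray, x: np.ndarray, y: np.ndarray, w: np.ndarray,
               hyper: LrHyper) -> float:
    """Weighted mean cross-entropy + lam * R(coefficients)."""
    a = np.column_stack([np.ones(len(x)), x])
    z = a @ theta
    # log(1+exp(-|z|)) formulation is numerically safe
    ce = np.logaddexp(0.0, -z) * y + np.logaddexp(0.0, z) * (1.0 - y)
    lam1, lam2 = _penalty_split(hyper)
    beta = theta[1:]
    return float(
        np.sum(w * ce) / np.sum(w)
        + lam1 * np.abs(beta).sum()
        + lam2 * np.square(beta).sum()
    )


@dataclass
class LrFit:
    beta0: float
    betas: np.ndarray
    converged: bool
    grad_norm: float
    n_iter: int
    hyper: Optional[LrHyper] = None

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([[self.beta0], self.betas])


def _smooth_grad(theta, a, y, wn, lam2):
    p = sigmoid(a @ theta)
    g = a.T @ (wn * (p - y))
    g[1:] += 2.0 * lam2 * theta[1:]
    return g


def _optimality_norm(theta, g, lam1):
    """Norm of the minimal subgradient (exact zero at an optimum)."""
    if lam1 == 0:
        return float(np.linalg.norm(g))
    sub = g.copy()
    beta = theta[1:]
    gb = g[1:].copy()
    gb[beta > 0] += lam1
    gb[beta < 0] -= lam1
    zero = beta == 0
    gb[zero] = np.sign(gb[zero]) * np.maximum(np.abs(gb[zero]) - lam1, 0.0)
    sub[1:] = gb
    return float(np.linalg.norm(sub))


def fit_weighted_lr(
    x: np.ndarray,
    y: np.ndarray,
    weights: Optional[np.ndarray] = None,
    hyper: Optional[LrHyper] = None,
) -> LrFit:
    """Minimize the weighted cross-entropy + penalty (intercept free).

    The deterministic solver is FISTA (proximal gradient with Nesterov
    momentum and a Lipschitz step); the stochastic one is a seeded
    proximal SGD with tail averaging.  Both honor the identical loss.
    """
    hyper = hyper or LrHyper()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if weights is None:
        weights = np.ones(len(y))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("sample weights must be > 0")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need both classes present to fit")
    n, p = x.shape
    a = np.column_stack([np.ones(n), x])
    wn = weights / weights.sum()
    lam1, lam2 = _penalty_split(hyper)

    if hyper.solver == "sgd":
        theta = _solve_sgd(a, y, wn, lam1, lam2, hyper)
    else:
        theta = _solve_fista(a, y, wn, lam1, lam2, hyper)

    g = _smooth_grad(theta, a, y, wn, lam2)
    gnorm = _optimality_norm(theta, g, lam1)
    converged = gnorm <= max(hyper.tol, 1e-6) * 10 or gnorm <= 1e-5
    if not converged and hyper.solver == "fista":
        warnings.warn(
            f"logistic fit did not reach tolerance (grad norm {gnorm:.2e} "
            f"after {hyper.max_iter} iterations)"
        )
    return LrFit(
        beta0=float(theta[0]),
        betas=theta[1:].copy(),
        converged=bool(converged),
        grad_norm=gnorm,
        n_iter=hyper.max_iter,
        hyper=hyper,
    )


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _solve_fista(a, y, wn, lam1, lam2, hyper) -> np.ndarray:
    n, d = a.shape
    # Lipschitz constant of the smooth part: 1/4 lambda_max(A^T W A) + 2 lam2
    aw = a * np.sqrt(wn)[:, None]
    lip = 0.25 * np.linalg.norm(aw, 2) ** 2 + 2.0 * lam2
    step = 1.0 / max(lip, 1e-12)
    theta = np.zeros(d)
    z = theta.copy()
    tm = 1.0
    for it in range(hyper.max_iter):
        g = _smooth_grad(z, a, y, wn, lam2)
        new = z - step * g
        if lam1 > 0:
            new[1:] = _soft_threshold(new[1:], step * lam1)
        tn = (1.0 + np.sqrt(1.0 + 4.0 * tm**2)) / 2.0
        z = new + ((tm - 1.0) / tn) * (new - theta)
        moved = np.linalg.norm(new - theta)
        theta, tm = new, tn
        if moved <= hyper.tol * max(1.0, np.linalg.norm(theta)):
            gn = _optimality_norm(theta, _smooth_grad(theta, a, y, wn, lam2), lam1)
            if gn <= 1e-6:
                break
    return theta


def _solve_sgd(a, y, wn, lam1, lam2, hyper) -> np.ndarray:
    """Seeded proximal SGD with tail-iterate averaging."""
    rng = np.random.default_rng(hyper.seed)
    n, d = a.shape
    theta = np.zeros(d)
    batch = min(64, n)
    aw = a * np.sqrt(wn)[:, None]
    lip = 0.25 * np.linalg.norm(aw, 2) ** 2 + 2.0 * lam2
    step0 = 1.0 / max(lip, 1e-12)
    avg = np.zeros(d)
    n_avg = 0
    total = hyper.max_iter
    for it in range(total):
        idx = rng.integers(0, n, size=batch)
        wi = wn[idx]
        p = sigmoid(a[idx] @ theta)
        # gradient estimate of the weighted mean CE over the minibatch
        g = a[idx].T @ (wi * (p - y[idx])) / max(wi.sum(), 1e-12)
        g[1:] += 2.0 * lam2 * theta[1:]
        step = step0 / (1.0 + it / 200.0)
        theta = theta - step * g
        if lam1 > 0:
            theta[1:] = _soft_threshold(theta[1:], step * lam1)
        if it >= total // 2:
            avg += theta
            n_avg += 1
    return avg / max(n_avg, 1)


def predict_proba(fit: LrFit, x: np.ndarray) -> np.ndarray:
    return sigmoid(fit.beta0 + np.asarray(x, dtype=float) @ fit.betas)


# ---------------------------------------------------------------------------
# thresholds & evaluation
# ---------------------------------------------------------------------------


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0
    lo = s[0] / 2.0
    hi = (s[-1] + 1.0) / 2.0
    return np.concatenate([[lo], mids, [hi]])


def select_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    target_specificity: float = 0.95,
) -> float:
    """Smallest probability cutoff with specificity >= target.

    Candidates are midpoints between consecutive sorted unique scores
    plus one candidate below and one above all scores.  Predicted
    reliable means ``score >= cutoff``; because sensitivity is
    non-increasing in the cutoff, the smallest qualifying cutoff ties
    toward the highest sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    neg = scores[~labels]
    if len(neg) < 1:
        raise ValueError("95%-specificity target unreachable: no negatives")
    for t in _threshold_candidates(scores):
        spec = float(np.mean(neg < t))
        if spec >= target_specificity:
            return float(t)
    return float((scores.max() + 1.0) / 2.0)  # unreachable in practice


def average_fold_thresholds(thresholds: Sequence[float]) -> float:
    """Final operating cutoff: arithmetic mean of the fold cutoffs."""
    t = np.asarray(list(thresholds), dtype=float)
    if t.size == 0:
        raise ValueError("no fold thresholds to average")
    return float(t.mean())


@dataclass
class ConfusionReport:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    sensitivity: Optional[float]  # tp / (tp + fn)
    specificity: Optional[float]  # 1 - fp / (tn + fp)
    auc: Optional[float] = None
    dataset_id: str = ""
    roc: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "dataset_id": self.dataset_id,
        }
        return d


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    dataset_id: str = "",
    with_roc: bool = False,
) -> ConfusionReport:
    """Confusion counts and metrics at ``score >= threshold``.

    Sensitivity is ``TP/(TP+FN)``; specificity ``1 - FP/(TN+FP)``.  A
    metric whose denominator is empty is reported as None, not 0.  AUC
    is the trapezoidal area under the ROC over all score cutoffs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 1.0 - fp / (tn + fp) if (tn + fp) > 0 else None
    auc = None
    roc = None
    if labels.any() and (~labels).any():
        auc = float(roc_auc_score(labels, scores))
        if with_roc:
            fpr, tpr, thr = roc_curve(labels, scores)
            roc = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "threshold": thr.tolist()}
    return ConfusionReport(
        tp=tp, fp=fp, tn=tn, fn=fn, threshold=float(threshold),
        sensitivity=sens, specificity=spec, auc=auc, dataset_id=dataset_id, roc=roc,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    held_out: str
    fit: LrFit
    thresholds: Dict[str, float]
    val_report: Optional[ConfusionReport]
    val_auc: Optional[float]
    scaler_state: ScalerState


@dataclass
class ModelFit:
    """Final fitted model + per-fold summaries for one modality."""

    modality: str
    beta0: float
    betas: np.ndarray
    thresholds: Dict[str, float]  # final per-domain operating cutoffs
    fold_thresholds: Dict[str, List[float]]
    fold_aucs: List[float]
    coef_interval: Dict[str, tuple]  # 2.5/97.5 percentiles across folds
    scaler_state: ScalerState
    hyper: LrHyper
    folds: List[FoldResult] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "modality": self.modality,
                "beta0": self.beta0,
                "betas": list(map(float, self.betas)),
                "design_columns": DESIGN_COLUMNS,
                "thresholds": self.thresholds,
                "fold_thresholds": self.fold_thresholds,
                "fold_aucs": self.fold_aucs,
                "coef_interval": {k: list(v) for k, v in self.coef_interval.items()},
                "scaler_state": self.scaler_state.to_dict(),
                "hyper": {
                    "lam": self.hyper.lam,
                    "penalty": self.hyper.penalty,
                    "l1_ratio": self.hyper.l1_ratio,
                    "solver": self.hyper.solver,
                    "seed": self.hyper.seed,
                },
            },
            indent=1,
        )


def _prepare(train: pd.DataFrame, quality_by_dataset, scheme, per_domain):
    state = fit_scalers(train, per_domain=per_domain)
    scaled = apply_scalers(train, state)
    scaled = assign_weights(scaled, quality_by_dataset, scheme)
    x, y, w = build_design_matrix(scaled)
    return state, scaled, x, y, w


def _domain_thresholds(scaled, fit, target_specificity):
    thresholds = {}
    for domain, grp in scaled.groupby("domain"):
        xg, yg, _ = build_design_matrix(grp)
        sg = predict_proba(fit, xg)
        if yg.min() == yg.max():
            continue
        thresholds[domain] = select_threshold(sg, yg, target_specificity)
    return thresholds


def loo_cv(
    table: pd.DataFrame,
    quality_by_dataset: Dict[str, str],
    hyper: Optional[LrHyper] = None,
    scheme: Optional[WeightScheme] = None,
    target_specificity: float = 0.95,
    per_domain_scalers: bool = True,
) -> ModelFit:
    """Leave-one-dataset-out CV over the patient-like datasets.

    Phantom runs stay in every training set; each patient-like dataset
    is held out exactly once.  Per fold, scalers are refit on the
    training rows only, the model is refit, and the per-domain
    95%-specificity cutoffs are selected on training rows.  The final
    model is fit on all data and its operating cutoffs are the fold
    averages.
    """
    hyper = hyper or LrHyper()
    scheme = scheme or WeightScheme()
    patient_ids = sorted(table.loc[table["domain"] == "patient", "dataset_id"].unique())
    if len(patient_ids) < 3:
        raise ValueError("need at least 3 patient-like datasets for LOO CV")
    modality = str(table["modality"].iloc[0]) if "modality" in table.columns else ""

    folds: List[FoldResult] = []
    for held in patient_ids:
        train = table[table["dataset_id"] != held]
        val = table[table["dataset_id"] == held]
        if train["label"].nunique() < 2:
            warnings.warn(f"fold {held!r}: training set lost a class; skipped")
            continue
        state, scaled, x, y, w = _prepare(train, quality_by_dataset, scheme,
                                          per_domain_scalers)
        fit = fit_weighted_lr(x, y, w, hyper)
        thresholds = _domain_thresholds(scaled, fit, target_specificity)
        val_report = None
        val_auc = None
        if len(val) and "patient" in thresholds:
            val_scaled = apply_scalers(val, state)
            xv, yv, _ = build_design_matrix(
                assign_weights(val_scaled, quality_by_dataset, scheme)
            )
            sv = predict_proba(fit, xv)
            val_report = evaluate(sv, yv, thresholds["patient"], dataset_id=held)
            val_auc = val_report.auc
        folds.append(
            FoldResult(held, fit, thresholds, val_report, val_auc, state)
        )
    if not folds:
        raise ValueError("all folds skipped; cannot cross-validate")

    state, scaled, x, y, w = _prepare(table, quality_by_dataset, scheme,
                                      per_domain_scalers)
    final = fit_weighted_lr(x, y, w, hyper)
    fold_thresholds: Dict[str, List[float]] = {}
    for fr in folds:
        for domain, t in fr.thresholds.items():
            fold_thresholds.setdefault(domain, []).append(t)
    thresholds = {
        d: average_fold_thresholds(ts) for d, ts in fold_thresholds.items()
    }
    coefs = np.array([np.concatenate([[fr.fit.beta0], fr.fit.betas]) for fr in folds])
    names = ["beta0"] + [f"beta{i}" for i in range(1, coefs.shape[1])]
    interval = {
        name: tuple(np.percentile(coefs[:, j], [2.5, 97.5]))
        for j, name in enumerate(names)
    }
    return ModelFit(
        modality=modality,
        beta0=final.beta0,
        betas=final.betas,
        thresholds=thresholds,
        fold_thresholds=fold_thresholds,
        fold_aucs=[fr.val_auc for fr in folds if fr.val_auc is not None],
        coef_interval=interval,
        scaler_state=state,
        hyper=hyper,
        folds=folds,
    )


def evaluate_model(
    model: ModelFit,
    frames: pd.DataFrame,
    quality_by_dataset: Optional[Dict[str, str]] = None,
    dataset_id: str = "",
    with_roc: bool = False,
) -> ConfusionReport:
    """Apply the final model to labeled frames at its per-domain cutoffs."""
    scaled = apply_scalers(frames, model.scaler_state)
    x, y, _ = build_design_matrix(scaled)
    scores = predict_proba(
        LrFit(model.beta0, model.betas, True, 0.0, 0), x
    )
    domains = scaled["domain"].to_numpy()
    # a domain with single-class training rows has no cutoff of its own;
    # fall back to the mean of the available domain cutoffs
    fallback = float(np.mean(list(model.thresholds.values())))
    thr = np.array([model.thresholds.get(d, fallback) for d in domains])
    pred = scores >= thr
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 1.0 - fp / (tn + fp) if (tn + fp) > 0 else None
    auc = float(roc_auc_score(y, scores)) if 0 < y.sum() < len(y) else None
    roc = None
    if with_roc and auc is not None:
        fpr, tpr, t = roc_curve(y, scores)
        roc = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "threshold": t.tolist()}
    mean_thr = float(np.mean(thr))
    return ConfusionReport(tp, fp, tn, fn, mean_thr, sens, spec, auc, dataset_id, roc)


def model_scores(model: ModelFit, frames: pd.DataFrame) -> np.ndarray:
    scaled = apply_scalers(frames, model.scaler_state)
    x, _, _ = build_design_matrix(scaled)
    return predict_proba(LrFit(model.beta0, model.betas, True, 0.0, 0), x)


# ---------------------------------------------------------------------------
# weight / hyper sweep and the paired SE-vs-DE study
# ---------------------------------------------------------------------------


def sweep_weights_and_hyper(
    table: pd.DataFrame,
    quality_by_dataset: Dict[str, str],
    moderate_grid: Sequence[float] = (0.4, 0.5, 0.6, 0.7, 0.8),
    poor_grid: Sequence[float] = (0.1, 0.15, 0.2, 0.25, 0.3),
    hyper_grid: Optional[Sequence[LrHyper]] = None,
    target_specificity: float = 0.95,
):
    """Grid search over band weights and hyper-parameters via LOO CV.

    Selects the point maximizing mean validation sensitivity subject to
    mean validation specificity >= the target; if no point meets the
    constraint, the best-specificity point is returned with a warning.
    Returns ``(scheme, hyper, sweep_table)``.
    """
    hyper_grid = list(hyper_grid) if hyper_grid is not None else [LrHyper()]
    rows = []
    for mod_w in moderate_grid:
        for poor_w in poor_grid:
            scheme = WeightScheme(moderate=mod_w, poor=poor_w)
            for hyper in hyper_grid:
                mf = loo_cv(table, quality_by_dataset, hyper, scheme,
                            target_specificity)
                reports = [f.val_report for f in mf.folds if f.val_report]
                sens = [r.sensitivity for r in reports if r.sensitivity is not None]
                spec = [r.specificity for r in reports if r.specificity is not None]
                rows.append(
                    {
                        "moderate": mod_w,
                        "poor": poor_w,
                        "lam": hyper.lam,
                        "penalty": hyper.penalty,
                        "mean_sensitivity": float(np.mean(sens)) if sens else np.nan,
                        "mean_specificity": float(np.mean(spec)) if spec else np.nan,
                        "mean_auc": float(np.mean(mf.fold_aucs))
                        if mf.fold_aucs
                        else np.nan,
                        "_scheme": scheme,
                        "_hyper": hyper,
                    }
                )
    sweep = pd.DataFrame(rows)
    ok = sweep[sweep["mean_specificity"] >= target_specificity]
    if len(ok):
        best = ok.sort_values("mean_sensitivity", ascending=False).iloc[0]
    else:
        warnings.warn("no sweep point met the specificity target; "
                      "returning the best-specificity point")
        best = sweep.sort_values("mean_specificity", ascending=False).iloc[0]
    return best["_scheme"], best["_hyper"], sweep.drop(columns=["_scheme", "_hyper"])


def sensitivity_at_specificity(
    scores: np.ndarray, labels: np.ndarray, target_specificity: float = 0.95
) -> float:
    """Sensitivity at the smallest cutoff whose specificity meets the target.

    The matched-specificity comparison used to contrast modalities.
    """
    t = select_threshold(scores, labels, target_specificity)
    labels = np.asarray(labels).astype(bool)
    return float(np.mean(np.asarray(scores, dtype=float)[labels] >= t))


def mcnemar_exact(correct_a: np.ndarray, correct_b: np.ndarray) -> float:
    """Exact McNemar p-value on paired per-frame correctness indicators."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired indicator arrays differ in length")
    n01 = int(np.sum(~a & b))
    n10 = int(np.sum(a & ~b))
    n = n01 + n10
    if n == 0:
        return 1.0
    return float(binomtest(n01, n, 0.5).pvalue)


def run_modality_study(
    se_table: pd.DataFrame,
    de_table: pd.DataFrame,
    quality_by_dataset: Dict[str, str],
    hyper: Optional[LrHyper] = None,
    scheme: Optional[WeightScheme] = None,
    holdout_se: Optional[pd.DataFrame] = None,
    holdout_de: Optional[pd.DataFrame] = None,
    holdout_bands: Optional[Dict[str, str]] = None,
    target_specificity: float = 0.95,
) -> dict:
    """Paired SE vs DE reliability study.

    Fits one model per modality on the same datasets, reports training
    sensitivities at the matched 95%-specificity operating point, an
    exact McNemar test on frame-level correctness paired across
    modalities, and per-band held-out metrics when hold-out tables are
    given.
    """
    se_ids = set(se_table["dataset_id"].unique())
    de_ids = set(de_table["dataset_id"].unique())
    if se_ids != de_ids:
        raise ValueError("SE and DE feature tables cover different datasets")

    fits = {}
    reports = {}
    matched = {}
    for name, tab in (("SE", se_table), ("DE", de_table)):
        mf = loo_cv(tab, quality_by_dataset, hyper, scheme, target_specificity)
        fits[name] = mf
        reports[name] = {
            domain: evaluate_model(mf, grp, dataset_id=f"train:{domain}")
            for domain, grp in tab.groupby("domain")
        }
        scores = model_scores(mf, tab)
        y = tab["label"].to_numpy()
        matched[name] = {"pooled": sensitivity_at_specificity(scores, y,
                                                              target_specificity)}
        for domain, grp in tab.groupby("domain"):
            yg = grp["label"].to_numpy()
            if 0 < yg.sum() < len(yg):
                sg = model_scores(mf, grp)
                matched[name][domain] = sensitivity_at_specificity(
                    sg, yg, target_specificity
                )

    # paired frame-level correctness on frames tracked in both modalities
    keys = ["dataset_id", "frame_index"]
    merged = se_table.merge(
        de_table, on=keys, suffixes=("_se", "_de"), how="inner"
    )
    p_by_domain = {}
    for domain in merged["domain_se"].unique():
        sub = merged[merged["domain_se"] == domain]
        correct = {}
        for name, suffix in (("SE", "_se"), ("DE", "_de")):
            cols = {
                c + suffix: c
                for c in ["match_score", "psr", "vx", "vy", "label", "domain"]
            }
            frames = sub[keys + list(cols)].rename(columns=cols)
            frames["modality"] = name
            s = model_scores(fits[name], frames)
            thrs = fits[name].thresholds
            thr = thrs.get(domain, float(np.mean(list(thrs.values()))))
            correct[name] = (s >= thr) == (frames["label"].to_numpy() == 1)
        p_by_domain[domain] = mcnemar_exact(correct["SE"], correct["DE"])

    holdout_rows = []
    if holdout_se is not None and holdout_de is not None:
        for ds in sorted(holdout_se["dataset_id"].unique()):
            row = {
                "dataset_id": ds,
                "band": (holdout_bands or {}).get(ds, ""),
            }
            for name, tab in (("SE", holdout_se), ("DE", holdout_de)):
                rep = evaluate_model(fits[name], tab[tab["dataset_id"] == ds],
                                     dataset_id=ds)
                row[f"{name}_sensitivity"] = rep.sensitivity
                row[f"{name}_specificity"] = rep.specificity
            holdout_rows.append(row)

    return {
        "fits": fits,
        "train_reports": reports,
        "matched_specificity_sensitivity": matched,
        "mcnemar_p": p_by_domain,
        "holdout_table": pd.DataFrame(holdout_rows) if holdout_rows else None,
    }
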