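"""Design-matrix construction for the reliability model.

Per-frame features: match score (x1), PSR (x2), x-velocity (x3) and
y-velocity (x4), a domain indicator DI (phantom = 0, patient = 1) and
the four DI-by-feature interaction columns that let one model adapt its
coefficients between domains.  The match score is standard-scaled
(mean/std); PSR and the velocities, which are more outlier-prone, are
robust-scaled (median/IQR).  Scalers are fit on training rows only and
reapplied unchanged to validation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from sklearn.preprocessing import RobustScaler, StandardScaler

from .config import WeightScheme
from .ground_truth import Trajectory, TsrResult
from .tracking import TrackSeries

__all__ = [
    "RAW_FEATURES",
    "DESIGN_COLUMNS",
    "velocities",
    "build_feature_table",
    "ScalerState",
    "fit_scalers",
    "apply_scalers",
    "build_design_matrix",
    "assign_weights",
]

RAW_FEATURES = ["match_score", "psr", "vx", "vy"]
# column order fixed to the beta1..beta9 reporting convention
DESIGN_COLUMNS = [
    "x1",
    "x2",
    "x3",
    "x4",
    "di",
    "di_x1",
    "di_x2",
    "di_x3",
    "di_x4",
]


def velocities(track: TrackSeries) -> np.ndarray:
    """Per-frame (vx, vy) in mm/s from tracked positions.

    Central finite differences over the *tracked* (non-missing) frames
    using actual timestamps; endpoints and frames adjacent to a missing
    gap fall back to the available side.  Missing frames get NaN.
    """
    tracked = ~track.missing
    if tracked.sum() < 2:
        raise ValueError("need at least 2 tracked frames for velocities")
    t = track.t_s[tracked]
    pos = track.positions_mm[tracked]
    v = np.column_stack(
        [np.gradient(pos[:, 0], t), np.gradient(pos[:, 1], t)]
    )
    out = np.full((len(track), 2), np.nan)
    out[tracked] = v
    return out


def build_feature_table(
    track: TrackSeries,
    reference: Trajectory,
    tsr_result: TsrResult,
    domain: str,
) -> pd.DataFrame:
    """One row per tracked frame: raw features + reliability label.

    Rows from missing frames are dropped (no imputation).
    """
    if domain not in ("phantom", "patient"):
        raise ValueError("domain must be 'phantom' or 'patient'")
    v = velocities(track)
    tracked = ~track.missing
    df = pd.DataFrame(
        {
            "dataset_id": track.dataset_id,
            "modality": track.modality,
            "domain": domain,
            "frame_index": track.frame_index[tracked],
            "t_s": track.t_s[tracked],
            "match_score": track.match_score[tracked],
            "psr": track.psr[tracked],
            "vx": v[tracked, 0],
            "vy": v[tracked, 1],
            "error_mm": tsr_result.error_mm[tracked],
            "label": tsr_result.labels[tracked].astype(int),
        }
    )
    return df.reset_index(drop=True)


@dataclass
class ScalerState:
    """Serializable per-domain scaling statistics.

    ``params[domain]`` holds ``(center, scale)`` pairs for each raw
    feature: mean/std for the match score, median/IQR for the rest.
    """

    params: Dict[str, Dict[str, tuple]] = field(default_factory=dict)
    per_domain: bool = True
    fit_population: str = ""

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "per_domain": self.per_domain,
            "fit_population": self.fit_population,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(
            params={k: {f: tuple(v) for f, v in p.items()} for k, p in d["params"].items()},
            per_domain=d["per_domain"],
            fit_population=d.get("fit_population", ""),
        )


def _fit_one(df: pd.DataFrame) -> Dict[str, tuple]:
    params: Dict[str, tuple] = {}
    std = StandardScaler().fit(df[["match_score"]].to_numpy())
    params["match_score"] = (float(std.mean_[0]), float(std.scale_[0]))
    rob = RobustScaler().fit(df[["psr", "vx", "vy"]].to_numpy())
    for j, feat in enumerate(["psr", "vx", "vy"]):
        center = float(rob.center_[j])
        scale = float(rob.scale_[j])
        vals = df[feat].to_numpy()
        # degenerate IQR (exactly or numerically zero, e.g. when most
        # frames share one value): fall back to the std-based scale
        iqr = float(np.subtract(*np.percentile(vals, [75, 25])))
        if iqr <= 1e-6 * (np.abs(vals).max() + 1.0):
            warnings.warn(f"degenerate IQR for {feat}; using std-based scale")
            scale = float(np.std(vals)) or 1.0
        params[feat] = (center, scale)
    return params


def fit_scalers(
    train: pd.DataFrame, per_domain: bool = True, fit_population: str = ""
) -> ScalerState:
    """Fit feature scalers on training rows (per domain by default)."""
    state = ScalerState(per_domain=per_domain, fit_population=fit_population)
    if per_domain:
        for domain, grp in train.groupby("domain"):
            state.params[domain] = _fit_one(grp)
    else:
        state.params["pooled"] = _fit_one(train)
    return state


def apply_scalers(df: pd.DataFrame, state: ScalerState) -> pd.DataFrame:
    """Add scaled columns x1..x4 using the stored state verbatim."""
    out = df.copy()
    for col in ("x1", "x2", "x3", "x4"):
        out[col] = np.nan
    for domain in out["domain"].unique():
        key = domain if state.per_domain else "pooled"
        if key not in state.params:
            raise KeyError(f"scaler state has no parameters for domain {key!r}")
        sel = out["domain"] == domain
        for xcol, feat in zip(("x1", "x2", "x3", "x4"), RAW_FEATURES):
            center, scale = state.params[key][feat]
            out.loc[sel, xcol] = (out.loc[sel, feat] - center) / scale
    return out


def build_design_matrix(frames: pd.DataFrame):
    """Design matrix with columns ordered x1..x4, DI, DI*x1..DI*x4.

    Returns ``(X, y, w)``; phantom rows have columns 5-9 identically
    zero.  Requires scaled features, labels and weights.
    """
    required = ["x1", "x2", "x3", "x4", "domain", "label"]
    missing = [c for c in required if c not in frames.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    if frames["label"].isna().any():
        raise ValueError("unlabeled frames in the feature table")
    di = (frames["domain"] == "patient").astype(float).to_numpy()
    xs = frames[["x1", "x2", "x3", "x4"]].to_numpy(dtype=float)
    x = np.column_stack([xs, di, xs * di[:, None]])
    y = frames["label"].to_numpy(dtype=float)
    w = (
        frames["weight"].to_numpy(dtype=float)
        if "weight" in frames.columns
        else np.ones(len(frames))
    )
    if np.any(w <= 0):
        raise ValueError("sample weights must be > 0")
    return x, y, w


def assign_weights(
    frames: pd.DataFrame,
    quality_by_dataset: Dict[str, str],
    scheme: Optional[WeightScheme] = None,
) -> pd.DataFrame:
    """Per-row sample weights from the dataset quality band.

    Phantom rows get the phantom weight (1.0 by default); patient rows
    get the band weight of their dataset.  A patient dataset without a
    stratified band is an error.
    """
    scheme = scheme or WeightScheme()
    out = frames.copy()
    weights = np.full(len(out), scheme.phantom)
    patient = out["domain"] == "patient"
    for ds in out.loc[patient, "dataset_id"].unique():
        if ds not in quality_by_dataset:
            raise KeyError(f"no quality band for patient dataset {ds!r}")
        weights[(out["dataset_id"] == ds).to_numpy() & patient.to_numpy()] = (
            scheme.for_band(quality_by_dataset[ds])
        )
    out["weight"] = weights
    return out
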