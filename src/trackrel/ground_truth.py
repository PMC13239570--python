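"""Reference trajectories, tracking errors, TSR and quality bands.

Phantom runs use the programmed breathing waveform as ground truth
(GT).  Patient-like runs have no GT; a constant-acceleration Kalman
filter applied to the tracked positions provides an estimated ground
truth (eGT), with an automated outlier report replacing manual review.
A tracked frame is labeled reliable when its Euclidean error versus the
(e)GT is below 2 mm; the tracking success rate (TSR) is the percentage
of tracked (non-missing) frames labeled reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import KalmanConfig, MotionSpec, QualityBands
from .synthetic import trajectory as _motion_trajectory
from .tracking import TrackSeries

__all__ = [
    "Trajectory",
    "phantom_gt",
    "kalman_egt",
    "flag_egt_outliers",
    "tracking_errors",
    "tsr",
    "TsrResult",
    "quality_midpoints",
    "stratify",
]


@dataclass
class Trajectory:
    """Per-frame reference positions, optionally with errors and labels."""

    positions_mm: np.ndarray  # (n, 2) (x, y) at isocenter
    t_s: np.ndarray
    source: str  # programmed | kalman
    error_mm: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions_mm)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "t_s": self.t_s,
                "x_mm": self.positions_mm[:, 0],
                "y_mm": self.positions_mm[:, 1],
                "source": self.source,
            }
        )
        if self.error_mm is not None:
            df["error_mm"] = self.error_mm
        if self.labels is not None:
            df["label"] = self.labels
        return df


def phantom_gt(motion: MotionSpec, timestamps) -> Trajectory:
    """Ground truth from the programmed waveform (shared code path with
    the synthetic generator, so GT matches the generator exactly)."""
    t = np.asarray(timestamps, dtype=float)
    return Trajectory(
        positions_mm=_motion_trajectory(motion, t), t_s=t, source="programmed"
    )


def kalman_egt(
    measurements: np.ndarray,
    dt: float,
    config: Optional[KalmanConfig] = None,
    timestamps=None,
) -> Trajectory:
    """Estimated GT: per-axis constant-acceleration Kalman filter.

    ``measurements`` is (n, 2) with NaN rows marking missing frames;
    those frames get a predict step only (no update), as do
    measurements rejected by the per-axis innovation gate
    (``config.innovation_gate_sigma``).  The returned positions are the
    corrected (posterior) estimates — causal filtering, matching a
    real-time setting; set ``config.smoother`` for an additional RTS
    smoothing pass.
    """
    config = config or KalmanConfig()
    z = np.asarray(measurements, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2:
        raise ValueError("measurements must be (n, 2)")
    valid = ~np.isnan(z).any(axis=1)
    if valid.sum() < 3:
        raise ValueError("need at least 3 non-missing measurements")

    q, r = config.process_noise_q, config.measurement_noise_r
    f = np.array([[1, dt, dt**2 / 2], [0, 1, dt], [0, 0, 1]])
    qm = q * np.array(
        [
            [dt**5 / 20, dt**4 / 8, dt**3 / 6],
            [dt**4 / 8, dt**3 / 3, dt**2 / 2],
            [dt**3 / 6, dt**2 / 2, dt],
        ]
    )
    h = np.array([[1.0, 0.0, 0.0]])

    n = len(z)
    out = np.empty_like(z)
    first = int(np.argmax(valid))
    for axis in range(2):
        x = np.array([z[first, axis], 0.0, 0.0])
        p = np.eye(3) * config.initial_cov_scale
        states = np.empty((n, 3))
        covs = np.empty((n, 3, 3))
        preds = np.empty((n, 3))
        pred_covs = np.empty((n, 3, 3))
        for i in range(n):
            if i > first:
                x = f @ x
                p = f @ p @ f.T + qm
            preds[i] = x
            pred_covs[i] = p
            if valid[i]:
                innov = float(z[i, axis] - (h @ x)[0])
                s = float((h @ p @ h.T)[0, 0]) + r
                gated = (
                    i > first
                    and abs(innov) > config.innovation_gate_sigma * np.sqrt(s)
                )
                if not gated:
                    k = (p @ h.T) / s
                    x = x + (k * innov).ravel()
                    p = (np.eye(3) - k @ h) @ p
            states[i] = x
            covs[i] = p
        if config.smoother:
            for i in range(n - 2, first - 1, -1):
                c = covs[i] @ f.T @ np.linalg.inv(pred_covs[i + 1])
                states[i] = states[i] + c @ (states[i + 1] - preds[i + 1])
        out[:, axis] = states[:, 0]
        out[:first, axis] = states[first, 0]
    t = (
        np.asarray(timestamps, dtype=float)
        if timestamps is not None
        else np.arange(n) * dt
    )
    return Trajectory(positions_mm=out, t_s=t, source="kalman")


def flag_egt_outliers(
    egt: Trajectory, measurements: np.ndarray, k_sigma: float = 4.0
) -> np.ndarray:
    """Frames where |measurement - eGT| exceeds ``k_sigma`` robust
    (MAD-based) deviations: flagged for review, never auto-corrected.

    The automated surrogate for human inspection of the eGT.
    """
    z = np.asarray(measurements, dtype=float)
    if len(z) != len(egt):
        raise ValueError("eGT and measurements are not aligned")
    resid = np.linalg.norm(z - egt.positions_mm, axis=1)
    finite = np.isfinite(resid)
    if not finite.any() or not np.isfinite(k_sigma):
        return np.array([], dtype=int)
    med = np.median(resid[finite])
    mad = np.median(np.abs(resid[finite] - med))
    sigma = 1.4826 * mad
    if sigma == 0:
        sigma = np.std(resid[finite])
    if sigma == 0:
        return np.array([], dtype=int)
    return np.where(finite & (np.abs(resid - med) > k_sigma * sigma))[0]


def tracking_errors(track: TrackSeries, ref: Trajectory) -> np.ndarray:
    """Per-frame Euclidean error (mm); NaN on missing frames."""
    if len(track) != len(ref):
        raise ValueError("track and reference lengths differ")
    return np.linalg.norm(track.positions_mm - ref.positions_mm, axis=1)


@dataclass
class TsrResult:
    tsr: float  # percentage over tracked frames
    labels: np.ndarray  # per tracked+missing frame; False on missing
    error_mm: np.ndarray
    n_tracked: int
    n_missing: int


def tsr(track: TrackSeries, ref: Trajectory, threshold_mm: float = 2.0) -> TsrResult:
    """Tracking success rate: % of tracked frames with error < threshold.

    Missing frames are excluded from the denominator and reported
    separately as the MF count.  The comparison is strict (<), so an
    error of exactly 2.0 mm is unreliable.
    """
    err = tracking_errors(track, ref)
    tracked = ~track.missing
    n_tracked = int(tracked.sum())
    if n_tracked == 0:
        raise ValueError("TSR undefined: no tracked frames")
    labels = np.zeros(len(track), dtype=bool)
    labels[tracked] = err[tracked] < threshold_mm
    value = 100.0 * labels[tracked].mean()
    return TsrResult(
        tsr=float(value),
        labels=labels,
        error_mm=err,
        n_tracked=n_tracked,
        n_missing=int((~tracked).sum()),
    )


def quality_midpoints(baseline_tsr_by_size: Dict[int, float]) -> Tuple[float, float]:
    """Arithmetic midpoints between consecutive tumor-size TSR baselines."""
    sizes = sorted(baseline_tsr_by_size)
    if len(sizes) != 3:
        raise ValueError("expected baselines for exactly three tumor sizes")
    a, b, c = (baseline_tsr_by_size[s] for s in sizes)
    return ((a + b) / 2.0, (b + c) / 2.0)


def stratify(tsr_value: float, bands: Optional[QualityBands] = None) -> str:
    """Three-level tracking quality: poor (< poor_upper), moderate
    (closed interval), good (> good_lower)."""
    bands = bands or QualityBands()
    if not 0.0 <= tsr_value <= 100.0:
        raise ValueError("TSR must lie in [0, 100]")
    if tsr_value < bands.poor_upper:
        return "poor"
    if tsr_value <= bands.good_lower:
        return "moderate"
    return "good"
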