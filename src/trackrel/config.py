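"""Configuration dataclasses shared across the pipeline.

Conventions used throughout the package:

* images are ``(rows, cols)`` float arrays, origin at the top-left,
  0-based pixel indices;
* the superior-inferior (SI) motion axis maps to the image row (y) axis;
* physical positions are reported in mm *at isocenter*, i.e. detector
  millimetres divided by the projection magnification ``sdd / sad``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass
class MotionSpec:
    """Programmed respiratory motion of the simulated tumor.

    ``amplitude_mm`` is the peak-to-peak SI displacement (see
    ``amplitude_is_peak_to_peak`` for the alternative half-range
    reading).  The even-power breathing waveform is
    ``z(t) = A * cos^4(pi * (t - phase) / T)``, so displacement spans
    ``[0, A]`` and the period is ``T``.
    """

    waveform: str = "cos4"  # cos4 | irregular | stationary
    amplitude_mm: float = 7.5
    period_s: float = 5.0
    phase_s: float = 0.0
    amplitude_jitter_frac: float = 0.0
    period_jitter_frac: float = 0.0
    drift_mm_per_s: float = 0.0
    lateral_frac: float = 0.0  # lateral (x) displacement as a fraction of z(t)
    amplitude_is_peak_to_peak: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.waveform not in ("cos4", "irregular", "stationary"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be >= 0")
        if self.waveform != "stationary" and self.period_s <= 0:
            raise ValueError("period_s must be > 0 for non-stationary motion")
        for name in ("amplitude_jitter_frac", "period_jitter_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")

    @property
    def peak_mm(self) -> float:
        """Waveform peak value (equals A for the peak-to-peak reading)."""
        if self.amplitude_is_peak_to_peak:
            return self.amplitude_mm
        return 2.0 * self.amplitude_mm


@dataclass
class PhantomSpec:
    """Thorax-like digital phantom: tissue slab, ribs, spine, spherical tumor.

    Attenuation coefficients are per-mm linear coefficients at the high
    (HE) and low (LE) tube energies.  Physically the bone LE/HE ratio
    exceeds the soft-tissue LE/HE ratio; that ordering is what gives
    dual-energy subtraction its bone-cancelling weight and is enforced
    here.  The default bone coefficients are chosen so that the
    bone-cancelling weight ``mu_bone(HE)/mu_bone(LE)`` equals 0.69, the
    weight used for thorax phantom acquisitions.
    """

    image_shape: tuple = (128, 128)
    pixel_spacing_mm: float = 0.776
    tumor_diameter_mm: float = 10.0
    tumor_center_px: Optional[tuple] = None  # (row, col); default = image center
    # per-mm linear attenuation (HE, LE)
    mu_tissue: tuple = (0.017, 0.022)
    mu_bone: tuple = (0.035, 0.035 / 0.69)
    mu_tumor: tuple = (0.010, 0.0129)
    tissue_thickness_mm: float = 160.0
    body_halfwidth_frac: float = 0.55  # lateral body profile half width
    rib_rows: tuple = ()  # explicit rib center rows; empty -> regular grid
    rib_spacing_px: int = 44
    rib_halfwidth_px: float = 3.0
    rib_thickness_mm: float = 7.0
    spine_halfwidth_px: float = 6.0
    spine_thickness_mm: float = 25.0
    spine_col: Optional[int] = None  # default: near the left edge
    # static spherical clutter: soft-tissue blobs (vessels) confuse both
    # energy streams; bone blobs (calcifications, rib-vessel crossings)
    # are cancelled by dual-energy subtraction and distract SE only
    clutter_n: int = 0
    clutter_diameter_mm: tuple = (2.5, 5.0)
    clutter_bone_frac: float = 0.0
    clutter_box_half_px: Optional[int] = None  # confine blobs near the center
    clutter_on_ribs: bool = False  # seat bone blobs on rib lines (costal knobs)
    clutter_seed: int = 0

    def __post_init__(self) -> None:
        for mus in (self.mu_tissue, self.mu_bone, self.mu_tumor):
            if min(mus) < 0:
                raise ValueError("attenuation coefficients must be >= 0")
        tissue_ratio = self.mu_tissue[1] / self.mu_tissue[0]
        bone_ratio = self.mu_bone[1] / self.mu_bone[0]
        if not bone_ratio > tissue_ratio:
            raise ValueError(
                "bone LE/HE attenuation ratio must exceed the tissue ratio "
                "(dual-energy contrast condition)"
            )
        if self.tumor_diameter_mm <= 0:
            raise ValueError("tumor_diameter_mm must be > 0")

    @property
    def tumor_center(self) -> tuple:
        if self.tumor_center_px is not None:
            return tuple(self.tumor_center_px)
        return (self.image_shape[0] / 2.0, self.image_shape[1] / 2.0)

    @property
    def ws_oracle(self) -> float:
        """Analytic bone-cancelling weight mu_bone(HE) / mu_bone(LE)."""
        return self.mu_bone[0] / self.mu_bone[1]


@dataclass
class AcquisitionSpec:
    """Fast-kV-switching acquisition: alternating HE/LE pulses.

    ``frame_rate_fps`` is the pulse rate; each consecutive HE/LE pair
    yields one dual-energy frame, so the DE-effective rate is half the
    pulse rate (7.5 fps at the default 15 fps).
    """

    frame_rate_fps: float = 15.0
    n_frames: int = 120
    energies: tuple = ("HE", "LE")
    inter_pulse_offset_px: tuple = (0.0, 0.0)  # (drow, dcol) shift of LE frames
    sdd_cm: float = 150.0
    sad_cm: float = 100.0
    noise_model: str = "gaussian"  # none | poisson | gaussian
    noise_scale: float = 1.0
    # incident fluence high enough that subtracted (DE) frames keep usable
    # tumor SNR without any DE noise filtering (which this package omits)
    i0: float = 5.0e5

    def __post_init__(self) -> None:
        if self.frame_rate_fps <= 0:
            raise ValueError("frame_rate_fps must be > 0")
        if not self.sdd_cm > self.sad_cm > 0:
            raise ValueError("require sdd_cm > sad_cm > 0")
        if self.i0 <= 0:
            raise ValueError("i0 must be > 0")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def magnification(self) -> float:
        return self.sdd_cm / self.sad_cm

    @property
    def pair_interval_s(self) -> float:
        """Time between successive HE/LE pairs (the DE frame interval)."""
        return 2.0 / self.frame_rate_fps


@dataclass
class WlsConfig:
    """Weighted logarithmic subtraction settings.

    ``ws`` defaults per domain: 0.69 for phantom and 0.42 for
    patient acquisitions.
    """

    ws: float = 0.69
    max_shift_px: int = 5
    mi_bins: int = 32
    log_clamp_frac: float = 1e-6  # clamp intensities at frac * i0 before log
    # optional ROI registration: when set, the mutual information is
    # evaluated inside a square of half-width roi_half_px around
    # roi_center_px (row, col), aligning the tumor region between the
    # two pulses instead of the global (bone-dominated) anatomy
    roi_center_px: Optional[tuple] = None
    roi_half_px: int = 24

    DEFAULT_WS = {"phantom": 0.69, "patient": 0.42}

    def __post_init__(self) -> None:
        if self.ws < 0:
            raise ValueError("ws must be >= 0")
        if self.max_shift_px < 0:
            raise ValueError("max_shift_px must be >= 0")


@dataclass
class TrackConfig:
    """Template tracking settings."""

    search_half_px: int = 20
    window_mode: str = "fixed"  # fixed (anchor at the reference position) | follow
    min_score: float = 0.3
    psr_exclusion_radius_px: int = 5  # 11x11 exclusion window
    psr_cap: float = 100.0
    subpixel: bool = False
    drop_boundary_peaks: bool = True
    log_domain: bool = True  # match SE frames in log-intensity (line-integral) space

    def __post_init__(self) -> None:
        if self.search_half_px <= 0:
            raise ValueError("search_half_px must be > 0")
        if self.window_mode not in ("fixed", "follow"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")


@dataclass
class KalmanConfig:
    """Constant-acceleration Kalman filter used for the estimated GT.

    ``process_noise_q`` is the white acceleration-noise spectral density
    (mm^2/s^5); ``measurement_noise_r`` the per-axis measurement
    variance (mm^2).  Defaults were selected by maximizing trajectory
    recovery on the package's irregular-breathing generator and are
    artifact choices, not literature values.
    """

    process_noise_q: float = 10.0
    measurement_noise_r: float = 1.0
    initial_cov_scale: float = 100.0
    smoother: bool = False  # optional RTS pass; causal filtering by default
    # innovation gate (sigmas): measurements whose innovation exceeds the
    # gate are skipped (predict-only), the automated analog of manually
    # rejecting implausible tracked points when refining the estimate
    innovation_gate_sigma: float = 3.5

    def __post_init__(self) -> None:
        if self.process_noise_q <= 0 or self.measurement_noise_r <= 0:
            raise ValueError("q and r must be > 0")
        if self.innovation_gate_sigma <= 0:
            raise ValueError("innovation_gate_sigma must be > 0")


@dataclass
class QualityBands:
    """Three-level tracking-quality stratification by TSR.

    Default cut points are the operational 59.5 / 78.0 thresholds; the
    arithmetic midpoints of the phantom size baselines (59.9 / 78.2) are
    also available through :func:`trackrel.ground_truth.quality_midpoints`.
    """

    poor_upper: float = 59.5
    good_lower: float = 78.0
    baseline_tsr_by_size: dict = field(
        default_factory=lambda: {5: 47.6, 10: 72.2, 15: 84.2}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.poor_upper < self.good_lower < 100.0:
            raise ValueError("require 0 < poor_upper < good_lower < 100")


@dataclass
class WeightScheme:
    """Per-band sample weights for the reliability model."""

    good: float = 1.0
    moderate: float = 0.6
    poor: float = 0.2
    phantom: float = 1.0

    def __post_init__(self) -> None:
        for name in ("good", "moderate", "poor", "phantom"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"weight {name} must lie in (0, 1]")

    def for_band(self, band: str) -> float:
        return {"good": self.good, "moderate": self.moderate, "poor": self.poor}[band]


@dataclass
class LrHyper:
    """Hyper-parameters of the weighted, regularized logistic model."""

    lam: float = 0.01
    penalty: str = "l2"  # l1 | l2 | elastic_net
    l1_ratio: float = 0.5
    solver: str = "fista"  # fista (deterministic) | sgd (stochastic)
    max_iter: int = 5000
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.penalty not in ("l1", "l2", "elastic_net"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.solver not in ("fista", "sgd"):
            raise ValueError(f"unknown solver {self.solver!r}")


def to_dict(obj) -> dict:
    """Serialize any of the config dataclasses to a plain dict."""
    return asdict(obj)
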