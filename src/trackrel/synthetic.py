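"""Synthetic fast-kV-switching fluoroscopy of a breathing thorax phantom.

Stands in for dynamic-thorax-phantom and patient acquisitions: a
Beer-Lambert line-integral renderer projects a tissue slab, ribs, spine
and a spherical tumor moving along the superior-inferior axis with an
even-power (cos^4) breathing waveform, optionally with cycle-to-cycle
amplitude/period jitter and baseline drift ("patient-like" mode).
Rendering is 2-D parallel-path with precomputed thickness maps — enough
to create bone-overlap tracking failures, which is what the downstream
pipeline must exercise — not cone-beam ray tracing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .config import AcquisitionSpec, MotionSpec, PhantomSpec

__all__ = [
    "FrameMeta",
    "ImageSequence",
    "lujan_trajectory",
    "irregular_trajectory",
    "trajectory",
    "render_projection",
    "generate_sequence",
    "make_template_images",
]


@dataclass
class FrameMeta:
    index: int
    t_s: float
    energy: str  # HE | LE | DE


@dataclass
class ImageSequence:
    """Ordered frame stack plus acquisition metadata.

    ``true_positions`` holds the programmed tumor displacement per frame
    as ``(x_mm, y_mm)`` at isocenter, relative to the tumor rest
    position (None for loaded data without a known trajectory).
    """

    frames: np.ndarray  # (n, rows, cols) float32
    meta: List[FrameMeta]
    pixel_spacing_mm: float
    sdd_cm: float
    sad_cm: float
    dataset_id: str = "unnamed"
    domain: str = "phantom"  # phantom | patient
    true_positions: Optional[np.ndarray] = None  # (n, 2) mm at isocenter
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = [m.t_s for m in self.meta]
        if len(ts) != len(self.frames):
            raise ValueError("metadata length must match frame count")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be strictly increasing")
        energies = {m.energy for m in self.meta}
        if energies <= {"HE", "LE"} and len(energies) == 2:
            pattern = [m.energy for m in self.meta]
            if any(a == b for a, b in zip(pattern, pattern[1:])):
                raise ValueError("HE/LE frames must strictly alternate")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def magnification(self) -> float:
        return self.sdd_cm / self.sad_cm

    def select(self, energy: str) -> "ImageSequence":
        """Sub-sequence of frames with the given energy label."""
        idx = [i for i, m in enumerate(self.meta) if m.energy == energy]
        if not idx:
            raise ValueError(f"no frames with energy {energy!r}")
        return ImageSequence(
            frames=self.frames[idx],
            meta=[self.meta[i] for i in idx],
            pixel_spacing_mm=self.pixel_spacing_mm,
            sdd_cm=self.sdd_cm,
            sad_cm=self.sad_cm,
            dataset_id=self.dataset_id,
            domain=self.domain,
            true_positions=None
            if self.true_positions is None
            else self.true_positions[idx],
            extras=dict(self.extras),
        )


# ---------------------------------------------------------------------------
# breathing trajectories
# ---------------------------------------------------------------------------


def lujan_trajectory(motion: MotionSpec, timestamps) -> np.ndarray:
    """Even-power breathing displacement ``z(t) = A cos^4(pi (t-phase)/T)``.

    Returns SI displacement in mm, in ``[0, A]``; periodic with period
    ``T``.  Stationary specs return zeros.
    """
    t = np.asarray(timestamps, dtype=float)
    if motion.waveform == "stationary":
        return np.zeros_like(t)
    if motion.period_s <= 0:
        raise ValueError("period_s must be > 0")
    a = motion.peak_mm
    x = np.pi * (t - motion.phase_s) / motion.period_s
    return a * np.cos(x) ** 4


def irregular_trajectory(motion: MotionSpec, timestamps) -> np.ndarray:
    """Patient-like breathing: per-cycle amplitude/period jitter + drift.

    Each breathing cycle k spans one jittered period ``T_k = T (1 + u_k
    * period_jitter)`` and carries its own amplitude ``A_k = A (1 + v_k
    * amplitude_jitter)`` with u, v ~ Uniform(-1, 1) drawn from
    ``motion.seed``; a linear baseline drift is added relative to the
    first timestamp.  With zero jitter and drift this reduces exactly to
    :func:`lujan_trajectory`.
    """
    t = np.asarray(timestamps, dtype=float)
    if motion.waveform == "stationary":
        return np.zeros_like(t)
    if motion.period_s <= 0:
        raise ValueError("period_s must be > 0")
    rng = np.random.default_rng(motion.seed)
    a0, t0 = motion.peak_mm, motion.period_s

    def draw():
        u = rng.uniform(-1.0, 1.0)
        v = rng.uniform(-1.0, 1.0)
        return (
            a0 * (1.0 + motion.amplitude_jitter_frac * u),
            t0 * (1.0 + motion.period_jitter_frac * v),
        )

    # cycle k spans [edges[k], edges[k+1]); the waveform peaks at the
    # cycle center, so with zero jitter centers sit at phase + k*T
    amp0, per0 = draw()
    edges = [motion.phase_s - per0 / 2.0]
    amps, pers = [amp0], [per0]
    while edges[-1] + pers[-1] < t.max():
        edges.append(edges[-1] + pers[-1])
        a_k, p_k = draw()
        amps.append(a_k)
        pers.append(p_k)
    while edges[0] > t.min():
        a_k, p_k = draw()
        edges.insert(0, edges[0] - p_k)
        amps.insert(0, a_k)
        pers.insert(0, p_k)

    edges_arr = np.asarray(edges)
    k = np.clip(np.searchsorted(edges_arr, t, side="right") - 1, 0, len(amps) - 1)
    amps_arr = np.asarray(amps)[k]
    pers_arr = np.asarray(pers)[k]
    centers = edges_arr[k] + pers_arr / 2.0
    z = amps_arr * np.cos(np.pi * (t - centers) / pers_arr) ** 4
    if motion.drift_mm_per_s:
        z = z + motion.drift_mm_per_s * (t - t[0])
    return z


def trajectory(motion: MotionSpec, timestamps) -> np.ndarray:
    """Dispatch on the waveform; returns (n, 2) ``(x_mm, y_mm)`` displacement."""
    if motion.waveform == "irregular":
        z = irregular_trajectory(motion, timestamps)
    else:
        z = lujan_trajectory(motion, timestamps)
    x = motion.lateral_frac * z
    return np.column_stack([x, z])


# ---------------------------------------------------------------------------
# projection renderer
# ---------------------------------------------------------------------------


def _thickness_maps(
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    displacement_mm,
    global_shift_px=(0.0, 0.0),
    include_background: bool = True,
    include_tumor: bool = True,
    frame_label: str = "",
):
    """Per-material path-length (mm) maps for one projection."""
    ny, nx = phantom.image_shape
    rows = np.arange(ny, dtype=float)[:, None] - global_shift_px[0]
    cols = np.arange(nx, dtype=float)[None, :] - global_shift_px[1]
    mag = acq.magnification
    px_per_iso_mm = mag / phantom.pixel_spacing_mm

    tissue = np.zeros((ny, nx))
    bone = np.zeros((ny, nx))
    tumor = np.zeros((ny, nx))

    if include_background:
        # lateral body profile: elliptical chord through a tissue slab
        cx = nx / 2.0
        rx = phantom.body_halfwidth_frac * nx
        prof = 1.0 - ((cols - cx) / rx) ** 2
        tissue += phantom.tissue_thickness_mm * np.sqrt(np.clip(prof, 0.0, None))

        # spine: vertical bone column
        sc = phantom.spine_col if phantom.spine_col is not None else int(0.15 * nx)
        sp = 1.0 - ((cols - sc) / phantom.spine_halfwidth_px) ** 2
        bone += phantom.spine_thickness_mm * np.sqrt(np.clip(sp, 0.0, None)) * np.ones(
            (ny, 1)
        )

        # ribs: horizontal bone bands
        if phantom.rib_rows:
            rib_rows = list(phantom.rib_rows)
        else:
            # offset the grid so one rib sits inferior to the image center,
            # clear of the rest position but crossed during breathing
            sp = phantom.rib_spacing_px
            start = (ny / 2.0 + 13.0) % sp
            rib_rows = list(np.arange(start, ny, sp))
        for r0 in rib_rows:
            rp = 1.0 - ((rows - r0) / phantom.rib_halfwidth_px) ** 2
            bone += (
                phantom.rib_thickness_mm
                * np.sqrt(np.clip(rp, 0.0, None))
                * np.ones((1, nx))
            )

    if include_background and phantom.clutter_n > 0:
        # static clutter spheres: tumor-equivalent soft tissue (vessels)
        # plus, optionally, bone-like blobs that only SE frames retain
        crng = np.random.default_rng(phantom.clutter_seed)
        lo, hi = phantom.clutter_diameter_mm
        box = phantom.clutter_box_half_px
        r_lo, r_hi = (4, ny - 4) if box is None else (ny / 2 - box, ny / 2 + box)
        c_lo, c_hi = (4, nx - 4) if box is None else (nx / 2 - box, nx / 2 + box)
        for _ in range(phantom.clutter_n):
            br = crng.uniform(r_lo, r_hi)
            bc = crng.uniform(c_lo, c_hi)
            brad = crng.uniform(lo, hi) / 2.0
            bony = crng.uniform() < phantom.clutter_bone_frac
            if bony and phantom.clutter_on_ribs and rib_rows:
                # costal knob: sit on the nearest rib line with small jitter
                br = min(rib_rows, key=lambda r0: abs(r0 - br)) + crng.uniform(-2, 2)
            rho = np.hypot(rows - br, cols - bc) / px_per_iso_mm
            chord = 2.0 * np.sqrt(np.clip(brad**2 - rho**2, 0.0, None))
            if bony:
                # scaled so a bone blob's HE contrast matches a tumor
                # blob's (same size, same apparent strength in SE)
                bone += chord * (phantom.mu_tumor[0] / phantom.mu_bone[0])
            else:
                tumor += chord

    if include_tumor:
        dx, dy = float(displacement_mm[0]), float(displacement_mm[1])
        r0, c0 = phantom.tumor_center
        trow = r0 + dy * px_per_iso_mm
        tcol = c0 + dx * px_per_iso_mm
        if not (0 <= trow < ny and 0 <= tcol < nx):
            raise ValueError(
                f"tumor center ({trow:.1f}, {tcol:.1f}) px outside the "
                f"{ny}x{nx} field of view"
                + (f" at frame {frame_label}" if frame_label else "")
            )
        radius_mm = phantom.tumor_diameter_mm / 2.0
        # radial distance from projected center, in iso-mm
        rho = (
            np.hypot(rows - trow, cols - tcol) / px_per_iso_mm
        )
        chord = radius_mm**2 - rho**2
        tumor += 2.0 * np.sqrt(np.clip(chord, 0.0, None))

    return tissue, bone, tumor


def render_projection(
    phantom: PhantomSpec,
    displacement_mm,
    energy: str,
    acq: AcquisitionSpec,
    rng: Optional[np.random.Generator] = None,
    global_shift_px=(0.0, 0.0),
    include_background: bool = True,
    include_tumor: bool = True,
    frame_label: str = "",
) -> np.ndarray:
    """Beer-Lambert projection ``i0 * exp(-sum_m mu_m(E) * t_m)`` + noise.

    ``displacement_mm`` is the (x, y) tumor displacement at isocenter;
    the projected shift on the detector is scaled by the magnification
    ``sdd/sad``.  ``global_shift_px`` rigidly shifts every structure
    (used to emulate inter-pulse misregistration of LE frames).
    """
    if energy not in ("HE", "LE"):
        raise ValueError("energy must be 'HE' or 'LE'")
    ei = 0 if energy == "HE" else 1
    tissue, bone, tumor = _thickness_maps(
        phantom,
        acq,
        displacement_mm,
        global_shift_px,
        include_background,
        include_tumor,
        frame_label,
    )
    optical = (
        phantom.mu_tissue[ei] * tissue
        + phantom.mu_bone[ei] * bone
        + phantom.mu_tumor[ei] * tumor
    )
    img = acq.i0 * np.exp(-optical)
    if acq.noise_model == "none" or rng is None:
        return img
    if acq.noise_model == "poisson":
        img = rng.poisson(img).astype(float)
    elif acq.noise_model == "gaussian":
        # Gaussian approximation to photon statistics: sd = scale*sqrt(I)
        img = img + rng.normal(0.0, acq.noise_scale * np.sqrt(img))
    return np.clip(img, 1e-3, None)


def generate_sequence(
    phantom: PhantomSpec,
    motion: MotionSpec,
    acq: AcquisitionSpec,
    seed: int = 0,
    dataset_id: str = "synthetic",
    domain: str = "phantom",
) -> ImageSequence:
    """Alternating HE/LE sequence at the pulse rate, HE first.

    The LE frame of each pair is rendered with the tumor displaced per
    its own (later) timestamp and the whole scene shifted by
    ``acq.inter_pulse_offset_px``, emulating the small gantry motion
    between the two pulses of a pair.
    """
    if acq.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(acq.n_frames) / acq.frame_rate_fps
    disp = trajectory(motion, t)
    frames = []
    meta = []
    for i in range(acq.n_frames):
        energy = "HE" if i % 2 == 0 else "LE"
        shift = (0.0, 0.0) if energy == "HE" else tuple(acq.inter_pulse_offset_px)
        frames.append(
            render_projection(
                phantom,
                disp[i],
                energy,
                acq,
                rng=rng,
                global_shift_px=shift,
                frame_label=str(i),
            )
        )
        meta.append(FrameMeta(index=i, t_s=float(t[i]), energy=energy))
    return ImageSequence(
        frames=np.asarray(frames, dtype=np.float32),
        meta=meta,
        pixel_spacing_mm=phantom.pixel_spacing_mm,
        sdd_cm=acq.sdd_cm,
        sad_cm=acq.sad_cm,
        dataset_id=dataset_id,
        domain=domain,
        true_positions=disp,
    )


def make_template_images(phantom: PhantomSpec, acq: AcquisitionSpec):
    """Noiseless tumor-only HE/LE reference renders at zero displacement.

    The analog of deriving the template from the contoured tumor on the
    planning CT: only the tumor contributes, so the template carries no
    rib or spine signal.
    """
    kw = dict(include_background=False, include_tumor=True)
    ih = render_projection(phantom, (0.0, 0.0), "HE", acq, rng=None, **kw)
    il = render_projection(phantom, (0.0, 0.0), "LE", acq, rng=None, **kw)
    return ih, il
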