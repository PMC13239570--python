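"""Bone-suppressed dual-energy images by weighted logarithmic subtraction.

Each HE/LE pair is rigidly aligned (integer-translation search
maximizing mutual information) and combined as ``DE = ln I_H - ws * ln
I_L``.  The weight ``ws`` cancels the bone term when it equals the bone
attenuation ratio ``mu_bone(HE)/mu_bone(LE)``; domain defaults are 0.69
(phantom) and 0.42 (patient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .config import WlsConfig
from .synthetic import FrameMeta, ImageSequence

__all__ = [
    "RegistrationResult",
    "register_pair",
    "translate_image",
    "wls_subtract",
    "calibrate_ws",
    "subtract_sequence",
]


@dataclass
class RegistrationResult:
    shift_px: tuple  # (drow, dcol): translation mapping ih onto il
    mi: float
    degenerate: bool = False


def translate_image(img: np.ndarray, shift) -> np.ndarray:
    """Integer-translate with nearest-edge padding; content moves by +shift."""
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    out = np.roll(img, (dy, dx), axis=(0, 1))
    if dy > 0:
        out[:dy, :] = out[dy : dy + 1, :]
    elif dy < 0:
        out[dy:, :] = out[dy - 1 : dy, :]
    if dx > 0:
        out[:, :dx] = out[:, dx : dx + 1]
    elif dx < 0:
        out[:, dx:] = out[:, dx - 1 : dx]
    return out


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def register_pair(ih: np.ndarray, il: np.ndarray, config: WlsConfig) -> RegistrationResult:
    """Exhaustive integer-translation search maximizing mutual information.

    Returns the shift such that ``translate_image(ih, shift)`` best
    matches ``il`` — i.e. the displacement of the LE frame relative to
    the HE frame.  Align the pair by applying the negated shift to
    ``il``.  Constant (degenerate) inputs return a zero shift with the
    ``degenerate`` flag set.
    """
    if ih.shape != il.shape:
        raise ValueError("HE/LE shapes differ")
    if np.ptp(ih) == 0 or np.ptp(il) == 0:
        return RegistrationResult((0, 0), 0.0, degenerate=True)
    m = config.max_shift_px
    best = (0, 0)
    best_mi = -np.inf
    ny, nx = ih.shape
    roi = None
    if config.roi_center_px is not None:
        rc, cc = config.roi_center_px
        h = config.roi_half_px
        r0 = int(np.clip(round(rc) - h, m, ny - m - 1))
        r1 = int(np.clip(round(rc) + h + 1, r0 + 1, ny - m))
        c0 = int(np.clip(round(cc) - h, m, nx - m - 1))
        c1 = int(np.clip(round(cc) + h + 1, c0 + 1, nx - m))
        roi = (r0, r1, c0, c1)
    for dy in range(-m, m + 1):
        for dx in range(-m, m + 1):
            if roi is None:
                # overlap of ih shifted by (dy,dx) with il
                ys = slice(max(dy, 0), ny + min(dy, 0))
                xs = slice(max(dx, 0), nx + min(dx, 0))
                ysrc = slice(max(-dy, 0), ny + min(-dy, 0))
                xsrc = slice(max(-dx, 0), nx + min(-dx, 0))
                a, b = ih[ysrc, xsrc], il[ys, xs]
            else:
                r0, r1, c0, c1 = roi
                a = ih[r0:r1, c0:c1]
                b = il[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
            mi = _mutual_information(a, b, config.mi_bins)
            if mi > best_mi or (mi == best_mi and (dy, dx) < best):
                best_mi = mi
                best = (dy, dx)
    return RegistrationResult(best, best_mi)


def wls_subtract(ih: np.ndarray, il: np.ndarray, ws: float, i0: float = 1.0) -> np.ndarray:
    """Per-pixel ``ln(I_H) - ws * ln(I_L)`` on an aligned pair (no rescale).

    Intensities are clamped at ``1e-6 * i0`` before the logarithm.
    """
    if ih.shape != il.shape:
        raise ValueError("HE/LE shapes differ")
    eps = 1e-6 * i0
    return np.log(np.clip(ih, eps, None)) - ws * np.log(np.clip(il, eps, None))


def calibrate_ws(ih, il, bone_roi, reference_roi=None, bounds=(0.0, 2.0)) -> float:
    """Weight minimizing residual bone contrast (std of DE in the bone ROI).

    On noiseless synthetic input this equals the analytic attenuation
    ratio ``mu_bone(HE)/mu_bone(LE)``.  ``bone_roi`` is a boolean mask
    covering bone with varying thickness; ``reference_roi`` optionally
    adds a flat-tissue region to the objective.
    """
    bone_roi = np.asarray(bone_roi, dtype=bool)
    if not bone_roi.any():
        raise ValueError("bone_roi is empty")
    if np.std(np.log(np.clip(ih[bone_roi], 1e-12, None))) < 1e-12:
        raise ValueError("no contrast in bone_roi")

    lh = np.log(np.clip(ih, 1e-12, None))
    ll = np.log(np.clip(il, 1e-12, None))

    def objective(ws: float) -> float:
        de = lh - ws * ll
        val = float(np.std(de[bone_roi]))
        if reference_roi is not None:
            val += float(
                np.abs(np.mean(de[bone_roi]) - np.mean(de[np.asarray(reference_roi, bool)]))
            )
        return val

    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def subtract_sequence(seq: ImageSequence, config: WlsConfig) -> ImageSequence:
    """DE sequence from an alternating HE/LE sequence.

    Pairs are (HE, LE) in acquisition order; each LE frame is registered
    to its HE partner before subtraction.  DE frames carry the HE
    timestamp of the pair.  The output stack is min-max rescaled to
    [0, 1] using global sequence statistics so the template and search
    frames share one scale; the affine rescale is recorded in
    ``extras['de_rescale']``.
    """
    he_idx = [i for i, m in enumerate(seq.meta) if m.energy == "HE"]
    le_idx = [i for i, m in enumerate(seq.meta) if m.energy == "LE"]
    pairs = [(h, l) for h, l in zip(he_idx, le_idx) if l == h + 1]
    if not pairs:
        raise ValueError("sequence contains no HE/LE pairs")
    i0 = float(seq.extras.get("i0", np.median(seq.frames)))
    de_frames = []
    shifts = []
    for h, l in pairs:
        ih = np.asarray(seq.frames[h], dtype=float)
        il = np.asarray(seq.frames[l], dtype=float)
        reg = register_pair(ih, il, config)
        il_aligned = translate_image(il, (-reg.shift_px[0], -reg.shift_px[1]))
        de_frames.append(wls_subtract(ih, il_aligned, config.ws, i0=i0))
        shifts.append(reg.shift_px)
    de = np.asarray(de_frames)
    lo, hi = float(de.min()), float(de.max())
    scale = hi - lo if hi > lo else 1.0
    de = (de - lo) / scale
    meta = [
        FrameMeta(index=k, t_s=seq.meta[h].t_s, energy="DE")
        for k, (h, _) in enumerate(pairs)
    ]
    true_positions = (
        None
        if seq.true_positions is None
        else seq.true_positions[[h for h, _ in pairs]]
    )
    return ImageSequence(
        frames=de.astype(np.float32),
        meta=meta,
        pixel_spacing_mm=seq.pixel_spacing_mm,
        sdd_cm=seq.sdd_cm,
        sad_cm=seq.sad_cm,
        dataset_id=seq.dataset_id,
        domain=seq.domain,
        true_positions=true_positions,
        extras={
            **seq.extras,
            "de_rescale": {"offset": lo, "scale": scale},
            "registration_shifts": [list(s) for s in shifts],
            "ws": config.ws,
        },
    )
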