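"""Template-based tumor tracking: NCC surface, peak, PSR, missing frames.

The tracker slides a masked tumor template over a search window on each
frame, computes the zero-normalized cross-correlation (NCC) surface,
takes its peak as the predicted tumor location and the peak value as the
match score, and summarizes peak sharpness with the peak-to-sidelobe
ratio (PSR).  Frames are flagged missing when the peak is undefined,
the score falls below a threshold, or the peak sits on the window
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .config import TrackConfig
from .dual_energy import wls_subtract
from .synthetic import ImageSequence, make_template_images

__all__ = [
    "Template",
    "MatchSurface",
    "TrackSeries",
    "template_from_image",
    "synthetic_template",
    "ncc_surface",
    "locate_peak",
    "psr",
    "track_sequence",
]


@dataclass
class Template:
    """Masked tumor patch; ``origin_offset_px`` maps the patch top-left
    corner to the tumor centroid."""

    patch: np.ndarray
    mask: np.ndarray  # boolean, tumor support
    origin_offset_px: Tuple[float, float]

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.patch.shape != self.mask.shape:
            raise ValueError("patch and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if np.ptp(self.patch[self.mask]) == 0:
            raise ValueError("patch is constant within the mask")


@dataclass
class MatchSurface:
    """NCC values over template top-left placements; ``origin`` is the
    image coordinate of placement (0, 0)."""

    values: np.ndarray
    origin: Tuple[int, int]


@dataclass
class TrackSeries:
    """Per-frame tracking output for one modality stream."""

    frame_index: np.ndarray
    t_s: np.ndarray
    positions_mm: np.ndarray  # (n, 2) = (x, y) at isocenter; NaN when missing
    match_score: np.ndarray  # NaN when missing
    psr: np.ndarray  # NaN when missing
    missing: np.ndarray  # bool
    modality: str = "SE"
    dataset_id: str = "unnamed"
    search_window_px: int = 20
    effective_dt_s: float = 2.0 / 15.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.effective_dt_s <= 0:
            raise ValueError("effective_dt_s must be > 0")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset_id": self.dataset_id,
                "modality": self.modality,
                "frame_index": self.frame_index,
                "t_s": self.t_s,
                "x_mm": self.positions_mm[:, 0],
                "y_mm": self.positions_mm[:, 1],
                "match_score": self.match_score,
                "psr": self.psr,
                "missing": self.missing,
            }
        )


def template_from_image(
    image: np.ndarray,
    center_px: Tuple[float, float],
    half_size: int,
    mask: Optional[np.ndarray] = None,
) -> Template:
    """Crop a ``(2h+1)`` square patch around ``center_px`` (row, col)."""
    r0 = int(round(center_px[0])) - half_size
    c0 = int(round(center_px[1])) - half_size
    size = 2 * half_size + 1
    if r0 < 0 or c0 < 0 or r0 + size > image.shape[0] or c0 + size > image.shape[1]:
        raise ValueError("template crop exceeds image bounds")
    patch = np.array(image[r0 : r0 + size, c0 : c0 + size], dtype=float)
    if mask is None:
        mask = np.ones_like(patch, dtype=bool)
    return Template(patch=patch, mask=mask, origin_offset_px=(half_size, half_size))


def synthetic_template(
    phantom,
    acq,
    modality: str,
    ws: float = 0.69,
    margin_px: int = 3,
    log_domain: bool = True,
) -> Template:
    """Template from a noiseless tumor-only reference render.

    The analog of a planning-CT-contoured template: SE uses the HE
    render (in log-intensity space by default, where line integrals are
    additive), DE the weighted-log subtraction of the HE/LE pair.  The
    mask is a disk of the projected tumor radius plus ``margin_px`` so
    the background outside the contour is ignored by the masked NCC.
    """
    ih, il = make_template_images(phantom, acq)
    if modality == "SE":
        ref = np.log(np.clip(ih, 1e-12, None)) if log_domain else ih
    elif modality == "DE":
        ref = wls_subtract(ih, il, ws, i0=acq.i0)
    else:
        raise ValueError("modality must be 'SE' or 'DE'")
    radius_px = (
        phantom.tumor_diameter_mm / 2.0 * acq.magnification / phantom.pixel_spacing_mm
    )
    half = int(np.ceil(radius_px)) + margin_px
    center = phantom.tumor_center
    rr = np.arange(2 * half + 1) - half
    disk = (rr[:, None] ** 2 + rr[None, :] ** 2) <= (radius_px + margin_px) ** 2
    return template_from_image(ref, center, half, mask=disk)


def ncc_surface(
    image: np.ndarray,
    template: Template,
    window: Optional[Tuple[slice, slice]] = None,
) -> MatchSurface:
    """Masked zero-normalized cross-correlation over all template
    placements inside ``window`` (whole image by default).

    Values lie in [-1, 1]; placements where the image patch is constant
    under the mask are assigned 0 by convention.
    """
    th, tw = template.patch.shape
    if window is None:
        window = (slice(0, image.shape[0]), slice(0, image.shape[1]))
    win = np.asarray(image[window], dtype=float)
    if win.shape[0] < th or win.shape[1] < tw:
        raise ValueError("template does not fit inside the search window")
    sw = sliding_window_view(win, (th, tw))
    vals = sw[..., template.mask]  # (H', W', n)
    p = template.patch[template.mask]
    pt = p - p.mean()
    pn = float(np.linalg.norm(pt))
    vt = vals - vals.mean(axis=-1, keepdims=True)
    num = vt @ pt
    den = pn * np.linalg.norm(vt, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        surface = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    surface = np.clip(surface, -1.0, 1.0)
    return MatchSurface(values=surface, origin=(window[0].start, window[1].start))


def locate_peak(
    surface: np.ndarray, subpixel: bool = False
) -> Optional[Tuple[Tuple[float, float], float]]:
    """Argmax of the match surface with a deterministic tie-break
    (smallest row, then column).  Returns ``None`` when the surface is
    flat (peak undefined -> missing-frame signal)."""
    s = np.asarray(surface, dtype=float)
    if s.size == 0:
        raise ValueError("empty surface")
    if np.ptp(s) == 0:
        return None
    flat = int(np.argmax(s))  # row-major argmax == (smallest row, then col)
    r, c = np.unravel_index(flat, s.shape)
    score = float(s[r, c])
    rr, cc = float(r), float(c)
    if subpixel:
        rr += _parabolic_offset(s[max(r - 1, 0) : r + 2, c]) if 0 < r < s.shape[0] - 1 else 0.0
        cc += _parabolic_offset(s[r, max(c - 1, 0) : c + 2]) if 0 < c < s.shape[1] - 1 else 0.0
    return (rr, cc), score


def _parabolic_offset(triple: np.ndarray) -> float:
    if len(triple) != 3:
        return 0.0
    a, b, c = triple
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def psr(
    surface: np.ndarray,
    peak_offset: Tuple[int, int],
    exclusion_radius_px: int = 5,
    cap: float = 100.0,
) -> Tuple[float, bool]:
    """Peak-to-sidelobe ratio ``(peak - mean(side)) / std(side)``.

    The sidelobe is the surface minus a square of half-width
    ``exclusion_radius_px`` around the peak.  A zero sidelobe std
    returns the configured cap with the flag set.
    """
    s = np.asarray(surface, dtype=float)
    r, c = int(round(peak_offset[0])), int(round(peak_offset[1]))
    rows = np.arange(s.shape[0])[:, None]
    cols = np.arange(s.shape[1])[None, :]
    side_mask = (np.abs(rows - r) > exclusion_radius_px) | (
        np.abs(cols - c) > exclusion_radius_px
    )
    side = s[side_mask]
    if side.size == 0:
        raise ValueError("sidelobe region is empty; reduce exclusion radius")
    sd = float(side.std())
    if sd == 0:
        return cap, True
    return float((s[r, c] - side.mean()) / sd), False


def track_sequence(
    seq: ImageSequence,
    template: Template,
    config: TrackConfig,
    modality: str = "SE",
    reference_px: Optional[Tuple[float, float]] = None,
) -> TrackSeries:
    """Track the template through a modality stream.

    SE selects the HE frames of an energy-resolved sequence; DE expects
    a subtracted sequence.  The search window is anchored at the
    reference (planned) tumor position by default — the clinical setup,
    which lets transient occlusion failures recover — or recentered on
    the previous tracked position with ``window_mode='follow'`` (first
    frame: the reference position, or the image center).  Positions are
    reported as (x, y) mm at isocenter relative to ``reference_px``
    (default: the image center), so they are directly comparable with
    programmed displacement trajectories.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    energies = {m.energy for m in seq.meta}
    if modality == "SE":
        stream = seq.select("HE") if "HE" in energies else seq
    elif modality == "DE":
        if energies != {"DE"}:
            raise ValueError("DE tracking expects a subtracted (DE-labeled) sequence")
        stream = seq
    else:
        raise ValueError("modality must be 'SE' or 'DE'")

    img_shape = stream.frames[0].shape
    if reference_px is None:
        reference_px = (img_shape[0] / 2.0, img_shape[1] / 2.0)
    mm_per_px = stream.pixel_spacing_mm / stream.magnification
    th, tw = template.patch.shape
    oy, ox = template.origin_offset_px

    log_se = modality == "SE" and config.log_domain
    center = reference_px
    rows: List[dict] = []
    for k in range(len(stream)):
        img = np.asarray(stream.frames[k], dtype=float)
        if log_se:
            img = np.log(np.clip(img, 1e-12, None))
        half = config.search_half_px
        r_lo = int(np.clip(round(center[0] - oy) - half, 0, img_shape[0] - th))
        c_lo = int(np.clip(round(center[1] - ox) - half, 0, img_shape[1] - tw))
        r_hi = int(np.clip(round(center[0] - oy) + half + th, th, img_shape[0]))
        c_hi = int(np.clip(round(center[1] - ox) + half + tw, tw, img_shape[1]))
        surf = ncc_surface(img, template, (slice(r_lo, r_hi), slice(c_lo, c_hi)))
        peak = locate_peak(surf.values, subpixel=config.subpixel)
        missing = False
        score = np.nan
        psr_val = np.nan
        pos = (np.nan, np.nan)
        if peak is None:
            missing = True
        else:
            (pr, pc), score = peak
            on_boundary = (
                int(round(pr)) in (0, surf.values.shape[0] - 1)
                or int(round(pc)) in (0, surf.values.shape[1] - 1)
            )
            if score < config.min_score or (config.drop_boundary_peaks and on_boundary):
                missing = True
            else:
                psr_val, _ = psr(
                    surf.values,
                    (pr, pc),
                    config.psr_exclusion_radius_px,
                    config.psr_cap,
                )
                tumor_px = (surf.origin[0] + pr + oy, surf.origin[1] + pc + ox)
                pos = (
                    (tumor_px[1] - reference_px[1]) * mm_per_px,
                    (tumor_px[0] - reference_px[0]) * mm_per_px,
                )
                if config.window_mode == "follow":
                    center = tumor_px
        rows.append(
            dict(
                frame_index=stream.meta[k].index,
                t_s=stream.meta[k].t_s,
                x_mm=pos[0],
                y_mm=pos[1],
                match_score=score,
                psr=psr_val,
                missing=missing,
            )
        )

    t_arr = np.array([r["t_s"] for r in rows])
    dt = float(np.median(np.diff(t_arr))) if len(t_arr) > 1 else 1.0
    return TrackSeries(
        frame_index=np.array([r["frame_index"] for r in rows]),
        t_s=t_arr,
        positions_mm=np.column_stack(
            [[r["x_mm"] for r in rows], [r["y_mm"] for r in rows]]
        ),
        match_score=np.array([r["match_score"] for r in rows]),
        psr=np.array([r["psr"] for r in rows]),
        missing=np.array([r["missing"] for r in rows], dtype=bool),
        modality=modality,
        dataset_id=seq.dataset_id,
        search_window_px=config.search_half_px,
        effective_dt_s=dt,
    )
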