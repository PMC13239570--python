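"""Reading and writing image sequences and tabular results.

An :class:`~trackrel.synthetic.ImageSequence` is stored as a multi-page
TIFF plus a JSON sidecar holding per-frame metadata (timestamp, energy,
index), geometry and, when known, the true trajectory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import FrameMeta, ImageSequence

__all__ = ["write_sequence", "read_sequence"]


def write_sequence(seq: ImageSequence, basepath) -> Path:
    """Write ``<basepath>.tif`` and ``<basepath>.json``; returns the TIFF path."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    tif_path = base.with_suffix(".tif")
    tifffile.imwrite(
        tif_path,
        np.asarray(seq.frames, dtype=np.float32),
        photometric="minisblack",
    )
    sidecar = {
        "dataset_id": seq.dataset_id,
        "domain": seq.domain,
        "pixel_spacing_mm": seq.pixel_spacing_mm,
        "sdd_cm": seq.sdd_cm,
        "sad_cm": seq.sad_cm,
        "frames": [
            {"index": m.index, "t": m.t_s, "energy": m.energy} for m in seq.meta
        ],
        "extras": _jsonable(seq.extras),
    }
    if seq.true_positions is not None:
        sidecar["true_trajectory"] = np.asarray(seq.true_positions).tolist()
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return tif_path


def read_sequence(basepath) -> ImageSequence:
    base = Path(basepath)
    frames = tifffile.imread(base.with_suffix(".tif"))
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = json.loads(base.with_suffix(".json").read_text())
    meta = [
        FrameMeta(index=f["index"], t_s=f["t"], energy=f["energy"])
        for f in sidecar["frames"]
    ]
    true_positions = sidecar.get("true_trajectory")
    return ImageSequence(
        frames=np.asarray(frames, dtype=np.float32),
        meta=meta,
        pixel_spacing_mm=sidecar["pixel_spacing_mm"],
        sdd_cm=sidecar["sdd_cm"],
        sad_cm=sidecar["sad_cm"],
        dataset_id=sidecar["dataset_id"],
        domain=sidecar["domain"],
        true_positions=None if true_positions is None else np.asarray(true_positions),
        extras=sidecar.get("extras", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
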