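"""Reference summary statistics from the clinical/phantom tracking study
whose protocol this package implements.

The original image data are not shareable, but the study's published
per-group confusion counts and phantom TSR baselines are usable as
arithmetic inputs: sensitivities/specificities are *recomputed* here
from the raw counts with the same formulas the pipeline uses, never
hard-coded as percentages.

Count conventions: ``reliable = (correctly predicted reliable, total
truly reliable)`` gives (TP, TP+FN); ``unreliable = (correctly
predicted unreliable, total truly unreliable)`` gives (TN, TN+FP).
"""

from __future__ import annotations

from .model import ConfusionReport

__all__ = [
    "PHANTOM_BASELINE_TSR",
    "PHANTOM_TRAIN_COUNTS",
    "PATIENT_TRAIN_COUNTS",
    "report_from_counts",
]

# average phantom TSR (%) per tumor diameter (mm), SE stream
PHANTOM_BASELINE_TSR = {5: 47.6, 10: 72.2, 15: 84.2}

# phantom training counts per tumor size:
# {size: {"MF": n, "reliable": (pred, total), "unreliable": (pred, total)}}
PHANTOM_TRAIN_COUNTS = {
    "SE": {
        5: {"MF": 61, "reliable": (266, 617), "unreliable": (616, 622)},
        10: {"MF": 52, "reliable": (713, 944), "unreliable": (281, 311)},
        15: {"MF": 48, "reliable": (979, 1119), "unreliable": (143, 161)},
        "total": {"MF": 161, "reliable": (1958, 2680), "unreliable": (1040, 1094)},
    },
    "DE": {
        5: {"MF": 42, "reliable": (709, 872), "unreliable": (374, 392)},
        10: {"MF": 20, "reliable": (1134, 1215), "unreliable": (84, 89)},
        15: {"MF": 16, "reliable": (1183, 1246), "unreliable": (64, 69)},
        "total": {"MF": 78, "reliable": (3026, 3333), "unreliable": (522, 550)},
    },
}

# patient training counts per quality band
PATIENT_TRAIN_COUNTS = {
    "SE": {
        "poor": {"MF": 14, "reliable": (100, 316), "unreliable": (214, 224)},
        "moderate": {"MF": 137, "reliable": (578, 1130), "unreliable": (249, 264)},
        "good": {"MF": 65, "reliable": (1151, 1656), "unreliable": (99, 103)},
        "total": {"MF": 346, "reliable": (1829, 3102), "unreliable": (562, 591)},
    },
    "DE": {
        "poor": {"MF": 196, "reliable": (99, 260), "unreliable": (315, 328)},
        "moderate": {"MF": 119, "reliable": (658, 1135), "unreliable": (259, 277)},
        "good": {"MF": 60, "reliable": (1236, 1636), "unreliable": (121, 128)},
        "total": {"MF": 275, "reliable": (1993, 3031), "unreliable": (695, 733)},
    },
}


def report_from_counts(counts: dict) -> ConfusionReport:
    """Confusion report from a reliable/unreliable count pair.

    Sensitivity and specificity are computed by the package's standard
    formulas (TP/(TP+FN) and 1 - FP/(TN+FP)).
    """
    tp, n_pos = counts["reliable"]
    tn, n_neg = counts["unreliable"]
    fn = n_pos - tp
    fp = n_neg - tn
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 1.0 - fp / (tn + fp) if (tn + fp) > 0 else None
    return ConfusionReport(
        tp=tp, fp=fp, tn=tn, fn=fn, threshold=float("nan"),
        sensitivity=sens, specificity=spec,
    )
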