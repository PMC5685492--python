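"""Segmentation evaluation: Dice, 95-percentile surface distance, volume error.

* DSC(A, B) = 2|A n B| / (|A| + |B|) on the binary masks of one label; two
  empty masks count as perfect agreement (DSC = 1) by convention.
* MHD95 is the symmetrized (max of the two directions) 95th percentile of
  Euclidean surface-to-surface distances in mm.  A surface voxel is a mask
  voxel with at least one 6-connected neighbour outside the mask (lattice
  boundaries count as outside).  Percentiles use linear interpolation between
  order statistics.
* ABVD = |V_seg - V_truth| / V_truth * 100 (percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume_io import LabelMap, TISSUE_LABELS, VolumeError, check_same_lattice


class MetricsError(ValueError):
    pass


def dsc(a: LabelMap, b: LabelMap, label: int) -> float:
    """Dice similarity coefficient for one label; both-empty masks give 1."""
    check_same_lattice(a, b)
    ma = a.values == label
    mb = b.values == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean array of mask voxels with a 6-connected non-mask neighbour."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    interior = np.ones_like(mask, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    return mask & ~interior


def _directed_p95(src_pts: np.ndarray, dst_pts: np.ndarray) -> float:
    d, _ = cKDTree(dst_pts).query(src_pts, k=1)
    return float(np.percentile(d, 95, method="linear"))


def mhd95(
    a: LabelMap,
    b: LabelMap,
    label: int,
    spacing: tuple[float, float, float] | None = None,
    symmetrize: str = "max",
) -> float:
    """Symmetric 95th-percentile surface distance (mm) for one label."""
    check_same_lattice(a, b)
    spacing = spacing or a.spacing
    ma = a.values == label
    mb = b.values == label
    if not ma.any() or not mb.any():
        raise MetricsError(f"undefined distance: empty mask for label {label}")
    sp = np.asarray(spacing, dtype=float)
    pa = np.argwhere(surface_voxels(ma)) * sp
    pb = np.argwhere(surface_voxels(mb)) * sp
    d_ab = _directed_p95(pa, pb)
    d_ba = _directed_p95(pb, pa)
    if symmetrize == "max":
        return max(d_ab, d_ba)
    if symmetrize == "mean":
        return 0.5 * (d_ab + d_ba)
    raise MetricsError(f"unknown symmetrization {symmetrize!r}")


def abvd(a: LabelMap, b_truth: LabelMap, label: int) -> float:
    """Absolute volume difference relative to the truth mask, in percent."""
    check_same_lattice(a, b_truth)
    v_truth = int((b_truth.values == label).sum())
    if v_truth == 0:
        raise MetricsError(f"empty truth mask for label {label}")
    v_a = int((a.values == label).sum())
    return abs(v_a - v_truth) / v_truth * 100.0


@dataclass
class MetricsReport:
    """Per-label metric values for one (prediction, truth) pair."""

    dsc: dict[int, float]
    mhd95_mm: dict[int, float]
    abvd_pct: dict[int, float]
    voxel_counts: dict[int, int]
    spacing: tuple[float, float, float]

    def to_dataframe(self, subject: str = "subject") -> pd.DataFrame:
        rows = [
            {
                "subject": subject,
                "label": lab,
                "dsc": self.dsc[lab],
                "mhd95_mm": self.mhd95_mm[lab],
                "abvd_pct": self.abvd_pct[lab],
            }
            for lab in sorted(self.dsc)
        ]
        return pd.DataFrame(rows)


def evaluate(pred: LabelMap, truth: LabelMap, spacing=None) -> MetricsReport:
    """All three metrics for the tissue labels 1..3."""
    check_same_lattice(pred, truth)
    spacing = spacing or truth.spacing
    return MetricsReport(
        dsc={lab: dsc(pred, truth, lab) for lab in TISSUE_LABELS},
        mhd95_mm={lab: mhd95(pred, truth, lab, spacing) for lab in TISSUE_LABELS},
        abvd_pct={lab: abvd(pred, truth, lab) for lab in TISSUE_LABELS},
        voxel_counts={lab: int((truth.values == lab).sum()) for lab in TISSUE_LABELS},
        spacing=tuple(spacing),
    )


def batch_evaluate(pairs, subjects=None) -> pd.DataFrame:
    """Evaluate a list of (pred, truth) pairs; one row per (subject, label)."""
    frames = []
    for i, (pred, truth) in enumerate(pairs):
        name = subjects[i] if subjects else f"sub-{i:02d}"
        frames.append(evaluate(pred, truth).to_dataframe(name))
    return pd.concat(frames, ignore_index=True)
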