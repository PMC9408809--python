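"""Signal-intensity threshold segmentation of LGE myocardium.

Remote/border/infarct zones are separated with the two-threshold rule used
for chronic infarct sizing: the remote zone is everything at or below
μ_remote + 2σ_remote, the infarct zone is everything at or above the
midpoint (μ_remote + μ_infarct)/2, and the border zone lies strictly
between.  μ and σ are pooled over operator-supplied ROIs across all slices
of a subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import LabelMap, Volume3D


@dataclass
class SegThresholds:
    """Region intensity statistics and the derived classification thresholds."""

    mu_remote: float
    sigma_remote: float
    mu_infarct: float
    sigma_infarct: float

    @property
    def t_low(self) -> float:
        return self.mu_remote + 2.0 * self.sigma_remote

    @property
    def t_high(self) -> float:
        return 0.5 * (self.mu_remote + self.mu_infarct)

    @property
    def degenerate(self) -> bool:
        return not self.t_low < self.t_high

    def __post_init__(self) -> None:
        if self.sigma_remote < 0 or self.sigma_infarct < 0:
            raise ValueError("standard deviations must be nonnegative")


def estimate_region_stats(
    lge: Volume3D,
    remote_rois: LabelMap,
    infarct_rois: LabelMap,
    myocardium: np.ndarray | None = None,
    ddof: int = 0,
) -> SegThresholds:
    """Pool ROI voxels across all slices and compute μ and σ per class.

    σ defaults to the population standard deviation (ddof = 0).
    """
    rm = remote_rois.labels > 0
    im = infarct_rois.labels > 0
    if rm.shape != lge.data.shape or im.shape != lge.data.shape:
        raise ValueError("ROI grids must match the LGE grid")
    if not rm.any():
        raise ValueError("remote ROI required")
    if not im.any():
        raise ValueError("infarct ROI required")
    if myocardium is not None:
        myocardium = np.asarray(myocardium, bool)
        if np.any(rm & ~myocardium) or np.any(im & ~myocardium):
            raise ValueError("ROIs must lie within the myocardium mask")
    rvals = lge.data[rm].astype(float)
    ivals = lge.data[im].astype(float)
    return SegThresholds(
        mu_remote=float(np.mean(rvals)),
        sigma_remote=float(np.std(rvals, ddof=ddof)),
        mu_infarct=float(np.mean(ivals)),
        sigma_infarct=float(np.std(ivals, ddof=ddof)),
    )


def classify_voxels(
    lge: Volume3D, thr: SegThresholds, myocardium: LabelMap | np.ndarray
) -> LabelMap:
    """Label every myocardial voxel remote (1), border (2), or infarct (3).

    Rule (boundary handling follows the displayed inequalities):
    SI ≤ t_low → remote; t_low < SI < t_high → border; SI ≥ t_high → infarct.
    Voxels outside the myocardium are 0.  The three classes partition the
    myocardium by construction.
    """
    if thr.degenerate:
        raise ValueError("degenerate thresholds: t_low >= t_high")
    if isinstance(myocardium, LabelMap):
        myo = myocardium.labels > 0
        spacing, slice_z = myocardium.spacing_mm, myocardium.slice_z_mm
    else:
        myo = np.asarray(myocardium, bool)
        spacing, slice_z = lge.spacing_mm, lge.slice_z_mm
    if myo.shape != lge.data.shape:
        raise ValueError("myocardium mask grid must match the LGE grid")
    si = lge.data
    labels = np.zeros(si.shape, dtype=np.int16)
    labels[myo] = 1
    labels[myo & (si > thr.t_low) & (si < thr.t_high)] = 2
    labels[myo & (si >= thr.t_high)] = 3
    return LabelMap(labels, spacing, slice_z, orientation=lge.orientation)
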