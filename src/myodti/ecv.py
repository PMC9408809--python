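"""Extracellular volume fraction mapping from pre/post-contrast T1.

ECV = (1 − Hct) · ΔR1_myo / ΔR1_blood with ΔR1 = 1/T1_post − 1/T1_pre.
Blood relaxation rates come from a blood-pool ROI mean (scalar pair per
subject).  Voxels with nonpositive myocardial ΔR1 are set to 0 and flagged;
values above 1 are flagged but retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Volume3D


@dataclass
class ECVInputs:
    t1_pre_myo: Volume3D
    t1_post_myo: Volume3D
    t1_pre_blood: float
    t1_post_blood: float
    hct: float

    def __post_init__(self) -> None:
        if not 0 < self.hct < 1:
            raise ValueError("hematocrit must lie strictly between 0 and 1")
        if self.t1_pre_blood <= 0 or self.t1_post_blood <= 0:
            raise ValueError("blood T1 values must be positive")
        if 1.0 / self.t1_post_blood - 1.0 / self.t1_pre_blood <= 0:
            raise ValueError("blood ΔR1 must be positive (post-contrast T1 below native)")
        if not self.t1_pre_myo.same_grid(self.t1_post_myo):
            raise ValueError("pre and post T1 maps must share a grid")


def compute_ecv(inp: ECVInputs) -> tuple[Volume3D, np.ndarray]:
    """Voxelwise ECV map and a flag mask of out-of-range voxels.

    Flagged voxels are those with nonpositive myocardial ΔR1 (ECV forced to
    0) or ECV > 1 (retained).  T1 voxels must be positive where evaluated;
    nonpositive T1 voxels are flagged and set to 0.
    """
    t1_pre = inp.t1_pre_myo.data.astype(float)
    t1_post = inp.t1_post_myo.data.astype(float)
    ok = (t1_pre > 0) & (t1_post > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_r1_myo = np.where(ok, 1.0 / t1_post - 1.0 / t1_pre, 0.0)
    d_r1_blood = 1.0 / inp.t1_post_blood - 1.0 / inp.t1_pre_blood
    ecv = (1.0 - inp.hct) * d_r1_myo / d_r1_blood
    flagged = ~ok | (d_r1_myo <= 0) | (ecv > 1)
    ecv = np.where(ok & (d_r1_myo > 0), ecv, 0.0)
    vol = inp.t1_pre_myo.with_data(ecv, intensity_units="fraction")
    return vol, flagged
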