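"""Diffusion-tensor reconstruction and scalar biomarkers.

The tensor is fit voxelwise by ordinary least squares on the log signal
(monoexponential model ``ln S = ln S0 - b gᵀDg``).  Scalar biomarkers follow
the standard definitions: mean diffusivity MD = (e1+e2+e3)/3, radial
diffusivity RD = (e2+e3)/2 (average of the secondary and tertiary
eigenvalues), and fractional anisotropy

    FA = sqrt(3/2) · ||(e1-MD, e2-MD, e3-MD)|| / ||(e1, e2, e3)||.

Negative eigenvalues produced by noisy fits are reported as-is (optionally
clipped at zero); voxels whose MD exceeds the free diffusivity of water at
body temperature (3×10⁻³ mm²/s) can be rejected as corrupted.
"""

from __future__ import annotations

import numpy as np

from .core_io import DWISeries, TensorField, TensorInvariants, design_matrix, tensor_from_components

FREE_WATER_MD = 3.0e-3  # mm²/s, free diffusion of water


def fit_tensor_loglinear(dwi: DWISeries) -> TensorField:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    Voxels with any nonpositive signal are marked invalid (their tensor is
    still reported from the remaining finite rows when possible, but the
    valid mask excludes them).

    Requires a scheme with >= 6 independent nonzero-b directions and at
    least one b = 0 volume (enforced by :class:`GradientScheme`).
    """
    scheme = dwi.scheme
    nz = scheme.bvals > 0
    if np.count_nonzero(nz) < 6:
        raise ValueError("scheme needs at least 6 nonzero-b directions")
    signals = dwi.signal_array().astype(float)  # (n_vol, Z, Y, X)
    n_vol = signals.shape[0]
    grid_shape = signals.shape[1:]

    # design: ln S = ln S0 - b * (design_matrix rows · d)  with unknowns (d, ln S0)
    X = np.column_stack(
        [-scheme.bvals[:, None] * design_matrix(scheme.bvecs), np.ones(n_vol)]
    )
    flat = signals.reshape(n_vol, -1)
    valid = np.all(flat > 0, axis=0)

    y = np.where(flat > 0, np.log(np.where(flat > 0, flat, 1.0)), 0.0)
    beta = np.linalg.pinv(X) @ y  # (7, n_voxels)
    tensors = tensor_from_components(np.moveaxis(beta[:6], 0, -1)).reshape(grid_shape + (3, 3))
    return TensorField(
        tensor=tensors,
        valid_mask=valid.reshape(grid_shape),
        spacing_mm=dwi.grid.spacing_mm,
        slice_z_mm=dwi.grid.slice_z_mm,
    )


def compute_invariants(
    tensor: np.ndarray, clip_negative: bool = False, sym_tol: float = 1e-8
) -> TensorInvariants:
    """Eigenvalues and derived invariants of symmetric tensor(s).

    Accepts a single 3×3 matrix or an array of them.  Eigenvalues are sorted
    descending; FA is defined as 0 where all eigenvalues are 0.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ValueError("expected 3x3 tensor(s)")
    scale = max(np.nanmax(np.abs(t), initial=0.0), 1.0)
    if np.nanmax(np.abs(t - np.swapaxes(t, -1, -2)), initial=0.0) > sym_tol * scale:
        raise ValueError("tensor not symmetric within tolerance")
    evals = np.linalg.eigvalsh(t)[..., ::-1]  # descending
    if clip_negative:
        evals = np.clip(evals, 0.0, None)
    e1, e2, e3 = evals[..., 0], evals[..., 1], evals[..., 2]
    md = (e1 + e2 + e3) / 3.0
    rd = (e2 + e3) / 2.0
    dev = evals - md[..., None]
    num = np.sqrt(np.sum(dev**2, axis=-1))
    den = np.sqrt(np.sum(evals**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return TensorInvariants(e1=e1, e2=e2, e3=e3, md=md, rd=rd, fa=fa)


def reject_voxels_md(
    field: TensorField,
    threshold: float = FREE_WATER_MD,
    myocardium: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Reject voxels whose MD is strictly above the free-water threshold.

    Returns the updated validity mask and the rejected fraction, computed
    over myocardial voxels when a myocardium mask is given (otherwise over
    all initially valid voxels).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    inv = compute_invariants(field.tensor)
    # strict "above": a relative guard keeps MD == threshold despite
    # eigensolver rounding
    high = inv.md > threshold * (1.0 + 1e-9)
    mask = field.valid_mask & ~high
    domain = field.valid_mask if myocardium is None else (np.asarray(myocardium, bool) & field.valid_mask)
    n = int(np.count_nonzero(domain))
    rejected = int(np.count_nonzero(high & domain))
    frac = rejected / n if n else 0.0
    return mask, frac
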