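"""Domain containers and file I/O for the cardiac DTI pipeline.

Volumes are stored as ``(slice, row, col)`` arrays with explicit voxel
spacing, per-slice longitudinal (z) positions in mm, and an orientation
quaternion.  NIfTI-1 is the on-disk format for every volume and label map;
diffusion gradient tables use the FSL bval/bvec text dialect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

LABEL_BACKGROUND = 0
LABEL_REMOTE = 1
LABEL_BORDER = 2
LABEL_INFARCT = 3
LABEL_CODING = {
    LABEL_BACKGROUND: "background",
    LABEL_REMOTE: "remote",
    LABEL_BORDER: "border",
    LABEL_INFARCT: "infarct",
}
REGION_NAMES = {1: "remote", 2: "border", 3: "infarct"}

_QUAT_TOL = 1e-9


def _as_unit_quaternion(q: Sequence[float]) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("orientation quaternion must have 4 components")
    n = np.linalg.norm(q)
    if n == 0 or not np.isfinite(n):
        raise ValueError("orientation quaternion has zero or non-finite norm")
    if abs(n - 1.0) > 1e-6:
        q = q / n
    return q


def quaternion_to_matrix(q: Sequence[float]) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = _as_unit_quaternion(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quaternion(m: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a proper rotation matrix."""
    m = np.asarray(m, dtype=float)
    t = np.trace(m)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(m)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(m[i, i] - m[j, j] - m[k, k] + 1.0, 0.0)) * 2
        q = np.empty(4)
        q[0] = (m[k, j] - m[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (m[j, i] + m[i, j]) / s
        q[1 + k] = (m[k, i] + m[i, k]) / s
    if q[0] < 0:
        q = -q
    return _as_unit_quaternion(q)


def quaternion_multiply(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quaternion_conjugate(q: Sequence[float]) -> np.ndarray:
    w, x, y, z = q
    return np.array([w, -x, -y, -z])


@dataclass
class Volume3D:
    """Scalar image stack indexed ``(slice, row, col)``.

    Parameters
    ----------
    data : ndarray
        Voxel intensities, shape ``(n_slices, n_rows, n_cols)``.
    spacing_mm : tuple of float
        ``(dz, dy, dx)`` voxel spacing in mm.
    slice_z_mm : sequence of float
        Longitudinal position of each slice, strictly monotonic.
    orientation : sequence of float
        Unit quaternion ``(w, x, y, z)`` of the slice stack.
    intensity_units : str
        Free-text unit annotation (e.g. ``"ms"`` for T1 maps).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    slice_z_mm: np.ndarray = None  # type: ignore[assignment]
    orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    intensity_units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("expected 3D volume")
        dz, dy, dx = self.spacing_mm
        if not (dz > 0 and dy > 0 and dx > 0) or not np.all(np.isfinite([dz, dy, dx])):
            raise ValueError("spacing components must be positive and finite")
        self.spacing_mm = (float(dz), float(dy), float(dx))
        if self.slice_z_mm is None:
            self.slice_z_mm = np.arange(self.data.shape[0]) * dz
        self.slice_z_mm = np.asarray(self.slice_z_mm, dtype=float)
        if self.slice_z_mm.shape != (self.data.shape[0],):
            raise ValueError("slice_z_mm length must match the number of slices")
        d = np.diff(self.slice_z_mm)
        if self.data.shape[0] > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("slice_z_mm must be strictly monotonic")
        self.orientation = _as_unit_quaternion(self.orientation)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_grid(self, other: "Volume3D", tol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.slice_z_mm, other.slice_z_mm, atol=tol)
        )

    def with_data(self, data: np.ndarray, intensity_units: str | None = None) -> "Volume3D":
        return dataclasses.replace(
            self,
            data=np.asarray(data),
            intensity_units=intensity_units or self.intensity_units,
        )


@dataclass
class GradientScheme:
    """Diffusion gradient table: b-values (s/mm²) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvecs must have shape (n, 3) matching bvals")
        nz = self.bvals > 0
        if not np.any(self.bvals == 0):
            raise ValueError("scheme requires at least one b = 0 entry")
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("nonzero-b directions must be unit vectors")
        # rank requirements only apply once the scheme could support a tensor
        # fit; short tables (e.g. a single b0/b350 pair) are still valid I/O
        if np.count_nonzero(nz) >= 6:
            if np.linalg.matrix_rank(self.bvecs[nz]) < 3:
                raise ValueError("nonzero-b directions must span rank 3")
            if np.linalg.matrix_rank(design_matrix(self.bvecs[nz])) < 6:
                raise ValueError("outer-product design matrix must have rank 6")

    @property
    def supports_tensor_fit(self) -> bool:
        nz = self.bvals > 0
        return (
            np.count_nonzero(nz) >= 6
            and np.linalg.matrix_rank(design_matrix(self.bvecs[nz])) == 6
        )

    @property
    def n(self) -> int:
        return len(self.bvals)

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals == 0)


def design_matrix(directions: np.ndarray) -> np.ndarray:
    """Quadratic-form design rows ``[gx², gy², gz², 2gxgy, 2gxgz, 2gygz]``."""
    g = np.atleast_2d(np.asarray(directions, dtype=float))
    return np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def tensor_from_components(c: np.ndarray) -> np.ndarray:
    """Symmetric 3×3 tensor(s) from component vector(s) ordered as design_matrix."""
    c = np.asarray(c)
    out = np.empty(c.shape[:-1] + (3, 3), dtype=c.dtype)
    out[..., 0, 0] = c[..., 0]
    out[..., 1, 1] = c[..., 1]
    out[..., 2, 2] = c[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
    return out


@dataclass
class DWISeries:
    """Stack of diffusion-weighted volumes plus their gradient scheme."""

    volumes: list[Volume3D]
    scheme: GradientScheme

    def __post_init__(self) -> None:
        if len(self.volumes) != self.scheme.n:
            raise ValueError("number of volumes must equal the number of scheme entries")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not v.same_grid(ref):
                raise ValueError("all DWI volumes must share grid and spacing")

    @property
    def s0_index(self) -> np.ndarray:
        return self.scheme.b0_indices

    def signal_array(self) -> np.ndarray:
        """Signals stacked as ``(n_volumes, slices, rows, cols)``."""
        return np.stack([v.data for v in self.volumes])

    @property
    def grid(self) -> Volume3D:
        return self.volumes[0]


@dataclass
class LabelMap:
    """Integer region map: 0 background, 1 remote, 2 border, 3 infarct."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    slice_z_mm: np.ndarray = None  # type: ignore[assignment]
    orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    coding: dict = field(default_factory=lambda: dict(LABEL_CODING))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("labels must be integer-valued")
            self.labels = self.labels.astype(np.int16)
        bad = set(np.unique(self.labels)) - set(self.coding)
        if bad:
            raise ValueError(f"labels contain values outside the coding: {sorted(bad)}")
        vol = Volume3D(self.labels, self.spacing_mm, self.slice_z_mm, self.orientation)
        self.slice_z_mm = vol.slice_z_mm
        self.orientation = vol.orientation
        self.spacing_mm = vol.spacing_mm

    def as_volume(self) -> Volume3D:
        return Volume3D(
            self.labels, self.spacing_mm, self.slice_z_mm, self.orientation, "label"
        )

    def myocardium_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == code)) for code, name in REGION_NAMES.items()}


@dataclass
class TensorField:
    """Per-voxel symmetric 3×3 diffusion tensor in mm²/s."""

    tensor: np.ndarray  # (..., 3, 3)
    valid_mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_z_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape[-2:] != (3, 3):
            raise ValueError("tensor field must end in 3x3 matrices")
        asym = np.abs(self.tensor - np.swapaxes(self.tensor, -1, -2))
        if np.nanmax(asym, initial=0.0) > 1e-12:
            raise ValueError("tensors must be symmetric to 1e-12")
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.tensor.shape[:-2]:
            raise ValueError("valid_mask shape must match the voxel grid")


@dataclass
class TensorInvariants:
    """Eigenvalue-derived scalar maps (per voxel or scalar)."""

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    md: np.ndarray
    rd: np.ndarray
    fa: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"e1": self.e1, "e2": self.e2, "e3": self.e3,
                "MD": self.md, "RD": self.rd, "FA": self.fa}


# ---------------------------------------------------------------------------
# NIfTI readers / writers
# ---------------------------------------------------------------------------

def _affine_from_volume(vol: Volume3D) -> np.ndarray:
    # data axis order (slice, row, col) maps to world via (x<-col, y<-row, z<-slice)
    dz, dy, dx = vol.spacing_mm
    rot = quaternion_to_matrix(vol.orientation)
    affine = np.eye(4)
    affine[:3, :3] = rot @ np.diag([dx, dy, dz])
    z0 = float(vol.slice_z_mm[0])
    affine[:3, 3] = rot @ np.array([0.0, 0.0, z0])
    return affine


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a :class:`Volume3D` as a NIfTI-1 file.

    Integer arrays are written with an integer datatype so labels round-trip
    without value change.
    """
    if vol.data.size == 0:
        raise ValueError("refusing to write an empty volume")
    d = np.diff(vol.slice_z_mm)
    if len(d) and not np.allclose(d, d[0], atol=1e-9):
        raise ValueError("NIfTI export requires uniform slice spacing")
    # NIfTI is (x=col, y=row, z=slice) fastest-first
    arr = np.transpose(vol.data, (2, 1, 0))
    img = nib.Nifti1Image(arr, _affine_from_volume(vol))
    img.header.set_zooms((vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0]))
    if np.issubdtype(vol.data.dtype, np.integer):
        img.set_data_dtype(np.int16)
    else:
        img.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_volume(path: str | Path, intensity_units: str = "a.u.") -> Volume3D:
    """Read a 3D NIfTI-1 file into a :class:`Volume3D`.

    Slices are reordered so that ``slice_z_mm`` ascends.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError("expected 3D volume")
    affine = img.affine
    zooms = img.header.get_zooms()[:3]
    if not np.all(np.isfinite(zooms)) or np.any(np.asarray(zooms) <= 0):
        raise ValueError("non-finite or nonpositive voxel spacing in header")
    arr = np.asanyarray(img.dataobj)
    data = np.transpose(arr, (2, 1, 0))  # (slice, row, col)
    n_slices = data.shape[0]
    # world position of each slice origin along the slice axis
    k = np.arange(n_slices)
    slice_dir = affine[:3, 2]
    step = float(np.linalg.norm(slice_dir))
    origin = affine[:3, 3]
    rot = affine[:3, :3] / np.array(zooms)[None, :]
    # guard against reflections: quaternion needs a proper rotation
    if np.linalg.det(rot) < 0:
        rot = rot @ np.diag([1.0, 1.0, -1.0])
    quat = matrix_to_quaternion(rot)
    z_local = (rot.T @ origin)[2] + k * step
    if n_slices > 1 and z_local[1] < z_local[0]:
        data = data[::-1]
        z_local = z_local[::-1]
    return Volume3D(
        data=data,
        spacing_mm=(step if step > 0 else zooms[2], zooms[1], zooms[0]),
        slice_z_mm=z_local,
        orientation=quat,
        intensity_units=intensity_units,
    )


def write_label_map(labels: LabelMap, path: str | Path) -> None:
    write_volume(labels.as_volume(), path)


def read_label_map(path: str | Path) -> LabelMap:
    vol = read_volume(path, intensity_units="label")
    return LabelMap(
        labels=np.rint(vol.data).astype(np.int16),
        spacing_mm=vol.spacing_mm,
        slice_z_mm=vol.slice_z_mm,
        orientation=vol.orientation,
    )


def read_gradient_table(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read an FSL-dialect bval/bvec pair.

    The bvec file normally holds 3 rows (x, y, z); a transposed n×3 layout is
    auto-detected by shape.  Directions are renormalized to unit length; zero
    vectors are allowed only at b = 0.
    """
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[0] == 3 and bvecs.shape[1] == 3:
        # ambiguous 3x3: FSL convention is rows = components
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise ValueError(
            f"bval/bvec length mismatch: {len(bvals)} b-values, {bvecs.shape[0]} directions"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    out = np.zeros_like(bvecs)
    nz = norms > 0
    out[nz] = bvecs[nz] / norms[nz, None]
    if np.any((bvals > 0) & ~nz):
        raise ValueError("nonzero b-value with zero gradient direction")
    return GradientScheme(bvals=bvals, bvecs=out)


def write_gradient_table(
    scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.10g")


def write_dwi(dwi: DWISeries, nifti_path: str | Path,
              bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write a DWI series as a 4D NIfTI plus bval/bvec text files."""
    ref = dwi.grid
    arr = np.stack([np.transpose(v.data, (2, 1, 0)) for v in dwi.volumes], axis=-1)
    img = nib.Nifti1Image(arr.astype(np.float64), _affine_from_volume(ref))
    nib.save(img, str(nifti_path))
    write_gradient_table(dwi.scheme, bval_path, bvec_path)


def read_dwi(nifti_path: str | Path, bval_path: str | Path,
             bvec_path: str | Path) -> DWISeries:
    img = nib.load(str(nifti_path))
    if img.ndim != 4:
        raise ValueError("expected 4D DWI series")
    scheme = read_gradient_table(bval_path, bvec_path)
    arr = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    rot = img.affine[:3, :3] / np.array(zooms)[None, :]
    if np.linalg.det(rot) < 0:
        rot = rot @ np.diag([1.0, 1.0, -1.0])
    quat = matrix_to_quaternion(rot)
    n_slices = arr.shape[2]
    z0 = (rot.T @ img.affine[:3, 3])[2]
    z = z0 + np.arange(n_slices) * zooms[2]
    vols = [
        Volume3D(
            np.transpose(arr[..., i], (2, 1, 0)),
            spacing_mm=(zooms[2], zooms[1], zooms[0]),
            slice_z_mm=z,
            orientation=quat,
        )
        for i in range(arr.shape[3])
    ]
    return DWISeries(volumes=vols, scheme=scheme)


def default_12_directions() -> np.ndarray:
    """Icosahedron-vertex direction set (12 unit vectors, rank-6 design)."""
    phi = (1 + np.sqrt(5)) / 2
    raw = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            raw.append((0.0, s1 * 1.0, s2 * phi))
            raw.append((s1 * 1.0, s2 * phi, 0.0))
            raw.append((s2 * phi, 0.0, s1 * 1.0))
    g = np.array(raw)
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    assert np.linalg.matrix_rank(design_matrix(g)) == 6
    return g


def default_scheme(b: float = 350.0) -> GradientScheme:
    """One b = 0 volume plus 12 icosahedral directions at the given b-value."""
    g = default_12_directions()
    bvals = np.concatenate([[0.0], np.full(len(g), b)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], g])
    return GradientScheme(bvals=bvals, bvecs=bvecs)
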