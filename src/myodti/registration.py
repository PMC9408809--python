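"""Registration of diastolic LGE-based label maps onto systolic cDTI slices.

The chain has five stages:

1. rigid alignment from the orientation quaternions of the two acquisitions
   (rotation = q_fixed · q_moving⁻¹) plus a foreground-centroid translation,
   with label resampling onto the cDTI in-plane grid;
2. uniform longitudinal rescaling of the label-map slice positions so the
   most basal and apical LGE slices land on the corresponding cDTI slices
   (systolic longitudinal shortening);
3. Canny edge detection of the endocardial and epicardial borders on each
   cDTI slice, and distance-weighted averaging of the two neighboring cDTI
   myocardium masks at every LGE slice position;
4. in-plane non-rigid (symmetric-demons) registration of each label slice's
   myocardial support onto the averaged cDTI mask, warping the labels with
   nearest-neighbor sampling;
5. 3D interpolation of the warped label stack back to the original cDTI
   slice positions (one-hot linear in z, arg-max with a severity tie-break).

All stages map the label alphabet {0,1,2,3} into itself and the final map
partitions the detected cDTI myocardium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import feature, filters, measure

from .core_io import (
    DWISeries,
    LabelMap,
    Volume3D,
    quaternion_conjugate,
    quaternion_multiply,
    quaternion_to_matrix,
)

SEVERITY_ORDER = (3, 2, 1, 0)  # infarct wins ties


@dataclass
class RegistrationConfig:
    demons_iterations: int = 200
    demons_smoothing: float = 1.0
    dice_floor: float = 0.80
    canny_sigma: float = 1.5
    canny_low_factor: float = 0.5
    canny_high_factor: float = 1.0
    working_spacing_mm: float = 1.0  # in-plane grid for stages (a)-(d)
    quaternion_source: str = "metadata"  # or "image" (mask principal axes)
    mask_moment_refinement: bool = False
    skip_longitudinal_rescale: bool = False  # ablation switch


@dataclass
class RigidTransform:
    """Rigid map p_fixed = R(q)·p_moving + t, in mm."""

    rotation: np.ndarray  # unit quaternion (w, x, y, z)
    translation: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        n = np.linalg.norm(self.rotation)
        if n == 0 or not np.isfinite(n):
            raise ValueError("rotation quaternion has zero or non-finite norm")
        self.rotation = self.rotation / n
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        R = quaternion_to_matrix(self.rotation)
        return np.asarray(points, float) @ R.T + self.translation

    def inverse(self) -> "RigidTransform":
        R = quaternion_to_matrix(self.rotation)
        return RigidTransform(
            rotation=quaternion_conjugate(self.rotation),
            translation=-(R.T @ self.translation),
        )


@dataclass
class SliceContours:
    """Closed endo/epi contours of one short-axis slice, in mm."""

    endo: np.ndarray  # (n, 2) closed polygon, (y, x) mm
    epi: np.ndarray
    endo_mask: np.ndarray = None  # filled endocardial disk (incl. cavity)
    epi_mask: np.ndarray = None  # filled epicardial disk
    myocardium_mask: np.ndarray = None

    def __post_init__(self) -> None:
        for name in ("endo", "epi"):
            c = np.asarray(getattr(self, name), float)
            if len(c) < 4 or not np.allclose(c[0], c[-1]):
                raise ValueError(f"{name} contour must be a closed polygon")
            setattr(self, name, c)
        if _polygon_area(self.epi) <= _polygon_area(self.endo):
            raise ValueError("epicardial contour must enclose the endocardial contour")

    def mean_radii_mm(self) -> tuple[float, float]:
        def mean_r(c: np.ndarray) -> float:
            ctr = c[:-1].mean(axis=0)
            return float(np.mean(np.linalg.norm(c[:-1] - ctr, axis=1)))

        return mean_r(self.endo), mean_r(self.epi)


@dataclass
class DeformationField2D:
    """Per-pixel in-plane displacement vectors in mm, (rows, cols, 2=(dy,dx))."""

    field: np.ndarray

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if self.field.ndim != 3 or self.field.shape[-1] != 2:
            raise ValueError("deformation field must have shape (rows, cols, 2)")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("deformation field must be finite")

    @property
    def max_displacement_mm(self) -> float:
        return float(np.max(np.linalg.norm(self.field, axis=-1), initial=0.0))


def _polygon_area(c: np.ndarray) -> float:
    y, x = c[:, 0], c[:, 1]
    return 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))


def _inplane_world(shape: tuple[int, int], spacing_yx: tuple[float, float]):
    ny, nx = shape
    dy, dx = spacing_yx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    return y, x


def _foreground_centroid_mm(vol: Volume3D, mask: np.ndarray | None = None) -> np.ndarray:
    """Foreground centroid in the volume's local world frame (x, y, z).

    Without an explicit mask the foreground is the hole-filled Otsu mask,
    so bright-core anatomy (blood pool, enhancing scar) does not bias the
    centroid away from the organ center.
    """
    data = np.asarray(vol.data, float)
    if mask is None:
        thr = filters.threshold_otsu(data) if data.max() > data.min() else data.min()
        mask = data > thr
        mask = np.stack([ndimage.binary_fill_holes(m) for m in mask])
    else:
        mask = np.asarray(mask, bool)
    if not mask.any():
        mask = np.ones_like(data, bool)
    k, i, j = np.nonzero(mask)
    y, x = _inplane_world(data.shape[1:], vol.spacing_mm[1:])
    return np.array([x[j].mean(), y[i].mean(), vol.slice_z_mm[k].mean()])


def _principal_axis_quaternion(vol: Volume3D) -> np.ndarray:
    """In-plane rotation quaternion from foreground second moments."""
    data = np.asarray(vol.data, float)
    thr = filters.threshold_otsu(data) if data.max() > data.min() else data.min()
    mask = (data > thr).any(axis=0)
    if not mask.any():
        return np.array([1.0, 0.0, 0.0, 0.0])
    i, j = np.nonzero(mask)
    y, x = _inplane_world(mask.shape, vol.spacing_mm[1:])
    pts = np.column_stack([x[j], y[i]])
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    angle = math.atan2(v[1], v[0])
    return np.array([math.cos(angle / 2), 0.0, 0.0, math.sin(angle / 2)])


def rigid_align(
    moving: Volume3D,
    fixed: Volume3D,
    config: RegistrationConfig | None = None,
    moving_mask: np.ndarray | None = None,
    fixed_mask: np.ndarray | None = None,
) -> RigidTransform:
    """Rigid transform taking moving-space points into fixed image space.

    Rotation is composed from the two orientation quaternions
    (q_fixed · q_moving⁻¹ by default, or from mask principal axes when the
    config selects the image-based reading); translation aligns the
    foreground centroids (explicit masks take precedence over the
    hole-filled Otsu foreground).
    """
    config = config or RegistrationConfig()
    for v in (moving, fixed):
        if v.orientation is None or np.linalg.norm(v.orientation) == 0:
            raise ValueError("missing orientation metadata")
    if config.quaternion_source == "image":
        q = quaternion_multiply(
            _principal_axis_quaternion(fixed),
            quaternion_conjugate(_principal_axis_quaternion(moving)),
        )
    else:
        q = quaternion_multiply(fixed.orientation, quaternion_conjugate(moving.orientation))
    R = quaternion_to_matrix(q)
    c_m = _foreground_centroid_mm(moving, moving_mask)
    c_f = _foreground_centroid_mm(fixed, fixed_mask)
    return RigidTransform(rotation=q, translation=c_f - R @ c_m)


def resample_labels_inplane(
    labels: LabelMap,
    transform: RigidTransform,
    fixed_shape_inplane: tuple[int, int],
    fixed_spacing_yx: tuple[float, float],
) -> LabelMap:
    """Nearest-neighbor resample of a label stack onto the fixed in-plane grid.

    Slice z positions are carried through the transform; the rotation must
    be (near) in-plane for the slice geometry to stay well defined.
    """
    R = quaternion_to_matrix(transform.rotation)
    if abs(R[2, 2]) < 0.999:
        raise ValueError("rigid rotation is not in-plane; slice resampling undefined")
    inv = transform.inverse()
    ny, nx = fixed_shape_inplane
    yf, xf = _inplane_world(fixed_shape_inplane, fixed_spacing_yx)
    xx, yy = np.meshgrid(xf, yf)  # (ny, nx)
    ym, xm = _inplane_world(labels.labels.shape[1:], labels.spacing_mm[1:])
    out = np.zeros((labels.labels.shape[0], ny, nx), dtype=labels.labels.dtype)
    new_z = np.empty(labels.labels.shape[0])
    for k, z in enumerate(labels.slice_z_mm):
        z_f = transform.apply(np.array([[0.0, 0.0, float(z)]]))[0, 2]
        new_z[k] = z_f
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z_f)])
        src = inv.apply(pts)
        ci = (src[:, 1] - ym[0]) / labels.spacing_mm[1]
        cj = (src[:, 0] - xm[0]) / labels.spacing_mm[2]
        out[k] = ndimage.map_coordinates(
            labels.labels[k], np.vstack([ci, cj]), order=0, mode="constant", cval=0
        ).reshape(ny, nx)
    return LabelMap(out, (labels.spacing_mm[0], *fixed_spacing_yx), new_z)


def longitudinal_rescale(
    label_slice_z: np.ndarray, cdti_basal_z: float, cdti_apical_z: float
) -> np.ndarray:
    """Affine z map sending the LGE basal/apical slices onto the cDTI span."""
    z = np.asarray(label_slice_z, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 slices to rescale")
    if cdti_apical_z == cdti_basal_z:
        raise ValueError("cDTI span is degenerate")
    scale = (cdti_apical_z - cdti_basal_z) / (z[-1] - z[0])
    return cdti_basal_z + (z - z[0]) * scale


def detect_myocardial_edges(
    cdti_slice: np.ndarray,
    spacing_yx: tuple[float, float],
    config: RegistrationConfig | None = None,
) -> SliceContours:
    """Canny edges grouped into closed endo/epi contours of the annulus.

    Hysteresis thresholds derive from the Otsu level of the smoothed
    gradient magnitude (low = 0.5×, high = 1.0× by default); if fewer than
    two closed contours emerge, a single retry halves both thresholds.
    """
    config = config or RegistrationConfig()
    img = np.asarray(cdti_slice, float)
    if img.max() == img.min():
        raise ValueError("no myocardial contours: blank slice")
    smooth = ndimage.gaussian_filter(img, config.canny_sigma)
    grad = filters.sobel(smooth)
    level = filters.threshold_otsu(grad)

    def closed_components(scale: float):
        edges = feature.canny(
            img,
            sigma=config.canny_sigma,
            low_threshold=config.canny_low_factor * level * scale,
            high_threshold=config.canny_high_factor * level * scale,
        )
        lbl = measure.label(edges, connectivity=2)
        comps = []
        for idx in range(1, lbl.max() + 1):
            comp = lbl == idx
            filled = ndimage.binary_fill_holes(comp)
            interior = int(filled.sum()) - int(comp.sum())
            if interior > 4:  # encloses area: a closed loop
                comps.append((interior, comp, filled))
        comps.sort(key=lambda t: t[0], reverse=True)
        return comps

    comps = closed_components(1.0)
    if len(comps) < 2:
        comps = closed_components(0.5)
    if len(comps) < 2:
        raise ValueError("no myocardial contours: fewer than two closed contours found")
    (_, epi_edge, epi_fill), (_, endo_edge, endo_fill) = comps[0], comps[1]
    if not (epi_fill & endo_fill).sum() >= 0.9 * endo_fill.sum():
        raise ValueError("no myocardial contours: detected contours are not nested")

    def subpixel_contour(edge_ring: np.ndarray, fallback_fill: np.ndarray) -> np.ndarray:
        """Iso-contour of the smoothed image through the Canny ring (pixel rc).

        Canny localizes the edge at the gradient maximum, where the smoothed
        intensity crosses the midpoint level; tracing that level recovers the
        boundary with subpixel accuracy instead of the ±1-pixel bias of the
        rasterized ring.
        """
        ring_level = float(np.mean(smooth[edge_ring]))
        polys = [p for p in measure.find_contours(smooth, ring_level)
                 if len(p) >= 4 and np.allclose(p[0], p[-1])]
        ring_pts = np.argwhere(edge_ring)
        best, best_d = None, np.inf
        for p in polys:
            # mean distance from ring pixels to the polygon vertices
            d = np.mean(
                np.min(np.linalg.norm(ring_pts[:, None, :] - p[None, :, :], axis=-1), axis=1)
            )
            if d < best_d:
                best, best_d = p, d
        if best is None or best_d > 2.0:
            best = max(measure.find_contours(fallback_fill.astype(float), 0.5), key=len)
            best = best - 0.0  # rasterized fallback, half-pixel accuracy
        return best

    epi_rc = subpixel_contour(epi_edge, epi_fill)
    endo_rc = subpixel_contour(endo_edge, endo_fill)
    from skimage.draw import polygon2mask

    epi_mask = polygon2mask(img.shape, epi_rc)
    endo_mask = polygon2mask(img.shape, endo_rc)
    myo = epi_mask & ~endo_mask

    y, x = _inplane_world(img.shape, spacing_yx)

    def to_mm(contour_rc: np.ndarray) -> np.ndarray:
        c = np.column_stack(
            [y[0] + contour_rc[:, 0] * spacing_yx[0], x[0] + contour_rc[:, 1] * spacing_yx[1]]
        )
        if not np.allclose(c[0], c[-1]):
            c = np.vstack([c, c[0]])
        return c

    return SliceContours(
        endo=to_mm(endo_rc), epi=to_mm(epi_rc),
        endo_mask=endo_mask, epi_mask=epi_mask, myocardium_mask=myo,
    )


def rasterize_myocardium(
    contours: SliceContours, shape: tuple[int, int], spacing_yx: tuple[float, float]
) -> np.ndarray:
    """Myocardium mask from mm contours on an arbitrary centered grid."""
    from skimage.draw import polygon2mask

    y, x = _inplane_world(shape, spacing_yx)

    def to_rc(poly_mm: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [(poly_mm[:, 0] - y[0]) / spacing_yx[0], (poly_mm[:, 1] - x[0]) / spacing_yx[1]]
        )

    return polygon2mask(shape, to_rc(contours.epi)) & ~polygon2mask(shape, to_rc(contours.endo))


def weighted_average_masks(
    mask_above: np.ndarray,
    mask_below: np.ndarray,
    z_above: float,
    z_below: float,
    z_target: float,
) -> np.ndarray:
    """Distance-weighted average of two binary slices.

    The masks are averaged through their signed distance maps (negative
    inside) so that intermediate weights interpolate the *shape* rather
    than collapsing to a union/intersection vote; the result is the
    half-level set of the averaged indicator.  Weights are the z distances
    to the neighboring slices and sum to 1; at a weight of 1 the
    corresponding mask is returned exactly.
    """
    if not (z_below <= z_target <= z_above):
        raise ValueError("z_target outside [z_below, z_above]")
    mask_above = np.asarray(mask_above, bool)
    mask_below = np.asarray(mask_below, bool)
    if z_above == z_below:
        return mask_below.copy()
    w_below = (z_above - z_target) / (z_above - z_below)
    if w_below == 1.0:
        return mask_below.copy()
    if w_below == 0.0:
        return mask_above.copy()

    def signed_distance(mask: np.ndarray) -> np.ndarray:
        return ndimage.distance_transform_edt(~mask) - ndimage.distance_transform_edt(mask)

    avg = w_below * signed_distance(mask_below) + (1.0 - w_below) * signed_distance(mask_above)
    return avg <= 0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(a & b) / denom)


def dice_per_class(a: np.ndarray, b: np.ndarray, classes=(1, 2, 3)) -> dict[int, float]:
    return {c: dice(np.asarray(a) == c, np.asarray(b) == c) for c in classes}


def nonrigid_register(
    moving_labels: np.ndarray,
    fixed_mask: np.ndarray,
    spacing_yx: tuple[float, float],
    config: RegistrationConfig | None = None,
) -> tuple[DeformationField2D, np.ndarray, float]:
    """Symmetric-demons registration of the label support onto a binary mask.

    Returns the in-plane deformation field (mm), the warped labels
    (nearest-neighbor sampled, alphabet preserved) and the Dice of the
    warped support against the fixed mask.  A warning is logged through the
    returned Dice falling below ``config.dice_floor``.
    """
    config = config or RegistrationConfig()
    moving_labels = np.asarray(moving_labels)
    moving_mask = moving_labels > 0
    fixed = np.asarray(fixed_mask, bool)
    if not moving_mask.any() or not fixed.any():
        raise ValueError("empty mask in non-rigid registration")
    sp = (float(spacing_yx[1]), float(spacing_yx[0]))  # sitk order (x, y)

    def to_img(arr: np.ndarray) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.astype(np.float64)))
        img.SetSpacing(sp)
        return img

    f_img = sitk.SmoothingRecursiveGaussian(to_img(fixed * 100.0), 1.0)
    m_img = sitk.SmoothingRecursiveGaussian(to_img(moving_mask * 100.0), 1.0)
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(config.demons_iterations)
    demons.SetStandardDeviations(config.demons_smoothing)
    disp = demons.Execute(f_img, m_img)
    tx = sitk.DisplacementFieldTransform(sitk.Image(disp))

    lab_img = sitk.GetImageFromArray(np.ascontiguousarray(moving_labels.astype(np.float64)))
    lab_img.SetSpacing(sp)
    warped_img = sitk.Resample(
        lab_img, lab_img, tx, sitk.sitkNearestNeighbor, 0.0, sitk.sitkFloat64
    )
    warped = np.rint(sitk.GetArrayFromImage(warped_img)).astype(moving_labels.dtype)
    field_xy = sitk.GetArrayFromImage(disp)  # (rows, cols, 2) in (x, y) mm
    field = np.stack([field_xy[..., 1], field_xy[..., 0]], axis=-1)
    d = dice(warped > 0, fixed)
    return DeformationField2D(field), warped, d


def interpolate_labels_to_slices(
    warped: LabelMap, target_z: np.ndarray
) -> LabelMap:
    """One-hot linear interpolation in z with severity-biased arg-max.

    Target positions outside the stack's span extrapolate by the nearest
    slice.  Ties go to the more severe label (infarct > border > remote >
    background).
    """
    labels = warped.labels
    if labels.shape[0] == 0:
        raise ValueError("empty label stack")
    z = np.asarray(warped.slice_z_mm, float)
    tz = np.atleast_1d(np.asarray(target_z, float))
    onehot = np.stack([(labels == c) for c in range(4)]).astype(float)  # (4, K, H, W)
    out = np.zeros((len(tz),) + labels.shape[1:], dtype=labels.dtype)
    for n, zt in enumerate(tz):
        if zt <= z[0]:
            scores = onehot[:, 0]
        elif zt >= z[-1]:
            scores = onehot[:, -1]
        else:
            k = int(np.searchsorted(z, zt, side="right") - 1)
            k = min(k, len(z) - 2)
            w_hi = (zt - z[k]) / (z[k + 1] - z[k])
            scores = (1 - w_hi) * onehot[:, k] + w_hi * onehot[:, k + 1]
        # arg-max with severity tie-break: scan severity order, keep first max
        best = np.full(labels.shape[1:], 0, dtype=labels.dtype)
        best_score = np.full(labels.shape[1:], -1.0)
        for c in SEVERITY_ORDER:
            m = scores[c] > best_score
            best[m] = c
            best_score[m] = scores[c][m]
        out[n] = best
    return LabelMap(out, warped.spacing_mm, tz, orientation=warped.orientation)


def register_labels(
    labels_diastole: LabelMap,
    lge: Volume3D,
    dwi: DWISeries,
    config: RegistrationConfig | None = None,
) -> tuple[LabelMap, dict]:
    """Full registration chain: LGE-based labels → cDTI grid.

    Returns the label map on the cDTI grid (partitioning the detected cDTI
    myocardium) and a diagnostics dict with per-stage information.
    """
    config = config or RegistrationConfig()
    diagnostics: dict = {}

    b0 = dwi.volumes[int(dwi.s0_index[0])]
    z_cdti = np.asarray(b0.slice_z_mm, float)

    # in-plane working grid covering the cDTI field of view (finer than the
    # cDTI voxels so label boundaries survive the warp with subvoxel accuracy)
    w = float(config.working_spacing_mm)
    ny_c, nx_c = b0.data.shape[1:]
    work_shape = (
        int(math.ceil(ny_c * b0.spacing_mm[1] / w)),
        int(math.ceil(nx_c * b0.spacing_mm[2] / w)),
    )

    # (a) rigid: into the cDTI image space; the label support centers the
    # moving volume (immune to enhancement-driven intensity asymmetry)
    rigid = rigid_align(lge, b0, config, moving_mask=labels_diastole.myocardium_mask())
    diagnostics["rigid_rotation"] = rigid.rotation.tolist()
    diagnostics["rigid_translation_mm"] = rigid.translation.tolist()
    moved = resample_labels_inplane(labels_diastole, rigid, work_shape, (w, w))

    # (b) longitudinal shortening
    if config.skip_longitudinal_rescale:
        z_rescaled = np.asarray(moved.slice_z_mm, float)
    else:
        z_rescaled = longitudinal_rescale(moved.slice_z_mm, z_cdti[0], z_cdti[-1])
    diagnostics["label_slice_z_mm"] = z_rescaled.tolist()

    # (c) cDTI myocardium contours per slice (Canny), then weighted averages
    cdti_contours = [
        detect_myocardial_edges(b0.data[k], b0.spacing_mm[1:], config)
        for k in range(b0.data.shape[0])
    ]
    cdti_masks_native = np.asarray([c.myocardium_mask for c in cdti_contours])
    cdti_masks = np.asarray(
        [rasterize_myocardium(c, work_shape, (w, w)) for c in cdti_contours]
    )

    fixed_masks = []
    for zt in z_rescaled:
        if zt <= z_cdti[0]:
            fixed_masks.append(cdti_masks[0])
        elif zt >= z_cdti[-1]:
            fixed_masks.append(cdti_masks[-1])
        else:
            k = int(np.searchsorted(z_cdti, zt, side="right") - 1)
            k = min(k, len(z_cdti) - 2)
            fixed_masks.append(
                weighted_average_masks(
                    cdti_masks[k + 1], cdti_masks[k], z_cdti[k + 1], z_cdti[k], zt
                )
            )

    # (d) per-slice demons on the myocardial support
    warped_stack = np.zeros_like(moved.labels)
    slice_dice = []
    for k in range(moved.labels.shape[0]):
        _, warped, d = nonrigid_register(
            moved.labels[k], fixed_masks[k], (w, w), config
        )
        warped_stack[k] = warped
        slice_dice.append(d)
    diagnostics["demons_support_dice"] = slice_dice
    diagnostics["demons_dice_warning"] = bool(np.min(slice_dice) < config.dice_floor)

    # (e) 3D interpolation back to the cDTI slice positions
    warped_map = LabelMap(warped_stack, (moved.spacing_mm[0], w, w), z_rescaled)
    final = interpolate_labels_to_slices(warped_map, z_cdti)

    # sample the working grid at the cDTI voxel centers, then partition the
    # detected cDTI myocardium: clip outside, fill unlabeled voxels by
    # nearest labeled neighbor
    yw, xw = _inplane_world(work_shape, (w, w))
    yc, xc = _inplane_world((ny_c, nx_c), b0.spacing_mm[1:])
    ci = (yc[:, None] - yw[0]) / w * np.ones((1, nx_c))
    cj = np.ones((ny_c, 1)) * (xc[None, :] - xw[0]) / w
    out = np.zeros((len(z_cdti), ny_c, nx_c), dtype=final.labels.dtype)
    for k in range(out.shape[0]):
        sl = ndimage.map_coordinates(
            final.labels[k], np.vstack([ci.ravel(), cj.ravel()]), order=0,
            mode="constant", cval=0,
        ).reshape(ny_c, nx_c)
        myo = cdti_masks_native[k]
        sl[~myo] = 0
        hole = myo & (sl == 0)
        if hole.any() and (sl > 0).any():
            _, (ii, jj) = ndimage.distance_transform_edt(sl == 0, return_indices=True)
            sl[hole] = sl[ii[hole], jj[hole]]
        out[k] = sl
    result = LabelMap(out, (b0.spacing_mm[0], *b0.spacing_mm[1:]), z_cdti)
    diagnostics["final_region_counts"] = result.region_counts()
    return result, diagnostics
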