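"""Seeded infarcted-LV phantom generator.

The phantom emulates a chronically infarcted swine left ventricle imaged
with three short-axis protocols:

* LGE-PSIR at diastole (fine in-plane grid, 8 mm slices) with separated
  remote/infarct intensity distributions and a border zone in between;
* native and post-contrast T1 maps on the LGE grid;
* a diffusion-weighted series at systole (coarser in-plane grid) with the
  left ventricle thickened radially and shortened longitudinally, signals
  synthesized from region-wise ground-truth tensors at b = 0 and 350 s/mm²
  over 12 directions with Rician noise.

Ground-truth label maps are produced on both grids, and the analytic
diastole→systole transformation is stored with the study so registration
accuracy can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_io import (
    DWISeries,
    GradientScheme,
    LabelMap,
    TensorField,
    Volume3D,
    default_scheme,
)

# Region-wise ground-truth eigenvalues (mm²/s): pooled in vivo medians for
# remote / border / infarct myocardium in chronic swine infarcts.
DEFAULT_REGION_EIGENVALUES: dict[str, tuple[float, float, float]] = {
    "remote": (1.94e-3, 1.38e-3, 1.06e-3),
    "border": (2.14e-3, 1.65e-3, 1.24e-3),
    "infarct": (2.28e-3, 1.83e-3, 1.42e-3),
}

# Native T1 medians (ms) per region; post-contrast values are derived in
# default_t1_values() so that the regional ECV medians land on realistic
# chronic-infarct values (0.31 / 0.38 / 0.47) at hct = 0.30 with blood T1
# 1700 ms pre and 400 ms post.
DEFAULT_NATIVE_T1 = {"remote": 1282.0, "border": 1389.0, "infarct": 1554.0}
DEFAULT_ECV = {"remote": 0.31, "border": 0.38, "infarct": 0.47}
DEFAULT_BLOOD_T1 = (1700.0, 400.0)  # (native, post) ms
DEFAULT_HCT = 0.30


def default_t1_values(
    hct: float = DEFAULT_HCT,
    blood_t1: tuple[float, float] = DEFAULT_BLOOD_T1,
    native: Mapping[str, float] = DEFAULT_NATIVE_T1,
    ecv: Mapping[str, float] = DEFAULT_ECV,
) -> dict[str, dict[str, float]]:
    """Region-wise native/post-contrast T1 pairs hitting the target ECVs."""
    d_r1_blood = 1.0 / blood_t1[1] - 1.0 / blood_t1[0]
    out: dict[str, dict[str, float]] = {}
    for region, t1n in native.items():
        d_r1 = ecv[region] * d_r1_blood / (1.0 - hct)
        out[region] = {"native": t1n, "post": 1.0 / (1.0 / t1n + d_r1)}
    return out


@dataclass
class PhantomConfig:
    """All knobs of the LV phantom; defaults emulate the in vivo protocol."""

    n_slices: int = 5
    lge_spacing_mm: tuple[float, float, float] = (8.0, 1.33, 1.33)
    cdti_spacing_mm: tuple[float, float, float] = (8.0, 2.0, 2.0)
    lge_shape_inplane: tuple[int, int] = (96, 96)
    cdti_shape_inplane: tuple[int, int] = (64, 64)
    endo_radius_mm: float = 20.0
    epi_radius_mm: float = 30.0
    systolic_wall_thickening: float = 0.10
    systolic_z_scale: float = 0.75
    infarct_sector_deg: float = 90.0
    border_rim_deg: float = 35.0
    infarct_center_deg: float = 0.0
    infarct_apical_taper: float = 0.4  # fractional shrink of the sector half-angle basal→apical
    transmural_extent: float = 1.0
    region_tensors: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_EIGENVALUES)
    )
    helix_sweep_deg: float = 60.0  # e1 helix angle runs +sweep (endo) → -sweep (epi)
    lge_intensity: tuple[float, float, float, float] = (100.0, 10.0, 300.0, 20.0)
    t1_values: Mapping[str, Mapping[str, float]] = field(default_factory=default_t1_values)
    blood_t1: tuple[float, float] = DEFAULT_BLOOD_T1
    t1_noise_ms: float = 15.0
    hct: float = DEFAULT_HCT
    b_value: float = 350.0
    s0_myocardium: float = 100.0
    s0_blood: float = 80.0
    s0_background: float = 5.0
    snr: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        mu_r, sig_r, mu_i, _ = self.lge_intensity
        if not mu_i > mu_r + 2 * sig_r:
            raise ValueError("infarct LGE mean must exceed remote mean + 2 SD")
        if not 0 < self.transmural_extent <= 1:
            raise ValueError("transmural_extent must be in (0, 1]")
        if not 0 < self.systolic_z_scale <= 1:
            raise ValueError("systolic_z_scale must be in (0, 1]")
        if self.infarct_sector_deg + 2 * self.border_rim_deg > 360:
            raise ValueError("sector angles sum to more than 360 degrees")
        for spacing, shape in (
            (self.lge_spacing_mm, self.lge_shape_inplane),
            (self.cdti_spacing_mm, self.cdti_shape_inplane),
        ):
            half_fov = min(shape[0] * spacing[1], shape[1] * spacing[2]) / 2
            if self.epi_radius_mm >= half_fov:
                raise ValueError("epicardial radius exceeds the field of view")
        if self.endo_radius_mm >= self.epi_radius_mm:
            raise ValueError("endocardial radius must be below the epicardial radius")


@dataclass
class SystolicTransform:
    """Analytic diastole→systole map: radial thickening + uniform z scaling.

    The epicardial radius is held fixed; the wall thickens inward by the
    configured fraction, points inside the cavity scale linearly, and
    longitudinal positions scale by ``z_scale``.
    """

    endo_d: float
    epi_d: float
    wall_thickening: float
    z_scale: float

    @property
    def endo_s(self) -> float:
        return self.epi_d - (self.epi_d - self.endo_d) * (1.0 + self.wall_thickening)

    def radius_to_systole(self, r_d: np.ndarray) -> np.ndarray:
        r_d = np.asarray(r_d, dtype=float)
        out = np.where(
            r_d >= self.endo_d,
            self.epi_d - (self.epi_d - r_d) * (1.0 + self.wall_thickening),
            r_d * (self.endo_s / self.endo_d),
        )
        return np.where(r_d > self.epi_d, r_d, out)

    def radius_to_diastole(self, r_s: np.ndarray) -> np.ndarray:
        r_s = np.asarray(r_s, dtype=float)
        out = np.where(
            r_s >= self.endo_s,
            self.epi_d - (self.epi_d - r_s) / (1.0 + self.wall_thickening),
            r_s * (self.endo_d / self.endo_s),
        )
        return np.where(r_s > self.epi_d, r_s, out)

    def z_to_diastole(self, z_s: np.ndarray) -> np.ndarray:
        return np.asarray(z_s, dtype=float) / self.z_scale


@dataclass
class PhantomStudy:
    """A complete synthetic subject with ground truth."""

    lge: Volume3D
    t1_pre: Volume3D
    t1_post: Volume3D
    dwi: DWISeries
    truth_labels_diastole: LabelMap
    truth_labels_systole: LabelMap
    truth_tensors: TensorField
    hct: float
    transform: SystolicTransform
    config: PhantomConfig
    blood_t1: tuple[float, float] = DEFAULT_BLOOD_T1


def _inplane_coords(shape: tuple[int, int], spacing: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """World (y, x) mm coordinate grids centered on the array center."""
    ny, nx = shape
    dy, dx = spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    return np.meshgrid(y, x, indexing="ij")


def _sector_half_angle(cfg: PhantomConfig, z_d: np.ndarray, z_span: float) -> np.ndarray:
    """Infarct half-angle (deg) at diastolic z, shrinking toward the apex."""
    zeta = np.clip(np.asarray(z_d, dtype=float) / max(z_span, 1e-9), 0.0, 1.0)
    return (cfg.infarct_sector_deg / 2.0) * (1.0 - cfg.infarct_apical_taper * zeta)


def _classify_material(
    cfg: PhantomConfig,
    r_d: np.ndarray,
    theta_deg: np.ndarray,
    z_d: np.ndarray,
    z_span: float,
) -> np.ndarray:
    """Region labels from diastolic material coordinates."""
    labels = np.zeros(r_d.shape, dtype=np.int16)
    myo = (r_d >= cfg.endo_radius_mm) & (r_d <= cfg.epi_radius_mm)
    labels[myo] = 1
    half = _sector_half_angle(cfg, z_d, z_span)
    dtheta = np.abs((theta_deg - cfg.infarct_center_deg + 180.0) % 360.0 - 180.0)
    depth = (r_d - cfg.endo_radius_mm) / (cfg.epi_radius_mm - cfg.endo_radius_mm)
    transmural = depth <= cfg.transmural_extent
    infarct = myo & transmural & (dtheta <= half) & (half > 0)
    border = myo & transmural & (dtheta > half) & (dtheta <= half + cfg.border_rim_deg) & (half > 0)
    labels[border] = 2
    labels[infarct] = 3
    return labels


def add_rician_noise(signal: np.ndarray, sigma: float, seed: int | None = None) -> np.ndarray:
    """Magnitude of ``(signal + n1, n2)`` with n1, n2 ~ N(0, σ²).

    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + n1, n2)


def synthesize_dwi(
    tensors: TensorField,
    scheme: GradientScheme,
    s0: float | np.ndarray = 100.0,
    snr: float = np.inf,
    seed: int | None = None,
) -> DWISeries:
    """Forward monoexponential DWI synthesis: S = S0·exp(−b gᵀDg).

    Rician noise is applied with σ = S0/snr (the maximum S0 when S0 is a
    map); ``snr = inf`` yields the exact noise-free signal.
    """
    s0_arr = np.asarray(s0, dtype=float)
    if np.any(s0_arr < 0):
        raise ValueError("s0 must be nonnegative")
    grid_shape = tensors.tensor.shape[:-2]
    D = tensors.tensor.reshape(-1, 3, 3)
    vols = []
    sigma = 0.0 if np.isinf(snr) else float(np.max(s0_arr)) / snr
    for i in range(scheme.n):
        b = scheme.bvals[i]
        g = scheme.bvecs[i]
        adc = np.einsum("i,nij,j->n", g, D, g)
        signal = (s0_arr.ravel() if s0_arr.ndim else s0_arr) * np.exp(-b * adc)
        signal = np.broadcast_to(signal, D.shape[:1]).reshape(grid_shape).copy()
        if sigma > 0:
            signal = add_rician_noise(signal, sigma, seed=None if seed is None else seed + i)
        vols.append(
            Volume3D(
                signal,
                spacing_mm=tensors.spacing_mm,
                slice_z_mm=tensors.slice_z_mm,
            )
        )
    return DWISeries(volumes=vols, scheme=scheme)


def _truth_tensor_field(
    cfg: PhantomConfig,
    labels: np.ndarray,
    yy: np.ndarray,
    xx: np.ndarray,
    r_d: np.ndarray,
    spacing: tuple[float, float, float],
    slice_z: np.ndarray,
) -> TensorField:
    """Region eigenvalues on a circumferential/helical eigenvector frame.

    The primary eigenvector follows the myofiber direction: circumferential
    with a helix angle sweeping linearly from +sweep at the endocardium to
    −sweep at the epicardium.  The tertiary eigenvector is radial.  Only the
    eigenvalues matter to the scalar biomarkers; the frame makes the DWI
    signals directionally realistic.
    """
    shape = labels.shape
    theta = np.arctan2(yy, xx)
    depth = np.clip(
        (r_d - cfg.endo_radius_mm) / (cfg.epi_radius_mm - cfg.endo_radius_mm), 0.0, 1.0
    )
    alpha = np.deg2rad(cfg.helix_sweep_deg) * (1.0 - 2.0 * depth)  # + at endo, - at epi
    # orthonormal local frame in world (x, y, z)
    e_c = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
    e_r = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
    e_z = np.zeros(theta.shape + (3,))
    e_z[..., 2] = 1.0
    ca, sa = np.cos(alpha)[..., None], np.sin(alpha)[..., None]
    v1 = ca * e_c + sa * e_z
    v2 = -sa * e_c + ca * e_z
    v3 = e_r

    lam = np.zeros(shape + (3,))
    eigmap = {1: "remote", 2: "border", 3: "infarct"}
    for code, name in eigmap.items():
        lam[labels == code] = cfg.region_tensors[name]
    # non-myocardial voxels: isotropic free water (blood pool / background)
    lam[labels == 0] = (3.0e-3, 3.0e-3, 3.0e-3)

    tensor = (
        lam[..., 0, None, None] * v1[..., :, None] * v1[..., None, :]
        + lam[..., 1, None, None] * v2[..., :, None] * v2[..., None, :]
        + lam[..., 2, None, None] * v3[..., :, None] * v3[..., None, :]
    )
    tensor = 0.5 * (tensor + np.swapaxes(tensor, -1, -2))
    return TensorField(
        tensor=tensor,
        valid_mask=np.ones(shape, dtype=bool),
        spacing_mm=spacing,
        slice_z_mm=slice_z,
    )


def make_lv_phantom(cfg: PhantomConfig | None = None) -> PhantomStudy:
    """Generate a complete phantom study; deterministic for a fixed seed."""
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)

    dz_lge = cfg.lge_spacing_mm[0]
    z_lge = np.arange(cfg.n_slices) * dz_lge
    z_span = float(z_lge[-1] - z_lge[0]) if cfg.n_slices > 1 else 1.0
    transform = SystolicTransform(
        endo_d=cfg.endo_radius_mm,
        epi_d=cfg.epi_radius_mm,
        wall_thickening=cfg.systolic_wall_thickening,
        z_scale=cfg.systolic_z_scale,
    )

    # ---- diastolic grids (LGE + T1) -------------------------------------
    yy, xx = _inplane_coords(cfg.lge_shape_inplane, cfg.lge_spacing_mm[1:])
    r = np.hypot(yy, xx)
    theta_deg = np.degrees(np.arctan2(yy, xx))
    labels_d = np.stack(
        [
            _classify_material(cfg, r, theta_deg, np.full(r.shape, z), z_span)
            for z in z_lge
        ]
    )
    truth_d = LabelMap(labels_d, cfg.lge_spacing_mm, z_lge)

    mu_r, sig_r, mu_i, sig_i = cfg.lge_intensity
    t_low = mu_r + 2 * sig_r
    t_high = 0.5 * (mu_r + mu_i)
    lge_data = np.empty(labels_d.shape)
    cavity = (labels_d == 0) & (np.stack([r] * cfg.n_slices) < cfg.endo_radius_mm)
    air = (labels_d == 0) & ~cavity
    lge_data[labels_d == 1] = rng.normal(mu_r, sig_r, int(np.sum(labels_d == 1)))
    lge_data[labels_d == 3] = rng.normal(mu_i, sig_i, int(np.sum(labels_d == 3)))
    n_border = int(np.sum(labels_d == 2))
    span = t_high - t_low
    lge_data[labels_d == 2] = t_low + span * (0.02 + 0.96 * rng.random(n_border))
    lge_data[cavity] = rng.normal(mu_i * 0.9, sig_i, int(np.sum(cavity)))  # bright blood on PSIR
    lge_data[air] = rng.normal(0.3 * mu_r, sig_r, int(np.sum(air)))
    lge = Volume3D(lge_data, cfg.lge_spacing_mm, z_lge, intensity_units="a.u.")

    t1_pre_data = np.zeros(labels_d.shape)
    t1_post_data = np.zeros(labels_d.shape)
    for code, name in {1: "remote", 2: "border", 3: "infarct"}.items():
        m = labels_d == code
        t1_pre_data[m] = cfg.t1_values[name]["native"]
        t1_post_data[m] = cfg.t1_values[name]["post"]
    t1_pre_data[cavity] = cfg.blood_t1[0]
    t1_post_data[cavity] = cfg.blood_t1[1]
    if cfg.t1_noise_ms > 0:
        t1_pre_data += rng.normal(0.0, cfg.t1_noise_ms, t1_pre_data.shape)
        t1_post_data += rng.normal(0.0, cfg.t1_noise_ms / 2.0, t1_post_data.shape)
    t1_pre_data = np.clip(t1_pre_data, 1.0, None)
    t1_post_data = np.clip(t1_post_data, 1.0, None)
    t1_pre = Volume3D(t1_pre_data, cfg.lge_spacing_mm, z_lge, intensity_units="ms")
    t1_post = Volume3D(t1_post_data, cfg.lge_spacing_mm, z_lge, intensity_units="ms")

    # ---- systolic grid (cDTI) -------------------------------------------
    dz_c = cfg.cdti_spacing_mm[0]
    z_span_sys = z_span * cfg.systolic_z_scale
    n_cdti = int(np.floor(z_span_sys / dz_c + 1e-9)) + 1 if cfg.n_slices > 1 else 1
    z_cdti = np.arange(n_cdti) * dz_c
    yy_c, xx_c = _inplane_coords(cfg.cdti_shape_inplane, cfg.cdti_spacing_mm[1:])
    r_s = np.hypot(yy_c, xx_c)
    theta_c = np.degrees(np.arctan2(yy_c, xx_c))
    r_d_of_s = transform.radius_to_diastole(r_s)

    labels_s = np.stack(
        [
            _classify_material(
                cfg, r_d_of_s, theta_c, np.full(r_s.shape, transform.z_to_diastole(z)), z_span
            )
            for z in z_cdti
        ]
    )
    # systolic myocardium must use systolic radii: reclassify support
    myo_s = (r_s >= transform.endo_s) & (r_s <= cfg.epi_radius_mm)
    labels_s[:, ~myo_s] = 0
    truth_s = LabelMap(labels_s, cfg.cdti_spacing_mm, z_cdti)

    truth_tensors = _truth_tensor_field(
        cfg, labels_s, np.broadcast_to(yy_c, labels_s.shape),
        np.broadcast_to(xx_c, labels_s.shape),
        np.broadcast_to(r_d_of_s, labels_s.shape),
        cfg.cdti_spacing_mm, z_cdti,
    )

    s0_map = np.full(labels_s.shape, cfg.s0_background)
    s0_map[np.broadcast_to(r_s < transform.endo_s, labels_s.shape)] = cfg.s0_blood
    s0_map[labels_s > 0] = cfg.s0_myocardium
    dwi = synthesize_dwi(
        truth_tensors,
        default_scheme(cfg.b_value),
        s0=s0_map,
        snr=cfg.snr,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return PhantomStudy(
        lge=lge,
        t1_pre=t1_pre,
        t1_post=t1_post,
        dwi=dwi,
        truth_labels_diastole=truth_d,
        truth_labels_systole=truth_s,
        truth_tensors=truth_tensors,
        hct=cfg.hct,
        transform=transform,
        config=cfg,
        blood_t1=cfg.blood_t1,
    )


def auto_rois_from_truth(truth: LabelMap, erode_voxels: int = 1) -> tuple[LabelMap, LabelMap]:
    """Remote and infarct ROI label maps drawn from truth labels.

    Stands in for the manual per-slice ROI drawing of a human analyst:
    regions are eroded in-plane so ROI voxels sit inside their zones.
    """
    from scipy import ndimage

    remote = np.zeros_like(truth.labels)
    infarct = np.zeros_like(truth.labels)
    for k in range(truth.labels.shape[0]):
        rm = truth.labels[k] == 1
        im = truth.labels[k] == 3
        if erode_voxels > 0:
            st = ndimage.generate_binary_structure(2, 1)
            rm = ndimage.binary_erosion(rm, st, iterations=erode_voxels)
            im_er = ndimage.binary_erosion(im, st, iterations=erode_voxels)
            if im_er.any():
                im = im_er
        remote[k][rm] = 1
        infarct[k][im] = 1
    return (
        LabelMap(remote, truth.spacing_mm, truth.slice_z_mm),
        LabelMap(infarct, truth.spacing_mm, truth.slice_z_mm),
    )
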