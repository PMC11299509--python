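"""Synthetic cortical-bone data with known ground truth.

Three generators mirror the three experimental inputs of the study design:

* :func:`generate_volume` -- a 3D grayscale stack of an annular cortical
  slab containing ellipsoidal osteocyte lacunae, tubular intracortical
  canals and sub-resolution noise specks, with a per-object ground-truth
  table.
* :func:`generate_field2d` -- a 2D silver-stain-like field of lacuna
  bodies with radiating canaliculi of controlled length and angular
  dispersion, plus optional detached background network.
* :func:`generate_ct_table` -- a long-format qPCR Ct table with per-gene
  group offsets, exact in the noiseless limit.

Every generator is deterministic given its spec (which includes the seed),
and emits ground truth so each downstream analysis stage can be tested by
parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .core import (
    CLASS_CANAL,
    CLASS_LACUNA,
    CLASS_NOISE,
    LACUNA_MAX_UM3,
    NOISE_MAX_UM3,
    Field2D,
    VoxelVolume,
    wrap_angle_deg,
)


class GeometryError(RuntimeError):
    """Raised when requested objects cannot be placed in the given geometry."""


# ---------------------------------------------------------------------------
# 3D volumes
# ---------------------------------------------------------------------------

@dataclass
class Volume3DSpec:
    """Parameters of a synthetic cortical slab.

    The cortex is an annular tube aligned with the slice axis; its wall is
    bright (mineralized bone) and everything else dark. Lacunae are placed
    fully inside the wall; canals run the full slab length; noise specks
    are sub-resolution dark blobs inside the wall.
    """

    shape_voxels: tuple[int, int, int] = (144, 208, 208)
    voxel_size_um: float = 0.65
    outer_radius_um: float = 64.0
    wall_thickness_um: float = 28.0
    lacuna_density_per_mm3: float = 4.0e4
    lacuna_volume_mean_um3: float = 200.0
    lacuna_volume_sigma: float = 0.35  # lognormal shape parameter
    lacuna_aspect_ratios: tuple[float, float, float] = (2.0, 1.2, 1.0)
    canal_count: int = 2
    canal_radius_um: float = 3.0
    noise_speck_count: int = 25
    foreground_gray: float = 200.0
    background_gray: float = 60.0
    noise_sd: float = 8.0
    blur_sigma_um: float = 0.5
    seed: int = 0

    def wall_volume_um3(self) -> float:
        r_out = self.outer_radius_um
        r_in = r_out - self.wall_thickness_um
        height = self.shape_voxels[0] * self.voxel_size_um
        return math.pi * (r_out**2 - r_in**2) * height

    def n_lacunae(self) -> int:
        """Deterministic lacuna count: round(density x wall volume)."""
        return int(round(self.lacuna_density_per_mm3 * self.wall_volume_um3() * 1e-9))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _rasterize_ellipsoid(
    shape: tuple[int, int, int],
    center_vox: np.ndarray,
    semi_axes_vox: np.ndarray,
    rotation: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices (z, y, x arrays) inside a rotated ellipsoid."""
    pad = int(np.ceil(semi_axes_vox.max())) + 2
    lo = np.maximum(np.floor(center_vox).astype(int) - pad, 0)
    hi = np.minimum(np.floor(center_vox).astype(int) + pad + 1, shape)
    if np.any(lo >= hi):
        return np.empty(0, int), np.empty((0, 3), int)
    grids = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    local = (pts - center_vox) @ rotation  # rotate into ellipsoid frame
    inside = np.sum((local / semi_axes_vox) ** 2, axis=1) <= 1.0
    idx = np.stack([g.ravel()[inside] for g in grids], axis=1)
    return inside, idx


def generate_volume(spec: Volume3DSpec) -> tuple[VoxelVolume, pd.DataFrame]:
    """Generate a synthetic cortical slab and its ground-truth object table.

    Returns
    -------
    volume
        Grayscale uint8 stack (bright cortex, dark background and pores).
    truth
        One row per generated object with columns ``object_id``, ``cls``,
        ``true_volume_um3``, ``voxel_count``, ``centroid_z_um`` /
        ``_y_um`` / ``_x_um``. Table-level facts are stored in
        ``truth.attrs``: ``wall_voxels`` (solid annulus, pores filled) and
        ``cortex_voxels`` (annulus minus pores).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape_voxels
    vox = spec.voxel_size_um
    vox3 = vox**3

    r_out_v = spec.outer_radius_um / vox
    r_in_v = (spec.outer_radius_um - spec.wall_thickness_um) / vox
    if r_in_v <= 0:
        raise GeometryError("wall thickness exceeds outer radius")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    if r_out_v > min(cy, cx) - 2:
        raise GeometryError(
            f"annulus (outer radius {spec.outer_radius_um} um) does not fit "
            f"inside a {ny}x{nx} voxel cross-section at {vox} um/voxel"
        )

    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rr = np.hypot(yy - cy, xx - cx)
    annulus2d = (rr <= r_out_v) & (rr >= r_in_v)
    wall = np.broadcast_to(annulus2d, (nz, ny, nx)).copy()
    wall_voxels = int(wall.sum())

    pores = np.zeros((nz, ny, nx), dtype=bool)
    records: list[dict] = []
    spheres: list[tuple[np.ndarray, float]] = []  # (center vox, clearance vox)
    canals: list[tuple[float, float, float]] = []  # (y, x, radius vox)

    def _clear(c: np.ndarray, margin_vox: float) -> bool:
        if any(np.linalg.norm(c - pc) <= margin_vox + pm + 2.0 for pc, pm in spheres):
            return False
        return all(
            math.hypot(c[1] - y0, c[2] - x0) > margin_vox + r0 + 2.0
            for y0, x0, r0 in canals
        )

    def _place_inside_wall(margin_vox: float, max_tries: int) -> np.ndarray:
        """Random center inside the wall, `margin_vox` clear of all surfaces."""
        lo_r = r_in_v + margin_vox
        hi_r = r_out_v - margin_vox
        if lo_r >= hi_r or nz - 1 - 2 * margin_vox <= 0:
            raise GeometryError(
                f"wall too thin for object of clearance {margin_vox:.1f} voxels"
            )
        for _ in range(max_tries):
            rad = math.sqrt(rng.uniform(lo_r**2, hi_r**2))
            ang = rng.uniform(0, 2 * math.pi)
            z = rng.uniform(margin_vox, nz - 1 - margin_vox)
            c = np.array([z, cy + rad * math.sin(ang), cx + rad * math.cos(ang)])
            if _clear(c, margin_vox):
                return c
        raise GeometryError(
            "could not place object without overlap after "
            f"{max_tries} tries (density/geometry too crowded)"
        )

    # --- lacunae -----------------------------------------------------------
    ratios = np.asarray(spec.lacuna_aspect_ratios, dtype=float)
    mu = math.log(spec.lacuna_volume_mean_um3) - spec.lacuna_volume_sigma**2 / 2
    n_lac = spec.n_lacunae()
    for i in range(n_lac):
        for _ in range(100):
            v_true = float(rng.lognormal(mu, spec.lacuna_volume_sigma))
            if NOISE_MAX_UM3 + 5 <= v_true <= LACUNA_MAX_UM3 - 200:
                break
        else:  # pragma: no cover - essentially impossible at default sigma
            raise GeometryError("could not draw lacuna volume inside class band")
        scale = (v_true / (4.0 / 3.0 * math.pi * np.prod(ratios))) ** (1.0 / 3.0)
        semi_um = scale * ratios
        semi_vox = semi_um / vox
        rot = _random_rotation(rng)
        center = _place_inside_wall(float(semi_vox.max()) + 1.5, 400)
        _, idx = _rasterize_ellipsoid((nz, ny, nx), center, semi_vox, rot)
        pores[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        spheres.append((center, float(semi_vox.max())))
        records.append(
            {
                "object_id": len(records),
                "cls": CLASS_LACUNA,
                "true_volume_um3": v_true,
                "voxel_count": int(len(idx)),
                "centroid_z_um": center[0] * vox,
                "centroid_y_um": center[1] * vox,
                "centroid_x_um": center[2] * vox,
            }
        )

    # --- intracortical canals (full-length tubes along z) ------------------
    canal_r_v = spec.canal_radius_um / vox
    canal_true_vol = math.pi * spec.canal_radius_um**2 * nz * vox
    if spec.canal_count and canal_true_vol <= LACUNA_MAX_UM3:
        raise GeometryError(
            "canal volume would not exceed the canal class band; increase "
            "canal radius or slab height"
        )
    for _ in range(spec.canal_count):
        center = _place_inside_wall(canal_r_v + 1.5, 400)
        dist2 = (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        tube2d = dist2 <= canal_r_v**2
        pores |= np.broadcast_to(tube2d, (nz, ny, nx))
        canals.append((float(center[1]), float(center[2]), canal_r_v))
        records.append(
            {
                "object_id": len(records),
                "cls": CLASS_CANAL,
                "true_volume_um3": canal_true_vol,
                "voxel_count": int(tube2d.sum()) * nz,
                "centroid_z_um": (nz - 1) / 2.0 * vox,
                "centroid_y_um": center[1] * vox,
                "centroid_x_um": center[2] * vox,
            }
        )

    # --- sub-resolution noise specks ---------------------------------------
    for _ in range(spec.noise_speck_count):
        r_um = rng.uniform(0.5, 1.0)  # true volume 0.5 .. 4.2 um^3, << 25
        center = _place_inside_wall(r_um / vox + 1.0, 400)
        _, idx = _rasterize_ellipsoid(
            (nz, ny, nx), center, np.full(3, r_um / vox), np.eye(3)
        )
        pores[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        spheres.append((center, r_um / vox))
        records.append(
            {
                "object_id": len(records),
                "cls": CLASS_NOISE,
                "true_volume_um3": 4.0 / 3.0 * math.pi * r_um**3,
                "voxel_count": int(len(idx)),
                "centroid_z_um": center[0] * vox,
                "centroid_y_um": center[1] * vox,
                "centroid_x_um": center[2] * vox,
            }
        )

    solid = wall & ~pores
    img = np.full((nz, ny, nx), spec.background_gray, dtype=np.float32)
    img[solid] = spec.foreground_gray
    if spec.blur_sigma_um > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_um / vox)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape).astype(np.float32)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        records,
        columns=[
            "object_id",
            "cls",
            "true_volume_um3",
            "voxel_count",
            "centroid_z_um",
            "centroid_y_um",
            "centroid_x_um",
        ],
    )
    truth.attrs["wall_voxels"] = wall_voxels
    truth.attrs["cortex_voxels"] = int(solid.sum())
    truth.attrs["wall_volume_um3"] = wall_voxels * vox3
    truth.attrs["voxel_size_um"] = vox
    return VoxelVolume(img, vox), truth


# ---------------------------------------------------------------------------
# 2D silver-stain fields
# ---------------------------------------------------------------------------

@dataclass
class Field2DSpec:
    """Parameters of a synthetic Ploton-silver-stain field.

    Lacuna bodies are dark ellipses with the major axis horizontal (the
    field is already aligned with the lamellae); canaliculi radiate up and
    down from each body at angles drawn about the vertical. When
    ``target_lcn_area_fraction`` is set, detached short network segments
    are added until the total network area reaches that fraction of the
    bone area, so the area-fraction effect size can be encoded
    independently of the canaliculus-length effect.
    """

    field_size_px: tuple[int, int] = (768, 768)
    pixel_size_um: float = 0.25
    lacuna_count: int = 9
    canaliculi_per_lacuna: int = 10
    canaliculus_length_mean_um: float = 15.0
    canaliculus_length_sd_um: float = 2.5
    canaliculus_angle_sd_deg: float | None = 15.0  # None => uniform(-90, 90]
    lacuna_semi_axes_um: tuple[float, float] = (5.0, 2.5)
    target_lcn_area_fraction: float | None = 0.06
    bone_gray: float = 200.0
    stain_gray: float = 40.0
    noise_sd: float = 5.0
    blur_sigma_px: float = 0.5
    seed: int = 0


def _stratified_angles_deg(
    rng: np.random.Generator, n: int, sd: float | None
) -> np.ndarray:
    """Stratified sample of n angles about the vertical.

    One draw per equal-probability stratum of the angular distribution
    (normal(0, sd), or uniform over (-90, 90] when sd is None). The
    marginal distribution is unchanged, but angles within one fan keep a
    near-deterministic separation so neighbouring canaliculi remain
    individually resolvable at realistic stain densities.
    """
    if n == 0:
        return np.empty(0)
    u = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
    if sd is None:
        ang = -90.0 + 180.0 * u
    elif sd == 0.0:
        ang = np.zeros(n)
    else:
        from scipy.stats import norm

        ang = norm.ppf(u, scale=sd)
    ang = np.clip(ang, -89.0, 89.0)
    return np.asarray(wrap_angle_deg(ang), dtype=float)


def generate_field2d(spec: Field2DSpec) -> tuple[Field2D, pd.DataFrame]:
    """Generate a synthetic LCN field and its ground truth.

    Returns
    -------
    field
        Grayscale uint8 field (dark stain on light bone).
    truth
        One row per lacuna-attached canaliculus: ``lacuna_id``,
        ``true_length_um``, ``true_angle_deg``. Field-level counts live in
        ``truth.attrs``: ``network_px``, ``body_px``, ``bone_px`` and
        ``true_area_fraction`` (network / (bone - body)).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    px = spec.pixel_size_um
    a_px = spec.lacuna_semi_axes_um[0] / px  # horizontal semi-axis
    b_px = spec.lacuna_semi_axes_um[1] / px
    # truncated at +/- 3 sd so the spatial reach of a fan is bounded
    reach_px = (
        spec.canaliculus_length_mean_um + 3 * spec.canaliculus_length_sd_um
    ) / px + max(a_px, b_px)

    # --- place lacuna bodies on a jittered grid ----------------------------
    # grid spacing >= 2 x fan reach keeps fans of neighbouring lacunae from
    # crossing, so network components map one-to-one onto canaliculi
    side = int(math.ceil(math.sqrt(spec.lacuna_count)))
    spacing = min(h, w) / side
    slack = spacing - 2.0 * (reach_px + 2.0)
    if spacing / 2.0 < reach_px + 2.0:
        raise GeometryError(
            f"overcrowded field: {spec.lacuna_count} lacunae with fan reach "
            f"{reach_px:.0f} px need a larger field than {h}x{w}"
        )
    jitter = min(16.0, slack / 2.0)
    cells = [(gi, gj) for gi in range(side) for gj in range(side)]
    chosen_cells = [
        cells[i] for i in rng.choice(len(cells), spec.lacuna_count, replace=False)
    ]
    centers: list[tuple[float, float]] = []
    for gi, gj in sorted(chosen_cells):
        r = (gi + 0.5) * spacing + rng.uniform(-jitter, jitter)
        c = (gj + 0.5) * spacing + rng.uniform(-jitter, jitter)
        centers.append((r, c))

    bodies = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for r, c in centers:
        bodies |= ((yy - r) / b_px) ** 2 + ((xx - c) / a_px) ** 2 <= 1.0

    # --- lacuna-attached canaliculi ----------------------------------------
    # fan construction: roots are spread along the upper/lower boundary in
    # left-to-right order while the stratified angle draw is used in
    # ascending order; with roots and angles sorted the same way, rays of
    # one fan never cross, so each canaliculus stays an individually
    # traceable, unbranched projection
    canal_lines = np.zeros((h, w), dtype=bool)
    records: list[dict] = []
    for lac_id, (r, c) in enumerate(centers):
        n_can = spec.canaliculi_per_lacuna
        n_up = (n_can + 1) // 2
        for up, thetas in (
            (True, _stratified_angles_deg(rng, n_up, spec.canaliculus_angle_sd_deg)),
            (False, _stratified_angles_deg(rng, n_can - n_up, spec.canaliculus_angle_sd_deg)),
        ):
            thetas = np.sort(thetas)
            n_side = len(thetas)
            for j, theta in enumerate(thetas):
                length_um = float(
                    np.clip(
                        rng.normal(
                            spec.canaliculus_length_mean_um,
                            spec.canaliculus_length_sd_um,
                        ),
                        max(
                            spec.canaliculus_length_mean_um
                            - 3 * spec.canaliculus_length_sd_um,
                            2 * px,
                        ),
                        spec.canaliculus_length_mean_um
                        + 3 * spec.canaliculus_length_sd_um,
                    )
                )
                length_px = length_um / px
                # direction of travel: angle theta from vertical, clockwise+
                t = math.radians(theta)
                sgn = -1.0 if up else 1.0
                dr = sgn * math.cos(t)
                dc = -sgn * math.sin(t)
                # root: boundary point at evenly spaced horizontal offsets;
                # order reversed on the down side so larger angles (which
                # drift left going down) start further left
                jj = j if up else n_side - 1 - j
                x_off = 0.85 * a_px * (2.0 * (jj + 0.5) / max(n_side, 1) - 1.0)
                x_off += rng.uniform(-1.0, 1.0)
                x_off = float(np.clip(x_off, -0.9 * a_px, 0.9 * a_px))
                y_off = sgn * b_px * math.sqrt(max(1.0 - (x_off / a_px) ** 2, 0.0))
                r0, c0 = r + y_off, c + x_off
                r1, c1 = r0 + length_px * dr, c0 + length_px * dc
                rr_l, cc_l = draw_line(
                    int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1))
                )
                ok = (rr_l >= 0) & (rr_l < h) & (cc_l >= 0) & (cc_l < w)
                canal_lines[rr_l[ok], cc_l[ok]] = True
                records.append(
                    {
                        "lacuna_id": lac_id,
                        "true_length_um": length_um,
                        "true_angle_deg": float(theta),
                    }
                )

    thick = np.ones((2, 2), dtype=bool)
    network = ndimage.binary_dilation(canal_lines, structure=thick) & ~bodies

    # --- detached background network to reach the target area fraction -----
    bone_px_count = h * w
    body_px_count = int(bodies.sum())
    denom = bone_px_count - body_px_count
    if spec.target_lcn_area_fraction is not None:
        target_px = spec.target_lcn_area_fraction * denom
        if network.sum() > target_px:
            raise GeometryError(
                "canaliculi alone exceed the target LCN area fraction "
                f"({network.sum() / denom:.4f} > {spec.target_lcn_area_fraction})"
            )
        # forbidden zone is maintained incrementally (local dilation per
        # accepted segment) so the top-up loop stays fast
        keep_out = ndimage.binary_dilation(
            network | bodies, structure=disk_footprint(4)
        )
        net_px = int(network.sum())
        tries = 0
        while net_px < target_px and tries < 30000:
            tries += 1
            seg_len = rng.uniform(16, 40)
            ang = rng.uniform(0, math.pi)
            r0 = rng.uniform(4, h - 5)
            c0 = rng.uniform(4, w - 5)
            r1 = r0 + seg_len * math.cos(ang)
            c1 = c0 + seg_len * math.sin(ang)
            if not (0 <= round(r1) < h - 1 and 0 <= round(c1) < w - 1):
                continue
            rr_l, cc_l = draw_line(
                int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1))
            )
            if keep_out[rr_l, cc_l].any() or keep_out[rr_l + 1, cc_l].any() or keep_out[rr_l, cc_l + 1].any():
                continue
            lo_r = max(int(rr_l.min()) - 6, 0)
            hi_r = min(int(rr_l.max()) + 7, h)
            lo_c = max(int(cc_l.min()) - 6, 0)
            hi_c = min(int(cc_l.max()) + 7, w)
            patch = np.zeros((hi_r - lo_r, hi_c - lo_c), dtype=bool)
            patch[rr_l - lo_r, cc_l - lo_c] = True
            patch = ndimage.binary_dilation(patch, structure=thick)
            added = patch & ~network[lo_r:hi_r, lo_c:hi_c]
            network[lo_r:hi_r, lo_c:hi_c] |= patch
            net_px += int(added.sum())
            keep_out[lo_r:hi_r, lo_c:hi_c] |= ndimage.binary_dilation(
                patch, structure=disk_footprint(4)
            )
        if net_px < target_px * 0.98:
            raise GeometryError("could not reach target LCN area fraction")

    stain = bodies | network
    img = np.full((h, w), spec.bone_gray, dtype=np.float32)
    img[stain] = spec.stain_gray
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape).astype(np.float32)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        records, columns=["lacuna_id", "true_length_um", "true_angle_deg"]
    )
    truth.attrs["network_px"] = int(network.sum())
    truth.attrs["body_px"] = body_px_count
    truth.attrs["bone_px"] = bone_px_count
    truth.attrs["true_area_fraction"] = float(network.sum()) / denom
    truth.attrs["lacuna_centers"] = centers
    return Field2D(img, px), truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass
class CtPreset:
    """Per-gene ddCt offsets and group sizes for a synthetic Ct table.

    ``genes`` maps gene name to its ddCt (tumor minus control difference in
    dCt); a negative ddCt means up-regulation in tumor. The reference gene
    always has ddCt = 0 by construction.
    """

    genes: dict[str, float] = field(
        default_factory=lambda: {"Dmp1": 0.0, "Sost": 0.0}
    )
    reference_gene: str = "Gapdh"
    n_tumor: int = 8
    n_naive: int = 3
    ct_noise_sd: float = 0.0
    seed: int = 0
    baseline_dct: float = 5.0
    reference_ct_mean: float = 18.0
    tumor_group: str = "tumor"
    control_group: str = "naive"


def generate_ct_table(preset: CtPreset) -> pd.DataFrame:
    """Long-format Ct table: columns ``sample``, ``group``, ``gene``, ``ct``.

    With ``ct_noise_sd = 0`` the realized ddCt of every gene equals the
    preset exactly (per-sample global offsets cancel in dCt).
    """
    if preset.reference_gene in preset.genes and preset.genes[
        preset.reference_gene
    ] != 0.0:
        raise ValueError("reference gene must have ddCt = 0")
    if min(preset.n_tumor, preset.n_naive) < 1:
        raise ValueError("each group needs at least one sample")
    if preset.ct_noise_sd > 0 and min(preset.n_tumor, preset.n_naive) < 2:
        raise ValueError("noisy tables need n >= 2 per group")

    rng = np.random.default_rng(preset.seed)
    rows = []
    samples = [(f"naive_{i + 1}", preset.control_group, 0.0) for i in range(preset.n_naive)]
    samples += [(f"tumor_{i + 1}", preset.tumor_group, 1.0) for i in range(preset.n_tumor)]
    for name, group, is_tumor in samples:
        offset = float(rng.normal(0.0, 0.5))  # sample-level loading offset
        ref_ct = preset.reference_ct_mean + offset
        rows.append(
            {
                "sample": name,
                "group": group,
                "gene": preset.reference_gene,
                "ct": ref_ct + float(rng.normal(0.0, preset.ct_noise_sd))
                if preset.ct_noise_sd > 0
                else ref_ct,
            }
        )
        for gene, ddct in preset.genes.items():
            if gene == preset.reference_gene:
                continue
            dct = preset.baseline_dct + is_tumor * ddct
            noise = (
                float(rng.normal(0.0, preset.ct_noise_sd))
                if preset.ct_noise_sd > 0
                else 0.0
            )
            rows.append(
                {
                    "sample": name,
                    "group": group,
                    "gene": gene,
                    "ct": ref_ct + dct + noise,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
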