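"""Analytic cortical phantoms: slab and spherical-shell geometries.

Both phantoms produce an index-paired inner/mid/outer surface set plus a
voxelized tensor field with a prescribed principal-eigenvector orientation,
so that every downstream quantity (radiality, thickness, sampled DTI maps,
regional means) has a known ground truth.  The slab is the exact-arithmetic
workhorse (flat normals, tilt angle set directly); the shell exercises
curvature, normal estimation and nearest-neighbour sampling error, and
carries deterministic hemisphere/lobe labels for group statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import trimesh

from .core import (
    LOBES,
    CorticalSurfaceSet,
    DWIVolume,
    GradientScheme,
    TensorVolume,
)

__all__ = [
    "DEFAULT_EIGENVALUES",
    "make_slab_phantom",
    "make_shell_phantom",
    "set_eigenvalues",
    "synthesize_dwi",
    "shell_sector_labels",
]

#: Default tensor eigenvalues (mm^2/s).  Chosen to look like healthy cortex:
#: MD = 0.833e-3 mm^2/s and FA ~= 0.17, safely inside the MD/FA inclusion
#: thresholds so phantom vertices survive the vertex filter.
DEFAULT_EIGENVALUES = (1.0e-3, 0.75e-3, 0.75e-3)


def _tensor_from_frame(e1: np.ndarray, e2: np.ndarray, e3: np.ndarray,
                       lams: tuple[float, float, float]) -> np.ndarray:
    """D = sum_i lambda_i e_i e_i^T for stacked unit frames (..., 3)."""
    l1, l2, l3 = lams
    return (l1 * e1[..., :, None] * e1[..., None, :]
            + l2 * e2[..., :, None] * e2[..., None, :]
            + l3 * e3[..., :, None] * e3[..., None, :])


def _grid_affine(centers_min: np.ndarray, voxel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_mm
    aff[:3, 3] = centers_min
    return aff


def _grid_quad_faces(nx: int, ny: int) -> np.ndarray:
    """Consistently oriented triangulation of an nx-by-ny vertex grid
    (normals +z for vertices laid out with x fastest)."""
    idx = np.arange(nx * ny).reshape(ny, nx)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    return np.concatenate([np.stack([a, b, d], 1), np.stack([a, d, c], 1)])


def make_slab_phantom(thickness_mm: float = 3.0,
                      extent_mm: float = 30.0,
                      voxel_mm: float = 1.5,
                      tilt_deg: float = 0.0,
                      eigenvalues: tuple = DEFAULT_EIGENVALUES,
                      ) -> tuple[CorticalSurfaceSet, TensorVolume]:
    """Flat cortical slab: inner surface at z=0, outer at z=thickness.

    The tensor principal eigenvector makes the angle ``tilt_deg`` with +z
    (the surface normal) everywhere, tilted within the x-z plane, so the
    ground-truth radiality is exactly ``|cos(tilt_deg)|`` at every vertex.
    Paired vertices share (x, y) coordinates, so paired-vertex thickness is
    exactly ``thickness_mm``.
    """
    if thickness_mm <= 0 or extent_mm <= 0 or voxel_mm <= 0:
        raise ValueError("phantom dimensions must be positive")
    if not 0.0 <= tilt_deg <= 90.0:
        raise ValueError("tilt_deg must be in [0, 90]")

    # Surface meshes: regular grid, vertex spacing == voxel size.
    n_side = max(int(round(extent_mm / voxel_mm)) + 1, 2)
    coords = np.linspace(0.0, extent_mm, n_side)
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    xy = np.stack([xx.ravel(), yy.ravel()], axis=1)
    nv = xy.shape[0]

    def at_height(z):
        return np.column_stack([xy, np.full(nv, float(z))])

    faces = _grid_quad_faces(n_side, n_side)
    hemi = np.where(xy[:, 0] < extent_mm / 2.0, "left", "right")
    lobe = np.full(nv, "frontal", dtype=object)
    surfaces = CorticalSurfaceSet(
        vertices_inner=at_height(0.0),
        vertices_mid=at_height(thickness_mm / 2.0),
        vertices_outer=at_height(thickness_mm),
        faces=faces,
        hemisphere_label=hemi,
        lobe_label=lobe.astype(str),
    )

    # Voxel grid with one voxel of padding around the slab; voxel centres
    # placed symmetrically about the slab mid-plane.
    pad = voxel_mm
    nxy = int(np.ceil((extent_mm + 2 * pad) / voxel_mm))
    nz = int(np.ceil((thickness_mm + 2 * pad) / voxel_mm))
    x0 = extent_mm / 2.0 - (nxy - 1) / 2.0 * voxel_mm
    z0 = thickness_mm / 2.0 - (nz - 1) / 2.0 * voxel_mm
    affine = _grid_affine(np.array([x0, x0, z0]), voxel_mm)

    zc = z0 + voxel_mm * np.arange(nz)
    mask = np.zeros((nxy, nxy, nz), dtype=bool)
    inside = (zc > 0.0) & (zc < thickness_mm)
    mask[:, :, inside] = True

    t = np.deg2rad(tilt_deg)
    e1 = np.array([np.sin(t), 0.0, np.cos(t)])
    e2 = np.array([np.cos(t), 0.0, -np.sin(t)])
    e3 = np.array([0.0, 1.0, 0.0])
    tensor = _tensor_from_frame(e1, e2, e3, tuple(eigenvalues))
    tensors = np.broadcast_to(tensor, (nxy, nxy, nz, 3, 3)).copy()

    return surfaces, TensorVolume(tensors=tensors, affine=affine, mask=mask)


def shell_sector_labels(points: np.ndarray) -> np.ndarray:
    """Deterministic lobe parcellation of the shell by polar angle.

    Five equal-width latitude bands (36 degrees each, measured from +z):
    frontal, parietal, insula, temporal, occipital.  The same rule is applied
    to surface vertices and to voxel centres, so planted per-lobe values can
    be recovered exactly by regional averaging.
    """
    pts = np.asarray(points, dtype=float)
    r = np.linalg.norm(pts, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(r > 0, pts[..., 2] / np.maximum(r, 1e-300), 1.0)
    theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    band = np.minimum((theta / 36.0).astype(int), 4)
    order = np.array(["frontal", "parietal", "insula", "temporal", "occipital"])
    assert set(order) == set(LOBES)
    return order[band]


def make_shell_phantom(inner_radius_mm: float = 40.0,
                       thickness_mm: float = 3.0,
                       voxel_mm: float = 1.5,
                       subdivisions: int = 3,
                       eigenvalues: tuple = DEFAULT_EIGENVALUES,
                       ) -> tuple[CorticalSurfaceSet, TensorVolume]:
    """Concentric spherical-shell cortex with a radial tensor field.

    The three surfaces are icospheres sharing a single unit-sphere topology,
    scaled to radii r, r + t/2 and r + t, so vertices are paired by
    construction and paired-vertex thickness equals ``thickness_mm`` exactly.
    """
    if inner_radius_mm <= 0 or thickness_mm <= 0 or voxel_mm <= 0:
        raise ValueError("phantom dimensions must be positive")
    if subdivisions < 2:
        raise ValueError("subdivisions must be >= 2")
    if thickness_mm < voxel_mm:
        warnings.warn(
            "shell thickness below voxel size: partial-volume regime",
            stacklevel=2,
        )

    unit = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    uv = np.asarray(unit.vertices, dtype=float)
    uv /= np.linalg.norm(uv, axis=1, keepdims=True)
    faces = np.asarray(unit.faces, dtype=int)

    r_in = inner_radius_mm
    r_out = inner_radius_mm + thickness_mm
    r_mid = inner_radius_mm + thickness_mm / 2.0

    hemi = np.where(uv[:, 0] < 0, "left", "right")
    lobe = shell_sector_labels(uv)
    surfaces = CorticalSurfaceSet(
        vertices_inner=uv * r_in,
        vertices_mid=uv * r_mid,
        vertices_outer=uv * r_out,
        faces=faces,
        hemisphere_label=hemi,
        lobe_label=lobe,
    )

    pad = voxel_mm
    half = r_out + pad
    n = int(np.ceil(2 * half / voxel_mm))
    c0 = -(n - 1) / 2.0 * voxel_mm
    affine = _grid_affine(np.array([c0, c0, c0]), voxel_mm)

    ax = c0 + voxel_mm * np.arange(n)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1)
    radius = np.linalg.norm(centers, axis=-1)
    mask = (radius > r_in) & (radius < r_out)

    # Radial frame: e1 = r_hat; e2, e3 span the tangent plane.
    rhat = centers / np.maximum(radius, 1e-300)[..., None]
    helper = np.zeros_like(rhat)
    helper[..., 2] = 1.0
    near_pole = np.abs(rhat[..., 2]) > 0.9
    helper[near_pole] = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(rhat, helper)
    e2 /= np.maximum(np.linalg.norm(e2, axis=-1, keepdims=True), 1e-300)
    e3 = np.cross(rhat, e2)
    tensors = _tensor_from_frame(rhat, e2, e3, tuple(eigenvalues))
    tensors[~mask] = 0.0

    return surfaces, TensorVolume(tensors=tensors, affine=affine, mask=mask)


def set_eigenvalues(tv: TensorVolume,
                    lambda1: float, lambda2: float, lambda3: float,
                    ) -> TensorVolume:
    """Rebuild every masked tensor with the given eigenvalues, keeping each
    voxel's eigenvector frame.  Requires lambda1 >= lambda2 >= lambda3 >= 0."""
    if not (lambda1 >= lambda2 >= lambda3 >= 0):
        raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 >= 0")
    tensors = tv.tensors.copy()
    d = tensors[tv.mask]
    # eigh returns ascending order; realign to descending.
    _, vecs = np.linalg.eigh(d)
    vecs = vecs[..., ::-1]
    lams = np.array([lambda1, lambda2, lambda3])
    rebuilt = np.einsum("...ik,k,...jk->...ij", vecs, lams, vecs)
    tensors[tv.mask] = rebuilt
    return TensorVolume(tensors=tensors, affine=tv.affine.copy(),
                        mask=tv.mask.copy())


def synthesize_dwi(tv: TensorVolume,
                   scheme: GradientScheme,
                   s0: float = 1000.0,
                   snr: float | None = None,
                   seed: int = 0) -> DWIVolume:
    """Mono-exponential tensor signal S = S0 exp(-b g^T D g), optionally with
    Rician noise.

    ``snr`` is defined as s0 / sigma with sigma the standard deviation of
    each underlying Gaussian channel; the magnitude of (S + n1, n2) is taken,
    which reproduces the positive bias of magnitude MRI at low SNR.  Voxels
    outside the mask get zero signal.
    """
    b = scheme.bvals
    g = scheme.bvecs
    # quadratic form g^T D g for every voxel x volume
    quad = np.einsum("...ij,vi,vj->...v", tv.tensors, g, g)
    signals = s0 * np.exp(-b * quad)
    signals[~tv.mask] = 0.0

    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, size=signals.shape)
        n2 = rng.normal(0.0, sigma, size=signals.shape)
        signals = np.sqrt((signals + n1) ** 2 + n2 ** 2)

    return DWIVolume(signals=signals, scheme=scheme, affine=tv.affine.copy(),
                     mask=tv.mask.copy())
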