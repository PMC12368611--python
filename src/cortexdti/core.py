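"""Core containers shared across the pipeline.

Conventions used throughout the package:

* World coordinates are RAS millimetres; voxel indices are 0-based and the
  affine maps voxel *centres* to world coordinates.
* Diffusivities are in mm^2/s (so cortical MD is ~0.8e-3), b-values in s/mm^2.
* The three cortical surfaces (inner = WM/cortex, mid-thickness, outer =
  cortex/CSF) are index-paired: vertex ``i`` corresponds across all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "GradientScheme",
    "TensorVolume",
    "DWIVolume",
    "ScalarVolume",
    "EigenVolume",
    "CorticalSurfaceSet",
    "default_scheme",
    "MD_EXCLUDE_THRESHOLD",
    "FA_EXCLUDE_THRESHOLD",
    "PRACTICAL_MARGINS",
    "LOBES",
    "REGIONS",
    "METRICS",
    "AGE_RANGE",
]

#: Vertices with MD above this (mm^2/s) are outside the plausible cortical
#: range (CSF partial volume) and are excluded from DTI metric averages.
MD_EXCLUDE_THRESHOLD = 1.5e-3

#: Vertices with FA above this are contaminated by superficial white matter.
FA_EXCLUDE_THRESHOLD = 0.3

#: Practical-significance margins: a group difference smaller than the margin
#: for its metric is treated as methodological noise, not a real effect.
PRACTICAL_MARGINS = {
    "thickness": 0.1,      # mm
    "radiality": 0.03,
    "FA": 0.01,
    "MD": 0.01e-3,         # mm^2/s
    "AD": 0.01e-3,
    "RD": 0.01e-3,
}

LOBES = ("frontal", "temporal", "insula", "parietal", "occipital")
REGIONS = ("total",) + LOBES
METRICS = ("thickness", "radiality", "FA", "MD", "AD", "RD")

#: Cohort age span in years.
AGE_RANGE = (5.0, 74.0)


def _as_unit_rows(v: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    nonzero = norms > 0
    bad = nonzero & (np.abs(norms - 1.0) > atol)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} gradient direction(s) are not unit vectors"
        )
    return v


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion-weighting scheme: one b-value and unit direction per volume.

    A zero direction vector is permitted (and conventional) for b=0 volumes.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = _as_unit_rows(self.bvecs)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError("bvals must be (n,), bvecs must be (n, 3)")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())


def default_scheme(b: float = 1000.0, n_b0: int = 6) -> GradientScheme:
    """The acquisition emulated by the phantom: 6 b=0 plus 30 diffusion
    directions at b=1000 s/mm^2, drawn from an electrostatic-repulsion set."""
    ref = resources.files("cortexdti.data").joinpath("gradients30.txt")
    dirs = np.loadtxt(str(ref))
    bvals = np.concatenate([np.zeros(n_b0), np.full(len(dirs), b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors on a regular grid."""

    tensors: np.ndarray          # (nx, ny, nz, 3, 3), mm^2/s
    affine: np.ndarray           # 4x4 voxel -> world (mm)
    mask: np.ndarray             # (nx, ny, nz) bool

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have trailing shape (3, 3)")
        if self.mask.shape != self.tensors.shape[:3]:
            raise ValueError("mask shape must match the tensor grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.tensors.shape[:3]


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal (grid x volumes) with its scheme."""

    signals: np.ndarray          # (nx, ny, nz, n_volumes), arbitrary units
    scheme: GradientScheme
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape[-1] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signals.shape[-1]} volumes but the scheme "
                f"defines {len(self.scheme)}"
            )
        if np.any(self.signals < 0):
            raise ValueError("DWI signals must be non-negative")


@dataclass
class ScalarVolume:
    """One scalar per voxel (FA dimensionless; diffusivities mm^2/s)."""

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class EigenVolume:
    """Ordered eigenvalues (l1 >= l2 >= l3) and unit principal eigenvector."""

    eigenvalues: np.ndarray      # (nx, ny, nz, 3), descending
    e1: np.ndarray               # (nx, ny, nz, 3), unit inside mask
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev[self.mask], axis=-1) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")


@dataclass
class CorticalSurfaceSet:
    """Inner/mid/outer cortical meshes with shared topology and labels.

    ``faces`` indexes all three vertex arrays; ``hemisphere_label`` is
    "left"/"right" and ``lobe_label`` one of the five lobes or "none".
    """

    vertices_inner: np.ndarray   # (V, 3) mm
    vertices_mid: np.ndarray
    vertices_outer: np.ndarray
    faces: np.ndarray            # (F, 3) int
    hemisphere_label: np.ndarray  # (V,) str
    lobe_label: np.ndarray        # (V,) str

    def __post_init__(self):
        v = self.vertices_mid.shape[0]
        for arr in (self.vertices_inner, self.vertices_outer):
            if arr.shape != (v, 3):
                raise ValueError("surface vertex arrays must be index-paired")
        if self.faces.size and self.faces.max() >= v:
            raise ValueError("faces index out-of-range vertices")
        for lab in (self.hemisphere_label, self.lobe_label):
            if len(lab) != v:
                raise ValueError("per-vertex labels must have length V")

    @property
    def n_vertices(self) -> int:
        return self.vertices_mid.shape[0]
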