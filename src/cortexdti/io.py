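"""Reading and writing the standard neuroimaging formats.

Volumes go through NIfTI (nibabel), gradient tables through FSL-style
``.bval``/``.bvec`` text files, and surfaces through GIFTI with a sidecar
CSV carrying per-vertex hemisphere/lobe labels.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CorticalSurfaceSet, DWIVolume, GradientScheme

__all__ = [
    "save_nifti", "load_nifti",
    "save_dwi", "load_dwi",
    "save_gradients", "load_gradients",
    "save_surfaces", "load_surfaces",
]


def save_nifti(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_gradients(prefix, scheme: GradientScheme) -> None:
    """FSL convention: one row of b-values, three rows of components."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), scheme.bvals[None], fmt="%.1f")
    np.savetxt(prefix.with_suffix(".bvec"), scheme.bvecs.T, fmt="%.8f")


def load_gradients(bval_path, bvec_path) -> GradientScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def save_dwi(out_dir, dwi: DWIVolume, stem: str = "dwi") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_nifti(out_dir / f"{stem}.nii", dwi.signals, dwi.affine)
    save_gradients(out_dir / stem, dwi.scheme)
    if dwi.mask is not None:
        save_nifti(out_dir / f"{stem}_mask.nii",
                   dwi.mask.astype(np.uint8), dwi.affine)


def load_dwi(out_dir, stem: str = "dwi") -> DWIVolume:
    out_dir = Path(out_dir)
    signals, affine = load_nifti(out_dir / f"{stem}.nii")
    scheme = load_gradients(out_dir / f"{stem}.bval",
                            out_dir / f"{stem}.bvec")
    mask_path = out_dir / f"{stem}_mask.nii"
    mask = None
    if mask_path.exists():
        mask = load_nifti(mask_path)[0].astype(bool)
    return DWIVolume(signals=signals, scheme=scheme, affine=affine, mask=mask)


def _surface_gifti(vertices: np.ndarray, faces: np.ndarray):
    gii = nib.gifti.GiftiImage()
    gii.add_gifti_data_array(nib.gifti.GiftiDataArray(
        np.asarray(vertices, dtype=np.float32),
        intent="NIFTI_INTENT_POINTSET"))
    gii.add_gifti_data_array(nib.gifti.GiftiDataArray(
        np.asarray(faces, dtype=np.int32),
        intent="NIFTI_INTENT_TRIANGLE"))
    return gii


def save_surfaces(out_dir, surfaces: CorticalSurfaceSet) -> None:
    """Write inner/mid/outer GIFTI meshes plus a label sidecar CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, verts in (("inner", surfaces.vertices_inner),
                        ("mid", surfaces.vertices_mid),
                        ("outer", surfaces.vertices_outer)):
        nib.save(_surface_gifti(verts, surfaces.faces),
                 str(out_dir / f"{name}.surf.gii"))
    pd.DataFrame({
        "vertex": np.arange(surfaces.n_vertices),
        "hemisphere": surfaces.hemisphere_label,
        "lobe": surfaces.lobe_label,
    }).to_csv(out_dir / "vertex_labels.csv", index=False)


def load_surfaces(out_dir) -> CorticalSurfaceSet:
    out_dir = Path(out_dir)
    meshes = {}
    faces = None
    for name in ("inner", "mid", "outer"):
        gii = nib.load(str(out_dir / f"{name}.surf.gii"))
        meshes[name] = gii.darrays[0].data.astype(float)
        faces = gii.darrays[1].data.astype(int)
    labels = pd.read_csv(out_dir / "vertex_labels.csv")
    return CorticalSurfaceSet(
        vertices_inner=meshes["inner"],
        vertices_mid=meshes["mid"],
        vertices_outer=meshes["outer"],
        faces=faces,
        hemisphere_label=labels["hemisphere"].to_numpy(dtype=object),
        lobe_label=labels["lobe"].to_numpy(dtype=object),
    )
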