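"""Diffusion tensor estimation and scalar map derivation.

The tensor is estimated per voxel by log-linear least squares on
``ln S = ln S0 - b g^T D g``.  At b = 1000 s/mm^2 this is standard practice
and, in the noiseless case, exactly invertible, which makes the phantom
round-trip a machine-precision identity check.  b=0 volumes are averaged
into a single sample before fitting.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import DWIVolume, EigenVolume, ScalarVolume, TensorVolume

logger = logging.getLogger(__name__)

__all__ = ["fit_tensor", "tensor_scalars", "fa_from_eigenvalues"]

# Row order of the 6 unique tensor elements in the design matrix.
_IJ = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Columns: [1 (ln S0), -b gi gj terms for Dxx Dyy Dzz Dxy Dxz Dyz]."""
    n = bvals.size
    x = np.empty((n, 7))
    x[:, 0] = 1.0
    for col, (i, j) in enumerate(_IJ, start=1):
        w = 2.0 if i != j else 1.0
        x[:, col] = -bvals * w * bvecs[:, i] * bvecs[:, j]
    return x


def _tensors_from_coeffs(d6: np.ndarray) -> np.ndarray:
    out = np.zeros(d6.shape[:-1] + (3, 3))
    for col, (i, j) in enumerate(_IJ):
        out[..., i, j] = d6[..., col]
        out[..., j, i] = d6[..., col]
    return out


def fit_tensor(dwi: DWIVolume,
               mask: np.ndarray | None = None,
               weighted: bool = False) -> TensorVolume:
    """Estimate the diffusion tensor in every masked voxel.

    Parameters
    ----------
    dwi
        4D signal plus gradient scheme.
    mask
        Boolean voxel mask; defaults to ``dwi.mask``, else all voxels.
    weighted
        If True, iterate once with weights proportional to the squared
        predicted signal (WLLS); default is plain OLS on log-signals.

    Non-positive signals are dropped per voxel; a voxel keeps its fit only if
    at least 7 usable samples remain, otherwise it is removed from the output
    mask.  Negative eigenvalues are clamped to zero and the affected voxel
    count is recorded on the result as ``n_clamped`` and logged.
    """
    scheme = dwi.scheme
    b0 = scheme.b0_mask
    if b0.sum() < 1:
        raise ValueError("scheme must contain at least one b=0 volume")

    # Average b=0 volumes into one sample, keep diffusion volumes as-is.
    sig_b0 = dwi.signals[..., b0].mean(axis=-1, keepdims=True)
    sig_dw = dwi.signals[..., ~b0]
    signals = np.concatenate([sig_b0, sig_dw], axis=-1)
    bvals = np.concatenate([[0.0], scheme.bvals[~b0]])
    bvecs = np.vstack([np.zeros(3), scheme.bvecs[~b0]])

    x = _design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError(
            "gradient scheme is rank-deficient for tensor fitting: need >= 6 "
            "distinct non-collinear directions plus a b=0 volume"
        )

    if mask is None:
        mask = dwi.mask if dwi.mask is not None else np.ones(
            dwi.signals.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    vox_sig = signals[mask]                       # (nvox, nvol)
    usable = vox_sig > 0
    out_mask = mask.copy()
    tensors = np.zeros(mask.shape + (3, 3))

    full = usable.all(axis=1)
    coeffs = np.full((vox_sig.shape[0], 7), np.nan)

    if np.any(full):
        y = np.log(vox_sig[full])
        sol = np.linalg.lstsq(x, y.T, rcond=None)[0].T
        if weighted:
            w = np.exp(x @ sol.T).T              # predicted signals
            for i, row in enumerate(np.flatnonzero(full)):
                xw = x * w[i, :, None]
                sol[i] = np.linalg.lstsq(xw, w[i] * y[i], rcond=None)[0]
        coeffs[full] = sol

    dropped = 0
    for i in np.flatnonzero(~full):
        keep = usable[i]
        if keep.sum() < 7:
            dropped += 1
            continue
        xi = x[keep]
        if np.linalg.matrix_rank(xi) < 7:
            dropped += 1
            continue
        yi = np.log(vox_sig[i, keep])
        coeffs[i] = np.linalg.lstsq(xi, yi, rcond=None)[0]
    if dropped:
        logger.warning("%d voxel(s) dropped: fewer than 7 usable samples",
                       dropped)
        flat_idx = np.flatnonzero(mask)
        bad = flat_idx[np.isnan(coeffs[:, 0])]
        out_flat = out_mask.ravel()
        out_flat[bad] = False
        out_mask = out_flat.reshape(mask.shape)

    good = ~np.isnan(coeffs[:, 0])
    vox_tensors = _tensors_from_coeffs(coeffs[:, 1:])
    vox_tensors[~good] = 0.0

    # Clamp negative eigenvalues to zero (partial-volume / noise floor).
    evals, evecs = np.linalg.eigh(vox_tensors[good])
    neg = evals < 0
    n_clamped = int(np.any(neg, axis=-1).sum())
    if n_clamped:
        evals = np.clip(evals, 0.0, None)
        vox_tensors[good] = np.einsum("...ik,...k,...jk->...ij",
                                      evecs, evals, evecs)
        logger.info("clamped negative eigenvalues in %d voxel(s)", n_clamped)

    tensors[mask] = vox_tensors
    tv = TensorVolume(tensors=tensors, affine=np.asarray(dwi.affine).copy(),
                      mask=out_mask)
    tv.n_clamped = n_clamped
    return tv


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (..., 3) eigenvalues:
    FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, 0 for zero tensors."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(evals - mean)).sum(axis=-1))
    den = np.sqrt(np.square(evals).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    return np.clip(fa, 0.0, 1.0)


def tensor_scalars(tv: TensorVolume) -> tuple[dict, EigenVolume]:
    """Eigendecompose the tensor field and derive the scalar maps.

    Returns ``(maps, eigen)`` where ``maps`` holds ScalarVolumes keyed
    "FA", "MD", "AD", "RD":  MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2.
    Voxels with non-finite tensor entries are dropped from the mask (count
    logged).  The principal eigenvector sign is fixed so its
    largest-magnitude component is positive.
    """
    mask = tv.mask.copy()
    finite = np.isfinite(tv.tensors).all(axis=(-2, -1))
    n_dropped = int((mask & ~finite).sum())
    if n_dropped:
        logger.warning("dropped %d voxel(s) with non-finite tensors",
                       n_dropped)
        mask &= finite

    shape = tv.shape
    evals_all = np.zeros(shape + (3,))
    e1_all = np.zeros(shape + (3,))

    d = tv.tensors[mask]
    if d.size:
        evals, evecs = np.linalg.eigh(d)       # ascending
        evals = evals[..., ::-1]
        e1 = evecs[..., ::-1][..., :, 0]
        # deterministic sign: largest-|component| positive
        lead = np.take_along_axis(
            e1, np.abs(e1).argmax(axis=-1, keepdims=True), axis=-1)
        e1 = e1 * np.where(lead < 0, -1.0, 1.0)
        evals_all[mask] = evals
        e1_all[mask] = e1

    md = evals_all.mean(axis=-1)
    ad = evals_all[..., 0]
    rd = evals_all[..., 1:].mean(axis=-1)
    fa = fa_from_eigenvalues(evals_all)
    for arr in (md, ad, rd, fa):
        arr[~mask] = 0.0

    aff = np.asarray(tv.affine)
    maps = {
        "FA": ScalarVolume(values=fa, affine=aff, mask=mask),
        "MD": ScalarVolume(values=md, affine=aff, mask=mask),
        "AD": ScalarVolume(values=ad, affine=aff, mask=mask),
        "RD": ScalarVolume(values=rd, affine=aff, mask=mask),
    }
    eigen = EigenVolume(eigenvalues=evals_all, e1=e1_all, affine=aff,
                        mask=mask)
    return maps, eigen
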