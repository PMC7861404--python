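"""NIfTI / bval / bvec readers and writers.

Volumes on disk may come in any order; the reader matches each volume's
(b-value, direction) against the scheme and reorders into the canonical
order (b0, axes at b1, second shell at b2).  Directions are matched
sign-blind (antipodal encodings are equivalent for diffusion).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .dki import DWIStudy, ParameterMaps
from .scheme import DiffusionScheme

__all__ = ["load_dwi", "save_parameter_maps", "load_mask", "save_mask"]

_B0_THRESHOLD = 50.0  # s/mm^2


class SidecarError(ValueError):
    """bval/bvec sidecars inconsistent with the acquisition scheme."""


def _match_volume_order(bvals: np.ndarray, bvecs: np.ndarray,
                        scheme: DiffusionScheme) -> np.ndarray:
    """Permutation mapping canonical scheme order -> file volume order."""
    want_b = scheme.bvals
    want_n = scheme.bvecs
    n = len(want_b)
    if len(bvals) != n:
        raise SidecarError(f"expected {n} volumes, sidecar lists {len(bvals)}")
    dwi_rows = bvals > _B0_THRESHOLD
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any(np.abs(norms[dwi_rows] - 1.0) > 1e-3):
        raise SidecarError("diffusion-weighted bvec columns must be unit vectors")

    used = np.zeros(n, bool)
    order = np.empty(n, int)
    for k in range(n):
        if want_b[k] <= _B0_THRESHOLD:
            cand = np.flatnonzero((bvals <= _B0_THRESHOLD) & ~used)
        else:
            dots = np.abs(bvecs @ want_n[k])
            cand = np.flatnonzero(
                (np.abs(bvals - want_b[k]) < 1.0) & (dots > 1.0 - 1e-6) & ~used
            )
        if len(cand) == 0:
            raise SidecarError(
                f"no sidecar row matches scheme volume {k} "
                f"(b={want_b[k]:g}, n={np.round(want_n[k], 4)})"
            )
        order[k] = cand[0]
        used[cand[0]] = True
    return order


def load_dwi(subject_dir, scheme: DiffusionScheme, subject_id: str = "") -> DWIStudy:
    """Read ``dwi.nii.gz`` + FSL-dialect ``dwi.bval``/``dwi.bvec`` and reorder
    the volumes into the canonical scheme order."""
    sdir = Path(subject_dir)
    img = nib.load(sdir / "dwi.nii.gz")
    data = np.asarray(img.dataobj, dtype=float)
    bvals = np.atleast_1d(np.loadtxt(sdir / "dwi.bval")).ravel()
    bvecs = np.loadtxt(sdir / "dwi.bvec")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    order = _match_volume_order(bvals, bvecs, scheme)
    return DWIStudy(data=data[..., order], affine=img.affine, scheme=scheme,
                    subject_id=subject_id or sdir.name)


def save_parameter_maps(maps: ParameterMaps, out_dir, prefix: str) -> None:
    """Write ``<prefix>_md.nii.gz`` (10^-3 mm^2/s), ``<prefix>_mkt.nii.gz``
    and ``<prefix>_qc.nii.gz`` (uint8)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(maps.md_map.astype(np.float32), maps.affine),
             out / f"{prefix}_md.nii.gz")
    nib.save(nib.Nifti1Image(maps.mkt_map.astype(np.float32), maps.affine),
             out / f"{prefix}_mkt.nii.gz")
    nib.save(nib.Nifti1Image(maps.qc_mask.astype(np.uint8), maps.affine),
             out / f"{prefix}_qc.nii.gz")


def load_parameter_maps(out_dir, prefix: str) -> ParameterMaps:
    out = Path(out_dir)
    md = nib.load(out / f"{prefix}_md.nii.gz")
    mkt = nib.load(out / f"{prefix}_mkt.nii.gz")
    qc = nib.load(out / f"{prefix}_qc.nii.gz")
    return ParameterMaps(
        md_map=np.asarray(md.dataobj, float),
        mkt_map=np.asarray(mkt.dataobj, float),
        qc_mask=np.asarray(qc.dataobj).astype(bool),
        affine=md.affine,
    )


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj).astype(np.uint8)


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, np.uint8), affine), path)
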