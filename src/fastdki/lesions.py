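"""Mask algebra and per-lesion value extraction.

Lesion categories follow the standard MS imaging taxonomy: contrast-enhancing
lesions (CE-L), FLAIR-hyperintense lesions (FLAIR-L), black holes (BH),
normal-appearing white matter (NAWM) ROIs in patients, and white-matter ROIs
in healthy controls (HC-WM).  Because CE-L and BH are also FLAIR
hyperintense, they are subtracted from the FLAIR-L mask before labeling, and
FLAIR-L components smaller than a voxel floor (default 10) are excluded to
limit partial-volume effects.  The unit of all downstream statistics is the
per-lesion / per-ROI mean over QC-valid voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .dki import ParameterMaps

__all__ = [
    "CATEGORIES",
    "LesionRecord",
    "label_lesions",
    "filter_small_lesions",
    "subtract_masks",
    "consensus_mask",
    "dice",
    "extract_lesion_values",
    "records_to_table",
    "write_lesion_table",
    "read_lesion_table",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("HC-WM", "NAWM", "CE-L", "FLAIR-L", "BH")

_TABLE_COLUMNS = [
    "patient_id", "lesion_id", "category",
    "voxel_count", "valid_voxel_count", "mean_md", "mean_mkt",
]


@dataclass(frozen=True)
class LesionRecord:
    """Per-lesion/ROI summary feeding all group statistics."""

    patient_id: str
    lesion_id: int
    category: str
    voxel_count: int
    valid_voxel_count: int
    mean_md: float    # 10^-3 mm^2/s
    mean_mkt: float


def _check_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask values must be 0/1")
    return m.astype(bool)


def _check_same_grid(*masks):
    shapes = {np.asarray(m).shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks live on different grids: {sorted(shapes)}")


def _relabel_deterministic(labels: np.ndarray) -> np.ndarray:
    """Relabel components 1..K ordered by their lexicographically smallest voxel."""
    flat = labels.ravel(order="C")
    # first occurrence in C order == lexicographic minimum voxel index
    vals, first = np.unique(flat, return_index=True)
    keep = vals > 0
    vals, first = vals[keep], first[keep]
    if vals.size == 0:
        return labels
    order = vals[np.argsort(first, kind="stable")]
    remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    remap[order] = np.arange(1, len(order) + 1)
    return remap[labels]


def label_lesions(mask: np.ndarray, connectivity: int = 26):
    """Connected-component labeling of a binary lesion mask.

    Returns (labeled grid, component count).  Default 26-connectivity (full
    3-D neighbourhood, so corner contact merges); labels are assigned 1..K
    in lexicographic order of each component's smallest voxel index.
    """
    m = _check_binary(mask)
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }.get(connectivity)
    if structure is None:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labels, count = ndimage.label(m, structure=structure)
    return _relabel_deterministic(labels), int(count)


def filter_small_lesions(labels: np.ndarray, min_voxels: int = 10) -> np.ndarray:
    """Drop components with fewer than ``min_voxels`` voxels ("smaller than"
    is strict: a 10-voxel component survives the default floor of 10).
    Survivors are relabeled 1..K preserving the deterministic order."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.copy()
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep > 0]
    remap = np.zeros(len(counts), dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def subtract_masks(flair_mask, cel_mask, bh_mask) -> np.ndarray:
    """Residual FLAIR-L mask: flair AND NOT (CE-L OR BH).

    CE-L and BH are hyperintense on FLAIR/T2 as well, so they are removed
    from the FLAIR-L mask before the small-lesion filter is applied."""
    _check_same_grid(flair_mask, cel_mask, bh_mask)
    f = _check_binary(flair_mask)
    c = _check_binary(cel_mask)
    b = _check_binary(bh_mask)
    return (f & ~(c | b)).astype(np.uint8)


def consensus_mask(rater_a_mask, rater_b_mask) -> np.ndarray:
    """Voxelwise product (intersection) of two raters' binarized masks."""
    _check_same_grid(rater_a_mask, rater_b_mask)
    a = _check_binary(rater_a_mask)
    b = _check_binary(rater_b_mask)
    return (a & b).astype(np.uint8)


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); undefined (error) for two empty masks."""
    _check_same_grid(mask_a, mask_b)
    a = _check_binary(mask_a)
    b = _check_binary(mask_b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("Dice coefficient is undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / denom


def extract_lesion_values(
    maps: ParameterMaps,
    labels: np.ndarray,
    category: str,
    patient_id: str,
) -> list[LesionRecord]:
    """One record per labeled component: means over QC-valid voxels only.

    Components whose voxels are all QC-invalid are dropped with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.md_map.shape:
        raise ValueError("label grid does not match the parameter-map grid")
    n_comp = int(labels.max())
    if n_comp == 0:
        return []
    inside = labels > 0
    lab = labels[inside]
    counts = np.bincount(lab, minlength=n_comp + 1)
    valid = inside & maps.qc_mask
    lab_v = labels[valid]
    valid_counts = np.bincount(lab_v, minlength=n_comp + 1)
    md_sum = np.bincount(lab_v, weights=maps.md_map[valid], minlength=n_comp + 1)
    mkt_sum = np.bincount(lab_v, weights=maps.mkt_map[valid], minlength=n_comp + 1)

    records = []
    for lid in range(1, n_comp + 1):
        if counts[lid] == 0:
            continue
        if valid_counts[lid] == 0:
            logger.warning(
                "%s %s lesion %d: all %d voxels QC-invalid, dropped",
                patient_id, category, lid, counts[lid],
            )
            continue
        records.append(LesionRecord(
            patient_id=patient_id,
            lesion_id=lid,
            category=category,
            voxel_count=int(counts[lid]),
            valid_voxel_count=int(valid_counts[lid]),
            mean_md=float(md_sum[lid] / valid_counts[lid]),
            mean_mkt=float(mkt_sum[lid] / valid_counts[lid]),
        ))
    return records


def records_to_table(records) -> pd.DataFrame:
    """LesionTable: one row per lesion/ROI, the input of the statistics stage."""
    if not records:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    return pd.DataFrame([asdict(r) for r in records], columns=_TABLE_COLUMNS)


def write_lesion_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_lesion_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str})
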