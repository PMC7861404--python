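"""Synthetic multi-shell DWI cohort with a ground-truth ledger.

Emulates a single-center MS study: 37 relapsing-remitting MS patients and 11
healthy controls on one co-registered 2 mm isotropic grid.  Five tissue
categories are simulated -- healthy-control white matter (HC-WM), normal-
appearing white matter (NAWM), contrast-enhancing lesions (CE-L), FLAIR
lesions (FLAIR-L) and black holes (BH) -- each with a bivariate (MD, MKT)
distribution (truncated normal) whose means, SDs and MK-MD correlation are
the packaged defaults below.  Lesions are disjoint ellipsoids with a one-
voxel gap; white-matter ROIs are spheres, six per subject.  Each voxel of a
component carries its component's true isotropic tissue model, the forward
1-3-9 signal is evaluated per voxel, and Rician magnitude noise is added at
the configured SNR.  Everything is a pure function of (CohortSpec, seed).

The generator writes/reads the standard on-disk layout (NIfTI volumes,
FSL-dialect .bval/.bvec, TSV metadata) and records every component's true
parameters in a ledger for recovery tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dki import DWIStudy, KurtosisTissueModel, forward_signal
from .scheme import DiffusionScheme, build_139_scheme

__all__ = [
    "TissueClassSpec",
    "CohortSpec",
    "SubjectTruth",
    "Component",
    "GroundTruthLedger",
    "PlacementError",
    "default_class_specs",
    "default_cohort_spec",
    "sample_class_values",
    "sample_covariates",
    "place_lesions",
    "brain_mask_for",
    "components_to_mask",
    "generate_subject_dwi",
    "write_cohort",
    "read_cohort",
]


class PlacementError(RuntimeError):
    """Could not place all components without overlap; use a larger grid."""


@dataclass(frozen=True)
class TissueClassSpec:
    """Generating (MD, MKT) distribution and geometry for one tissue class."""

    category: str
    mkt_mean: float
    mkt_sd: float
    md_mean: float          # 10^-3 mm^2/s
    md_sd: float
    mkt_md_correlation: float
    lesion_count_total: int = 0          # cohort-wide; 0 for ROI classes
    lesion_radius_range: tuple = (1.5, 2.8)   # ellipsoid semi-axes, voxels

    def __post_init__(self):
        if self.mkt_sd <= 0 or self.md_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not -1 < self.mkt_md_correlation < 1:
            raise ValueError("correlation must lie in (-1, 1)")
        if self.lesion_count_total < 0:
            raise ValueError("lesion count must be non-negative")


def default_class_specs() -> dict:
    """Per-class generating distributions (packaged defaults).

    Means/SDs are the study conditions the cohort emulates: MKT and MD
    (10^-3 mm^2/s) per category, the within-class MK-MD correlation, and the
    cohort-wide lesion counts (30 CE-L, 832 FLAIR-L, 667 BH).
    """
    return {
        "HC-WM": TissueClassSpec("HC-WM", 0.814, 0.129, 0.747, 0.068, -0.35),
        "NAWM": TissueClassSpec("NAWM", 0.724, 0.137, 0.808, 0.163, -0.47),
        "CE-L": TissueClassSpec("CE-L", 0.619, 0.096, 0.853, 0.211, -0.42,
                                lesion_count_total=30,
                                lesion_radius_range=(1.8, 3.2)),
        "FLAIR-L": TissueClassSpec("FLAIR-L", 0.565, 0.123, 0.976, 0.350, -0.275,
                                   lesion_count_total=832,
                                   lesion_radius_range=(1.5, 2.8)),
        "BH": TissueClassSpec("BH", 0.549, 0.120, 0.957, 0.304, -0.203,
                              lesion_count_total=667,
                              lesion_radius_range=(1.5, 2.8)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full generator configuration; the cohort is a pure function of this."""

    seed: int
    n_patients: int = 37
    n_controls: int = 11
    shape: tuple = (98, 98, 98)
    voxel_size_mm: float = 2.0
    snr: float = 50.0                    # S0 / sigma at b0; inf = noise-free
    rois_per_subject: int = 6
    roi_radius: float = 2.5              # voxels
    n_cel_patients: int = 11             # patients carrying CE-L
    brain_radius: float = 40.0           # voxels
    background_md: float = 0.75          # brain tissue outside components
    background_mkt: float = 0.75
    s0: float = 1.0
    class_specs: dict = field(default_factory=default_class_specs)
    scheme: DiffusionScheme = field(default_factory=build_139_scheme)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory (reproducibility contract)")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (use inf for noise-free)")

    @property
    def sigma(self) -> float:
        return 0.0 if np.isinf(self.snr) else self.s0 / self.snr

    @property
    def subject_ids(self) -> list:
        return ([f"MS{i + 1:02d}" for i in range(self.n_patients)]
                + [f"HC{i + 1:02d}" for i in range(self.n_controls)])

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in asdict(self).items()
            if k not in ("class_specs", "scheme")
        }
        d["shape"] = list(self.shape)
        d["class_specs"] = {k: asdict(v) for k, v in self.class_specs.items()}
        for cs in d["class_specs"].values():
            cs["lesion_radius_range"] = list(cs["lesion_radius_range"])
        d["scheme"] = {"b1": self.scheme.b1, "b2": self.scheme.b2}
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def default_cohort_spec(seed: int = 42, **overrides) -> CohortSpec:
    return CohortSpec(seed=seed, **overrides)


def scaled_cohort_spec(seed: int, n_patients: int, n_controls: int,
                       **overrides) -> CohortSpec:
    """Smaller cohort with lesion totals scaled in proportion to the patient
    count (the per-patient lesion burden stays at the default level).  Meant
    for smoke tests and quick runs."""
    scale = n_patients / 37.0
    specs = {}
    for cat, cs in default_class_specs().items():
        total = int(round(cs.lesion_count_total * scale))
        if cs.lesion_count_total > 0 and n_patients > 0:
            total = max(total, 1)
        specs[cat] = TissueClassSpec(**{**asdict(cs), "lesion_count_total": total,
                                        "lesion_radius_range": cs.lesion_radius_range})
    n_cel = max(1, int(round(11 * scale)))
    return CohortSpec(seed=seed, n_patients=n_patients, n_controls=n_controls,
                      class_specs=specs, n_cel_patients=min(n_cel, n_patients),
                      **overrides)


@dataclass(frozen=True)
class Component:
    """One generated lesion or ROI: voxel coordinates plus true parameters."""

    category: str
    coords: np.ndarray      # (n_voxels, 3) int
    true_md: float
    true_mkt: float

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    @property
    def anchor(self) -> tuple:
        """Lexicographically smallest voxel; ties the component to its label."""
        idx = np.lexsort((self.coords[:, 2], self.coords[:, 1], self.coords[:, 0]))
        return tuple(int(c) for c in self.coords[idx[0]])


@dataclass
class SubjectTruth:
    subject_id: str
    is_patient: bool
    components: list        # of Component


@dataclass
class GroundTruthLedger:
    """True per-component parameters plus generator provenance."""

    entries: pd.DataFrame   # subject_id, category, component_id, true_md, true_mkt, ...
    sigma: float
    seed: int
    config_hash: str


# --- deterministic per-purpose random streams -------------------------------

def _rng(spec: CohortSpec, *salt: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, *salt])


# --- value sampling ----------------------------------------------------------

_TRUNC_SD = 3.0
_MD_FLOOR = 0.1
_MKT_FLOOR = 0.05


def sample_class_values(spec: TissueClassSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n (MD, MKT) pairs from the class's truncated bivariate normal.

    Truncation at +-3 SD per coordinate and at the physical floors
    MD > 0.1e-3 mm^2/s, MKT > 0.05; with the packaged class parameters the
    truncation is symmetric, so sample means match the spec means.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mean = np.array([spec.md_mean, spec.mkt_mean])
    cov = np.array([
        [spec.md_sd ** 2, spec.mkt_md_correlation * spec.md_sd * spec.mkt_sd],
        [spec.mkt_md_correlation * spec.md_sd * spec.mkt_sd, spec.mkt_sd ** 2],
    ])
    lo = np.maximum(mean - _TRUNC_SD * np.array([spec.md_sd, spec.mkt_sd]),
                    [_MD_FLOOR, _MKT_FLOOR])
    hi = mean + _TRUNC_SD * np.array([spec.md_sd, spec.mkt_sd])
    if np.any(lo >= hi):
        raise ValueError(f"infeasible truncation for class {spec.category}")
    out = np.empty((0, 2))
    for _ in range(200):
        draw = rng.multivariate_normal(mean, cov, size=max(n, 64))
        ok = np.all((draw > lo) & (draw < hi), axis=1)
        out = np.vstack([out, draw[ok]])
        if len(out) >= n:
            return out[:n]
    raise ValueError(f"truncated sampling failed for class {spec.category}")


def sample_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Per-subject metadata: age, disease duration, EDSS.

    Scaled-beta draws matched to the emulated study population: patient age
    18.6-64.9 y (median ~36), duration 4-22 y (mean ~6), EDSS 0-5.5 in 0.5
    steps (median ~2).  Controls carry age only.
    """
    rng = _rng(spec, 1_000_000)
    rows = []
    for sid in spec.subject_ids:
        is_patient = sid.startswith("MS")
        if is_patient:
            age = 18.6 + (64.9 - 18.6) * rng.beta(2.0, 3.0)
            duration = 4.0 + 18.0 * rng.beta(1.0, 8.0)
            edss = np.round(5.5 * rng.beta(1.5, 2.5) * 2.0) / 2.0
            rows.append({"patient_id": sid, "group": "MS", "age_years": age,
                         "disease_duration_years": duration, "edss": edss})
        else:
            age = 23.5 + (59.1 - 23.5) * rng.beta(2.0, 3.0)
            rows.append({"patient_id": sid, "group": "HC", "age_years": age,
                         "disease_duration_years": np.nan, "edss": np.nan})
    return pd.DataFrame(rows)


# --- geometry ----------------------------------------------------------------

def brain_mask_for(spec: CohortSpec) -> np.ndarray:
    """Spherical brain mask shared by every subject (one co-registered grid)."""
    center = (np.array(spec.shape) - 1) / 2.0
    grids = np.ogrid[:spec.shape[0], :spec.shape[1], :spec.shape[2]]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= spec.brain_radius ** 2


def _ellipsoid_offsets(semi_axes: np.ndarray) -> np.ndarray:
    """Integer offsets inside an axis-aligned ellipsoid centered at 0."""
    ext = np.floor(semi_axes).astype(int)
    rng_ = [np.arange(-e, e + 1) for e in ext]
    dx, dy, dz = np.meshgrid(*rng_, indexing="ij")
    inside = ((dx / semi_axes[0]) ** 2 + (dy / semi_axes[1]) ** 2
              + (dz / semi_axes[2]) ** 2) <= 1.0
    return np.column_stack([dx[inside], dy[inside], dz[inside]])


def _per_patient_counts(spec: CohortSpec) -> dict:
    """Distribute cohort-wide lesion counts over patients (exact totals)."""
    rng = _rng(spec, 1_000_001)
    n = spec.n_patients
    counts = {}
    for cat in ("CE-L", "FLAIR-L", "BH"):
        total = spec.class_specs[cat].lesion_count_total
        if n == 0:
            if total:
                raise ValueError(f"{total} {cat} lesions but no patients")
            counts[cat] = np.zeros(0, int)
        elif cat == "CE-L" and total > 0:
            k = min(spec.n_cel_patients, n, total)
            carriers = rng.choice(n, size=k, replace=False)
            per = np.zeros(n, int)
            per[carriers] += 1
            if total > k:
                per[carriers] += rng.multinomial(total - k, np.full(k, 1.0 / k))
            counts[cat] = per
        else:
            counts[cat] = rng.multinomial(total, np.full(n, 1.0 / n))
    return counts


_MAX_TRIES = 400


def _place_subject(spec: CohortSpec, subject_id: str, is_patient: bool,
                   lesion_counts: dict, rng: np.random.Generator) -> SubjectTruth:
    shape = np.array(spec.shape)
    center = (shape - 1) / 2.0
    occupied = np.zeros(spec.shape, bool)
    components = []

    def place(category: str, semi_axes: np.ndarray, min_voxels: int = 1):
        offsets = _ellipsoid_offsets(semi_axes)
        if len(offsets) < min_voxels:
            raise PlacementError(
                f"component of class {category} smaller than {min_voxels} voxels"
            )
        ext = np.abs(offsets).max(axis=0)
        max_r = float(np.linalg.norm(ext + 1))
        for _ in range(_MAX_TRIES):
            lo_c = np.ceil(center - spec.brain_radius + max_r).astype(int)
            hi_c = np.floor(center + spec.brain_radius - max_r).astype(int)
            c = rng.integers(lo_c, hi_c + 1)
            if np.linalg.norm(c - center) + max_r > spec.brain_radius:
                continue
            lo = c - ext - 1
            hi = c + ext + 2
            box = occupied[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            if box.any():
                continue
            box[...] = True    # reserve the dilated bounding box: >=1 voxel gap
            return c + offsets
        raise PlacementError(
            f"could not place a {category} component for {subject_id} after "
            f"{_MAX_TRIES} tries; increase the grid or reduce counts"
        )

    roi_cat = "NAWM" if is_patient else "HC-WM"
    todo = [(roi_cat, None)] * spec.rois_per_subject
    if is_patient:
        for cat in ("CE-L", "FLAIR-L", "BH"):
            todo += [(cat, spec.class_specs[cat].lesion_radius_range)] * lesion_counts.get(cat, 0)

    values = {}
    cat_counts = {}
    for cat, _ in todo:
        cat_counts[cat] = cat_counts.get(cat, 0) + 1
    for cat, k in cat_counts.items():
        values[cat] = list(sample_class_values(spec.class_specs[cat], k, rng))

    taken = {cat: 0 for cat in cat_counts}
    for cat, rr in todo:
        if rr is None:
            semi = np.full(3, spec.roi_radius)
        else:
            semi = rng.uniform(rr[0], rr[1], size=3)
        coords = place(cat, semi, min_voxels=10 if cat == "FLAIR-L" else 1)
        md, mkt = values[cat][taken[cat]]
        taken[cat] += 1
        components.append(Component(category=cat, coords=coords,
                                    true_md=float(md), true_mkt=float(mkt)))
    return SubjectTruth(subject_id=subject_id, is_patient=is_patient,
                        components=components)


def place_lesions(spec: CohortSpec):
    """Generate every subject's components and the ground-truth ledger.

    Deterministic given the spec (per-subject random streams are derived from
    the cohort seed).  Cohort-wide category totals match the spec exactly.
    """
    counts = _per_patient_counts(spec)
    subjects = []
    rows = []
    for i, sid in enumerate(spec.subject_ids):
        is_patient = sid.startswith("MS")
        lc = {cat: int(counts[cat][i]) for cat in counts} if is_patient else {}
        rng = _rng(spec, 2, i)
        st = _place_subject(spec, sid, is_patient, lc, rng)
        subjects.append(st)
        for comp in st.components:
            rows.append({
                "subject_id": sid,
                "category": comp.category,
                "true_md": comp.true_md,
                "true_mkt": comp.true_mkt,
                "n_voxels": comp.n_voxels,
                "anchor": comp.anchor,
            })
    entries = pd.DataFrame(rows)
    # component_id mirrors deterministic labeling order (lex-min anchor voxel)
    entries["_flat"] = [np.ravel_multi_index(a, spec.shape) for a in entries["anchor"]]
    entries = entries.sort_values(["subject_id", "category", "_flat"], kind="stable")
    entries["component_id"] = entries.groupby(["subject_id", "category"]).cumcount() + 1
    entries = entries.drop(columns="_flat").reset_index(drop=True)
    ledger = GroundTruthLedger(entries=entries, sigma=spec.sigma,
                               seed=spec.seed, config_hash=spec.config_hash)
    return subjects, ledger


def components_to_mask(components, shape, category: str | None = None) -> np.ndarray:
    """Render components (optionally one category) as a uint8 mask volume."""
    mask = np.zeros(shape, np.uint8)
    for comp in components:
        if category is None or comp.category == category:
            mask[tuple(comp.coords.T)] = 1
    return mask


# --- signal synthesis --------------------------------------------------------

def generate_subject_dwi(spec: CohortSpec, subject: SubjectTruth,
                         subject_index: int | None = None) -> DWIStudy:
    """Forward 1-3-9 signals for one subject plus Rician magnitude noise.

    Every component voxel carries its component's isotropic tissue model;
    brain voxels outside components carry the background model; voxels
    outside the brain have zero amplitude (pure noise).  With snr = inf the
    volumes equal the noise-free forward signals exactly.
    """
    if subject_index is None:
        subject_index = spec.subject_ids.index(subject.subject_id)
    scheme = spec.scheme
    shape = spec.shape
    nv = scheme.n_volumes

    brain = brain_mask_for(spec)
    bg_model = KurtosisTissueModel.isotropic(spec.background_md, spec.background_mkt, spec.s0)
    data = np.zeros((*shape, nv))
    data[brain] = forward_signal(bg_model, scheme)
    for comp in subject.components:
        model = KurtosisTissueModel.isotropic(comp.true_md, comp.true_mkt, spec.s0)
        data[tuple(comp.coords.T)] = forward_signal(model, scheme)

    sigma = spec.sigma
    if sigma > 0:
        rng = _rng(spec, 3, subject_index)
        e1 = rng.standard_normal(data.shape)
        e2 = rng.standard_normal(data.shape)
        data = np.hypot(data + sigma * e1, sigma * e2)

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    return DWIStudy(data=data, affine=affine, scheme=scheme,
                    sigma=sigma if sigma > 0 else 0.0,
                    subject_id=subject.subject_id,
                    log=[f"synthetic cohort seed={spec.seed} snr={spec.snr}"])


# --- on-disk layout ----------------------------------------------------------

def write_cohort(spec: CohortSpec, out_dir, force: bool = False,
                 subjects=None, ledger=None) -> Path:
    """Materialize the cohort: per-subject NIfTI + sidecars, cohort tables.

    Layout: ``<out>/sub-<id>/dwi.nii.gz`` (+ ``dwi.bval``, ``dwi.bvec``,
    ``mask_<category>.nii.gz``, ``mask_brain.nii.gz``), plus cohort-level
    ``patients.tsv``, ``ground_truth.json`` and ``config.yaml``.
    """
    import nibabel as nib

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    if subjects is None or ledger is None:
        subjects, ledger = place_lesions(spec)
    brain = brain_mask_for(spec)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])

    for i, subject in enumerate(subjects):
        sdir = out / f"sub-{subject.subject_id}"
        sdir.mkdir(exist_ok=True)
        study = generate_subject_dwi(spec, subject, subject_index=i)
        nib.save(nib.Nifti1Image(study.data.astype(np.float32), affine),
                 sdir / "dwi.nii.gz")
        np.savetxt(sdir / "dwi.bval", spec.scheme.bvals[None, :], fmt="%.1f")
        np.savetxt(sdir / "dwi.bvec", spec.scheme.bvecs.T, fmt="%.10f")
        nib.save(nib.Nifti1Image(brain.astype(np.uint8), affine),
                 sdir / "mask_brain.nii.gz")
        cats = sorted({c.category for c in subject.components})
        for cat in cats:
            mask = components_to_mask(subject.components, spec.shape, cat)
            name = cat.lower().replace("-", "")
            nib.save(nib.Nifti1Image(mask, affine), sdir / f"mask_{name}.nii.gz")

    sample_covariates(spec).to_csv(out / "patients.tsv", sep="\t", index=False)
    gt = {
        "seed": ledger.seed,
        "sigma": ledger.sigma,
        "config_hash": ledger.config_hash,
        "entries": ledger.entries.assign(
            anchor=ledger.entries["anchor"].map(list)
        ).to_dict(orient="records"),
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    (out / "config.yaml").write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))
    return out


def read_cohort_config(cohort_dir) -> CohortSpec:
    """Rebuild the CohortSpec from a written cohort's config.yaml."""
    d = yaml.safe_load((Path(cohort_dir) / "config.yaml").read_text())
    sch = d.pop("scheme", None)
    scheme = build_139_scheme(sch["b1"], sch["b2"]) if sch else build_139_scheme()
    class_specs = {}
    for k, cs in d.pop("class_specs").items():
        cs["lesion_radius_range"] = tuple(cs["lesion_radius_range"])
        class_specs[k] = TissueClassSpec(**cs)
    d["shape"] = tuple(d["shape"])
    return CohortSpec(class_specs=class_specs, scheme=scheme, **d)


def read_cohort(cohort_dir):
    """Read back a written cohort: (spec, metadata, ledger)."""
    cohort_dir = Path(cohort_dir)
    spec = read_cohort_config(cohort_dir)
    metadata = pd.read_csv(cohort_dir / "patients.tsv", sep="\t",
                           dtype={"patient_id": str})
    gt = json.loads((cohort_dir / "ground_truth.json").read_text())
    entries = pd.DataFrame(gt["entries"])
    if len(entries):
        entries["anchor"] = entries["anchor"].map(tuple)
    ledger = GroundTruthLedger(entries=entries, sigma=gt["sigma"],
                               seed=gt["seed"], config_hash=gt["config_hash"])
    return spec, metadata, ledger
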