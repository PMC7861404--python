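"""End-to-end orchestration: generate -> fit -> analyze.

The three stages mirror the study workflow: synthesize (or read) a cohort of
13-volume 1-3-9 DWI series with lesion/ROI masks, fit voxelwise MD and MKT
maps after Rice-floor preprocessing, extract per-lesion/ROI means, and run
the group-statistics stage (Kruskal-Wallis, Dunn's pairwise tests with
Bonferroni adjustment -- both the five-group and the pooled non-enhancing
variant -- Pearson MK-MD correlations per category, and the patient-
clustered multinomial logistic regression of lesion category).

``run_cohort`` streams subject by subject so a full 48-subject cohort never
holds more than one 4-D series in memory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .cohort import (CohortSpec, GroundTruthLedger, brain_mask_for,
                     components_to_mask, generate_subject_dwi, place_lesions,
                     sample_covariates)
from .dki import QCBounds, fit_parameter_maps, ParameterMaps
from .lesions import (CATEGORIES, extract_lesion_values, filter_small_lesions,
                      label_lesions, records_to_table, subtract_masks,
                      write_lesion_table)
from .preprocess import apply_preprocessing, default_preprocess_config
from .stats import (GroupSample, dunn_pairwise, fit_multinomial,
                    kruskal_wallis, pearson_r, pool_nonenhancing)

__all__ = [
    "PipelineResult",
    "analyze_subject_masks",
    "run_cohort",
    "class_means",
    "analyze_tables",
    "cmd_generate",
    "cmd_fit",
    "cmd_analyze",
]

logger = logging.getLogger(__name__)

GROUP_ORDER = list(CATEGORIES)
POOLED_ORDER = ["HC-WM", "NAWM", "CE-L", "NE-L"]


@dataclass
class PipelineResult:
    lesion_table: pd.DataFrame
    metadata: pd.DataFrame
    ledger: GroundTruthLedger
    sigma_estimates: dict = field(default_factory=dict)

    @property
    def merged(self) -> pd.DataFrame:
        """Lesion table joined with the patient covariates."""
        return self.lesion_table.merge(self.metadata, on="patient_id", how="left")


def analyze_subject_masks(
    maps: ParameterMaps,
    masks: dict,
    patient_id: str,
    min_flair_voxels: int = 10,
) -> list:
    """Mask algebra + extraction for one subject.

    CE-L and BH are subtracted from FLAIR-L before labeling; FLAIR-L
    components under the voxel floor are excluded; every category is then
    labeled (26-connectivity) and summarized per component.
    """
    shape = maps.md_map.shape
    zeros = np.zeros(shape, np.uint8)
    records = []
    if "FLAIR-L" in masks:
        flair = subtract_masks(masks["FLAIR-L"], masks.get("CE-L", zeros),
                               masks.get("BH", zeros))
        labels, _ = label_lesions(flair)
        labels = filter_small_lesions(labels, min_flair_voxels)
        records += extract_lesion_values(maps, labels, "FLAIR-L", patient_id)
    for cat in ("CE-L", "BH", "NAWM", "HC-WM"):
        if cat in masks:
            labels, _ = label_lesions(masks[cat])
            records += extract_lesion_values(maps, labels, cat, patient_id)
    return records


def run_cohort(
    spec: CohortSpec,
    preprocess_config: dict | None = None,
    qc_bounds: QCBounds | None = None,
) -> PipelineResult:
    """Full in-memory pipeline on a synthetic cohort.

    Generates each subject's DWI series, applies preprocessing (Rice-floor
    with background-estimated sigma by default), fits the 1-3-9 parameter
    maps and extracts the per-lesion/ROI records.  Deterministic given the
    spec.
    """
    subjects, ledger = place_lesions(spec)
    metadata = sample_covariates(spec)
    brain = brain_mask_for(spec)
    config = preprocess_config or default_preprocess_config()

    records = []
    sigma_estimates = {}
    for i, subject in enumerate(subjects):
        study = generate_subject_dwi(spec, subject, subject_index=i)
        study = apply_preprocessing(study, config, brain_mask=brain)
        maps = fit_parameter_maps(study, brain, qc_bounds)
        masks = {
            cat: components_to_mask(subject.components, spec.shape, cat)
            for cat in {c.category for c in subject.components}
        }
        records += analyze_subject_masks(maps, masks, subject.subject_id)
        for line in study.log:
            if line.startswith("rice_floor: sigma="):
                sigma_estimates[subject.subject_id] = float(
                    line.split("sigma=")[1].split()[0])
        logger.info("fitted %s (%d/%d)", subject.subject_id, i + 1, len(subjects))

    table = records_to_table(records)
    return PipelineResult(lesion_table=table, metadata=metadata, ledger=ledger,
                          sigma_estimates=sigma_estimates)


def class_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-category n / mean / SD of the per-lesion MKT and MD means."""
    rows = []
    for cat in GROUP_ORDER:
        sub = table[table["category"] == cat]
        if not len(sub):
            continue
        rows.append({
            "category": cat, "n": len(sub),
            "mkt_mean": sub["mean_mkt"].mean(), "mkt_sd": sub["mean_mkt"].std(ddof=1),
            "md_mean": sub["mean_md"].mean(), "md_sd": sub["mean_md"].std(ddof=1),
        })
    return pd.DataFrame(rows)


def _group_samples(table: pd.DataFrame, value_col: str, order) -> list:
    out = []
    for cat in order:
        sub = table[table["category"] == cat]
        if len(sub):
            out.append(GroupSample(cat, sub[value_col].to_numpy(),
                                   sub["patient_id"].to_numpy()))
    return out


def analyze_tables(table: pd.DataFrame, metadata: pd.DataFrame,
                   alpha: float = 0.05, cluster: str | None = "patient_id") -> dict:
    """Group-statistics stage on a lesion table; returns a JSON-able report."""
    if not len(table):
        raise ValueError("empty lesion table")
    report = {"groups": class_means(table).to_dict(orient="records")}

    for metric, col in (("mkt", "mean_mkt"), ("md", "mean_md")):
        groups = _group_samples(table, col, GROUP_ORDER)
        if len(groups) >= 2:
            kw = kruskal_wallis(groups)
            dunn = dunn_pairwise(groups, alpha=alpha)
            report[f"kruskal_{metric}"] = {"H": kw.statistic, "df": kw.df,
                                           "p": kw.pvalue}
            report[f"dunn_{metric}"] = dunn.to_dict(orient="records")
        by_cat = {g.label: g for g in groups}
        if "FLAIR-L" in by_cat and "BH" in by_cat:
            pooled = pool_nonenhancing(by_cat["FLAIR-L"], by_cat["BH"])
            pooled_groups = [by_cat[c] for c in POOLED_ORDER if c in by_cat] + [pooled]
            kw = kruskal_wallis(pooled_groups)
            report[f"kruskal_pooled_{metric}"] = {"H": kw.statistic, "df": kw.df,
                                                  "p": kw.pvalue}
            report[f"dunn_pooled_{metric}"] = dunn_pairwise(
                pooled_groups, alpha=alpha).to_dict(orient="records")
            report[f"nel_pooled_mean_{metric}"] = float(pooled.values.mean())

    pearson = {}
    for cat in GROUP_ORDER:
        sub = table[table["category"] == cat]
        if len(sub) >= 3 and sub["mean_mkt"].nunique() > 1 and sub["mean_md"].nunique() > 1:
            r, p = pearson_r(sub["mean_mkt"], sub["mean_md"])
            pearson[cat] = {"r": r, "p": p, "n": len(sub)}
    lesions_only = table[table["category"].isin(("CE-L", "FLAIR-L", "BH", "NAWM"))]
    if len(lesions_only) >= 3:
        r, p = pearson_r(lesions_only["mean_mkt"], lesions_only["mean_md"])
        pearson["overall"] = {"r": r, "p": p, "n": len(lesions_only)}
    report["pearson"] = pearson

    merged = table.merge(metadata, on="patient_id", how="left")
    model_rows = merged[merged["category"].isin(("NAWM", "CE-L", "BH", "FLAIR-L"))]
    if model_rows["category"].nunique() >= 2:
        try:
            fit = fit_multinomial(model_rows, cluster=cluster)
            report["multinomial_mkt"] = fit.table("mean_mkt").to_dict(orient="records")
            report["multinomial_md"] = fit.table("mean_md").to_dict(orient="records")
        except Exception as exc:  # report the failure, keep the rest of the stats
            logger.warning("multinomial fit failed: %s", exc)
            report["multinomial_error"] = str(exc)

    counts = table[table["category"].isin(("CE-L", "FLAIR-L", "BH"))]
    n_patients = metadata[metadata["group"] == "MS"]["patient_id"].nunique() \
        if "group" in metadata else table["patient_id"].nunique()
    report["lesion_totals"] = {
        "total": int(len(counts)),
        "per_category": counts["category"].value_counts().to_dict(),
        "mean_per_patient": float(len(counts) / n_patients) if n_patients else np.nan,
    }
    return report


# --- on-disk commands ---------------------------------------------------------

_MASK_NAMES = {"hcwm": "HC-WM", "nawm": "NAWM", "cel": "CE-L",
               "flairl": "FLAIR-L", "bh": "BH"}


def cmd_generate(spec: CohortSpec, out_dir, force: bool = False) -> Path:
    from .cohort import write_cohort
    return write_cohort(spec, out_dir, force=force)


def cmd_fit(cohort_dir, preprocess_config: dict | None = None,
            qc_bounds: QCBounds | None = None) -> list:
    """Fit MD/MKT/QC maps for every subject directory; per-subject failures
    are recorded and the run continues."""
    from .cohort import read_cohort_config

    cohort_dir = Path(cohort_dir)
    spec = read_cohort_config(cohort_dir)
    config = preprocess_config or default_preprocess_config()
    failures = []
    for sdir in sorted(cohort_dir.glob("sub-*")):
        sid = sdir.name.removeprefix("sub-")
        try:
            study = fio.load_dwi(sdir, spec.scheme, subject_id=sid)
            brain = fio.load_mask(sdir / "mask_brain.nii.gz").astype(bool)
            study = apply_preprocessing(study, config, brain_mask=brain)
            maps = fit_parameter_maps(study, brain, qc_bounds)
            fio.save_parameter_maps(maps, sdir, "maps")
            (sdir / "processing_log.json").write_text(json.dumps(study.log, indent=1))
        except Exception as exc:
            logger.error("subject %s failed: %s", sid, exc)
            failures.append((sid, str(exc)))
    return failures


def cmd_analyze(cohort_dir, out_dir=None, alpha: float = 0.05) -> dict:
    """Build the lesion table from fitted maps + masks, run the statistics
    stage and write ``stats_report.json`` plus TSV tables."""
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir) if out_dir else cohort_dir
    out.mkdir(parents=True, exist_ok=True)
    metadata = pd.read_csv(cohort_dir / "patients.tsv", sep="\t",
                           dtype={"patient_id": str})
    records = []
    for sdir in sorted(cohort_dir.glob("sub-*")):
        sid = sdir.name.removeprefix("sub-")
        maps = fio.load_parameter_maps(sdir, "maps")
        masks = {}
        for stem, cat in _MASK_NAMES.items():
            p = sdir / f"mask_{stem}.nii.gz"
            if p.exists():
                masks[cat] = fio.load_mask(p)
        records += analyze_subject_masks(maps, masks, sid)
    table = records_to_table(records)
    if not len(table):
        raise ValueError("empty lesion table: nothing to analyze")
    write_lesion_table(table, out / "lesion_table.tsv")
    report = analyze_tables(table, metadata, alpha=alpha)
    (out / "stats_report.json").write_text(json.dumps(report, indent=1, default=float))
    for key in ("dunn_mkt", "dunn_md", "multinomial_mkt", "multinomial_md"):
        if key in report:
            pd.DataFrame(report[key]).to_csv(out / f"{key}.tsv", sep="\t", index=False)
    pd.DataFrame(report["groups"]).to_csv(out / "group_means.tsv", sep="\t", index=False)
    return report
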