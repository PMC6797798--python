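"""End-to-end orchestration of the levelled curation workflow.

Level 0 (raw export) -> level 2 (plate scaled on reference pools) ->
level 3 (analyte filtered) -> level 4 (cohort rows, LOD/2 imputed,
exclusion-flagged) -> level 5 (flagged samples removed, replicates
averaged, PCA outliers removed, log2).  Every stage emits a
:class:`~metabocurate.datamodel.LevelArtifact` whose provenance records the
stage parameters and the parent matrix hash, so identical inputs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import curation
from .curation import OutlierParams
from .datamodel import ConcentrationMatrix, LevelArtifact, WellRole
from .filtering import FilterThresholds, apply_analyte_filters
from .io import write_level_artifact
from .scaling import apply_scale_factors, compute_scale_factors

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings, serializable to/from YAML.

    Presets: ``adni1`` checks fasting, BMI and medication records;
    ``adnigo2`` checks fasting only (its cohort had complete BMI/medication
    coverage at baseline).
    """

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    outliers: OutlierParams = field(default_factory=OutlierParams)
    preset: str = "adni1"
    reference_role: str = WellRole.NIST.value
    check_fasting: bool = True
    check_bmi: bool = True
    check_medication: bool = True
    #: screen PCA outliers on log2-scale values (concentrations are
    #: log-normal; an SD-based rule needs roughly symmetric scores)
    pca_after_log2: bool = True
    on_missing_reference: str = "warn"
    seed: int = 0

    @classmethod
    def for_preset(cls, preset: str, **overrides) -> "PipelineConfig":
        if preset == "adni1":
            base = cls(preset="adni1")
        elif preset == "adnigo2":
            base = cls(preset="adnigo2", check_bmi=False, check_medication=False)
        elif preset == "custom":
            base = cls(preset="custom")
        else:
            raise ValueError(f"unknown preset {preset!r}")
        return dataclasses.replace(base, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = FilterThresholds(**d["thresholds"])
        if "outliers" in d:
            d["outliers"] = OutlierParams(**d["outliers"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        preset = d.pop("preset", "custom")
        base = cls.for_preset(preset).to_dict()
        base.update(d)
        base["preset"] = preset
        return cls.from_dict(base)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineResult:
    artifacts: dict[int, LevelArtifact]
    summary: dict

    def matrix(self, level: int) -> ConcentrationMatrix:
        return self.artifacts[level].matrix


def run_pipeline(
    matrix: ConcentrationMatrix,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute scaling, filtering, imputation, exclusion and finalization.

    ``matrix`` is a level-0 matrix with annotations attached (QC wells
    included — they drive the scaling).  When ``out_dir`` is given, every
    level artifact plus a ``run_summary.json`` is written there.
    """
    config = config or PipelineConfig()
    t0 = time.monotonic()
    artifacts: dict[int, LevelArtifact] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    # ---- level 2: plate scaling ------------------------------------------
    _stage("plate scaling")
    try:
        factors = compute_scale_factors(
            matrix, config.reference_role, config.on_missing_reference
        )
        m2 = apply_scale_factors(matrix, factors)
    except Exception as e:
        raise RuntimeError(f"plate scaling failed: {e}") from e
    artifacts[2] = LevelArtifact(
        matrix=m2,
        reports={"scale_factors": factors.to_frame()},
        provenance={
            "stage": "plate_scaling",
            "reference_role": config.reference_role,
            "parent_hash": matrix.content_hash(),
        },
    )

    # ---- level 3: analyte filters ----------------------------------------
    _stage("analyte filtering")
    try:
        m3, filter_report = apply_analyte_filters(m2, config.thresholds)
    except Exception as e:
        raise RuntimeError(f"analyte filtering failed: {e}") from e
    if m3.values.shape[1] == 0:
        logger.warning("no analytes survived filtering")
    artifacts[3] = LevelArtifact(
        matrix=m3,
        reports={"filter_report": filter_report},
        provenance={
            "stage": "analyte_filtering",
            "thresholds": dataclasses.asdict(config.thresholds),
            "parent_hash": m2.content_hash(),
        },
    )

    # ---- level 4: cohort rows, imputation, exclusion flags ----------------
    _stage("imputation and exclusion flagging")
    try:
        cohort_ids = m3.samples.index[m3.cohort_mask()]
        m4 = m3.subset_samples(cohort_ids)
        m4 = curation.impute_below_lod(m4)
        m4.level = 4
        m4.validate()
        exclusion_report = curation.flag_sample_exclusions(
            m4.samples,
            check_fasting=config.check_fasting,
            check_bmi=config.check_bmi,
            check_medication=config.check_medication,
        )
    except Exception as e:
        raise RuntimeError(f"imputation/exclusion flagging failed: {e}") from e
    artifacts[4] = LevelArtifact(
        matrix=m4,
        reports={"exclusion_report": exclusion_report},
        provenance={
            "stage": "imputation_and_flags",
            "checks": {
                "fasting": config.check_fasting,
                "bmi": config.check_bmi,
                "medication": config.check_medication,
            },
            "parent_hash": m3.content_hash(),
        },
    )

    # ---- level 5: exclusion, averaging, PCA screen, log2 ------------------
    _stage("finalization")
    try:
        # a flagged member excludes the whole subject
        flagged_subjects = set(
            m4.samples.loc[exclusion_report.index[exclusion_report["excluded"]], "subject_id"]
        )
        keep = m4.samples.index[~m4.samples["subject_id"].isin(flagged_subjects)]
        m5 = m4.subset_samples(keep)
        n_after_exclusion = len(m5.sample_ids)
        m5 = curation.average_blinded_replicates(m5)
        n_subjects_before_pca = len(m5.sample_ids)

        if config.pca_after_log2:
            pca_input = curation.log2_transform(m5)
        else:
            pca_input = m5
        pca_report = curation.detect_pca_outliers(pca_input, config.outliers)
        pca_out = set(pca_report.index[pca_report[curation.PCA_OUTLIER]])
        m5 = m5.subset_samples([s for s in m5.sample_ids if s not in pca_out])
        m5 = curation.log2_transform(m5)
        m5.level = 5
        m5.validate()
    except Exception as e:
        raise RuntimeError(f"finalization failed: {e}") from e
    artifacts[5] = LevelArtifact(
        matrix=m5,
        reports={"pca_outliers": pca_report},
        provenance={
            "stage": "finalization",
            "outlier_params": dataclasses.asdict(config.outliers),
            "pca_after_log2": config.pca_after_log2,
            "parent_hash": m4.content_hash(),
        },
    )

    # ---- summary -----------------------------------------------------------
    reason_cols = [
        curation.NON_FASTING, curation.MISSING_BMI, curation.MISSING_MEDICATION_RECORD,
    ]
    summary = {
        "config": config.to_dict(),
        "levels": {
            "0": {"samples": len(matrix.sample_ids), "analytes": len(matrix.analyte_ids)},
            "2": {"samples": len(m2.sample_ids), "analytes": len(m2.analyte_ids)},
            "3": {"samples": len(m3.sample_ids), "analytes": len(m3.analyte_ids)},
            "4": {
                "samples": len(m4.sample_ids),
                "subjects": int(m4.samples["subject_id"].nunique()),
                "analytes": len(m4.analyte_ids),
            },
            "5": {"subjects": len(m5.sample_ids), "analytes": len(m5.analyte_ids)},
        },
        "exclusions": {
            **{c: int(exclusion_report[c].sum()) for c in reason_cols},
            "samples_excluded_metadata": int(exclusion_report["excluded"].sum()),
            "subjects_excluded_metadata": len(flagged_subjects),
            "pca_outliers": len(pca_out),
            "samples_after_metadata_exclusion": n_after_exclusion,
            "subjects_before_pca": n_subjects_before_pca,
        },
        "filters": {
            "analytes_in": len(m2.analyte_ids),
            "analytes_retained": len(m3.analyte_ids),
            "failure_histogram": _failure_histogram(filter_report),
        },
        "seed": config.seed,
        "wall_time_s": round(time.monotonic() - t0, 3),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for art in artifacts.values():
            write_level_artifact(art, out_dir)
        (out_dir / "run_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return PipelineResult(artifacts=artifacts, summary=summary)


def _failure_histogram(filter_report: pd.DataFrame) -> dict[str, int]:
    hist: dict[str, int] = {}
    for reasons in filter_report["failure_reasons"]:
        if reasons:
            for r in reasons.split(";"):
                hist[r] = hist.get(r, 0) + 1
    return hist
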