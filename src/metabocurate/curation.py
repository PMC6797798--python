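"""Sample-level curation: imputation, exclusions, averaging, PCA screening, log2.

Censored (below-LOD) cells are replaced by half the plate-specific limit of
detection — the conventional substitution for left-censored targeted-assay
concentrations.  Metadata-based exclusions (non-fasting draw, missing BMI,
missing medication record) are *flagged* first and physically removed only
at the final level, so the flagged intermediate table remains available.
Blinded replicate injections are averaged to one row per subject, a PCA
screen removes gross multivariate outliers (any selected component score
further than ``sd_cutoff`` SDs from that component's mean, components
chosen as the smallest leading set explaining more than
``cum_var_threshold`` of the variance), and values move to log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import ConcentrationMatrix, MeasurementFlag, WellRole

__all__ = [
    "OutlierParams",
    "impute_below_lod",
    "flag_sample_exclusions",
    "average_blinded_replicates",
    "detect_pca_outliers",
    "log2_transform",
    "NON_FASTING",
    "MISSING_BMI",
    "MISSING_MEDICATION_RECORD",
    "PCA_OUTLIER",
]

logger = logging.getLogger(__name__)

NON_FASTING = "NON_FASTING"
MISSING_BMI = "MISSING_BMI"
MISSING_MEDICATION_RECORD = "MISSING_MEDICATION_RECORD"
PCA_OUTLIER = "PCA_OUTLIER"


@dataclass(frozen=True)
class OutlierParams:
    """PCA outlier screen settings.

    ``cum_var_threshold``: keep the smallest leading set of components whose
    cumulative explained-variance fraction strictly exceeds it (minimum 1).
    ``sd_cutoff``: how many SDs from the mean a subject must lie to be
    flagged.  With ``method="mahalanobis"`` (default) the distance is the
    Mahalanobis distance within the selected-component subspace (each score
    standardized by its own SD), which is invariant to how variance splits
    across near-degenerate components; ``method="per_component"`` instead
    flags a subject whose score on any single selected component deviates
    by more than ``sd_cutoff`` score-SDs.  The per-component reading is
    simpler but provably misses moderate outliers whose direction mixes
    into the sampling noise of the leading eigenvalues.
    """

    cum_var_threshold: float = 0.90
    sd_cutoff: float = 7.0
    standardize: bool = True
    method: str = "mahalanobis"

    def validate(self) -> None:
        if not 0 < self.cum_var_threshold <= 1:
            raise ValueError("cum_var_threshold must lie in (0, 1]")
        if not self.sd_cutoff > 0:
            raise ValueError("sd_cutoff must be > 0")
        if self.method not in ("mahalanobis", "per_component"):
            raise ValueError(f"unknown outlier method {self.method!r}")


def impute_below_lod(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Replace every BELOW_LOD cell by its plate-analyte LOD/2.

    Flags are kept as provenance; the cell value becomes usable.  Raises if
    a censored cell has no LOD defined for its (analyte, plate).
    """
    out = matrix.copy()
    lod_by_analyte = {a.analyte_id: a.lod for a in matrix.analytes}
    flg = matrix.flags.to_numpy()
    below = flg == MeasurementFlag.BELOW_LOD.value
    if not below.any():
        return out
    plates = matrix.samples["plate_id"].to_numpy()
    vals = out.values.to_numpy()
    missing_lod = []
    rows, cols = np.nonzero(below)
    for i, j in zip(rows, cols):
        analyte = matrix.analyte_ids[j]
        lod = lod_by_analyte[analyte].get(plates[i])
        if lod is None:
            missing_lod.append((matrix.sample_ids[i], analyte))
        else:
            vals[i, j] = lod / 2.0
    if missing_lod:
        raise ValueError(
            f"no LOD defined for {len(missing_lod)} censored cell(s), "
            f"e.g. {missing_lod[:5]}"
        )
    out.values = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return out


def flag_sample_exclusions(
    annotations: pd.DataFrame,
    check_fasting: bool = True,
    check_bmi: bool = True,
    check_medication: bool = True,
) -> pd.DataFrame:
    """Metadata exclusion flags for cohort samples (rows are kept, not removed).

    Returns an ExclusionReport DataFrame indexed by sample_id with boolean
    reason columns, ``excluded``, a ``reasons`` string and
    ``flagged_at_level`` = 4.
    """
    cohort = annotations[annotations["well_role"] == WellRole.COHORT.value]
    rep = pd.DataFrame(index=cohort.index.copy())
    rep[NON_FASTING] = ~cohort["is_fasting"] if check_fasting else False
    rep[MISSING_BMI] = ~cohort["has_bmi"] if check_bmi else False
    rep[MISSING_MEDICATION_RECORD] = (
        ~cohort["has_medication_record"] if check_medication else False
    )
    rep["excluded"] = rep[[NON_FASTING, MISSING_BMI, MISSING_MEDICATION_RECORD]].any(axis=1)
    rep["reasons"] = [
        ";".join(
            r for r in (NON_FASTING, MISSING_BMI, MISSING_MEDICATION_RECORD) if rep.at[s, r]
        )
        for s in rep.index
    ]
    rep["flagged_at_level"] = 4
    rep.index.name = "sample_id"
    return rep


def average_blinded_replicates(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Collapse blinded replicate injections to one row per subject.

    Values are arithmetic means per analyte; singleton subjects pass
    through.  All values must already be imputed (no censored NaNs).  The
    result is indexed by subject_id; per-injection fields (plate, well,
    injection order) are dropped as they no longer describe a single row.
    """
    ann = matrix.samples
    groups = ann[ann["replicate_group_id"].notna()].groupby("replicate_group_id")
    for gid, members in groups:
        if members["subject_id"].nunique() != 1:
            raise ValueError(
                f"replicate group {gid!r} spans subjects "
                f"{sorted(members['subject_id'].unique())}"
            )
    if matrix.values.isna().to_numpy().any():
        raise ValueError("matrix still contains missing values; impute before averaging")

    subj = ann["subject_id"]
    values = matrix.values.groupby(subj.to_numpy()).mean()
    # keep first-seen subject order
    order = list(dict.fromkeys(subj))
    values = values.loc[order]
    values.index.name = "subject_id"
    flags = pd.DataFrame(
        MeasurementFlag.VALID.value, index=values.index, columns=values.columns
    )
    meta = ann.groupby(subj.to_numpy()).agg(
        is_fasting=("is_fasting", "all"),
        has_bmi=("has_bmi", "all"),
        has_medication_record=("has_medication_record", "all"),
        n_injections=("subject_id", "size"),
    ).loc[order]
    samples = pd.DataFrame(index=values.index)
    samples["subject_id"] = samples.index
    samples["plate_id"] = "pooled"
    samples["well_role"] = WellRole.COHORT.value
    samples["injection_order"] = np.arange(1, len(samples) + 1)
    samples["replicate_group_id"] = None
    for c in ("is_fasting", "has_bmi", "has_medication_record"):
        samples[c] = meta[c]
    out = ConcentrationMatrix(
        values=values, flags=flags, samples=samples, analytes=list(matrix.analytes),
        level=matrix.level,
    )
    out.validate()
    return out


def detect_pca_outliers(
    matrix: ConcentrationMatrix, params: OutlierParams | None = None
) -> pd.DataFrame:
    """Flag multivariate outliers on leading principal components.

    Analytes are standardized (mean 0, SD 1) when ``params.standardize``;
    components are then computed and the smallest leading set whose
    cumulative explained variance strictly exceeds ``cum_var_threshold`` is
    screened.  A row is flagged when its distance from the score mean
    exceeds ``sd_cutoff`` SDs — Mahalanobis distance over the selected
    subspace by default, or the largest single-component z under
    ``method="per_component"``.

    Returns a DataFrame indexed like the matrix rows with columns
    ``distance`` (the screened statistic), ``max_abs_z`` (largest
    single-component z, for reference) and boolean ``PCA_OUTLIER``.
    """
    params = params or OutlierParams()
    params.validate()
    X = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("PCA screening needs >= 3 rows and >= 2 analytes")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute before PCA screening")

    report = pd.DataFrame(index=matrix.values.index.copy())
    report["distance"] = 0.0
    report["max_abs_z"] = 0.0
    report[PCA_OUTLIER] = False
    report.index.name = matrix.values.index.name or "sample_id"

    sd = X.std(axis=0, ddof=1)
    if params.standardize:
        keep = sd > 0
        if not keep.any():
            logger.warning("zero total variance; no components selectable")
            return report
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    elif np.allclose(sd, 0):
        logger.warning("zero total variance; no components selectable")
        return report

    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, params.cum_var_threshold, side="right")) + 1
    k = min(max(k, 1), scores.shape[1])

    sel = scores[:, :k]
    mean = sel.mean(axis=0)
    ssd = sel.std(axis=0, ddof=1)
    ssd = np.where(ssd > 0, ssd, np.inf)
    z = np.abs(sel - mean) / ssd
    report["max_abs_z"] = z.max(axis=1)
    if params.method == "mahalanobis":
        report["distance"] = np.sqrt(np.sum(z**2, axis=1))
    else:
        report["distance"] = report["max_abs_z"]
    report[PCA_OUTLIER] = report["distance"] > params.sd_cutoff
    return report


def log2_transform(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Replace every value by its base-2 logarithm (values must be > 0)."""
    vals = matrix.values.to_numpy(dtype=float)
    bad = ~(vals > 0)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [
            (matrix.sample_ids[i], matrix.analyte_ids[j]) for i, j in zip(rows, cols)
        ][:5]
        raise ValueError(f"non-positive value(s) at {cells} — cannot log2 transform")
    out = matrix.copy()
    out.values = pd.DataFrame(
        np.log2(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    return out
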