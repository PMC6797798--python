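"""Analyte quality filters driven by blinded replicates and censoring.

Three deterministic per-analyte criteria decide retention (level 2 -> 3):

* replicate coefficient of variation strictly below ``cv_max`` (default
  30%), where each blinded duplicate/triplicate group contributes
  CV = sample SD / mean and groups are aggregated (mean by default);
* one-way random-effects intraclass correlation strictly above ``icc_min``
  (default 0.6), from the ANOVA decomposition
  ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW) with the standard unbalanced
  correction k0 = (N - sum(k_i^2)/N) / (g - 1);
* fraction of cohort measurements below the limit of detection at most
  ``lod_frac_max`` (an analyte fails only when strictly above 40% by
  default).

The inequality directions are strict as stated: an analyte sitting exactly
at ICC = 0.6 fails, one at exactly 40% censoring passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ConcentrationMatrix, MeasurementFlag

__all__ = [
    "FilterThresholds",
    "compute_replicate_cv",
    "compute_replicate_icc",
    "compute_lod_fraction",
    "apply_analyte_filters",
    "oneway_icc",
]

#: failure reason codes
NO_REPLICATES = "NO_REPLICATES"
DEGENERATE = "DEGENERATE"
HIGH_CV = "HIGH_CV"
LOW_ICC = "LOW_ICC"
HIGH_LOD_FRACTION = "HIGH_LOD_FRACTION"


@dataclass(frozen=True)
class FilterThresholds:
    cv_max: float = 0.30
    icc_min: float = 0.60
    lod_frac_max: float = 0.40
    cv_aggregation: str = "mean"        # mean | median | rms over replicate groups
    icc_lod_policy: str = "half_lod"    # half_lod | exclude_group

    def validate(self) -> None:
        if not self.cv_max > 0:
            raise ValueError("cv_max must be > 0")
        if not -1 < self.icc_min <= 1:
            raise ValueError("icc_min must lie in (-1, 1]")
        if not 0 <= self.lod_frac_max <= 1:
            raise ValueError("lod_frac_max must lie in [0, 1]")
        if self.cv_aggregation not in ("mean", "median", "rms"):
            raise ValueError(f"unknown cv_aggregation {self.cv_aggregation!r}")
        if self.icc_lod_policy not in ("half_lod", "exclude_group"):
            raise ValueError(f"unknown icc_lod_policy {self.icc_lod_policy!r}")


def _replicate_values(
    matrix: ConcentrationMatrix,
    analyte: str,
    impute_half_lod: bool,
    valid_only: bool = False,
) -> list[np.ndarray]:
    """Per replicate group, the usable values of one analyte.

    VALID values always count.  With ``valid_only`` (the CV rule) nothing
    else does; otherwise BELOW_LLOQ cells contribute their reported number
    and, when ``impute_half_lod``, BELOW_LOD cells contribute their plate's
    LOD/2.
    """
    ann = matrix.samples
    grouped = ann[ann["replicate_group_id"].notna()].groupby("replicate_group_id")
    adef = {a.analyte_id: a for a in matrix.analytes}[analyte]
    out = []
    for _, members in grouped:
        vals = []
        for sid in members.index:
            flag = matrix.flags.at[sid, analyte]
            v = matrix.values.at[sid, analyte]
            if flag == MeasurementFlag.VALID.value:
                if not np.isnan(v):
                    vals.append(float(v))
            elif valid_only:
                continue
            elif flag == MeasurementFlag.BELOW_LOD.value:
                if impute_half_lod:
                    lod = adef.lod.get(members.at[sid, "plate_id"])
                    if lod is not None:
                        vals.append(lod / 2.0)
            elif not np.isnan(v):
                vals.append(float(v))
        out.append(np.asarray(vals, dtype=float))
    return out


def compute_replicate_cv(
    matrix: ConcentrationMatrix, aggregation: str = "mean"
) -> pd.Series:
    """Per-analyte replicate CV (NaN where no usable group exists).

    Each blinded group with >= 2 VALID values contributes
    CV = sample SD (ddof=1) / mean; the per-analyte statistic aggregates the
    group CVs (``mean``, ``median`` or ``rms``).
    """
    out = {}
    for a in matrix.analyte_ids:
        cvs = []
        for vals in _replicate_values(matrix, a, impute_half_lod=False, valid_only=True):
            if len(vals) >= 2 and vals.mean() != 0:
                cvs.append(vals.std(ddof=1) / vals.mean())
        if not cvs:
            out[a] = np.nan
        elif aggregation == "mean":
            out[a] = float(np.mean(cvs))
        elif aggregation == "median":
            out[a] = float(np.median(cvs))
        elif aggregation == "rms":
            out[a] = float(np.sqrt(np.mean(np.square(cvs))))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return pd.Series(out, name="cv")


def oneway_icc(groups: list[np.ndarray]) -> float:
    """One-way random-effects ICC from between/within mean squares.

    Groups with fewer than 2 values are dropped.  Returns NaN when fewer
    than 2 groups remain or when the design is degenerate (MSB = MSW = 0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
    g = len(groups)
    if g < 2:
        return np.nan
    ks = np.array([len(x) for x in groups])
    n = ks.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([x.mean() for x in groups])
    ssb = float(np.sum(ks * (means - grand) ** 2))
    ssw = float(sum(np.sum((x - x.mean()) ** 2) for x in groups))
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    if msb == 0 and msw == 0:
        return np.nan
    k0 = (n - np.sum(ks**2) / n) / (g - 1)
    return (msb - msw) / (msb + (k0 - 1) * msw)


def compute_replicate_icc(
    matrix: ConcentrationMatrix, icc_lod_policy: str = "half_lod"
) -> pd.Series:
    """Per-analyte one-way ICC over blinded replicate groups.

    ``icc_lod_policy`` controls censored members: ``half_lod`` substitutes
    LOD/2 so the group stays usable, ``exclude_group`` keeps only fully
    observed values (groups dropping below 2 members are skipped).
    """
    if icc_lod_policy not in ("half_lod", "exclude_group"):
        raise ValueError(f"unknown icc_lod_policy {icc_lod_policy!r}")
    impute = icc_lod_policy == "half_lod"
    out = {}
    for a in matrix.analyte_ids:
        groups = _replicate_values(matrix, a, impute_half_lod=impute)
        out[a] = oneway_icc(groups)
    return pd.Series(out, name="icc")


def compute_lod_fraction(matrix: ConcentrationMatrix) -> pd.Series:
    """Per-analyte fraction of COHORT cells flagged BELOW_LOD."""
    cohort = matrix.cohort_mask().to_numpy()
    if cohort.sum() == 0:
        raise ValueError("matrix has no cohort rows")
    flg = matrix.flags[cohort]
    return (flg == MeasurementFlag.BELOW_LOD.value).mean(axis=0).rename("lod_fraction")


def apply_analyte_filters(
    matrix: ConcentrationMatrix, thresholds: FilterThresholds | None = None
) -> tuple[ConcentrationMatrix, pd.DataFrame]:
    """Drop failing analytes (level 3) and report every input analyte.

    Returns the filtered matrix (column order preserved) and a FilterReport
    DataFrame indexed by analyte with columns ``cv``, ``icc``,
    ``lod_fraction``, ``pass_cv``, ``pass_icc``, ``pass_lod``, ``retained``,
    ``failure_reasons``.
    """
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    cv = compute_replicate_cv(matrix, thresholds.cv_aggregation)
    icc = compute_replicate_icc(matrix, thresholds.icc_lod_policy)
    lodf = compute_lod_fraction(matrix)

    report = pd.DataFrame({"cv": cv, "icc": icc, "lod_fraction": lodf})
    report.index.name = "analyte"
    report["pass_cv"] = cv.notna() & (cv < thresholds.cv_max)
    report["pass_icc"] = icc.notna() & (icc > thresholds.icc_min)
    report["pass_lod"] = lodf <= thresholds.lod_frac_max
    report["retained"] = report[["pass_cv", "pass_icc", "pass_lod"]].all(axis=1)

    reasons = []
    for a in report.index:
        r = []
        if not report.at[a, "pass_cv"]:
            r.append(NO_REPLICATES if np.isnan(cv[a]) else HIGH_CV)
        if not report.at[a, "pass_icc"]:
            r.append(DEGENERATE if np.isnan(icc[a]) else LOW_ICC)
        if not report.at[a, "pass_lod"]:
            r.append(HIGH_LOD_FRACTION)
        reasons.append(";".join(r))
    report["failure_reasons"] = reasons

    keep = list(report.index[report["retained"]])
    out = matrix.subset_analytes(keep, level=3)
    out.validate()
    return out, report
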