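"""Shared data model for the levelled curation pipeline.

A :class:`ConcentrationMatrix` is a samples x analytes table of quantitative
concentrations (µM) in which every cell carries a :class:`MeasurementFlag`
recording whether the value is a trusted measurement (``VALID``), censored
below the limit of detection (``BELOW_LOD``), below the lowest calibration
standard (``BELOW_LLOQ``), or absent (``MISSING``).  Sample annotations
(plate, well role, blinded-replicate grouping, fasting/BMI/medication
metadata) ride along as a pandas DataFrame aligned to the value rows, and
per-analyte LOD/LLOQ definitions as :class:`AnalyteDef` objects aligned to
the columns.

The ``level`` tag follows the curation workflow: 0 = raw export, 2 = plate
scaled, 3 = analyte filtered, 4 = imputed with exclusion flags attached,
5 = analysis-ready (one row per subject, log2 scale).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementFlag",
    "WellRole",
    "SampleRecord",
    "AnalyteDef",
    "ConcentrationMatrix",
    "LevelArtifact",
    "ANNOTATION_COLUMNS",
    "lod_table",
]


class MeasurementFlag(str, Enum):
    """Per-cell measurement status."""

    VALID = "VALID"
    BELOW_LOD = "BELOW_LOD"
    BELOW_LLOQ = "BELOW_LLOQ"
    MISSING = "MISSING"


class WellRole(str, Enum):
    """Role of a well on the 96-well preparation plate.

    Only ``COHORT`` wells enter cohort statistics; ``NIST`` wells anchor the
    cross-plate scaling; the remaining roles are carried for layout fidelity.
    """

    COHORT = "COHORT"
    SPQC = "SPQC"
    NIST = "NIST"
    GOLDENWEST = "GOLDENWEST"
    QC_LOW = "QC_LOW"
    QC_MID = "QC_MID"
    QC_HIGH = "QC_HIGH"
    BLANK = "BLANK"
    ZERO = "ZERO"
    CALIBRATOR = "CALIBRATOR"


#: Columns of the sample-annotation table, in canonical order.
ANNOTATION_COLUMNS = [
    "subject_id",
    "plate_id",
    "well_role",
    "injection_order",
    "replicate_group_id",
    "is_fasting",
    "has_bmi",
    "has_medication_record",
]


@dataclass(frozen=True)
class SampleRecord:
    """Annotation for a single injection.

    ``sample_id`` identifies the injection; blinded replicates of one serum
    draw share ``subject_id`` and ``replicate_group_id`` while carrying
    distinct sample ids.
    """

    sample_id: str
    subject_id: str
    plate_id: str
    well_role: WellRole
    injection_order: int
    replicate_group_id: str | None = None
    is_fasting: bool = True
    has_bmi: bool = True
    has_medication_record: bool = True


@dataclass(frozen=True)
class AnalyteDef:
    """Analyte identity plus its detection limits.

    ``lod`` maps plate id -> limit of detection (µM); LODs are plate
    specific because instrument sensitivity varies between batches.
    ``lloq`` is the per-analyte lower limit of quantification (µM).
    """

    analyte_id: str
    lod: Mapping[str, float] = field(default_factory=dict)
    lloq: float | None = None

    def __post_init__(self) -> None:
        for plate, v in self.lod.items():
            if not v > 0:
                raise ValueError(
                    f"analyte {self.analyte_id!r}: LOD for plate {plate!r} must be > 0"
                )


def lod_table(analytes: Iterable[AnalyteDef], plates: Iterable[str]) -> pd.DataFrame:
    """Assemble a plates x analytes table of LODs (NaN where undefined)."""
    plates = list(plates)
    cols = {}
    for a in analytes:
        cols[a.analyte_id] = [a.lod.get(p, np.nan) for p in plates]
    return pd.DataFrame(cols, index=pd.Index(plates, name="plate_id"))


def _records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "subject_id": r.subject_id,
                "plate_id": r.plate_id,
                "well_role": WellRole(r.well_role).value,
                "injection_order": r.injection_order,
                "replicate_group_id": r.replicate_group_id,
                "is_fasting": r.is_fasting,
                "has_bmi": r.has_bmi,
                "has_medication_record": r.has_medication_record,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class ConcentrationMatrix:
    """Samples x analytes quantitative table with per-cell flags.

    Parameters
    ----------
    values
        Float DataFrame (µM), indexed by sample_id with analyte columns.
        Cells without a trusted number (censored before imputation, missing)
        hold NaN.
    flags
        Same-shaped DataFrame of :class:`MeasurementFlag` string codes.
    samples
        Annotation DataFrame indexed by sample_id with
        :data:`ANNOTATION_COLUMNS`; row order matches ``values``.
    analytes
        One :class:`AnalyteDef` per column, in column order.
    level
        Pipeline level tag (0–5).
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    samples: pd.DataFrame
    analytes: list[AnalyteDef]
    level: int = 0

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_records(
        cls,
        values: pd.DataFrame,
        flags: pd.DataFrame,
        records: Iterable[SampleRecord],
        analytes: Iterable[AnalyteDef],
        level: int = 0,
    ) -> "ConcentrationMatrix":
        m = cls(values, flags, _records_to_frame(records), list(analytes), level)
        m.validate()
        return m

    # -- invariants -----------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if self.values.shape != self.flags.shape:
            raise ValueError("values and flags dimensions differ")
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise ValueError("values and flags must share index and columns")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample_id(s): {dupes}")
        if not self.values.index.equals(self.samples.index):
            raise ValueError("sample annotations do not align with value rows")
        ids = [a.analyte_id for a in self.analytes]
        if ids != list(self.values.columns):
            raise ValueError("analyte definitions do not align with value columns")
        allowed = {f.value for f in MeasurementFlag}
        bad = set(np.unique(self.flags.to_numpy().astype(str))) - allowed
        if bad:
            raise ValueError(f"unknown flag codes: {sorted(bad)}")
        if self.level >= 4:
            lod = (self.flags == MeasurementFlag.BELOW_LOD.value).to_numpy()
            if np.isnan(self.values.to_numpy()[lod]).any():
                raise ValueError("level >= 4 matrix contains unimputed BELOW_LOD cells")
        # per-plate unique injection order
        ann = self.samples
        if "injection_order" in ann and ann["injection_order"].notna().all():
            dup = ann.groupby("plate_id")["injection_order"].apply(
                lambda s: s.duplicated().any()
            )
            if dup.any():
                raise ValueError(
                    f"duplicate injection_order within plate(s): {list(dup[dup].index)}"
                )

    # -- convenience ----------------------------------------------------------
    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def cohort_mask(self) -> pd.Series:
        """Boolean Series: True for COHORT injections."""
        return self.samples["well_role"] == WellRole.COHORT.value

    def role_mask(self, role: WellRole | str) -> pd.Series:
        return self.samples["well_role"] == WellRole(role).value

    def flag_counts(self) -> pd.Series:
        flat = pd.Series(self.flags.to_numpy().ravel())
        return flat.value_counts()

    def subset_analytes(self, keep: Iterable[str], level: int | None = None) -> "ConcentrationMatrix":
        keep = [a for a in self.analyte_ids if a in set(keep)]  # preserve column order
        return ConcentrationMatrix(
            values=self.values[keep].copy(),
            flags=self.flags[keep].copy(),
            samples=self.samples.copy(),
            analytes=[a for a in self.analytes if a.analyte_id in set(keep)],
            level=self.level if level is None else level,
        )

    def subset_samples(self, keep: Iterable[str], level: int | None = None) -> "ConcentrationMatrix":
        keep_set = set(keep)
        idx = [s for s in self.sample_ids if s in keep_set]
        return ConcentrationMatrix(
            values=self.values.loc[idx].copy(),
            flags=self.flags.loc[idx].copy(),
            samples=self.samples.loc[idx].copy(),
            analytes=list(self.analytes),
            level=self.level if level is None else level,
        )

    def copy(self, level: int | None = None) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            values=self.values.copy(),
            flags=self.flags.copy(),
            samples=self.samples.copy(),
            analytes=list(self.analytes),
            level=self.level if level is None else level,
        )

    def lods(self) -> pd.DataFrame:
        """Plates x analytes LOD table for the plates present in the matrix."""
        plates = pd.unique(self.samples["plate_id"].dropna())
        return lod_table(self.analytes, plates)

    def content_hash(self) -> str:
        """Deterministic SHA-256 over values, flags and annotations."""
        h = hashlib.sha256()
        h.update(self.values.to_csv().encode())
        h.update(self.flags.to_csv().encode())
        h.update(self.samples.to_csv().encode())
        h.update(str(self.level).encode())
        return h.hexdigest()


@dataclass
class LevelArtifact:
    """A pipeline stage output: the matrix plus its reports and provenance.

    ``provenance`` records the stage parameters and the parent matrix hash so
    that a rerun with identical inputs reproduces the artifact byte for byte.
    """

    matrix: ConcentrationMatrix
    reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def level(self) -> int:
        return self.matrix.level
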