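"""Reading and writing of concentration exports, annotations and level artifacts.

The wide-table export dialect is minimal and documented: first column
``sample_id``, one column per analyte, cells either a numeric concentration
(µM), a censoring marker (``<LOD`` / ``<LLOQ``, case- and
whitespace-tolerant), or blank (missing).  Vendor exports with different
column headers are handled through an optional ``column_map``.

Artifacts are written as plain CSV/JSON: ``levelN_matrix.csv`` (markers in
place of untrusted cells), ``levelN_flags.csv`` (full flag sidecar, so
imputed cells keep their provenance), ``levelN_samples.csv``,
``levelN_lods.csv``, one CSV per report, and ``levelN_provenance.json``.
Floats are written with pandas' shortest round-trip representation, so
read(write(M)) reproduces M exactly and identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ANNOTATION_COLUMNS,
    AnalyteDef,
    ConcentrationMatrix,
    LevelArtifact,
    MeasurementFlag,
    WellRole,
)

__all__ = [
    "read_concentration_export",
    "read_annotations",
    "attach_annotations",
    "read_lod_table",
    "analytes_from_lod_table",
    "write_level_artifact",
    "read_level_artifact",
    "write_matrix_csv",
]

_MARKER_RE = re.compile(r"^<\s*(lod|lloq)$")

#: canonical textual encodings emitted for censored cells
MARKER_FOR_FLAG = {
    MeasurementFlag.BELOW_LOD.value: "<LOD",
    MeasurementFlag.BELOW_LLOQ.value: "<LLOQ",
}


def _parse_cell(raw: object) -> tuple[float, str]:
    """Map one export cell to (value, flag code).

    Returns NaN + BELOW_LOD/BELOW_LLOQ for censoring markers, NaN + MISSING
    for blanks, and the parsed float + VALID otherwise.  Raises ValueError
    for anything else.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan, MeasurementFlag.MISSING.value
    if isinstance(raw, (int, float, np.integer, np.floating)):
        return float(raw), MeasurementFlag.VALID.value
    text = str(raw).strip()
    if text == "":
        return np.nan, MeasurementFlag.MISSING.value
    m = _MARKER_RE.match(text.lower())
    if m:
        flag = (
            MeasurementFlag.BELOW_LOD
            if m.group(1) == "lod"
            else MeasurementFlag.BELOW_LLOQ
        )
        return np.nan, flag.value
    try:
        return float(text), MeasurementFlag.VALID.value
    except ValueError:
        raise ValueError(f"unparseable cell {raw!r}") from None


def read_concentration_export(
    path: str | Path,
    dialect: str = "csv",
    column_map: dict[str, str] | None = None,
    sample_id_column: str = "sample_id",
) -> ConcentrationMatrix:
    """Read a MetIDQ-style wide concentration export as a level-0 matrix.

    Parameters
    ----------
    path
        CSV or spreadsheet file; header row names the analytes.
    dialect
        ``"csv"`` or ``"spreadsheet"``/``"xlsx"``.
    column_map
        Optional mapping from the file's column names to canonical names,
        for vendor exports with a different schema.
    sample_id_column
        Name (after mapping) of the sample-identifier column.

    The returned matrix carries placeholder annotations (every row a COHORT
    well); join the real annotation table with :func:`attach_annotations`
    before running the pipeline.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect in ("spreadsheet", "xlsx"):
        raw = pd.read_excel(path, dtype=object)
    elif dialect == "csv":
        raw = pd.read_csv(path, dtype=object, keep_default_na=False, na_values=[])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if column_map:
        raw = raw.rename(columns=column_map)
    if sample_id_column not in raw.columns:
        raise ValueError(f"export lacks a {sample_id_column!r} column")
    raw = raw.set_index(sample_id_column)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample_id(s) in export: {dupes}")

    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    flags = pd.DataFrame(
        MeasurementFlag.MISSING.value, index=raw.index, columns=raw.columns, dtype=object
    )
    for col in raw.columns:
        for sid, cell in raw[col].items():
            try:
                v, f = _parse_cell(cell)
            except ValueError:
                raise ValueError(
                    f"unparseable cell {cell!r} at sample {sid!r}, analyte {col!r}"
                ) from None
            values.at[sid, col] = v
            flags.at[sid, col] = f

    samples = _placeholder_annotations(values.index)
    analytes = [AnalyteDef(analyte_id=c) for c in values.columns]
    m = ConcentrationMatrix(values, flags, samples, analytes, level=0)
    m.validate()
    return m


def _placeholder_annotations(index: pd.Index) -> pd.DataFrame:
    samples = pd.DataFrame(index=index.rename("sample_id"))
    samples["subject_id"] = samples.index
    samples["plate_id"] = "plate01"
    samples["well_role"] = WellRole.COHORT.value
    samples["injection_order"] = np.arange(1, len(samples) + 1)
    samples["replicate_group_id"] = None
    samples["is_fasting"] = True
    samples["has_bmi"] = True
    samples["has_medication_record"] = True
    return samples


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False, "yes": True, "no": False,
    "t": True, "f": False,
}


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    out = s.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if out.isna().any():
        bad = s[out.isna()].unique().tolist()
        raise ValueError(f"column {s.name!r}: unparseable boolean value(s) {bad}")
    return out.astype(bool)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation CSV (sample_id + :data:`ANNOTATION_COLUMNS`)."""
    ann = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str, "plate_id": str})
    missing = {"sample_id", *ANNOTATION_COLUMNS} - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks column(s): {sorted(missing)}")
    ann = ann.set_index("sample_id")
    for col in ("is_fasting", "has_bmi", "has_medication_record"):
        ann[col] = _coerce_bool(ann[col])
    ann["well_role"] = [WellRole(r).value for r in ann["well_role"]]
    ann["injection_order"] = ann["injection_order"].astype(int)
    rep = ann["replicate_group_id"]
    ann["replicate_group_id"] = rep.where(rep.notna() & (rep.astype(str) != ""), None)
    return ann[ANNOTATION_COLUMNS]


def attach_annotations(
    matrix: ConcentrationMatrix, annotations: pd.DataFrame
) -> ConcentrationMatrix:
    """Join an annotation table onto a matrix; every row must be annotated."""
    missing = [s for s in matrix.sample_ids if s not in annotations.index]
    if missing:
        raise ValueError(
            f"{len(missing)} sample(s) missing from annotations, e.g. {missing[:5]}"
        )
    out = matrix.copy()
    out.samples = annotations.loc[matrix.sample_ids, ANNOTATION_COLUMNS].copy()
    out.validate()
    return out


def read_lod_table(path: str | Path) -> pd.DataFrame:
    """Read a plates x analytes LOD table (first column ``plate_id``)."""
    return pd.read_csv(path, index_col="plate_id")


def analytes_from_lod_table(
    lods: pd.DataFrame, lloqs: dict[str, float] | None = None
) -> list[AnalyteDef]:
    """Build AnalyteDef objects from a plates x analytes LOD table."""
    lloqs = lloqs or {}
    out = []
    for a in lods.columns:
        col = lods[a].dropna()
        out.append(AnalyteDef(analyte_id=a, lod=col.to_dict(), lloq=lloqs.get(a)))
    return out


def write_matrix_csv(matrix: ConcentrationMatrix, path: str | Path) -> None:
    """Write the wide table, encoding untrusted cells as their markers.

    A cell is written as ``<LOD``/``<LLOQ`` when it carries that flag and has
    no numeric value (pre-imputation); numeric cells are written as numbers
    regardless of provenance flag (the flag sidecar keeps the history).
    """
    vals = matrix.values
    flg = matrix.flags
    out = vals.astype(object).copy()
    for code, marker in MARKER_FOR_FLAG.items():
        mask = (flg == code) & vals.isna()
        out = out.mask(mask, marker)
    out = out.mask((flg == MeasurementFlag.MISSING.value) & vals.isna(), "")
    out.index.name = "sample_id"
    out.to_csv(path)


def write_level_artifact(artifact: LevelArtifact, path: str | Path) -> list[Path]:
    """Persist an artifact to a directory; returns the files written."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lvl = artifact.level
    m = artifact.matrix
    written = []

    p = path / f"level{lvl}_matrix.csv"
    write_matrix_csv(m, p)
    written.append(p)

    p = path / f"level{lvl}_flags.csv"
    m.flags.rename_axis("sample_id").to_csv(p)
    written.append(p)

    p = path / f"level{lvl}_samples.csv"
    m.samples.rename_axis("sample_id").to_csv(p)
    written.append(p)

    lods = m.lods()
    p = path / f"level{lvl}_lods.csv"
    lods.to_csv(p)
    written.append(p)
    lloqs = {a.analyte_id: a.lloq for a in m.analytes if a.lloq is not None}

    for name, report in sorted(artifact.reports.items()):
        p = path / f"level{lvl}_{name}.csv"
        report.to_csv(p)
        written.append(p)

    prov = dict(artifact.provenance)
    prov["level"] = lvl
    prov["lloqs"] = lloqs
    prov["reports"] = sorted(artifact.reports.keys())
    prov["report_index_names"] = {
        k: (artifact.reports[k].index.name or "index") for k in artifact.reports
    }
    p = path / f"level{lvl}_provenance.json"
    p.write_text(json.dumps(prov, indent=2, sort_keys=True, default=str) + "\n")
    written.append(p)
    return written


def read_level_artifact(path: str | Path, level: int) -> LevelArtifact:
    """Reload an artifact written by :func:`write_level_artifact`."""
    path = Path(path)
    prov = json.loads((path / f"level{level}_provenance.json").read_text())

    raw = pd.read_csv(
        path / f"level{level}_matrix.csv",
        index_col="sample_id",
        dtype=object,
        keep_default_na=False,
        na_values=[],
    )
    flags = pd.read_csv(path / f"level{level}_flags.csv", index_col="sample_id")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for sid, cell in raw[col].items():
            v, _ = _parse_cell(cell)
            values.at[sid, col] = v
    samples = pd.read_csv(path / f"level{level}_samples.csv", index_col="sample_id")
    for col in ("is_fasting", "has_bmi", "has_medication_record"):
        samples[col] = _coerce_bool(samples[col])
    rep = samples["replicate_group_id"]
    samples["replicate_group_id"] = rep.where(rep.notna(), None)
    samples.index = samples.index.astype(str)
    values.index = values.index.astype(str)
    flags.index = flags.index.astype(str)

    lods = read_lod_table(path / f"level{level}_lods.csv")
    lods.index = lods.index.astype(str)
    samples["plate_id"] = samples["plate_id"].astype(str)
    analytes = analytes_from_lod_table(lods[values.columns], prov.get("lloqs", {}))
    matrix = ConcentrationMatrix(values, flags, samples, analytes, level=level)
    matrix.validate()

    reports = {}
    for name in prov.get("reports", []):
        idx = prov.get("report_index_names", {}).get(name, "index")
        reports[name] = pd.read_csv(path / f"level{level}_{name}.csv", index_col=idx)
    return LevelArtifact(matrix=matrix, reports=reports, provenance=prov)
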