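"""Cross-plate batch-effect scaling anchored on reference-pool wells.

Each 96-well plate carries aliquots of the same reference material (NIST
SRM-1950 by default).  For analyte *a* on plate *p* the scale factor is

    factor(p, a) = global mean of reference values of a / plate-p mean

and every value on plate *p* is multiplied by it, so the per-plate
reference means coincide with the global reference mean afterwards.
Ratios of samples within a plate are untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ConcentrationMatrix, MeasurementFlag, WellRole

__all__ = ["ScaleFactorTable", "compute_scale_factors", "apply_scale_factors"]

logger = logging.getLogger(__name__)


@dataclass
class ScaleFactorTable:
    """Per-(plate, analyte) multiplicative scale factors.

    ``factors`` is a plates x analytes DataFrame; ``n_reference`` counts the
    VALID reference wells that entered each plate mean (0 means the factor
    defaulted to 1).
    """

    factors: pd.DataFrame
    n_reference: pd.DataFrame
    reference_role: str

    def validate(self) -> None:
        f = self.factors.to_numpy()
        if not np.all(np.isfinite(f)) or not np.all(f > 0):
            raise ValueError("scale factors must be positive and finite")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (plate_id, analyte, factor, n_reference) table."""
        long = self.factors.stack().rename("factor").reset_index()
        long.columns = ["plate_id", "analyte", "factor"]
        nref = self.n_reference.stack().rename("n_reference").reset_index()
        long["n_reference"] = nref["n_reference"].astype(int)
        long["reference_role"] = self.reference_role
        return long.set_index(["plate_id", "analyte"])


def compute_scale_factors(
    matrix: ConcentrationMatrix,
    reference_role: WellRole | str = WellRole.NIST,
    on_missing_reference: str = "warn",
) -> ScaleFactorTable:
    """Derive plate scale factors from reference-pool wells.

    Only VALID reference values enter the means (censored reference wells
    are excluded, not imputed, to avoid circularity with the later
    imputation stage).  A plate with no usable reference value for an
    analyte gets factor 1 with a warning (``on_missing_reference="warn"``)
    or raises (``"error"``).
    """
    role = WellRole(reference_role)
    ref_rows = matrix.role_mask(role)
    if not ref_rows.any():
        raise ValueError(f"matrix contains no {role.value} reference wells")

    vals = matrix.values[ref_rows.to_numpy()]
    flg = matrix.flags[ref_rows.to_numpy()]
    usable = vals.where((flg == MeasurementFlag.VALID.value).to_numpy())
    plates = matrix.samples.loc[ref_rows[ref_rows].index, "plate_id"]

    plate_means = usable.groupby(plates.to_numpy()).mean()
    n_ref = usable.notna().groupby(plates.to_numpy()).sum()
    all_plates = pd.Index(pd.unique(matrix.samples["plate_id"]), name="plate_id")
    plate_means = plate_means.reindex(all_plates)
    n_ref = n_ref.reindex(all_plates).fillna(0).astype(int)
    global_means = usable.mean(axis=0)

    missing = plate_means.isna() | (global_means.isna().to_numpy()[None, :])
    if missing.any().any():
        cells = [
            (p, a) for p in plate_means.index for a in plate_means.columns
            if bool(missing.loc[p, a])
        ]
        msg = (
            f"{len(cells)} (plate, analyte) pair(s) have no VALID {role.value} "
            f"reference value, e.g. {cells[:4]}; factor defaults to 1"
        )
        if on_missing_reference == "error":
            raise ValueError(msg)
        logger.warning(msg)

    factors = global_means.to_numpy()[None, :] / plate_means.to_numpy()
    factors = pd.DataFrame(factors, index=all_plates, columns=plate_means.columns)
    factors = factors.where(~missing, 1.0)
    n_ref = n_ref.where(~missing, 0)
    table = ScaleFactorTable(factors=factors, n_reference=n_ref, reference_role=role.value)
    table.validate()
    return table


def apply_scale_factors(
    matrix: ConcentrationMatrix, factors: ScaleFactorTable
) -> ConcentrationMatrix:
    """Multiply every numeric cell by its plate/analyte factor (level 2).

    Flags are untouched; censored cells keep their (absent) values.
    """
    f = factors.factors
    plates = pd.unique(matrix.samples["plate_id"])
    missing_p = [p for p in plates if p not in f.index]
    missing_a = [a for a in matrix.analyte_ids if a not in f.columns]
    if missing_p or missing_a:
        raise ValueError(
            f"scale factors missing for plate(s) {missing_p} / analyte(s) {missing_a}"
        )
    per_row = f.loc[matrix.samples["plate_id"], matrix.analyte_ids].to_numpy()
    out = matrix.copy(level=2)
    out.values = matrix.values * per_row
    out.validate()
    return out
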