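"""Shared fixtures: hand-built matrices and module-scoped synthetic cohorts."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from metabocurate.datamodel import (
    AnalyteDef,
    ConcentrationMatrix,
    MeasurementFlag,
    WellRole,
)
from metabocurate.pipeline import PipelineConfig
from metabocurate.simulate import adni1_params, generate_dataset

logging.getLogger("metabocurate").setLevel(logging.ERROR)
logging.getLogger("metabocurate.scaling").setLevel(logging.ERROR)


def build_matrix(
    values,
    analyte_ids,
    plate_ids=None,
    roles=None,
    flags=None,
    replicate_groups=None,
    subject_ids=None,
    lods=None,
    level=0,
    is_fasting=None,
    has_bmi=None,
    has_medication_record=None,
):
    """Assemble a ConcentrationMatrix from plain lists for small test cases."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = [f"S{i + 1}" for i in range(n)]
    idx = pd.Index(sample_ids, name="sample_id")
    plate_ids = plate_ids or ["plate01"] * n
    roles = roles or [WellRole.COHORT.value] * n
    subject_ids = subject_ids or [f"SUB{i + 1}" for i in range(n)]
    vdf = pd.DataFrame(values, index=idx, columns=analyte_ids)
    if flags is None:
        fdf = pd.DataFrame(
            np.where(np.isnan(values), MeasurementFlag.MISSING.value, MeasurementFlag.VALID.value),
            index=idx, columns=analyte_ids,
        )
    else:
        fdf = pd.DataFrame(np.asarray(flags, dtype=object), index=idx, columns=analyte_ids)
    order = {}
    inj = []
    for pl in plate_ids:
        order[pl] = order.get(pl, 0) + 1
        inj.append(order[pl])
    samples = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "plate_id": plate_ids,
            "well_role": roles,
            "injection_order": inj,
            "replicate_group_id": replicate_groups or [None] * n,
            "is_fasting": is_fasting if is_fasting is not None else [True] * n,
            "has_bmi": has_bmi if has_bmi is not None else [True] * n,
            "has_medication_record": (
                has_medication_record if has_medication_record is not None else [True] * n
            ),
        },
        index=idx,
    )
    lods = lods or {}
    analytes = [AnalyteDef(a, lod=lods.get(a, {}), lloq=None) for a in analyte_ids]
    m = ConcentrationMatrix(vdf, fdf, samples, analytes, level=level)
    m.validate()
    return m


def gaussian_cohort_matrix(X):
    """Wrap a plain numeric array as an imputed subject-level matrix."""
    n, p = X.shape
    return build_matrix(X, [f"A{j}" for j in range(p)], level=4)


PLANTED = (
    ("CA", "HIGH_CV"),
    ("GCA", "HIGH_CV"),
    ("TCA", "LOW_ICC"),
    ("CDCA", "HIGH_CENSORING"),
    ("GCDCA", "HIGH_CENSORING"),
)


def seed17_params():
    """The end-to-end fixture: 800 cohort injections, 18 blinded duplicates,
    5 planted failing analytes, 20 non-fasting, 2 missing-BMI, 5 whole-profile
    outliers displaced 12 SD."""
    return adni1_params(
        seed=17,
        n_plates=10,
        cohort_wells_per_plate=80,
        planted_bad_analytes=PLANTED,
        planted_outlier_subjects=tuple((100 + i, 12.0) for i in range(5)),
        nonfasting_fraction=20 / 800,
        missing_bmi_count=2,
    )


@pytest.fixture(scope="session")
def seed17_dataset():
    return generate_dataset(seed17_params())


@pytest.fixture(scope="session")
def default_dataset():
    """A plain ADNI1-style cohort without planted defects (seed 1)."""
    return generate_dataset(adni1_params(seed=1))


@pytest.fixture()
def adni1_config():
    return PipelineConfig.for_preset("adni1")
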