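"""Synthetic plate-structured cohorts with known ground truth.

Emulates the study design the pipeline targets: 96-well plates carrying 75
cohort wells plus 3 study-pool QC (SPQC), 3 NIST SRM-1950, 1 GoldenWest and
kit low/mid/high QC wells; blinded analytical duplicates/triplicates
scattered across plates; strictly positive, right-skewed (log-normal)
analyte concentrations; multiplicative per-plate batch effects; per-plate
limits of detection; and planted failure modes (noisy analytes,
irreproducible analytes, heavily censored analytes, displaced outlier
subjects) whose labels are returned as ground truth for recovery tests.

Generative model, per cohort injection of analyte *a* on plate *p* for
subject *s*::

    y = exp(mu_a + sigma_subj_a * Z_s) * f_pa * exp(sigma_rep_a * Z_inj)

with ``f_pa = exp(N(0, plate_effect_sd))`` the batch effect and
``sigma_rep = sqrt(log(1 + CV^2))`` calibrated so replicate noise has the
requested coefficient of variation on the concentration scale.  The LOD for
(a, p) sits at the ``lod_quantile`` quantile of the plate-level marginal of
y (perturbed ±10% per plate); measurements below it are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalyteDef, ConcentrationMatrix, MeasurementFlag, WellRole

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_dataset",
    "generate_medication_table",
    "adni1_params",
    "adnigo2_params",
    "BILE_ACID_PANEL",
]

#: bile-acid-style analyte codes used as default labels (free + glycine/taurine
#: conjugates of the major primary and secondary bile acids)
BILE_ACID_PANEL = [
    "CA", "GCA", "TCA", "CDCA", "GCDCA", "TCDCA", "DCA", "GDCA", "TDCA",
    "LCA", "GLCA", "TLCA", "UDCA", "GUDCA", "TUDCA", "HDCA", "GHDCA",
    "THDCA", "MCA", "TMCA",
]

#: planted analyte failure modes
FAILURE_MODES = ("HIGH_CV", "LOW_ICC", "HIGH_CENSORING")

# QC wells added to every plate besides the cohort wells
_QC_LAYOUT = [
    (WellRole.SPQC, 3),
    (WellRole.NIST, 3),
    (WellRole.GOLDENWEST, 1),
    (WellRole.QC_LOW, 1),
    (WellRole.QC_MID, 1),
    (WellRole.QC_HIGH, 1),
]

# relative level of each QC pool vs the analyte median concentration
_POOL_LEVELS = {
    WellRole.SPQC: 0.95,
    WellRole.NIST: 1.10,
    WellRole.GOLDENWEST: 1.05,
    WellRole.QC_LOW: 0.25,
    WellRole.QC_MID: 1.00,
    WellRole.QC_HIGH: 4.00,
}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort; defaults mirror the emulated design."""

    n_plates: int = 11
    cohort_wells_per_plate: int = 75
    n_analytes: int = 20
    n_blinded_duplicates: int = 18
    n_blinded_triplicates: int = 0
    plate_effect_sd: float = 0.05          # log-scale SD of multiplicative batch effect
    replicate_cv: float = 0.08             # technical CV of one injection
    between_subject_sd: float = 0.5        # log-scale biological SD
    lod_quantile: float = 0.02             # target censored fraction per analyte
    planted_bad_analytes: tuple = ()       # ((analyte_id, failure_mode), ...)
    planted_outlier_subjects: tuple = ()   # ((subject index or id, displacement in SD), ...)
    nonfasting_fraction: float = 0.0
    missing_bmi_count: int = 0
    missing_med_count: int = 0
    high_cv_value: float = 0.5             # replicate CV given to HIGH_CV analytes
    low_icc_between_sd: float = 0.01       # biological SD given to LOW_ICC analytes
    high_censoring_quantile: float = 0.6   # censored fraction given to HIGH_CENSORING analytes
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_plates, self.cohort_wells_per_plate, self.n_analytes) <= 0:
            raise ValueError("plate, well and analyte counts must be positive")
        if self.n_blinded_duplicates < 0 or self.n_blinded_triplicates < 0:
            raise ValueError("replicate counts must be >= 0")
        qc_wells = sum(n for _, n in _QC_LAYOUT)
        if self.cohort_wells_per_plate + qc_wells > 96:
            raise ValueError(
                f"{self.cohort_wells_per_plate} cohort + {qc_wells} QC wells exceed a 96-well plate"
            )
        n_inj = self.n_plates * self.cohort_wells_per_plate
        rep_inj = 2 * self.n_blinded_duplicates + 3 * self.n_blinded_triplicates
        if rep_inj > n_inj:
            raise ValueError("replicate injections exceed available cohort wells")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0 <= self.nonfasting_fraction <= 1:
            raise ValueError("nonfasting_fraction must be in [0, 1]")
        for a, mode in self.planted_bad_analytes:
            if mode not in FAILURE_MODES:
                raise ValueError(f"unknown failure mode {mode!r} for analyte {a!r}")


def adni1_params(**overrides) -> SimulationParams:
    """Preset emulating the first cohort: 18 blinded duplicates."""
    return replace(SimulationParams(), **overrides)


def adnigo2_params(**overrides) -> SimulationParams:
    """Preset emulating the follow-on cohort: 15 blinded triplicates."""
    base = SimulationParams(n_blinded_duplicates=0, n_blinded_triplicates=15)
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Planted parameters returned for recovery tests."""

    plate_factors: pd.DataFrame            # plates x analytes multiplicative effects
    subject_true_concentrations: pd.DataFrame  # subjects x analytes, pre-noise
    censoring_thresholds: pd.DataFrame     # plates x analytes LODs (µM)
    bad_analyte_labels: dict               # analyte_id -> failure mode
    outlier_subject_labels: dict           # subject_id -> displacement (SD units)
    nonfasting_subjects: list = field(default_factory=list)
    missing_bmi_subjects: list = field(default_factory=list)
    missing_med_subjects: list = field(default_factory=list)

    def clean_analytes(self, all_analytes: Sequence[str]) -> list[str]:
        return [a for a in all_analytes if a not in self.bad_analyte_labels]

    def expected_level5_subjects(self, n_subjects: int) -> int:
        """Subjects surviving metadata + planted-outlier exclusion."""
        excluded = (
            set(self.nonfasting_subjects)
            | set(self.missing_bmi_subjects)
            | set(self.missing_med_subjects)
            | set(self.outlier_subject_labels)
        )
        return n_subjects - len(excluded)


def _analyte_names(n: int) -> list[str]:
    if n <= len(BILE_ACID_PANEL):
        return BILE_ACID_PANEL[:n]
    extra = [f"BA{i:02d}" for i in range(1, n - len(BILE_ACID_PANEL) + 1)]
    return BILE_ACID_PANEL + extra


def generate_dataset(
    params: SimulationParams,
) -> tuple[ConcentrationMatrix, pd.DataFrame, GroundTruth]:
    """Draw a level-0 cohort with annotations and ground truth.

    Returns
    -------
    matrix
        Level-0 :class:`ConcentrationMatrix` including QC wells, with
        BELOW_LOD/BELOW_LLOQ flags applied.
    annotations
        The matrix's annotation table (also embedded in the matrix).
    truth
        :class:`GroundTruth` with every planted parameter.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_a = params.n_analytes
    analyte_ids = _analyte_names(n_a)
    plates = [f"plate{i + 1:02d}" for i in range(params.n_plates)]
    bad = {a: m for a, m in params.planted_bad_analytes}
    unknown = set(bad) - set(analyte_ids)
    if unknown:
        raise ValueError(f"planted analytes not in panel: {sorted(unknown)}")

    # --- per-analyte distribution parameters -------------------------------
    mu = rng.uniform(np.log(0.05), np.log(5.0), n_a)          # log median µM
    sigma_subj = np.full(n_a, params.between_subject_sd)
    cv = np.full(n_a, params.replicate_cv)
    q = np.full(n_a, params.lod_quantile)
    for j, a in enumerate(analyte_ids):
        mode = bad.get(a)
        if mode == "HIGH_CV":
            cv[j] = params.high_cv_value
        elif mode == "LOW_ICC":
            sigma_subj[j] = params.low_icc_between_sd
        elif mode == "HIGH_CENSORING":
            q[j] = params.high_censoring_quantile
    sigma_rep = np.sqrt(np.log1p(cv**2))
    sigma_tot = np.sqrt(sigma_subj**2 + sigma_rep**2)

    # --- plate factors and censoring thresholds ----------------------------
    plate_factors = np.exp(
        rng.normal(0.0, params.plate_effect_sd, (params.n_plates, n_a))
    )
    lod_base = np.exp(mu + sigma_tot * stats.norm.ppf(np.clip(q, 1e-12, None)))
    lod_perturb = rng.uniform(0.9, 1.1, (params.n_plates, n_a))
    lods = lod_base[None, :] * plate_factors * lod_perturb     # plates x analytes
    lloq = np.nanmax(lods, axis=0) * 1.15                      # per analyte, >= every plate LOD

    # --- subjects and replicate structure ----------------------------------
    n_inj = params.n_plates * params.cohort_wells_per_plate
    n_dup, n_trip = params.n_blinded_duplicates, params.n_blinded_triplicates
    n_subjects = n_inj - n_dup - 2 * n_trip
    subjects = [f"SUB{i + 1:04d}" for i in range(n_subjects)]

    group_sizes = [2] * n_dup + [3] * n_trip
    rep_subjects = subjects[: len(group_sizes)]  # first subjects carry the replicate groups
    injections: list[tuple[str, str | None]] = []  # (subject_id, replicate_group_id)
    for i, (s, k) in enumerate(zip(rep_subjects, group_sizes)):
        gid = f"RG{i + 1:03d}"
        injections.extend([(s, gid)] * k)
    injections.extend((s, None) for s in subjects[len(group_sizes):])
    order = rng.permutation(len(injections))
    injections = [injections[i] for i in order]  # scatter replicates across plates

    singleton = subjects[len(group_sizes):]

    # --- planted outliers (displaced along the first analyte) --------------
    outliers: dict[str, float] = {}
    for ref, disp in params.planted_outlier_subjects:
        sid = singleton[ref] if isinstance(ref, (int, np.integer)) else str(ref)
        if sid not in set(subjects):
            raise ValueError(f"unknown planted outlier subject {sid!r}")
        outliers[sid] = float(disp)

    # --- metadata exclusions (disjoint from outliers and replicate groups) --
    eligible = [s for s in singleton if s not in outliers]
    n_nonfast = int(round(params.nonfasting_fraction * n_inj))
    need = n_nonfast + params.missing_bmi_count + params.missing_med_count
    if need > len(eligible):
        raise ValueError("not enough singleton subjects for requested metadata exclusions")
    chosen = list(rng.choice(eligible, size=need, replace=False)) if need else []
    nonfasting = chosen[:n_nonfast]
    missing_bmi = chosen[n_nonfast:n_nonfast + params.missing_bmi_count]
    missing_med = chosen[n_nonfast + params.missing_bmi_count:]

    # --- true subject concentrations ----------------------------------------
    z = rng.standard_normal((n_subjects, n_a))
    true_conc = np.exp(mu[None, :] + sigma_subj[None, :] * z)
    # Displaced subjects model a sample-level artifact (dilution or handling
    # error) that moves the whole profile: every analyte is set to its
    # marginal mean plus `disp` marginal SDs.  A profile-wide shift is what
    # gross sample outliers look like in practice, and it survives analyte
    # filtering (single-analyte spikes would vanish whenever that analyte is
    # dropped, and several equal spikes mask each other under per-component
    # screening).
    marg_mean = np.exp(mu + sigma_tot**2 / 2)
    marg_sd = marg_mean * np.sqrt(np.expm1(sigma_tot**2))
    subj_index = {s: i for i, s in enumerate(subjects)}
    for sid, disp in outliers.items():
        true_conc[subj_index[sid], :] = marg_mean + disp * marg_sd

    # --- assemble injections (cohort then QC wells, plate by plate) ----------
    rows = []
    sample_values = []
    c = 0
    for p_i, plate in enumerate(plates):
        inj_order = 0
        for _ in range(params.cohort_wells_per_plate):
            subj, gid = injections[c]
            c += 1
            inj_order += 1
            noise = np.exp(sigma_rep * rng.standard_normal(n_a))
            y = true_conc[subj_index[subj]] * plate_factors[p_i] * noise
            sample_values.append(y)
            rows.append(
                dict(
                    sample_id=f"{plate}_W{inj_order:02d}",
                    subject_id=subj,
                    plate_id=plate,
                    well_role=WellRole.COHORT.value,
                    injection_order=inj_order,
                    replicate_group_id=gid,
                    is_fasting=subj not in set(nonfasting),
                    has_bmi=subj not in set(missing_bmi),
                    has_medication_record=subj not in set(missing_med),
                )
            )
        for role, n_wells in _QC_LAYOUT:
            pool = np.exp(mu) * _POOL_LEVELS[role]
            for w in range(n_wells):
                inj_order += 1
                noise = np.exp(sigma_rep * rng.standard_normal(n_a))
                y = pool * plate_factors[p_i] * noise
                sample_values.append(y)
                rows.append(
                    dict(
                        sample_id=f"{plate}_{role.value}{w + 1}",
                        subject_id=f"{role.value}_POOL",
                        plate_id=plate,
                        well_role=role.value,
                        injection_order=inj_order,
                        replicate_group_id=None,
                        is_fasting=True,
                        has_bmi=True,
                        has_medication_record=True,
                    )
                )

    annotations = pd.DataFrame(rows).set_index("sample_id")
    values = pd.DataFrame(
        np.vstack(sample_values), index=annotations.index, columns=analyte_ids
    )

    # --- censoring -----------------------------------------------------------
    plate_idx = np.array([plates.index(p) for p in annotations["plate_id"]])
    lod_rows = lods[plate_idx]                        # per-injection LOD row
    vals = values.to_numpy()
    below_lod = vals < lod_rows
    below_lloq = ~below_lod & (vals < lloq[None, :])
    flags = np.where(
        below_lod,
        MeasurementFlag.BELOW_LOD.value,
        np.where(below_lloq, MeasurementFlag.BELOW_LLOQ.value, MeasurementFlag.VALID.value),
    )
    vals = np.where(below_lod, np.nan, vals)          # censored cells carry no number
    values = pd.DataFrame(vals, index=annotations.index, columns=analyte_ids)
    flags = pd.DataFrame(flags, index=annotations.index, columns=analyte_ids)

    lod_df = pd.DataFrame(lods, index=pd.Index(plates, name="plate_id"), columns=analyte_ids)
    analytes = [
        AnalyteDef(analyte_id=a, lod=lod_df[a].to_dict(), lloq=float(lloq[j]))
        for j, a in enumerate(analyte_ids)
    ]
    matrix = ConcentrationMatrix(values, flags, annotations, analytes, level=0)
    matrix.validate()

    truth = GroundTruth(
        plate_factors=pd.DataFrame(
            plate_factors, index=pd.Index(plates, name="plate_id"), columns=analyte_ids
        ),
        subject_true_concentrations=pd.DataFrame(
            true_conc, index=pd.Index(subjects, name="subject_id"), columns=analyte_ids
        ),
        censoring_thresholds=lod_df,
        bad_analyte_labels=bad,
        outlier_subject_labels=outliers,
        nonfasting_subjects=list(nonfasting),
        missing_bmi_subjects=list(missing_bmi),
        missing_med_subjects=list(missing_med),
    )
    return matrix, annotations, truth


# ---------------------------------------------------------------------------
# medication-table fixture generator
# ---------------------------------------------------------------------------

def generate_medication_table(
    n_subjects: int,
    class_prevalences: dict[str, float],
    seed: int,
    dictionary=None,
    dosage_noise_prob: float = 0.5,
):
    """Draw a free-text medication table plus its true class flags.

    For each subject and drug class, membership is Bernoulli(prevalence); a
    member gets one dictionary name (brand or generic) for that class,
    optionally suffixed with dosage noise (``"10mg"``, ``"20 mg tab"`` ...).

    Returns ``(med_table, truth)``: a DataFrame of (subject_id,
    medication_text) records and a subjects x classes boolean truth matrix
    covering every dictionary class.
    """
    from .medications import load_default_dictionary

    if dictionary is None:
        dictionary = load_default_dictionary()
    for cls, p in class_prevalences.items():
        if cls not in dictionary.classes:
            raise ValueError(f"unknown drug class {cls!r}")
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence for {cls!r} outside [0, 1]")

    rng = np.random.default_rng(seed)
    subjects = [f"SUB{i + 1:04d}" for i in range(n_subjects)]
    truth = pd.DataFrame(
        False, index=pd.Index(subjects, name="subject_id"), columns=dictionary.classes
    )
    names_by_class = {
        cls: sorted(
            n for n, ing in dictionary.name_to_ingredient.items()
            if cls in dictionary.ingredient_classes[ing]
        )
        for cls in class_prevalences
    }
    doses = ["5", "10", "20", "25", "40", "50", "100"]
    records = []
    for s in subjects:
        for cls in sorted(class_prevalences):
            if rng.random() < class_prevalences[cls]:
                name = names_by_class[cls][rng.integers(len(names_by_class[cls]))]
                text = name
                if rng.random() < dosage_noise_prob:
                    dose = doses[rng.integers(len(doses))]
                    style = rng.integers(3)
                    suffix = {0: f" {dose}mg", 1: f" {dose} mg", 2: f" {dose}mg tab"}[style]
                    text = name + suffix
                # casing noise
                if rng.random() < 0.3:
                    text = text.upper()
                records.append({"subject_id": s, "medication_text": text})
                ing = dictionary.name_to_ingredient[name]
                for c in dictionary.ingredient_classes[ing]:
                    truth.loc[s, c] = True
    med_table = pd.DataFrame(records, columns=["subject_id", "medication_text"])
    return med_table, truth
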