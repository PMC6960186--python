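"""Cohort-level analysis: specimen averaging, tumor/biopsy ratios,
subgroup association, and ratio-range survival probabilities.

The study design behind this module: each rectal-cancer patient
contributes a biopsy (taken before preoperative radiotherapy) and a
primary-tumor specimen (resected after radiotherapy).  Network metrics
(CC, CP) are averaged over the kept tiles of each specimen, and the
tumor-to-biopsy ratio of each metric is the candidate predictive
biomarker.  The cohort splits into a shorter-survival group
(<= 75 months) and a longer-survival group (>= 101 months); within each
group the ratio is correlated with survival time (Pearson R, reported
alongside a two-sided sign-test p-value 2 * (1/2)^n), and a predictive
probability is estimated as the fraction of patients inside a ratio
window whose survival falls in a target range.

A 25-patient cohort table ships with the package
(``load_cohort_table()`` with no argument).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CohortValidationError,
    DegenerateRatioError,
    EmptyDenominatorError,
    EmptySpecimenError,
    GroupTooSmallError,
    UndefinedCorrelationError,
    UnpairedPatientError,
)
from .metrics import NetworkMetrics

__all__ = [
    "PatientRecord",
    "SpecimenMetrics",
    "RatioResult",
    "AssociationResult",
    "SHORTER_MAX_MONTHS",
    "LONGER_MIN_MONTHS",
    "load_cohort_table",
    "aggregate_specimen",
    "tumor_biopsy_ratios",
    "subgroup_association",
    "sign_test_pvalue",
    "survival_range_probability",
]

#: Survival-group boundaries (months): the cohort's shorter-survival
#: patients lived 15-75 months, the longer-survival patients 101-288.
SHORTER_MAX_MONTHS = 75
LONGER_MIN_MONTHS = 101

_VALID_IHC = {0, 1, 2, 3}


@dataclass
class PatientRecord:
    """One cohort row: survival outcome plus pathologist IHC scores.

    IHC scores grade stain intensity 0-3 (negative, weak, moderate,
    strong).  ``group`` is "shorter" for survival <= 75 months,
    "longer" for >= 101 months; survivals strictly between the group
    boundaries are left unlabelled with a warning.
    """

    patient_id: str
    disease_free_months: int
    recurrence: bool
    survival_months: int
    ihc_score_tumor: int
    ihc_score_biopsy: int

    def __post_init__(self) -> None:
        if self.disease_free_months < 0 or self.survival_months < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: months must be non-negative"
            )
        for name, score in (
            ("tumor", self.ihc_score_tumor),
            ("biopsy", self.ihc_score_biopsy),
        ):
            if score not in _VALID_IHC:
                raise CohortValidationError(
                    f"patient {self.patient_id}: IHC {name} score {score} "
                    f"outside {{0,1,2,3}}"
                )

    @property
    def group(self) -> str | None:
        if self.survival_months <= SHORTER_MAX_MONTHS:
            return "shorter"
        if self.survival_months >= LONGER_MIN_MONTHS:
            return "longer"
        warnings.warn(
            f"patient {self.patient_id}: survival {self.survival_months} mo "
            f"falls between the group boundaries "
            f"({SHORTER_MAX_MONTHS}, {LONGER_MIN_MONTHS}); left unclassified",
            stacklevel=2,
        )
        return None


@dataclass
class SpecimenMetrics:
    """Tile-averaged network metrics for one specimen of one patient."""

    patient_id: str
    specimen_type: str  # "biopsy" | "primary_tumor"
    mean_CC: float
    mean_CP: float
    n_tiles_used: int


@dataclass
class RatioResult:
    """Tumor-to-biopsy metric ratios for one patient."""

    patient_id: str
    cc_ratio: float
    cp_ratio: float


@dataclass
class AssociationResult:
    """Within-group ratio-survival association."""

    R: float
    p: float
    n: int


def load_cohort_table(path: str | Path | None = None) -> list[PatientRecord]:
    """Load a cohort CSV (or the packaged 25-patient table).

    Expected columns: patient_id, disease_free_months, recurrence,
    survival_months, ihc_tumor, ihc_biopsy.
    """
    if path is None:
        src = resources.files("fwrnet.data") / "rectal_cohort.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {
        "patient_id",
        "disease_free_months",
        "recurrence",
        "survival_months",
        "ihc_tumor",
        "ihc_biopsy",
    }
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"cohort table missing columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        rec_raw = str(row["recurrence"]).strip().lower()
        if rec_raw in {"yes", "true", "1"}:
            recurrence = True
        elif rec_raw in {"no", "false", "0"}:
            recurrence = False
        else:
            raise CohortValidationError(
                f"row {idx}: recurrence value {row['recurrence']!r} not yes/no"
            )
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    disease_free_months=int(row["disease_free_months"]),
                    recurrence=recurrence,
                    survival_months=int(row["survival_months"]),
                    ihc_score_tumor=int(row["ihc_tumor"]),
                    ihc_score_biopsy=int(row["ihc_biopsy"]),
                )
            )
        except CohortValidationError as err:
            raise CohortValidationError(f"row {idx}: {err}") from err
    return records


def aggregate_specimen(
    tile_metrics: Sequence[NetworkMetrics],
    patient_id: str,
    specimen_type: str,
) -> SpecimenMetrics:
    """Arithmetic means of CC and CP across the kept tiles of a specimen."""
    if not tile_metrics:
        raise EmptySpecimenError(
            f"patient {patient_id} {specimen_type}: no kept tiles to average"
        )
    return SpecimenMetrics(
        patient_id=patient_id,
        specimen_type=specimen_type,
        mean_CC=float(np.mean([t.CC for t in tile_metrics])),
        mean_CP=float(np.mean([t.CP for t in tile_metrics])),
        n_tiles_used=len(tile_metrics),
    )


def tumor_biopsy_ratios(specimens: Iterable[SpecimenMetrics]) -> list[RatioResult]:
    """Per-patient tumor/biopsy ratios of mean CC and mean CP.

    Each patient must contribute exactly one biopsy and one
    primary_tumor entry (tiles from several slides of the same specimen
    should be pooled into one SpecimenMetrics beforehand).
    """
    by_patient: dict[str, dict[str, SpecimenMetrics]] = {}
    for s in specimens:
        if s.specimen_type not in {"biopsy", "primary_tumor"}:
            raise UnpairedPatientError(
                f"unknown specimen_type {s.specimen_type!r} for patient "
                f"{s.patient_id}"
            )
        slot = by_patient.setdefault(s.patient_id, {})
        if s.specimen_type in slot:
            raise UnpairedPatientError(
                f"patient {s.patient_id}: duplicate {s.specimen_type} specimen"
            )
        slot[s.specimen_type] = s
    results = []
    for pid, slot in by_patient.items():
        if set(slot) != {"biopsy", "primary_tumor"}:
            have = ", ".join(sorted(slot)) or "none"
            raise UnpairedPatientError(
                f"patient {pid}: incomplete specimen pair (have: {have})"
            )
        b, t = slot["biopsy"], slot["primary_tumor"]
        if b.mean_CC == 0 or b.mean_CP == 0:
            raise DegenerateRatioError(
                f"patient {pid}: biopsy metric is zero, ratio undefined"
            )
        results.append(
            RatioResult(
                patient_id=pid,
                cc_ratio=t.mean_CC / b.mean_CC,
                cp_ratio=t.mean_CP / b.mean_CP,
            )
        )
    return results


def sign_test_pvalue(n: int) -> float:
    """Two-sided sign-test probability 2 * (1/2)^n for a group of size n."""
    return 2.0 * 0.5**n


def subgroup_association(
    ratios: Sequence[float] | np.ndarray,
    survival: Sequence[float] | np.ndarray,
    mask: Sequence[bool] | np.ndarray | None = None,
) -> AssociationResult:
    """Pearson correlation of ratio vs survival within a patient subgroup.

    The significance value reported alongside R is the two-sided
    sign-test form 2 * (1/2)^n, which depends only on the subgroup size
    n: with ratios paired to survivals the sign test asks whether the
    concordance direction could arise by symmetric chance.  (A Pearson
    t-test p is easy to add via scipy, but the sign-test form is the
    package's reporting convention for these small subgroups.)

    Raises
    ------
    GroupTooSmallError
        If the subgroup has fewer than 3 patients.
    UndefinedCorrelationError
        If either variable is constant within the subgroup.
    """
    ratios = np.asarray(ratios, dtype=float)
    survival = np.asarray(survival, dtype=float)
    if ratios.shape != survival.shape:
        raise CohortValidationError("ratios and survival must have equal length")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        ratios, survival = ratios[mask], survival[mask]
    n = ratios.size
    if n < 3:
        raise GroupTooSmallError(f"subgroup has {n} patients; need >= 3")
    if np.ptp(ratios) == 0 or np.ptp(survival) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: constant ratios or survivals"
        )
    R = float(np.corrcoef(ratios, survival)[0, 1])
    return AssociationResult(R=R, p=sign_test_pvalue(n), n=n)


def survival_range_probability(
    ratios: Sequence[RatioResult],
    ratio_field: str,
    ratio_range: tuple[float, float],
    survival_range: tuple[float, float],
    cohort: Sequence[PatientRecord],
) -> tuple[int, int, float]:
    """Predictive probability of a survival range given a ratio window.

    Among the n patients whose ``ratio_field`` ("cc_ratio" or
    "cp_ratio") lies in the closed interval ``ratio_range``, k have
    survival months in the closed interval ``survival_range``; the
    probability is k / n.

    Returns
    -------
    (k, n, probability)
    """
    if ratio_field not in {"cc_ratio", "cp_ratio"}:
        raise CohortValidationError(f"unknown ratio_field {ratio_field!r}")
    lo, hi = ratio_range
    s_lo, s_hi = survival_range
    if lo > hi or s_lo > s_hi:
        raise CohortValidationError("ranges must satisfy lo <= hi")
    survival_by_id = {r.patient_id: r.survival_months for r in cohort}
    in_window = [
        r for r in ratios if lo <= getattr(r, ratio_field) <= hi
    ]
    n = len(in_window)
    if n == 0:
        raise EmptyDenominatorError(
            f"no patients with {ratio_field} in [{lo}, {hi}]"
        )
    k = sum(
        1
        for r in in_window
        if s_lo <= survival_by_id[r.patient_id] <= s_hi
    )
    return k, n, k / n
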