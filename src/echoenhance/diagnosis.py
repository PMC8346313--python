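"""Rule-based echocardiographic diagnosis and concordance arithmetic.

Positivity rules
----------------
Cardiac-ultrasound CHF indices (all strict inequalities):

* LAD > 30 mm
* LVDD > 55 mm (male) / > 50 mm (female)
* LVEF < 50 %

Sarcopenia (AWGS-style, any criterion fires => positive, strict inequalities):

* skeletal-muscle index < 7.0 kg/m2 (male) / < 5.4 kg/m2 (female)
* grip strength < 26 kg (male) / < 18 kg (female)
* gait speed < 0.8 m/s

Concordance arithmetic: a group's similarity to the final diagnosis is
``100 * group_chf_count / final_chf_count``; a group's CHF proportion is
``100 * chf_count / cohort_total``; both rounded half-up to one decimal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Sex",
    "PatientRecord",
    "PositivityResult",
    "DiagnosisTable",
    "chf_index_flags",
    "sarcopenia_positive",
    "similarity_percent",
    "proportion_percent",
    "group_compare",
    "count_compare",
    "concordance_report",
    "LAD_CUTOFF_MM",
    "LVDD_CUTOFF_MM",
    "LVEF_CUTOFF_PCT",
    "SMI_CUTOFF_KG_M2",
    "GRIP_CUTOFF_KG",
    "GAIT_CUTOFF_M_S",
]

LAD_CUTOFF_MM = 30.0
LVDD_CUTOFF_MM = {"male": 55.0, "female": 50.0}
LVEF_CUTOFF_PCT = 50.0

SMI_CUTOFF_KG_M2 = {"male": 7.0, "female": 5.4}
GRIP_CUTOFF_KG = {"male": 26.0, "female": 18.0}
GAIT_CUTOFF_M_S = 0.8


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


def _as_sex(sex: "Sex | str") -> Sex:
    if isinstance(sex, Sex):
        return sex
    try:
        return Sex(str(sex).lower())
    except ValueError:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'") from None


@dataclass(frozen=True)
class PatientRecord:
    """One subject's echocardiographic and sarcopenia measurements.

    Echo fields (``lad`` mm, ``lvdd`` mm, ``lvef`` %) and sarcopenia fields
    (``smi`` kg/m2, ``grip`` kg, ``gait_speed`` m/s) may each be ``None``
    when not measured; the rules validate presence of what they need.
    """

    patient_id: str
    sex: Sex
    lad: Optional[float] = None
    lvdd: Optional[float] = None
    lvef: Optional[float] = None
    smi: Optional[float] = None
    grip: Optional[float] = None
    gait_speed: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", _as_sex(self.sex))
        for name in ("lad", "lvdd", "lvef", "smi", "grip", "gait_speed"):
            value = getattr(self, name)
            if value is None:
                continue
            value = float(value)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {value}")
            object.__setattr__(self, name, value)
        if self.lvef is not None and self.lvef > 100:
            raise ValueError(f"lvef must be <= 100 %, got {self.lvef}")


@dataclass(frozen=True)
class PositivityResult:
    """Per-index CHF positivity flags for one patient."""

    lad_positive: bool
    lvdd_positive: bool
    lvef_positive: bool
    chf_ultrasound_positive: bool
    n_positive_indices: int


def chf_index_flags(p: PatientRecord, positive_threshold: int = 1) -> PositivityResult:
    """Apply the three cardiac-ultrasound CHF positivity rules to one patient.

    Parameters
    ----------
    p:
        Patient with ``lad``, ``lvdd``, ``lvef`` present and sex known.
    positive_threshold:
        Number of positive indices (1-3) required to call the overall
        ultrasound result positive.  Default 1 (any-of-three).
    """
    if positive_threshold not in (1, 2, 3):
        raise ValueError(f"positive_threshold must be 1, 2 or 3, got {positive_threshold}")
    missing = [name for name in ("lad", "lvdd", "lvef") if getattr(p, name) is None]
    if missing:
        raise ValueError(f"patient {p.patient_id!r} missing required fields: {missing}")

    lad_pos = p.lad > LAD_CUTOFF_MM
    lvdd_pos = p.lvdd > LVDD_CUTOFF_MM[p.sex.value]
    lvef_pos = p.lvef < LVEF_CUTOFF_PCT
    n_pos = int(lad_pos) + int(lvdd_pos) + int(lvef_pos)
    return PositivityResult(
        lad_positive=bool(lad_pos),
        lvdd_positive=bool(lvdd_pos),
        lvef_positive=bool(lvef_pos),
        chf_ultrasound_positive=n_pos >= positive_threshold,
        n_positive_indices=n_pos,
    )


def sarcopenia_positive(p: PatientRecord) -> bool:
    """AWGS-style sarcopenia call: positive iff any present criterion fires."""
    if p.smi is None and p.grip is None and p.gait_speed is None:
        raise ValueError(
            f"patient {p.patient_id!r} has no sarcopenia measurements "
            "(need at least one of smi/grip/gait_speed)"
        )
    if p.smi is not None and p.smi < SMI_CUTOFF_KG_M2[p.sex.value]:
        return True
    if p.grip is not None and p.grip < GRIP_CUTOFF_KG[p.sex.value]:
        return True
    if p.gait_speed is not None and p.gait_speed < GAIT_CUTOFF_M_S:
        return True
    return False


def _round_half_up(value: float, decimals: int = 1) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def similarity_percent(group_chf: int, final_chf: int) -> float:
    """Similarity of a group's CHF calls to the final diagnosis, in percent.

    ``100 * group_chf / final_chf`` rounded half-up to one decimal.
    """
    if final_chf < 1:
        raise ValueError(f"final_chf must be >= 1, got {final_chf}")
    if group_chf < 0:
        raise ValueError(f"group_chf must be >= 0, got {group_chf}")
    return _round_half_up(100.0 * group_chf / final_chf)


def proportion_percent(count: int, total: int, decimals: int = 1) -> float:
    """Share of a cohort, in percent, rounded half-up to ``decimals`` places."""
    if total < 1:
        raise ValueError(f"total must be >= 1, got {total}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return _round_half_up(100.0 * count / total, decimals)


@dataclass(frozen=True)
class DiagnosisTable:
    """Per-group CHF / other-disease counts over one cohort.

    ``groups`` maps a group label to ``(chf_count, other_count)``; every
    column must sum to ``cohort_total``.
    """

    groups: Mapping[str, tuple[int, int]]
    cohort_total: int

    def __post_init__(self) -> None:
        if self.cohort_total < 1:
            raise ValueError("cohort_total must be >= 1")
        groups = dict(self.groups)
        for label, (chf, other) in groups.items():
            if chf < 0 or other < 0:
                raise ValueError(f"negative count in group {label!r}")
            if chf + other != self.cohort_total:
                raise ValueError(
                    f"group {label!r}: chf_count + other_count = {chf + other} "
                    f"!= cohort_total = {self.cohort_total}"
                )
        object.__setattr__(self, "groups", groups)

    def chf_count(self, label: str) -> int:
        return self.groups[label][0]


def concordance_report(table: DiagnosisTable, final_label: str = "final") -> dict[str, dict[str, float]]:
    """Similarity-to-final and CHF-proportion summary for every group.

    Returns ``{label: {"chf_count", "other_count", "chf_proportion_pct",
    "similarity_to_final_pct"}}``.  The final-diagnosis column's similarity
    to itself is 100.0 by construction.
    """
    if final_label not in table.groups:
        raise ValueError(f"table has no column {final_label!r}")
    final_chf = table.chf_count(final_label)
    report: dict[str, dict[str, float]] = {}
    for label, (chf, other) in table.groups.items():
        report[label] = {
            "chf_count": float(chf),
            "other_count": float(other),
            "chf_proportion_pct": proportion_percent(chf, table.cohort_total),
            "similarity_to_final_pct": similarity_percent(chf, final_chf),
        }
    return report


@dataclass(frozen=True)
class TestSummary:
    """Statistic/p-value pair from a two-group comparison."""

    statistic: float
    pvalue: float
    df: float


def group_compare(a: Sequence[float], b: Sequence[float]) -> TestSummary:
    """Two-independent-samples t test with pooled variance."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise ValueError("both samples have zero variance; t statistic undefined")
    result = stats.ttest_ind(a, b, equal_var=True)
    return TestSummary(
        statistic=float(result.statistic),
        pvalue=float(result.pvalue),
        df=float(a.size + b.size - 2),
    )


def count_compare(table: Sequence[Sequence[int]]) -> TestSummary:
    """Pearson chi-square test (no continuity correction) on a 2xk count table."""
    arr = np.asarray(table, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("count table must be 2-D")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("count table has a zero margin; chi-square undefined")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return TestSummary(statistic=float(chi2), pvalue=float(p), df=float(dof))
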