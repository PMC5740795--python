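"""The four trauma mortality scores: ISS/NISS, RTS, MTOS-TRISS, NTrD-TRISS.

ISS sums the squares of the highest AIS grade in each of the three most
severely injured *distinct* body regions; NISS sums the squares of the three
highest grades regardless of region, so NISS >= ISS always. Any AIS-6
(currently untreatable) injury forces both scores to the ceiling of 75, the
standard registry convention.

RTS is the Champion Revised Trauma Score: each of respiratory rate, systolic
blood pressure and GCS is banded to an ordinal 0-4 category score, then

    RTS = 0.2908*RRscore + 0.7326*SBPscore + 0.9368*GCSscore

giving a range of [0, 7.8408].

TRISS combines anatomy and physiology in a logistic survival model
Ps = 1/(1+exp(-b)). MTOS-TRISS uses the Major Trauma Outcome Study
coefficients on (RTS, ISS, AgeIndex), with separate blunt and penetrating
sets; the blunt set is applied universally to children under 15 and, here,
to blast injuries (for which MTOS defines no set). NTrD-TRISS uses the
Malaysian National Trauma Database refit on (NISS, AgeIndex, and the three
RTS category scores), identical for all mechanisms. AgeIndex is 1 for age
>= 55 and 0 otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .registry import AISInjury, Mechanism, PatientRecord, Physiology

__all__ = [
    "RTS_COEFFS",
    "RTS_MAX",
    "MTOS_BLUNT",
    "MTOS_PENETRATING",
    "NTRD_COEFFS",
    "CategoryScores",
    "ScorePanel",
    "score_respiratory_rate",
    "score_systolic_bp",
    "score_gcs",
    "category_scores",
    "compute_rts",
    "compute_iss",
    "compute_niss",
    "age_index",
    "ps_mtos_triss",
    "ps_ntrd_triss",
    "score_panel",
]

#: RTS weights for (RRscore, SBPscore, GCSscore).
RTS_COEFFS = (0.2908, 0.7326, 0.9368)

#: Maximum attainable RTS: all three category scores at 4.
RTS_MAX = 4 * sum(RTS_COEFFS)  # 7.8408

#: MTOS logit coefficients (intercept, RTS, ISS, AgeIndex), blunt mechanism.
MTOS_BLUNT = (-0.4499, 0.8085, -0.0835, -1.7430)

#: MTOS logit coefficients, penetrating mechanism.
MTOS_PENETRATING = (-2.5355, 0.9934, -0.0651, -1.1360)

#: NTrD logit coefficients
#: (intercept, NISS, AgeIndex, RRscore, SBPscore, GCSscore).
NTRD_COEFFS = (-3.6167, -0.0160, -1.1358, 0.2671, 0.8206, 0.6071)


@dataclass(frozen=True)
class CategoryScores:
    """The three 0-4 ordinal physiology categories feeding RTS and NTrD-TRISS."""

    rr_score: int
    sbp_score: int
    gcs_score: int

    def __post_init__(self) -> None:
        for name in ("rr_score", "sbp_score", "gcs_score"):
            value = getattr(self, name)
            if value not in (0, 1, 2, 3, 4):
                raise ValueError(f"{name} must be in 0..4, got {value}")


@dataclass(frozen=True)
class ScorePanel:
    """All scores for one patient, plus the inputs needed to audit them."""

    iss: int
    niss: int
    rts: float
    ps_mtos: float
    ps_ntrd: float
    cats: CategoryScores
    age_index: int
    coefficient_set: str  # "blunt" or "penetrating"


def score_respiratory_rate(rr: int) -> int:
    """Band respiratory rate (breaths/min) to its RTS category score."""
    if rr < 0:
        raise ValueError(f"respiratory rate must be >= 0, got {rr}")
    if 10 <= rr <= 29:
        return 4
    if rr > 29:
        return 3
    if 6 <= rr <= 9:
        return 2
    if 1 <= rr <= 5:
        return 1
    return 0


def score_systolic_bp(sbp: int) -> int:
    """Band systolic blood pressure (mmHg) to its RTS category score."""
    if sbp < 0:
        raise ValueError(f"systolic BP must be >= 0, got {sbp}")
    if sbp > 89:
        return 4
    if 76 <= sbp <= 89:
        return 3
    if 50 <= sbp <= 75:
        return 2
    if 1 <= sbp <= 49:
        return 1
    return 0


def score_gcs(gcs: int) -> int:
    """Band the Glasgow Coma Scale to its RTS category score."""
    if not 3 <= gcs <= 15:
        raise ValueError(f"GCS must be in 3..15, got {gcs}")
    if gcs >= 13:
        return 4
    if gcs >= 9:
        return 3
    if gcs >= 6:
        return 2
    if gcs >= 4:
        return 1
    return 0


def category_scores(phys: Physiology) -> CategoryScores:
    """Band all three physiology variables."""
    return CategoryScores(
        rr_score=score_respiratory_rate(phys.respiratory_rate),
        sbp_score=score_systolic_bp(phys.systolic_bp),
        gcs_score=score_gcs(phys.gcs),
    )


def compute_rts(phys: Physiology) -> float:
    """Revised Trauma Score: weighted sum of the category scores."""
    cats = category_scores(phys)
    w_rr, w_sbp, w_gcs = RTS_COEFFS
    return w_rr * cats.rr_score + w_sbp * cats.sbp_score + w_gcs * cats.gcs_score


def _top_severities_by_region(injuries: tuple[AISInjury, ...] | list[AISInjury]):
    worst: dict[str, int] = {}
    for inj in injuries:
        key = inj.body_region.value
        worst[key] = max(worst.get(key, 0), inj.severity)
    return sorted(worst.values(), reverse=True)


def compute_iss(injuries: tuple[AISInjury, ...] | list[AISInjury]) -> int:
    """Injury Severity Score over the three worst distinct body regions."""
    if any(inj.severity == 6 for inj in injuries):
        return 75
    per_region = _top_severities_by_region(injuries)
    return sum(s * s for s in per_region[:3])


def compute_niss(injuries: tuple[AISInjury, ...] | list[AISInjury]) -> int:
    """New Injury Severity Score over the three worst injuries anywhere."""
    if any(inj.severity == 6 for inj in injuries):
        return 75
    severities = sorted((inj.severity for inj in injuries), reverse=True)
    return sum(s * s for s in severities[:3])


def age_index(age: int) -> int:
    """Binary age covariate: 1 for age >= 55, else 0.

    The source definition covers ages 15-54 (0) and >= 55 (1) only; patients
    under 15 take 0, consistent with applying the blunt coefficient set
    universally to children.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    return 1 if age >= 55 else 0


def _mtos_coefficient_set(age: int, mechanism: Mechanism) -> str:
    mechanism = Mechanism(mechanism)
    if age < 15:
        return "blunt"
    if mechanism is Mechanism.PENETRATING:
        return "penetrating"
    # blast carries no MTOS set of its own; treated as blunt
    return "blunt"


def ps_mtos_triss(
    rts: float, iss: int, age: int, mechanism: Mechanism | str
) -> float:
    """MTOS-TRISS probability of survival.

    Blunt coefficients for blunt and blast mechanisms and for all patients
    under 15 years; penetrating coefficients otherwise.
    """
    coeffs = (
        MTOS_PENETRATING
        if _mtos_coefficient_set(age, Mechanism(mechanism)) == "penetrating"
        else MTOS_BLUNT
    )
    b0, b_rts, b_iss, b_age = coeffs
    b = b0 + b_rts * rts + b_iss * iss + b_age * age_index(age)
    return 1.0 / (1.0 + math.exp(-b))


def ps_ntrd_triss(niss: int, age: int, cats: CategoryScores) -> float:
    """NTrD-TRISS probability of survival; one coefficient set for all
    mechanisms."""
    b0, b_niss, b_age, b_rr, b_sbp, b_gcs = NTRD_COEFFS
    b = (
        b0
        + b_niss * niss
        + b_age * age_index(age)
        + b_rr * cats.rr_score
        + b_sbp * cats.sbp_score
        + b_gcs * cats.gcs_score
    )
    return 1.0 / (1.0 + math.exp(-b))


def score_panel(record: PatientRecord) -> ScorePanel:
    """Compute the full score panel for one validated record."""
    cats = category_scores(record.physiology)
    rts = compute_rts(record.physiology)
    iss = compute_iss(record.injuries)
    niss = compute_niss(record.injuries)
    return ScorePanel(
        iss=iss,
        niss=niss,
        rts=rts,
        ps_mtos=ps_mtos_triss(rts, iss, record.age, record.mechanism),
        ps_ntrd=ps_ntrd_triss(niss, record.age, cats),
        cats=cats,
        age_index=age_index(record.age),
        coefficient_set=_mtos_coefficient_set(record.age, record.mechanism),
    )
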