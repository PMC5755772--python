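"""Clinical classification rules: spine deformity index, osteoporosis,
fracture grouping and the three-step risk triage.

The spine deformity index (SDI) is the sum of per-vertebra Genant
semiquantitative fracture grades (0 normal … 3 severe) over the 13 vertebral
levels T4–L4, so it ranges 0–39.  Osteoporosis is a bone-density T-score
≤ −2.5 at any measured site.  Two distinct fracture dichotomies are used:

* ``fracture_status`` — morphometric fracture presence (SDI ≥ 1), the
  "Fracture yes"/"Fracture no" node of the semantic maps;
* ``assign_fracture_group`` — the subgroup split for the map comparison,
  SDI > 5 (VFx_yes) versus the rest (VFx_no).  The boundary SDI = 5 falls in
  VFx_no: only ">5" defines the fractured subgroup, so the gap at exactly 5
  is closed toward the non-fractured group.

The triage rule screens with three instruments — densitometry (bone quantity
via T-score, bone quality via TBS and bone strain), a serum CTX bone-turnover
test, and the Romberg balance test.  A patient is *high* risk when impaired
balance coincides with impaired bone quality, *intermediate* when any single
criterion fires, *low* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

N_VERTEBRAL_LEVELS = 13  # T4..L4
VFX_YES = "VFx_yes"
VFX_NO = "VFx_no"


@dataclass(frozen=True)
class VertebralGradeSet:
    """Per-vertebra Genant grades for the 13 levels T4–L4."""

    grades: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.grades) != N_VERTEBRAL_LEVELS:
            raise ValueError(
                f"expected {N_VERTEBRAL_LEVELS} vertebral grades, got {len(self.grades)}"
            )
        bad = [g for g in self.grades if g not in (0, 1, 2, 3)]
        if bad:
            raise ValueError(f"Genant grades must be in {{0,1,2,3}}; got {bad[0]}")


def compute_sdi(grades: VertebralGradeSet | Sequence[int]) -> int:
    """Spine deformity index: sum of the 13 Genant grades (range 0–39)."""
    if not isinstance(grades, VertebralGradeSet):
        grades = VertebralGradeSet(tuple(int(g) for g in grades))
    return sum(grades.grades)


def classify_osteoporosis(t_scores: Iterable[float], threshold: float = -2.5) -> bool:
    """Osteoporosis: BMD T-score ≤ −2.5 at any measured site."""
    scores = [float(t) for t in t_scores]
    if not scores:
        raise ValueError("at least one site T-score is required")
    return min(scores) <= threshold


def _check_sdi(sdi: int) -> int:
    sdi = int(sdi)
    if sdi < 0:
        raise ValueError(f"SDI must be non-negative, got {sdi}")
    return sdi


def assign_fracture_group(sdi: int) -> str:
    """Subgroup label for the map comparison: VFx_yes iff SDI > 5."""
    return VFX_YES if _check_sdi(sdi) > 5 else VFX_NO


def fracture_status(sdi: int) -> int:
    """Morphometric fracture presence: 1 iff SDI ≥ 1."""
    return 1 if _check_sdi(sdi) >= 1 else 0


@dataclass(frozen=True)
class TriageThresholds:
    """Cutoffs for the three-step triage.

    Defaults: the T-score cutoff is the operational osteoporosis definition;
    TBS, bone-strain and CTX cutoffs default to the study population's own
    central statistics (no consensus cutoffs exist for these instruments) and
    are meant to be overridden per laboratory.
    """

    t_score_max: float = -2.5     # osteoporotic at or below
    tbs_min: float = 1.20         # impaired microarchitecture below
    bs_max: float = 4.06          # impaired quality above (average strain)
    ctx_max: float = 484.08       # elevated bone turnover above (pg/dl)


@dataclass(frozen=True)
class RiskCategory:
    level: str  # "low" | "intermediate" | "high"
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.level not in ("low", "intermediate", "high"):
            raise ValueError(f"unknown risk level {self.level!r}")
        if self.level != "low" and not self.reasons:
            raise ValueError("non-low risk category requires at least one reason")


_TRIAGE_FIELDS = ("Tscore_Neck", "TBS", "BS_Lumbar", "CTX", "Romberg")


def triage_risk(
    record: Mapping[str, float],
    thresholds: TriageThresholds | None = None,
) -> RiskCategory:
    """Three-step fracture-risk triage of one patient record.

    Criteria: osteoporotic T-score; impaired bone quality (low TBS or high
    bone strain); elevated CTX; positive Romberg.  *high* = positive Romberg
    together with impaired quality; *intermediate* = at least one criterion
    triggered otherwise; *low* = none.
    """
    th = thresholds or TriageThresholds()
    missing = [f for f in _TRIAGE_FIELDS if f not in record]
    if missing:
        raise KeyError(f"record missing triage field(s): {missing}")

    reasons: list[str] = []
    osteoporotic = float(record["Tscore_Neck"]) <= th.t_score_max
    if osteoporotic:
        reasons.append("osteoporotic T-score")
    low_tbs = float(record["TBS"]) < th.tbs_min
    high_bs = float(record["BS_Lumbar"]) > th.bs_max
    impaired_quality = low_tbs or high_bs
    if low_tbs:
        reasons.append("low TBS")
    if high_bs:
        reasons.append("high bone strain")
    elevated_ctx = float(record["CTX"]) > th.ctx_max
    if elevated_ctx:
        reasons.append("elevated CTX")
    romberg = int(record["Romberg"]) == 1
    if romberg:
        reasons.append("positive Romberg")

    if romberg and impaired_quality:
        return RiskCategory("high", tuple(reasons))
    if reasons:
        return RiskCategory("intermediate", tuple(reasons))
    return RiskCategory("low", ())
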