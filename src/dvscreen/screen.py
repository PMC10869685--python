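"""Screening decision rule and radiologist-queue prioritization.

Per breast, the pipeline runs: (1) acquire the CC and MLO views, (2) suspicious
mass detection on both views, (3) detection of other abnormalities on both
views, (4) dual-view abnormality probability, (5) the binary decision, and
(6) sorting into a four-tier review queue:

    tier 1 — suspicious mass detected (objectness ≥ threshold)
    tier 2 — classifier calls abnormal (probability > threshold), no tier-1 mass
    tier 3 — only the all-abnormality detector found something
    tier 4 — clean

By default a breast is called abnormal when the classifier OR the mass detector
triggers (prob > 0.5 strictly, or mass objectness ≥ 0.25): the detector exists
to rescue masses the classifier misses, which raises sensitivity at some cost
in precision. A conjunctive variant is available via ``logic="and"``. Findings
from the all-abnormality detector never flip the binary decision — they only
inform prioritization — because mixing annotation conventions across sources
makes that detector too false-positive-prone to gate the call.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .detect import BoundingBox, DetectorContract, detect_exam, max_objectness
from .imaging import BreastExam

logger = logging.getLogger("dvscreen.screen")

NORMAL_DECISION = "normal"
ABNORMAL_DECISION = "abnormal"


@dataclass(frozen=True)
class ScreeningThresholds:
    """Decision thresholds: classifier probability (strict >) and mass objectness (≥)."""

    prob_threshold: float = 0.5
    objectness_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0 and 0.0 < self.objectness_threshold < 1.0):
            raise ValueError("both thresholds must lie strictly in (0,1)")


@dataclass(frozen=True)
class ScreeningDecision:
    """One breast's screening outcome, ready for the review queue."""

    study_id: str
    laterality: str
    prob: float
    mass_objectness: float
    other_findings: tuple[BoundingBox, ...]
    decision: str
    tier: int
    reasons: tuple[str, ...]
    mass_boxes: tuple[BoundingBox, ...] = ()

    @property
    def priority_score(self) -> float:
        return max(self.prob, self.mass_objectness)


def decide(prob: float, mass_objectness: float,
           thresholds: ScreeningThresholds = ScreeningThresholds(),
           logic: str = "or") -> str:
    """Binary screening decision from the classifier and mass-detector scores.

    ``logic="or"`` (default): abnormal when either trigger fires — probability
    strictly above ``prob_threshold`` or mass objectness at/above
    ``objectness_threshold``. ``logic="and"`` requires both.
    """
    if not (0.0 <= prob <= 1.0 and 0.0 <= mass_objectness <= 1.0):
        raise ValueError("prob and mass_objectness must be in [0,1]")
    cls_trigger = prob > thresholds.prob_threshold
    det_trigger = mass_objectness >= thresholds.objectness_threshold
    if logic == "or":
        fired = cls_trigger or det_trigger
    elif logic == "and":
        fired = cls_trigger and det_trigger
    else:
        raise ValueError(f"logic must be 'or' or 'and', got {logic!r}")
    return ABNORMAL_DECISION if fired else NORMAL_DECISION


def assign_tier(prob: float, mass_objectness: float, other_findings: Sequence[BoundingBox],
                thresholds: ScreeningThresholds = ScreeningThresholds()) -> int:
    """Review-queue tier 1..4 (lower = seen earlier by the radiologist)."""
    if mass_objectness >= thresholds.objectness_threshold:
        return 1
    if prob > thresholds.prob_threshold:
        return 2
    if other_findings:
        return 3
    return 4


def build_decision(exam: BreastExam, prob: float, mass_boxes_cc: Sequence[BoundingBox],
                   mass_boxes_mlo: Sequence[BoundingBox],
                   other_findings: Sequence[BoundingBox],
                   thresholds: ScreeningThresholds = ScreeningThresholds(),
                   logic: str = "or") -> ScreeningDecision:
    """Assemble the full per-breast decision record with human-readable reasons."""
    mass_obj = max_objectness(mass_boxes_cc, mass_boxes_mlo, "suspicious_mass")
    decision = decide(prob, mass_obj, thresholds, logic)
    tier = assign_tier(prob, mass_obj, other_findings, thresholds)
    reasons: list[str] = []
    if mass_obj >= thresholds.objectness_threshold:
        reasons.append(f"suspicious mass detected (objectness {mass_obj:.2f} >= "
                       f"{thresholds.objectness_threshold})")
    if prob > thresholds.prob_threshold:
        reasons.append(f"classifier abnormal (p={prob:.2f} > {thresholds.prob_threshold})")
    if other_findings:
        classes = sorted({b.class_name for b in other_findings})
        reasons.append(f"abnormality detector findings: {', '.join(classes)}")
    if decision == ABNORMAL_DECISION and not reasons:
        reasons.append("flagged abnormal")
    return ScreeningDecision(
        study_id=exam.study_id, laterality=exam.laterality, prob=float(prob),
        mass_objectness=float(mass_obj), other_findings=tuple(other_findings),
        decision=decision, tier=tier, reasons=tuple(reasons),
        mass_boxes=tuple((*mass_boxes_cc, *mass_boxes_mlo)))


def screen_cohort(exams: Sequence[BreastExam], classifier: Callable[[BreastExam], float],
                  mass_detector: DetectorContract,
                  abnormality_detector: DetectorContract | None = None,
                  thresholds: ScreeningThresholds = ScreeningThresholds(),
                  logic: str = "or") -> list[ScreeningDecision]:
    """Screen every breast and return decisions in radiologist review order.

    Ordering: ascending tier, then descending max(prob, mass objectness), then
    (study_id, laterality) for a stable, deterministic queue.
    """
    decisions: list[ScreeningDecision] = []
    for exam in exams:
        try:
            prob = float(classifier(exam))
        except Exception:
            logger.warning("skipping breast %s/%s: classifier failed",
                           exam.study_id, exam.laterality)
            continue
        m_cc, m_mlo = detect_exam(mass_detector, exam)
        mass_boxes_cc = [b for b in m_cc if b.class_name == "suspicious_mass"]
        mass_boxes_mlo = [b for b in m_mlo if b.class_name == "suspicious_mass"]
        other: list[BoundingBox] = []
        if abnormality_detector is not None:
            a_cc, a_mlo = detect_exam(abnormality_detector, exam)
            other = [b for b in (*a_cc, *a_mlo) if b.class_name != "suspicious_mass"]
        decisions.append(build_decision(exam, prob, mass_boxes_cc, mass_boxes_mlo,
                                        other, thresholds, logic))
    decisions.sort(key=lambda dec: (dec.tier, -dec.priority_score, dec.study_id, dec.laterality))
    return decisions


def patient_queue(decisions: Sequence[ScreeningDecision]) -> list[tuple[str, int, float]]:
    """Collapse breast-level decisions to a per-patient queue.

    A patient is queued at the best (lowest) tier of their breasts, with the
    higher priority score breaking ties within a tier.
    """
    best: dict[str, tuple[int, float]] = {}
    for dec in decisions:
        tier, score = best.get(dec.study_id, (5, -1.0))
        cand = (dec.tier, dec.priority_score)
        if cand[0] < tier or (cand[0] == tier and cand[1] > score):
            best[dec.study_id] = cand
    rows = [(sid, t, s) for sid, (t, s) in best.items()]
    rows.sort(key=lambda r: (r[1], -r[2], r[0]))
    return rows


def write_report(decisions: Sequence[ScreeningDecision], path: str | Path) -> None:
    """JSON-lines report: one object per breast with scores, tier and overlay boxes."""
    with open(path, "w") as fh:
        for dec in decisions:
            fh.write(json.dumps({
                "study_id": dec.study_id, "laterality": dec.laterality,
                "prob": dec.prob, "mass_objectness": dec.mass_objectness,
                "decision": dec.decision, "tier": dec.tier, "reasons": list(dec.reasons),
                "mass_boxes": [list(b.as_tuple()) for b in dec.mass_boxes],
                "other_findings": [
                    {"class": b.class_name, "box": list(b.as_tuple()),
                     "objectness": b.objectness} for b in dec.other_findings],
            }) + "\n")


def write_queue(decisions: Sequence[ScreeningDecision], path: str | Path) -> None:
    """CSV review queue, already in priority order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "study_id", "laterality", "tier", "decision",
                         "prob", "mass_objectness"])
        for rank, dec in enumerate(decisions, start=1):
            writer.writerow([rank, dec.study_id, dec.laterality, dec.tier, dec.decision,
                             f"{dec.prob:.4f}", f"{dec.mass_objectness:.4f}"])
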