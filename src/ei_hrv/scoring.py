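"""Emotion-recognition scoring and stimulus-selection filters.

Responses live on a two-dimensional emotion model: 7-point Likert arousal and
valence plus a keyword naming one of the four quadrants HAHV / HALV / LALV /
LAHV (high/low arousal × high/low valence).  A Likert value of 5–7 counts as
the high half, 1–3 as the low half, and the midpoint 4 belongs to no quadrant
(so it can never match a target) — this midpoint exclusion is configurable.

Three evaluation kinds are scored, 10 points apiece, all-or-nothing:

* ``self_awareness`` (photo items): arousal half, valence half and keyword
  must all be consistent with the target quadrant;
* ``others_awareness`` (avatar items): the expression must be recognised AND
  the chosen domain must equal the target;
* ``discrimination`` (four avatars placed side by side): the ``recognized``
  flag carries the "all four placements correct" outcome for the item.

The full design is 3 evaluations × 4 domains × 10 stimuli = 120 items, hence
a 1200-point maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("HAHV", "HALV", "LALV", "LAHV")
EVALUATIONS = ("self_awareness", "others_awareness", "discrimination")
POINTS_PER_ITEM = 10
MAX_TOTAL = POINTS_PER_ITEM * len(EVALUATIONS) * len(DOMAINS) * 10  # 1200

#: target quadrant → (arousal half, valence half); True = high half
_QUADRANT = {
    "HAHV": (True, True),
    "HALV": (True, False),
    "LALV": (False, False),
    "LAHV": (False, True),
}


class ScoringError(ValueError):
    pass


def likert_half(value: int, midpoint_excluded: bool = True) -> bool | None:
    """Map a 1–7 Likert value to the high (True) or low (False) half.

    The midpoint 4 maps to ``None`` (no quadrant) unless
    ``midpoint_excluded`` is False, in which case it counts as high.
    """
    if not 1 <= value <= 7:
        raise ScoringError(f"Likert value {value} outside 1–7")
    if value >= 5:
        return True
    if value <= 3:
        return False
    return None if midpoint_excluded else True


@dataclass(frozen=True)
class ResponseItem:
    """One questionnaire item."""

    evaluation: str
    domain_target: str
    chosen_arousal: int = 4
    chosen_valence: int = 4
    chosen_keyword_domain: str = "neutral"
    recognized: bool = False
    stimulus_id: object = None

    def __post_init__(self) -> None:
        if self.evaluation not in EVALUATIONS:
            raise ScoringError(f"unknown evaluation kind {self.evaluation!r}")
        if self.domain_target not in DOMAINS:
            raise ScoringError(f"unknown target domain {self.domain_target!r}")
        if self.chosen_keyword_domain not in DOMAINS + ("neutral",):
            raise ScoringError(f"unknown keyword domain {self.chosen_keyword_domain!r}")
        for v in (self.chosen_arousal, self.chosen_valence):
            if not 1 <= v <= 7:
                raise ScoringError(f"Likert value {v} outside 1–7")

    @property
    def identity(self) -> tuple:
        return (self.evaluation, self.domain_target, self.stimulus_id)


@dataclass(frozen=True)
class EvaluationScore:
    """Item points and totals for one participant (max 1200)."""

    participant_id: str
    item_points: tuple[int, ...]
    per_evaluation: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.item_points):
            raise ScoringError("total does not equal sum of item points")
        if self.total > MAX_TOTAL:
            raise ScoringError(f"total {self.total} exceeds maximum {MAX_TOTAL}")


def score_item(item: ResponseItem, midpoint_excluded: bool = True) -> int:
    """10 points iff every required field matches the target, else 0."""
    target = item.domain_target
    if item.evaluation == "self_awareness":
        halves = _QUADRANT[target]
        a = likert_half(item.chosen_arousal, midpoint_excluded)
        v = likert_half(item.chosen_valence, midpoint_excluded)
        ok = (a, v) == halves and item.chosen_keyword_domain == target
    elif item.evaluation == "others_awareness":
        ok = item.recognized and item.chosen_keyword_domain == target
    elif item.evaluation == "discrimination":
        ok = item.recognized
    else:  # pragma: no cover - guarded in __post_init__
        raise ScoringError(f"unknown evaluation kind {item.evaluation!r}")
    return POINTS_PER_ITEM if ok else 0


def total_score(
    items: list[ResponseItem],
    participant_id: str = "",
    midpoint_excluded: bool = True,
) -> EvaluationScore:
    """Sum item points per evaluation and overall.

    Raises on duplicate item identity (same evaluation, target domain and
    stimulus id).
    """
    seen = set()
    for it in items:
        if it.identity in seen:
            raise ScoringError(f"duplicate item identity {it.identity}")
        seen.add(it.identity)
    points = tuple(score_item(it, midpoint_excluded) for it in items)
    per_eval = {ev: 0 for ev in EVALUATIONS}
    for it, p in zip(items, points):
        per_eval[it.evaluation] += p
    return EvaluationScore(
        participant_id=participant_id,
        item_points=points,
        per_evaluation=per_eval,
        total=sum(points),
    )


def domain_accuracy(
    items: list[ResponseItem], domain: str, midpoint_excluded: bool = True
) -> float:
    """Percentage of correct items among those targeting ``domain``."""
    in_domain = [it for it in items if it.domain_target == domain]
    if not in_domain:
        raise ScoringError(f"no responses for domain {domain}")
    correct = sum(score_item(it, midpoint_excluded) > 0 for it in in_domain)
    return 100.0 * correct / len(in_domain)


def select_photo_stimuli(
    accuracies: dict, threshold: float = 81.0
) -> list:
    """Keep photos whose recognition accuracy is at or above the threshold.

    The comparison is inclusive (accuracy of exactly 81 % is kept).  Returns
    the kept photo ids in input order; warns when nothing survives.
    """
    for pid, acc in accuracies.items():
        if not 0 <= acc <= 100:
            raise ScoringError(f"accuracy {acc} for {pid!r} outside [0, 100]")
    kept = [pid for pid, acc in accuracies.items() if acc >= threshold]
    if not kept:
        logger.warning("no photo reached the %.0f%% accuracy threshold", threshold)
    return kept


def select_peak_intensity(accuracy_by_intensity: dict) -> tuple:
    """Intensity level with maximal recognition accuracy.

    Ties are broken toward the lower intensity.  Returns (intensity,
    accuracy).
    """
    if not accuracy_by_intensity:
        raise ScoringError("no intensity levels supplied")
    best = max(
        sorted(accuracy_by_intensity),
        key=lambda k: (accuracy_by_intensity[k], -k),
    )
    return best, accuracy_by_intensity[best]


def responses_from_frame(frame: pd.DataFrame) -> list[ResponseItem]:
    """Build items from a response table.

    Expected columns: evaluation, target_domain, arousal, valence, keyword,
    recognized; optional participant and stimulus_id.
    """
    items = []
    for i, row in frame.iterrows():
        items.append(
            ResponseItem(
                evaluation=row["evaluation"],
                domain_target=row["target_domain"],
                chosen_arousal=int(row["arousal"]),
                chosen_valence=int(row["valence"]),
                chosen_keyword_domain=row["keyword"],
                recognized=bool(row["recognized"]),
                stimulus_id=row.get("stimulus_id", i),
            )
        )
    return items
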