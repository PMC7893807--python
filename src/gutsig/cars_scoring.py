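"""CARS behavioral domain scores and severity labelling.

The Childhood Autism Rating Scale has 15 items scored 1-4 in half-point
steps. Three domain scores are used here: *social impairment* (a broad item
set), *negative emotionality* (affect, adaptation to change, anxiety) and
*distorted sensory response* (visual, auditory, near-receptor items 7-9).
Item sets are configurable because published domain definitions vary; the
defaults below follow the common clinical grouping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_core import CARS_ITEM_GRID, CARS_ITEM_NAMES, CohortMetadata, ValidationError

__all__ = [
    "CarsDomainScores",
    "DEFAULT_SOCIAL_ITEMS",
    "DEFAULT_NEGATIVE_ITEMS",
    "DEFAULT_SENSORY_ITEMS",
    "SEVERITY_THRESHOLD",
    "score_domains",
    "severity_label",
    "score_cohort",
]

# 1-based item indices for each behavioral domain. Note cars10 (anxiety
# reaction) contributes to both the social and negative-emotionality sets.
DEFAULT_SOCIAL_ITEMS: tuple[int, ...] = (1, 2, 4, 5, 10, 11, 12, 13, 14, 15)
DEFAULT_NEGATIVE_ITEMS: tuple[int, ...] = (3, 6, 10)
DEFAULT_SENSORY_ITEMS: tuple[int, ...] = (7, 8, 9)

#: CARS total at or above which a child is labelled "severe".
SEVERITY_THRESHOLD = 36.0


@dataclass(frozen=True)
class CarsDomainScores:
    social_impairment: float
    negative_emotionality: float
    distorted_sensory_response: float
    cars_total: float
    items_ge3: int


def _check_items(items: Sequence[float]) -> None:
    if len(items) != 15:
        raise ValidationError(f"expected 15 CARS items, got {len(items)}")
    for name, v in zip(CARS_ITEM_NAMES, items):
        if not any(math.isclose(v, g, abs_tol=1e-9) for g in CARS_ITEM_GRID):
            raise ValidationError(f"item {name} value {v} is off the 1-4 half-point grid")


def score_domains(
    cars_items: Sequence[float],
    social_items: Sequence[int] = DEFAULT_SOCIAL_ITEMS,
    negative_items: Sequence[int] = DEFAULT_NEGATIVE_ITEMS,
    sensory_items: Sequence[int] = DEFAULT_SENSORY_ITEMS,
) -> CarsDomainScores:
    """Compute the three domain scores, the total, and the count of items >= 3.

    Parameters
    ----------
    cars_items : sequence of 15 floats
        Item scores in item order (cars1 ... cars15), each on the legal grid.
    social_items, negative_items, sensory_items : sequences of int
        1-based item indices defining each domain.
    """
    _check_items(cars_items)

    def dsum(idx: Sequence[int]) -> float:
        return float(sum(cars_items[i - 1] for i in idx))

    return CarsDomainScores(
        social_impairment=dsum(social_items),
        negative_emotionality=dsum(negative_items),
        distorted_sensory_response=dsum(sensory_items),
        cars_total=float(sum(cars_items)),
        items_ge3=int(sum(1 for v in cars_items if v >= 3)),
    )


def severity_label(cars_total: float, threshold: float = SEVERITY_THRESHOLD) -> str:
    """Label a CARS total as ``severe`` (>= threshold) or ``mild_moderate``."""
    if not (15.0 <= cars_total <= 60.0):
        raise ValidationError(f"cars_total {cars_total} outside the [15, 60] range")
    return "severe" if cars_total >= threshold else "mild_moderate"


def score_cohort(records: Iterable[CohortMetadata], **domain_sets) -> pd.DataFrame:
    """Score every sample; returns a DataFrame indexed by sample id.

    Columns: the three domain scores, cars_total, items_ge3, severity.
    """
    rows = {}
    for r in records:
        s = score_domains(r.cars_items, **domain_sets)
        rows[r.sample_id] = {
            "social_impairment": s.social_impairment,
            "negative_emotionality": s.negative_emotionality,
            "distorted_sensory_response": s.distorted_sensory_response,
            "cars_total": s.cars_total,
            "items_ge3": s.items_ge3,
            "severity": severity_label(s.cars_total),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")
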