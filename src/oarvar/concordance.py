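"""Pairwise concordance index (intersection over union) and its aggregation.

The concordance index of two masks is |A∩B| / |A∪B| by voxel count: 1 for
identical structures, 0 for disjoint ones.  Per-organ summaries pool all
observer pairs and all scans with equal weight.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .grid import BinaryMask, DegenerateMaskError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseCI:
    patient_id: str
    scan_time: str
    organ: str
    observer_a: str
    observer_b: str
    ci: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci <= 1.0:
            raise ValueError(f"ci must be in [0, 1], got {self.ci}")


@dataclass(frozen=True)
class CISummary:
    organ: str
    mean_ci: float
    min_ci: float
    max_ci: float
    n_pairs_total: int


def pairwise_ci(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard overlap of two masks on the identical grid.

    One empty mask against a non-empty one is genuine zero agreement and
    returns 0 (logged); two empty masks are undefined and raise.
    """
    if a.grid != b.grid:
        raise ValueError(f"grid mismatch: {a.grid} vs {b.grid}")
    if a.is_empty() and b.is_empty():
        raise DegenerateMaskError("concordance undefined for two empty masks")
    if a.is_empty() or b.is_empty():
        logger.warning("one mask empty: concordance 0")
        return 0.0
    inter = int((a.occupancy & b.occupancy).sum())
    union = int((a.occupancy | b.occupancy).sum())
    return inter / union


def dice_from_ci(ci: float) -> float:
    """Dice coefficient implied by a Jaccard value: 2*ci / (1 + ci)."""
    return 2.0 * ci / (1.0 + ci)


def all_pairs_ci(
    masks: Mapping[str, BinaryMask],
    patient_id: str,
    scan_time: str,
    organ: str,
) -> list[PairwiseCI]:
    """CI for every unordered observer pair of one (patient, scan, organ)."""
    out = []
    for obs_a, obs_b in itertools.combinations(sorted(masks), 2):
        out.append(
            PairwiseCI(
                patient_id=patient_id,
                scan_time=scan_time,
                organ=organ,
                observer_a=obs_a,
                observer_b=obs_b,
                ci=pairwise_ci(masks[obs_a], masks[obs_b]),
            )
        )
    return out


def aggregate_ci(pairs: Sequence[PairwiseCI], organ: str) -> CISummary:
    """Unweighted mean/min/max over all pair-and-scan records of one organ."""
    values = [p.ci for p in pairs if p.organ == organ]
    if not values:
        raise ValueError(f"no pairwise records for organ {organ!r}")
    return CISummary(
        organ=organ,
        mean_ci=sum(values) / len(values),
        min_ci=min(values),
        max_ci=max(values),
        n_pairs_total=len(values),
    )


def pairs_to_frame(pairs: Sequence[PairwiseCI]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "scan_time": p.scan_time,
                "organ": p.organ,
                "observer_a": p.observer_a,
                "observer_b": p.observer_b,
                "ci": p.ci,
            }
            for p in pairs
        ]
    )
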