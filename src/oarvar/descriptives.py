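"""Volume descriptives: per-organ mean/SE/CV, per-observer ratios, Friedman test.

All statistics run on a long-format volume table with one record per
(patient, scan time, observer, organ) structure.  Sample standard
deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contours import DelineationSet
from .grid import delineation_volume

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """The record layout does not satisfy a test's design requirements."""


@dataclass(frozen=True)
class VolumeRecord:
    patient_id: str
    scan_time: str
    observer_id: str
    organ: str
    volume: float  # cm^3

    def __post_init__(self) -> None:
        if not (np.isfinite(self.volume) and self.volume >= 0):
            raise ValueError(f"volume must be finite and >= 0, got {self.volume}")


@dataclass(frozen=True)
class OrganSummary:
    organ: str
    mean_volume: float  # cm^3
    se: float  # cm^3
    cv: float  # fraction
    oar_ratio: dict[str, float]  # observer -> ratio
    n_records: int


@dataclass(frozen=True)
class FriedmanResult:
    organ: str
    statistic: float
    dof: int
    p_value: float
    n_blocks: int


def records_to_frame(records: Iterable[VolumeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "scan_time": r.scan_time,
                "observer_id": r.observer_id,
                "organ": r.organ,
                "volume": r.volume,
            }
            for r in records
        ]
    )


def build_volume_table(cset: DelineationSet) -> list[VolumeRecord]:
    """One volume record per delineation, skipping flagged exclusions.

    Exclusions are listed in ``cset.metadata["excluded"]`` as
    ``[patient_id, organ]`` pairs and are dropped with a log message.
    """
    excluded = {tuple(e) for e in cset.metadata.get("excluded", [])}
    out: list[VolumeRecord] = []
    for d in cset:
        if (d.patient_id, d.organ) in excluded:
            logger.info("excluding %s / %s from the volume table", d.patient_id, d.organ)
            continue
        out.append(
            VolumeRecord(
                patient_id=d.patient_id,
                scan_time=d.scan_time,
                observer_id=d.observer_id,
                organ=d.organ,
                volume=delineation_volume(d),
            )
        )
    return out


def summarize_organ(
    records: Sequence[VolumeRecord],
    organ: str,
    cv_method: Literal["per_scan", "pooled"] = "per_scan",
    se_method: Literal["all_records", "patient_means"] = "all_records",
) -> OrganSummary:
    """Mean volume, SE, CV and per-observer volume ratios for one organ.

    ``cv_method='per_scan'`` (default) averages the across-observer CV over
    the (patient, scan) cells; ``'pooled'`` is SD/mean over all records.
    ``se_method`` picks the SD pool for the standard error of the mean.
    """
    df = records_to_frame(records)
    df = df[df["organ"] == organ]
    if len(df) < 2:
        raise DesignError(f"need >= 2 records for organ {organ!r}, got {len(df)}")
    vols = df["volume"].to_numpy()
    mean_volume = float(vols.mean())

    if se_method == "all_records":
        se = float(vols.std(ddof=1) / np.sqrt(len(vols)))
    elif se_method == "patient_means":
        pm = df.groupby("patient_id")["volume"].mean()
        se = float(pm.std(ddof=1) / np.sqrt(len(pm)))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    if cv_method == "per_scan":
        per_scan = df.groupby(["patient_id", "scan_time"])["volume"].agg(
            lambda v: v.std(ddof=1) / v.mean() if len(v) > 1 and v.mean() > 0 else np.nan
        )
        cv = float(per_scan.dropna().mean()) if per_scan.notna().any() else 0.0
    elif cv_method == "pooled":
        cv = float(vols.std(ddof=1) / mean_volume) if mean_volume > 0 else 0.0
    else:
        raise ValueError(f"unknown cv_method {cv_method!r}")

    obs_means = df.groupby("observer_id")["volume"].mean()
    grand = float(obs_means.mean())
    if grand > 0:
        ratios = {str(o): float(v / grand) for o, v in obs_means.items()}
    else:
        logger.warning("organ %s: zero grand mean, OAR ratios set to 1", organ)
        ratios = {str(o): 1.0 for o in obs_means.index}

    return OrganSummary(
        organ=organ,
        mean_volume=mean_volume,
        se=se,
        cv=cv,
        oar_ratio=ratios,
        n_records=len(df),
    )


def friedman_test(
    records: Sequence[VolumeRecord], organ: str, scan_time: str = "plan"
) -> FriedmanResult:
    """Friedman rank test for a systematic observer effect on one scan time.

    Blocks are patients, treatments are observers; mid-ranks with the usual
    tie correction (as implemented by :func:`scipy.stats.friedmanchisquare`).
    Requires a complete (patient x observer) block design.
    """
    df = records_to_frame(records)
    df = df[(df["organ"] == organ) & (df["scan_time"] == scan_time)]
    if df.empty:
        raise DesignError(f"no records for organ {organ!r} at scan_time {scan_time!r}")
    table = df.pivot(index="patient_id", columns="observer_id", values="volume")
    missing = [
        (str(p), str(o))
        for p in table.index
        for o in table.columns
        if pd.isna(table.loc[p, o])
    ]
    if missing:
        raise DesignError(f"incomplete block design; missing cells: {missing}")
    n_patients, n_observers = table.shape
    if n_observers < 2 or n_patients < 2:
        raise DesignError(
            f"need >= 2 observers and >= 2 patients, got {n_observers} x {n_patients}"
        )
    columns = [table[c].to_numpy() for c in table.columns]
    if np.allclose(np.ptp(np.asarray(columns), axis=0), 0):
        # all observers tie within every patient: statistic is 0 by definition,
        # scipy rejects the degenerate all-equal input
        return FriedmanResult(organ, 0.0, n_observers - 1, 1.0, n_patients)
    stat, p = stats.friedmanchisquare(*columns)
    return FriedmanResult(
        organ=organ,
        statistic=float(stat),
        dof=n_observers - 1,
        p_value=float(p),
        n_blocks=n_patients,
    )


def summaries_to_frame(summaries: Sequence[OrganSummary]) -> pd.DataFrame:
    """Table-style export: one row per organ, ratio columns per observer."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "organ": s.organ,
            "mean_volume_cm3": s.mean_volume,
            "se_cm3": s.se,
            "cv": s.cv,
            "n_records": s.n_records,
        }
        for obs, ratio in sorted(s.oar_ratio.items()):
            row[f"oar_ratio_{obs}"] = ratio
        rows.append(row)
    return pd.DataFrame(rows)
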