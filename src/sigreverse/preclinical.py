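"""Quantification of DSS-colitis read-outs and qPCR relative expression.

Implements the scoring formulas used to follow up screening hits in the
dextran-sodium-sulfate (DSS) mouse colitis model:

* Disease Activity Index: DAI = (weight score + stool score + blood score)/3,
  with weight-loss bands 0-4 and three-level stool/blood categories mapping
  to {0, 2, 4};
* trapezoidal area under the DAI time course;
* a 0-40 histopathology composite: per-feature severity grade times the area
  score (fraction of section involved), summed over inflammation, extent of
  damage and crypt damage;
* myeloperoxidase activity normalized per gram of colon tissue;
* ddCp relative quantification of qPCR crossing points against a
  housekeeping gene (GAPDH) and a sham reference, with fold change 2^ddCp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

STOOL_SCORES = {"normal": 0, "loose": 2, "diarrhea": 4}
BLOOD_SCORES = {"none": 0, "visible": 2, "rectal": 4}

# (severity ceiling) per histopathology feature; area score is 1-4 throughout
HISTOPATH_FEATURES = {"inflammation": 3, "extent_of_damage": 3, "crypt_damage": 4}


@dataclass(frozen=True)
class AnimalObservation:
    """One animal-day of colitis observations.

    weight_pct_change is percent of day-0 body weight (negative = loss).
    stool/blood categories come from three-level vocabularies; scorers using
    intermediate grades (1 or 3) can bypass the category mapping with the
    numeric override fields.
    """

    animal_id: str
    group: str
    day: int
    weight_pct_change: float
    stool_category: str
    blood_category: str
    stool_score_override: int | None = None
    blood_score_override: int | None = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.stool_category not in STOOL_SCORES:
            raise ValueError(
                f"unknown stool category {self.stool_category!r}; "
                f"expected one of {sorted(STOOL_SCORES)}"
            )
        if self.blood_category not in BLOOD_SCORES:
            raise ValueError(
                f"unknown blood category {self.blood_category!r}; "
                f"expected one of {sorted(BLOOD_SCORES)}"
            )
        for override in (self.stool_score_override, self.blood_score_override):
            if override is not None and override not in range(5):
                raise ValueError("score overrides must be integers 0-4")


@dataclass(frozen=True)
class DAIRecord:
    """Component scores and their mean, the Disease Activity Index."""

    weight_score: int
    stool_score: int
    blood_score: int
    dai: float

    def __post_init__(self) -> None:
        expected = (self.weight_score + self.stool_score + self.blood_score) / 3.0
        if not math.isclose(self.dai, expected, abs_tol=1e-12):
            raise ValueError("dai must equal the mean of the three component scores")


@dataclass(frozen=True)
class HistopathObservation:
    """Severity grade and area score for each colon histopathology feature.

    Severity scales: inflammation 0-3 (none to severe), extent of damage 0-3
    (none to transmural), crypt damage 0-4 (none to entire crypt and
    epithelium lost). Area scores grade the fraction of the section involved
    in quartiles (1: 1-25% ... 4: 76-100%); a feature with severity 0 must
    have area 0.
    """

    inflammation_severity: int
    inflammation_area: int
    extent_severity: int
    extent_area: int
    crypt_severity: int
    crypt_area: int

    def __post_init__(self) -> None:
        grades = {
            "inflammation": (self.inflammation_severity, self.inflammation_area),
            "extent_of_damage": (self.extent_severity, self.extent_area),
            "crypt_damage": (self.crypt_severity, self.crypt_area),
        }
        for feature, (severity, area) in grades.items():
            max_sev = HISTOPATH_FEATURES[feature]
            if not 0 <= severity <= max_sev:
                raise ValueError(f"{feature} severity {severity} outside 0-{max_sev}")
            if severity == 0:
                if area != 0:
                    raise ValueError(f"{feature}: severity 0 requires area 0, got {area}")
            elif not 1 <= area <= 4:
                raise ValueError(f"{feature} area score {area} outside 1-4")


@dataclass(frozen=True)
class CpMeasurement:
    """qPCR crossing points for a target gene and the GAPDH housekeeping gene."""

    sample_id: str
    gene: str
    cp: float
    cp_gapdh: float

    def __post_init__(self) -> None:
        for name, value in (("cp", self.cp), ("cp_gapdh", self.cp_gapdh)):
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and positive, got {value}")


class DdcpResult(NamedTuple):
    delta_cp: float
    delta_delta_cp: float
    fold_change: float


def weight_score(weight_pct_change: float) -> int:
    """Body-weight-loss score: 0 (<1% loss) to 4 (>=15% loss)."""
    if not math.isfinite(weight_pct_change):
        raise ValueError("weight_pct_change must be finite")
    loss = -weight_pct_change  # positive loss = percent below day-0 weight
    if loss < 1.0:
        return 0
    if loss < 5.0:
        return 1
    if loss < 10.0:
        return 2
    if loss < 15.0:
        return 3
    return 4


def score_observation(obs: AnimalObservation) -> DAIRecord:
    """Disease Activity Index of one animal-day.

    DAI = (body weight score + stool consistency score + fecal blood
    score) / 3, each component on a 0-4 scale.
    """
    w = weight_score(obs.weight_pct_change)
    s = obs.stool_score_override if obs.stool_score_override is not None else STOOL_SCORES[obs.stool_category]
    b = obs.blood_score_override if obs.blood_score_override is not None else BLOOD_SCORES[obs.blood_category]
    return DAIRecord(weight_score=w, stool_score=s, blood_score=b, dai=(w + s + b) / 3.0)


def dai_auc(timecourse: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a (day, DAI) time course; no extrapolation."""
    if len(timecourse) < 2:
        raise ValueError("need at least 2 time points for an AUC")
    days = np.asarray([d for d, _ in timecourse], dtype=float)
    dai = np.asarray([v for _, v in timecourse], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing with no duplicates")
    return float(np.trapezoid(dai, days))


def histopath_score(obs: HistopathObservation) -> int:
    """Composite colon histopathology score on the 0-40 scale.

    Sum over the three features of severity grade x area score; the maximum
    (3x4 + 3x4 + 4x4) is 40.
    """
    return (
        obs.inflammation_severity * obs.inflammation_area
        + obs.extent_severity * obs.extent_area
        + obs.crypt_severity * obs.crypt_area
    )


def mpo_per_gram(activity_units: float, tissue_mass_g: float) -> float:
    """Myeloperoxidase activity normalized per gram of colon tissue."""
    if not (math.isfinite(tissue_mass_g) and tissue_mass_g > 0):
        raise ValueError(f"tissue mass must be positive, got {tissue_mass_g}")
    return activity_units / tissue_mass_g


def delta_delta_cp(sample: CpMeasurement, sham_delta_cp: float) -> DdcpResult:
    """Relative qPCR quantification against GAPDH and a sham reference.

    delta_cp = Cp(GAPDH) - Cp(sample); delta_delta_cp subtracts the sham
    group's delta_cp; fold change is 2^delta_delta_cp (1 = sham level).
    """
    if not math.isfinite(sham_delta_cp):
        raise ValueError("sham_delta_cp must be finite")
    dcp = sample.cp_gapdh - sample.cp
    ddcp = dcp - sham_delta_cp
    return DdcpResult(delta_cp=dcp, delta_delta_cp=ddcp, fold_change=2.0 ** ddcp)


def score_animal_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Score every row of an animal observation table; adds the DAI columns."""
    records = []
    for row in observations.itertuples(index=False):
        rec = score_observation(AnimalObservation(
            animal_id=str(row.animal_id), group=str(row.group), day=int(row.day),
            weight_pct_change=float(row.weight_pct_change),
            stool_category=str(row.stool_category), blood_category=str(row.blood_category),
        ))
        records.append(dict(weight_score=rec.weight_score, stool_score=rec.stool_score,
                            blood_score=rec.blood_score, dai=rec.dai))
    return pd.concat([observations.reset_index(drop=True), pd.DataFrame(records)], axis=1)


def auc_by_animal(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-animal trapezoidal DAI AUC from a scored observation table."""
    rows = []
    for (animal_id, group), sub in scored.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("day")
        rows.append(dict(animal_id=animal_id, group=group,
                         dai_auc=dai_auc(list(zip(sub["day"], sub["dai"])))))
    return pd.DataFrame(rows)


def summarize_groups(
    values: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group mean and standard error (sd/sqrt(n)) of a per-animal quantity."""
    if values.empty:
        raise ValueError("no records to summarize")
    for col in (value_col, group_col):
        if col not in values.columns:
            raise ValueError(f"column {col!r} not in table")
    grouped = values.groupby(group_col)[value_col]
    summary = grouped.agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    summary.loc[summary["n"] == 1, ["sd", "se"]] = float("nan")
    return summary[[group_col, "n", "mean", "sd", "se"]]
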