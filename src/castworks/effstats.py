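"""Editing-efficiency statistics from serial-dilution spot plates.

Conjugation assays quantify editing as the ratio of transconjugant CFU/ml
(selective plates) to total CFU/ml (nonselective plates).  This module
turns raw colony counts from 10-fold dilution series into titers,
efficiencies with detection-limit handling, day-paired fold changes
against a same-day control, and one-sample one-tailed t tests against a
hypothetical normalised mean of 1.

Titers pool all countable spots of a series as a Poisson maximum-
likelihood estimate: total colonies divided by total plated equivalent
volume.  For a single countable spot this reduces to
``count x dilution_factor x (1000 / spot_volume_ul)`` CFU/ml.  Series
with no countable spot and no lawn yield a censored upper bound (the
detection limit), which is propagated - never imputed as zero - although
exports may additionally show the conventional zero-with-flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COUNTABLE_RANGE = (3, 300)


class PairingError(ValueError):
    """A treatment has no same-day control to normalise against."""


@dataclass
class TiterEstimate:
    cfu_per_ml: float
    below_detection: bool
    detection_limit: float | None
    n_spots_used: int


@dataclass
class EfficiencyMeasurement:
    sample_id: str
    day: str
    transconjugant_cfu_per_ml: float
    total_cfu_per_ml: float
    efficiency: float
    below_detection: bool

    def export_value(self) -> float:
        """Plotting/export convention: censored samples are shown as an
        explicit zero (the ``below_detection`` flag carries the bound)."""
        return 0.0 if self.below_detection else self.efficiency


@dataclass
class NormalizedEffect:
    treatment_id: str
    control_id: str
    day: str
    fold_change: float


@dataclass
class TestResult:
    n: int
    mean: float
    sd: float
    t_statistic: float
    df: int
    p_one_tailed: float
    direction: str


def cfu_from_spots(spots: pd.DataFrame, spot_volume_ul: float = 10.0,
                   countable_range: tuple[int, int] = DEFAULT_COUNTABLE_RANGE,
                   ) -> TiterEstimate:
    """Titer from one dilution series.

    ``spots`` needs ``dilution_factor`` and ``count`` columns (optional
    boolean ``lawn``).  Lawn-flagged spots are never counted.  A dilution
    is *countable* when the mean count of its readable spots lies within
    ``countable_range``; all readable spots of countable dilutions are
    pooled (total colonies / total plated equivalent volume).  Selecting
    whole dilutions rather than individual spots keeps the estimate free
    of truncation bias when counts straddle a range boundary.  A series
    with nothing countable and no lawn is below detection, bounded by one
    countable minimum at the least-dilute spot examined.
    """
    if spot_volume_ul <= 0:
        raise ValueError("spot_volume_ul must be positive")
    lo, hi = countable_range
    lawn = spots["lawn"] if "lawn" in spots else pd.Series(False, index=spots.index)
    readable = spots[~lawn]
    dilution_mean = readable.groupby("dilution_factor")["count"].mean()
    countable = dilution_mean[(dilution_mean >= lo) & (dilution_mean <= hi)]
    vol_ml = spot_volume_ul / 1000.0
    if len(countable):
        sub = readable[readable["dilution_factor"].isin(countable.index)]
        total_count = float(sub["count"].sum())
        total_volume = float((vol_ml / sub["dilution_factor"]).sum())
        return TiterEstimate(total_count / total_volume, False, None,
                             int(len(sub)))
    # nothing countable: if every readable spot is below the countable
    # minimum the sample is below detection at the most sensitive spot
    if len(readable) and (readable["count"] < lo).all():
        min_factor = float(readable["dilution_factor"].min())
        limit = lo * min_factor * (1000.0 / spot_volume_ul)
        return TiterEstimate(float("nan"), True, limit, 0)
    raise ValueError("no countable spot and series not clearly below "
                     "detection (all readable spots above range or lawns)")


def editing_efficiency(transconjugant: TiterEstimate, total: TiterEstimate,
                       sample_id: str = "sample", day: str = "day1",
                       ) -> EfficiencyMeasurement:
    """Transconjugant/total ratio with censoring propagation.

    When the transconjugant titer is below detection the efficiency is
    the upper bound ``limit / total`` with ``below_detection`` set.  A
    total below detection leaves the efficiency undefined.
    """
    if total.below_detection or not np.isfinite(total.cfu_per_ml) \
            or total.cfu_per_ml <= 0:
        raise ValueError("total titer undefined or below detection; "
                         "efficiency cannot be computed")
    if transconjugant.below_detection:
        bound = transconjugant.detection_limit / total.cfu_per_ml
        return EfficiencyMeasurement(sample_id, day, float("nan"),
                                     total.cfu_per_ml, bound, True)
    eff = transconjugant.cfu_per_ml / total.cfu_per_ml
    return EfficiencyMeasurement(sample_id, day, transconjugant.cfu_per_ml,
                                 total.cfu_per_ml, eff, False)


def fold_change(treatment: EfficiencyMeasurement,
                controls: list[EfficiencyMeasurement]) -> NormalizedEffect:
    """Day-paired normalisation of a treatment efficiency.

    Controls are matched strictly by day label (efficiencies vary day to
    day, so cross-day pooling is never performed); multi-control days use
    the mean control efficiency.
    """
    same_day = [c for c in controls if c.day == treatment.day]
    if not same_day:
        raise PairingError(f"no control measured on day {treatment.day!r}")
    ctrl_eff = float(np.mean([c.efficiency for c in same_day]))
    if ctrl_eff <= 0 or not np.isfinite(ctrl_eff):
        raise ValueError("control efficiency is zero or undefined")
    return NormalizedEffect(treatment.sample_id,
                            ",".join(c.sample_id for c in same_day),
                            treatment.day,
                            treatment.efficiency / ctrl_eff)


def one_sample_t(values, mu: float = 1.0,
                 direction: str = "greater") -> TestResult:
    """One-sample t test of mean(values) against ``mu``, one-tailed.

    ``direction`` states the alternative hypothesis ("greater" or
    "less"), chosen a priori from the expected sign of the effect.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("at least two observations are required")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    res = stats.ttest_1samp(values, popmean=mu, alternative=direction)
    return TestResult(n, float(values.mean()), sd, float(res.statistic),
                      n - 1, float(res.pvalue), direction)


def efficiency_analysis(plates: pd.DataFrame, spot_volume_ul: float | None = None,
                        countable_range=DEFAULT_COUNTABLE_RANGE,
                        mu: float = 1.0, direction: str = "greater"):
    """Full analysis of a tidy plate table.

    Expected columns: sample, day, role (treatment/control), population
    (transconjugant/total), dilution_factor, count, and optionally lawn
    and spot_volume_ul.  Returns a dict with per-sample efficiencies, the
    day-paired fold changes of every treatment, and the one-sample t test
    over fold changes (when >= 2 days are available).
    """
    measurements: dict[str, EfficiencyMeasurement] = {}
    roles: dict[str, str] = {}
    for (sample, day, role), grp in plates.groupby(["sample", "day", "role"]):
        vol = spot_volume_ul
        if vol is None:
            vol = float(grp["spot_volume_ul"].iloc[0]) \
                if "spot_volume_ul" in grp else 10.0
        titers = {}
        for pop, series in grp.groupby("population"):
            titers[pop] = cfu_from_spots(series, spot_volume_ul=vol,
                                         countable_range=countable_range)
        key = f"{sample}@{day}"
        measurements[key] = editing_efficiency(
            titers["transconjugant"], titers["total"], sample_id=sample, day=day)
        roles[key] = role
    controls = [m for k, m in measurements.items() if roles[k] == "control"]
    folds = [fold_change(m, controls)
             for k, m in measurements.items() if roles[k] == "treatment"]
    result = {"efficiencies": measurements, "fold_changes": folds, "test": None}
    if len(folds) >= 2:
        result["test"] = one_sample_t([f.fold_change for f in folds],
                                      mu=mu, direction=direction)
    return result
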