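"""Map-quality metrics, the cost-benefit model and nutrient-runoff risk.

Conventions: *positive* means healthy.  A false positive is a truly unhealthy
zone classified healthy (it goes untreated and loses yield, ~$0.8/zone); a
false negative is a truly healthy zone classified unhealthy (it is treated
unnecessarily, ~$0.1/zone, and contributes to nutrient-runoff risk).  The
missed-unhealthy : over-treatment cost ratio is 8.

Per-zone dollar constants derive from per-acre figures: $763.8 revenue/acre
and $130 fertilizer/acre over 4.3 m2 zones give $0.8 and $0.1 per zone after
one-decimal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_core import HEALTHY, UNHEALTHY

#: Mid-range of a 15-25 min commodity-UAS flight, in hours.
DEFAULT_HOURS_PER_CHARGE: float = 0.33


@dataclass(frozen=True)
class ConfusionCounts:
    """Zone counts against ground truth (positive = healthy)."""

    tp: int  # healthy classified healthy
    tn: int  # unhealthy classified unhealthy
    fp: int  # unhealthy classified healthy  (missed unhealthy -> crop loss)
    fn: int  # healthy classified unhealthy  (overtreated healthy -> runoff)

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    # semantic aliases used by the cost model
    @property
    def missed_unhealthy(self) -> int:
        return self.fp

    @property
    def overtreated_healthy(self) -> int:
        return self.fn

    @property
    def treated(self) -> int:
        """Zones classified unhealthy, i.e. slated for treatment."""
        return self.tn + self.fn


@dataclass(frozen=True)
class EconParams:
    """2018-season corn economics."""

    revenue_per_acre: float = 763.8  # $3.8/bushel x 200 bushels/acre
    fertilizer_cost_per_acre: float = 130.0
    zone_area_m2: float = 4.3
    m2_per_acre: float = 4046.86
    crop_loss_per_missed_unhealthy_zone: float = 0.8
    treatment_cost_per_treated_zone: float = 0.1
    wage_unskilled: float = 10.0  # $/h
    wage_skilled: float = 20.0  # $/h

    def __post_init__(self) -> None:
        vals = [
            self.revenue_per_acre,
            self.fertilizer_cost_per_acre,
            self.zone_area_m2,
            self.m2_per_acre,
            self.crop_loss_per_missed_unhealthy_zone,
            self.treatment_cost_per_treated_zone,
            self.wage_unskilled,
            self.wage_skilled,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all economic parameters must be positive")


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count zone outcomes of a complete predicted map against truth."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth maps must have the same shape")
    return ConfusionCounts(
        tp=int(np.sum((truth == HEALTHY) & (predicted == HEALTHY))),
        tn=int(np.sum((truth == UNHEALTHY) & (predicted == UNHEALTHY))),
        fp=int(np.sum((truth == UNHEALTHY) & (predicted == HEALTHY))),
        fn=int(np.sum((truth == HEALTHY) & (predicted == UNHEALTHY))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, positive/negative precision and recall.

    Zero-denominator metrics are reported as None (undefined), never as 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": ratio(c.tp + c.tn, c.n),
        "pos_precision": ratio(c.tp, c.tp + c.fp),
        "pos_recall": ratio(c.tp, c.tp + c.fn),
        "neg_precision": ratio(c.tn, c.tn + c.fn),
        "neg_recall": ratio(c.tn, c.tn + c.fp),
    }


def per_zone_constants(p: EconParams | None = None) -> tuple[float, float]:
    """(revenue, fertilizer cost) per management zone, one-decimal rounded."""
    if p is None:
        p = EconParams()
    factor = p.zone_area_m2 / p.m2_per_acre
    return (
        round(p.revenue_per_acre * factor, 1),
        round(p.fertilizer_cost_per_acre * factor, 1),
    )


def net_revenue(c: ConfusionCounts, labor: float, p: EconParams | None = None) -> float:
    """Field profit under the treat-what-looks-unhealthy policy.

    Full yield over all zones, minus crop loss on unhealthy zones the map
    missed (classified healthy, hence untreated), minus treatment of every
    zone classified unhealthy, minus labor.
    """
    if p is None:
        p = EconParams()
    revenue_per_zone, _ = per_zone_constants(p)
    return (
        c.n * revenue_per_zone
        - p.crop_loss_per_missed_unhealthy_zone * c.missed_unhealthy
        - p.treatment_cost_per_treated_zone * c.treated
        - labor
    )


def labor_cost(
    policy: str,
    charges: int,
    p: EconParams | None = None,
    hours_per_charge: float = DEFAULT_HOURS_PER_CHARGE,
) -> float:
    """Scouting labor in dollars.

    Autonomous policies need one unskilled worker; exhaustive scouting needs
    an additional skilled worker to plan routes and swap batteries.  Hours
    scale linearly with the number of charges.
    """
    if charges < 1:
        raise ValueError("charges must be >= 1")
    if p is None:
        p = EconParams()
    hours = charges * hours_per_charge
    rate = p.wage_unskilled + (p.wage_skilled if policy == "exhaustive" else 0.0)
    return hours * rate


def cost_reduction_ratio(exhaustive_cost: float, autonomous_cost: float) -> float:
    """Exhaustive-to-autonomous labor cost ratio, one-decimal rounded."""
    if autonomous_cost <= 0:
        raise ValueError("autonomous cost must be positive")
    return round(exhaustive_cost / autonomous_cost, 1)


def charges_at_coverage(exhaustive_charges: float, coverage: float) -> int:
    """Charges needed at partial coverage, assuming linear scaling with zones
    visited (nearest integer)."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    return int(round(exhaustive_charges * coverage))


def runoff_risk(c: ConfusionCounts) -> float | None:
    """Percentage of truly healthy zones slated for unnecessary fertilization.

    None (undefined) when the field has no healthy zones.
    """
    den = c.tp + c.fn
    if den == 0:
        return None
    return 100.0 * c.fn / den
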