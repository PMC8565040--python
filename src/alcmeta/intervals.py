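"""Mapping raw survey responses to daily-consumption intervals.

Frequency-quantity questionnaires record how often a respondent drinks
(occasions per reference period, as a categorical range) and how much per
occasion (standard drinks, as a categorical range).  Combining the lower
limits of both and the upper limits of both yields an interval of average
daily ethanol intake in grams/day; open-ended top categories yield an
infinite upper bound.  Surveys that record an exact weekly drink count yield
a degenerate (point) interval instead.

A standard drink is assumed to contain 12 g of pure ethanol by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GRAMS_PER_DRINK",
    "FrequencyQuantityResponse",
    "ConsumptionInterval",
    "fq_to_interval",
    "weekly_count_to_interval",
    "read_category_table",
    "instrument_partition",
]

#: grams of pure ethanol per standard drink (South African convention)
GRAMS_PER_DRINK = 12.0


@dataclass(frozen=True)
class FrequencyQuantityResponse:
    """One frequency-quantity category: occasion and quantity ranges.

    ``freq_low``/``freq_high`` are drinking occasions per reference period of
    ``period_days`` days; ``qty_low``/``qty_high`` are standard drinks per
    occasion.  Open-ended upper limits are ``math.inf``.
    """

    freq_low: float
    freq_high: float
    qty_low: float
    qty_high: float
    period_days: float = 7.0

    def __post_init__(self) -> None:
        for name in ("freq_low", "qty_low"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.freq_high < self.freq_low:
            raise ValueError("freq_high must be >= freq_low")
        if self.qty_high < self.qty_low:
            raise ValueError("qty_high must be >= qty_low")
        if self.period_days <= 0:
            raise ValueError("period_days must be positive")


@dataclass(frozen=True)
class ConsumptionInterval:
    """Average daily consumption interval [lc, uc] in grams ethanol/day."""

    lc: float
    uc: float

    def __post_init__(self) -> None:
        if self.lc < 0:
            raise ValueError("lc must be non-negative")
        if self.uc < self.lc:
            raise ValueError("uc must be >= lc")

    @property
    def degenerate(self) -> bool:
        return self.lc == self.uc


def fq_to_interval(
    resp: FrequencyQuantityResponse, grams_per_drink: float = GRAMS_PER_DRINK
) -> ConsumptionInterval:
    """Daily-consumption interval implied by a frequency-quantity category.

    lc = freq_low * qty_low * grams_per_drink / period_days and analogously
    for uc; any open-ended component makes uc infinite.
    """
    if grams_per_drink <= 0:
        raise ValueError("grams_per_drink must be positive")
    lc = resp.freq_low * resp.qty_low * grams_per_drink / resp.period_days
    if math.isinf(resp.freq_high) or math.isinf(resp.qty_high):
        uc = math.inf
    else:
        uc = resp.freq_high * resp.qty_high * grams_per_drink / resp.period_days
    # a zero-frequency category is a point at zero regardless of quantity
    if resp.freq_high == 0:
        uc = 0.0
    return ConsumptionInterval(lc=lc, uc=uc)


def weekly_count_to_interval(
    n_drinks: float, grams_per_drink: float = GRAMS_PER_DRINK
) -> ConsumptionInterval:
    """Degenerate interval from an exact drinks-in-the-past-week count."""
    if n_drinks < 0:
        raise ValueError("n_drinks must be non-negative")
    if grams_per_drink <= 0:
        raise ValueError("grams_per_drink must be positive")
    x = n_drinks * grams_per_drink / 7.0
    return ConsumptionInterval(lc=x, uc=x)


def read_category_table(path, grams_per_drink: float = GRAMS_PER_DRINK):
    """Read an instrument definition table into consumption intervals.

    The file is CSV with columns freq_low, freq_high, qty_low, qty_high,
    period_days; empty freq_high/qty_high cells mean an open-ended category.
    Returns a list of (FrequencyQuantityResponse, ConsumptionInterval).
    """
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        resp = FrequencyQuantityResponse(
            freq_low=float(row.freq_low),
            freq_high=math.inf if _missing(row.freq_high) else float(row.freq_high),
            qty_low=float(row.qty_low),
            qty_high=math.inf if _missing(row.qty_high) else float(row.qty_high),
            period_days=float(row.period_days),
        )
        out.append((resp, fq_to_interval(resp, grams_per_drink)))
    return out


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def instrument_partition(categories, grams_per_drink: float = GRAMS_PER_DRINK):
    """Non-overlapping partition of [0, inf) induced by an instrument.

    Collects the finite endpoints of every category's consumption interval
    and returns the ordered list of disjoint intervals between consecutive
    breakpoints, closing with an open-ended top interval.  Used by the
    synthetic-data generator to bin continuous consumption the way a
    discrete-response questionnaire does.
    """
    edges = {0.0}
    for resp in categories:
        iv = fq_to_interval(resp, grams_per_drink)
        edges.add(iv.lc)
        if math.isfinite(iv.uc):
            edges.add(iv.uc)
    pts = sorted(edges)
    parts = [ConsumptionInterval(a, b) for a, b in zip(pts[:-1], pts[1:]) if b > a]
    parts.append(ConsumptionInterval(pts[-1], math.inf))
    return parts
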