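"""Necromass carrying-capacity model.

If bacterial proliferation in coculture is fed by lysed algal cells, the
observed CFU increase, divided by the CFU yield a single lysed algal cell
supports, gives the lysed-cell density required to explain the growth — and
that requirement can be checked against the lysis fraction measured
independently by a membrane-integrity assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LysisBudget",
    "yield_per_lysed_cell",
    "required_lysed_density",
    "required_lysis_fraction",
    "consistency_check",
    "round_to_one_sig_fig",
]


def round_to_one_sig_fig(x: float) -> float:
    """Headline rounding (e.g. 106.25 -> 100)."""
    if x == 0:
        return 0.0
    mag = 10 ** math.floor(math.log10(abs(x)))
    return round(x / mag) * mag


def yield_per_lysed_cell(
    cfu_in_lysate,
    lysed_algal_density: float,
    cfu_baseline=0.0,
) -> dict:
    """CFU supported per lysed algal cell.

    ``cfu_in_lysate`` (and optionally ``cfu_baseline``) may be scalars or
    replicate vectors; replicate scatter propagates into the sd.  Returns
    the full-precision mean, sd, a one-significant-figure headline value,
    and the same quantities without baseline subtraction.
    """
    if lysed_algal_density <= 0:
        raise ValueError("lysed algal density must be positive")
    cfu = np.atleast_1d(np.asarray(cfu_in_lysate, dtype=float))
    base = np.atleast_1d(np.asarray(cfu_baseline, dtype=float))
    if np.any(cfu < 0) or np.any(base < 0):
        raise ValueError("CFU densities must be non-negative")
    if float(np.mean(base)) > float(np.mean(cfu)):
        raise ValueError("baseline exceeds final CFU density")
    per_cell = (cfu - np.mean(base)) / lysed_algal_density
    per_cell_raw = cfu / lysed_algal_density
    mean = float(per_cell.mean())
    sd = float(per_cell.std(ddof=1)) if per_cell.size > 1 else 0.0
    return {
        "yield_cfu_per_cell": mean,
        "yield_sd": sd,
        "headline": round_to_one_sig_fig(mean),
        "yield_no_baseline": float(per_cell_raw.mean()),
        "n": int(per_cell.size),
    }


def required_lysed_density(observed_proliferation: float, yield_cfu_per_cell: float) -> float:
    """Algal cells/ml that must lyse to supply the observed CFU increase."""
    if yield_cfu_per_cell <= 0:
        raise ValueError("yield must be positive")
    if observed_proliferation < 0:
        raise ValueError("observed proliferation must be non-negative")
    return observed_proliferation / yield_cfu_per_cell


def required_lysis_fraction(required_density: float, algal_density: float) -> float:
    """Required lysed-cell density as a percentage of the algal population."""
    if algal_density <= 0:
        raise ValueError("algal density must be positive")
    if required_density < 0:
        raise ValueError("required density must be non-negative")
    return 100.0 * required_density / algal_density


@dataclass
class LysisBudget:
    """Complete lysis carrying-capacity budget for one coculture."""

    yield_cfu_per_cell: float
    yield_sd: float
    observed_proliferation: float  # CFU/ml increase in coculture
    algal_density: float           # cells/ml
    measured_lysis_range_pct: tuple[float, float] | None = None
    required_density: float = field(init=False)
    required_fraction_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.required_density = required_lysed_density(
            self.observed_proliferation, self.yield_cfu_per_cell
        )
        self.required_fraction_pct = required_lysis_fraction(
            self.required_density, self.algal_density
        )

    def to_dict(self) -> dict:
        d = {
            "yield_cfu_per_cell": self.yield_cfu_per_cell,
            "yield_headline": round_to_one_sig_fig(self.yield_cfu_per_cell),
            "yield_sd": self.yield_sd,
            "observed_proliferation_cfu_per_ml": self.observed_proliferation,
            "required_lysed_density_per_ml": self.required_density,
            "algal_density_per_ml": self.algal_density,
            "required_fraction_pct": self.required_fraction_pct,
        }
        if self.measured_lysis_range_pct is not None:
            d.update(consistency_check(self, self.measured_lysis_range_pct))
        return d


def consistency_check(
    budget: LysisBudget, measured_lysis_range_pct: tuple[float, float]
) -> dict:
    """Judge whether measured lysis can account for the required lysis.

    The measured range is widened by first-order (delta-method) propagation
    of the yield sd into the required fraction: the required fraction scales
    as 1/yield, so its relative uncertainty equals the yield's.  Verdicts:
    ``consistent`` when the required fraction falls inside the widened
    range, ``insufficient_lysis`` when it exceeds the top (lysis alone
    cannot explain the growth), ``excess_lysis`` when it falls below the
    bottom (lysis over-explains it).
    """
    lo, hi = measured_lysis_range_pct
    if lo > hi:
        raise ValueError("measured lysis range must be (low, high)")
    req = budget.required_fraction_pct
    rel_sd = (
        budget.yield_sd / budget.yield_cfu_per_cell
        if budget.yield_cfu_per_cell > 0
        else 0.0
    )
    pad = req * rel_sd
    lo_x, hi_x = lo - pad, hi + pad
    if lo_x <= req <= hi_x:
        verdict = "consistent"
        margin = min(req - lo_x, hi_x - req)
    elif req > hi_x:
        verdict = "insufficient_lysis"
        margin = req - hi_x
    else:
        verdict = "excess_lysis"
        margin = lo_x - req
    return {
        "verdict": verdict,
        "margin_pct": float(margin),
        "required_fraction_pct": float(req),
        "required_fraction_sd_pct": float(pad),
        "measured_lysis_range_pct": [float(lo), float(hi)],
    }
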