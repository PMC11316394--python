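"""Growth inference: doublings, expected biomass synthesis, reductive
division, cell-size statistics and the significance tests used throughout.

The central diagnostic compares the net biomass synthesis measured by the
isotope tracer with the synthesis expected from the observed increase in
colony-forming units.  After ``d`` balanced doublings the pre-existing
biomass fraction of a cell is ``2**-d``, so the expected fraction of newly
synthesized biomass is ``1 - 2**-d``.  When the measured fraction falls far
below that expectation while CFUs keep increasing, the population is
dividing without commensurate biomass gain — reductive division, the
starvation hallmark that also shows up as shrinking cell length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def doublings(N0: float, Nt: float) -> float:
    """Number of population doublings: ``log2(Nt / N0)``.

    Negative values (density decline) are returned and logged, not raised.
    """
    if N0 <= 0 or Nt <= 0:
        raise ValueError("densities must be positive")
    d = float(np.log2(Nt / N0))
    if d < 0:
        logger.warning("density declined: %g -> %g (d = %.3f)", N0, Nt, d)
    return d


def expected_xnet(d: float) -> float:
    """Expected new-biomass fraction after ``d`` balanced doublings."""
    if d < 0:
        raise ValueError("doublings must be non-negative")
    return float(1.0 - 2.0 ** (-d))


@dataclass
class BiomassSynthesisAssessment:
    timepoint_h: float
    d: float
    expected_xnet: float
    measured_xnet: float
    gap: float
    reductive_division_flag: bool


def assess_synthesis(
    series: pd.DataFrame,
    measured: pd.DataFrame,
    flag_ratio: float = 0.5,
    N0: float | None = None,
) -> pd.DataFrame:
    """Compare measured net biomass synthesis with the CFU-expected value.

    Parameters
    ----------
    series :
        Bacterial growth observations with columns ``time_h``, ``density``
        and optionally ``replicate`` (replicates are averaged).
    measured :
        Tracer-measured net assimilation per timepoint: columns
        ``timepoint_h`` and ``xnet``.
    flag_ratio :
        Reductive division is flagged at a timepoint when
        ``measured < flag_ratio * expected`` while doublings have increased
        since the previous assessed timepoint.
    N0 :
        Inoculation density; defaults to the first observation (averaged
        over replicates).

    Returns a tidy frame with one row per measured timepoint.
    """
    if measured.empty:
        raise ValueError("no measured timepoints")
    dens = (
        series.groupby("time_h")["density"].mean().sort_index()
        if "replicate" in series.columns
        else series.set_index("time_h")["density"].sort_index()
    )
    n0 = float(dens.iloc[0]) if N0 is None else float(N0)
    rows = []
    prev_d = 0.0
    for _, m in measured.sort_values("timepoint_h").iterrows():
        tp = float(m["timepoint_h"])
        matched = dens.index[np.isclose(dens.index.to_numpy(), tp, atol=1e-6)]
        if len(matched) == 0:
            # interpolate between observations bracketing the timepoint
            if tp < dens.index.min() or tp > dens.index.max():
                raise ValueError(f"no growth observation matches timepoint {tp}")
            nt = float(np.interp(tp, dens.index.to_numpy(), dens.to_numpy()))
        else:
            nt = float(dens.loc[matched[0]])
        d = doublings(n0, nt)
        exp = expected_xnet(max(d, 0.0))
        meas = float(m["xnet"])
        flag = bool(meas < flag_ratio * exp and d > prev_d)
        rows.append(
            BiomassSynthesisAssessment(
                timepoint_h=tp,
                d=d,
                expected_xnet=exp,
                measured_xnet=meas,
                gap=exp - meas,
                reductive_division_flag=flag,
            )
        )
        prev_d = d
    return pd.DataFrame([r.__dict__ for r in rows])


def length_stats(lengths_um) -> dict:
    """Mean, sd (ddof=1; 0 for a single cell) and n of pole-to-pole lengths."""
    arr = np.asarray(lengths_um, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cell-size sample")
    if np.any(arr <= 0):
        raise ValueError("cell lengths must be positive")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd, "n": int(arr.size)}


def percent_reduction(l_ref: float, l_t: float) -> float:
    """Percent reduction in length relative to a reference:
    ``100 * (l_ref - l_t) / l_ref``."""
    if l_ref <= 0 or l_t <= 0:
        raise ValueError("lengths must be positive")
    return 100.0 * (l_ref - l_t) / l_ref


def max_density_fold(
    series_a: pd.DataFrame, series_b: pd.DataFrame
) -> tuple[float, dict]:
    """Ratio of maximum densities between two growth series (a / b).

    The maximum is taken over the replicate-mean trajectory of each series;
    per-replicate maxima are returned alongside for inspection.
    """
    for s in (series_a, series_b):
        if s.empty:
            raise ValueError("empty growth series")
    units_a, units_b = set(series_a["unit"]), set(series_b["unit"])
    if units_a != units_b:
        raise ValueError(f"unit mismatch: {units_a} vs {units_b}")

    def _max_of_mean(s):
        return float(s.groupby("time_h")["density"].mean().max())

    def _per_rep(s):
        if "replicate" not in s.columns:
            return {}
        return s.groupby("replicate")["density"].max().to_dict()

    fold = _max_of_mean(series_a) / _max_of_mean(series_b)
    return fold, {"per_replicate_max_a": _per_rep(series_a),
                  "per_replicate_max_b": _per_rep(series_b)}


def t_test_two_tailed(
    x, y, paired: bool = False, alpha: float = 0.05, welch: bool = False
) -> dict:
    """Two-tailed Student's t-test (pooled variance; paired on request).

    Returns ``{"t", "p", "significant", "df"}``.  Degenerate zero-variance
    comparisons with identical means return t = 0, p = 1 by convention
    (logged).  ``welch=True`` switches the unpaired test to unequal-variance
    form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal group sizes")
        diff = x - y
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                logger.info("zero-variance identical paired samples: p = 1")
                return {"t": 0.0, "p": 1.0, "significant": False,
                        "df": int(x.size - 1)}
            raise ValueError("paired differences constant but non-zero")
        res = stats.ttest_rel(x, y)
        df = x.size - 1
    else:
        if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
            if np.allclose(x.mean(), y.mean()):
                logger.info("zero-variance identical groups: p = 1")
                return {"t": 0.0, "p": 1.0, "significant": False,
                        "df": int(x.size + y.size - 2)}
            raise ValueError("zero variance with different means")
        res = stats.ttest_ind(x, y, equal_var=not welch)
        df = x.size + y.size - 2
    p = float(res.pvalue)
    return {
        "t": float(res.statistic),
        "p": p,
        "significant": bool(p < alpha),
        "df": df if not (welch and not paired) else float(res.df),
    }
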