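"""Supporting wet-lab assay quantification.

* B12 bioassay: two E. coli indicator strains are grown in the sample; the
  dmetE strain grows when either methionine or B12 is available while the
  dmetE-dmetH control cannot use B12 at all, so their OD600 difference is a
  B12-specific growth signal that a standard curve converts to ng/l.
* Cytotoxicity: membrane-impermeable DNA dye fluorescence, blank-subtracted
  and expressed relative to a heat-killed (100% compromised) control.
* NPOC: dilution-corrected non-purgeable organic carbon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


def b12_delta_growth(od_dmetE: float, od_control: float) -> tuple[float, bool]:
    """B12-specific growth signal: ``od_dmetE - od_control``.

    Negative differences are biologically meaningless (the control strain
    cannot out-grow the responder on B12), so they are floored at 0 with a
    QC flag.  Returns ``(delta_od, floored)``.
    """
    if od_dmetE is None or od_control is None or np.isnan(od_dmetE) or np.isnan(od_control):
        raise ValueError("both strain ODs are required for a sample")
    delta = od_dmetE - od_control
    if delta < 0:
        return 0.0, True
    return float(delta), False


def _four_pl(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


@dataclass
class StandardCurve:
    """Monotone map between B12 concentration (ng/l) and delta-OD.

    ``model`` is "4pl" (four-parameter logistic in log10 concentration,
    fitted when >= 6 standards are available) or "interp" (monotone
    piecewise-linear interpolation in log10 concentration, the fallback for
    sparse standard series).  Quantification inverts the fitted model;
    values outside the calibrated delta-OD range are censored at the
    nearest standard with a flag.
    """

    log_conc: np.ndarray
    delta_od: np.ndarray
    model: str
    params: dict = field(default_factory=dict)
    residual_sd: float = 0.0

    @property
    def lod_delta_od(self) -> float:
        """Limit of detection: the delta-OD of the lowest standard."""
        return float(self.delta_od[0])

    @property
    def valid_range_ng_per_l(self) -> tuple[float, float]:
        return (float(10 ** self.log_conc[0]), float(10 ** self.log_conc[-1]))

    def predict(self, conc_ng_per_l):
        logc = np.log10(np.asarray(conc_ng_per_l, dtype=float))
        if self.model == "4pl":
            return _four_pl(logc, **self.params)
        return np.interp(logc, self.log_conc, self.delta_od)

    def quantify(self, delta_od: float) -> dict:
        """Invert the curve for one delta-OD reading.

        Returns ``{"b12_ng_per_l", "censored", "flag"}`` where flag is
        ``"<LOD"`` / ``">ULOQ"`` for out-of-range readings (the reported
        concentration is then the censoring bound, never an extrapolation).
        """
        lo, hi = self.valid_range_ng_per_l
        if delta_od < self.lod_delta_od:
            return {"b12_ng_per_l": lo, "censored": True, "flag": "<LOD"}
        if delta_od > float(self.delta_od[-1]):
            return {"b12_ng_per_l": hi, "censored": True, "flag": ">ULOQ"}
        if self.model == "4pl":
            b, t = self.params["bottom"], self.params["top"]
            h, le = self.params["hill"], self.params["log_ec50"]
            frac = (delta_od - b) / (t - b)
            frac = min(max(frac, 1e-12), 1 - 1e-12)
            logc = le - np.log10(1.0 / frac - 1.0) / h
        else:
            logc = np.interp(delta_od, self.delta_od, self.log_conc)
        conc = float(np.clip(10 ** logc, lo, hi))
        return {"b12_ng_per_l": conc, "censored": False, "flag": ""}


def fit_standard_curve(standards: pd.DataFrame, noise_tol: float = 0.05) -> StandardCurve:
    """Fit a monotone standard curve from calibration wells.

    ``standards`` needs columns ``nominal_b12_ng_per_l`` and ``delta_od``
    (replicates are averaged per concentration).  At least 4 standards
    spanning >= 2 orders of magnitude are required.  With >= 6 distinct
    concentrations a four-parameter logistic is fitted; otherwise a
    monotone piecewise-linear interpolant in log10 concentration is used.
    Standards that decrease by more than ``noise_tol`` OD between
    consecutive concentrations are rejected as non-monotone.
    """
    agg = (
        standards.groupby("nominal_b12_ng_per_l")["delta_od"]
        .mean()
        .sort_index()
    )
    agg = agg[agg.index > 0]
    if len(agg) < 4:
        raise ValueError("need at least 4 positive-concentration standards")
    span = np.log10(agg.index.max() / agg.index.min())
    if span < 2:
        raise ValueError(
            f"standards span only {span:.2f} orders of magnitude (need >= 2)"
        )
    dod = agg.to_numpy()
    drops = np.diff(dod)
    if np.any(drops < -noise_tol):
        bad = agg.index.to_numpy()[1:][drops < -noise_tol]
        raise ValueError(
            "standard series not monotone beyond noise tolerance at "
            f"concentration(s) {bad.tolist()} ng/l"
        )
    # enforce strict monotonicity for inversion (tie/noise smoothing)
    dod_mono = np.maximum.accumulate(dod)
    dod_mono += np.arange(len(dod_mono)) * 1e-12
    logc = np.log10(agg.index.to_numpy())

    if len(agg) >= 6:
        p0 = [dod_mono[0], dod_mono[-1], float(np.median(logc)), 1.0]
        try:
            popt, _ = curve_fit(
                _four_pl, logc, dod_mono, p0=p0,
                bounds=([-0.5, 0.0, logc[0] - 2, 0.2], [1.0, 5.0, logc[-1] + 2, 5.0]),
                maxfev=20000,
            )
            params = dict(zip(("bottom", "top", "log_ec50", "hill"), map(float, popt)))
            resid = dod_mono - _four_pl(logc, **params)
            return StandardCurve(
                log_conc=logc, delta_od=dod_mono, model="4pl", params=params,
                residual_sd=float(np.std(resid)),
            )
        except RuntimeError:
            logger.warning("4PL fit failed to converge; using interpolation")
    return StandardCurve(log_conc=logc, delta_od=dod_mono, model="interp")


def quantify_b12(curve: StandardCurve, delta_od) -> pd.DataFrame:
    """Quantify one or more delta-OD readings against a fitted curve."""
    vals = np.atleast_1d(np.asarray(delta_od, dtype=float))
    return pd.DataFrame([curve.quantify(float(v)) for v in vals])


def quantify_plate(plate: pd.DataFrame) -> tuple[pd.DataFrame, StandardCurve]:
    """Full bioassay quantification of a two-strain plate table.

    ``plate`` has columns sample_id, strain (dmetE / dmetE_dmetH), od600,
    is_standard, nominal_b12_ng_per_l (standards only), and optionally
    replicate.  Returns per-sample concentrations with censoring flags and
    the fitted curve.
    """
    wide = (
        plate.groupby(["sample_id", "is_standard", "strain"])["od600"]
        .mean()
        .unstack("strain")
    )
    if "dmetE" not in wide.columns or "dmetE_dmetH" not in wide.columns:
        raise ValueError("plate must contain both dmetE and dmetE_dmetH strains")
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        raise ValueError(
            f"samples missing one strain: {[i[0] for i in missing]}"
        )
    deltas, floored = zip(
        *(b12_delta_growth(r["dmetE"], r["dmetE_dmetH"]) for _, r in wide.iterrows())
    )
    wide = wide.reset_index()
    wide["delta_od"] = deltas
    wide["delta_floored"] = floored
    nominal = (
        plate[plate["is_standard"]]
        .groupby("sample_id")["nominal_b12_ng_per_l"]
        .first()
    )
    wide["nominal_b12_ng_per_l"] = wide["sample_id"].map(nominal)
    curve = fit_standard_curve(wide[wide["is_standard"]])
    quant = quantify_b12(curve, wide["delta_od"].to_numpy())
    out = pd.concat([wide, quant], axis=1)
    return out, curve


def cytotoxicity_percent(sample: float, blank: float, killed: float) -> float:
    """Percent of cells with compromised membranes, relative to the killed
    control: ``100 * (sample - blank) / (killed - blank)``.

    Values above 100 are reported as-is (callers flag them), never clipped.
    """
    if killed <= blank:
        raise ValueError("killed-control fluorescence must exceed the blank")
    return 100.0 * (sample - blank) / (killed - blank)


def quantify_cytotox(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`cytotoxicity_percent` to a fluorescence table."""
    out = table.copy()
    out["percent_compromised"] = [
        cytotoxicity_percent(
            r["fluorescence_sample"], r["fluorescence_blank"], r["fluorescence_killed"]
        )
        for _, r in table.iterrows()
    ]
    out["over_100_flag"] = out["percent_compromised"] > 100.0
    return out


def npoc_dilution_correct(measured_mg_per_l: float, dilution_factor: float) -> float:
    """Undo sample dilution: ``measured * dilution_factor``."""
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if measured_mg_per_l < 0:
        raise ValueError("measured NPOC must be non-negative")
    return measured_mg_per_l * dilution_factor
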