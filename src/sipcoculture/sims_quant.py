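"""Per-cell isotope enrichment quantification from ion-count images.

Secondary-ion mass spectrometry of labeled cells yields co-registered count
images for the ion species 12C2-, 12C13C-, 12C14N-, 12C15N- and 32S-.  Carbon
enrichment is read from the dimer pair (12C2 vs 12C13C), nitrogen enrichment
from the cyanide pair (12C14N vs 12C15N).  This module sums counts over cell
regions of interest (ROIs), converts count ratios to heavy-isotope atom
fractions, and expresses enrichment as atom percent enrichment (APE) and as
net assimilation::

    X_net = (F_cell - F_unlabeled) / (F_substrate - F_unlabeled)

the fraction of a cell's biomass newly synthesized from the labeled source.
For nitrogen the source composition is known from the medium recipe (half the
ammonium supplied at 99 atom% 15N); for carbon, where the label is delivered
as gas in an open system, the mean algal biomass composition of the
experiment serves as the source estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Canonical channel keys, in acquisition order.
CHANNELS = ("C2", "C13C", "CN", "C15N", "S")

# Default instrument standards: unlabeled-biomass count ratios for the two
# isotope pairs.  At natural abundance the carbon dimer ratio 12C13C/12C2 is
# 0.02247 and the cyanide ratio 12C15N/12C14N is 0.00367.
DEFAULT_R_STD_C = 0.02247
DEFAULT_R_STD_N = 0.00367


@dataclass(frozen=True)
class IsotopeStandards:
    """Natural-abundance standards and labeling-design constants.

    Parameters
    ----------
    R_std_C, R_std_N :
        Unlabeled count ratios (12C13C/12C2, 12C15N/12C14N).
    p_label_15N :
        Atom fraction 15N of the labeled ammonium stock (0.99).
    substrate_mix_fraction :
        Fraction of medium ammonium supplied from the labeled stock (0.5).
    dimer_model :
        ``"pairing"`` (random-pairing binomial dimer statistics, the default)
        or ``"linear"`` (treat the dimer ratio like a monomer ratio,
        p = R/(1+R)) for comparability with simpler conventions.
    """

    R_std_C: float = DEFAULT_R_STD_C
    R_std_N: float = DEFAULT_R_STD_N
    p_label_15N: float = 0.99
    substrate_mix_fraction: float = 0.5
    dimer_model: str = "pairing"

    def __post_init__(self) -> None:
        if self.R_std_C <= 0 or self.R_std_N <= 0:
            raise ValueError("standard ratios must be positive")
        for name in ("p_label_15N", "substrate_mix_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dimer_model not in ("pairing", "linear"):
            raise ValueError("dimer_model must be 'pairing' or 'linear'")

    @property
    def F_unlabeled_C(self) -> float:
        """Natural 13C atom fraction implied by the carbon standard ratio."""
        return ratio_to_atom_fraction(
            self.R_std_C, "C_dimer", dimer_model=self.dimer_model
        )

    @property
    def F_unlabeled_N(self) -> float:
        """Natural 15N atom fraction implied by the nitrogen standard ratio."""
        return ratio_to_atom_fraction(self.R_std_N, "N_cyanide")

    @property
    def F_substrate_N(self) -> float:
        """15N atom fraction of the medium ammonium pool.

        A two-component mix: labeled stock at ``p_label_15N`` replacing
        ``substrate_mix_fraction`` of otherwise natural-abundance ammonium.
        """
        m = self.substrate_mix_fraction
        return m * self.p_label_15N + (1.0 - m) * self.F_unlabeled_N


@dataclass
class IonImageStack:
    """Co-registered integer ion-count rasters keyed by species.

    All channels share one shape; ``pixel_size_um`` is the edge length of a
    pixel in micrometres.  ``meta`` carries acquisition provenance (field id,
    timepoint_h, culture/condition, replicate).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {k: np.asarray(v).shape for k, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for k, v in self.channels.items():
            arr = np.asarray(v)
            if arr.size and arr.min() < 0:
                raise ValueError(f"negative counts in channel {k!r}")
            self.channels[k] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class ROISet:
    """Labeled cell regions with per-cell annotations.

    ``mask`` is an integer label image aligned to the stack (0 = background);
    ``annotations`` has one row per cell with at least columns ``cell_id``
    (the mask label) and ``partner`` ("alga" or "bacterium"), plus optional
    provenance columns (culture, replicate, timepoint_h, condition).
    """

    mask: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.size and self.mask.min() < 0:
            raise ValueError("mask labels must be non-negative")
        ann = self.annotations
        if len(ann):
            if (ann["cell_id"] <= 0).any():
                raise ValueError("annotated cell_id labels must be positive")
            present = set(np.unique(self.mask)) - {0}
            missing = set(ann["cell_id"]) - present
            if missing:
                raise ValueError(
                    f"annotated labels absent from mask: {sorted(missing)}"
                )


def ratio_to_atom_fraction(
    R: float | np.ndarray, species: str, dimer_model: str = "pairing"
) -> float | np.ndarray:
    """Convert an ion count ratio to a heavy-isotope atom fraction.

    For the cyanide pair the molecule carries one nitrogen atom, so
    ``p = R/(1+R)``.  For the carbon dimer, random pairing of atoms with
    heavy fraction p gives expected species abundances (1-p)^2 : 2p(1-p) for
    12C2 : 12C13C, hence R = 2p/(1-p) and ``p = R/(2+R)``.  The ``linear``
    dimer model applies the monomer formula to the dimer ratio instead.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("count ratio must be non-negative")
    if species == "C_dimer":
        p = R / (1.0 + R) if dimer_model == "linear" else R / (2.0 + R)
    elif species == "N_cyanide":
        p = R / (1.0 + R)
    else:
        raise ValueError(f"unknown species {species!r}")
    return float(p) if p.ndim == 0 else p


def atom_fraction_to_ratio(
    p: float | np.ndarray, species: str, dimer_model: str = "pairing"
) -> float | np.ndarray:
    """Inverse of :func:`ratio_to_atom_fraction`."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("atom fraction must lie in [0, 1)")
    if species == "C_dimer" and dimer_model != "linear":
        R = 2.0 * p / (1.0 - p)
    elif species in ("C_dimer", "N_cyanide"):
        R = p / (1.0 - p)
    else:
        raise ValueError(f"unknown species {species!r}")
    return float(R) if R.ndim == 0 else R


def ape(F_cell, F_natural):
    """Atom percent enrichment: ``100 * (F_cell - F_natural)``."""
    F_cell = np.asarray(F_cell, dtype=float)
    F_natural = np.asarray(F_natural, dtype=float)
    if np.any((F_cell < 0) | (F_cell > 1)) or np.any((F_natural < 0) | (F_natural > 1)):
        raise ValueError("atom fractions must lie in [0, 1]")
    out = 100.0 * (F_cell - F_natural)
    return float(out) if out.ndim == 0 else out


def x_net(F_cell, F_unlabeled, F_substrate):
    """Net assimilation: fraction of biomass newly synthesized from source.

    ``(F_cell - F_unlabeled) / (F_substrate - F_unlabeled)``.  Values outside
    [0, 1] are returned as-is (callers flag them); a degenerate denominator
    raises.
    """
    F_cell = np.asarray(F_cell, dtype=float)
    if np.isclose(F_substrate, F_unlabeled):
        raise ValueError(
            "F_substrate equals F_unlabeled: net assimilation undefined"
        )
    out = (F_cell - F_unlabeled) / (F_substrate - F_unlabeled)
    return float(out) if out.ndim == 0 else out


def summarize_rois(
    stack: IonImageStack, rois: ROISet, min_pixels: int = 5
) -> pd.DataFrame:
    """Sum each channel over every annotated ROI.

    Returns one row per annotated cell with columns ``cell_id``, ``partner``,
    any provenance columns from the annotations, ``n_pixels``, one summed
    column per channel, and ``excluded`` (True when the ROI has fewer than
    ``min_pixels`` pixels; such ROIs are reported, never silently dropped).
    """
    if rois.mask.shape != stack.shape:
        raise ValueError(
            f"mask shape {rois.mask.shape} != image shape {stack.shape}"
        )
    ann = rois.annotations.reset_index(drop=True)
    if ann.empty:
        warnings.warn("empty ROI annotation table: no cells to summarize")
        cols = list(ann.columns) + ["n_pixels", *stack.channels, "excluded"]
        return pd.DataFrame(columns=cols)
    labels = ann["cell_id"].to_numpy()
    out = ann.copy()
    out["n_pixels"] = ndimage.sum_labels(
        np.ones(rois.mask.shape, dtype=np.int64), rois.mask, labels
    ).astype(int)
    for name, img in stack.channels.items():
        out[name] = ndimage.sum_labels(img, rois.mask, labels)
    out["excluded"] = out["n_pixels"] < min_pixels
    n_small = int(out["excluded"].sum())
    if n_small:
        logger.info(
            "%d ROI(s) below min_pixels=%d excluded from quantification: %s",
            n_small, min_pixels, out.loc[out["excluded"], "cell_id"].tolist(),
        )
    return out


def source_carbon_fraction(records: pd.DataFrame) -> float:
    """Mean algal 13C atom fraction across an experiment.

    The gas-delivered 13C source cannot be mass-balanced in an open system,
    so the arithmetic mean of algal biomass F13C over all algal cells and
    timepoints of the experiment stands in for the source composition.
    """
    algal = records.loc[records["partner"] == "alga", "F13C"].dropna()
    if algal.empty:
        raise ValueError("no algal records: cannot estimate carbon source")
    return float(algal.mean())


def enrich_records(
    sums: pd.DataFrame, standards: IsotopeStandards
) -> pd.DataFrame:
    """Ratios, atom fractions and APE for a table of per-cell channel sums."""
    rec = sums.loc[~sums["excluded"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rec["R_C"] = np.where(rec["C2"] > 0, rec["C13C"] / rec["C2"], np.nan)
        rec["R_N"] = np.where(rec["CN"] > 0, rec["C15N"] / rec["CN"], np.nan)
    rec["F13C"] = ratio_to_atom_fraction(
        rec["R_C"].fillna(0.0).to_numpy(), "C_dimer", standards.dimer_model
    )
    rec["F15N"] = ratio_to_atom_fraction(
        rec["R_N"].fillna(0.0).to_numpy(), "N_cyanide"
    )
    rec.loc[rec["R_C"].isna(), "F13C"] = np.nan
    rec.loc[rec["R_N"].isna(), "F15N"] = np.nan
    rec["APE_C"] = 100.0 * (rec["F13C"] - standards.F_unlabeled_C)
    rec["APE_N"] = 100.0 * (rec["F15N"] - standards.F_unlabeled_N)
    return rec


def quantify_experiment(
    fields: list[tuple[IonImageStack, ROISet]],
    standards: IsotopeStandards | None = None,
    min_pixels: int = 5,
    control_fields: list[tuple[IonImageStack, ROISet]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Quantify every ROI of an experiment and summarize per group.

    Parameters
    ----------
    fields :
        (stack, rois) pairs belonging to one experiment (one labeling run).
    standards :
        Isotope standards; defaults to the packaged natural-abundance values.
    control_fields :
        Optional unlabeled / killed-control fields; when given, the maximum
        absolute APE observed among control cells is reported as the
        background threshold for each isotope.

    Returns
    -------
    records :
        One row per retained cell: summed counts, ratios, atom fractions,
        APE_C/APE_N, C_net/N_net and out-of-range flags.
    summary :
        Dict with the carbon source estimate, per-(partner, condition,
        timepoint) medians of C_net/N_net and means of APE (pooled and per
        culture), and background thresholds when controls were supplied.
    """
    standards = standards or IsotopeStandards()
    per_field = []
    for stack, rois in fields:
        sums = summarize_rois(stack, rois, min_pixels=min_pixels)
        for key, val in stack.meta.items():
            if key not in sums.columns:
                sums[key] = val
        per_field.append(sums)
    all_sums = pd.concat(per_field, ignore_index=True) if per_field else pd.DataFrame()
    if all_sums.empty or all_sums["excluded"].all():
        raise ValueError("no ROI passed the minimum-size filter")
    try:
        records = enrich_records(all_sums, standards)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"missing channel for cell quantification: {exc}") from exc

    F_sub_C = source_carbon_fraction(records)
    records["C_net"] = x_net(
        records["F13C"].to_numpy(), standards.F_unlabeled_C, F_sub_C
    )
    records["N_net"] = x_net(
        records["F15N"].to_numpy(), standards.F_unlabeled_N, standards.F_substrate_N
    )
    for col in ("C_net", "N_net"):
        records[f"{col}_out_of_range"] = (records[col] < 0) | (records[col] > 1)

    group_cols = [
        c for c in ("partner", "condition", "timepoint_h") if c in records.columns
    ]
    med = (
        records.groupby(group_cols, dropna=False)[["C_net", "N_net"]]
        .median()
        .reset_index()
        if group_cols
        else pd.DataFrame()
    )
    ape_means = (
        records.groupby(group_cols, dropna=False)[["APE_C", "APE_N"]]
        .mean()
        .reset_index()
        if group_cols
        else pd.DataFrame()
    )
    per_culture = None
    if "culture" in records.columns or "replicate" in records.columns:
        rep_col = "culture" if "culture" in records.columns else "replicate"
        per_culture = (
            records.groupby(group_cols + [rep_col], dropna=False)[["C_net", "N_net"]]
            .median()
            .reset_index()
        )
    summary = {
        "F_substrate_C": F_sub_C,
        "F_substrate_N": standards.F_substrate_N,
        "F_unlabeled_C": standards.F_unlabeled_C,
        "F_unlabeled_N": standards.F_unlabeled_N,
        "median_xnet": med,
        "mean_ape": ape_means,
        "median_xnet_per_culture": per_culture,
        "n_cells": int(len(records)),
        "n_excluded": int(all_sums["excluded"].sum()),
    }
    if control_fields:
        ctrl_records = []
        for stack, rois in control_fields:
            s = summarize_rois(stack, rois, min_pixels=min_pixels)
            ctrl_records.append(enrich_records(s, standards))
        ctrl = pd.concat(ctrl_records, ignore_index=True)
        summary["background_ape_C"] = float(ctrl["APE_C"].abs().max())
        summary["background_ape_N"] = float(ctrl["APE_N"].abs().max())
    return records, summary
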