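"""End-to-end pipeline: simulate, quantify, assess, budget, report.

:func:`run_full` drives every stage on the packaged synthetic scenarios (or
user-supplied configuration) and emits the per-cell isotope table, growth
assessment, lysis budget and assay quantifications, plus a JSON report of
the headline comparisons.  All randomness flows from one root seed split
per stage, so a rerun with the same configuration reproduces the report
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, growth as gm, io as sio, lysis
from .scenario import CocultureScenario
from .simulate import (
    FieldSpec,
    render_experiment,
    simulate_bioassay_plate,
    simulate_coculture,
    simulate_cytotox_table,
)
from .sims_quant import CHANNELS, IsotopeStandards, quantify_experiment

logger = logging.getLogger(__name__)


def packaged_path(name: str):
    """Path to a packaged data file (scenario / fixture YAML)."""
    return resources.files("sipcoculture.data") / name


def load_standards(path: str | Path | None = None) -> IsotopeStandards:
    src = Path(path) if path else packaged_path("standards.yaml")
    d = yaml.safe_load(src.read_text())
    return IsotopeStandards(**d)


@dataclass
class RunConfig:
    """Configuration for a full synthetic-bundle run."""

    seed: int = 0
    out_dir: str | Path | None = None
    alpha: float = 0.05
    flag_ratio: float = 0.5
    dimer_model: str = "pairing"
    welch: bool = False
    write_images: bool = False
    scenario_continuous: CocultureScenario | None = None
    scenario_diurnal: CocultureScenario | None = None
    b12_true_by_timepoint: dict = field(
        default_factory=lambda: {14.0: 0.0, 24.0: 0.0, 36.0: 20.0, 48.0: 50.0}
    )
    lysis_fixture: str | Path | None = None  # defaults to packaged fixture

    def resolved_scenarios(self) -> tuple[CocultureScenario, CocultureScenario]:
        cont = self.scenario_continuous or CocultureScenario.load_yaml(
            packaged_path("sip_continuous.yaml")
        )
        diur = self.scenario_diurnal or CocultureScenario.load_yaml(
            packaged_path("sip_diurnal.yaml")
        )
        return cont, diur

    def to_jsonable(self) -> dict:
        cont, diur = self.resolved_scenarios()
        return {
            "seed": self.seed,
            "alpha": self.alpha,
            "flag_ratio": self.flag_ratio,
            "dimer_model": self.dimer_model,
            "welch": self.welch,
            "b12_true_by_timepoint": {str(k): v for k, v in
                                      sorted(self.b12_true_by_timepoint.items())},
            "scenario_continuous": cont.to_dict(),
            "scenario_diurnal": diur.to_dict(),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _seed_for(root: int, stage: int) -> int:
    ss = np.random.SeedSequence([root, stage])
    return int(ss.generate_state(1)[0] % (2**31))


def load_lysis_fixture(path: str | Path | None = None) -> dict:
    src = Path(path) if path else packaged_path("coculture_default.yaml")
    raw = yaml.safe_load(src.read_text())

    def _num(v):
        # plain-YAML "1.6e6" lacks the exponent sign and loads as str
        if isinstance(v, str):
            return float(v)
        if isinstance(v, list):
            return [_num(x) for x in v]
        return v

    return {k: _num(v) for k, v in raw.items()}


def lysis_budget_from_fixture(fixture: dict) -> dict:
    """Worked-example lysis budget from a fixture of measured quantities.

    The per-lysed-cell yield is computed from lysate CFU replicates; the
    headline (one-significant-figure) yield then drives the headline
    required-density and required-fraction arithmetic, with full-precision
    values reported alongside.
    """
    y = lysis.yield_per_lysed_cell(
        fixture["cfu_in_lysate_per_ml"],
        fixture["lysed_algal_density_per_ml"],
        fixture.get("cfu_baseline_per_ml", 0.0),
    )
    budget = lysis.LysisBudget(
        yield_cfu_per_cell=y["headline"],
        yield_sd=y["yield_sd"],
        observed_proliferation=fixture["observed_proliferation_cfu_per_ml"],
        algal_density=fixture["algal_density_per_ml"],
        measured_lysis_range_pct=tuple(fixture["measured_lysis_range_pct"]),
    )
    out = budget.to_dict()
    out["yield_full_precision"] = y["yield_cfu_per_cell"]
    out["yield_sd"] = y["yield_sd"]
    full = lysis.LysisBudget(
        yield_cfu_per_cell=y["yield_cfu_per_cell"],
        yield_sd=y["yield_sd"],
        observed_proliferation=fixture["observed_proliferation_cfu_per_ml"],
        algal_density=fixture["algal_density_per_ml"],
    )
    out["required_density_full_precision"] = full.required_density
    out["required_fraction_full_precision_pct"] = full.required_fraction_pct
    return out


def run_full(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written to disk
    when ``config.out_dir`` is set)."""
    seed = config.seed
    standards = IsotopeStandards(dimer_model=config.dimer_model)
    cont_sc, diur_sc = config.resolved_scenarios()
    cont_sc = cont_sc.replace(seed=_seed_for(seed, 1))
    diur_sc = diur_sc.replace(seed=_seed_for(seed, 2))

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "stage_seeds": {f"stage_{i}": _seed_for(seed, i) for i in range(1, 7)},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- stage 1-2: simulate + render + quantify per regime --------------
    records_all, sims = [], {}
    for sc, stage in ((cont_sc, 1), (diur_sc, 2)):
        sim = simulate_coculture(sc)
        sims[sc.light_regime] = sim
        fields = render_experiment(
            sim.truth.assign(condition=sc.light_regime),
            FieldSpec(),
            seed=_seed_for(seed, 10 + stage),
        )
        if out_dir and config.write_images:
            for i, (stack, rois) in enumerate(fields):
                sio.write_field(stack, rois, out_dir / "fields",
                                f"{sc.light_regime}_{i:02d}")
        recs, summary = quantify_experiment(fields, standards=standards)
        recs["condition"] = sc.light_regime
        records_all.append(recs)
        report[f"quantification_{sc.light_regime}"] = {
            "F_substrate_C": summary["F_substrate_C"],
            "n_cells": summary["n_cells"],
            "median_xnet": summary["median_xnet"].to_dict("records"),
        }
    records = pd.concat(records_all, ignore_index=True)

    # ---- headline C_net comparison ---------------------------------------
    final_tp = max(cont_sc.sampling_timepoints_h)
    sel = (records["partner"] == "bacterium") & (records["timepoint_h"] == final_tp)
    cnet_cont = records.loc[sel & (records["condition"] == "continuous"), "C_net"]
    cnet_diur = records.loc[
        sel & (records["condition"] == "diurnal_12_12"), "C_net"
    ]
    ttest = gm.t_test_two_tailed(
        cnet_cont, cnet_diur, alpha=config.alpha, welch=config.welch
    )
    report["cnet_comparison"] = {
        "timepoint_h": final_tp,
        "median_continuous": float(cnet_cont.median()),
        "median_diurnal": float(cnet_diur.median()),
        **ttest,
    }

    # ---- growth: max-density fold + synthesis assessment ------------------
    bact = {
        k: s.growth[s.growth["partner"] == "bacterium"] for k, s in sims.items()
    }
    fold, per_rep = gm.max_density_fold(bact["continuous"], bact["diurnal_12_12"])
    report["max_bacterial_density_fold"] = {"fold": fold, **per_rep}
    report["algal_plateau"] = {
        k: float(
            s.growth[s.growth["partner"] == "alga"]
            .groupby("time_h")["density"].mean().max()
        )
        for k, s in sims.items()
    }
    nnet_meas = (
        records[(records["partner"] == "bacterium")
                & (records["condition"] == "continuous")]
        .groupby("timepoint_h")["N_net"].median()
        .rename("xnet").reset_index()
    )
    assessment = gm.assess_synthesis(
        bact["continuous"], nnet_meas, flag_ratio=config.flag_ratio
    )
    report["synthesis_assessment_continuous"] = assessment.to_dict("records")

    # ---- cell length statistics -------------------------------------------
    truth_cont = sims["continuous"].truth
    lstats = {}
    for tp, sub in truth_cont[truth_cont["partner"] == "bacterium"].groupby(
        "timepoint_h"
    ):
        lstats[str(tp)] = gm.length_stats(sub["true_length_um"])
    first_tp, last_tp = min(lstats, key=float), max(lstats, key=float)
    report["bacterial_length"] = {
        "per_timepoint": lstats,
        "percent_reduction_start_to_end": gm.percent_reduction(
            cont_sc.cell_length_start_um, lstats[last_tp]["mean"]
        ),
    }

    # ---- lysis budget ------------------------------------------------------
    fixture = load_lysis_fixture(config.lysis_fixture)
    report["lysis_budget_fixture"] = lysis_budget_from_fixture(fixture)

    wt_sc = CocultureScenario.wildtype_coculture(seed=_seed_for(seed, 5))
    wt_sim = simulate_coculture(wt_sc)
    true_lysis_frac = (
        wt_sim.ledger["lysed_cells_cum_per_ml"].iloc[-1]
        / wt_sim.ledger["algal_density"].iloc[-1]
    )
    cyto = simulate_cytotox_table(
        np.full(3, true_lysis_frac), seed=_seed_for(seed, 3)
    )
    cyto_q = assays.quantify_cytotox(cyto)
    # measured interval: replicate mean +/- 3 sd of the integrity assay
    m, s = cyto_q["percent_compromised"].mean(), cyto_q["percent_compromised"].std()
    measured_range = (max(float(m - 3 * s), 0.0), float(m + 3 * s))
    wt_bact = wt_sim.growth[wt_sim.growth["partner"] == "bacterium"]
    prolif = (
        wt_bact.groupby("replicate")["density"].max()
        - wt_bact[wt_bact["time_h"] == 0].groupby("replicate")["density"].mean()
    ).mean()
    sim_budget = lysis.LysisBudget(
        yield_cfu_per_cell=wt_sc.bacterial_yield_per_lysed_cell,
        yield_sd=0.0,
        observed_proliferation=float(prolif),
        algal_density=float(wt_sim.ledger["algal_density"].iloc[-1]),
        measured_lysis_range_pct=measured_range,
    )
    report["lysis_budget_simulated"] = {
        **sim_budget.to_dict(),
        "true_lysis_fraction_pct": 100.0 * float(true_lysis_frac),
    }

    # ---- B12 bioassay ------------------------------------------------------
    tps = sorted(config.b12_true_by_timepoint)
    plate = simulate_bioassay_plate(
        [config.b12_true_by_timepoint[t] for t in tps], seed=_seed_for(seed, 4)
    )
    b12_table, curve = assays.quantify_plate(plate)
    samples = b12_table[~b12_table["is_standard"]].reset_index(drop=True)
    report["b12_bioassay"] = {
        "curve_model": curve.model,
        "per_timepoint": [
            {
                "timepoint_h": float(tp),
                "true_ng_per_l": float(config.b12_true_by_timepoint[tp]),
                "quantified_ng_per_l": float(samples.loc[i, "b12_ng_per_l"]),
                "censored": bool(samples.loc[i, "censored"]),
                "flag": str(samples.loc[i, "flag"]),
            }
            for i, tp in enumerate(tps)
        ],
    }

    # ---- write outputs -----------------------------------------------------
    if out_dir:
        records.to_csv(out_dir / "cells.csv", index=False)
        assessment.to_csv(out_dir / "assessment.csv", index=False)
        for k, s in sims.items():
            sio.write_growth_csv(s.growth, out_dir / f"growth_{k}.csv")
            s.ledger.to_csv(out_dir / f"ledger_{k}.csv", index=False)
            s.truth.to_csv(out_dir / f"truth_{k}.csv", index=False)
        b12_table.to_csv(out_dir / "b12.csv", index=False)
        cyto_q.to_csv(out_dir / "cytotox.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float)
        )
        (out_dir / "report.txt").write_text(render_report_text(report))
    return report


def render_report_text(report: dict) -> str:
    """Human-readable summary of the headline numbers."""
    c = report["cnet_comparison"]
    f = report["max_bacterial_density_fold"]
    lb = report["lysis_budget_fixture"]
    lines = [
        "SIP coculture report",
        f"  config {report['config_hash']}  seed {report['seed']}",
        "",
        f"Median bacterial C_net at {c['timepoint_h']:g} h: "
        f"{c['median_continuous']:.3f} (continuous) vs "
        f"{c['median_diurnal']:.3f} (diurnal); "
        f"t = {c['t']:.2f}, p = {c['p']:.2g}"
        + (" *" if c["significant"] else ""),
        f"Max bacterial density fold (continuous/diurnal): {f['fold']:.2f}",
        "Algal plateau (cells/ml): "
        + ", ".join(f"{k} {v:.3g}" for k, v in report["algal_plateau"].items()),
        "",
        "Lysis budget (worked example): "
        f"yield {lb['yield_full_precision']:.1f} CFU/cell "
        f"(headline {lb['yield_headline']:g} ± {lb['yield_sd']:.0f}), "
        f"required {lb['required_lysed_density_per_ml']:.3g} cells/ml = "
        f"{lb['required_fraction_pct']:.2g}% of the population -> {lb['verdict']}",
    ]
    for row in report["synthesis_assessment_continuous"]:
        lines.append(
            f"  t={row['timepoint_h']:5.1f} h  d={row['d']:.2f}  "
            f"expected={row['expected_xnet']:.3f}  measured={row['measured_xnet']:.3f}"
            + ("  REDUCTIVE DIVISION" if row["reductive_division_flag"] else "")
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    growth_csv: str | Path | None = None,
    image_dir: str | Path | None = None,
    plate_csv: str | Path | None = None,
) -> ValidationReport:
    """Check input files for schema and alignment problems.

    Collects warnings (e.g. a missing 32S channel, unused by the core math)
    and errors (shape mismatches, bad units, missing columns); never raises
    unless a file is unreadable.
    """
    rep = ValidationReport()
    if growth_csv is not None:
        try:
            df = pd.read_csv(growth_csv)
        except Exception as exc:
            rep.errors.append(f"growth CSV unreadable: {exc}")
            df = None
        if df is not None:
            missing = set(sio.GROWTH_COLUMNS) - set(df.columns)
            if missing:
                rep.errors.append(f"growth CSV missing columns {sorted(missing)}")
            elif (bad := set(df["unit"]) - sio.DENSITY_UNITS):
                rep.errors.append(
                    f"growth CSV column 'unit' has unsupported values {sorted(bad)}"
                )
            if df is not None and "density" in df.columns and (df["density"] <= 0).any():
                rep.errors.append("growth CSV contains non-positive densities")
    if image_dir is not None:
        image_dir = Path(image_dir)
        prefixes = sorted(
            {p.name.rsplit("_mask.tif", 1)[0] for p in image_dir.glob("*_mask.tif")}
        )
        if not prefixes:
            rep.errors.append(f"no label masks (*_mask.tif) found in {image_dir}")
        import tifffile

        for prefix in prefixes:
            try:
                mask = tifffile.imread(image_dir / f"{prefix}_mask.tif")
                channels = {
                    ch: tifffile.imread(image_dir / f"{prefix}_{ch}.tif")
                    for ch in CHANNELS
                    if (image_dir / f"{prefix}_{ch}.tif").exists()
                }
            except Exception as exc:
                rep.errors.append(f"field {prefix}: unreadable ({exc})")
                continue
            missing = set(CHANNELS) - set(channels)
            if missing == {"S"}:
                rep.warnings.append(
                    f"field {prefix}: 32S channel missing (unused by core math)"
                )
            elif missing:
                rep.errors.append(f"field {prefix}: missing channels {sorted(missing)}")
            shapes = {img.shape for img in channels.values()}
            if len(shapes) > 1:
                rep.errors.append(f"field {prefix}: channel shapes differ: {shapes}")
            elif shapes and mask.shape not in shapes:
                rep.errors.append(
                    f"field {prefix}: mask shape {mask.shape} != image "
                    f"shape {next(iter(shapes))}"
                )
    if plate_csv is not None:
        try:
            df = pd.read_csv(plate_csv)
        except Exception as exc:
            rep.errors.append(f"plate CSV unreadable: {exc}")
            df = None
        if df is not None:
            need = {"sample_id", "strain", "od600", "is_standard"}
            missing = need - set(df.columns)
            if missing:
                rep.errors.append(f"plate CSV missing columns {sorted(missing)}")
    return rep
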