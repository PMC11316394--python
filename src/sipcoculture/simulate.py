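"""Seeded synthetic-data generator for the coculture SIP pipeline.

Three generators cover every input the analysis consumes:

* :func:`simulate_coculture` — population dynamics plus a carbon ledger and a
  per-cell isotope/size ground-truth table for one scenario;
* :func:`render_sip_field` — Poisson ion-count images (12C2-, 12C13C-,
  12C14N-, 12C15N-, 32S-) with a matching label mask for a set of cells;
* :func:`simulate_bioassay_plate` / :func:`simulate_cytotox_table` — assay
  plate tables for the B12 bioassay and the membrane-integrity assay.

The population layer is deterministic given the scenario (logistic algal
growth in continuous light, synchronized division at nightfall in diurnal
light, first-order exudation, a constant daily lysis fraction, and Monod
bacterial uptake of a shared dissolved-organic-carbon pool with a fixed CFU
yield).  The single-cell enrichment truth is a phenomenological layer riding
on top of it: per-cell heavy-isotope atom fractions follow saturating
trajectories anchored to the endpoint enrichments the scenario specifies,
with seeded lognormal cell-to-cell spread.  All randomness flows from the
scenario seed (or an explicit override), so identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenario import CocultureScenario
from .sims_quant import IonImageStack, IsotopeStandards, ROISet

__all__ = [
    "SimulationResult",
    "FieldSpec",
    "simulate_coculture",
    "render_sip_field",
    "render_experiment",
    "simulate_bioassay_plate",
    "simulate_cytotox_table",
]


@dataclass
class SimulationResult:
    """Outputs of one simulated scenario.

    growth :
        Long-format density observations: time_h, condition, replicate,
        partner, density, unit.
    ledger :
        Per-timestep carbon accounting: exuded NPOC (total and
        bioavailable), lysed cells and their carbon, cumulative bacterial
        assimilation, and the dissolved pool.
    truth :
        One row per simulated (samplable) cell: cell_id, partner, true
        atom fractions, true length, timepoint, replicate, condition.
    scenario :
        The scenario that produced the run.
    """

    growth: pd.DataFrame
    ledger: pd.DataFrame
    truth: pd.DataFrame
    scenario: CocultureScenario


def _algal_density(sc: CocultureScenario, t: np.ndarray) -> np.ndarray:
    """Deterministic algal density trajectory (cells/ml)."""
    A0, K = sc.algal_inoculum, sc.algal_K
    if A0 <= 0:
        return np.zeros_like(t)
    if sc.light_regime == "continuous":
        r = math.log(2.0) / sc.algal_doubling_h
        c = (K - A0) / A0
        return K / (1.0 + c * np.exp(-r * t))
    # diurnal 12/12: density holds through the light phase and doubles just
    # after each nightfall (t = 12, 36, 60, ...), capped at K
    n_div = np.floor((t - 12.0 - 1e-9) / 24.0) + 1
    n_div = np.clip(n_div, 0, None)
    return np.minimum(A0 * 2.0 ** n_div, K)


def _bacterial_dynamics(
    sc: CocultureScenario, t: np.ndarray, A: np.ndarray
) -> pd.DataFrame:
    """Integrate the DOC pool and bacterial CFU density (explicit Euler)."""
    dt = sc.dt_h
    n = len(t)
    lam = sc.lysis_fraction_per_day / 24.0
    y_cfu = (
        sc.bacterial_yield_per_lysed_cell / sc.carbon_per_algal_cell_ug
        if sc.carbon_per_algal_cell_ug > 0
        else 0.0
    )  # CFU per µg usable C
    B = np.empty(n)
    S = np.empty(n)
    exuded = np.empty(n)
    usable = np.empty(n)
    lysed_cells = np.empty(n)
    lysed_c = np.empty(n)
    assim = np.empty(n)
    B[0], S[0] = sc.bacterial_inoculum_cfu, sc.initial_doc_ug_per_ml
    exuded[0] = usable[0] = lysed_cells[0] = lysed_c[0] = assim[0] = 0.0
    m0 = sc.carbon_per_cfu_ug
    for i in range(1, n):
        a = A[i - 1]
        exu = sc.exudation_rate * (a / 1e6) * dt            # µg/ml, total NPOC
        exu_use = sc.exudate_usable_fraction * exu
        lys_cells = lam * a * dt
        lys_c = sc.carbon_per_algal_cell_ug * lys_cells
        supply = exu_use + lys_c
        s_avail = S[i - 1] + supply
        uptake = min(
            sc.vmax_ug_per_cfu_h * s_avail / (sc.Ks_ug_per_ml + s_avail) * B[i - 1] * dt,
            s_avail,
        )
        S[i] = s_avail - uptake
        new_B = B[i - 1] + y_cfu * uptake
        # biomass-capped division: CFUs cannot exceed what the assimilated
        # biomass allows even after reductive_division_max extra doublings
        if m0 > 0:
            biomass = sc.bacterial_inoculum_cfu * m0 + sc.biomass_retention * (
                assim[i - 1] + uptake
            )
            new_B = min(new_B, biomass / m0 * 2.0 ** sc.reductive_division_max)
        B[i] = max(new_B, B[i - 1])
        exuded[i] = exuded[i - 1] + exu
        usable[i] = usable[i - 1] + exu_use
        lysed_cells[i] = lysed_cells[i - 1] + lys_cells
        lysed_c[i] = lysed_c[i - 1] + lys_c
        assim[i] = assim[i - 1] + uptake
    return pd.DataFrame(
        {
            "time_h": t,
            "algal_density": A,
            "bacterial_cfu": B,
            "doc_pool_ug_per_ml": S,
            "exuded_npoc_cum_ug_per_ml": exuded,
            "exuded_usable_cum_ug_per_ml": usable,
            "lysed_cells_cum_per_ml": lysed_cells,
            "lysed_carbon_cum_ug_per_ml": lysed_c,
            "assimilated_cum_ug_per_ml": assim,
        }
    )


def _saturating_ramp(t: np.ndarray, t0: float, tau: float, t_ref: float) -> np.ndarray:
    """(1 - exp(-(t-t0)/tau)) normalized to 1 at t_ref; 0 before t0."""
    ref = 1.0 - math.exp(-max(t_ref - t0, 1e-9) / tau)
    out = (1.0 - np.exp(-np.clip(t - t0, 0.0, None) / tau)) / ref
    return np.where(t <= t0, 0.0, out)


class _EnrichmentTruth:
    """Deterministic per-population enrichment and size trajectories."""

    def __init__(self, sc: CocultureScenario, ledger: pd.DataFrame,
                 standards: IsotopeStandards):
        self.sc = sc
        self.nat_C = standards.F_unlabeled_C
        self.nat_N = standards.F_unlabeled_N
        self.F_sub_N = (
            sc.f15N_substrate
            if sc.f15N_substrate is not None
            else standards.F_substrate_N
        )
        self._ledger = ledger
        tps = np.asarray(sc.sampling_timepoints_h, dtype=float)
        self.p_bar_alga = float(np.mean(self.algal_p13C(tps))) if sc.algal_inoculum > 0 else self.nat_C
        # carbon-depletion time for the length / balanced-growth logic
        scarce = ledger["doc_pool_ug_per_ml"].to_numpy() < 0.5
        t = ledger["time_h"].to_numpy()
        self.t_scarce = float(t[scarce][0]) if scarce.any() else float(t[-1])

    def algal_p13C(self, t):
        sc = self.sc
        rise = 1.0 - np.exp(
            -np.clip(np.asarray(t, float) - sc.label_start_h, 0.0, None)
            / sc.algal_label_tau_h
        )
        return self.nat_C + (sc.f13C_source_max - self.nat_C) * rise

    def algal_p15N(self, t):
        sc = self.sc
        A = _algal_density(sc, np.asarray(t, float))
        with np.errstate(divide="ignore", invalid="ignore"):
            new_frac = np.where(A > 0, 1.0 - sc.algal_inoculum / A, 0.0)
        return self.nat_N + np.clip(new_frac, 0.0, 1.0) * (self.F_sub_N - self.nat_N)

    def bacterial_p13C(self, t):
        sc = self.sc
        prof = sc.cnet_48h * _saturating_ramp(
            np.asarray(t, float), sc.label_start_h, sc.cnet_tau_h, 48.0
        )
        return self.nat_C + prof * (self.p_bar_alga - self.nat_C)

    def bacterial_nnet(self, t):
        """Bacterial new-biomass fraction read by the 15N tracer."""
        sc = self.sc
        t = np.asarray(t, float)
        if sc.algal_inoculum > 0:
            return sc.nnet_max * (1.0 - np.exp(-t / sc.nnet_tau_h))
        # monoculture: biomass tracks division while carbon lasts (balanced
        # growth), then no further synthesis
        led = self._ledger
        B = np.interp(np.minimum(t, self.t_scarce), led["time_h"], led["bacterial_cfu"])
        return 1.0 - self.sc.bacterial_inoculum_cfu / np.maximum(
            B, self.sc.bacterial_inoculum_cfu
        )

    def bacterial_p15N(self, t):
        return self.nat_N + self.bacterial_nnet(t) * (self.F_sub_N - self.nat_N)

    def bacterial_length(self, t):
        """Mean pole-to-pole length: shrinks once carbon becomes scarce."""
        sc = self.sc
        t = np.asarray(t, float)
        dt_scarce = np.clip(t - self.t_scarce, 0.0, None)
        decay = np.exp(-dt_scarce / sc.cell_length_tau_h)
        lmin, l0 = sc.cell_length_min_um, sc.cell_length_start_um
        return np.where(t <= self.t_scarce, l0, lmin + (l0 - lmin) * decay)


def simulate_coculture(
    scenario: CocultureScenario,
    seed: int | None = None,
    standards: IsotopeStandards | None = None,
) -> SimulationResult:
    """Simulate one scenario: densities, carbon ledger, per-cell truth.

    ``seed`` overrides ``scenario.seed``.  The returned growth table carries
    observation noise (multiplicative lognormal, CV ``obs_noise_cv``) per
    replicate; the ledger is the underlying deterministic trajectory.
    """
    sc = scenario
    standards = standards or IsotopeStandards()
    root = np.random.SeedSequence(sc.seed if seed is None else seed)
    obs_ss, truth_ss = root.spawn(2)

    t = np.arange(0.0, sc.duration_h + sc.dt_h / 2, sc.dt_h)
    if t[0] < 0:
        raise ValueError("negative time grid")
    A = _algal_density(sc, t)
    ledger = _bacterial_dynamics(sc, t, A)

    # --- observed growth series -------------------------------------------
    obs_t = np.arange(0.0, sc.duration_h + 1e-9, sc.obs_every_h)
    A_obs = np.interp(obs_t, t, A)
    B_obs = np.interp(obs_t, t, ledger["bacterial_cfu"])
    rng = np.random.default_rng(obs_ss)
    rows = []
    for rep in range(1, sc.n_replicates + 1):
        for partner, dens, unit in (
            ("alga", A_obs, "cells/ml"),
            ("bacterium", B_obs, "CFU/ml"),
        ):
            if partner == "alga" and sc.algal_inoculum <= 0:
                continue
            noise = rng.lognormal(0.0, sc.obs_noise_cv, size=len(obs_t))
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": obs_t,
                        "condition": sc.light_regime,
                        "replicate": rep,
                        "partner": partner,
                        "density": dens * noise,
                        "unit": unit,
                    }
                )
            )
    growth = pd.concat(rows, ignore_index=True)

    # --- per-cell ground truth --------------------------------------------
    tr = _EnrichmentTruth(sc, ledger, standards)
    rng_t = np.random.default_rng(truth_ss)
    cells = []
    cell_id = 0
    for rep in range(1, sc.n_replicates + 1):
        for tp in sc.sampling_timepoints_h:
            for partner, n_cells in (
                ("alga", sc.n_algae_per_sample if sc.algal_inoculum > 0 else 0),
                ("bacterium", sc.n_bacteria_per_sample),
            ):
                for _ in range(n_cells):
                    cell_id += 1
                    jit_c = rng_t.lognormal(0.0, sc.enrichment_jitter)
                    jit_n = rng_t.lognormal(0.0, sc.enrichment_jitter)
                    if partner == "alga":
                        p13 = tr.nat_C + (float(tr.algal_p13C(tp)) - tr.nat_C) * jit_c
                        p15 = tr.nat_N + (float(tr.algal_p15N(tp)) - tr.nat_N) * jit_n
                        length = float(
                            rng_t.uniform(*sc.alga_diameter_um)
                        )  # diameter for a disk-shaped alga
                    else:
                        p13 = tr.nat_C + (float(tr.bacterial_p13C(tp)) - tr.nat_C) * jit_c
                        p15 = tr.nat_N + (float(tr.bacterial_p15N(tp)) - tr.nat_N) * jit_n
                        length = float(
                            max(
                                0.6,
                                rng_t.normal(
                                    float(tr.bacterial_length(tp)),
                                    sc.cell_length_sd_um,
                                ),
                            )
                        )
                    cells.append(
                        {
                            "cell_id": cell_id,
                            "partner": partner,
                            "true_p13C": float(np.clip(p13, 0.0, 0.98)),
                            "true_p15N": float(np.clip(p15, 0.0, 0.98)),
                            "true_length_um": length,
                            "timepoint_h": float(tp),
                            "replicate": rep,
                            "condition": sc.light_regime,
                        }
                    )
    truth = pd.DataFrame(cells)
    return SimulationResult(growth=growth, ledger=ledger, truth=truth, scenario=sc)


# ---------------------------------------------------------------------------
# ion-image rendering
# ---------------------------------------------------------------------------


@dataclass
class FieldSpec:
    """Geometry and count budget of one rendered raster field.

    256 x 256 pixels at 0.1 µm/px resolves 1.4–2.3 µm rods with >= 14 px
    length.  ``*_c_counts`` are expected total carbon-dimer ion counts per
    cell; the nitrogen budget is ``n_to_c_ratio`` times the carbon budget.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    alga_c_counts: float = 6e5
    bacterium_c_counts: float = 1e5
    n_to_c_ratio: float = 0.6
    s_counts_per_px: float = 5.0
    background_per_px: float = 0.01
    bacterium_width_um: float = 0.5
    margin_px: int = 4
    max_place_tries: int = 500
    positions: dict | None = None  # cell_id -> (row, col[, angle_rad])

    def __post_init__(self) -> None:
        if self.alga_c_counts <= 0 or self.bacterium_c_counts <= 0:
            raise ValueError("mean counts per cell must be positive")


def _cell_footprint(row: pd.Series, spec: FieldSpec, center, angle, shape):
    """Boolean pixel footprint of one cell: disk (alga) or capsule (rod)."""
    px = spec.pixel_size_um
    r0, c0 = center
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    if row["partner"] == "alga":
        radius = row["true_length_um"] / 2.0 / px
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    half = max(row["true_length_um"] - spec.bacterium_width_um, 0.1) / 2.0 / px
    wr = spec.bacterium_width_um / 2.0 / px
    dr, dc = math.sin(angle) * half, math.cos(angle) * half
    # distance from each pixel to the capsule axis segment
    ar, ac = r0 - dr, c0 - dc
    br, bc = r0 + dr, c0 + dc
    vr, vc = br - ar, bc - ac
    seg2 = vr * vr + vc * vc
    tpar = np.clip(((rr - ar) * vr + (cc - ac) * vc) / max(seg2, 1e-9), 0.0, 1.0)
    dist2 = (rr - (ar + tpar * vr)) ** 2 + (cc - (ac + tpar * vc)) ** 2
    return dist2 <= wr**2


def render_sip_field(
    truth: pd.DataFrame,
    field_spec: FieldSpec | None = None,
    seed: int = 0,
    standards: IsotopeStandards | None = None,
    meta: dict | None = None,
) -> tuple[IonImageStack, ROISet]:
    """Render a set of cells as Poisson ion-count images plus a label mask.

    Each cell's expected counts are spread uniformly over its footprint and
    partitioned between light and heavy channels by its true atom fractions:
    for the carbon dimer, 12C2 : 12C13C expectations follow
    (1-p)^2 : 2p(1-p); for cyanide, 12C14N : 12C15N follow (1-q) : q.  Every
    pixel of every channel is an independent Poisson draw.
    """
    spec = field_spec or FieldSpec()
    rng = np.random.default_rng(seed)
    shape = spec.shape
    mask = np.zeros(shape, dtype=np.uint16)
    expect = {ch: np.full(shape, spec.background_per_px) for ch in
              ("C2", "C13C", "CN", "C15N", "S")}
    occupied = np.zeros(shape, dtype=bool)

    for _, row in truth.iterrows():
        cid = int(row["cell_id"])
        placed = False
        if spec.positions and cid in spec.positions:
            pos = spec.positions[cid]
            angle = pos[2] if len(pos) > 2 else rng.uniform(0, math.pi)
            fp = _cell_footprint(row, spec, pos[:2], angle, shape)
            if not fp.any():
                raise ValueError(f"cell {cid} does not fit in the field")
            clash = occupied & fp
            if clash.any():
                hit = sorted(set(mask[clash].tolist()) - {0})
                raise ValueError(f"cell {cid} overlaps cells {hit}")
            placed = True
        else:
            extent = row["true_length_um"] / spec.pixel_size_um / 2 + spec.margin_px
            lo, hi_r, hi_c = extent, shape[0] - extent, shape[1] - extent
            if hi_r <= lo or hi_c <= lo:
                raise ValueError(f"cell {cid} does not fit in the field")
            for _ in range(spec.max_place_tries):
                center = (rng.uniform(lo, hi_r), rng.uniform(lo, hi_c))
                angle = rng.uniform(0, math.pi)
                fp = _cell_footprint(row, spec, center, angle, shape)
                if fp.any() and not (occupied & fp).any():
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place cell {cid} without overlap after "
                    f"{spec.max_place_tries} tries; reduce cells per field"
                )
        area = int(fp.sum())
        occupied |= fp
        mask[fp] = cid
        budget_c = (
            spec.alga_c_counts if row["partner"] == "alga" else spec.bacterium_c_counts
        )
        lam_c = budget_c / area
        lam_n = spec.n_to_c_ratio * budget_c / area
        p, q = float(row["true_p13C"]), float(row["true_p15N"])
        expect["C2"][fp] += lam_c * (1.0 - p) ** 2
        expect["C13C"][fp] += lam_c * 2.0 * p * (1.0 - p)
        expect["CN"][fp] += lam_n * (1.0 - q)
        expect["C15N"][fp] += lam_n * q
        expect["S"][fp] += spec.s_counts_per_px

    channels = {
        ch: rng.poisson(lam).astype(np.uint32) for ch, lam in expect.items()
    }
    stack = IonImageStack(
        channels=channels, pixel_size_um=spec.pixel_size_um, meta=dict(meta or {})
    )
    ann_cols = [
        c
        for c in ("cell_id", "partner", "timepoint_h", "replicate", "condition")
        if c in truth.columns
    ]
    rois = ROISet(mask=mask, annotations=truth[ann_cols].reset_index(drop=True))
    return stack, rois


def render_experiment(
    truth: pd.DataFrame,
    field_spec: FieldSpec | None = None,
    seed: int = 0,
    group_cols: tuple[str, ...] = ("condition", "replicate", "timepoint_h"),
) -> list[tuple[IonImageStack, ROISet]]:
    """Render one field per (condition, replicate, timepoint) group."""
    ss = np.random.SeedSequence(seed)
    groups = list(truth.groupby(list(group_cols), sort=True))
    fields = []
    for (key, sub), child in zip(groups, ss.spawn(len(groups))):
        meta = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        stack, rois = render_sip_field(
            sub,
            field_spec,
            seed=int(child.generate_state(1)[0] % (2**31)),
            meta=meta,
        )
        fields.append((stack, rois))
    return fields


# ---------------------------------------------------------------------------
# assay plate simulators
# ---------------------------------------------------------------------------

DEFAULT_B12_CURVE = {"bottom": 0.05, "top": 0.90, "ec50_ng_per_l": 50.0, "hill": 1.0}


def _b12_response(conc, params):
    """Four-parameter logistic growth response in log10 concentration."""
    conc = np.asarray(conc, dtype=float)
    b, t, ec50, h = (
        params["bottom"], params["top"], params["ec50_ng_per_l"], params["hill"]
    )
    with np.errstate(divide="ignore"):
        frac = np.where(conc > 0, conc**h / (conc**h + ec50**h), 0.0)
    return b + (t - b) * frac


def simulate_bioassay_plate(
    true_b12_ng_per_l,
    curve_params: dict | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    standards_ng_per_l=(1.0, 10.0, 100.0, 1000.0),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a two-strain B12 bioassay plate (standards + samples).

    The B12-responsive dmetE strain grows along a saturating logistic of
    concentration; the dmetE-dmetH control strain (no functional methionine
    synthase isoform) grows to the assay baseline regardless of B12.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    conc = np.asarray(true_b12_ng_per_l, dtype=float)
    if np.any(conc < 0):
        raise ValueError("B12 concentrations must be non-negative")
    params = dict(DEFAULT_B12_CURVE, **(curve_params or {}))
    rng = np.random.default_rng(seed)
    rows = []

    def add_wells(sample_id, c, is_standard):
        for rep in range(1, n_replicates + 1):
            od_e = _b12_response(c, params) + rng.normal(0.0, noise_sd)
            od_ctrl = params["bottom"] + rng.normal(0.0, noise_sd)
            for strain, od in (("dmetE", od_e), ("dmetE_dmetH", od_ctrl)):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "strain": strain,
                        "replicate": rep,
                        "od600": max(float(od), 0.0),
                        "is_standard": is_standard,
                        "nominal_b12_ng_per_l": float(c) if is_standard else np.nan,
                    }
                )

    for c in standards_ng_per_l:
        add_wells(f"std_{c:g}", c, True)
    for i, c in enumerate(conc):
        add_wells(f"sample_{i + 1}", c, False)
    return pd.DataFrame(rows)


def simulate_cytotox_table(
    true_fraction_compromised,
    seed: int = 0,
    blank_fluorescence: float = 50.0,
    killed_fluorescence: float = 1050.0,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a membrane-integrity (cytotoxicity) fluorescence table.

    Sample fluorescence interpolates between a medium blank and a
    heat-killed (100% compromised) control according to the true fraction of
    lysed cells.
    """
    fracs = np.atleast_1d(np.asarray(true_fraction_compromised, dtype=float))
    rng = np.random.default_rng(seed)
    rows = []
    for i, f in enumerate(fracs):
        for rep in range(1, n_replicates + 1):
            signal = blank_fluorescence + f * (
                killed_fluorescence - blank_fluorescence
            ) * rng.lognormal(0.0, noise_cv)
            rows.append(
                {
                    "sample_id": f"sample_{i + 1}",
                    "replicate": rep,
                    "fluorescence_sample": float(signal),
                    "fluorescence_blank": blank_fluorescence,
                    "fluorescence_killed": killed_fluorescence
                    * float(rng.lognormal(0.0, noise_cv / 5)),
                }
            )
    return pd.DataFrame(rows)
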