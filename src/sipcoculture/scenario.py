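"""Coculture scenario configuration.

A :class:`CocultureScenario` bundles everything the simulator needs to
emulate one labeling experiment: the light regime, algal and bacterial
inoculum densities, carbon release rates (exudation and lysis), the isotope
label schedule, and the single-cell enrichment endpoints the run should
reproduce.  Factory methods supply the packaged default conditions for the
continuous-light and diurnal (12 h light / 12 h dark) cocultures, a
sucrose-fed bacterial monoculture, and a carbon-free monoculture control.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

LIGHT_REGIMES = ("continuous", "diurnal_12_12")


@dataclass
class CocultureScenario:
    """Simulation conditions for one coculture (or monoculture) run.

    Densities are per ml; rates are per hour unless noted.  Exudation is in
    µg non-purgeable organic carbon (NPOC) per 1e6 algal cells per hour.
    """

    light_regime: str = "continuous"
    duration_h: float = 72.0
    # --- algal population ---
    algal_inoculum: float = 2e5           # cells/ml
    algal_K: float = 4e6                  # carrying capacity, cells/ml
    algal_doubling_h: float = 8.0         # continuous light; diurnal divides at nightfall
    # --- carbon release ---
    exudation_rate: float = 0.10          # µg NPOC / 1e6 cells / h
    exudate_usable_fraction: float = 0.5  # fraction of exuded NPOC bacteria can use
    lysis_fraction_per_day: float = 0.01  # fraction of algal population lysing per day
    carbon_per_algal_cell_ug: float = 2e-5  # 20 pg C per algal cell
    # --- bacterial population ---
    bacterial_inoculum_cfu: float = 1e6
    bacterial_yield_per_lysed_cell: float = 100.0  # CFU per lysed algal cell
    vmax_ug_per_cfu_h: float = 4e-8  # with the CFU yield this caps growth at ~0.2/h
    Ks_ug_per_ml: float = 0.3
    biomass_retention: float = 0.3        # fraction of assimilated C kept as biomass
    carbon_per_cfu_ug: float = 4e-8       # inoculum-cell carbon, 40 fg
    reductive_division_max: float = 2.0   # extra doublings allowed without biomass gain
    initial_doc_ug_per_ml: float = 0.0    # e.g. sucrose-carbon for monocultures
    # --- label schedule & enrichment truth ---
    label_start_h: float = 13.0           # 13CO2 bubbling begins 13 h post-inoculation
    f15N_substrate: float | None = None   # computed from standards when None
    f13C_source_max: float = 0.35         # asymptotic algal 13C atom fraction
    algal_label_tau_h: float = 12.0
    cnet_48h: float = 0.17                # bacterial carbon-new fraction at 48 h
    cnet_tau_h: float = 20.0
    nnet_max: float = 0.34                # asymptotic bacterial nitrogen-new fraction
    nnet_tau_h: float = 30.0
    b12_onset_h: float = 24.0
    # --- cell size truth ---
    cell_length_start_um: float = 2.3
    cell_length_min_um: float = 1.4
    cell_length_tau_h: float = 8.0
    cell_length_sd_um: float = 0.15
    alga_diameter_um: tuple[float, float] = (5.0, 7.0)
    # --- sampling design & noise ---
    sampling_timepoints_h: tuple[float, ...] = (14.0, 24.0, 36.0, 48.0)
    n_replicates: int = 2                 # duplicate cocultures
    n_algae_per_sample: int = 3           # measurable algal cells per field
    n_bacteria_per_sample: int = 8        # measurable bacterial cells per field
    enrichment_jitter: float = 0.15       # lognormal sd of per-cell enrichment spread
    obs_noise_cv: float = 0.05            # multiplicative noise on density observations
    obs_every_h: float = 2.0
    dt_h: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.light_regime not in LIGHT_REGIMES:
            raise ValueError(f"light_regime must be one of {LIGHT_REGIMES}")
        for name in (
            "duration_h", "algal_K", "algal_doubling_h", "dt_h", "obs_every_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        rates = (
            "algal_inoculum", "exudation_rate", "bacterial_inoculum_cfu",
            "bacterial_yield_per_lysed_cell", "vmax_ug_per_cfu_h",
            "Ks_ug_per_ml", "carbon_per_algal_cell_ug", "initial_doc_ug_per_ml",
            "reductive_division_max",
        )
        for name in rates:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.lysis_fraction_per_day <= 1.0:
            raise ValueError("lysis_fraction_per_day must lie in [0, 1]")
        if not 0.0 <= self.exudate_usable_fraction <= 1.0:
            raise ValueError("exudate_usable_fraction must lie in [0, 1]")
        if self.duration_h <= self.label_start_h:
            raise ValueError("duration_h must exceed label_start_h")
        for name in ("f13C_source_max", "cnet_48h", "nnet_max"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be an atom fraction in [0, 1]")

    # ------------------------------------------------------------------
    # packaged study conditions
    # ------------------------------------------------------------------
    @classmethod
    def continuous_default(cls, seed: int = 0) -> "CocultureScenario":
        """Continuous-light coculture; plateaus near 4e6 algal cells/ml."""
        return cls(light_regime="continuous", seed=seed)

    @classmethod
    def diurnal_default(cls, seed: int = 0) -> "CocultureScenario":
        """12 h/12 h diurnal coculture: synchronized division at nightfall.

        Diurnally grown algae exude less organic carbon per cell, and the
        slower (once-daily) division means less cumulative algal biomass;
        together these roughly third the bacterial carrying capacity.
        """
        return cls(
            light_regime="diurnal_12_12",
            algal_inoculum=5e5,
            exudation_rate=0.028,
            cnet_48h=0.09,
            seed=seed,
        )

    @classmethod
    def wildtype_coculture(cls, seed: int = 0) -> "CocultureScenario":
        """Wild-type-strain coculture used for the lysis-budget closure.

        The wild-type alga reaches a higher plateau but its exudates are
        not metabolized by the bacterium (usable fraction 0), so bacterial
        proliferation is fed by lysed-cell carbon alone and the necromass
        budget closes exactly against the simulated lysis fraction.
        """
        return cls(
            light_regime="continuous",
            algal_K=6.1e6,
            exudation_rate=0.05,
            exudate_usable_fraction=0.0,
            cnet_48h=0.17,
            seed=seed,
        )

    @classmethod
    def sucrose_monoculture(cls, seed: int = 0) -> "CocultureScenario":
        """Bacterial monoculture on 150 µg/ml sucrose (~60 µg C/ml)."""
        return cls(
            algal_inoculum=0.0,
            exudation_rate=0.0,
            lysis_fraction_per_day=0.0,
            initial_doc_ug_per_ml=60.0,
            cnet_48h=0.0,
            seed=seed,
        )

    @classmethod
    def no_carbon_monoculture(cls, seed: int = 0) -> "CocultureScenario":
        """Bacterial monoculture with no reduced carbon source at all."""
        return cls(
            algal_inoculum=0.0,
            exudation_rate=0.0,
            lysis_fraction_per_day=0.0,
            cnet_48h=0.0,
            seed=seed,
        )

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alga_diameter_um"] = list(self.alga_diameter_um)
        d["sampling_timepoints_h"] = list(self.sampling_timepoints_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CocultureScenario":
        d = dict(d)
        if "alga_diameter_um" in d:
            d["alga_diameter_um"] = tuple(d["alga_diameter_um"])
        if "sampling_timepoints_h" in d:
            d["sampling_timepoints_h"] = tuple(d["sampling_timepoints_h"])
        return cls(**d)

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "CocultureScenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "CocultureScenario":
        return dataclasses.replace(self, **kw)
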