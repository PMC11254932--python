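"""Synthetic incubation datasets and ASV count tables with known truth.

The incubation generator inverts the rate equations of
:mod:`phyllon.tracer`: it fixes true per-area rates per process, site and
light condition, then emits vial-level measurements (tissue atom% 15N,
dissolved delta-15N-NO3, 29/30N2 concentrations, nutrient concentrations)
that, run back through :func:`phyllon.tracer.estimate_rates` with zero
measurement noise, return the true rates exactly. The emitted design
mirrors the study layout: two sites (ambient and CO2-vent pH), light and
dark incubations, 4 replicates with epiphytes and 3 without, T0/T1/T2(/T3)
destructive sampling, no-leaf control vials, and natural-abundance tissue
controls.

Measurement noise is multiplicative Gaussian (relative SD per measured
quantity, truncated at zero), which is the simplest model consistent with
the replicate scatter such incubations show; see docs/methods.md for what
this does and does not emulate.

Count tables come from a log-normal composition + multinomial depth model;
a zero effect size yields exchangeable groups for null calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .community import AsvTable, RANKS
from .constants import DEFAULT_CONSTANTS, IsotopeConstants
from .tracer import atom_percent_to_delta

SITES = ("ambient", "vent")
LIGHTS = ("light", "dark")

#: default true rates: {process: {(site, light): value}}; study-magnitude means.
DEFAULT_TRUE_RATES = {
    # nmol N cm-2 h-1 (tissue incorporation); dark fixation absent by default
    "n2_fixation": {("ambient", "light"): 0.12, ("vent", "light"): 0.62,
                    ("ambient", "dark"): 0.0, ("vent", "dark"): 0.0},
    # pmol N cm-2 h-1; detected only at the vent site
    "nitrification": {("ambient", "light"): 0.0, ("ambient", "dark"): 0.0,
                      ("vent", "light"): 0.058, ("vent", "dark"): 0.031},
    # pmol N cm-2 h-1; no light/dark effect on 29N2
    "n2_production_29": {("ambient", "light"): 2.43, ("ambient", "dark"): 2.43,
                         ("vent", "light"): 7.14, ("vent", "dark"): 7.14},
    # pmol N cm-2 h-1; 30N2 only at the vent in the light
    "n2_production_30": {("ambient", "light"): 0.0, ("ambient", "dark"): 0.0,
                         ("vent", "light"): 18.84, ("vent", "dark"): 0.0},
    # nmol cm-2 h-1, uptake positive
    "nh4_uptake": {("ambient", "light"): 3.0, ("ambient", "dark"): 1.5,
                   ("vent", "light"): 5.5, ("vent", "dark"): 2.5},
    # NO3/PO4 pools in the vials are small (1.94 / 0.3 uM), so feasible
    # uptake rates are bounded by pool exhaustion; vent/ambient ratios keep
    # the observed ~4x (NO3) and ~1.8x (NH4) enhancement under OA
    "no3_uptake": {("ambient", "light"): 0.15, ("ambient", "dark"): 0.08,
                   ("vent", "light"): 0.6, ("vent", "dark"): 0.3},
    "po4_uptake": {("ambient", "light"): 0.05, ("ambient", "dark"): 0.02,
                   ("vent", "light"): 0.1, ("vent", "dark"): 0.04},
}


@dataclass
class IncubationScenario:
    """Ground truth and design for one synthetic incubation campaign.

    Defaults reproduce the study conditions: ~16 atom% 15N2 medium,
    ~95.9 atom% 15NH4+ medium, natural-abundance tissue baseline at the air
    value, n=4 vials with epiphytes / n=3 without, 24 mL vials, T0/T1/T2/T3
    sampling, and 5% relative measurement noise.
    """

    true_rates: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_RATES.items()})
    medium_atom_pct: dict = field(default_factory=lambda: {"15N2": 16.0, "15NH4": 95.9, "15NO3": 95.9})
    baseline_atom_pct: float = DEFAULT_CONSTANTS.atom_pct_air
    baseline_sd_atom_pct: float = 0.0002      # IRMS tissue replicate scatter, atom%
    delta_no3_baseline_permil: float = 5.0    # natural delta15N of ambient NO3
    n_with_epiphytes: int = 4
    n_without_epiphytes: int = 3
    n_baseline: int = 3                       # natural-abundance tissue controls
    n_controls: int = 3                       # no-leaf vials
    fixation_timepoints_h: tuple = (0.0, 5.0, 9.0)
    water_timepoints_h: tuple = (0.0, 2.0, 5.0, 9.0)
    vial_volume_mL: float = 24.0
    leaf_area_cm2: float = 6.0
    pn_tissue_ug: float = 120.0               # tissue N per incubated section
    c_pct: float = 33.0
    n_pct: float = 2.2
    ambient_nh4_uM: float = 0.65
    ambient_no3_uM: float = 1.94
    no2_uM: float = 0.2
    pnr_no3_uM: float = 1.94                  # NO3 pool in the 15NH4 experiment
    n2prod_no3_uM: float = 10.0               # after 15NO3 spike
    nh4_spike_uM: float = 20.0                # after 15NH4 spike
    po4_uM: float = 0.3
    background_29n2_nM: float = 1.0
    background_30n2_nM: float = 0.5
    control_pool_rate_nmol_h: float = 0.0     # water-column background activity
    noise_rel_sd: float = 0.05
    dark_fixation_one_hot: bool = False       # one dark replicate fixes (dedicated scenario)
    dark_fixation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for proc, cells in self.true_rates.items():
            for key, v in cells.items():
                if v < 0:
                    raise ValueError(f"true rate {proc}{key} must be >= 0")
        if self.noise_rel_sd < 0:
            raise ValueError("noise_rel_sd must be >= 0")
        if min(self.n_with_epiphytes, self.n_without_epiphytes, self.n_baseline) < 1:
            raise ValueError("replicate counts must be >= 1")


def _noisy(rng: np.random.Generator, value: float, rel_sd: float) -> float:
    if rel_sd == 0:
        return float(value)
    return float(max(0.0, value * (1.0 + rel_sd * rng.standard_normal())))


def _base_row(experiment, site, light, epi, tracer, role, t, rep, volume):
    return {
        "experiment": experiment, "site": site, "light": light, "epiphytes": epi,
        "tracer": tracer, "role": role, "timepoint_h": t, "replicate_id": rep,
        "vial_volume_mL": volume,
    }


def gen_incubation(scenario: IncubationScenario,
                   constants: IsotopeConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Emit the records table for all four experiments of a scenario.

    Deterministic for a fixed scenario seed. With ``noise_rel_sd == 0`` the
    analysis pipeline recovers ``scenario.true_rates`` exactly.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    rows: list[dict] = []
    rows += _gen_fixation(s, rng, constants)
    rows += _gen_pnr(s, rng, constants)
    rows += _gen_n2_production(s, rng)
    rows += _gen_nutrient_flux(s, rng)
    return pd.DataFrame(rows)


def _gen_fixation(s, rng, constants):
    rows = []
    pn_nmol = s.pn_tissue_ug / constants.molar_mass_n * 1000.0
    t_end = s.fixation_timepoints_h[-1]
    for i in range(s.n_baseline):
        row = _base_row("n2_fixation", "ambient", "light", "present", "15N2",
                        "baseline", 0.0, f"na{i + 1}", s.vial_volume_mL)
        atom = s.baseline_atom_pct + s.baseline_sd_atom_pct * rng.standard_normal() \
            if s.noise_rel_sd > 0 else s.baseline_atom_pct
        row.update(atom_pct_15n_tissue=atom, pn_tissue_ug=s.pn_tissue_ug,
                   c_pct=s.c_pct, n_pct=s.n_pct, leaf_area_cm2=s.leaf_area_cm2)
        rows.append(row)
    for site in SITES:
        for light in LIGHTS:
            for epi, n_rep in (("present", s.n_with_epiphytes),
                               ("removed", s.n_without_epiphytes)):
                rate = s.true_rates["n2_fixation"][(site, light)]
                for i in range(n_rep):
                    r = rate
                    if (light == "dark" and epi == "present"
                            and s.dark_fixation_one_hot):
                        r = s.dark_fixation_rate if i == 0 else 0.0
                    excess = (r * s.leaf_area_cm2 * t_end / pn_nmol
                              * s.medium_atom_pct["15N2"])
                    atom = s.baseline_atom_pct + excess
                    row = _base_row("n2_fixation", site, light, epi, "15N2",
                                    "sample", t_end, f"r{i + 1}", s.vial_volume_mL)
                    if s.noise_rel_sd > 0:
                        # labeled vials scatter with the measurement; unlabeled
                        # vials scatter like the natural-abundance baseline
                        atom = (_noisy(rng, atom, s.noise_rel_sd) if excess > 0
                                else atom + s.baseline_sd_atom_pct * rng.standard_normal())
                    row.update(
                        atom_pct_15n_tissue=atom,
                        pn_tissue_ug=_noisy(rng, s.pn_tissue_ug, s.noise_rel_sd),
                        c_pct=_noisy(rng, s.c_pct, s.noise_rel_sd),
                        n_pct=_noisy(rng, s.n_pct, s.noise_rel_sd),
                        leaf_area_cm2=s.leaf_area_cm2)
                    rows.append(row)
    return rows


def _gen_pnr(s, rng, constants):
    rows = []
    medium = s.medium_atom_pct["15NH4"]
    pool_nmol = s.pnr_no3_uM * s.vial_volume_mL
    base_atom = _delta_atom(s.delta_no3_baseline_permil, constants)
    t_end = s.water_timepoints_h[-1]
    for site in SITES:
        for light in LIGHTS:
            for epi, n_rep in (("present", s.n_with_epiphytes),
                               ("removed", s.n_without_epiphytes)):
                rate_pmol = s.true_rates["nitrification"][(site, light)]
                pool_rate_nmol_h = rate_pmol / 1000.0 * s.leaf_area_cm2 + s.control_pool_rate_nmol_h
                for t in s.water_timepoints_h:
                    for i in range(n_rep):
                        excess = medium * t * pool_rate_nmol_h / pool_nmol
                        atom = base_atom + excess
                        if s.noise_rel_sd > 0 and t > 0 and excess > 0:
                            atom = base_atom + _noisy(rng, excess, s.noise_rel_sd)
                        row = _base_row("nitrification", site, light, epi, "15NH4",
                                        "sample", t, f"r{i + 1}", s.vial_volume_mL)
                        row.update(delta15n_no3_permil=atom_percent_to_delta(atom, constants),
                                   nox_uM=s.pnr_no3_uM + s.no2_uM, no2_uM=s.no2_uM,
                                   nh4_uM=s.nh4_spike_uM, leaf_area_cm2=s.leaf_area_cm2)
                        rows.append(row)
        # no-leaf controls per site carry only the water-column background
        for t in s.water_timepoints_h:
            for i in range(s.n_controls):
                excess = medium * t * s.control_pool_rate_nmol_h / pool_nmol
                atom = base_atom + excess
                row = _base_row("nitrification", site, "light", "none", "15NH4",
                                "control", t, f"c{i + 1}", s.vial_volume_mL)
                row.update(delta15n_no3_permil=atom_percent_to_delta(atom, constants),
                           nox_uM=s.pnr_no3_uM + s.no2_uM, no2_uM=s.no2_uM,
                           nh4_uM=s.nh4_spike_uM)
                rows.append(row)
    return rows


def _delta_atom(delta, constants):
    from .tracer import delta_to_atom_percent
    return delta_to_atom_percent(delta, constants)


def _gen_n2_production(s, rng):
    rows = []
    vol_L = s.vial_volume_mL / 1000.0
    t1, t2 = s.water_timepoints_h[1], s.water_timepoints_h[2]
    for site in SITES:
        for light in LIGHTS:
            for epi, n_rep in (("present", s.n_with_epiphytes),
                               ("removed", s.n_without_epiphytes)):
                slopes = {}
                for species, col, bg in (("n2_production_29", "conc_29n2_nM", s.background_29n2_nM),
                                         ("n2_production_30", "conc_30n2_nM", s.background_30n2_nM)):
                    r = s.true_rates[species][(site, light)]
                    slopes[col] = (bg, r * s.leaf_area_cm2 / (2.0 * 1000.0 * vol_L))
                for i in range(n_rep):
                    for t in (t1, t2):
                        row = _base_row("n2_production", site, light, epi, "15NO3",
                                        "sample", t, f"r{i + 1}", s.vial_volume_mL)
                        for col, (bg, slope) in slopes.items():
                            c = bg + slope * t
                            row[col] = _noisy(rng, c, s.noise_rel_sd)
                        row.update(leaf_area_cm2=s.leaf_area_cm2,
                                   nox_uM=s.n2prod_no3_uM + s.no2_uM, no2_uM=s.no2_uM)
                        rows.append(row)
    for i in range(s.n_controls):
        for t in (t1, t2):
            row = _base_row("n2_production", "ambient", "light", "none", "15NO3",
                            "control", t, f"c{i + 1}", s.vial_volume_mL)
            row.update(conc_29n2_nM=s.background_29n2_nM, conc_30n2_nM=s.background_30n2_nM,
                       nox_uM=s.n2prod_no3_uM + s.no2_uM, no2_uM=s.no2_uM)
            rows.append(row)
    return rows


def _gen_nutrient_flux(s, rng):
    rows = []
    vol_L = s.vial_volume_mL / 1000.0
    t_end = s.water_timepoints_h[-1]
    init = {"nh4_uM": s.ambient_nh4_uM + s.nh4_spike_uM, "po4_uM": s.po4_uM}
    init_no3 = s.ambient_no3_uM
    for site in SITES:
        for light in LIGHTS:
            for epi, n_rep in (("present", s.n_with_epiphytes),
                               ("removed", s.n_without_epiphytes)):
                for i in range(n_rep):
                    for t in (0.0, t_end):
                        row = _base_row("nutrient_flux", site, light, epi, "15N2",
                                        "sample", t, f"r{i + 1}", s.vial_volume_mL)
                        conc = {}
                        for proc, col, c0 in (("nh4_uptake", "nh4_uM", init["nh4_uM"]),
                                              ("no3_uptake", None, init_no3),
                                              ("po4_uptake", "po4_uM", init["po4_uM"])):
                            u = s.true_rates[proc][(site, light)]
                            c = c0 - u * s.leaf_area_cm2 * t / (1000.0 * vol_L)
                            c = _noisy(rng, c, s.noise_rel_sd) if t > 0 else c
                            if col is None:
                                conc["nox_uM"] = c + s.no2_uM
                                conc["no2_uM"] = s.no2_uM
                            else:
                                conc[col] = c
                        row.update(leaf_area_cm2=s.leaf_area_cm2, **conc)
                        rows.append(row)
    for i in range(s.n_controls):
        for t in (0.0, t_end):
            row = _base_row("nutrient_flux", "ambient", "light", "none", "15N2",
                            "control", t, f"c{i + 1}", s.vial_volume_mL)
            row.update(nh4_uM=init["nh4_uM"], po4_uM=init["po4_uM"],
                       nox_uM=init_no3 + s.no2_uM, no2_uM=s.no2_uM)
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

_PHYLA = ["Proteobacteria", "Bacteroidota", "Cyanobacteria", "Planctomycetota",
          "Desulfobacterota", "Actinobacteriota", "Verrucomicrobiota", "Firmicutes"]
_GENERA = ["Granulosicoccus", "Epibacterium", "Pseudovibrio", "Marinicella",
           "Schizothrix", "Trichodesmium", "Blastopirellula", "Lewinella"]


@dataclass
class CountScenario:
    """Design for a synthetic ASV count table with a known group effect.

    ``effect_size`` shifts the log-abundance of the first
    ``n_affected_asvs`` ASVs in the second group; 0 gives exchangeable
    groups (a true null).
    """

    n_samples_per_group: tuple = (4, 3)
    group_names: tuple = ("leaf", "water")
    n_asvs: int = 120
    effect_size: float = 0.0
    n_affected_asvs: int = 20
    base_log_sd: float = 1.5       # spread of mean log-abundances across ASVs
    dispersion: float = 0.6        # per-sample log-normal noise SD
    mean_depth: int = 20000
    depth_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def gen_counts(scenario: CountScenario) -> AsvTable:
    """Log-normal composition + multinomial depth count table with taxonomy."""
    s = scenario
    rng = np.random.default_rng(s.seed)
    base = rng.normal(0.0, s.base_log_sd, size=s.n_asvs)
    sample_rows, meta_rows, index = [], [], []
    for g, (gname, n_g) in enumerate(zip(s.group_names, s.n_samples_per_group)):
        shift = np.zeros(s.n_asvs)
        if g == 1 and s.effect_size != 0.0:
            shift[: s.n_affected_asvs] = s.effect_size
        for i in range(n_g):
            logit = base + shift + rng.normal(0.0, s.dispersion, size=s.n_asvs)
            p = np.exp(logit - logit.max())
            p /= p.sum()
            depth = int(round(s.mean_depth * np.exp(rng.normal(0.0, s.depth_log_sd))))
            sample_rows.append(rng.multinomial(depth, p))
            meta_rows.append({"group": gname, "site": gname, "compartment": gname})
            index.append(f"{gname}_{i + 1}")
    asv_ids = [f"ASV{j + 1:04d}" for j in range(s.n_asvs)]
    counts = pd.DataFrame(sample_rows, index=index, columns=asv_ids)
    tax = pd.DataFrame({
        "domain": "Bacteria",
        "phylum": [_PHYLA[j % len(_PHYLA)] for j in range(s.n_asvs)],
        "genus": [_GENERA[j % len(_GENERA)] if j % 3 else "" for j in range(s.n_asvs)],
    }, index=pd.Index(asv_ids, name="asv"))
    meta = pd.DataFrame(meta_rows, index=index)
    return AsvTable(counts=counts, taxonomy=tax, sample_meta=meta)
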