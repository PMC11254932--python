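"""15N tracer conversions and per-incubation rate equations.

This module implements the rate calculations for the four leaf-incubation
experiments:

* **N2 fixation** — incorporation of 15N2 into tissue, following the
  classic dilution form ``rate = (atom%excess / atom%medium) * (PN / t)``,
  normalized to leaf area (nmol N cm-2 h-1).
* **Potential nitrification (PNR)** — appearance of 15N in the NO3- pool of
  15NH4+-amended incubations, same dilution form applied to the dissolved
  pool (pmol N cm-2 h-1), corrected for no-leaf controls.
* **N2 production (denitrification + anammox)** — linear increase of 29N2
  and 30N2 between two timepoints after a lag phase, corrected for no-leaf
  controls (pmol N cm-2 h-1).
* **Net nutrient fluxes** — start-minus-end concentration changes corrected
  for controls and normalized to leaf area (nmol cm-2 h-1), uptake positive.

Enrichment above the baseline counts as real tracer uptake only when the
excess exceeds ``k`` times the standard deviation of the baseline vials
(k = 2.5 by default); non-significant rates carry ``significant=False`` and
are zeroed by the budget stage, never here.

Scalar operations accept floats or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, IsotopeConstants
from .errors import (
    EmptyPoolError,
    IncompleteRecordError,
    InvalidDeltaError,
    InvalidWindowError,
    NegativeNitrateError,
    UndefinedRatioError,
    ZeroDurationError,
)

DEFAULT_GATE_K = 2.5
#: Theoretical medium enrichments achieved by the tracer additions, atom% 15N.
DEFAULT_MEDIUM_ATOM_PCT = {"15N2": 16.0, "15NH4": 95.9, "15NO3": 95.9}
USGS32_DELTA = 180.0  # permil, nitrate isotope reference standard


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineStats:
    """Summary of baseline vials: natural-abundance tissue or T0 water pools.

    ``kind`` records which baseline this is: ``"natural_abundance"`` for
    unenriched tissue controls, ``"t0"`` for start-of-incubation water pools.
    """

    mean_atom_pct: float
    sd_atom_pct: float
    n: int
    kind: str = "natural_abundance"

    def __post_init__(self) -> None:
        if self.sd_atom_pct < 0:
            raise ValueError("baseline SD must be non-negative")
        if self.n < 2:
            raise ValueError("baseline needs at least 2 vials")
        if self.kind not in ("natural_abundance", "t0"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")

    @classmethod
    def from_samples(cls, values: Iterable[float], kind: str = "natural_abundance") -> "BaselineStats":
        arr = np.asarray(list(values), dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise ValueError("need at least 2 baseline measurements")
        return cls(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size), kind)


@dataclass
class RateEstimate:
    """One computed rate with its provenance.

    ``significant`` reflects the 2.5 x SD enrichment gate; the raw value is
    always retained here, downstream budget code substitutes 0 for
    non-significant rates.
    """

    value: float
    units: str
    significant: bool
    excess_atom_pct: float = float("nan")
    medium_atom_pct: float = float("nan")
    control_corrected: bool = False
    baseline_mean: float = float("nan")
    baseline_sd: float = float("nan")
    baseline_n: int = 0
    raw_signed_flux: float = float("nan")

    @property
    def gated_value(self) -> float:
        """The value the budget stage consumes: 0 unless significant."""
        return self.value if self.significant else 0.0


@dataclass
class IncubationRecord:
    """One vial x timepoint observation from a leaf incubation.

    Mirrors one row of the records CSV (see :mod:`phyllon.schemas`);
    measurement fields are optional because each experiment fills a
    different subset.
    """

    site: str
    light: str
    epiphytes: str
    tracer: str
    timepoint_h: float
    replicate_id: str
    is_control: bool = False
    atom_pct_15n_tissue: Optional[float] = None
    pn_tissue_ug: Optional[float] = None
    c_pct: Optional[float] = None
    n_pct: Optional[float] = None
    leaf_area_cm2: Optional[float] = None
    conc_29n2_nM: Optional[float] = None
    conc_30n2_nM: Optional[float] = None
    delta15n_no3_permil: Optional[float] = None
    nh4_uM: Optional[float] = None
    no2_uM: Optional[float] = None
    nox_uM: Optional[float] = None
    po4_uM: Optional[float] = None
    vial_volume_mL: float = 24.0

    def __post_init__(self) -> None:
        if self.timepoint_h < 0:
            raise ValueError("timepoint_h must be >= 0")
        if self.vial_volume_mL <= 0:
            raise ValueError("vial_volume_mL must be > 0")
        for name in ("conc_29n2_nM", "conc_30n2_nM", "nh4_uM", "no2_uM", "nox_uM", "po4_uM"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.nox_uM is not None and self.no2_uM is not None and self.nox_uM < self.no2_uM:
            raise NegativeNitrateError(
                f"NOx ({self.nox_uM}) below NO2 ({self.no2_uM}): impossible speciation"
            )


# ---------------------------------------------------------------------------
# isotope conversions
# ---------------------------------------------------------------------------

def delta_to_atom_percent(delta_permil, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Convert delta-15N (permil vs air) to atom% 15N.

    ``R = r_air * (delta/1000 + 1)``; ``atom% = 100 * R / (1 + R)``.
    Strictly increasing in delta; delta = -1000 maps to 0 atom%.
    """
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta < -1000.0):
        raise InvalidDeltaError("delta below -1000 permil implies negative 15N content")
    r = constants.r_air_15n * (delta / 1000.0 + 1.0)
    out = 100.0 * r / (1.0 + r)
    return out if out.ndim else float(out)


def atom_percent_to_delta(atom_pct, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Inverse of :func:`delta_to_atom_percent` (atom% in [0, 100))."""
    a = np.asarray(atom_pct, dtype=float)
    if np.any((a < 0) | (a >= 100)):
        raise ValueError("atom% must lie in [0, 100)")
    r = a / (100.0 - a)
    out = (r / constants.r_air_15n - 1.0) * 1000.0
    return out if out.ndim else float(out)


def atom_percent_excess(sample_atom_pct, baseline: BaselineStats):
    """Tracer signal: sample atom% minus baseline mean; may be negative."""
    out = np.asarray(sample_atom_pct, dtype=float) - baseline.mean_atom_pct
    return out if out.ndim else float(out)


def significance_gate(excess, baseline: BaselineStats, k: float = DEFAULT_GATE_K):
    """True when the excess exceeds k standard deviations of the baseline.

    A zero baseline SD degenerates to "any positive excess passes", an
    explicit choice for noise-free baselines.
    """
    if k <= 0:
        raise ValueError("gate multiplier k must be > 0")
    out = np.asarray(excess, dtype=float) > k * baseline.sd_atom_pct
    return out if out.ndim else bool(out)


def medium_enrichment(ambient_conc_uM: float, ambient_atom_pct: float,
                      spike_conc_uM: float, spike_atom_pct: float) -> float:
    """Concentration-weighted atom% of an ambient pool mixed with a tracer spike."""
    total = ambient_conc_uM + spike_conc_uM
    if total <= 0:
        raise EmptyPoolError("cannot mix two empty pools")
    return (ambient_conc_uM * ambient_atom_pct + spike_conc_uM * spike_atom_pct) / total


def no3_from_nox(nox_uM: float, no2_uM: float) -> float:
    """Nitrate by difference: NO3- = NOx- - NO2-. Never clips a negative result."""
    if nox_uM < 0 or no2_uM < 0:
        raise ValueError("concentrations must be >= 0")
    if nox_uM < no2_uM:
        raise NegativeNitrateError(f"NOx ({nox_uM}) < NO2 ({no2_uM})")
    return nox_uM - no2_uM


def cn_ratio(c_pct: float, n_pct: float) -> float:
    """Molar C:N from mass percentages: (%C/12)/(%N/14)."""
    if n_pct <= 0:
        raise UndefinedRatioError("n_pct must be > 0 for a C:N ratio")
    return (c_pct / 12.0) / (n_pct / 14.0)


def delta15n_mass_balance(delta_mix_permil: float, conc_sample: float,
                          conc_std: float, delta_std_permil: float = USGS32_DELTA) -> float:
    """Recover the sample delta-15N from a sample+standard mixture measurement.

    The nitrate isotope method measures a mixture of the sample with a
    spike of a reference standard (USGS32, +180 permil); the sample value is
    obtained from the isotope mass balance over the relative NO3- amounts:

    ``delta_sample = (delta_mix*(cs+cstd) - delta_std*cstd) / cs``

    Inverting :func:`mix_delta` is the identity for any positive split.
    """
    if conc_sample <= 0:
        raise ValueError("conc_sample must be > 0")
    if conc_std < 0:
        raise ValueError("conc_std must be >= 0")
    total = conc_sample + conc_std
    return (delta_mix_permil * total - delta_std_permil * conc_std) / conc_sample


def mix_delta(delta_sample_permil: float, conc_sample: float,
              conc_std: float, delta_std_permil: float = USGS32_DELTA) -> float:
    """Forward mixing model: amount-weighted delta of sample + standard."""
    total = conc_sample + conc_std
    if total <= 0:
        raise EmptyPoolError("cannot mix two empty pools")
    return (delta_sample_permil * conc_sample + delta_std_permil * conc_std) / total


# ---------------------------------------------------------------------------
# rate equations
# ---------------------------------------------------------------------------

def n2_fixation_rate(record: IncubationRecord, baseline: BaselineStats,
                     medium_atom_pct: float, k: float = DEFAULT_GATE_K,
                     constants: IsotopeConstants = DEFAULT_CONSTANTS) -> RateEstimate:
    """N2 fixation from 15N2 incorporation into tissue, nmol N cm-2 h-1.

    ``rate = (excess / medium) * (PN / t) / area`` with PN converted from
    ug N to nmol N.
    """
    if record.tracer != "15N2":
        raise IncompleteRecordError(f"expected a 15N2 record, got tracer {record.tracer!r}")
    missing = [f for f in ("atom_pct_15n_tissue", "pn_tissue_ug", "leaf_area_cm2")
               if getattr(record, f) is None]
    if missing:
        raise IncompleteRecordError(f"missing tissue fields: {', '.join(missing)}")
    if record.timepoint_h <= 0:
        raise ZeroDurationError("N2 fixation needs timepoint_h > 0")
    if not 0 < medium_atom_pct <= 100:
        raise ValueError("medium_atom_pct must be in (0, 100]")

    excess = atom_percent_excess(record.atom_pct_15n_tissue, baseline)
    pn_nmol = record.pn_tissue_ug / constants.molar_mass_n * 1000.0
    rate = (excess / medium_atom_pct) * (pn_nmol / record.timepoint_h) / record.leaf_area_cm2
    return RateEstimate(
        value=float(rate),
        units="nmol N cm-2 h-1",
        significant=significance_gate(excess, baseline, k),
        excess_atom_pct=float(excess),
        medium_atom_pct=medium_atom_pct,
        baseline_mean=baseline.mean_atom_pct,
        baseline_sd=baseline.sd_atom_pct,
        baseline_n=baseline.n,
    )


def _pool_transfer_nmol_h(excess_atom_pct: float, medium_atom_pct: float,
                          pool_nmol: float, t_h: float) -> float:
    """Tracer dilution rate at the vial level: nmol N moved into the pool per hour."""
    return (excess_atom_pct / medium_atom_pct) * (pool_nmol / t_h)


def pnr(record: IncubationRecord, baseline_t0: BaselineStats, medium_atom_pct: float,
        no3_uM: Optional[float] = None, control_rate_nmol_h: float = 0.0,
        control_excess_atom_pct: float = 0.0, k: float = DEFAULT_GATE_K,
        constants: IsotopeConstants = DEFAULT_CONSTANTS) -> RateEstimate:
    """Potential nitrification rate from 15N appearance in the NO3- pool.

    The NO3- pool is ``[NO3-] * vial volume`` so that the per-vial transfer
    rate can be normalized to the leaf area of the incubated section.
    Control incubations without leaves measure water-column background;
    their vial-level rate is subtracted before area normalization, and the
    significance gate is applied to the control-corrected excess.
    Result in pmol N cm-2 h-1.
    """
    if record.tracer != "15NH4":
        raise IncompleteRecordError(f"expected a 15NH4 record, got tracer {record.tracer!r}")
    if record.delta15n_no3_permil is None:
        raise IncompleteRecordError("missing delta15n_no3_permil")
    if record.timepoint_h <= 0:
        raise ZeroDurationError("PNR needs timepoint_h > 0")
    if no3_uM is None:
        if record.nox_uM is None or record.no2_uM is None:
            raise IncompleteRecordError("need no3_uM or (nox_uM, no2_uM)")
        no3_uM = no3_from_nox(record.nox_uM, record.no2_uM)
    if record.leaf_area_cm2 is None:
        raise IncompleteRecordError("missing leaf_area_cm2")

    atom_t = delta_to_atom_percent(record.delta15n_no3_permil, constants)
    excess = atom_percent_excess(atom_t, baseline_t0)
    pool_nmol = no3_uM * record.vial_volume_mL  # uM * mL = nmol
    sample_rate = _pool_transfer_nmol_h(excess, medium_atom_pct, pool_nmol, record.timepoint_h)
    corrected = sample_rate - control_rate_nmol_h
    corrected_excess = excess - control_excess_atom_pct
    rate_pmol = corrected / record.leaf_area_cm2 * 1000.0
    return RateEstimate(
        value=float(rate_pmol),
        units="pmol N cm-2 h-1",
        significant=significance_gate(corrected_excess, baseline_t0, k),
        excess_atom_pct=float(excess),
        medium_atom_pct=medium_atom_pct,
        control_corrected=control_rate_nmol_h != 0.0 or control_excess_atom_pct != 0.0,
        baseline_mean=baseline_t0.mean_atom_pct,
        baseline_sd=baseline_t0.sd_atom_pct,
        baseline_n=baseline_t0.n,
    )


def n2_production_rate(c_t1_nM: float, c_t2_nM: float, t1_h: float, t2_h: float,
                       vial_volume_mL: float, leaf_area_cm2: float,
                       control_slope_nmol_h: float = 0.0,
                       n2_as_molecules: bool = False) -> RateEstimate:
    """Labeled N2 production from the T1 -> T2 concentration increase.

    Applied separately to 29N2 and 30N2. The early window is skipped because
    of a lag phase. By default the molecular rate is doubled to N atoms to
    report pmol **N** cm-2 h-1; ``n2_as_molecules=True`` keeps pmol N2.
    """
    if t2_h <= t1_h:
        raise InvalidWindowError(f"need t2 > t1, got {t1_h} -> {t2_h}")
    if vial_volume_mL <= 0 or leaf_area_cm2 <= 0:
        raise ValueError("vial volume and leaf area must be > 0")
    vol_L = vial_volume_mL / 1000.0
    slope_nmol_h = (c_t2_nM - c_t1_nM) * vol_L / (t2_h - t1_h)  # nM * L = nmol N2
    corrected = slope_nmol_h - control_slope_nmol_h
    atoms = 1.0 if n2_as_molecules else 2.0
    rate_pmol = corrected * atoms / leaf_area_cm2 * 1000.0
    return RateEstimate(
        value=float(rate_pmol),
        units="pmol N2 cm-2 h-1" if n2_as_molecules else "pmol N cm-2 h-1",
        significant=bool(corrected > 0),
        control_corrected=control_slope_nmol_h != 0.0,
    )


def nutrient_flux(initial_uM: float, final_uM: float, control_delta_uM: float,
                  t_h: float, vial_volume_mL: float, leaf_area_cm2: float) -> RateEstimate:
    """Net nutrient flux from start/end concentrations, nmol cm-2 h-1.

    ``control_delta_uM`` is the concentration change (final - initial) in
    no-leaf control vials over the same window. Uptake (a concentration
    decrease beyond the control) is reported positive; the raw signed flux
    (release positive) is retained in ``raw_signed_flux``.
    """
    if t_h <= 0:
        raise ZeroDurationError("nutrient flux needs t_h > 0")
    if vial_volume_mL <= 0 or leaf_area_cm2 <= 0:
        raise ValueError("vial volume and leaf area must be > 0")
    vol_L = vial_volume_mL / 1000.0
    delta_uM = (final_uM - initial_uM) - control_delta_uM
    signed_nmol = delta_uM * vol_L * 1000.0  # uM * L = umol -> nmol
    signed_rate = signed_nmol / t_h / leaf_area_cm2
    return RateEstimate(
        value=float(-signed_rate),  # uptake positive
        units="nmol cm-2 h-1",
        significant=True,
        control_corrected=control_delta_uM != 0.0,
        raw_signed_flux=float(signed_rate),
    )


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

_RATE_ROW_COLS = ["experiment", "process", "site", "light", "epiphytes", "replicate_id",
                  "value", "units", "significant", "gated_value", "excess_atom_pct",
                  "medium_atom_pct", "control_corrected", "baseline_mean", "baseline_sd",
                  "baseline_n"]


def _rate_row(experiment: str, process: str, key: tuple, rep: str, est: RateEstimate) -> dict:
    site, light, epi = key
    return {
        "experiment": experiment, "process": process, "site": site, "light": light,
        "epiphytes": epi, "replicate_id": rep, "value": est.value, "units": est.units,
        "significant": est.significant, "gated_value": est.gated_value,
        "excess_atom_pct": est.excess_atom_pct, "medium_atom_pct": est.medium_atom_pct,
        "control_corrected": est.control_corrected, "baseline_mean": est.baseline_mean,
        "baseline_sd": est.baseline_sd, "baseline_n": est.baseline_n,
    }


def _record_from_row(row: pd.Series) -> IncubationRecord:
    def opt(name):
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    return IncubationRecord(
        site=row["site"], light=row["light"], epiphytes=row["epiphytes"],
        tracer=row["tracer"], timepoint_h=float(row["timepoint_h"]),
        replicate_id=str(row["replicate_id"]), is_control=row.get("role") == "control",
        atom_pct_15n_tissue=opt("atom_pct_15n_tissue"), pn_tissue_ug=opt("pn_tissue_ug"),
        c_pct=opt("c_pct"), n_pct=opt("n_pct"), leaf_area_cm2=opt("leaf_area_cm2"),
        conc_29n2_nM=opt("conc_29n2_nM"), conc_30n2_nM=opt("conc_30n2_nM"),
        delta15n_no3_permil=opt("delta15n_no3_permil"), nh4_uM=opt("nh4_uM"),
        no2_uM=opt("no2_uM"), nox_uM=opt("nox_uM"), po4_uM=opt("po4_uM"),
        vial_volume_mL=float(row.get("vial_volume_mL", 24.0)),
    )


def estimate_rates(records: pd.DataFrame,
                   medium_atom_pct: Optional[dict] = None,
                   k: float = DEFAULT_GATE_K,
                   n2_as_molecules: bool = False,
                   constants: IsotopeConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Run every rate calculation the records table supports.

    Groups rows by ``experiment`` x site x light x epiphytes, builds the
    appropriate baselines (natural-abundance vials for tissue, T0 vials for
    water pools) and control corrections (no-leaf vials), and returns one
    row per vial x process with provenance columns.
    """
    medium = dict(DEFAULT_MEDIUM_ATOM_PCT)
    if medium_atom_pct:
        medium.update(medium_atom_pct)
    rows: list[dict] = []
    for exp, df in records.groupby("experiment", sort=False):
        handler = _EXPERIMENT_HANDLERS.get(exp)
        if handler is None:
            raise IncompleteRecordError(f"unknown experiment {exp!r}")
        rows.extend(handler(df, medium, k, n2_as_molecules, constants))
    return pd.DataFrame(rows, columns=_RATE_ROW_COLS)


def _fixation_rows(df, medium, k, n2_as_molecules, constants):
    rows = []
    baseline_df = df[df["role"] == "baseline"]
    if len(baseline_df) < 2:
        raise IncompleteRecordError("n2_fixation needs >= 2 natural-abundance baseline vials")
    baseline = BaselineStats.from_samples(baseline_df["atom_pct_15n_tissue"], "natural_abundance")
    samples = df[(df["role"] == "sample") & (df["timepoint_h"] > 0)]
    for key, grp in samples.groupby(["site", "light", "epiphytes"], sort=False):
        for _, row in grp.iterrows():
            est = n2_fixation_rate(_record_from_row(row), baseline, medium["15N2"], k, constants)
            rows.append(_rate_row("n2_fixation", "n2_fixation", key, row["replicate_id"], est))
    return rows


def _pnr_rows(df, medium, k, n2_as_molecules, constants):
    rows = []
    for key, grp in df[df["role"] != "control"].groupby(["site", "light", "epiphytes"], sort=False):
        t0 = grp[grp["timepoint_h"] == 0]
        if len(t0) < 2:
            raise IncompleteRecordError(f"nitrification {key}: needs >= 2 T0 vials")
        baseline = BaselineStats.from_samples(
            delta_to_atom_percent(t0["delta15n_no3_permil"].to_numpy(float), constants), "t0")
        # no-leaf controls: mean vial-level background rate at each timepoint
        ctrl = df[(df["role"] == "control") & (df["site"] == key[0]) & (df["timepoint_h"] > 0)]
        ctrl_by_t = {}
        for t, cgrp in ctrl.groupby("timepoint_h"):
            excesses, crates = [], []
            for _, crow in cgrp.iterrows():
                catom = delta_to_atom_percent(crow["delta15n_no3_permil"], constants)
                cex = atom_percent_excess(catom, baseline)
                cpool = no3_from_nox(crow["nox_uM"], crow["no2_uM"]) * crow["vial_volume_mL"]
                excesses.append(cex)
                crates.append(_pool_transfer_nmol_h(cex, medium["15NH4"], cpool, t))
            ctrl_by_t[t] = (float(np.mean(crates)), float(np.mean(excesses)))
        samples = grp[(grp["role"] == "sample") & (grp["timepoint_h"] > 0)]
        for _, row in samples.iterrows():
            c_rate, c_ex = ctrl_by_t.get(row["timepoint_h"], (0.0, 0.0))
            est = pnr(_record_from_row(row), baseline, medium["15NH4"],
                      control_rate_nmol_h=c_rate, control_excess_atom_pct=c_ex,
                      k=k, constants=constants)
            rows.append(_rate_row("nitrification", "nitrification", key, row["replicate_id"], est))
    return rows


def _n2_production_rows(df, medium, k, n2_as_molecules, constants):
    rows = []
    times = sorted(t for t in df["timepoint_h"].unique() if t > 0)
    if len(times) < 2:
        raise IncompleteRecordError("n2_production needs two positive timepoints (T1, T2)")
    t1, t2 = times[0], times[1]  # lag phase before T1; slope from T1 -> T2
    for species, col in (("n2_production_29", "conc_29n2_nM"), ("n2_production_30", "conc_30n2_nM")):
        ctrl = df[df["role"] == "control"]
        ctrl_slopes = []
        for rep, cgrp in ctrl.groupby("replicate_id"):
            byt = cgrp.set_index("timepoint_h")[col]
            if t1 in byt.index and t2 in byt.index:
                vol_L = cgrp["vial_volume_mL"].iloc[0] / 1000.0
                ctrl_slopes.append((byt[t2] - byt[t1]) * vol_L / (t2 - t1))
        ctrl_slope = float(np.mean(ctrl_slopes)) if ctrl_slopes else 0.0
        samples = df[df["role"] == "sample"]
        for key, grp in samples.groupby(["site", "light", "epiphytes"], sort=False):
            for rep, rgrp in grp.groupby("replicate_id"):
                byt = rgrp.set_index("timepoint_h")
                if t1 not in byt.index or t2 not in byt.index:
                    continue
                est = n2_production_rate(
                    byt.loc[t1, col], byt.loc[t2, col], t1, t2,
                    byt["vial_volume_mL"].iloc[0], byt["leaf_area_cm2"].iloc[0],
                    control_slope_nmol_h=ctrl_slope, n2_as_molecules=n2_as_molecules)
                rows.append(_rate_row("n2_production", species, key, rep, est))
    return rows


_NUTRIENTS = {"nh4_uptake": "nh4_uM", "no3_uptake": "no3_uM", "po4_uptake": "po4_uM"}


def _nutrient_flux_rows(df, medium, k, n2_as_molecules, constants):
    rows = []
    df = df.copy()
    df["no3_uM"] = [
        no3_from_nox(r.nox_uM, r.no2_uM) if pd.notna(r.nox_uM) and pd.notna(r.no2_uM) else np.nan
        for r in df.itertuples()
    ]
    t_end = df.loc[df["role"] == "sample", "timepoint_h"].max()
    for process, col in _NUTRIENTS.items():
        if df[col].isna().all():
            continue
        ctrl = df[df["role"] == "control"]
        ctrl_delta = 0.0
        if len(ctrl):
            c0 = ctrl.loc[ctrl["timepoint_h"] == 0, col].mean()
            c1 = ctrl.loc[ctrl["timepoint_h"] == t_end, col].mean()
            if pd.notna(c0) and pd.notna(c1):
                ctrl_delta = float(c1 - c0)
        samples = df[df["role"] == "sample"]
        for key, grp in samples.groupby(["site", "light", "epiphytes"], sort=False):
            init = grp.loc[grp["timepoint_h"] == 0, col].mean()
            if pd.isna(init):
                raise IncompleteRecordError(f"nutrient_flux {key}: no T0 concentration for {col}")
            for _, row in grp[grp["timepoint_h"] == t_end].iterrows():
                est = nutrient_flux(float(init), float(row[col]), ctrl_delta,
                                    float(row["timepoint_h"]), float(row["vial_volume_mL"]),
                                    float(row["leaf_area_cm2"]))
                rows.append(_rate_row("nutrient_flux", process, key, row["replicate_id"], est))
    return rows


_EXPERIMENT_HANDLERS = {
    "n2_fixation": _fixation_rows,
    "nitrification": _pnr_rows,
    "n2_production": _n2_production_rows,
    "nutrient_flux": _nutrient_flux_rows,
}
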