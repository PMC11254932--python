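"""Daily meadow-scale nitrogen budgets.

Per-area hourly rates from the incubations are integrated over a light/dark
cycle (12:12 by default), scaled from leaf area to meadow area through the
leaf-area index (LAI, cm2 leaf per m2 meadow), and combined into a daily
budget per site:

* N demand = (NCP / PQ) / C:N — net community production converted to the
  nitrogen required to sustain it;
* % contribution of N2 fixation to that demand;
* net N gain = fixation + NH4+ uptake + NO3- uptake - N loss (exact
  identity on every emitted budget row). Nitrification appears in the
  budget table but not in the net gain: it transforms N between dissolved
  pools rather than adding or removing it from the holobiont.

Only significance-gated rates enter the integration: a rate whose tracer
enrichment failed the 2.5 x SD gate contributes 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import ConfigError, UndefinedRatioError
from .units import convert_units


@dataclass(frozen=True)
class MeadowParams:
    """Site-level scaling parameters for the meadow budget.

    ``leaf_area_index`` (cm2 leaf per m2 meadow) can be given directly or
    derived from ``leaf_density * dw_per_leaf * specific_leaf_area``.
    ``ncp`` is net community production in mmol C m-2 d-1 (O2-based values
    are converted with the photosynthetic quotient ``pq``); ``cn_molar`` is
    the molar C:N of the holobiont tissue.
    """

    ncp: float
    cn_molar: float
    pq: float = 1.0
    photoperiod_h: float = 12.0
    leaf_area_index: Optional[float] = None
    leaf_density: Optional[float] = None        # leaves m-2 meadow
    dw_per_leaf: Optional[float] = None         # g DW per leaf
    specific_leaf_area: Optional[float] = None  # cm2 leaf per g DW

    def __post_init__(self) -> None:
        if not 0 <= self.photoperiod_h <= 24:
            raise ConfigError(f"photoperiod_h must be in [0, 24], got {self.photoperiod_h}")
        for name in ("ncp", "cn_molar", "pq"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @property
    def lai_cm2_per_m2(self) -> float:
        if self.leaf_area_index is not None:
            return self.leaf_area_index
        parts = (self.leaf_density, self.dw_per_leaf, self.specific_leaf_area)
        if all(p is not None for p in parts):
            return parts[0] * parts[1] * parts[2]
        raise ConfigError(
            "need leaf_area_index or (leaf_density, dw_per_leaf, specific_leaf_area)"
        )


@dataclass
class DailyBudget:
    """Per-site daily budget, every process in mmol N m-2 meadow d-1."""

    site: str
    n2_fixation: float
    nh4_uptake: float
    no3_uptake: float
    n_loss: float
    nitrification: float
    n_demand: float
    pct_of_demand: float
    units: str = "mmol N m-2 d-1"

    @property
    def net_n_gain(self) -> float:
        """Exact identity: fixation + NH4+ uptake + NO3- uptake - N loss."""
        return self.n2_fixation + self.nh4_uptake + self.no3_uptake - self.n_loss


def integrate_daily(light_rate: float, dark_rate: float, photoperiod_h: float = 12.0) -> float:
    """Integrate hourly light/dark rates over one day (same per-area units, per day)."""
    if not 0 <= photoperiod_h <= 24:
        raise ConfigError(f"photoperiod_h must be in [0, 24], got {photoperiod_h}")
    return light_rate * photoperiod_h + dark_rate * (24.0 - photoperiod_h)


def scale_to_meadow(rate_per_cm2_d: float, params: MeadowParams,
                    from_amount: str = "nmol") -> float:
    """Scale a per-cm2-leaf daily rate to mmol N m-2 meadow d-1 via the LAI."""
    per_meadow = rate_per_cm2_d * params.lai_cm2_per_m2  # amount per m2 meadow per day
    return convert_units(per_meadow, f"{from_amount} N", "mmol N")


def n_demand(ncp: float, pq: float, cn_molar: float) -> float:
    """Daily N demand (mmol N m-2 d-1) from NCP (mmol C m-2 d-1), PQ, and molar C:N."""
    if cn_molar <= 0:
        raise UndefinedRatioError("cn_molar must be > 0")
    if pq <= 0:
        raise ConfigError("pq must be > 0")
    return (ncp / pq) / cn_molar


def percent_contribution(daily_fixation: float, demand: float) -> float:
    """Percent of the daily N demand met by N2 fixation."""
    if demand <= 0:
        raise UndefinedRatioError("demand must be > 0")
    return 100.0 * daily_fixation / demand


def net_n_gain(budget: DailyBudget) -> float:
    """Net daily N gain of the holobiont (see :class:`DailyBudget`)."""
    return budget.net_n_gain


#: process name in the rates table -> (native per-hour amount unit, budget column)
_PROCESS_MAP = {
    "n2_fixation": ("nmol", "n2_fixation"),
    "nh4_uptake": ("nmol", "nh4_uptake"),
    "no3_uptake": ("nmol", "no3_uptake"),
    "nitrification": ("pmol", "nitrification"),
    "n2_production_29": ("pmol", "n_loss"),
    "n2_production_30": ("pmol", "n_loss"),
}


def build_budget(rates: pd.DataFrame, params_by_site: dict[str, MeadowParams],
                 epiphytes: str = "present", emit_umol: bool = False) -> pd.DataFrame:
    """Assemble per-site daily budgets from a rates table.

    ``rates`` is the output of :func:`phyllon.tracer.estimate_rates`. For
    each site and process the replicate mean of the **gated** rates is taken
    per light condition, integrated over the photoperiod, scaled by the LAI
    and emitted in mmol N m-2 d-1 (or umol with ``emit_umol``).
    """
    sub = rates[rates["epiphytes"] == epiphytes]
    out_rows = []
    target = "umol" if emit_umol else "mmol"
    for site, params in params_by_site.items():
        terms = {col: 0.0 for _, col in _PROCESS_MAP.values()}
        site_rates = sub[sub["site"] == site]
        for process, (amount, col) in _PROCESS_MAP.items():
            proc = site_rates[site_rates["process"] == process]
            if proc.empty:
                continue
            by_light = proc.groupby("light")["gated_value"].mean()
            daily = integrate_daily(by_light.get("light", 0.0), by_light.get("dark", 0.0),
                                    params.photoperiod_h)
            terms[col] += scale_to_meadow(daily, params, from_amount=amount)
        demand = n_demand(params.ncp, params.pq, params.cn_molar)
        budget = DailyBudget(
            site=site,
            n2_fixation=terms["n2_fixation"],
            nh4_uptake=terms["nh4_uptake"],
            no3_uptake=terms["no3_uptake"],
            n_loss=terms["n_loss"],
            nitrification=terms["nitrification"],
            n_demand=demand,
            pct_of_demand=percent_contribution(terms["n2_fixation"], demand),
        )
        scale = (lambda v: convert_units(v, "mmol N", "umol N")) if emit_umol else (lambda v: v)
        out_rows.append({
            "site": site,
            "n2_fixation": scale(budget.n2_fixation),
            "nh4_uptake": scale(budget.nh4_uptake),
            "no3_uptake": scale(budget.no3_uptake),
            "n_loss": scale(budget.n_loss),
            "nitrification": scale(budget.nitrification),
            "n_demand": scale(budget.n_demand),
            "pct_of_demand": budget.pct_of_demand,
            "net_n_gain": scale(budget.net_n_gain),
            "units": f"{target} N m-2 d-1",
        })
    return pd.DataFrame(out_rows)
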