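"""Turn raw measurements into the per-condition data the ensemble stage fits.

Three experimentally determined fluxes characterise the pathway at steady
state: the two carotenoid accumulation sinks (from carotenoid content and
dilution rate in chemostat culture) and the squalene-forming ERG9b flux
(proportional to growth rate, the proportionality constant being a config
input derived upstream from genome-scale analysis).  Specific rates
(per gDCW) are converted to intracellular volumetric rates (mmol/L/h) via
cell density and moisture content.  Relative enzyme concentrations are
proxied by relative transcript levels computed from qPCR threshold cycles
with the Common Base method: per replicate the efficiency-weighted log
quantity L = -Cq*log10(E), relative expression 10^(Lbar_cond - Lbar_ref)
with a pooled-variance t interval on the difference of means.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FREE_FLUX_IDS = ("SK_lyc", "SK_b_car", "ERG9b")


class DataPrepError(ValueError):
    pass


@dataclass(frozen=True)
class CellConstants:
    """Physical constants for unit conversion and the ERG9b growth coupling."""

    density: float = 1.1029        # g/mL wet cell
    moisture: float = 1.525        # g water per gDCW
    erg9b_coeff: float = 0.025     # mmol/gDCW per unit specific growth rate

    def __post_init__(self) -> None:
        if self.density <= 0 or self.moisture <= 0 or self.erg9b_coeff <= 0:
            raise DataPrepError("cell constants must be positive")

    @property
    def volumetric_multiplier(self) -> float:
        """gDCW per litre of cell volume: density*1000/(1+moisture)."""
        return self.density * 1000.0 / (1.0 + self.moisture)


@dataclass
class ChemostatObservation:
    strain: str
    dilution_rate: tuple[float, float, float]             # mean, lo, hi (1/h)
    carotenoid_content: dict[str, tuple[float, float, float]]  # nmol/gDCW
    biomass_factor: float | None = None                   # OD600 -> gDCW/L, provenance only

    def __post_init__(self) -> None:
        if self.dilution_rate[0] <= 0:
            raise DataPrepError("dilution rate must be positive")
        for k, (m, lo, hi) in self.carotenoid_content.items():
            if m < 0 or lo < 0:
                raise DataPrepError(f"negative carotenoid content for {k!r}")


@dataclass
class QpcrTable:
    gene: str
    condition: str
    cq_replicates: Sequence[float]
    efficiency: float              # amplification factor per cycle
    no_rt_flag: bool = False

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.2):
            raise DataPrepError(
                f"{self.gene}/{self.condition}: efficiency must be in (1, 2.2], got {self.efficiency}"
            )
        if len(self.cq_replicates) < 2:
            raise DataPrepError(f"{self.gene}/{self.condition}: need >= 2 Cq replicates")


@dataclass
class ConditionData:
    strain: str
    growth_rate: float
    free_fluxes: dict[str, tuple[float, float, float]]    # mean, lo, hi (mmol/L/h)
    rel_enzyme: dict[str, tuple[float, float, float]]     # mean, lo, hi vs reference
    degenerate_fluxes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for k, (m, lo, hi) in self.free_fluxes.items():
            if not (lo <= m <= hi):
                raise DataPrepError(f"flux {k!r}: CI does not bracket the mean")
            if m <= 0 and k not in self.degenerate_fluxes:
                raise DataPrepError(f"flux {k!r} must be positive (or flagged degenerate)")
        for k, (m, lo, hi) in self.rel_enzyme.items():
            if not (lo <= m <= hi):
                raise DataPrepError(f"enzyme {k!r}: CI does not bracket the mean")


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def sink_flux_specific(content: float, dilution_rate: float) -> float:
    """Specific accumulation rate (nmol/gDCW/h) from content and D.

    At chemostat steady state the intracellular pool is diluted by growth,
    so production balances content * D.
    """
    if content < 0:
        raise DataPrepError("carotenoid content must be >= 0")
    if dilution_rate <= 0:
        raise DataPrepError("dilution rate must be positive")
    return content * dilution_rate


def erg9b_flux(mu: float, coeff: float) -> float:
    """Specific ERG9b rate (mmol/gDCW/h), proportional to growth rate."""
    if mu <= 0 or coeff <= 0:
        raise DataPrepError("growth rate and coefficient must be positive")
    return coeff * mu


def to_volumetric(v_spec: float, constants: CellConstants = CellConstants()) -> float:
    """mmol/gDCW/h -> mmol per litre of cell volume per hour."""
    return v_spec * constants.volumetric_multiplier


# ---------------------------------------------------------------------------
# Common Base transcript normalisation
# ---------------------------------------------------------------------------

def _common_base_logs(t: QpcrTable) -> np.ndarray:
    return -np.asarray(t.cq_replicates, dtype=float) * np.log10(t.efficiency)


def common_base_expression(
    tables: Sequence[QpcrTable],
    reference_condition: str,
    alpha: float = 0.05,
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Relative expression (mean, CI_lo, CI_hi) per (gene, condition).

    Every gene must be measured in the reference condition.  The interval is
    a pooled-variance t interval on the difference of common-base log means,
    exponentiated back to the ratio scale.
    """
    by_gene: dict[str, dict[str, QpcrTable]] = {}
    for t in tables:
        by_gene.setdefault(t.gene, {})[t.condition] = t
    out: dict[tuple[str, str], tuple[float, float, float]] = {}
    for gene, conds in by_gene.items():
        if reference_condition not in conds:
            raise DataPrepError(
                f"gene {gene!r}: reference condition {reference_condition!r} missing"
            )
        ref = conds[reference_condition]
        l_ref = _common_base_logs(ref)
        for cond, t in conds.items():
            l = _common_base_logs(t)
            n1, n2 = len(l), len(l_ref)
            diff = l.mean() - l_ref.mean()
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * l.var(ddof=1) + (n2 - 1) * l_ref.var(ddof=1)) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            tcrit = stats.t.ppf(1.0 - alpha / 2.0, df) if se > 0 else 0.0
            out[(gene, cond)] = (
                float(10.0 ** diff),
                float(10.0 ** (diff - tcrit * se)),
                float(10.0 ** (diff + tcrit * se)),
            )
    return out


# ---------------------------------------------------------------------------
# condition assembly
# ---------------------------------------------------------------------------

def _sink_flux_volumetric(content_ci, d_ci, constants) -> tuple[float, float, float]:
    # linear conversions: multiply CI endpoints through
    vals = [
        sink_flux_specific(c, d) * 1e-6 * constants.volumetric_multiplier
        for c, d in zip(content_ci, d_ci)
    ]
    return tuple(vals)  # (mean, lo, hi): endpoints stay ordered for positive c, d


def free_fluxes_from_observation(
    obs: ChemostatObservation,
    constants: CellConstants = CellConstants(),
) -> tuple[dict[str, tuple[float, float, float]], set[str]]:
    """Free-flux means and CIs (mmol/L/h) from one chemostat observation."""
    d = obs.dilution_rate
    fluxes = {}
    degenerate = set()
    for sink, key in (("SK_lyc", "lycopene"), ("SK_b_car", "b_carotene")):
        ci = obs.carotenoid_content[key]
        fluxes[sink] = _sink_flux_volumetric(ci, d, constants)
        if ci[0] == 0:
            degenerate.add(sink)
    e9 = tuple(erg9b_flux(x, constants.erg9b_coeff) * constants.volumetric_multiplier
               for x in d)
    fluxes["ERG9b"] = e9
    return fluxes, degenerate


def build_condition(
    obs: ChemostatObservation,
    reference_obs: ChemostatObservation,
    qpcr_tables: Sequence[QpcrTable],
    constants: CellConstants = CellConstants(),
    enzymes: Sequence[str] | None = None,
) -> ConditionData:
    """Assemble ConditionData for one strain against the reference strain.

    qPCR condition ids must equal strain ids; genes are enzyme ids.  Enzymes
    without qPCR data get relative level 1 with a degenerate CI (only
    sensible for the reference itself); restrict via ``enzymes``.
    """
    if not np.isclose(obs.dilution_rate[0], reference_obs.dilution_rate[0], rtol=1e-6):
        raise DataPrepError(
            f"growth-rate mismatch: {obs.strain} at {obs.dilution_rate[0]} vs "
            f"{reference_obs.strain} at {reference_obs.dilution_rate[0]}"
        )
    fluxes, degenerate = free_fluxes_from_observation(obs, constants)
    rel = {}
    if qpcr_tables:
        expr = common_base_expression(qpcr_tables, reference_condition=reference_obs.strain)
        for (gene, cond), v in expr.items():
            if cond == obs.strain:
                rel[gene] = v
    if enzymes is not None:
        for e in enzymes:
            rel.setdefault(e, (1.0, 1.0, 1.0))
        rel = {e: rel[e] for e in enzymes}
    return ConditionData(
        strain=obs.strain,
        growth_rate=obs.dilution_rate[0],
        free_fluxes=fluxes,
        rel_enzyme=rel,
        degenerate_fluxes=degenerate,
    )


# ---------------------------------------------------------------------------
# packaged chemostat fixture
# ---------------------------------------------------------------------------

def load_rate_table(path: str | Path | None = None) -> pd.DataFrame:
    """Measured growth and carotenoid production rates (packaged fixture)."""
    if path is None:
        text = resources.files("carokin.data").joinpath("chemostat_rates.csv").read_text()
        return pd.read_csv(io.StringIO(text), comment="#")
    return pd.read_csv(path, comment="#")


def load_qpcr_long(path: str | Path) -> list[QpcrTable]:
    """Read qPCR tables from long-format CSV (gene, condition, replicate, Cq,
    efficiency); the replicate column is ignored beyond grouping."""
    df = pd.read_csv(path, comment="#")
    required = {"gene", "condition", "Cq", "efficiency"}
    if not required <= set(df.columns):
        raise DataPrepError(f"qPCR CSV needs columns {sorted(required)}")
    tables = []
    for (gene, cond), grp in df.groupby(["gene", "condition"], sort=True):
        eff = grp["efficiency"].unique()
        if len(eff) != 1:
            raise DataPrepError(f"{gene}/{cond}: inconsistent efficiencies")
        tables.append(QpcrTable(gene=str(gene), condition=str(cond),
                                cq_replicates=grp["Cq"].astype(float).tolist(),
                                efficiency=float(eff[0])))
    return tables


def observation_from_rates(row: Mapping[str, float]) -> ChemostatObservation:
    """Build an observation from a production-rate row (rate = content * D)."""
    d = (float(row["D"]), float(row["D_lo"]), float(row["D_hi"]))
    # invert the chemostat balance at the mean dilution rate
    content = {
        "lycopene": tuple(float(row[k]) / d[0] for k in ("lyc_rate", "lyc_lo", "lyc_hi")),
        "b_carotene": tuple(float(row[k]) / d[0] for k in ("bcar_rate", "bcar_lo", "bcar_hi")),
    }
    return ChemostatObservation(strain=str(row["strain"]), dilution_rate=d,
                                carotenoid_content=content)


def reference_condition_fluxes(
    strain: str = "b_car4",
    growth_rate: float = 0.101,
    constants: CellConstants = CellConstants(),
) -> dict[str, tuple[float, float, float]]:
    """Free fluxes (mmol/L/h, with CIs) of a strain/growth from the fixture.

    Conversion keeps the dilution rate fixed at its mean so that the rate CIs
    printed with the data propagate linearly to the sink fluxes.
    """
    df = load_rate_table()
    sel = df[(df["strain"] == strain) & np.isclose(df["D"], growth_rate)]
    if len(sel) != 1:
        raise DataPrepError(f"no unique fixture row for {strain!r} at D={growth_rate}")
    obs = observation_from_rates(sel.iloc[0])
    fluxes, _ = free_fluxes_from_observation(obs, constants)
    return fluxes
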