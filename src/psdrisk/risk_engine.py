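"""Risk metrics: risk quotients, internal toxic units and effect units.

Three complementary scores prioritise contaminants for a benthic
invertebrate (*Gammarus pulex*):

* **RQ** = MEC / PNEC on the water scale, banded into insignificant
  (<0.1), low (0.1-1), medium (1-10) and high (>10) risk;
* **log10 TU_int** = log10(C_invert / EC50_int) with EC50_int = EC50 x BCF
  on the tissue (ng/g) scale — pesticides with acute invertebrate EC50
  data; values above -3.0 indicate possible adverse effects;
* **log10 EU_int** — the PC_crit analogue used to *rank* pharmaceuticals
  lacking EC50 data: C_invert over PC_crit x BCF.

The sampler-as-organism substitution feeds the contaminant mass on a
sorbent disk, divided by the disk weight (0.0115 g), into the TU/EU
formulas in place of the tissue concentration, so risk can be read
directly off a passive sampler without calibrated uptake rates.

Unit conventions: EC50 [ug/L] x BCF [L/kg] = ug/kg = ng/g exactly.  The
EU denominator is computed as PC_crit [ng/L] x BCF [L/kg] and read on the
ng/g scale; see docs/methods.md for why this convention (a global 10^3
offset against the strict mg/kg -> ng/g conversion) is the one the
reported effect-unit magnitudes follow.  EU is a ranking score, so a
global offset is immaterial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .campaign_io import PSD_MATRICES, CompoundRecord, month_of
from .sampler_kinetics import twa_concentration

logger = logging.getLogger(__name__)

RQ_CATEGORIES = ("insignificant", "low", "medium", "high")

EU_DENOMINATOR_FORMS = ("pc_crit_times_bcf", "pc_crit_only")


@dataclass(frozen=True)
class RiskThresholds:
    """Risk-band breakpoints and fixed constants of the scoring scheme.

    ``rq_bands`` are the RQ breakpoints between insignificant/low/medium/
    high; ``tu_log_threshold`` is the adverse-effect line for log10 TU;
    ``disk_mass_g`` is the weight of one 9 mm sorbent disk used in the
    sampler-as-organism substitution; ``eu_denominator`` selects the
    effect-unit denominator form.
    """

    rq_bands: tuple[float, float, float] = (0.1, 1.0, 10.0)
    tu_log_threshold: float = -3.0
    disk_mass_g: float = 0.0115
    eu_denominator: str = "pc_crit_times_bcf"

    def __post_init__(self) -> None:
        if not (self.rq_bands[0] < self.rq_bands[1] < self.rq_bands[2]):
            raise ValueError("rq_bands must be strictly increasing")
        if self.disk_mass_g <= 0:
            raise ValueError("disk_mass_g must be > 0")
        if self.eu_denominator not in EU_DENOMINATOR_FORMS:
            raise ValueError(f"unknown eu_denominator {self.eu_denominator!r}")


DEFAULT_THRESHOLDS = RiskThresholds()


@dataclass(frozen=True)
class RiskResult:
    compound_id: str
    matrix: str
    month: str
    metric: str  # RQ | TU | EU
    value: float  # RQ unitless; TU/EU on the log10 scale
    category: str | None = None  # RQ only
    exceeds_tu_threshold: bool | None = None  # TU only


# --------------------------------------------------------------------------
# elementary scores
# --------------------------------------------------------------------------


def risk_quotient(mec: float, pnec: float) -> float:
    """RQ = MEC/PNEC, both on the aqueous ng/L scale."""
    if pnec <= 0:
        raise ValueError(f"pnec must be > 0 (got {pnec})")
    if mec < 0:
        raise ValueError(f"mec must be >= 0 (got {mec})")
    return mec / pnec


def classify_rq(rq: float, thresholds: RiskThresholds = DEFAULT_THRESHOLDS) -> str:
    """Band an RQ: [0,0.1) insignificant, [0.1,1) low, [1,10] medium, (10,inf) high.

    Lower bounds are inclusive for low/medium and 10 belongs to medium, so
    the bands partition [0, inf); RQ > 1.0 is always at least medium.
    """
    if rq < 0:
        raise ValueError(f"rq must be >= 0 (got {rq})")
    lo, mid, hi = thresholds.rq_bands
    if rq < lo:
        return "insignificant"
    if rq < mid:
        return "low"
    if rq <= hi:
        return "medium"
    return "high"


def select_worst_case_bcf(bcf_candidates: Sequence[float]) -> float:
    """Worst-case rule: of the candidate BCFs, take the highest."""
    if not bcf_candidates:
        raise ValueError("no BCF candidates")
    if any(b <= 0 for b in bcf_candidates):
        raise ValueError("BCF candidates must be > 0")
    return max(bcf_candidates)


def internal_ec50(ec50_ug_l: float, bcf_l_kg: float) -> float:
    """EC50_int = EC50 x BCF, in ng/g (ug/L x L/kg = ug/kg = ng/g)."""
    if ec50_ug_l <= 0 or bcf_l_kg <= 0:
        raise ValueError("ec50 and bcf must be > 0")
    return ec50_ug_l * bcf_l_kg


def toxic_unit(
    c_invert_ng_g: float,
    ec50_int_ng_g: float,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> tuple[float, bool]:
    """log10 internal toxic unit and whether it exceeds the -3.0 threshold.

    The threshold comparison is strict: exactly -3.0 does not exceed.
    """
    if c_invert_ng_g <= 0 or ec50_int_ng_g <= 0:
        raise ValueError("concentration and EC50_int must be > 0")
    value = math.log10(c_invert_ng_g / ec50_int_ng_g)
    return value, value > thresholds.tu_log_threshold


def eu_denominator_ng_g(
    pc_crit_mg_l: float,
    bcf_l_kg: float,
    form: str = "pc_crit_times_bcf",
) -> float:
    """Effect-unit denominator on the ng/g scale.

    ``pc_crit_times_bcf`` (default): PC_crit [ng/L] x BCF [L/kg] read as
    ng/g.  ``pc_crit_only``: PC_crit [ng/L] alone read as ng/g (no
    internalisation).
    """
    if pc_crit_mg_l <= 0:
        raise ValueError("pc_crit must be > 0")
    pc_crit_ng_l = pc_crit_mg_l * 1e6
    if form == "pc_crit_times_bcf":
        if bcf_l_kg <= 0:
            raise ValueError("bcf must be > 0")
        return pc_crit_ng_l * bcf_l_kg
    if form == "pc_crit_only":
        return pc_crit_ng_l
    raise ValueError(f"unknown eu denominator form {form!r}")


def effect_unit(
    c_invert_ng_g: float,
    pc_crit_mg_l: float,
    bcf_l_kg: float,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """log10 internal effect unit: c_invert over the PC_crit-based denominator."""
    if c_invert_ng_g <= 0:
        raise ValueError("c_invert must be > 0")
    denom = eu_denominator_ng_g(pc_crit_mg_l, bcf_l_kg, thresholds.eu_denominator)
    return math.log10(c_invert_ng_g / denom)


def psd_pseudo_concentration(mass_ng: float, disk_mass_g: float = 0.0115) -> float:
    """Sampler-as-organism pseudo-concentration: disk load over disk weight (ng/g)."""
    if disk_mass_g <= 0:
        raise ValueError("disk_mass_g must be > 0")
    if mass_ng < 0:
        raise ValueError("mass_ng must be >= 0")
    return mass_ng / disk_mass_g


# --------------------------------------------------------------------------
# campaign-level table
# --------------------------------------------------------------------------


def _sorbent_of(matrix: str) -> str:
    return matrix.removeprefix("psd_")


def risk_table(
    measurements: pd.DataFrame,
    compounds: Iterable[CompoundRecord],
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
    deployment_days: float = 7.0,
) -> pd.DataFrame:
    """Score every quantifiable (compound, matrix, month) observation.

    Produces, per quantified measurement:

    * water rows — RQ (needs PNEC);
    * sampler rows — RQ from the TWA concentration (only where a
      calibrated Rs exists for that sorbent), plus TU/EU from the
      sampler-as-organism pseudo-concentration;
    * biota rows — TU for pesticides with EC50+BCF, EU for pharmaceuticals
      with PC_crit (+BCF under the default denominator form).

    Replicates within a month are averaged before scoring.  Compounds
    lacking the needed constants are skipped and logged.  The result is
    sorted by metric, then value descending.
    """
    by_id = {c.compound_id: c for c in compounds}
    quant = measurements[measurements["censor"] == "quantified"].copy()
    quant["month"] = quant["timepoint"].map(month_of)
    grouped = (
        quant.groupby(["compound_id", "matrix", "month"])["value"].mean().reset_index()
    )

    results: list[RiskResult] = []
    for _, row in grouped.iterrows():
        cid, matrix, month = row["compound_id"], row["matrix"], row["month"]
        value = float(row["value"])
        rec = by_id.get(cid)
        if rec is None:
            logger.info("risk_table: no compound record for %s; skipped", cid)
            continue
        if matrix == "water":
            _score_aqueous(results, rec, matrix, month, value, thresholds)
        elif matrix in PSD_MATRICES:
            sorbent = _sorbent_of(matrix)
            rs = rec.rs.get(sorbent)
            if rs is not None and rs > 0:
                c_twa = twa_concentration(value, rs, deployment_days)
                _score_aqueous(results, rec, matrix, month, c_twa, thresholds)
            else:
                logger.info(
                    "risk_table: no Rs for %s on %s; RQ skipped", cid, sorbent
                )
            pseudo = psd_pseudo_concentration(value, thresholds.disk_mass_g)
            _score_internal(results, rec, matrix, month, pseudo, thresholds)
        elif matrix == "biota":
            _score_internal(results, rec, matrix, month, value, thresholds)
        # blank matrices carry no risk

    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "matrix": r.matrix,
                "month": r.month,
                "metric": r.metric,
                "value": r.value,
                "category": r.category,
                "exceeds_tu_threshold": r.exceeds_tu_threshold,
            }
            for r in results
        ],
        columns=[
            "compound_id",
            "matrix",
            "month",
            "metric",
            "value",
            "category",
            "exceeds_tu_threshold",
        ],
    )
    return df.sort_values(
        ["metric", "value"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def _score_aqueous(results, rec, matrix, month, c_ng_l, thresholds) -> None:
    if rec.pnec_ng_l is None or rec.pnec_ng_l <= 0:
        logger.info("risk_table: no PNEC for %s; RQ skipped", rec.compound_id)
        return
    rq = risk_quotient(c_ng_l, rec.pnec_ng_l)
    results.append(
        RiskResult(rec.compound_id, matrix, month, "RQ", rq, classify_rq(rq, thresholds))
    )


def _score_internal(results, rec, matrix, month, c_ng_g, thresholds) -> None:
    if c_ng_g <= 0:
        return
    bcf = select_worst_case_bcf(rec.bcf_candidates) if rec.bcf_candidates else None
    if rec.ec50_ug_l and bcf:
        tu, exceeds = toxic_unit(c_ng_g, internal_ec50(rec.ec50_ug_l, bcf), thresholds)
        results.append(
            RiskResult(rec.compound_id, matrix, month, "TU", tu, None, exceeds)
        )
    elif rec.pc_crit_mg_l:
        need_bcf = thresholds.eu_denominator == "pc_crit_times_bcf"
        if need_bcf and not bcf:
            logger.info(
                "risk_table: no BCF for %s; EU skipped", rec.compound_id
            )
            return
        eu = effect_unit(c_ng_g, rec.pc_crit_mg_l, bcf or 1.0, thresholds)
        results.append(RiskResult(rec.compound_id, matrix, month, "EU", eu))
    else:
        logger.info(
            "risk_table: no EC50/PC_crit constants for %s; TU/EU skipped",
            rec.compound_id,
        )


def summarise_risk(risk: pd.DataFrame) -> pd.DataFrame:
    """Pool the monthly table: mean +- sd per compound x matrix x metric."""
    return (
        risk.groupby(["compound_id", "matrix", "metric"])["value"]
        .agg(mean="mean", sd="std", n_months="count")
        .reset_index()
    )
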