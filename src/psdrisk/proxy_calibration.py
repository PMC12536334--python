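"""Calibrate sampler-derived effect units against biota-derived ones.

The core idea: treat the passive sampler as if it were the organism.
Effect units computed from the disk pseudo-concentration (mass / disk
weight) are regressed, per sorbent, on the effect units computed from
invertebrate tissue.  If the linear relation is tight, the sampler alone
— without calibrated uptake rates and without sacrificing animals —
predicts the biota-side effect unit, and because the effect-unit
denominator (PC_crit x BCF) is known per compound, the internal tissue
concentration can be back-calculated from the prediction.

Model quality is reported as in-sample mean error (predicted minus
observed, identically ~0 for an OLS with intercept — reported for
transparency), and honestly via seeded k-fold cross-validation (k=5,
matching the small campaign datasets), on both the log10 effect-unit
scale and the back-calculated ng/g scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .campaign_io import CompoundRecord, month_of
from .risk_engine import (
    DEFAULT_THRESHOLDS,
    RiskThresholds,
    effect_unit,
    eu_denominator_ng_g,
    internal_ec50,
    psd_pseudo_concentration,
    select_worst_case_bcf,
    toxic_unit,
)
from .sampler_kinetics import theoretical_disk_mass

__all__ = [
    "CalibrationFit",
    "CvReport",
    "eu_pairs",
    "eu_calibration",
    "kfold_validate",
    "predict_internal_concentration",
    "tu_crosscheck",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Per-sorbent linear model EU_biota ~ EU_psd with error summaries.

    ``mean_error``/``error_sd``/``ci95`` are in log10 effect-unit units,
    sign convention predicted - observed; the 95% CI is the normal
    approximation mean +- 1.96 sd/sqrt(n) (``t_ci95`` uses Student's t
    for small n).
    """

    sorbent: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    mean_error: float
    error_sd: float
    ci95: tuple[float, float]
    t_ci95: tuple[float, float]
    residuals: pd.DataFrame  # per-pair: compound_id, month, eu_psd, eu_biota, residual

    def predict(self, eu_psd) -> np.ndarray:
        return self.slope * np.asarray(eu_psd, dtype=float) + self.intercept


@dataclass(frozen=True)
class CvReport:
    """k-fold cross-validation of the effect-unit calibration.

    Errors are predicted - observed on the held-out fold, reported both in
    log10 EU units and back-calculated to tissue concentration (ng/g)
    through each pair's own denominator.
    """

    k: int
    seed: int
    fold_sizes: tuple[int, ...]
    fold_mean_errors_eu: tuple[float, ...]
    fold_mean_errors_ng_g: tuple[float, ...]
    mean_error_eu: float
    sd_eu: float
    ci95_eu: tuple[float, float]
    mean_error_ng_g: float
    sd_ng_g: float
    ci95_ng_g: tuple[float, float]


def _normal_ci(mean: float, sd: float, n: int) -> tuple[float, float]:
    half = 1.96 * sd / math.sqrt(n) if n > 0 else float("nan")
    return (mean - half, mean + half)


# --------------------------------------------------------------------------
# pairing
# --------------------------------------------------------------------------


def eu_pairs(
    measurements: pd.DataFrame,
    compounds: Iterable[CompoundRecord],
    sorbent: str,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Paired sampler/biota effect units per compound x month for one sorbent.

    Monthly-mean quantified disk masses go through the
    sampler-as-organism pseudo-concentration; monthly-mean tissue
    concentrations are used directly.  Only compounds with PC_crit (and
    BCF under the default denominator) enter.  Columns: ``compound_id,
    month, eu_psd, eu_biota, denominator_ng_g``.
    """
    by_id = {c.compound_id: c for c in compounds}
    matrix = f"psd_{sorbent}"
    quant = measurements[measurements["censor"] == "quantified"].copy()
    quant["month"] = quant["timepoint"].map(month_of)
    means = (
        quant[quant["matrix"].isin([matrix, "biota"])]
        .groupby(["compound_id", "month", "matrix"])["value"]
        .mean()
        .unstack()
    )
    if matrix not in means.columns or "biota" not in means.columns:
        return pd.DataFrame(
            columns=["compound_id", "month", "eu_psd", "eu_biota", "denominator_ng_g"]
        )
    paired = means[[matrix, "biota"]].dropna().reset_index()

    rows = []
    for _, row in paired.iterrows():
        rec = by_id.get(row["compound_id"])
        if rec is None or rec.pc_crit_mg_l is None:
            continue
        bcf = select_worst_case_bcf(rec.bcf_candidates) if rec.bcf_candidates else None
        if thresholds.eu_denominator == "pc_crit_times_bcf" and bcf is None:
            continue
        mass, c_biota = float(row[matrix]), float(row["biota"])
        if mass <= 0 or c_biota <= 0:
            continue
        pseudo = psd_pseudo_concentration(mass, thresholds.disk_mass_g)
        rows.append(
            {
                "compound_id": row["compound_id"],
                "month": row["month"],
                "eu_psd": effect_unit(pseudo, rec.pc_crit_mg_l, bcf or 1.0, thresholds),
                "eu_biota": effect_unit(
                    c_biota, rec.pc_crit_mg_l, bcf or 1.0, thresholds
                ),
                "denominator_ng_g": eu_denominator_ng_g(
                    rec.pc_crit_mg_l, bcf or 1.0, thresholds.eu_denominator
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["compound_id", "month", "eu_psd", "eu_biota", "denominator_ng_g"]
    )


# --------------------------------------------------------------------------
# calibration and validation
# --------------------------------------------------------------------------


def eu_calibration(
    eu_psd: Sequence[float],
    eu_biota: Sequence[float],
    sorbent: str = "",
    pair_index: pd.DataFrame | None = None,
) -> CalibrationFit:
    """Fit EU_biota = slope * EU_psd + intercept by OLS.

    ``pair_index`` (optional, columns compound_id/month aligned with the
    value arrays) labels the per-pair residual table.
    """
    x = np.asarray(eu_psd, dtype=float)
    y = np.asarray(eu_biota, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need >= 3 aligned EU pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: sampler EUs have no variance")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    errors = pred - y
    mean_error = float(np.mean(errors))
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    n = int(x.size)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    half_t = tcrit * sd / math.sqrt(n)
    resid = pd.DataFrame(
        {
            "eu_psd": x,
            "eu_biota": y,
            "residual": errors,
        }
    )
    if pair_index is not None:
        resid.insert(0, "compound_id", pair_index["compound_id"].to_numpy())
        resid.insert(1, "month", pair_index["month"].to_numpy())
    return CalibrationFit(
        sorbent=sorbent,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=n,
        mean_error=mean_error,
        error_sd=sd,
        ci95=_normal_ci(mean_error, sd, n),
        t_ci95=(mean_error - half_t, mean_error + half_t),
        residuals=resid,
    )


def kfold_validate(
    pairs: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
) -> CvReport:
    """Seeded k-fold cross-validation of the EU calibration.

    ``pairs`` must have columns ``eu_psd, eu_biota, denominator_ng_g``.
    Folds are a uniform shuffle (sizes differing by at most one, every
    pair in exactly one validation fold).  Each fold's model is fit on the
    other k-1 folds and evaluated on the held-out pairs.
    """
    n = len(pairs)
    if n < k:
        raise ValueError(f"need at least k={k} pairs (got {n})")
    x = pairs["eu_psd"].to_numpy(dtype=float)
    y = pairs["eu_biota"].to_numpy(dtype=float)
    denom = pairs["denominator_ng_g"].to_numpy(dtype=float)

    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_sizes, fold_eu, fold_ng = [], [], []
    all_eu_err, all_ng_err = [], []
    for train, test in splitter.split(x):
        res = stats.linregress(x[train], y[train])
        pred = res.slope * x[test] + res.intercept
        err_eu = pred - y[test]
        c_pred = 10.0**pred * denom[test]
        c_obs = 10.0 ** y[test] * denom[test]
        err_ng = c_pred - c_obs
        fold_sizes.append(len(test))
        fold_eu.append(float(np.mean(err_eu)))
        fold_ng.append(float(np.mean(err_ng)))
        all_eu_err.extend(err_eu)
        all_ng_err.extend(err_ng)

    all_eu_err = np.asarray(all_eu_err)
    all_ng_err = np.asarray(all_ng_err)
    mean_eu, sd_eu = float(np.mean(all_eu_err)), float(np.std(all_eu_err, ddof=1))
    mean_ng, sd_ng = float(np.mean(all_ng_err)), float(np.std(all_ng_err, ddof=1))
    return CvReport(
        k=k,
        seed=seed,
        fold_sizes=tuple(fold_sizes),
        fold_mean_errors_eu=tuple(fold_eu),
        fold_mean_errors_ng_g=tuple(fold_ng),
        mean_error_eu=mean_eu,
        sd_eu=sd_eu,
        ci95_eu=_normal_ci(mean_eu, sd_eu, n),
        mean_error_ng_g=mean_ng,
        sd_ng_g=sd_ng,
        ci95_ng_g=_normal_ci(mean_ng, sd_ng, n),
    )


def predict_internal_concentration(
    eu_pred: float,
    pc_crit_mg_l: float,
    bcf_l_kg: float,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Back-calculate the tissue concentration (ng/g) from a predicted log10 EU.

    Exact inverse of :func:`psdrisk.risk_engine.effect_unit` under the
    configured denominator form: ``c = 10^eu * denominator``.
    """
    denom = eu_denominator_ng_g(pc_crit_mg_l, bcf_l_kg, thresholds.eu_denominator)
    return 10.0**eu_pred * denom


# --------------------------------------------------------------------------
# toxic-unit cross-check across matrices
# --------------------------------------------------------------------------


def tu_crosscheck(
    compound: CompoundRecord,
    tissue_ng_g: float,
    water_ng_l: float,
    disk_masses_ng: dict[str, float] | None = None,
    duration_days: float = 7.0,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Compare log10 TU routes and their threshold classifications.

    Routes:

    * ``tissue`` — measured tissue concentration over EC50_int (the
      reference classification);
    * ``water`` — dissolved concentration over the *unadjusted* EC50
      (both on the ug/L scale), the conventional water-only assessment;
    * ``psd_<sorbent>`` — measured disk mass via the sampler-as-organism
      pseudo-concentration;
    * ``psd_theoretical_<sorbent>`` — disk mass reconstructed from the
      water concentration via the calibrated Rs (used when no sampler was
      physically deployed).

    Returns one row per route with the log10 TU, whether it exceeds the
    -3.0 threshold, and whether that classification agrees with the
    tissue route.  Routes missing constants (e.g. no Rs for a sorbent)
    are omitted.
    """
    if not (compound.ec50_ug_l and compound.bcf_candidates):
        raise ValueError(
            f"{compound.compound_id}: tu_crosscheck needs EC50 and BCF"
        )
    bcf = select_worst_case_bcf(compound.bcf_candidates)
    ec50_int = internal_ec50(compound.ec50_ug_l, bcf)

    rows: list[dict] = []

    def add(route: str, matrix: str, log_tu: float) -> None:
        rows.append(
            {
                "route": route,
                "matrix": matrix,
                "log_tu": log_tu,
                "exceeds_threshold": log_tu > thresholds.tu_log_threshold,
            }
        )

    tu_tissue, _ = toxic_unit(tissue_ng_g, ec50_int, thresholds)
    add("tissue", "biota", tu_tissue)

    water_ug_l = water_ng_l / 1e3
    if water_ug_l > 0:
        add("water", "water", math.log10(water_ug_l / compound.ec50_ug_l))

    for sorbent, mass in (disk_masses_ng or {}).items():
        if mass > 0:
            pseudo = psd_pseudo_concentration(mass, thresholds.disk_mass_g)
            add(f"psd_{sorbent}", f"psd_{sorbent}", toxic_unit(pseudo, ec50_int)[0])

    for sorbent, rs in compound.rs.items():
        mass = theoretical_disk_mass(water_ng_l, rs, duration_days)
        if mass > 0:
            pseudo = psd_pseudo_concentration(mass, thresholds.disk_mass_g)
            add(
                f"psd_theoretical_{sorbent}",
                f"psd_{sorbent}",
                toxic_unit(pseudo, ec50_int)[0],
            )

    df = pd.DataFrame(rows)
    tissue_exceeds = bool(df.loc[df["route"] == "tissue", "exceeds_threshold"].iloc[0])
    df["agrees_with_tissue"] = df["exceeds_threshold"] == tissue_exceeds
    return df
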