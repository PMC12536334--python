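"""Synthetic monitoring campaigns with known ground truth.

Emulates a monthly multi-matrix river campaign: grab water samples with
log-normal analytical/environmental noise and an optional linear seasonal
trend; first-order integrative sampler uptake over 7-day deployments on
three sorbent chemistries; invertebrate tissue concentrations proportional
to water through an apparent bioconcentration factor; LOD/LOQ censoring;
and sporadic blank contamination.  Every generated observation is
recomputable from the seed, and the returned :class:`SyntheticTruth`
carries the realized water series and true parameters so estimator
recovery can be verified exactly.

Unit note: the apparent biota factor ``bcf_app`` is in L/kg, so tissue
concentration is ``bcf_app * C_water / 1000`` ng/g (ng/L x L/kg = ng/kg).

The sampler integrates the *realized* water series over the deployment
window (the mean of that month's realized water replicate values), not the
nominal monthly mean — this keeps the TWA relationship exact in the
noiseless limit.  Biota uptake is instantaneous proportionality, with no
toxicokinetic lag; see docs/methods.md for what this simplification does
and does not let a green test establish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .campaign_io import (
    MATRIX_UNITS,
    MEASUREMENT_COLUMNS,
    SORBENTS,
    CompoundRecord,
)

__all__ = [
    "CompoundTruth",
    "CampaignConfig",
    "SyntheticTruth",
    "generate_campaign",
    "generate_calibration_series",
    "scenario_presets",
    "get_preset",
]

DEFAULT_MONTHS = ("2021-07", "2021-08", "2021-09", "2021-10", "2021-11", "2021-12")


@dataclass(frozen=True)
class CompoundTruth:
    """Ground-truth parameters of one simulated compound."""

    compound_id: str
    chem_class: str = "pharmaceutical"
    water_mean_ng_l: float = 100.0
    trend_ng_l_per_month: float = 0.0
    rs_true: Mapping[str, float] = field(default_factory=dict)  # sorbent -> L/day
    bcf_app_l_kg: float = 500.0
    pnec_ng_l: float | None = None
    ec50_ug_l: float | None = None
    bcf_candidates: tuple[float, ...] = ()
    pc_crit_mg_l: float | None = None


@dataclass(frozen=True)
class CampaignConfig:
    """Full specification of a simulated campaign.

    Noise parameters are log-normal sigmas (natural-log scale); LOD/LOQ
    are per matrix in that matrix's unit; ``blank_prob`` is the chance of
    a contaminated field blank per compound-month.
    """

    compounds: tuple[CompoundTruth, ...]
    months: tuple[str, ...] = DEFAULT_MONTHS
    n_water_reps: int = 3
    n_psd_reps: int = 3
    n_biota_reps: int = 3
    water_noise_sd: float = 0.0
    sampler_noise_sd: float = 0.0
    biota_noise_sd: float = 0.0
    lod: Mapping[str, float] = field(default_factory=dict)
    loq: Mapping[str, float] = field(default_factory=dict)
    blank_prob: float = 0.0
    deployment_days: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        if not self.compounds:
            errors.append("compounds: at least one compound required")
        if not self.months:
            errors.append("months: at least one month required")
        for name in ("n_water_reps", "n_psd_reps", "n_biota_reps"):
            if getattr(self, name) < 1:
                errors.append(f"{name}: must be >= 1")
        for name in ("water_noise_sd", "sampler_noise_sd", "biota_noise_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name}: must be >= 0")
        if not 0.0 <= self.blank_prob <= 1.0:
            errors.append("blank_prob: must be in [0, 1]")
        if self.deployment_days <= 0:
            errors.append("deployment_days: must be > 0")
        for m in list(self.lod) + list(self.loq):
            if m not in MATRIX_UNITS:
                errors.append(f"lod/loq: unknown matrix {m!r}")
        for c in self.compounds:
            n = len(self.months)
            low = c.water_mean_ng_l + c.trend_ng_l_per_month * (n - 1)
            if c.water_mean_ng_l <= 0 or low <= 0:
                errors.append(
                    f"{c.compound_id}: water mean must stay > 0 over the campaign"
                )
            if c.bcf_app_l_kg <= 0:
                errors.append(f"{c.compound_id}: bcf_app_l_kg must be > 0")
            if any(rs <= 0 for rs in c.rs_true.values()):
                errors.append(f"{c.compound_id}: rs_true values must be > 0")
        if errors:
            raise ValueError("invalid CampaignConfig:\n" + "\n".join(errors))


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to recompute/verify the generated observations."""

    config: CampaignConfig
    water_deployment_means: pd.DataFrame  # compound_id, month, c_ng_l (realized)
    rs_true: dict[str, dict[str, float]]
    bcf_app: dict[str, float]
    censored: tuple[tuple[str, str, str, int], ...]  # (cid, matrix, month, rep)
    contaminated_blanks: tuple[tuple[str, str], ...]  # (cid, month)


def _censor(value: float, matrix: str, config: CampaignConfig) -> tuple[float, str]:
    lod = config.lod.get(matrix)
    loq = config.loq.get(matrix)
    if lod is not None and value < lod:
        return math.nan, "not_detected"
    if loq is not None and value < loq:
        return math.nan, "detected_below_loq"
    return value, "quantified"


def generate_campaign(
    config: CampaignConfig,
) -> tuple[pd.DataFrame, list[CompoundRecord], SyntheticTruth]:
    """Simulate one campaign; deterministic given ``config.seed``.

    Returns the long measurement table (campaign_io conventions), the
    matching compound-property table, and the ground truth.
    """
    config.validate()
    # one root seed, sub-streams per observation family so partial re-runs
    # of one family reproduce
    ss = np.random.SeedSequence(config.seed)
    rng_water, rng_psd, rng_biota, rng_blank = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    rows: list[dict] = []
    means_rows: list[dict] = []
    censored: list[tuple[str, str, str, int]] = []
    contaminated: list[tuple[str, str]] = []

    def emit(cid: str, matrix: str, month: str, rep: int, raw: float) -> None:
        value, censor = _censor(raw, matrix, config)
        if censor != "quantified":
            censored.append((cid, matrix, month, rep))
        rows.append(
            {
                "compound_id": cid,
                "matrix": matrix,
                "timepoint": month,
                "replicate": rep,
                "value": value,
                "censor": censor,
            }
        )

    for c in config.compounds:
        for m_idx, month in enumerate(config.months):
            nominal = c.water_mean_ng_l + c.trend_ng_l_per_month * m_idx
            water = nominal * np.exp(
                rng_water.normal(0.0, config.water_noise_sd, config.n_water_reps)
            )
            deployment_mean = float(np.mean(water))
            means_rows.append(
                {"compound_id": c.compound_id, "month": month, "c_ng_l": deployment_mean}
            )
            for rep, v in enumerate(water, start=1):
                emit(c.compound_id, "water", month, rep, float(v))

            for sorbent, rs in c.rs_true.items():
                base_mass = rs * deployment_mean * config.deployment_days
                masses = base_mass * np.exp(
                    rng_psd.normal(0.0, config.sampler_noise_sd, config.n_psd_reps)
                )
                for rep, v in enumerate(masses, start=1):
                    emit(c.compound_id, f"psd_{sorbent}", month, rep, float(v))

            base_tissue = c.bcf_app_l_kg * deployment_mean / 1e3  # ng/kg -> ng/g
            tissue = base_tissue * np.exp(
                rng_biota.normal(0.0, config.biota_noise_sd, config.n_biota_reps)
            )
            for rep, v in enumerate(tissue, start=1):
                emit(c.compound_id, "biota", month, rep, float(v))

            if config.blank_prob > 0 and rng_blank.random() < config.blank_prob:
                lod_psd = min(
                    (config.lod.get(f"psd_{s}", 0.0) for s in SORBENTS), default=0.0
                )
                contamination = max(2.0 * lod_psd, 0.01)
                rows.append(
                    {
                        "compound_id": c.compound_id,
                        "matrix": "blank_field",
                        "timepoint": month,
                        "replicate": 1,
                        "value": contamination,
                        "censor": "quantified",
                    }
                )
                contaminated.append((c.compound_id, month))

    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    compounds = [_compound_record(c, config) for c in config.compounds]
    truth = SyntheticTruth(
        config=config,
        water_deployment_means=pd.DataFrame(
            means_rows, columns=["compound_id", "month", "c_ng_l"]
        ),
        rs_true={c.compound_id: dict(c.rs_true) for c in config.compounds},
        bcf_app={c.compound_id: c.bcf_app_l_kg for c in config.compounds},
        censored=tuple(censored),
        contaminated_blanks=tuple(contaminated),
    )
    return measurements, compounds, truth


def _compound_record(c: CompoundTruth, config: CampaignConfig) -> CompoundRecord:
    return CompoundRecord(
        compound_id=c.compound_id,
        name=c.compound_id,
        chem_class=c.chem_class,
        pnec_ng_l=c.pnec_ng_l,
        ec50_ug_l=c.ec50_ug_l,
        bcf_candidates=c.bcf_candidates,
        pc_crit_mg_l=c.pc_crit_mg_l,
        rs=dict(c.rs_true),
        lod=dict(config.lod),
        loq=dict(config.loq),
    )


def generate_calibration_series(
    rs_true: float,
    c_lab: float,
    timepoints,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Lab uptake series mass(t) = rs * c_lab * t * exp(eps), eps ~ N(0, sd)."""
    if rs_true <= 0 or c_lab <= 0:
        raise ValueError("rs_true and c_lab must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.sort(np.asarray(timepoints, dtype=float))
    rng = np.random.default_rng(seed)
    mass = rs_true * c_lab * t * np.exp(rng.normal(0.0, noise_sd, t.size))
    return pd.DataFrame({"time_days": t, "mass_ng": mass})


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------


def _wandle_like(seed: int = 0) -> CampaignConfig:
    """A campaign shaped like the six-month urban-river study.

    ~100 compounds (4:1 pharmaceuticals:pesticides) with nominal water
    means spanning the observed 10-1350 ng/L range, three sorbents with
    uptake rates 0.01-0.1 L/day, apparent biota factors 100-2000 L/kg,
    ~20% log-normal noise, realistic LOD/LOQ censoring and sporadic blank
    contamination.
    """
    n = 100
    water_means = np.geomspace(10.0, 1350.0, n)
    pc_crits = np.geomspace(1e-6, 1e-2, n)  # mg/L, spans clopidogrel-like lows
    ec50s = np.geomspace(1.0, 100.0, n)  # ug/L
    pnecs = np.geomspace(5.0, 500.0, n)  # ng/L
    bcf_apps = np.geomspace(100.0, 2000.0, n)
    compounds = []
    for i in range(n):
        is_pesticide = i % 5 == 4
        rs = {
            "hlb": 0.01 + 0.09 * ((i * 7) % n) / n,
            "anion": 0.01 + 0.09 * ((i * 13) % n) / n,
            "cation": 0.01 + 0.09 * ((i * 29) % n) / n,
        }
        compounds.append(
            CompoundTruth(
                compound_id=f"cpd{i:03d}",
                chem_class="pesticide" if is_pesticide else "pharmaceutical",
                water_mean_ng_l=float(water_means[i]),
                trend_ng_l_per_month=-0.02 * float(water_means[i]),
                rs_true=rs,
                bcf_app_l_kg=float(bcf_apps[(i * 17) % n]),
                pnec_ng_l=float(pnecs[(i * 11) % n]),
                ec50_ug_l=float(ec50s[i]) if is_pesticide else None,
                bcf_candidates=(
                    float(bcf_apps[(i * 17) % n]),
                    float(bcf_apps[(i * 17) % n]) * 0.7,
                ),
                pc_crit_mg_l=None if is_pesticide else float(pc_crits[(i * 23) % n]),
            )
        )
    return CampaignConfig(
        compounds=tuple(compounds),
        water_noise_sd=0.2,
        sampler_noise_sd=0.2,
        biota_noise_sd=0.3,
        lod={"water": 1.0, "psd_hlb": 0.004, "psd_anion": 0.004,
             "psd_cation": 0.004, "biota": 1.0},
        loq={"water": 3.0, "psd_hlb": 0.012, "psd_anion": 0.012,
             "psd_cation": 0.012, "biota": 3.8},
        blank_prob=0.02,
        seed=seed,
    )


def _proxy_ideal(seed: int = 0) -> CampaignConfig:
    """Biota and sampler uptake exactly proportional: EU calibration R^2 = 1.

    All compounds share one uptake rate and one apparent biota factor, so
    EU_biota - EU_psd is the same constant for every pair; PC_crit spans
    four orders of magnitude to spread the EU axis.  Zero noise, no
    censoring.
    """
    n = 12
    pc_crits = np.geomspace(1e-6, 1e-2, n)
    water_means = np.geomspace(20.0, 500.0, n)
    compounds = tuple(
        CompoundTruth(
            compound_id=f"pharma{i:02d}",
            chem_class="pharmaceutical",
            water_mean_ng_l=float(water_means[i]),
            rs_true={"hlb": 0.05, "anion": 0.05, "cation": 0.05},
            bcf_app_l_kg=50.0,
            bcf_candidates=(50.0,),
            pc_crit_mg_l=float(pc_crits[i]),
        )
        for i in range(n)
    )
    return CampaignConfig(compounds=compounds, seed=seed)


def _misclassify(seed: int = 0) -> CampaignConfig:
    """Water-only assessment misses the risk; the sampler catches it.

    A single pesticide at 10 ng/L in water: the water-route toxic unit
    (C_water / EC50, unadjusted) sits below -3.0, while the tissue route
    (apparent BCF 100 L/kg -> 1 ng/g over EC50_int = 200 ng/g) and the
    sampler-as-organism route both exceed it.
    """
    compound = CompoundTruth(
        compound_id="pesticide_x",
        chem_class="pesticide",
        water_mean_ng_l=10.0,
        rs_true={"hlb": 0.05, "anion": 0.05, "cation": 0.05},
        bcf_app_l_kg=100.0,
        pnec_ng_l=6.8,
        ec50_ug_l=20.0,
        bcf_candidates=(10.0,),
    )
    return CampaignConfig(compounds=(compound,), seed=seed)


_PRESETS = {
    "wandle_like": _wandle_like,
    "proxy_ideal": _proxy_ideal,
    "misclassify": _misclassify,
}


def scenario_presets(seed: int = 0) -> dict[str, CampaignConfig]:
    """All named preset configurations, built with the given seed."""
    return {name: make(seed) for name, make in _PRESETS.items()}


def get_preset(name: str, seed: int = 0) -> CampaignConfig:
    try:
        return _PRESETS[name](seed)
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
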