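"""Read, validate and write the tabular campaign data.

All downstream modules assume the conventions enforced here:

* canonical units — aqueous concentrations in ng/L, sorbent-disk loads in
  ng/disk, invertebrate tissue in ng/g, EC50 in ug/L, PC_crit in mg/L,
  BCF in L/kg, sampling rates Rs in L/day;
* censoring — ``not_detected`` rows carry no value and contribute to no
  statistic; ``detected_below_loq`` rows carry no value but count towards
  detection sets; only ``quantified`` rows enter concentration or risk
  arithmetic;
* file dialect — comma-separated UTF-8 with a mandatory header, ISO-8601
  dates, months as ``YYYY-MM``.

CSV schemas are documented in ``docs/formats.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

# --------------------------------------------------------------------------
# unit conversion constants (exact powers of ten)
# --------------------------------------------------------------------------

NG_PER_MG = 1e6
NG_PER_UG = 1e3
UG_PER_MG = 1e3

#: matrices a measurement may come from, with their fixed units
MATRIX_UNITS: dict[str, str] = {
    "water": "ng/L",
    "psd_hlb": "ng/disk",
    "psd_anion": "ng/disk",
    "psd_cation": "ng/disk",
    "biota": "ng/g",
    "blank_field": "ng/disk",
    "blank_extraction": "ng/disk",
}

SORBENTS = ("hlb", "anion", "cation")
PSD_MATRICES = ("psd_hlb", "psd_anion", "psd_cation")
BLANK_MATRICES = ("blank_field", "blank_extraction")

CENSOR_STATES = ("quantified", "detected_below_loq", "not_detected")

CHEM_CLASSES = (
    "pharmaceutical",
    "pesticide",
    "illicit",
    "transformation_product",
    "other",
)

MEASUREMENT_COLUMNS = [
    "compound_id",
    "matrix",
    "timepoint",
    "replicate",
    "value",
    "censor",
]


# --------------------------------------------------------------------------
# domain records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """Per-chemical constants used by the risk and kinetics modules.

    Optional fields are ``None`` (or empty containers) when the study has no
    value for them; operations that need them skip the compound and log it
    rather than fail.
    """

    compound_id: str
    name: str = ""
    chem_class: str = "other"
    pnec_ng_l: float | None = None
    ec50_ug_l: float | None = None
    bcf_candidates: tuple[float, ...] = ()
    pc_crit_mg_l: float | None = None
    rs: Mapping[str, float] = field(default_factory=dict)  # sorbent -> L/day
    lod: Mapping[str, float] = field(default_factory=dict)  # matrix -> limit
    loq: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(
                f"{self.compound_id}: unknown chem_class {self.chem_class!r}"
            )
        for label, v in (
            ("pnec_ng_l", self.pnec_ng_l),
            ("ec50_ug_l", self.ec50_ug_l),
            ("pc_crit_mg_l", self.pc_crit_mg_l),
        ):
            if v is not None and v < 0:
                raise ValueError(f"{self.compound_id}: negative {label}: {v}")
        if any(b <= 0 for b in self.bcf_candidates):
            raise ValueError(f"{self.compound_id}: BCF candidates must be > 0")
        for m in set(self.lod) & set(self.loq):
            if self.loq[m] < self.lod[m]:
                raise ValueError(
                    f"{self.compound_id}: loq < lod for matrix {m!r}"
                )

    @property
    def pc_crit_ng_l(self) -> float | None:
        """PC_crit converted to the canonical aqueous unit (1 mg = 10^6 ng)."""
        if self.pc_crit_mg_l is None:
            return None
        return self.pc_crit_mg_l * NG_PER_MG

    def lod_for(self, matrix: str) -> float | None:
        """LOD for ``matrix``; blank matrices fall back to the sorbent-disk LOD."""
        if matrix in self.lod:
            return self.lod[matrix]
        if matrix in BLANK_MATRICES:
            disk = [self.lod[m] for m in PSD_MATRICES if m in self.lod]
            return min(disk) if disk else None
        return None


@dataclass(frozen=True)
class Measurement:
    """One observation of one compound in one matrix at one timepoint."""

    compound_id: str
    matrix: str
    timepoint: str
    replicate: int
    value: float | None
    censor: str = "quantified"

    def __post_init__(self) -> None:
        if self.matrix not in MATRIX_UNITS:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.censor not in CENSOR_STATES:
            raise ValueError(f"unknown censor state {self.censor!r}")
        has_value = self.value is not None and not math.isnan(self.value)
        if self.censor == "quantified" and not has_value:
            raise ValueError(
                f"{self.compound_id}/{self.matrix}/{self.timepoint}: "
                "quantified measurement without a value"
            )
        if self.censor != "quantified" and has_value:
            raise ValueError(
                f"{self.compound_id}/{self.matrix}/{self.timepoint}: "
                f"censored ({self.censor}) measurement carries a value"
            )
        if has_value and self.value < 0:
            raise ValueError(f"negative measurement value {self.value}")

    @property
    def unit(self) -> str:
        return MATRIX_UNITS[self.matrix]


@dataclass(frozen=True)
class DeploymentRecord:
    """One passive-sampler deployment window (the study used seven days)."""

    sorbent: str
    start: str
    end: str
    duration_days: float = 7.0

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")
        d0, d1 = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if abs((d1 - d0).days - self.duration_days) > 1:
            raise ValueError(
                f"deployment window {self.start}..{self.end} inconsistent "
                f"with duration {self.duration_days} d"
            )


# --------------------------------------------------------------------------
# compound table io
# --------------------------------------------------------------------------

_OPTIONAL_SCALARS = {
    "pnec_ng_l": "pnec_ng_l",
    "ec50_ug_l": "ec50_ug_l",
    "pc_crit_mg_l": "pc_crit_mg_l",
}


def _opt(row: Mapping, col: str) -> float | None:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read ``compounds.csv`` into :class:`CompoundRecord` objects.

    Unknown columns are ignored; missing optional fields become ``None``.
    Duplicate ``compound_id`` rows and negative concentrations are hard
    errors (with the offending row index in the message).
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'compound_id'")
    dup = df["compound_id"][df["compound_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate compound_id(s): {sorted(set(dup))}")

    records: list[CompoundRecord] = []
    for idx, row in df.iterrows():
        kwargs: dict = {"compound_id": row["compound_id"]}
        if "name" in df.columns and isinstance(row.get("name"), str):
            kwargs["name"] = row["name"]
        if "chem_class" in df.columns and isinstance(row.get("chem_class"), str):
            kwargs["chem_class"] = row["chem_class"].strip().lower()
        for col, attr in _OPTIONAL_SCALARS.items():
            v = _opt(row, col)
            if v is not None and v < 0:
                raise ValueError(f"{path}: row {idx}: negative {col}: {v}")
            kwargs[attr] = v
        bcf_raw = row.get("bcf_l_kg")
        if isinstance(bcf_raw, str) and bcf_raw.strip():
            kwargs["bcf_candidates"] = tuple(
                float(x) for x in bcf_raw.split(";") if x.strip()
            )
        elif isinstance(bcf_raw, (int, float)) and not math.isnan(bcf_raw):
            kwargs["bcf_candidates"] = (float(bcf_raw),)
        rs = {}
        for sorbent in SORBENTS:
            v = _opt(row, f"rs_{sorbent}_l_d")
            if v is not None:
                if v < 0:
                    raise ValueError(
                        f"{path}: row {idx}: negative rs_{sorbent}_l_d: {v}"
                    )
                rs[sorbent] = v
        lod, loq = {}, {}
        for matrix in MATRIX_UNITS:
            for mapping, prefix in ((lod, "lod"), (loq, "loq")):
                v = _opt(row, f"{prefix}_{matrix}")
                if v is not None:
                    if v < 0:
                        raise ValueError(
                            f"{path}: row {idx}: negative {prefix}_{matrix}: {v}"
                        )
                    mapping[matrix] = v
        kwargs["rs"], kwargs["lod"], kwargs["loq"] = rs, lod, loq
        records.append(CompoundRecord(**kwargs))
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records back to the ``compounds.csv`` schema (round-trip safe)."""
    rows = []
    for r in records:
        row: dict = {
            "compound_id": r.compound_id,
            "name": r.name,
            "chem_class": r.chem_class,
            "pnec_ng_l": r.pnec_ng_l,
            "ec50_ug_l": r.ec50_ug_l,
            "pc_crit_mg_l": r.pc_crit_mg_l,
            "bcf_l_kg": ";".join(repr(b) for b in r.bcf_candidates) or None,
        }
        for sorbent in SORBENTS:
            row[f"rs_{sorbent}_l_d"] = r.rs.get(sorbent)
        for matrix in MATRIX_UNITS:
            row[f"lod_{matrix}"] = r.lod.get(matrix)
            row[f"loq_{matrix}"] = r.loq.get(matrix)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# measurement table io
# --------------------------------------------------------------------------

_MATRIX_ALIASES = {m.lower(): m for m in MATRIX_UNITS}
_MATRIX_ALIASES.update({"hlb": "psd_hlb", "anion": "psd_anion", "cation": "psd_cation"})


def normalise_matrix(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _MATRIX_ALIASES:
        raise ValueError(f"unknown matrix label {label!r}")
    return _MATRIX_ALIASES[key]


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a long-format ``measurements.csv`` into a validated DataFrame.

    Returns rows in input order with columns ``compound_id, matrix,
    timepoint, replicate, value, censor``.  The ``censor`` column is
    optional in the file (default ``quantified``).  Every row is validated
    through :class:`Measurement`, so the value/censor convention holds on
    the returned frame.
    """
    df = pd.read_csv(path, dtype={"compound_id": str, "timepoint": str})
    missing = {"compound_id", "matrix", "timepoint", "replicate", "value"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "censor" not in df.columns:
        df["censor"] = "quantified"
    df["censor"] = df["censor"].fillna("quantified").astype(str).str.strip().str.lower()
    df["matrix"] = [normalise_matrix(m) for m in df["matrix"]]
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = pd.to_numeric(df["value"])
    for idx, row in df.iterrows():
        try:
            Measurement(
                compound_id=row["compound_id"],
                matrix=row["matrix"],
                timepoint=row["timepoint"],
                replicate=int(row["replicate"]),
                value=None if pd.isna(row["value"]) else float(row["value"]),
                censor=row["censor"],
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
    return df[MEASUREMENT_COLUMNS].reset_index(drop=True)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def measurements_frame(measurements: Iterable[Measurement]) -> pd.DataFrame:
    """Build the canonical measurement DataFrame from row objects."""
    return pd.DataFrame(
        [
            {
                "compound_id": m.compound_id,
                "matrix": m.matrix,
                "timepoint": m.timepoint,
                "replicate": m.replicate,
                "value": math.nan if m.value is None else m.value,
                "censor": m.censor,
            }
            for m in measurements
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def month_of(timepoint: str) -> str:
    """Collapse a timepoint (date or month) to ``YYYY-MM``."""
    return str(timepoint)[:7]


# --------------------------------------------------------------------------
# blank-based exclusion
# --------------------------------------------------------------------------


def apply_blank_exclusion(
    measurements: pd.DataFrame,
    blanks: pd.DataFrame | None = None,
    compounds: Sequence[CompoundRecord] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop every (compound, month) with a contaminated blank from all matrices.

    A blank contaminates when it is *quantified* above the compound's LOD
    for the blank's matrix (field and extraction blanks are treated
    identically).  When no LOD is known for a compound, any quantified
    blank value > 0 triggers exclusion — the conservative reading.
    ``detected_below_loq`` or ``not_detected`` blanks never exclude.

    ``blanks`` defaults to the blank-matrix rows of ``measurements``
    itself.  Returns the filtered frame (blank rows retained) and a sorted
    exclusion log of ``(compound_id, month)`` pairs.  Idempotent.
    """
    if blanks is None:
        blanks = measurements[measurements["matrix"].isin(BLANK_MATRICES)]
    by_id = {c.compound_id: c for c in compounds} if compounds else {}

    excluded: set[tuple[str, str]] = set()
    for _, row in blanks.iterrows():
        if row["censor"] != "quantified":
            continue
        rec = by_id.get(row["compound_id"])
        lod = rec.lod_for(row["matrix"]) if rec is not None else None
        threshold = lod if lod is not None else 0.0
        if float(row["value"]) > threshold:
            excluded.add((row["compound_id"], month_of(row["timepoint"])))

    if not excluded:
        return measurements.copy(), []

    months = measurements["timepoint"].map(month_of)
    is_sample = ~measurements["matrix"].isin(BLANK_MATRICES)
    hit = [
        (cid, m) in excluded
        for cid, m in zip(measurements["compound_id"], months)
    ]
    drop = pd.Series(hit, index=measurements.index) & is_sample
    return measurements[~drop].reset_index(drop=True), sorted(excluded)
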