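import pandas as pd
import pytest

from psdrisk.campaign_io import CompoundRecord, measurements_frame, Measurement


@pytest.fixture
def imidacloprid() -> CompoundRecord:
    """A neonicotinoid-like pesticide with the constants every route needs.

    PNEC 6.8 ng/L; EC50 20 ug/L x worst-case BCF 10 -> EC50_int 200 ng/g;
    calibrated Rs on the anion/cation sorbents only (no HLB value).
    """
    return CompoundRecord(
        compound_id="imidacloprid",
        name="imidacloprid",
        chem_class="pesticide",
        pnec_ng_l=6.8,
        ec50_ug_l=20.0,
        bcf_candidates=(10.0, 7.0),
        rs={"anion": 0.048, "cation": 0.052},
        lod={"water": 1.0, "psd_hlb": 0.004, "psd_anion": 0.004,
             "psd_cation": 0.004, "biota": 1.0},
        loq={"water": 3.0, "psd_hlb": 0.012, "psd_anion": 0.012,
             "psd_cation": 0.012, "biota": 3.8},
    )


@pytest.fixture
def citalopram() -> CompoundRecord:
    """A pharmaceutical scored through the PC_crit effect-unit route."""
    return CompoundRecord(
        compound_id="citalopram",
        name="citalopram",
        chem_class="pharmaceutical",
        pc_crit_mg_l=1.4e-4,
        bcf_candidates=(1443.0,),
        rs={"hlb": 0.03, "anion": 0.03, "cation": 0.03},
    )


def frame(rows) -> pd.DataFrame:
    """Measurement DataFrame from (cid, matrix, month, rep, value, censor) tuples."""
    return measurements_frame(
        Measurement(cid, matrix, month, rep, value, censor)
        for cid, matrix, month, rep, value, censor in rows
    )


@pytest.fixture
def tiny_campaign(imidacloprid, citalopram):
    """Two compounds x two months across water, one sorbent, and biota."""
    rows = [
        ("imidacloprid", "water", "2021-07", 1, 60.0, "quantified"),
        ("imidacloprid", "water", "2021-07", 2, 72.0, "quantified"),
        ("imidacloprid", "water", "2021-09", 1, 89.0, "quantified"),
        ("imidacloprid", "psd_anion", "2021-07", 1, 22.0, "quantified"),
        ("imidacloprid", "psd_anion", "2021-09", 1, 30.0, "quantified"),
        ("imidacloprid", "biota", "2021-07", 1, 63.0, "quantified"),
        ("imidacloprid", "biota", "2021-09", 1, 70.0, "quantified"),
        ("citalopram", "water", "2021-07", 1, None, "detected_below_loq"),
        ("citalopram", "psd_anion", "2021-07", 1, 0.9, "quantified"),
        ("citalopram", "biota", "2021-07", 1, 101.0, "quantified"),
        ("citalopram", "biota", "2021-09", 1, None, "not_detected"),
    ]
    return frame(rows), [imidacloprid, citalopram]
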