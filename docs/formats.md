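# File formats

All files are comma-separated UTF-8 with a mandatory header row.  Dates are
ISO-8601 (`YYYY-MM-DD`); months are `YYYY-MM`.  Unknown columns are ignored on
read.  Canonical units are fixed per column and never inferred.

## compounds.csv

One row per compound; `compound_id` must be unique.

| column          | unit    | required | notes |
|-----------------|---------|----------|-------|
| compound_id     | —       | yes      | short key used everywhere else |
| name            | —       | no       | display name |
| chem_class      | —       | no       | one of `pharmaceutical`, `pesticide`, `illicit`, `transformation_product`, `other` |
| pnec_ng_l       | ng/L    | no       | predicted no-effect concentration (risk quotients) |
| ec50_ug_l       | µg/L    | no       | lowest acute 48 h EC50 (toxic units, pesticides) |
| bcf_l_kg        | L/kg    | no       | one value, or several separated by `;` — the highest is used (worst case) |
| pc_crit_mg_l    | mg/L    | no       | predicted critical environmental concentration (effect units, pharmaceuticals) |
| rs_hlb_l_d      | L/day   | no       | calibrated sampling rate, HLB sorbent |
| rs_anion_l_d    | L/day   | no       | sampling rate, mixed-mode anion sorbent |
| rs_cation_l_d   | L/day   | no       | sampling rate, mixed-mode cation sorbent |
| lod_`<matrix>`  | matrix unit | no   | limit of detection, e.g. `lod_water`, `lod_psd_hlb`, `lod_biota` |
| loq_`<matrix>`  | matrix unit | no   | limit of quantification; must be ≥ the matching LOD |

## measurements.csv

Long format, one observation per row.

| column      | notes |
|-------------|-------|
| compound_id | must match compounds.csv |
| matrix      | `water` (ng/L), `psd_hlb` / `psd_anion` / `psd_cation` (ng/disk), `biota` (ng/g), `blank_field` / `blank_extraction` (ng/disk); case-insensitive |
| timepoint   | month `YYYY-MM` or full date |
| replicate   | integer ≥ 1 |
| value       | concentration/mass in the matrix unit; empty iff censored |
| censor      | `quantified` (default), `detected_below_loq`, `not_detected` |

A `quantified` row must carry a value; a censored row must not.

## deployments.csv

| column        | notes |
|---------------|-------|
| sorbent       | `hlb`, `anion`, `cation` |
| start, end    | dates |
| duration_days | numeric; the field study used 7 |

## calibration_series.csv

Laboratory uptake series feeding `calibrate_rs`.

| column      | unit  |
|-------------|-------|
| compound_id | —     |
| sorbent     | —     |
| time_days   | days  |
| mass_ng     | ng/disk |
| c_lab_ng_l  | ng/L (constant per series) |

## Outputs

* `rs_table.csv` — calibrated sampling rates with fit diagnostics
  (compound, sorbent, rs_l_d, fit_r2, n_points, window, valid).
* `risk_report.csv` — one row per compound × matrix × month × metric:
  `compound_id, matrix, month, metric (RQ|TU|EU), value, category,
  exceeds_tu_threshold`.
* `calibration_report.json` — per-sorbent effect-unit calibration fits and
  the k-fold cross-validation report, with the seed used.
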