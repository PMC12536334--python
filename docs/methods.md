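# Methods

## The problem

Measuring contaminants of emerging concern (CECs) directly in aquatic
invertebrate tissue is the most faithful record of long-term exposure, but
wild-caught biomonitoring is slow, costly and requires animal sacrifice.
Passive sampler devices (PSDs) — sorbent disks deployed in the water column —
accumulate dissolved chemicals along a diffusion gradient, much as an organism
does.  `psdrisk` implements a complete desk pipeline around that analogy for a
multi-matrix monitoring campaign (grab water samples, multi-sorbent PSDs,
*Gammarus pulex* tissue): uptake-rate calibration and time-weighted-average
(TWA) water concentrations, three risk metrics, cross-matrix occurrence
comparison, and the sampler-as-organism proxy model with cross-validated
calibration against biota.

## Sampler kinetics

In the linear (integrative) phase of first-order uptake, the mass on a disk
after `t` days at water concentration `C` is

    m = Rs · C · t,

with `Rs` (L/day) the sampling rate — the equivalent water volume cleared per
day.  `Rs` is calibrated by OLS of mass on time at a constant lab
concentration (`Rs = slope / C_lab`), with a free intercept so a short lag
phase cannot bias the slope.  A single-pass linear-window rule guards against
the onset of curvature towards equilibrium: the line is also fit to the first
n−1 points, and if the last timepoint deviates from it by more than 3× that
fit's residual standard deviation the point is dropped and the shorter fit
kept.  (The check is leave-last-out because a full fit absorbs a curving
endpoint into its own residual scale and a full-fit rule never fires.)
Non-positive slopes are flagged invalid and unusable downstream.  Field
inversion gives the TWA concentration `C_TWA = m / (Rs · t)`;
`theoretical_disk_mass` is the exact inverse and places literature water data
on the disk-mass scale when no sampler was deployed.

Not modelled: membrane/boundary-layer resistance, the curvilinear
equilibrium-phase regime, and in-situ adjustment of `Rs` for flow or
temperature.  Lab-calibrated `Rs` is assumed transferable to the field, a
known source of cross-site error.

## Risk metrics

* **Risk quotient** `RQ = MEC / PNEC` (both ng/L), banded
  `[0, 0.1)` insignificant, `[0.1, 1)` low, `[1, 10]` medium, `(10, ∞)` high.
  Published band edges are open/closed inconsistently; lower bounds are taken
  inclusive and 10 assigned to medium so the bands partition `[0, ∞)`.  The
  breakpoints are configurable (`RiskThresholds.rq_bands`).
* **Internal toxic unit** (pesticides with acute invertebrate EC50 data):
  `log10 TU = log10(C_invert / EC50_int)`, `EC50_int = EC50 · BCF`
  (µg/L × L/kg = µg/kg ≡ ng/g).  Where several BCF estimates exist the
  highest is used (worst case).  `log10 TU > −3.0` (strictly) marks possible
  adverse effects; exactly −3.0 does not exceed.
* **Internal effect unit** (pharmaceuticals without EC50):
  `log10 EU = log10(C_invert / (PC_crit · BCF))`, where `PC_crit` derives
  from human therapeutic plasma concentrations.  EU has no established effect
  threshold and is used only to rank compounds.

### Effect-unit denominator convention

The denominator is computed as `PC_crit[ng/L] × BCF[L/kg]` and read on the
ng/g scale.  Dimensionally, ng/L × L/kg = ng/kg, so a strict conversion to
ng/g would divide by a further 10³; the ng/L-basis convention is adopted
because it is the one under which the reported effect-unit magnitudes in this
problem domain are reproducible with realistic (~10³ L/kg) bioconcentration
factors.  Since every EU shares the offset, ranking, correlation, calibration
slope/R² and the back-calculated concentrations are all unaffected by the
choice.  An alternative `pc_crit_only` denominator (no internalisation) is
available via `RiskThresholds.eu_denominator`.

### Sampler as organism

The substitution feeds `m_disk / 0.0115 g` (the weight of one 9 mm sorbent
disk) into the TU/EU formulas in place of the tissue concentration.  It is
transparent by construction: when the pseudo-concentration equals the tissue
concentration the scores are identical.  `tu_crosscheck` compares four
classification routes for one compound — tissue (reference), water over
unadjusted EC50, measured disk mass, and theoretical disk mass reconstructed
from water via `Rs` — and reports which routes agree with the tissue verdict
at the −3.0 line.

## Cross-matrix comparison

Detection sets count `quantified ∪ detected_below_loq`; quantification sets
only `quantified`.  Venn regions are exclusive-region cardinalities summing
to the union.  For ordination, replicate profiles (rows = matrix × month ×
replicate, columns = compounds) are zero-filled for censored entries — a
non-detect is a genuine low in an occurrence profile — then min–max scaled
per row to [0, 1] (constant rows map to 0).  PCA is centered, on the
covariance of the scaled data (the covariance-vs-correlation choice after
row scaling is open; covariance is used), with each component's sign fixed so
its largest-magnitude loading is positive.  Hierarchical clustering uses
Euclidean distance with Ward linkage (configurable); both choices are
standard for min–max-scaled chemical profiles and make the tree
deterministic.  Inter-matrix regressions are OLS on compound × month paired
monthly means, with the two-sided slope t-test.

## Proxy calibration

Per sorbent, `EU_biota = a · EU_psd + b` is fit by OLS on compound × month
pairs.  The in-sample mean error (predicted − observed) is identically ~0
for an OLS with intercept and is reported only for transparency; the honest
error estimate is seeded 5-fold cross-validation (small campaign datasets,
n ≈ 20–70, make more folds unstable).  Folds are a uniform shuffle —
stratification by compound is off by default but available — with sizes
differing by at most one.  Held-out errors are reported in log10 EU units
and back-calculated to ng/g through each pair's own denominator
(`c = 10^EU · PC_crit · BCF`), with normal-approximation 95% CIs
(`mean ± 1.96·sd/√n`; a t-based CI is also provided on the full fit).
No pooled multi-sorbent model is fit, and no uncertainty from the `Rs`
calibration is propagated.

## Synthetic campaigns

The generator states a world and sticks to it:

* monthly water concentrations: nominal mean (optionally with a linear
  monthly trend) × log-normal noise per replicate;
* sampler masses: `Rs · W · t` × log-normal noise, where `W` is the mean of
  that month's *realized* water replicates — so the TWA relationship closes
  exactly at zero noise;
* biota: `BCF_app · W / 1000` ng/g × log-normal noise (instantaneous
  proportionality; no toxicokinetic lag — the proxy model only needs
  proportional structure, so a green test establishes linear-calibration
  behaviour, not uptake kinetics in a real amphipod);
* LOD/LOQ censoring per matrix and sporadic quantified field blanks with a
  stated per-compound-month probability.

All randomness flows from one seed through per-family substreams
(`numpy` `SeedSequence.spawn`), so tables are byte-identical across runs.

Presets:

* `wandle_like` — 100 compounds (4:1 pharmaceuticals:pesticides), nominal
  water means spanning 10–1350 ng/L (the range observed in a heavily
  wastewater-impacted urban river), 7-day deployments on three sorbents with
  `Rs` 0.01–0.1 L/day, apparent biota factors 100–2000 L/kg, ~20–30%
  log-normal noise, LOD/LOQ censoring, 2% blank contamination.  Parameter
  spreads are deterministic (geometric grids), not drawn.
* `proxy_ideal` — all compounds share one `Rs` and one `BCF_app`, zero
  noise: `EU_biota − EU_psd` is one constant, so the calibration is exact
  (slope 1, R² = 1) by construction.
* `misclassify` — one pesticide at 10 ng/L: the water-route TU
  (log10(0.01/20 µg/L) ≈ −3.3) sits below the −3.0 line while tissue
  (BCF_app 100 L/kg → 1 ng/g over EC50_int 200 ng/g, TU ≈ −2.3) and both
  sampler routes (TU ≈ +0.2) exceed it — the scenario in which a water-only
  assessment calls a bioaccumulating compound safe.  Note the apparent
  accumulation factor (100 L/kg) deliberately differs from the predicted BCF
  used in `EC50_int` (10 L/kg); kinetic accumulation and predicted
  steady-state partitioning are different quantities in real campaigns too.

What the generator does **not** emulate: instrument (LC-MS/MS) error
structure and matrix effects, temperature-dependent bioaccumulation,
organism movement, or between-site variation of `Rs`.

## Numerical conventions

* Censored values never enter concentration or risk arithmetic;
  `detected_below_loq` counts for detection sets only.
* Blank exclusion removes a (compound, month) from all matrices when any
  blank is quantified above that compound's LOD (field and extraction blanks
  treated identically; with no LOD on record, any quantified blank value
  triggers).  The operation is idempotent.
* Replicates are averaged within month before scoring or pairing.
* `twa_agreement` with a single pair reports sd = 0 by convention.
* Sample standard deviations use the n−1 denominator throughout.

## Known limitations

The calibration transfers a statistical association, not a mechanism: a tight
EU fit is driven substantially by the shared per-compound denominator
(`PC_crit · BCF` appears on both axes), so prediction degrades for compounds
whose sampler/biota uptake ratio departs from the campaign's typical value.
Cross-site use inherits every caveat of lab-calibrated `Rs` values.  EU
values rank compounds; they are not a toxicity endpoint.
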