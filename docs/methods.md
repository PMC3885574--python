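# Methods

## Thermogram model

A plasma thermogram is modelled as a mass-fraction-weighted sum of
independent two-state (native ⇌ denatured) transitions.  For a transition
with midpoint T_m (°C), van't Hoff enthalpy ΔH_vH (cal/mol) and
calorimetric enthalpy ΔH_cal (cal per gram of the component),

    K(T)  = exp(−(ΔH_vH/R)(1/T − 1/T_m,K)),   R = 1.987 cal/(mol·K)
    Cp(T) = ΔH_cal · (ΔH_vH / R T²) · K/(1+K)²

with T in kelvin.  The curve integrates to ΔH_cal, peaks at
ΔH_cal·ΔH_vH/(4 R T_m²), and has FWHM ≈ 3.526·R·T_m²/ΔH_vH.  The 1/T²
prefactor pulls the argmax ≈ 0.06 °C below T_m and skews the flanks by a
few percent — within one step of the 0.1 °C analysis grid.  Numerically
K/(1+K)² is evaluated as 1/(4 cosh²(x/2)), which cannot overflow for any
realistic enthalpy.

### Default control mixture

Five components emulate the abundant-protein composition of healthy
plasma (fractions of total protein mass; areas in cal/g of plasma
protein):

| component | T_m (°C) | ΔH_vH (cal/mol) | area (cal/g) | mass fraction |
| --- | --- | --- | --- | --- |
| fibrinogen-like | 55.0 | 200,000 | 0.26 | 0.06 |
| albumin (primary) | 62.2 | 160,000 | 2.45 | 0.55 |
| globulins (secondary) | 70.0 | 120,000 | 1.50 | 0.24 |
| transferrin/IgA shoulder | 75.5 | 140,000 | 0.35 | 0.08 |
| IgG/IgM shoulder | 79.0 | 250,000 | 0.38 | 0.07 |

The parameters were fixed once, numerically, so that the *processed*
control profile lands on the published healthy-plasma anchors: total area
≈ 4.94 cal/g, first-moment temperature ≈ 66.3 °C, peak maximum 62.2 °C,
primary/secondary amplitude ratio ≈ 2.2, width ≈ 5.4 °C.  The two edge
transitions are deliberately sharp (large ΔH_vH) so the 45–50 and
85–90 °C baseline anchor windows see near-zero true signal; otherwise the
linear baseline fit would eat real area.

### Disease model

Two knobs transform the control mixture into a disease group:

* `albumin_shift` (°C) — thermal stabilisation of the primary transition,
  added to its T_m;
* `redistribution` ∈ [0, 1) — the fraction of primary mass that leaves
  the free-albumin transition and reappears as a **stabilised-complex**
  transition at `T_m(secondary) + albumin_shift` with a broader
  ΔH_vH = 90,000 cal/mol (heterogeneous ligated species).

With both zero the disease generator is *exactly* the control generator.
The complex mechanism (rather than piling moved mass onto the fixed
70 °C species) makes the positive lobe of the disease-minus-control
difference curve both grow and move to higher temperature with burden,
and it is what lets the half-height width increase strictly across the
progression; mass moved onto a fixed secondary cannot outrun the
left-edge loss caused by shifting the primary.

Group defaults (shift °C / redistribution): control 0/0, LSIL 1.5/0.12,
HSIL 1.5/0.22, Stage I 2.5/0.38, Stage II–IV 3.5/0.55 — monotone in
burden.  Default group sizes follow the study cohort (4/3/29/14/21).

### Instrument nuisances

Scans are simulated on 20–110 °C at 0.1 °C.  Each scan (sample and
buffer independently) draws a linear baseline: offset 0.05 ± U(±0.05)
cal/(°C·g), slope 0.001 ± U(±0.001) cal/(°C²·g), plus i.i.d. Gaussian
noise of SD 0.005 cal/(°C·g).  No quantitative noise model is published
for this instrument class; these values give group-variance curves that
are small for controls and leave all calibration margins intact, and they
are stated here as the package's own choice.  Raw records are scaled to
absolute heat capacity by the in-cell protein mass (concentration ×
135 µL sensing volume; default 2.8 g/L, i.e. 25-fold-diluted plasma), so
normalisation is a genuine inverse operation.  Scan-rate dependence,
feedback-mode effects and post-envelope aggregation exotherms are not
modelled.

## Preprocessing

Fixed order, enforced by a stage tag on every record:
`raw → reference_subtracted → normalized → baseline_corrected → final`.

1. **Reference subtraction** — buffer scan linearly interpolated onto the
   sample grid and subtracted; the overlap must cover 45–90 °C.
2. **Concentration normalisation** — division by protein mass
   (g/L × cell volume); yields cal/(°C·g).
3. **Linear baseline** — least-squares line through the points of two
   anchor windows (defaults 45–50 and 85–90 °C; both configurable but
   required to avoid 55–80 °C), subtracted everywhere.
4. **Truncation/resampling** — linear interpolation onto the common
   45.0–90.0 °C, 0.1 °C grid.

Duplicate scans of one sample are averaged after the final stage (the
combination rule for duplicates is not published; averaging final-stage
curves keeps one value per sample in all group statistics).  All
interpolation is linear — monotone, parameter-free and exact at 0.1 °C
resolution for these smooth profiles.

## Shape metrics

Eight metrics per final thermogram: trapezoidal **area**; global maximum
**height**; **width** at half the global maximum, measured between the
first and last half-height crossings (linear interpolation between
bracketing grid points) so that multimodal disease envelopes get their
full span; **T_max** (argmax; ties broken to the lowest temperature);
**T_FM**, the area centroid (trapezoidal moments); window amplitudes
**C_p(Peak 1)** = max on 60–65 °C and **C_p(Peak 2)** = max on 68–72 °C
(window maxima rather than fixed-temperature reads, robust to ±0.5 °C
drift); and their **ratio**.  Height is the global maximum, not
C_p(Peak 1): the two coincide for controls but can differ slightly for
advanced disease.  A non-positive secondary amplitude leaves the ratio
NaN with a warning; an all-zero curve raises.

## Group statistics

Pointwise group mean and (n−1)-SD curves; difference curves against the
control mean; box summaries at the 1/5/25/50/75/95/99 percentiles
(numpy's linear interpolation convention, which reproduces the
closest-rank worked values, e.g. p25 of 1..100 = 25.75); and a
Mann–Whitney U test per metric per group pair.  U counts pairs with
x > y plus half-ties.  `auto` mode enumerates the exact permutation null
when C(n_x+n_y, n_x) ≤ 20,000 and the pooled data are tie-free, else
uses the normal approximation with tie and continuity corrections (both
modes exposed; which one the original tables used is not stated).  Raw
p-values are reported — no multiplicity correction by default, with a
Benjamini–Hochberg option off by default.  Pairs are ordered control vs
each disease group, then within-disease pairs.

## Peptidome pipeline

Spectra are profile-mode peak lists on 900–3000 m/z.  The chemical
baseline is estimated by a moving minimum followed by a moving average
(default 50 m/z window) and subtracted, negatives clipped.  This
operator leaves a small positive noise floor in empty regions (the
moving minimum sits below the noise mean); consequently per-peak
quantities use a **peak cluster**: the target 1-m/z bin ± 1 bin, minus a
per-sample local background (median of bins 3–6 away on each side).
Binning sums intensities into half-open [edge, edge+width) bins — edge
points go up — conserving in-range intensity exactly; shared binning is
also the alignment step (no warping).  Replicate spots are averaged
element-wise.

Scaling: mean-centring or Pareto (centred columns divided by √SD;
zero-variance columns left centred).  PCA by SVD with each component's
sign fixed so its largest-magnitude loading is positive.  Discriminant
PCA is the classic PCA-DA construction: Fisher LDA axes (generalised
eigenproblem, ridge-regularised within-scatter) on the retained scores;
`n_pcs` defaults to min(10, n − groups − 1).  Reported purity is the
in-sample nearest-centroid agreement; because in-sample purity flatters
random labels at n ≈ 12, a leave-one-out variant (`cross_validate=True`)
is provided and is the appropriate chance-level control for permutation
checks.  Differential testing is the unpaired two-tailed pooled-variance
t-test per bin (p < 0.05), with a one-way F variant for the three-group
comparison; identical constant bins give p = 1.

Pattern calls order groups by mean cluster intensity: groups below 10%
of the top group are "Absent in G"; adjacent groups within 0.7 on the
log2 scale are joined "=", else ">".  Tied runs are re-ordered by a fixed
priority (Cerv Ca, CIN 2, Control) so calls are deterministic.

### MALDI generator

Planted marker panel: 15 masses with group-mean intensities realising
each pattern (absent = 0; "=" equal; ">" ≥ ~2.4-fold).  Per sample a
lognormal biological factor (σ = 0.25) scales every peak; per spot a
lognormal factor (σ = 0.10) scales the whole spectrum; peaks are
Gaussian (σ = 0.25 Th) on a 0.5 Th grid; 200 nuisance peaks (lognormal
amplitudes around 60) are drawn once per cohort, shared by all groups,
and kept ≥ 4 m/z from every planted mass so marker clusters remain
interpretable; a chemical baseline 20·exp(−(m/z−900)/400) and Gaussian
noise (SD 2, clipped at 0) complete the spectrum.

## What the generators do and do not show

The synthetic cohorts reproduce the *statistical structure* the analyses
assume — multi-transition thermograms with a progressive stabilisation
trend; spectra with group-structured markers over shared nuisance — so a
green test suite demonstrates that the pipelines recover planted effects
of realistic size under realistic noise, with calibrated type-I error.
It does not demonstrate performance on real patient data: real plasma
has correlated inter-protein variation, hemolysis/handling artefacts,
m/z-dependent peak widths and calibration drift, isotope envelopes, and
disease effects that are not a clean two-parameter family.

## Problem sizes and determinism

Default verification scenarios: trend cohort 20 samples/group (100
scans), control calibration 8 samples, peptidome cohort 3 × 4 samples ×
3 spots, null calibration 1000 features at n = 30 per arm (large enough
that the asymptotic U test attains its nominal level despite the
discrete null).  Every stochastic step is a pure function of an integer
seed; cohort members draw from per-sample substreams so subsetting a
cohort does not change the samples kept.

## Known limitations

* The linear baseline removes a small amount of true signal wherever the
  mixture has mass in the anchor windows; with the default composition
  this bias is < 1% of area.
* Width at half height is a discontinuous functional near the point
  where a secondary mode crosses half of the global maximum; group
  medians are stable but single samples near the transition can jump.
* The exact Mann–Whitney branch requires tie-free data; with ties the
  corrected normal approximation is used regardless of mode.
* Pattern calls on 4-sample groups carry ~1-in-30 per-panel miscall
  rates from biological sampling noise alone; calls on larger cohorts
  stabilise.
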