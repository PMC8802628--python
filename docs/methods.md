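# Methods

## Scope and data model

The package analyzes TMT reporter-ion quantification at the PSM level
(one row per peptide-spectrum match with per-channel intensities,
isolation specificity, total intensity, a search score and a decoy
flag) for three experimental arms of a target-deconvolution study, and
fits the enzyme-kinetic models used to characterize the resulting
target. Raw spectra, database search and isotope-impurity correction
are upstream of this package; synthetic tables start at reporter
intensities.

## PSM processing

Identification confidence uses classic target-decoy thresholding: the
retained threshold is the smallest score s at which
#decoys(≥s)/#targets(≥s) ≤ the FDR level (default 2%); decoys are then
removed. This is a deliberate simplification of search-engine rescoring
(linear-discriminant or percolator-style), which is out of scope; the
contract preserved is the FDR level itself. Quality gates are exact
inequalities: total reporter intensity > 30,000, isolation specificity
> 0.7, peptide length ≥ 7. Protein summarization is the median of log2
PSM intensities per channel — the aggregator is a design choice (robust
to the Dirichlet-like heterogeneity of peptide response factors); zero
intensities become missing cells rather than −∞, and proteins with all
channels missing are dropped with a count.

Normalization is median alignment: per temperature across conditions
for melting-curve designs (so condition medians coincide at each
temperature), or every channel to the median of channel medians for
single-condition-per-channel designs. Both modes are idempotent.

## Melting curves and ΔTm

Each protein/condition series (≥ 6 of 8 temperatures observed) is fit
with a four-parameter logistic by least squares. Self-start: plateaus
from the 10th/90th abundance percentiles, midpoint at the temperature
nearest their mean, scale from the central-difference slope there; a
second start with the opposite slope sign guards near-flat curves, and
the better SSE wins. Parameters are canonicalized to upper ≥ lower
(the (l,u,m,s) ↔ (u,l,m,−s) symmetry). Failures return
converged=False, never an exception.

Tm is defined at 50% between the fitted intensities at the window
endpoints and computed by analytic inversion:
Tm = m + s·ln((upper − y\*)/(y\* − lower)) with
y\* = (f(T_min)+f(T_max))/2. Undefined (None, distinct from a numerical
failure) when the plateau span is < 0.1 log2 units or y\* saturates at a
plateau. Because a logistic is monotone, a y\* strictly between the
endpoint values always inverts inside the window; the out-of-window
guard is defensive.

The two-curve quality score is
QS = min(R²) · g(|slope_v|) · g(|slope_t|) · exp(−(ln(slope_v/slope_t))²/0.5)
with the saturating gate g(x) = x²/(x²+c²). The published description
of such scores names the ingredients (R², steepness, slope similarity)
but not a formula; this surrogate is smooth, bounded in [0,1], monotone
in each R² and vanishes as either curve flattens. c is calibrated to
25% of the proteome's median |slope at midpoint| (standalone default
0.05 log2/°C).

A definitional subtlety, verified analytically and by the tests: the
generative solubility curve is logistic in *linear* intensity while
fitting happens on log2 values with an endpoint-based Tm, so shallow
transitions compress an injected midpoint shift (a 4 °C shift reads as
~3.2 °C at scale 2 °C/floor 5%, ~3.9 °C at scale 1 °C/floor 2%). The
planted reference target therefore melts sharply (scale 1 °C, floor 2%),
consistent with immunoblot-style melting of the protein it emulates;
background proteins draw scale ~ U(1, 2.5) °C.

## PISA and pull-down statistics

PISA replicates are physical pools over six temperatures in 44–58 °C;
the simulator's expected pooled intensity is the mean of the soluble
fraction over those temperatures, and the differential test is a
two-sided Student's t (equal-variance by default; Welch and paired
modes by option — the pairing convention of the emulated study is
ambiguous, so neither is asserted) on log2 protein abundance, fold
change = difference of group means. No multiple-testing correction is
applied by default, matching the raw-p-value convention of this assay;
the TPP–PISA concordance is a Spearman correlation over proteins above
a quality-score threshold.

The pull-down arm computes three contrasts (probe vs vehicle, probe vs
probe+competitor, probe vs inactive probe) with equal-variance t tests.
"Absent in the negative controls" is operationalized as a ≥ 1 log2
probe-vs-inactive margin rather than literal absence, since reporter
intensities are rarely zero. The specific-binder call requires all
three margins (two with p < α = 0.05). Thresholds are configuration,
not published values.

## Integration

A target call requires complete coverage across arms, ΔTm ≥ 2 °C with
quality ≥ 0.5, and the competition call. The combined rank score is the
sum of per-arm z-scores (ΔTm; competition log2 FC) across the
quantified proteome — affine-invariant per axis, which is the natural
way to rank incommensurate evidence. Raising any threshold can only
remove calls (tested monotonicity). Partial-coverage proteins are
reported, flagged, and never called.

## Kinetics

* **Trace → rate**: linear fit of A340 vs time; specific activity =
  |slope|/(ε·path) · volume / (stoichiometry · mass), with
  ε(NADH) = 6220 M⁻¹cm⁻¹ (standard constant) and stoichiometry 2 NADH
  per FBP for the aldolase/TPI/GPDH chemistry (one per triose
  phosphate), 1 per ADP for PK/LDH. A curvature check (poor linear R²
  plus a halved second-half slope) signals substrate exhaustion.
* **Hill fit**: v = V_max·S^h/(K^h+S^h), scipy least squares with data-
  driven starts, bounds h ∈ [0.1, 20]; standard errors from the fit
  covariance. With h fixed by data near 1 it reproduces a
  Michaelis–Menten fit (tested).
* **EC50/IC50**: four-parameter log-logistic on concentration;
  zero-concentration wells are retained as direct observations of the
  zero-compound asymptote rather than entering a log scale. IC50 fits
  constrain floor ≥ 0 and ceiling ≤ 100 (percent of cells), reject
  responses that *increase* with inhibitor, and flag IC50s outside the
  tested range as extrapolated. Activation fits also report the
  fractional inhibition at zero activator, 1 − v_floor/v_ceiling.
* **Thermal inactivation**: per-condition a₀·e^(−kt) fits; the
  protection contrast k_control − k_ligand gets a two-sided case-
  resampling bootstrap p value (default 500 resamples, add-one
  corrected, seeded).

## Synthetic data

Reporter noise is multiplicative log-normal with unit mean and
configurable CV (default 0.1) — TMT intensity error scales with signal.
A protein's intensity splits across its PSMs by Dirichlet(2) shares.
QC fields: isolation specificity ~ Beta(8,2), peptide lengths uniform
on 6–30, target scores N(3, 0.5²) vs decoy scores N(1, 0.5²), decoy
rows at 2% of the table. Background melting midpoints ~ N(50, 4²) °C
clipped to 40–60; abundances log-normal (median 10⁶). The reporter-
noise CV is a free parameter of the generator, not a published value.
Everything is a pure function of (config, truth, seed).

What the generator does **not** emulate: co-isolation interference
beyond the scalar specificity field, chromatographic/fractionation
effects, missing-value structure of real TMT data, channel bridging
across runs, and search-engine score distributions. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated noise model, not performance on real spectra.

## Reference recovery experiments

`thermotarget.benchmarks` plants published-style ground truths and
re-estimates them end to end. Kinetic fixtures mirror bench practice:
each determination is an independently simulated titration (3
replicate wells, 5% CV) fitted alone; the reported value is the mean
over the stated number of determinations (5–8 for enzymatic constants,
3 donors for cellular IC50s). The TPP benchmark uses 1000 proteins with
one planted +4 °C target; this size keeps a full run in seconds while
leaving > 900 null proteins for calibration checks. Null simulations
(no targets) give uniform PISA/PAL p values (KS-tested) and zero
integrated calls at default thresholds.

## Known limitations

No MWC-style two-state modelling of the PFK1 tetramer or
filament/assembly effects; effector combinations are exercised only as
separate titrations at fixed effector levels. pH enters as per-assay
configuration, not as a response model. The TPP arm reports shifts, not
replicate-level significance. The FDR filter is peptide-level,
classic target-decoy only.
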