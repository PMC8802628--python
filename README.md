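# thermotarget

Dual chemoproteomic target deconvolution — thermal proteome profiling
(TPP), proteome integral solubility alteration (PISA) and
photoaffinity-labeling (PAL) competition pull-downs integrated into a
single ranked target call — together with the allosteric enzyme
kinetics used to characterize the identified target, liver-type
phosphofructokinase-1 (PFKL).

## Who this is for

Chemical biologists doing small-molecule target identification with
multiplexed (TMT) quantitative proteomics, and enzymologists fitting
cooperative PFK1 kinetics. Raw mass-spectrometry data are not required:
a first-class synthetic-data generator emulates the statistical
structure of all three proteomic arms with a ground-truth manifest, so
every stage of the pipeline is testable by planted-effect recovery.

## The models

**Melting curves.** Per protein and condition, log2 reporter abundance
vs temperature is fit with a four-parameter logistic

&nbsp;&nbsp;&nbsp;&nbsp;f(T) = lower + (upper − lower) / (1 + exp((T − m)/s)),

and the melting temperature Tm is the temperature at 50% between
f(T_min) and f(T_max), obtained by analytic inversion. ΔTm =
Tm(treated) − Tm(vehicle). A [0,1] quality score combines both curves'
R², steepness and slope similarity. The PISA arm pools the heated
aliquots (44–58 °C) per replicate, so each channel measures the mean of
the soluble-fraction curve; treated-vs-vehicle differences are
Student's t tests on log2 abundance. The PAL arm tests three contrasts
(probe vs vehicle, probe vs probe+competitor, probe vs inactive probe);
a specific binder must be enriched, competed, and unlabeled by the
inactive probe. The integrated call requires ΔTm ≥ 2 °C at quality
≥ 0.5 AND the competition call, ranked by summed per-arm z-scores.

**Kinetics.** F6P saturation follows the Hill equation
v = V_max·S^h/(K^h + S^h); activator relief of ATP inhibition and
cellular dose-response (% NETosis) are ascending/descending
four-parameter log-logistic fits reporting EC50/IC50; thermal
inactivation is first-order decay a₀·e^(−kt) with a bootstrap
ligand-protection contrast; coupled-assay A340 traces convert to
specific activity via ε(NADH) = 6220 M⁻¹cm⁻¹ and the chemistry's
NADH-per-product stoichiometry.

## Worked example

`examples/02_dual_arm_target_call.py` simulates a 300-protein proteome
with one planted dual-evidence target and runs all four stages:

```
protein_id  delta_tm  quality_score  pisa_log2_fc  log2_probe_vs_competition  combined_rank_score  called
 PROT00001      4.19           0.86          0.30                       2.31                22.29    True
 PROT00215      1.09           0.50         -0.00                       0.27                 3.42   False
 ...
Called 1 target(s): ['PROT00001'] (planted: ['PROT00001']).
```

The planted target (true shift +4 °C, 8-fold probe enrichment, 90%
competition) is recovered with ΔTm = 4.19 °C and a competition log2
fold change of 2.31 (expected log2(8/1.7) ≈ 2.23); no background
protein is called. `examples/03_pfk1_kinetics.py` refits simulated
PFKL titrations:

```
F6P saturation: Vmax=12.85 umol/min/mg, K_M=1.90 mM, h=3.48 (truth 13.28 / 1.97 / 3.16)
Activation: EC50=14.6 nM (truth 14.0), ATP inhibition depth at zero activator = 84%
NETosis inhibition: IC50=4.14 nM (truth 4.0), floor=7.2% ceiling=75.6%
```

A thin CLI covers shell use: `thermotarget simulate --seed 1 --out out/`
writes the synthetic PSM tables and channel designs;
`thermotarget run --seed 1 --out out/` executes the configured stages
and writes result TSVs plus a seed/config-hash manifest.

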