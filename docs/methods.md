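# Methods

`cfmethyl` re-implements, as a tested pipeline, a cfDNA-methylation
liquid-biopsy workflow for breast-cancer detection: candidate-marker
selection from methylation-array β-values, absolute quantification of
methylated fragments by droplet digital methylation-specific PCR (ddMSP),
construction of a 15-variable feature table, exhaustive variable-subset
selection of a linear-SVM detection model under leave-one-out
cross-validation (LOOCV), and the evaluation statistics around it. A
synthetic-data module generates array, cohort and droplet data with the
statistical structure the analysis assumes, so every stage is testable
without clinical data.

## Marker selection from array data

Group means are computed per probe for non-cancer samples (meanNC), all
tumour samples (meanBC), and the luminal (meanLum) and triple-negative
(meanTN) subtypes. Because cell-line and FFPE strata are differently
represented across subtypes, tumour-group means are *balanced*: the
unweighted average of the cell-line-stratum mean and the FFPE-stratum mean.
meanNC is a plain mean over all non-cancer samples (blood leukocytes,
normal epithelia, non-cancer cell lines) — a cfDNA assay demands markers
unmethylated in blood, so blood belongs in the background pool. Whether the
all-tumour mean should be balanced is genuinely open; we balance it for
symmetry and expose `balanced_bc=False` for the pooled alternative.

Candidates must satisfy meanNC < 0.05 and are then ranked under four
independent conditions: (a) top 20 by meanBC − meanNC, (b) top 20 by lowest
meanNC among probes with meanBC > 0.6, (c) top 50 by meanLum − meanTN,
(d) top 50 by meanTN − meanLum. A probe can appear under several conditions
but counts once in the unique-locus tally; rank ties break by lexicographic
probe id so selection is deterministic and invariant to sample ordering.
Welch's unequal-variance t test annotates each candidate (tumour vs
non-cancer for conditions a/b, luminal vs TN for c/d) via
`scipy.stats.ttest_ind(equal_var=False)`.

## ddMSP quantification

A droplet is positive when its amplitude lies in the half-open window
(lower, upper]; the half-open convention fixes boundary behaviour that the
assay description leaves open. Counts convert to concentrations by the
digital-PCR Poisson estimator λ = −ln(1 − n_pos/n_total), copies in the
measured partitions λ·n_total, and the volume chain

    copies/ml plasma = λ · n_total · (elution / template volume) / plasma volume

with defaults 0.85 nl droplets, 2 µl template per reaction, 20 µl eluate,
0.9 ml plasma. All volumes are configurable. A fully saturated well raises
an error unless the (n_pos − 0.5)/n_total continuity correction is enabled
(the cohort driver enables it). Wells of one sample × marker are pooled
before Poisson correction.

The amplitude window is fitted per marker on training data by maximising
the Mann–Whitney AUC of the per-sample concentrations against the
cancer/healthy labels, over a grid of pooled-amplitude quantiles (64 levels
by default, half uniform and half log-spaced in the upper tail where
positive droplets live). Quantile grids make the fit invariant to any
strictly monotone amplitude rescaling. Exact ties break toward the smallest
lower, then largest upper threshold. Per-marker positivity cutoffs
(copies/ml) maximise the Youden index over midpoints of sorted unique
concentrations. Thresholds and cutoffs persist to a model-state JSON so a
validation cohort is always processed with training-derived values.

**Identifiability caveat.** An AUC objective is invariant under
rank-preserving transforms of the per-sample counts, so it determines the
window only up to per-marker monotone distortion: a window clipping part of
the positive cluster (multiplicative bias) or dipping into the negative
cluster (additive bias) can tie with — or, through label overfitting, beat —
the generative window on training AUC. Absolute accuracy of fitted-window
concentrations is therefore *not* guaranteed by design; what is guaranteed,
and what the tests pin down, is (i) the quantification chain itself —
counting with the true window reproduces manifest concentrations at pooled
Spearman ρ > 0.95 and recovers λ ∈ [0.001, 1] to within 5% in the median —
and (ii) within-marker rank fidelity of fitted-window estimates (median
Spearman ρ > 0.8 on samples with signal). Downstream modelling consumes
log-scale, per-marker-calibrated features, so it is insensitive to these
per-marker distortions.

## Feature table

Fifteen variables per sample: log10(copies/ml + ε) for each of the 12
methylation markers; their mean (Mean12); the log10 geometric mean of the
four internal-control concentrations (IC), each floored at ε — equivalently
the arithmetic mean of the four log10 values, an identity the tests assert
to 1e-12; and the count of methylation-positive markers (Npos). ε defaults
to the concentration equivalent of 0.5 copies per reaction (≈ 5.6 copies/ml
under default volumes) because zero-positive wells are common and the log
must stay finite. Mean12 averages on the log scale for consistency with the
model's other variables; a linear-scale mean sits behind
`mean12_scale="linear"`. Samples missing any of the 16 markers are dropped
with a logged reason; there is no imputation.

## Detection model

The detection index is the decision value of a linear soft-margin SVM
(`sklearn.svm.SVC`, C = 1 by default) over a variable subset; a sample is
called cancer when its index strictly exceeds the decision cutoff. The
fixed published model ships as a constant: variables RASGRF1, CPXM1,
HOXA10, DACH1, Mean12, IC with weights 0.62449, 0.78110, 0.12115, 0.36760,
0.65288, 2.44704, intercept −6.98073 and cutoff −0.07923.

Model selection enumerates every nonempty subset of the supplied variables
(2^V − 1 combinations), scores each by the AUC of pooled LOOCV decision
values, and selects the best-scoring subset whose full-training refit has
strictly positive weights on every variable — hypermethylation or elevated
cfDNA must never argue against a cancer call. Ties resolve toward fewer
variables, then lexicographic subset order. If no subset passes the
positivity constraint the unconstrained best is returned with an explicit
flag. The selected model's decision cutoff is the Youden-optimal point on
its pooled LOOCV scores. The V = 15 search at cohort scale is supported but
is an hours-scale job on one core; tests and examples search reduced
variable sets (V ≤ 10).

Features are z-scored for every fit and the weights and intercept
transformed back to the original log10 scale, so reported coefficients stay
interpretable. This is load-bearing, not cosmetic: log10-concentration
features have small spread around a large offset, which leaves the raw
(w, b) SVM objective nearly flat along the offset direction; fold-to-fold
intercepts then drift with fold class imbalance and pooled LOOCV scores
lose their ranking (we measured a variable with univariate AUC 0.97
dropping to pooled LOOCV AUC ≈ 0 without standardisation).
Standardisation inside LOOCV is fold-local, so nothing leaks from the
held-out sample. `standardize=False` restores the raw-scale fit.

## Evaluation

AUC is the tie-corrected Mann–Whitney statistic. Confusion metrics use the
same strict `score > cutoff` rule as classification. The train/validation
split is stratified by (class, stage); the published-cohort preset fixes
per-stratum training counts so 133 + 145 samples divide into 167 training
and 111 validation. Subgroup tables report n, sensitivity and AUC per stage
bucket (0–I, IIA, IIB–III, metastatic; configurable) and per subtype, with
stage-bucket AUCs computed against the split's own healthy controls (the
alternative — pooling all controls — is flagged in report metadata).
Kruskal–Wallis (across subtypes) and Pearson's age correlation come from
scipy. The Jonckheere–Terpstra trend test across ordered stages is
implemented here (no scipy/statsmodels equivalent): the statistic is the
sum of pairwise Mann–Whitney counts over ordered group pairs, with a
tie-corrected normal approximation and an exact permutation enumeration for
small samples (auto-selected at total n ≤ 12 when under 200 000 distinct
orderings); the default alternative is one-sided, later stage → higher
index.

## Synthetic data

The array generator plants four disjoint probe classes on a low background
(β ≈ 0.02 ± 0.01, clipped to [0, 1]): common class a (β ≈ 0.80 in tumour),
common class b (β ≈ 0.70 with a near-zero non-cancer background, so it wins
the lowest-meanNC condition), and luminal-/TN-dominant classes
(β ≈ 0.85 in the dominant subtype, ≈ 0.02 in the other). Default stratum
sizes mirror a discovery design of a few luminal cell lines, a large
luminal FFPE stratum, many TN cell lines, a smaller TN FFPE stratum, blood
and pooled epithelia. The planted manifest is always emitted and selection
recall/precision against it is 1.0 under strong effects.

The cohort generator reproduces the published cohort composition (133
healthy / 145 cancer; stages 4/47/31/22/9/32 for 0/I/IIA/IIB/III/IV;
subtypes 98/25/10/8/4 luminal/TN/HER2/luminal-HER2/DCIS-unassessed) via
largest-remainder apportionment, uniform ages (22–70 healthy, 36–81
cancer), and 0.9 ml plasma. Total cfDNA is log-normal: log10 copies/ml ~
N(3.0, 0.22) in healthy samples and shifted upward in cancer by a
stage-dependent 0.32–0.60 (sd 0.28) — effect sizes chosen so univariate
AUCs approximate the published ones (each internal control > 0.80, the
internal-control mean ≈ 0.89). Each methylation marker sheds with a
subtype-dependent probability (0.55 for the matching dominant subtype, 0.45
for common markers, 0.15 for the mismatched subtype) at a methylated
fraction of cfDNA that is log-normal around 2% and scales 0.5–2.5× with
stage; healthy samples carry rare (5%) low-level background. Per-marker
single-variable AUCs land in the published 0.56–0.71 band.

Droplets: template copies are Poisson(λ·N) and assigned uniformly to
droplets, so the positive-droplet fraction concentrates on 1 − e^(−λ);
negative and positive amplitude clusters are Gaussian (1000 ± 120,
8000 ± 400) and 10% of positive droplets land uniformly between the
cluster means as "rain". The accepted-droplet count varies well to well
(CV 8% around the nominal 12 000), as on a real droplet reader — without
this variation, windows dipping into the negative cluster would be
AUC-free and the threshold fit unidentifiable. The droplet count and
amplitude scales are conventions, not reported values.

What the generator does *not* emulate: bisulfite-conversion chemistry and
primer efficiency, probe cross-hybridisation, batch effects, age-dependent
methylation drift, correlated shedding across markers beyond the shared
cfDNA load, and real inter-laboratory amplitude variation. Passing tests
therefore demonstrate the pipeline's statistical machinery under the
assumed data structure, not clinical performance.

## Problem sizes used in tests

The published headline numbers were computed on 278 undeposited clinical
samples and are not reproducible from data; tests therefore check worked
examples, structural contracts and designed-recovery properties. The
end-to-end suite runs a reduced preset — 30 healthy / 30 cancer samples,
2 000 droplets per well, search over the six published-model variables —
with the same composition and effect sizes as the full preset; at these
sizes the selected model reaches training LOOCV AUC ≥ 0.9 with all-positive
weights in ≥ 18 of 20 seeded replicates. The full-size preset (278 samples,
12 000 droplets) is exercised for roster and split contracts and is the
default for pipeline runs.

## Known limitations

* The published SVM's regularisation and scaling are unreported, so the
  printed coefficients cannot be regenerated exactly; the fixed model is
  used verbatim and refits are internally consistent instead.
* Fitted amplitude windows are identified only up to per-marker monotone
  distortion (see the quantification caveat above).
* The exact-permutation trend test is limited to small groups; larger
  samples use the normal approximation.
* No probe-type bias correction for array data; β-values are assumed
  normalised upstream.
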