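# cfmethyl

A cfDNA-methylation liquid-biopsy pipeline for cancer detection, built for
methods work on droplet-digital methylation-specific PCR (ddMSP) panels.
It covers the full analysis chain of a marker-panel study:

1. **Marker selection** — four top-k conditions on balanced group-mean
   β-values from methylation arrays (common, luminal-dominant and
   TN-dominant hypermethylated loci on a meanNC < 0.05 background), with
   Welch t statistics.
2. **ddMSP quantification** — supervised amplitude-window fitting
   (AUC-maximising lower/upper thresholds on a quantile grid), digital-PCR
   Poisson correction λ = −ln(1 − n_pos/n_total), and conversion to
   copies per ml plasma through the extraction volume chain, plus
   Youden-optimal per-marker positivity cutoffs.
3. **Feature engineering** — the 15 model variables per sample: 12 log10
   marker concentrations, their mean (Mean12), the log10 geometric mean of
   four internal-control amplicons (IC, the total cfDNA concentration),
   and the positive-marker count.
4. **Detection model** — a linear soft-margin SVM detection index with
   exhaustive variable-subset search (2^V − 1 combinations) scored by
   pooled leave-one-out cross-validation AUC under an all-positive-weight
   constraint; the fixed published six-variable model ships as a constant:

       index = 0.62449·[RASGRF1] + 0.78110·[CPXM1] + 0.12115·[HOXA10]
             + 0.36760·[DACH1] + 0.65288·[Mean12] + 2.44704·[IC] − 6.98073

   with a sample called cancer-positive when index > −0.07923 (strict).
5. **Evaluation** — Mann–Whitney ROC/AUC, sensitivity/specificity/PPV/NPV/
   accuracy at the cutoff, stratified train/validation splitting, per-stage
   and per-subtype subgroup analysis, a Jonckheere–Terpstra stage-trend
   test, Kruskal–Wallis across subtypes, and the age-bias correlation.
6. **Synthetic data** — generators for planted array matrices, cohort
   rosters (including the 133 HV / 145 BC study-composition preset) and
   droplet-level ddMSP data with two amplitude clusters, rain, and Poisson
   occupancy, each with a ground-truth manifest.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Score a feature vector with the fixed published model:

```python
from cfmethyl.model import FIXED_PUBLISHED_MODEL

fv = {"RASGRF1": 1.2, "CPXM1": 0.8, "HOXA10": 0.8, "DACH1": 0.8,
      "Mean12": 1.1, "IC": 3.2}
idx = FIXED_PUBLISHED_MODEL.detection_index(fv)
print(f"detection index = {idx:.5f}")
print(f"call            = {'cancer-positive' if FIXED_PUBLISHED_MODEL.classify(idx) else 'negative'}")
```

```
detection index = 3.33323
call            = cancer-positive
```

The index is the weighted sum of the log10 concentrations plus the
intercept; 3.33 is far above the −0.07923 cutoff, so this sample — with a
clearly elevated cfDNA load (IC = 3.2, i.e. ~1600 copies/ml) and methylated
fragments at four markers — is called cancer-positive.

Run the model search end-to-end on a synthetic cohort:

```python
import numpy as np
from cfmethyl import synthetic, ddmsp, features, model
from cfmethyl.panel import DEFAULT_PANEL

cfg = synthetic.small_cohort_config(seed=11)          # 30 HV / 30 BC
roster = synthetic.gen_roster(cfg)
wells, _ = synthetic.gen_droplet_dataset(roster, DEFAULT_PANEL, cfg)
labels = {s: int(c == "BC") for s, c in zip(roster["sample_id"], roster["class"])}

state = ddmsp.fit_quantification(wells, labels)       # thresholds + cutoffs
quants = ddmsp.quantify_cohort(wells, state)          # copies/ml per marker
table = features.build_feature_table(quants)          # 15 variables
y = np.array([labels[s] for s in table.index])

vars6 = list(model.FIXED_PUBLISHED_MODEL.variable_names)
res = model.exhaustive_search(table[vars6], y, vars6)
print(f"combinations scored : {len(res.records)}")
print(f"selected variables  : {res.best.variable_names}")
print(f"training LOOCV AUC  : {res.best_loocv_auc:.3f}")
print(f"all weights positive: {res.constraint_satisfied}")
```

```
combinations scored : 63
selected variables  : ('Mean12',)
training LOOCV AUC  : 0.991
all weights positive: True
```

All 63 subsets of the six candidate variables were scored by pooled-LOOCV
AUC; on this synthetic cohort the mean of the 12 methylation markers alone
separates the classes, and the parsimony tie-break keeps the single-variable
model.

A `cfmethyl` console script exposes the stages
(`simulate`, `select-markers`, `quantify`, `features`, `search`, `score`,
`evaluate`) with `--preset table1_cohort|toy`, `--seed`, `--config`,
`--model-state` and `--fixed-model` options.

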