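# hspcflow

Reference-based annotation and perturbation analysis for single-cell
RNA-seq of hematopoietic stem and progenitor cells (HSPCs).

## The problem

Early hematopoiesis is a continuous landscape of CD34+ stem and progenitor
states. Studies of how that landscape changes — with age, or in myeloid
malignancies such as myelodysplastic syndromes — need three recurring
computations once a labeled healthy reference exists:

1. **Annotation**: assign every query cell (e.g. from an elderly donor or a
   patient) a reference cell type, or admit it cannot be assigned;
2. **Composition**: test which cell-type proportions shift between
   conditions;
3. **Dynamics and regulation**: detect genes whose expression trends along
   differentiation pseudotime change, and regulons
   (transcription-factor target programs) whose activity pattern changes.

`hspcflow` implements this pipeline as a reusable, tested library, together
with a synthetic-data generator that emulates a CD34+ HSPC landscape
(14 stem→progenitor→committed cell types, negative-binomial UMI counts,
marker genes, mitochondrial content, donor batch effects, doublets, latent
branching pseudotime, regulon activity) so every stage can be validated
against ground truth without any download.

## The core method

The annotation model is a one-vs-rest **elastic-net logistic regression
ensemble**. For each reference cell type, a balanced training set (all
positive cells plus an equal random negative draw, split 75/25) is fitted
over a grid of mixing parameters α ∈ {1, 0.75, 0.5, 0.25, 0.1}, minimizing

    −(1/n) Σᵢ [ yᵢ ηᵢ − log(1 + e^{ηᵢ}) ] + λ ( α‖β‖₁ + (1−α)/2 ‖β‖₂² ),

with λ chosen on a warm-started path by 10-fold cross-validated deviance.
Per α, the best model is selected by a validation cascade — a 20–150
variable window, then max AUC, min FPR, min FNR, max variable count — and
the whole procedure repeats 10 times. Prediction averages the 10 logistic
responses per type; a cell is labeled arg max only if that averaged
probability exceeds 0.5, else **"not assigned"**.

Around it: QC (per-sample gene/UMI ceilings, mitochondrial bounds),
log-normalization (`ln(1 + c·10⁴/L)`), variance-stabilized HVG selection;
pooled two-proportion z-tests with Holm correction for composition shifts;
branch-probability-weighted penalized-spline trends on pseudotime compared
by rank-sum tests on the fitted curves; and regulon analytics (batch
centering, Gaussian-mixture binarization, percent-active summaries,
Jensen–Shannon regulon specificity scores, top-k selection, third-quartile
network trimming). See `docs/methods.md` for the full model description.

## Worked example

The `analysis/` scripts run the whole study on simulated data: a young
reference (5 donors) and an elderly query (3 donors) carrying known
perturbations — +0.10 HSC proportion, −0.03 CLP, −0.04 monocyte
progenitors, one monocytic gene's sigmoid trend delayed by 0.2 pseudotime
units and another dampened to 60% amplitude.

```bash
python analysis/01_simulate.py    # cohort with ground truth
python analysis/02_qc.py          # ceilings, mito bounds, HVGs
python analysis/03_classify.py    # train ensemble, annotate query
python analysis/04_composition.py # proportion-shift tests
python analysis/05_trends.py      # pseudotime trend comparison
python analysis/06_regulons.py    # regulon activity analytics
```

Selected output (what it means in brackets):

```
$ python analysis/02_qc.py
reference: kept 2913/3090 cells (ceilings: 1624 genes, 12389 UMIs)
  removed by mito_high: 89        [dying cells, >10% mitochondrial]
  removed by mito_low: 61         [anomalous <1% mitochondrial population]
  removed by max_genes: 26        [doublet-like]
  removed by max_umis: 25

$ python analysis/03_classify.py
trained 140 binary models (14 types x 10 repetitions, 593 shared HVG features) in 296s
query accuracy on pure cells: 0.9971
'not assigned' rate on pure cells: 0.0029
worst per-type recall: 0.9769

$ python analysis/04_composition.py
injected shifts: {'CLP': -0.03, 'HSC': 0.1, 'Mono_prog': -0.04}
significant composition shifts (2 of 15 types, adjusted p < 0.05):
  HSC: 0.203 -> 0.293 (adjusted p = 3.86e-11)   [the injected +0.10 expansion]
  Mono_prog: 0.078 -> 0.047 (adjusted p = 5.40e-04)

$ python analysis/05_trends.py
genes with altered trends (adjusted p < 0.05): 19
  G00263: *** (adjusted p = 2.33e-49) <- injected perturbation
  G00012: *** (adjusted p = 3.57e-31) <- injected perturbation
injected perturbations recovered: 2/2
```

The classifier recovers 99.7% of pure query cells with 0.3% "not
assigned"; the composition test flags the injected HSC expansion and the
monocyte-progenitor loss (the small −0.03 CLP shift is below its power at
this cohort size); the two injected trend perturbations are the two
strongest trend hits (the remaining flags reflect donor batch effects,
which the full-landscape run leaves in; see `docs/methods.md`); and the
top-RSS regulon matches the simulated truth in all 14 cell types.

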