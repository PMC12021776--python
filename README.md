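# habikit

Habitat radiomics for dual-phase CT: cluster tumor voxels into
enhancement-ordered subregions, extract IBSI-style radiomics features from
the whole tumor and each subregion, screen and model them against
lymph-node-metastasis (LNM) labels, and analyse how model assistance
changes radiologist performance — all exercisable end to end on synthetic
phantoms, with no imaging download required.

## The problem

Preoperative CT staging of nodal disease in adenocarcinoma of the
esophagogastric junction (AEG) is insensitive: readers working from node
size and morphology, or from the Node-RADS 1.0 score (1–5, ≥ 3 read as
metastatic), miss many positive nodes.  Habitat radiomics asks whether the
*primary tumor's* internal structure predicts nodal status better than
whole-tumor ("conventional") radiomics.  Each tumor's voxels — represented
as (arterial HU, venous HU) pairs — are partitioned by K-means into k
subregions ("habitats"), with k chosen by the Calinski–Harabasz score

        CH(k) = [B/(k−1)] / [W/(n−k)],

B and W the between- and within-cluster dispersions over the n in-mask
voxels.  Subregions are renumbered by mean enhancement (sub1 = most
enhancing, typically the blood-rich middle layer; sub3 = the rim), giving a
cross-patient correspondence.  Per phase, the whole tumor yields 18
first-order + 14 shape + 73 texture features (GLCM 22, GLRLM 16, GLSZM 16,
GLDM 14, NGTDM 5 — bin width 25 HU, minimum-anchored) = 210 conventional
(CR) columns; each of the three subregions yields first-order + texture =
546 habitat (HR) columns; the union is 756.  Features are screened
(reproducibility ICC ≥ 0.75 when two segmentations exist, univariate
t/Mann-Whitney at α = 0.05, Spearman pruning at |ρ| > 0.9, then
L1-penalized logistic selection), modelled with six classifiers (RBF-SVM
with Platt-scaled probabilities, random forest, extra trees, XGBoost,
LightGBM, logistic regression) tuned by stratified many-fold CV, and
operated at the training Youden cutoff (call positive at score > cutoff).
Evaluation covers ROC AUC with DeLong CIs and paired DeLong tests, McNemar
tests, Hosmer–Lemeshow calibration, decision-curve net benefit, average
precision, Fleiss' kappa, kernel-Shapley attributions, and the reader-study
bookkeeping (three-repeat consensus calls, Node-RADS binarization,
per-score metrics, Sankey reclassification flows).

Because the motivating cohorts are private, the package ships a first-class
synthetic-data module: dual-phase ellipsoid phantoms whose in-mask voxels
come from three concentric intensity populations, cohorts in which habitat
composition and enhancement drive the LNM label through a logistic link,
and reader calls simulated at the call level.

## Worked example

The analysis drivers under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_habitat_clustering.py
python analysis/03_extract_features.py
python analysis/04_model_and_evaluate.py
python analysis/05_explain_model.py
python analysis/06_reader_study.py
```

Habitat-count selection (script 02) prints:

```
CH selection over k = 2..10 on 20 three-population phantoms
  per-phantom best k: [3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3]
  modal k = 3 (selected in 20/20 phantoms)
```

i.e. the Calinski–Harabasz curve peaks at the number of planted intensity
populations in every phantom.  Modelling the 60-case demonstration cohort
(script 04) prints:

```
   model     cohort  n_features   auc  accuracy  sensitivity  specificity
      HR   training          16 0.998     0.979        0.964          1.0
      HR validation          16 0.771     0.750        0.714          0.8
      CR   training           2 0.936     0.896        0.893          0.9
      CR validation           2 0.886     0.750        0.714          0.8
DeLong HR vs CR (validation): AUC 0.771 vs 0.886, p = 0.475
```

At this deliberately small demonstration size the 16-feature habitat
signature overfits while two volume-linked whole-tumor features
generalize; the recovery tests in `tests/test_acceptance.py` run the same
pipeline at n = 250 and verify that the habitat model's mean held-out AUC
exceeds 0.9 when a strong habitat-composition effect is planted, and stays
at chance (0.4–0.6) when no effect is planted.  Script 06 shows all four
empirical-group readers improving AUC and accuracy significantly under
model assistance (paired DeLong and McNemar p < 0.001) while the
RADS-group readers' scores are reclassified by the model mostly in
Node-RADS 1–2.

A `habikit` CLI wraps the same stages for file-based use
(`habikit simulate/preprocess/habitats/features/select/train/evaluate/
explain/readers/run`); volumes are NIfTI or NRRD, tables CSV.

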