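# roilogit

Suprathreshold voxel-count feature extraction and logistic classification
for parcellated statistical brain maps.

The package implements, end to end, a classification pipeline for
case/control (and three-way phenotype-subgroup) discrimination from
functional-imaging activation counts:

1. **Feature extraction** (`roilogit.parcellation_features`): per-subject
   3D t-statistic maps are reduced to a subjects × regions table by
   counting, within each atlas region, the voxels whose t-value strictly
   exceeds a threshold (default 3.17, whose normal-reference upper-tail
   probability is below 10⁻³). A threshold diagnostic curve (total
   suprathreshold voxels vs. t) is also provided.
2. **Collinearity screening** (`roilogit.collinearity_screen`): Pearson
   correlation of region features with an |R| ≥ 0.9 elimination gate run
   on training, test and full data, plus a census of strongly correlated
   pairs (R > 0.7 / 0.8 / 0.9, and R < −0.5).
3. **Classifier core** (`roilogit.classifier_core`): unpenalized logistic
   regression (deterministic Newton ML, optional SGD mode, ridge-stabilized
   fallback under perfect separation) with age/sex/BMI always included as
   covariates; recursive feature elimination with inner-CV model-size
   selection; stratified train/test split search over 50:50 … 90:10;
   stratified 10-fold cross-validation; confusion-matrix metrics
   (sensitivity, specificity, PPV, NPV); Sidak correction of coefficient
   p-values. A one-vs-rest path handles three-class subgroup models.
4. **Permutation significance** (`roilogit.permutation_significance`):
   the label-shuffle test — rebuild the whole pipeline on permuted labels
   (default 1000 runs, escalating to 10,000 when no run reaches the
   observed accuracy) and report the empirical p-value.
5. **Synthetic cohorts** (`roilogit.synthetic_cohort`): negative-binomial
   activation counts with planted group/subgroup effects, optional
   copula-coupled region pairs, demographic covariates, and jointly
   generated voxel-level maps over a toy atlas that re-extract to the
   returned count table exactly.
6. **Printed model fixtures** (`roilogit.paper_fixtures`): checksummed
   transcriptions of the published Day-1/Day-2 case/control and
   START/STOPP/POTS subgroup coefficient tables with set-algebra helpers
   (region counts, overlaps, extreme coefficients, subset checks).

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with one test per acceptance criterion
(extraction oracles, fit oracle vs. an independent derivative-free
optimizer, RFE recovery of planted regions, null calibration of CV and
of the shuffle-test verdict, fixture structure checks).

## CLI

```bash
# synthesize a cohort (optionally with NIfTI maps + toy atlas)
roilogit simulate --seed 1 --out cohort.csv
roilogit simulate --seed 1 --out cohort.csv --maps-dir maps/ --atlas-out atlas.nii

# extract counts from maps
roilogit extract --maps maps/ --atlas atlas.nii --regions atlas_regions.csv \
                 --meta meta.csv --tthresh 3.17 --out features.csv

# screen, fit, cross-validate, subgroup model, shuffle test
roilogit screen  --features features.csv --rmax 0.9 --out screen.json
roilogit fit     --features features.csv --ratio 0.7 --seed 1 --out model.json
roilogit cv      --features features.csv --k 10 --seed 1
roilogit fit3    --features features.csv --outcome subgroup --seed 1
roilogit shuffle --features features.csv --observed 0.706 --n 1000 --seed 1
```

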