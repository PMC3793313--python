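# pfavox

Voxel selection for fMRI multivoxel pattern analysis (MVPA) built around
**principal feature analysis (PFA)**: instead of projecting data onto
principal components, PFA clusters the *rows* of the truncated
eigenvector matrix of the voxel dependency (covariance/correlation)
matrix with cosine k-means and keeps, per cluster, the one original
voxel whose row lies closest to the cluster center. Mutually redundant
(highly correlated) voxels share a cluster and collapse to a single
representative; a leading-eigenvector magnitude filter then discards
noise-derived clusters. The package also provides the standard
comparators — univariate t-statistic ranking and spherical-searchlight
average-|t| scoring — and a decoding-evaluation harness (stratified
cross-validated linear SVM, similarity-matrix analysis, exact Wilcoxon
signed-rank comparison), plus a synthetic fMRI generator with planted
ground truth so everything is testable offline.

## Layout

| module | contents |
| --- | --- |
| `pfavox.io` | NIfTI/mask loading, voxel↔coordinate flattening, design tables, per-run linear detrending |
| `pfavox.pfa` | dependency matrix, eigendecomposition, cosine k-means, cluster representatives, leading-eigenvector filter, `pfa_select` pipeline |
| `pfavox.baselines` | t-statistic scores, sphere offsets, searchlight scores, top-N selection, per-category union protocol |
| `pfavox.evaluate` | trial-pattern extraction, CV SVM accuracy, similarity matrices, within/between contrast, Wilcoxon signed-rank |
| `pfavox.simulate` | block-design localizer and event-related task-run generation with strong/weak/redundant/noise voxels and ground truth |
| `pfavox.experiments` | canned end-to-end studies (redundancy elimination, PFA-vs-t-stat decoding over a cohort) |

## CLI

```bash
# generate a synthetic subject (NIfTI volumes + design tables + ground truth)
pfavox simulate --out sim/ --seed 1

# select voxels (pfa | tstat | searchlight)
pfavox select --method pfa --series sim/localizer.nii --mask sim/mask.nii \
    --design sim/localizer_design.tsv --n-features 20 --seed 1 --out sel.txt

pfavox select --method tstat --series sim/localizer.nii --mask sim/mask.nii \
    --design sim/localizer_design.tsv --n-features 20 --per-category --budget 5 \
    --out sel_t.txt

# evaluate a selection on the task runs (5-fold linear-SVM decoding)
pfavox evaluate --series sim/task.nii --mask sim/mask.nii \
    --design sim/task_design.tsv --selection sel.txt --folds 5 --seed 1 --out report.json

# paired comparison of two reports
pfavox compare --a report.json --b report_t.json --alternative greater
```

Delimited text matrices (voxels × observations) are accepted in place
of NIfTI via `--matrix`.

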