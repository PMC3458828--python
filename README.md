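# connclass

Whole-brain structural-connectome classification of two subject groups
(e.g. depressed patients vs healthy controls), built around the analysis
design used in DTI probabilistic-tractography studies of major depression:

1. **Connectome construction.** For a 90-region AAL parcellation, the
   directed connectivity strength from region *i* to region *j* is the
   streamline count *m<sub>ij</sub>* normalized by the samples seeded in
   *i*: `s_ij = m_ij / (5000 · n_i)` for a region of *n<sub>i</sub>* voxels
   and 5000 samples per voxel. The two directed estimates are averaged and
   a floor of 0.01 removes spurious weak connections, giving a symmetric
   90×90 matrix per subject (4005 edge features).
2. **Group statistics.** Per-group mean matrices, an edge-wise two-sample
   t-test significance matrix, and a comparison of per-subject mean
   nonzero strengths.
3. **Classification.** Nested leave-one-out cross-validation: in each fold
   the 50 most discriminating edges are selected by two-sample t-tests on
   the training subjects only, embedded by locally linear embedding
   (k = 23 neighbors, d = 15 dimensions, with a reconstruction-weight
   out-of-sample projection for the held-out subject) and classified by a
   Gaussian-RBF SVM, `k(x, x') = exp(−‖x−x'‖² / (2σ²))` with σ = 3.
   Performance is reported as sensitivity `SS = TP/(TP+FN)`, specificity
   `SC = TN/(TN+FP)` and generalization rate `GR = (TP+TN)/N`, plus a ROC
   curve swept over the per-subject decision scores.
4. **Significance and consensus.** A label-permutation test of GR
   (re-running the full nested pipeline per permutation, add-one p-value
   estimator), the consensus connections selected in *every* fold, and
   per-region weights (incidence counts of consensus connections).

Because clinical diffusion MRI cohorts of this kind are rarely shared, the
package includes a first-class synthetic-cohort generator
(`connclass.simulate`) that emulates the statistical structure of such
data — sparse log-normal connectivity templates, per-subject noise, a
global group contrast calibrated to mean nonzero strengths of 0.0499
(patients) vs 0.0412 (controls), and a configurable set of implanted
discriminating edges — so every stage is testable end to end.

## Worked example

```python
from connclass import (SimulationConfig, PipelineConfig, generate_cohort,
                       run_loocv, consensus_features, permutation_test)

synth = generate_cohort(SimulationConfig(seed=1))   # 22 patients, 26 controls
cohort = synth.as_cohort()
cv = run_loocv(cohort, PipelineConfig())
print(f"GR={cv.generalization_rate:.1f}% SS={cv.sensitivity:.1f}% "
      f"SC={cv.specificity:.1f}% AUC={cv.auc:.3f}")
report = consensus_features(cv, cohort)
print(len(report.edges), "consensus connections")
```

prints

```
GR=93.8% SS=95.5% SC=92.3% AUC=0.993
41 consensus connections
```

i.e. 45 of the 48 synthetic subjects are classified correctly from their
connectivity patterns, and 41 connections are selected in every
cross-validation fold (the generator implanted 33; the extras are edges
that ride the global patient-side elevation).

The same workflow is available from the shell:

```bash
connclass simulate --out cohort/ --seed 1
connclass classify --cohort cohort/manifest.csv --out run/ --seed 1
connclass report --results run/cv_results.json --cohort cohort/manifest.csv --out run/
connclass permute --cohort cohort/manifest.csv --out run/ --n-permutations 10000
```

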