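# petvoi

Automated volume-of-interest (VOI) analysis for dynamic PET, built around a
fully synthetic, ground-truth-known phantom cohort.

Quantitative PET studies of Alzheimer's disease (AD) and mild cognitive
impairment (MCI) summarize tracer binding as regional averages over
cortical VOIs. Drawing those VOIs per subject is slow and introduces
inter-investigator variance; an alternative is to warp every subject into a
common space and reuse a single VOI set. `petvoi` implements the complete
analysis chain needed to study that trade-off:

* **Kinetics** — reference-region Logan graphical analysis. For a target
  time-activity curve C_T(t) and a cerebellar-cortex reference C_R(t), the
  plot of ∫₀ᵗC_T/C_T(t) against ∫₀ᵗC_R/C_T(t) becomes linear at late times;
  its slope over the frames from 15 min to the end of the scan estimates the
  distribution volume ratio, DVR = BP + 1. An early-frame (first six
  minutes, frames 1–7) duration-weighted sum provides the perfusion-like
  image on which the reference region is drawn.
* **VOI geometry** — projection of surface-drawn ROIs into 3D VOIs (every
  voxel within 9 mm of the drawn voxels), pull-back resampling of labels and
  DVR images through dense displacement fields, Dice overlap
  κ = 2·#(A∩B)/(#A+#B), and the reduction in mask-averaged across-subject
  voxel variance as normalization-quality metrics.
* **Discriminant analysis** — classification of subjects into
  control / MCI / AD by linear discriminant analysis with a pooled
  within-class covariance, an exhaustive search over all 2⁹−1 = 511 regional
  feature subsets (optionally adding the MMSE cognitive score), ranking by
  leave-one-out cross-validation, and permutation tests that shuffle group
  labels while preserving the 10/6/7 group counts.
* **Phantom** — a synthetic generator for everything above: an 11-region
  label phantom (9 cortical VOIs, white matter, a cerebellar reference), a
  23-subject cohort with group-structured MMSE and regional DVR elevations
  in AD-associated regions, dynamic 4D images whose voxel curves follow the
  simplified reference tissue model (so the planted DVR is exactly what
  Logan analysis should recover), and smooth invertible deformation fields.
* **Pipeline** — the end-to-end two-arm experiment: arm A extracts regional
  DVR with individual (deformed, error-perturbed) VOIs in subject space;
  arm B warps each subject back to the common space with the known inverse
  field and reuses the single common VOI set. Both feature tables feed the
  discriminant search.

Volumes are NIfTI-1 (via nibabel), tables are TSV, reports are JSON.

## Worked example

The whole experiment is driven by one seeded configuration:

```sh
petvoi run --seed 1 --out results/run1
```

which prints (abridged):

```
Best discriminant models:
                     model  classification_pct  cross_validation_pct   regions permutation_p
                 MMSE only                69.6                  69.6       N/A           N/A
    Unwarped PET data only                82.6                  69.6 1,2,4,6,9    P = 0.0215
Unwarped PET data and MMSE                91.3                  82.6     3,4,8    P = 0.0005
      Warped PET data only                87.0                  82.6     4,8,9    P < 0.0005
  Warped PET data and MMSE               100.0                  91.3   1,5,8,9    P < 0.0005

Variance reduction (misaligned -> realigned): 93.7%

Dice overlap after realignment (mean +/- SD):
  upper parietal lobe          0.983 +/- 0.010
  ...
  white matter                 0.994 +/- 0.004
  gray matter                  0.990 +/- 0.005
  whole brain                  0.996 +/- 0.002
```

Reading the table: `classification_pct` is resubstitution accuracy of the
best model found by the exhaustive search, `cross_validation_pct` its
leave-one-out accuracy, `regions` the VOIs it uses (listing order 1–9), and
`permutation_p` the fraction of group-count-preserving label permutations
that classified as well or better (here 2000 permutations, so `P < 0.0005`
means not one did). On this synthetic cohort the common-space ("warped")
extraction beats the individual-VOI ("unwarped") arm, models using PET data
beat MMSE alone, and realignment with the known inverse deformation
recovers the common-space anatomy almost exactly (Dice ≥ 0.98 everywhere,
94% variance reduction).

The same run is available from Python:

```python
from petvoi import RunConfig, run_two_arm_experiment, write_report

report = run_two_arm_experiment(RunConfig(seed=1))
print(report.summary_rows())
write_report(report, "results/run1")
```

and the individual stages compose freely — e.g. fitting one Logan slope:

```python
from petvoi import (default_schedule, make_reference_tac, srtm_target_tac,
                    KineticParams, ReferenceCurve, logan_slope)

sched = default_schedule()                      # 18 frames / 125 min
ref = ReferenceCurve()                          # analytic reference input
target = srtm_target_tac(ref, KineticParams(r1=1.0, k2=0.1, dvr=1.5), sched)
fit = logan_slope(target, make_reference_tac(sched), t_start=900.0)
print(round(fit.dvr, 3))                        # 1.492  (truth: 1.5)
```

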