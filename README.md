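# patsim — patient similarity from sequential EMR data

`patsim` measures similarity between hospitalized patients using the
*sequential* information in their electronic medical records — not just
a static feature vector — and uses that similarity for k-nearest-neighbor
outcome prediction (in-hospital mortality, readmission). It is aimed at
clinical-informatics researchers who want an interpretable,
neighbor-based alternative to black-box models for uneven, irregular,
variable-length EMR data.

## The model

Each hospitalization contributes three kinds of features:

**Event-sequence similarity (edit distance).** A patient's lab orders,
radiological examinations and procedures each form a timestamped event
sequence r = {(e_1, t_1), (e_2, t_2), …} ordered by day (same-day ties
alphabetical). The distance between two sequences is the minimum total
cost of edit operations transforming one into the other, where
c(Ins) = c(Del) = 1 and substitution — shifting the occurrence day of the
*same* event — costs c(Sub(e, t_i, t_j)) = 0.5·|t_i − t_j|. Substitution
between different event codes is not allowed. The minimum M(m, n) is
found by dynamic programming over order-preserving alignments and mapped
to S = 1 − M/(m+n) ∈ [0, 1].

**Trend similarity (DTW / Haar).** A lab test observed on ≥ 2 days is a
variable-length time series. Pairwise distances come either from dynamic
time warping (cumulative |a−b| cost along the optimal monotone warping
path) or from Haar wavelet decomposition (linear interpolation to a
dyadic length, orthonormal Haar transform, Euclidean distance between
the retained coarse coefficients). Per test, distances are converted to
similarities by min–max: S = (d_max − D)/(d_max − d_min).

**Cross-sectional similarity.** Jaccard similarity on four binary
demographics (age ≥ 60, male, married, insured) and on binary text
features extracted from radiology reports by lexicon phrase matching;
1 − min–max-normalized Euclidean distance on admission-only lab panels.

**Fusion and prediction.** Three *dominant* features are selected by
majority voting over resampled subsets (ranking features by the AUROC of
their single-feature leave-one-out kNN predictions), and their weights
are grid-searched in 0.05 steps under w1 + w2 + w3 = 1,
w1 ≥ w2 ≥ w3 > 0. The fused similarity S = Σ w_f S_f drives a kNN risk
score: the fraction of outcome-positive patients among the index
patient's k = 50 most similar training patients. Model variants combine
sequence (E), DTW-trend (D) and Haar-trend (H) similarities (kNN_E,
kNN_D, kNN_H, kNN_ED, kNN_EH), always together with the cross-sectional
similarities; kNN_Eucli is the Euclidean-distance baseline on static
features. Evaluation is leave-one-out, repeated over independently
reseeded runs, at three index time points (admission, day 7, discharge).

Real EMR extracts are read from three CSV tables (`events.csv`,
`labs.csv`, `patients.csv`); a synthetic-cohort generator with planted
class structure makes every stage testable without protected data.

## Worked example

The reference sequence pair r1 = {(A,1), (B,2), (C,3), (D,4)},
r2 = {(A,2), (B,5), (C,8)}:

```python
import patsim as ps

scheme = ps.EditCostScheme()            # ins=del=1, sub=0.5/day
r1, r2 = ps.generate_worked_example()
os1, os2 = ps.worked_example_operation_series()
print("cost(Os1) =", ps.operation_series_cost(os1, scheme))
print("cost(Os2) =", ps.operation_series_cost(os2, scheme))
M, trace = ps.edit_distance(r1, r2, scheme)
print("edit distance M =", M)
print("similarity =", round(ps.sequence_similarity(r1, r2), 4))
```

prints

```
cost(Os1) = 7.0
cost(Os2) = 5.5
edit distance M = 5.0
similarity = 0.2857
```

Os1 deletes all of r1 and inserts all of r2 (7 unit operations); Os2
substitutes the days of A, B, C and deletes D (0.5 + 1.5 + 2.5 + 1 =
5.5). The free DP minimum is 5.0 because deleting and re-inserting C
(cost 2) undercuts the far-day substitution Sub(C, 3, 8) (cost 2.5);
`EditCostScheme(forced_substitution=True)` mandates matching shared
codes and returns 5.5. The similarity is 1 − 5/7 ≈ 0.286.

End-to-end on the packaged synthetic cohort (300 patients, seed 7,
23 deaths):

```python
cohort = ps.generate_cohort(ps.GeneratorConfig(n_patients=300, seed=7))
fss = ps.compute_feature_similarities(cohort)
result = ps.loo_evaluate(ps.ModelSpec(variant="kNN_ED"), cohort, seed=0, fss=fss)
print("kNN_ED AUROC =", round(result.auroc, 3))
print("dominant features:", dict(zip(result.weights.features, result.weights.weights)))
```

```
kNN_ED AUROC = 0.725
dominant features: {'S_pro-edit': 0.4, 'S_text': 0.4, 'S_dtw:serum_creatinine': 0.2}
```

The model recovers the structure the generator plants: the procedure
sequence (distinct rescue procedures in the high-risk class) and the
rising creatinine trend are selected as dominant features, and the fused
kNN (AUROC 0.725) beats the Euclidean-distance kNN baseline (0.627) on
the same cohort. With ~8% mortality the class-noise ceiling on AUROC is
about 0.71–0.73, so the fused model is close to the attainable optimum.

The same pipeline is scriptable from the shell:

```sh
patsim simulate --n-patients 300 --seed 7 --outdir cohort/
patsim similarity --events cohort/events.csv --labs cohort/labs.csv \
    --patients cohort/patients.csv --feature S_pro-edit --outdir sim/
patsim evaluate --events cohort/events.csv --labs cohort/labs.csv \
    --patients cohort/patients.csv --variant kNN_ED --variant kNN_E \
    --n-runs 20 --outdir eval/
```

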