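# Methods

## Data model and assumptions

A hospitalization is represented by (i) three timestamped event
sequences — laboratory test orders, radiological examinations,
procedures — with 1-based integer days (admission day = 1; sub-day
timestamps are floored to days at ingestion), (ii) lab-test time series
(a test with ≥ 2 values during the stay), (iii) cross-sectional
features: four binary demographics, admission-only lab values, and
binary phrase-presence features from radiology report text, and
(iv) binary outcomes plus length of stay. Within a sequence, events are
ordered by day and alphabetically by raw event code within a day, so the
sequence is a deterministic function of the raw rows; duplicate
(code, day) pairs are retained because a test can be repeated same-day.
Missing demographics default to 0 with a logged warning, which keeps
Jaccard similarity computable.

## Edit distance on event sequences

Insertion and deletion cost 1; substitution is only defined between
identical event codes and costs `sub_rate · |t_i − t_j|` with
`sub_rate = 0.5` per day. The distance is the minimum total cost over
order-preserving operation series, computed with the standard
O(mn) alignment DP; the traceback prefers Sub over Del over Ins on cost
ties, which fixes the returned operation series without affecting the
cost. Similarity is `S = 1 − M/(m+n)`: m + n is the cost of the
always-available delete-all/insert-all series under unit costs, so S is
guaranteed to lie in [0, 1]; two empty sequences are defined maximally
similar (S = 1).

Under these costs, substituting an event across a gap of more than
`(ins_cost + del_cost)/sub_rate = 4` days is never optimal — deleting
and re-inserting the event is cheaper. Because some practitioners
instead want every shared code matched regardless of day gap, a
`forced_substitution` mode is provided: occurrences of each code are
matched in temporal order (k-th to k-th) and substituted, surplus
occurrences deleted/inserted. This matching is per code and ignores
cross-code ordering; its cost is never below the free DP minimum. The
free minimum is the default because it is the true minimum under the
stated cost model.

## Trend similarity

DTW uses per-step cost |a − b|, the unit step set {(1,0),(0,1),(1,1)},
aligned endpoints, no warping window and no path-length normalization —
the plain cumulative distance. The Haar route resamples the value list
by linear interpolation over the observation index (not calendar day:
neither metric uses day spacing, and the series is defined by its
temporally sorted values) to `target_length = 8` points, applies the
orthonormal discrete Haar transform (PyWavelets, energy-preserving), and
keeps `keep_levels = 3` coefficient groups coarsest-first — the
approximation plus the two coarsest detail levels, 4 of 8 coefficients.
The truncation is deliberate dimension reduction: it keeps the series'
level and broad trend and discards fine fluctuation, which is also why
the Haar route can lose information relative to DTW.

Distances become similarities by per-test min–max over available
off-diagonal pairs, `S = (d_max − D)/(d_max − d_min)`, mirroring the
"1 − normalized Euclidean distance" convention of the cross-sectional
labs; if all pairwise distances are equal the available pairs get
similarity 1. d_min/d_max are recomputed per test, per method, and per
index time point, because truncation changes the series. A patient
lacking the test gets similarity 0 to everyone (absence of a repeated
test is itself informative) and is flagged in the availability mask
rather than imputed.

## Cross-sectional similarity

Demographics and text features use Jaccard similarity over positive
indicators, with the both-empty case defined as 1 (two patients with no
positive indicators are identical, and sparse fixtures stay
deterministic). Admission labs are compared in two stages: per-test
min–max scaling across the cohort (constant tests dropped with a
warning, missing values imputed by the cohort median), then pairwise
Euclidean distances min–max-normalized over off-diagonal pairs and
flipped to similarities. Text features are case-insensitive substring
matches of user-supplied lexicon phrases; no tokenization, negation
detection or non-English processing is attempted.

## Fusion and kNN prediction

Each model variant (kNN_E/D/H/ED/EH) defines a candidate pool: its
sequence and/or trend similarity families plus the cross-sectional
similarities. Dominant-feature selection draws `reps = 11` (odd, for
voting) stratified random subsets of the training patients — each
subset `subset_fraction = 0.5` of them, preserving outcome prevalence —
ranks the pool by single-feature leave-one-out kNN AUROC within the
subset, and lets each repetition vote for its top 3; vote ties break by
mean AUROC, then name. Weights come from an exhaustive grid in 0.05
steps on {w1 ≥ w2 ≥ w3 > 0, Σw = 1} (33 triples), with w1 attached to
the feature ranked best by single-feature AUROC — weights follow
importance rank rather than being permuted freely, so more important
features always receive the larger weights. Grid ties keep the first
triple in enumeration order (w1 descending), which makes the optimizer
deterministic. The kNN risk score is the positive fraction among the
top k = 50 training neighbors, with rank-k similarity ties broken by
ascending patient id.

At admission no temporal feature exists, so the registry reduces to
S_dem and S_lab: the temporal-only variants (kNN_D/H/ED/EH) refuse to
predict there, while kNN_E degrades to the cross-sectional pair and the
selection/grid machinery generalizes to min(3, pool) features (pairs
w1 ≥ w2 > 0 on the same step). At day 7, report-text features are
disabled (radiology reports are too sparse in the first week) and
patients with stays under 7 days are excluded from the training pool
and weight-determination subsets, though they are still scored.

## Evaluation protocol

Each run fits selection and weights once on the run's stratified
weight-determination subsets of the training patients, then scores every
patient leave-one-out against all others. Fitting once per run (rather
than refitting for every held-out patient) is the package's design
choice: the subsample is the protocol's only source of run-to-run
variability, per-patient refitting multiplies cost by the cohort size,
and the held-out patient influences the fit only through at most one
membership in a half-cohort subset. Runs are repeated with seeds
`base_seed + r` and summarized as "mean (SD)". Model A significantly
outperforms B when A's metric is strictly higher in ≥ 95% of paired
runs; ties count for neither.

AUROC is the rank statistic (ties credited 0.5). The classification
threshold for F1/precision/sensitivity/specificity defaults to the
training-set outcome prevalence: with k = 50 and ~8% prevalence a fixed
0.5 threshold would predict essentially no positives and make F1
degenerate. The Euclidean-distance kNN baseline z-scores its static
features — cross-sectional features plus either zero-padded flattened
series or six summary statistics per series (min, max, mean, sample SD,
moment skewness with 0 for n < 3 or zero variance, length) — and ranks
neighbors by Euclidean distance.

## Synthetic cohorts

The generator emulates the structure the framework assumes: a latent
2-class mixture (50/50) with class-dependent outcome probabilities
(mortality 2% vs 15%, ~8.5% prevalence), length of stay
round(Gamma(3, 3.5)) clipped to ≥ 1 day (mean ~10.5, SD ~6), per-domain
Poisson event streams (~12 lab, ~3 radiology, ~3–4 procedure events per
stay), lab series as linear trend + Gaussian noise observed at
irregular days drawn without replacement from the stay, class-skewed
demographics and report phrases, and per-test missingness. The class
signals every feature family at configurable strength; by construction
the procedure sequence is the strongest single feature (the high-risk
class receives a rescue-procedure motif — IABP, CRRT, ventilation on
characteristic early days — that the edit distance must pay
delete+insert for across classes), followed by the rising
creatinine-like trend. `PLANTED_STRONGEST_FEATURE` names this feature
for tests.

Event counts per stay are two orders of magnitude below a real ICU lab
stream: the package targets desk-scale cohorts (a few hundred patients)
where all O(n²) pairwise dynamic programs complete in seconds, and the
similarity structure, not the event volume, is what the framework's
correctness depends on. Passing tests on these cohorts demonstrate that
the machinery recovers planted structure under realistic noise,
prevalence and unevenness — not that any particular real-data AUROC is
reproduced. Real-data properties the generator does not emulate:
cross-correlated lab panels, informative missingness, non-linear trends,
coded vocabularies of realistic size, and free-text beyond lexicon
phrases.

## Numerical and degenerate-case choices

Backtrack cost comparisons use an absolute 1e-9 tolerance; weight-grid
sums are exact to 1e-12. Degenerate inputs are defined rather than
errors where a convention is defensible (both-empty sequences similar,
both-zero Jaccard 1, all-equal distances similarity 1) and errors where
silence would hide data problems (empty series in DTW, single-value
series in the Haar route, k exceeding the training pool, single-class
AUROC, no available pair for a trend test).

## Known limitations

Abnormality-status (categorical) trend similarity is not implemented.
The forced-substitution mode's per-code matching can violate cross-code
temporal monotonicity. Similarity matrices are dense (O(n²) memory);
cohorts beyond a few thousand patients would need banded or blocked
computation. The admission-time model degenerates to two cross-sectional
features by construction. LR/RF/LSTM/RNN comparison models are out of
scope; the Euclidean-distance kNN is the packaged baseline.
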