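# Methods

## Data model

A dataset is a universe of n labeled objects over m features; each
(object, feature) record is an ordered series of real values of arbitrary
length d ≥ 0, with d = 0 the empty record ∅. Timestamps in the long-format
input are used only to order values within a record (ties keep file order —
a convention, since simultaneous measurements have no canonical order);
sampling irregularity is otherwise ignored, i.e. a record is treated as an
ordered value set. A record absent from the input and a record with zero
measurements are the same ∅; no third "missing" state exists. Class labels
are opaque strings; two classes is the primary, tested case, but every
entropy/gain computation is written over k classes and nothing assumes
k = 2.

## Discretization

Non-empty records pass through z-normalization → PAA → SAX:

- **z-normalization** uses the population (1/n) standard deviation. A
  zero-variance series maps to all zeros rather than failing: constant
  series are legitimate in laboratory data and must reach discovery.
- **PAA** is parameterized by a per-series compression ratio r ∈ (0, 1]
  (target length w = ⌈r·d⌉) rather than a fixed w, so that symbolic records
  keep their variable lengths; the default r = 1 disables PAA. When w does
  not divide d, index j joins partition ⌊j·w/d⌋ (equal-width real-valued
  partitioning). This default is a documented design choice, not a claim
  about any particular upstream setting.
- **SAX breakpoints** are N(0,1) quantiles at i/α (scipy `norm.ppf`), so the
  α regions are equiprobable; for α = 2 the single breakpoint is 0 (below vs
  above the mean). A value exactly on a breakpoint maps to the upper region
  ("lower than the first breakpoint" is strict). Candidate alphabet sizes
  default to {2, 3, 5}.

## Discovery

Candidates are random snippets of observed symbolic records: per draw,
length uniform in [1, l_max] (l_max = longest record of the feature), then a
uniform record among those long enough, then a uniform start offset. When
the requested pool size reaches the total number of (record, start, length)
positions, the space is enumerated exhaustively instead. The pool size
defaults to 50 per (feature, alphabet).

The distance of candidate s to a non-empty record is the minimum Levenshtein
distance over all contiguous windows of length |s| (full Levenshtein against
records shorter than |s| — the window set would be empty, and this degrades
gracefully). Hamming distance is not offered; the windowed form already
removes the length sensitivity that motivates the subsequence match. The DP
is vectorized across all windows of a column at once; a prefix-minimum
identity (cur[j] = j + cummin(full − j)[j]) removes the within-row data
dependency of the insertion term, and per-column window blocks are cached so
evaluating many candidates against one column re-uses the encoded records.

The split search evaluates every distinct observed distance plus
(max + 1) as threshold δ, assigning records with Dist < δ to the left side.
Information gain is Shannon entropy (base 2) of the parent minus the
size-weighted entropies of the two sides. Empty records enter per strategy:

- **plain**: Dist(s, ∅) = |s|; ∅ competes like any record.
- **mc**: ∅ is excluded from the search; the parent set of the gain is the
  non-empty sub-column. The ∅ encoding learned for transform time is the
  modal training distance of the winning shapelet, computed per feature over
  the training objects (smallest value on frequency ties).
- **lr**: at every threshold both bulk placements of all ∅s are tried —
  left, recording Dist(s, ∅) = 0, or right, recording the maximum observed
  distance — and the better kept. The placement is a forced side
  assignment, which is exactly what guarantees gain(lr) ≥ gain(plain) on
  every column: plain's effective placement at any threshold is one of lr's
  two options. On a column without ∅ the two placements coincide and the
  tie-break (left, hence encoding 0) supplies the stored value in case ∅
  appears at prediction time.

Tie-breaks are all deterministic: equal gain among thresholds → smallest δ;
among placements → left; among candidates → shorter sequence, then
lexicographic; among alphabets → smaller α. Gains closer than 1e-12 are
treated as ties (mathematically equal partitions can differ by float
round-off), which keeps selection reproducible and comparable to exhaustive
enumeration. One integer seed drives all sampling and is stored in the
serialized model; refitting with the same seed yields byte-identical JSON.

## Transformation

The fitted transform retains the features whose empty fraction is ≤ τ_sp
(inclusive) with at least one non-empty training record, and stores per
retained feature the shapelet, its alphabet, δ_osp, gain and ∅ encoding.
Transforming any dataset discretizes each record with the feature's stored
alphabet and PAA ratio, computes Dist(s\*, ·), and substitutes the learned
encoding for ∅ (plain: |s\*|; mc: modal training distance; lr: the stored
winning-side distance — the concrete number, so no training data is needed
at prediction time). The sl baseline stores no shapelets; values are raw
series lengths with ∅ → 0. Distances are emitted as floats for a single
downstream dtype. Models serialize to a versioned JSON document with stable
key order; a version mismatch is an explicit error.

## Synthetic data

The generator emulates the structure the method assumes, without any real
source: variable-length Gaussian series (lengths uniform in [8, 16], noise
sd 1), a positive-class prior p_pos = 0.5, and three feature roles. Motif
features add a fixed shape (+1, +1, +1, −1, −1, −1) scaled by an amplitude
(default 4 noise sd) at a random offset of positive-class records only.
Sparse features draw record-level missingness from class-conditional rates
(q_pos, q_neg) — missingness *is* the signal (MNAR). All other features use
a base rate defaulting to (q_pos + q_neg)/2, so equal class rates imply a
uniform overall empty fraction (default 0.3, matching the ≥ 20% sparsity
regime the method targets). Defaults: 200 objects, five features (two
motif, one sparse, two noise). Timestamps written to CSV are consecutive
integers with sub-unit jitter and shuffled row order, exercising the
reader's sort path.

What the generator does **not** emulate: correlated analytes, non-Gaussian
laboratory distributions, informative sampling *times*, drift, multi-class
structure, or cohort-level confounding. Passing tests therefore demonstrate
correctness and the intended qualitative behaviours of the machinery, not
clinical performance on real records.

Two named study conditions fix the experiments:

- **Motif recovery** (`motif_recovery_config`): one motif feature among two
  noise features, no missingness, amplitude 6. Rationale: the study probes
  whether discovery recovers a class-exclusive motif. Because the motif
  occupies about half of each series, z-normalization caps its standardized
  height near √(d/|motif|) ≈ 1.4 regardless of amplitude; what shrinks with
  amplitude is the residual noise jitter, i.e. the SAX symbol-corruption
  rate (≈ 7% per point at amplitude 4, ≈ 1% at 6). At amplitude 6 the
  motif's symbolic form is stable, making it genuinely class-exclusive in
  symbol space. This experiment uses a candidate pool of 200 per
  (feature, alphabet): the motif's (length, offset) position space holds on
  the order of 10³ snippets, which 50 draws under-sample.
- **MNAR signal** (`mnar_signal_config`): two sparse features
  (q_pos = 0.6, q_neg = 0.1, ≈ 35% empty overall — excluded at τ_sp = 0.2,
  admitted at 1.0) plus two near-dense noise features (base rate 0.05), so
  the AUC contrast between τ_sp = 0.2 and 1.0 isolates the value of the
  missingness signal for both sl and lr.

## Evaluation

Stratified k-fold cross-validation (default 10 folds, shuffled with a fold
seed separate from the sampling seed). Per fold the transform is fit on the
training split only — shapelets, modal distances and lr encodings never see
the held-out fold. The default classifier is a random forest with 100
trees, information-gain (entropy) splits and √m features per split; it is
pluggable behind a fit/predict_proba factory. AUC uses the positive-class
probability with midrank tie handling (scikit-learn's `roc_auc_score`);
with more than two classes, macro one-vs-rest AUC is reported. The paired
comparison reports per-pair win counts and a two-sided Wilcoxon signed-rank
p-value at α = 0.05; identical vectors return p = 1.0 (no rejection) rather
than an error, since "no detectable difference" is the correct reading of
all-tied pairs.

## Problem sizes and numerical conventions

The test-suite and `scripts/acceptance.py` sizes are: 10,000 random pairs
for the distance/brute-force agreement (records up to length 8, alphabets
up to 5); 1,000 random columns of up to 12 records for the split-search
agreement and for the lr-dominance count; 200-object datasets with medians
over 10 generator seeds (tests) or 5 seeds (script) for the motif-recovery
and MNAR experiments. Gains are compared to enumeration within 1e-9;
distances are exact integers. These sizes were chosen to give stable
medians and tight binomial error bars at desk scale.

## Known limitations

- Candidate sampling is random, not exhaustive; on large symbol spaces the
  selected shapelet is only the best of the pool. The pool size is the
  knob.
- The lr encoding stores a single global value per feature; records missing
  for different reasons are indistinguishable.
- Strings are ASCII-encoded internally, capping the alphabet at 26 symbols
  (far above the useful SAX range).
- The transform of a zero-variance record is the all-`b`-region string of
  its length (for α = 2); downstream distances remain well-defined but
  carry no amplitude information, by construction of z-normalization.
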