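# Methods

This note documents the model implemented by `succpred`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Inputs and coordinate conventions

Four inputs describe a training set: FASTA sequences; one PSI-BLAST ASCII
PSSM per protein; one SPD3-style structural table per protein (ASA in Å²,
secondary-structure probabilities, four backbone angles in degrees); and a
site table of (protein id, 1-based position, ±1 label). All external
coordinates are 1-based and inclusive. Annotated positions that are not
lysine in the supplied sequence are skipped with a warning rather than
aborting the run — annotation databases and sequence databases drift out of
sync, and a hard failure on every such site would make real inputs
unusable.

**PSSM probability scale.** A PSI-BLAST ASCII file carries two 20-column
blocks: integer log-odds scores and weighted observed percentages. The
predictor needs linear probabilities; the percentages divided by 100 are
the only columns natively on that scale and are the default
(`scale_mode="percent"`). A logistic transform 1/(1+e^(−s)) of the log-odds
block is available as `scale_mode="logodds-logistic"` for sensitivity
analysis. Columns are remapped at parse time to the canonical header order
`A R N D C Q E G H I L K M F P S T W Y V`, so feature layouts never depend
on a file's own column order.

## Windows and mirror padding

Each lysine is described by its 15 upstream and 15 downstream residues
(31 in total). Near a terminus the missing residues are filled by the
mirror effect. The reflection axis is the terminal residue itself:
p < 1 ⇒ p → 2 − p and p > L ⇒ p → 2L − p, applied iteratively for proteins
shorter than the window. Terminus-inclusive reflection is a documented
convention choice: it matches the padding used by earlier modification-site
predictors and guarantees every resolved index is a real residue for any
L ≥ 2. An alternative `mirror-center` mode (reflection about the lysine,
falling back to the terminus rule) exists purely for sensitivity checks.
The flank is configurable (`--flank`, default 15) because the bigram
transform keeps the feature count fixed for any window size.

## Feature vector

The descriptor concatenates, in this frozen order:

| block | size | content |
|---|---|---|
| structural | 248 | 31 values each of ASA, p_h, p_e, p_c, ϕ, Ψ, θ, τ (track-major) |
| PSSM bigram | 400 | B_pq = Σₖ m_{k,p} m_{k+1,q}, row-major flatten |
| SS bigram | 9 | same transform on the 31×3 secondary-structure profile |

for 657 components. The block order itself is a reproducibility convention
— any fixed permutation is equivalent for a kernel machine. Angles enter
raw in degrees (no sin/cos encoding) to preserve the 657 dimensionality;
the subsequent z-scoring puts them on a comparable scale. A useful exact
invariant used throughout the tests: the total mass of a bigram profile
equals Σₖ sₖ·sₖ₊₁ of the input row sums, hence exactly 30 for
row-normalized profiles, and reversing the window transposes B.

An ablation configuration (`use_bigram=False`, CLI `--no-bigram`) replaces
the two bigram blocks with the raw flattened window profiles
(248 + 620 + 93 = 961 components), supporting bigram-vs-no-bigram
comparisons on any dataset.

## Class balancing

Negative (non-succinylated) lysines typically outnumber positives by an
order of magnitude. The elimination rule removes every negative whose k
nearest neighbours contain at least one positive, starting at k = 10 and
incrementing until retained negatives ≤ 1.10 × positives (the ratio is
configurable; 1.10 reflects "similar class sizes" with a small margin). Open
choices resolved here:

- **Neighbour pool**: all samples of both classes, excluding self.
- **Metric**: Euclidean on per-feature z-scores (population SD, computed on
  the dataset being balanced). Without scaling, ASA and angle columns would
  dominate the probability-scale features by two orders of magnitude.
- **Ties**: broken by ascending sample id, making the procedure fully
  deterministic.
- **Schedule semantics**: decisions at every k are made simultaneously
  against the original dataset. Because a positive inside the (k−1)-NN is
  inside the k-NN, removal sets grow monotonically with k, and this rule
  coincides with the variant that shrinks the pool cumulatively — which is
  why it was chosen. Internally the whole schedule is encoded by each
  negative's rank of its nearest positive, so incrementing k is free.
- **Non-convergence**: if k_max (default 200) is reached the best-so-far
  reduction is returned with a warning rather than an error. With strongly
  separated classes no negative ever acquires a positive neighbour and the
  rule simply does not bite; that is a property of the data, not a failure
  of the procedure.

Positives are never removed. By default balancing runs once on the full
dataset before cross-validation, matching the original study design; a
`balance_within_folds` option restricts elimination to training folds for a
leakage-free protocol, and both are reported with per-k removal counts.

## Classifier

A soft-margin SVM with RBF kernel K(u,v) = exp(−γ‖u−v‖²), C = 1, γ = 0.01
and solver tolerance 0.001. Features are z-scored with training-fold
statistics before the kernel: the fixed γ is only meaningful on a common
scale (switchable via `standardize=False`). The quadratic dual is solved by
libsvm through scikit-learn; the fitted model is stored as the explicit
expansion (support vectors in scaled space, dual weights αᵢyᵢ, bias β,
scaler), so a serialized model predicts without the solver and agrees with
it to < 1e-8 on decision values. The legacy ε = 1e-12 round-off parameter
of SMO implementations has no exact libsvm analogue; it is recorded in the
parameter set for provenance and the solver tolerance governs convergence.
Prediction is sign of the decision value with sign(0) ⇒ +1 (arbitrary but
fixed). ROC curves use the real-valued margin; no probability calibration
is applied.

## Evaluation

Sensitivity, specificity, accuracy and MCC follow their standard confusion-
table definitions; an MCC denominator of zero yields 0 by convention (and
is logged). AUC is the threshold-free trapezoidal area, equal to the
normalized Mann–Whitney statistic (verified against a brute-force pairwise
oracle in the tests). Cross-validation partitions the data once per run
with a stratified shuffle (class proportions preserved per fold — plain
random partitions can produce single-class validation folds on small data),
rotates the held-out fold, and averages; "repeat n times" is read as this
standard rotation, with a `repeats` option providing the independent
re-partition reading. A single integer seed controls partitioning and is
recorded in the report.

## Synthetic data

The generator emulates all four inputs with a class-conditional effect size
δ ∈ [0, 1]: PSSM rows are symmetric-Dirichlet probability vectors, mixed
with a fixed motif vector at weight δ inside the windows of positive sites;
secondary-structure rows (Dirichlet(1,1,1)) and ASA (half-normal, scale
50 Å²) are mixed toward class targets (helix-rich, ASA 120 Å²) the same
way; backbone angles stay uniform and carry no signal so ablations can
attribute performance to specific blocks. Sites are placed on a random-
offset grid at least one full window (2·flank+1 residues) apart, so every
window is class-pure: at δ = 0 the two classes are identically distributed
and at δ = 1 positive windows carry the motif exactly. The default study
set (60 proteins of 250–500 residues, 300 positive + 300 negative sites)
provides enough window-disjoint slots for those sizes. Written fixtures use
the real integer-percentage PSSM dialect and are therefore quantized to
0.01; in-memory tests use unquantized matrices.

What passing synthetic tests shows: the feature transforms, balancing rule,
solver contract and evaluation protocol behave as specified, chance-level
accuracy at δ = 0 and signal recovery at δ > 0. What it does not show:
performance on real proteomes — real PSSMs are phylogenetically structured,
real succinylation motifs are weaker and position-dependent, and real
negatives overlap positives in feature space far more than the class-pure
generator allows. The balancing demonstration accordingly uses a small δ
(overlapping classes), the regime the elimination rule was designed for.

## Numerical choices and degenerate inputs

- Bigram computation is a single matrix product (track[:-1]ᵀ · track[1:]),
  verified against the naive triple loop to 1e-10.
- Constant feature columns get SD 1 in the model scaler (values become 0)
  and are zeroed in the balancing z-score; both avoid division by zero
  without perturbing distances.
- Proteins of length 1 cannot be mirror-padded and are rejected; windows
  on length-2 proteins reflect iteratively.
- Identical features for both classes train without error and score ≈ 0.5.
- Feature tables are written with 10 significant digits, enough to
  round-trip float32-scale differences well below solver tolerance.

## Problem sizes

Default test and demonstration sizes (600 sites, ≤ 60 proteins, ≤ 200
balancing candidates against brute-force oracles) were chosen so the whole
suite and the acceptance script each complete in well under a minute on a
single core while still exercising every code path at the study's stated
sample sizes.
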