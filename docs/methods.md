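# Methods

`melmp` predicts moonlighting proteins (MPs) — single proteins with two or
more independent biological functions — *de novo*, i.e. from inputs that can
be computed for any sequence, without requiring interaction networks, gene
expression or other omics annotation. This note records the model, the
numerical and design choices, and what the synthetic benchmark does and does
not demonstrate.

## Feature views

Each protein is encoded into four fixed-length views.

**Seq — autocorrelation-compressed k-mer composition.** Counts of all 3-, 2-
and 1-mers over the 20-letter amino-acid alphabet are concatenated into an
8,420-dimensional `rawkmers` vector (20³ + 20² + 20; blocks ordered 3-mer,
2-mer, 1-mer; lexicographic k-mer index within each block). The
autocorrelation coefficient function compresses this to m lags
(default m = 400):

    r_j = Σ_{i=1..n−j} (x_i − x̄)(x_{i+j} − x̄) / Σ_{i=1..n} (x_i − x̄)²,  j = 1…m

This is the standard centered autocorrelation. The source formulation of
this statistic circulates with a `+x̄` in the lagged factor and a lag range
written as [0, m]; we use the centered product (the uncentered variant is
unbounded and non-standard) and lags 1…m (lag 0 is identically 1 and carries
no information). A constant series has undefined coefficients; the encoder
returns zeros and warns. Raw counts (not frequencies) enter the
autocorrelation, matching the counts-based definition of `rawkmers`.

**PSSM — evolutionary profile composition.** A PSI-BLAST position-specific
scoring matrix (L × 20 log-odds; our parser reads the ASCII output of
`psiblast -out_ascii_pssm`, and the recommended invocation for users who
bring their own profiles is e-value 0.001, 3 iterations against swiss-prot)
is aggregated into a 20 × 20 matrix: cell (i, k) is the sum of profile
column i over the positions occupied by residue k, divided by the full
sequence length L; the matrix is flattened row-major over i then k into 400
values. Positions carrying a nonstandard residue code (X, B, Z, U, O)
contribute to no cell but still count in L — the divisor is the full
sequence length, so the unnormalized cell total is conserved: it equals the
profile total over standard-residue positions (a tested invariant).

**AA — physicochemical summary.** Every retained AAindex1 property maps the
sequence to a numeric series (nonstandard residues dropped); the mean and
population variance (divide by L, no Bessel correction — "variance of the
sequence" with no stated correction; switchable in code) of each series are
concatenated: (mean₁, var₁, …, mean_P, var_P), length 2P. Properties with
any missing residue value are excluded at parse time; on a full AAindex1
release this retains 553 of 566 scales, so the AA view is 1,106-dimensional.

**SS — eight-state secondary-structure composition.** 3-, 2- and 1-mer
counts over the SSpro8/DSSP alphabet {H, B, E, G, I, T, S, C}
(8³ + 8² + 8 = 584 values). Predicting secondary structure is out of scope;
the package consumes precomputed strings.

k-mer windows containing an out-of-alphabet symbol are skipped in the Seq
view; in the SS view an out-of-alphabet symbol is an error, because the
eight-state alphabet is closed.

## Sub-models

Each view gets the model family that won the original per-view selection:

| view | family | default configuration |
|------|--------|------------------------|
| Seq  | bidirectional LSTM | 50 steps of width 8, hidden 16/direction, mean-pooled states → logistic head; full-batch Adam (lr 0.01), ≤60 epochs, early stopping on a 10% validation split |
| PSSM | random forest | grid search (declared grid: 100 trees; depth ∈ {∞, 10}) with inner 3-fold validation |
| AA   | multilayer perceptron | standardized inputs, one hidden layer of 64 relu units, Adam, ≤200 epochs |
| SS   | autoencoder + random forest | 256–128–256 relu autoencoder on standardized counts; forest (100 trees) on the 128-dim bottleneck |

The recurrent model is implemented directly in NumPy with hand-derived
backpropagation through time (verified against finite differences in the
test suite to 1e-7). The published description does not fix the recurrent
architecture; we chose a small mean-pooled BiLSTM and a step layout of 50
time steps × 8 lags, which keeps the recurrence shallow enough to train
reliably at desk scale. The generic reshape utility defaults to width-1
steps; the Seq sub-model's default width is 8. The SS sub-model's
autoencoder adopts the 256–128–256 shape, the only width triple published
for that view (in the multimodal-autoencoder baseline). Autoencoders are
scikit-learn `MLPRegressor`s reconstructing the standardized input;
bottleneck activations are read out of the fitted weights.

All sub-models expose positive-class probabilities. Every family is
deterministic under a fixed seed. Class weighting is off by default (the
published pipeline does not state any); the evaluation metrics handle the
class imbalance instead.

## Stacked fusion

The meta-learner is a logistic regression over the four sub-model outputs:

    φ(z) = 1 / (1 + exp(−z)),   z = w₀ + Σᵢ wᵢ xᵢ

(the standard negative-exponent logistic with an intercept; the sign of the
exponent is absorbable into the weights). Meta inputs are the sub-models'
positive-class probabilities rather than hard labels — the meta-layer
formula consumes continuous inputs, and probabilities dominate in stacking
practice; a hard-label mode is exposed via `meta_kind="label"`.

How the first-layer training outputs are generated is the key honesty
question in stacking and is not specified in the source description; we use
the standard out-of-fold scheme (inner stratified 5-fold): each training
row's meta features come from sub-models fitted with that row held out, and
the final sub-models are refit on all rows afterwards. A regression test
confirms the honest scheme stays at chance on permuted labels. If all meta
columns are constant the meta-learner degrades to an intercept-only model at
the class prior, with a warning.

Two comparison strategies are provided: direct concatenation of the four
views (order Seq, PSSM, AA, SS; joint width 400+400+2P+584, i.e. 2,490 at
P = 553), optionally compressed by a single autoencoder; and a multimodal
autoencoder (per-view widths Seq 256–128–256, PSSM 256–128–256,
AA 512–128–512, SS 256–128–256) whose four 128-dim bottlenecks are
concatenated (512 values) before classification. The decision threshold is
0.5 throughout and config-exposed.

## Negative-set construction from GO

There is no experimentally verified set of non-moonlighting proteins, so
negatives are screened from Gene Ontology annotation.

Term statistics: `freq(c) = anno(c) + Σ_{h∈children(c)} freq(h)` and
`p(c) = freq(c)/freq(root)` within each namespace. On a DAG the literal
recursion counts a multi-parent descendant once per path; we implement it
literally (it is the stated recursion), and provide a unique-descendant
variant (`term_freq_unique`) for users who prefer the de-duplicated count.
Terms with zero frequency have undefined information content and are
excluded from similarity with a warning.

Similarity is simRel:

    simRel(c₁,c₂) = max_{c ∈ ancestors(c₁) ∩ ancestors(c₂)}
                    [ 2·log p(c) / (log p(c₁) + log p(c₂)) ] · (1 − p(c))

with each term counting among its own ancestors, clamped to [0, 1]. Because
p is monotone along ancestry the ratio never exceeds 1, and the (1 − p)
factor sends similarity through the root to 0.

Clustering of a protein's terms is average-linkage agglomerative on simRel,
merging while the average similarity is ≥ 0.1 (the lower band edge); the
cluster score is the mean pairwise simRel, undefined (NaN) for singletons.
The clustering algorithm behind the published screen is not specified;
average linkage is deterministic and parameter-light, and the threshold,
band edges and openness are config-exposed.

A protein is accepted as a negative when (1) it carries ≥ 8 GO terms in
total across namespaces; (2) its BP terms form exactly one cluster whose
score lies inside the open interval (0.1, 0.5); (3) at most one of its MF
clusters scores inside that band. A protein with no BP terms cannot satisfy
principle 2 and is rejected. Whether the published band is open or closed at
its edges is unstated; we read "between" as open. Negatives that share an
exact (case-normalized) sequence with any positive are removed.

## Evaluation

Stratified k-fold cross-validation (default 10; stratification keeps the
class ratio stable in every fold, which matters when one class is scarce).
Per-fold support-weighted precision, recall and F-score are averaged
arithmetically across folds; per-class values with a zero denominator are
set to 0 with a warning (bounded and conservative). ROC/AUC uses the full
threshold sweep with trapezoid integration; both per-fold AUCs and a single
pooled curve are reported, since it is not stated which a summary figure
should use. All fold plans are seeded and exhaustive (every id tests exactly
once).

## Enrichment test and the tail convention

Over-representation is tested with the exact hypergeometric upper tail: for
a population of N proteins containing M of a category, n draws and m
observed category members,

    P(X ≥ m) = 1 − CDF(m − 1).

`hypergeom_enrich` defaults to this standard inclusive convention. The
package's reference disease-association values for the human proteome case
study (N = 20,354 reviewed proteins, M = 7,250 predicted MPs, n = 2,894
disease-mapped proteins, m = 1,112 predicted MPs among them → P = 0.00033;
the complementary non-MP set M = 13,104, m = 1,782 → P = 0.99962) are
reproduced exactly by the strictly-exceeding tail P(X > m) = 1 − CDF(m),
not by the inclusive tail (which gives 0.00038 and 0.99967) — an off-by-one
between the stated formula and the computation that produced the reference
numbers. Both conventions are exposed (`tail="ge"` / `"gt"`); the acceptance
script reports the strict tail because that is the computation the reference
values came from. n = 2,894 is the sum 1,112 + 1,782, the only value
consistent with a disease-mapped set partitioned into MPs and non-MPs.
SciPy's hypergeometric survival function (computed stably in log space) does
the arithmetic.

## Synthetic benchmark

The generators emulate the statistical structure of the curated benchmark,
not its biology. Defaults: 200 proteins per class (close to the 268
positives / 162 negatives of the curated set while keeping runtimes
desk-scale), lengths uniform on [100, 300], per-view signal strengths 1.0.
Signals: class-1 sequences embed 5-mer motifs (Poisson rate 6 × signal);
class-1 profiles get an additive log-odds bias on three fixed columns;
class-1 residue background is exponentially tilted toward charged residues;
class-1 secondary structure is tilted toward helix/strand. At signal 0 the
two classes are drawn from one distribution per view. Per-record random
streams are derived from the global seed plus a CRC32 of the record id, so
regenerating any subset is byte-stable.

Because the Seq and AA views both derive from the sequence, their signals
are not perfectly orthogonal: sequence motifs slightly shift composition
even at AA signal 0. The label-independence guarantee holds exactly when all
signals are 0, which is what the no-signal tests assert.

The GO generator builds a three-namespace ontology with annotation counts
chosen analytically: leaves under a p = 0.4 ancestor share simRel ≈ 0.18
(inside the selection band) and leaves under a p = 0.02 ancestor share
≈ 0.62 (outside it), so planted proteins either satisfy all three selection
principles or violate exactly one, with known expected outcomes. Annotation
counts are carried in a separate term-counts table rather than derived from
the candidate proteins' own annotations, keeping database-wide statistics
decoupled from the screening inputs.

What passing tests show: the encoders are exact (oracle-checked), the
training harness does not leak labels, the stacked pipeline learns when
class signal exists (5-fold weighted F > 0.8 at full signal, 200/class) and
invents nothing when it does not (F ≈ 0.5 at zero signal), and the
negative-set screen applies the three principles exactly. What they do not
show: performance on real MoonProt-derived data, which requires external
PSI-BLAST and SSpro8 runs and the curated annotation corpus, and is out of
scope here.

## Problem sizes and other choices

The shipped benchmark scale (200 per class, 5 outer × 5 inner folds) was
chosen as a desk-scale working point; a full run of the synthetic end-to-end
suite takes a few minutes on one CPU. Forest grids are deliberately small
and declared in config. Model directories serialize sub-models with joblib
plus a JSON metadata file; loading refuses mismatched feature lengths.

Known limitations: the literal DAG frequency recursion over-counts
multi-parent descendants (variant provided); the recurrent architecture is
our own choice, unconstrained by the source description; synthetic profiles
are i.i.d. noise around residue identity and carry no realistic
substitution structure; the negative-set screen has no notion of evidence
codes (which the published screen also leaves unstated).
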