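# Methods

`evograph` annotates protein function from sequence-derived evolutionary
statistics and localizes each predicted function onto individual residues.
This note documents the model, its parameters and defaults, the synthetic
data used to validate it, and the numerical and design choices a user
should know about.

## Alignment statistics

An input alignment (FASTA or A3M; A3M lowercase/`.` insertion states are
removed so rows match the query's match columns) is trimmed by discarding
sequences with **more than** 80% gaps — the inequality is strict, and the
query row is always kept so residue indices cover the full target
sequence. Sequences are then reweighted by redundancy: the weight of a row
is 1/(number of rows at ≥ 80% identity, itself included), the standard
correction for uneven phylogenetic sampling; the sum of weights is the
effective depth M_eff.

Single-site and pair frequencies use q = 21 states (20 amino acids plus
the gap as its own state, which stabilizes the inverse-covariance step)
with a uniform pseudocount λ:

    f_i(a)    = λ/q  + (1−λ)·(weighted count)/M_eff,
    f_ij(a,b) = λ/q² + (1−λ)·(weighted pair count)/M_eff,   i ≠ j,

with diagonal blocks pinned to f_ii(a,b) = δ_ab f_i(a) so single- and
pair-marginals agree exactly. λ defaults to 0.5, the customary
regularization for mean-field coupling inference. Unknown residues (`X`)
contribute 1/20 of a count to every amino-acid state rather than becoming
a fake 22nd letter; this keeps unknowns from inducing spurious couplings.
Per-column conservation is 1 − H(f_i)/log q (1 = fully conserved,
0 = uniform) and is computed from *unregularized* (λ = 0) frequencies,
since the coupling pseudocount would flatten it.

## Evolutionary couplings (EVC channel)

Couplings are inferred by mean-field direct coupling analysis: the
connected correlation matrix C[(i,a),(j,b)] = f_ij(a,b) − f_i(a) f_j(b) is
assembled over the first q−1 = 20 states (the gap state is excluded from
the coupling norm, the usual guard against gap-driven edges), inverted,
and negated; the pair score is the Frobenius norm of each 20×20 block
after a zero-sum gauge transform. The average product correction

    APC(i,j) = S_ij − S_i·S_j / S̄

removes the entropic/phylogenetic background; negative corrected scores
are clipped to zero. Mean-field inversion was chosen over pseudo-likelihood
because it is deterministic, seconds-fast at alignment sizes a workstation
handles, and its planted-signal behaviour is well characterized; the
estimator sits behind a single function so an alternative can be swapped
in. Scores are normalized per protein by the maximum off-diagonal entry —
whether normalization should instead be global across a corpus is an open
choice; per-protein was selected because each protein's graph is built
independently. The EVC adjacency keeps pairs with normalized score
**≥ 0.2** (inclusive, matching the ≥ convention used for residue-site
calling).

## Residue communities (RC channel)

Communities — groups of residues with strong mutual couplings, the
coevolving "sectors" of a family — come from spectral analysis of the
normalized coupling matrix. Eigenmodes are retained when their eigenvalue
exceeds the largest eigenvalue observed across 20 structureless null
matrices, each built by shuffling the off-diagonal entries and
re-symmetrizing; the shuffle preserves the entry distribution exactly
while destroying all block structure. (A column-permutation null breaks
the symmetry of the matrix; the symmetric shuffle is the cleanest
equivalent.) Each residue is hard-assigned to the retained mode on which
its absolute loading is largest, provided that loading is at least 2/√L —
twice the root-mean-square loading of a flat eigenvector — and its
membership strength is the loading relative to the mode's peak.
Communities with fewer than two members are dropped. Hard assignment was
chosen because a residue's community is displayed and consumed as a single
color/group; soft assignment is a possible extension.

Note a geometric constraint: a block of k residues carries flat loadings
1/√k, so the 2/√L cutoff can only admit blocks with k > L/4 — community
detection is meaningful when the protein is several times larger than its
communities (e.g. 10-residue blocks need L ≳ 40). The RC adjacency
connects two residues when they share a community and both strengths are
≥ 0.2.

## Node features

The network consumes an L×D per-residue feature matrix. In production this
is an externally computed language-model embedding loaded from a plain
numeric text file (one residue per row; D = 1280 for the common
transformer embedding). For self-contained work the package provides
deterministic featurizers: one-hot (D = 21), a seeded per-letter random
projection of any width, and a sinusoidal positional encoding. Synthetic
experiments default to D = 32.

## Dual-channel graph network

Each channel applies three graph convolutions

    H^(k+1) = ReLU( D̂^{-1/2}(A+I)D̂^{-1/2} · H^(k) · W^(k) + b^(k) )

with its own adjacency (EVC or RC) and independent weights; hidden width
h defaults to 512 (32 in synthetic experiments). The channel outputs are
concatenated into the residue-resolved feature map F ∈ R^{L×2h} — the
only layer at which per-residue information still exists, and therefore
the layer that class-activation mapping reads — then summed over residues
(SumPooling; permutation-invariant, so predictions cannot depend on
residue order), passed through FC1 (2h→h, ReLU) and FC2 (h→F classes)
with dropout 0.3 applied between them, and squashed per class by a
sigmoid. The output is sigmoid rather than softmax because EC/GO
annotation is multi-label and the loss is a per-class binary
cross-entropy; a softmax head is available behind a config flag for the
single-label reading.

ReLU is used for all hidden activations; biases are present on every
layer. Weights are Glorot-uniform from a seeded generator. At training
start the final FC layer is set to zero so predictions open at the base
rate: with sum pooling over ~60 residues a fully random head starts deep
in sigmoid saturation (initial loss an order of magnitude above the
unsaturated F·log 2), which costs many epochs to escape.

## Training

The loss is

    L = −(1/N) Σ_{i=1..N} Σ_{j=1..F} [ y_ij log ŷ_ij + (1−y_ij) log(1−ŷ_ij) ]

— mean over samples, sum over classes — with predictions clipped to
[1e−7, 1−1e−7]. Optimization is Adam with learning rate 2·10⁻⁴, β₁ = 0.9,
β₂ = 0.999, ε = 10⁻⁶, and decoupled L2 weight decay 2·10⁻⁵ applied to
weight matrices only (not biases), batch size 64, at most 500 epochs.
Early stopping monitors validation loss with patience 20 (any improvement
resets the counter); the returned parameters are those of the best
validation epoch. An optional `target_validation_loss` stops training as
soon as validation loss crosses a target — useful when many replicate
models are trained and full convergence is not needed.

Within a minibatch, equal-length proteins are stacked into one 3-D tensor
and variable lengths fall back to per-length sub-stacks; the accumulated
gradient is identical to per-protein accumulation. Training arithmetic
runs in float32 (the standard deep-learning precision; on one CPU the
BLAS float32 path is several times faster than float64) and is
bit-reproducible given the seed; returned parameters are float64, and all
inference APIs are float64. Gradients are hand-written and verified
against central finite differences in the test suite. A NaN in any layer
or gradient aborts with the layer named.

## Residue-level scoring (class activation maps)

For function class c with predicted score Y^c (the post-sigmoid
probability; the pre-sigmoid logit is available behind a flag), neuron
importances and residue scores are

    α_k^c = (1/L) Σ_i ∂Y^c/∂F_i^k,      S^c(i) = ReLU( Σ_k α_k^c F_i^k ),

computed at the concatenated channel feature map — because sum pooling is
linear, ∂Y^c/∂F_i^k is the same for every residue i, and α is exactly
that shared gradient. Scores are normalized per protein to [0, 1] by the
maximum (an all-zero map stays zero); residues with normalized score
**≥ 0.5** are called functional sites. Per-protein normalization (rather
than per-class or global) was chosen because the score is read per
protein against that protein's reference sites. Profiles are compared to
curated reference sites by AUROC plus precision/recall of the called set.
The score says *which residues carry the evidence for this class*; when a
protein has several functions it does not discriminate which site belongs
to which of two overlapping functions beyond what the per-class gradients
separate.

## Evaluation metrics

* **F_max** (protein-centric): thresholds t ∈ {0, 0.01, …, 1}; at each t,
  precision is averaged over proteins with at least one prediction ≥ t
  and recall over proteins with at least one true term (the CAFA
  convention for the precision denominator); F_max is the maximum
  harmonic mean.
* **AUPR** (term-centric): per-term area under the precision–recall curve
  with step interpolation (average precision), macro-averaged over terms
  that have positives; terms without positives are skipped. A micro
  variant pools all (protein, term) pairs, and a literal threshold
  integral ∫₀¹ p(t)·r(t) dt is provided for comparison — that printed
  form is not the standard PR area and is not the default.
* **MCC**: Matthews correlation over confusion counts pooled across all
  (protein, term) pairs at cutoff 0.5; zero denominator yields 0.
* **Bootstrap**: proteins resampled with replacement (seeded); replicates
  whose resample has no positive truth are redrawn.
* **Identity-stratified evaluation**: given per-protein maximum identity
  to the training set (supplied by the caller; identity computation
  against a training corpus is outside the package), any metric is
  evaluated on the subsets with identity ≤ {30, 40, 50, 70, 95}%; empty
  strata are reported as missing.

No ontology ancestor propagation is applied to truths or predictions; the
evaluation report states this in its header.

## Synthetic data: what it emulates and what it does not

The generators exist so the entire pipeline can be validated against
known ground truth without external databases.

**Alignments.** Columns are sampled i.i.d. from per-column Dirichlet
draws; a planted pair (i, j, ρ) copies a fixed bijective image of column
i's letter into column j with probability ρ, giving analytically
controllable mutual information; a planted group couples all its members
to a latent column the same way (a coevolving sector that community
detection should find); conserved positions emit a dominant letter with
stated probability; gaps are i.i.d. Sequences are exchangeable — there is
no phylogeny — so redundancy reweighting is exercised only trivially, and
real alignments' tree-structured correlations (the main source of APC
background in practice) are absent. Passing the planted-pair recovery
tests therefore shows the estimator recovers direct dependencies at
realistic depth (M = 2000, L = 50), not that it is robust to phylogenetic
confounding.

**Labeled proteins.** Each of F = 4 function labels owns three designated
residues forming a clique in both channel adjacencies; the label fires
iff all three carry letters from the label's 12-letter residue class (a
coarse physicochemical class; prevalence 0.6³ ≈ 0.22). The rule is
deliberately symmetric over the block: symmetric-normalized propagation
gives all members of a clique identical representations, so only
block-symmetric statistics (here, the within-block class count) survive
the first convolution — a rule that depended on *which* block member
carried which letter would be unlearnable by construction, not merely
hard. Sparse background edges (p = 0.02) are drawn among non-motif
residues only, keeping the planted communities exact. Node features are
a seeded per-letter random projection (24 dims) concatenated with
sinusoidal positional encodings (8 dims, amplitude 3), scaled by 0.25 —
emulating the two essential properties of real sequence embeddings,
letter identity and position awareness, while keeping the sum-pooled head
unsaturated. What the synthetic task does not emulate: contextual
embeddings (real embedding rows depend on the whole sequence), correlated
labels, label noise at realistic rates (a noise-rate knob exists, default
0), and variable protein length (default fixed length for batching).
Success here shows the architecture, optimizer and attribution machinery
work end to end on a recoverable signal; it is not evidence about
transfer to real annotation corpora.

**Metric fixtures.** Truths are Bernoulli(0.2); predictions blend truth
with uniform noise under a quality knob, so metric implementations can be
checked against brute-force scans at every quality level.

## Problem sizes used by the test suite and acceptance script

Chosen so the full validation runs comfortably on a single CPU:
coupling recovery uses 20 alignments of M = 2000 × L = 50 with five
planted pairs at ρ = 0.9; community recovery uses two 10-residue blocks
in L = 50; the end-to-end task trains n = 2000 proteins of L = 60
(D = 32, h = 32, F = 4) for up to 500 epochs at the stated optimizer
settings; residue-localization robustness trains ten independent
scaled-down replicates (n = 1000, L = 30, up to 600 epochs, stopping at
validation loss 1.0) and reports the median AUROC of planted-site
recovery.

## Known limitations

* Mean-field DCA degrades on shallow alignments (M_eff ≲ L); the
  pseudocount keeps the inversion defined but couplings shrink toward
  zero. There is no phylogenetic correction beyond sequence reweighting.
* Community detection cannot see blocks smaller than ~L/4 residues (the
  flat-loading cutoff, above) and assigns each residue to one community
  only.
* The network operates on binary adjacencies; coupling magnitudes below/
  above threshold are discarded rather than used as edge weights.
* Training is CPU-bound NumPy: practical for corpora of thousands of
  ~100-residue proteins, not for tens of thousands of long chains.
* Residue scores are normalized per protein; absolute activation
  magnitudes are not comparable across proteins or models.
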