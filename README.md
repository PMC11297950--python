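# evograph

Statistics-informed graph networks for protein function annotation and
residue-level functional-site scoring, from sequence alone.

Given a multiple sequence alignment of a protein family, `evograph`

1. infers **evolutionary couplings** (EVCs) between residue pairs by
   mean-field direct coupling analysis with average product correction,
2. derives **residue communities** (RCs) — groups of strongly coupled,
   coevolving residues — by spectral analysis of the coupling matrix
   against a permutation null,
3. feeds per-residue features through a **dual-channel stacked graph
   convolutional network** whose two edge sets are the thresholded EVC and
   RC graphs, trained with multi-label binary cross-entropy to predict
   EC/GO-style function annotations, and
4. scores every residue's importance for a predicted function with
   **gradient-weighted class activation maps** (Grad-CAM), calling
   functional sites at activation ≥ 0.5.

The intended users are computational biologists who have alignments (or
precomputed per-residue embeddings) and want function predictions that can
be traced back to individual residues — binding pockets, catalytic sites —
without requiring a structure.

## Model

For a protein of length L with binary adjacency A (EVC or RC channel),
each graph convolution applies the symmetric normalized propagation

    H' = σ( D̂^{-1/2} (A + I) D̂^{-1/2} · H · W + b ),      σ = ReLU,

three layers per channel with hidden width h. The channel outputs are
concatenated into the residue-resolved feature map F ∈ R^{L×2h}, sum-pooled
over residues, and passed through two fully connected layers (ReLU, then
dropout 0.3) to per-class sigmoid probabilities Y^c. Training minimizes

    L = −(1/N) Σ_i Σ_j [ y_ij log ŷ_ij + (1−y_ij) log(1−ŷ_ij) ]

with Adam (lr 2·10⁻⁴, β₁ 0.9, β₂ 0.999, ε 10⁻⁶, decoupled L2 weight decay
2·10⁻⁵), batch size 64, at most 500 epochs, early-stopped on validation
loss. Residue importance for class c is

    S^c(i) = ReLU( Σ_k α_k^c F_i^k ),   α_k^c = (1/L) Σ_i ∂Y^c/∂F_i^k,

normalized per protein to [0, 1]. Evaluation uses the CAFA-style
protein-centric F_max, term-centric AUPR, and pooled MCC.

Everything is plain NumPy (float64) with hand-written backward passes;
given a seed, runs are bit-reproducible.

## Worked example

`examples/01_evolutionary_signatures.py` builds a 500×40 synthetic
alignment with a planted five-residue coevolving sector (residues 3, 10,
24, 32, 37, 1-based), one planted covarying pair (4–18) and two conserved
positions, then runs the statistics pipeline:

```
alignment: 500 sequences x 40 columns, effective depth 500.0
most conserved positions (1-based): [(6, 0.827), (21, 0.764), (27, 0.19)]
top coupled pairs (1-based, score):
    4 -  18  1.000
    3 -  24  0.414
    3 -  37  0.409
   24 -  37  0.385
    3 -  32  0.381
    3 -  10  0.371
   24 -  32  0.368
   10 -  24  0.363
EVC adjacency at threshold 0.2: 11 edges
residue communities found: 1
  community 1: residues [3, 10, 24, 32, 37]
RC adjacency: 10 edges
```

The planted pair tops the coupling ranking, the sector's mutual pairs
fill the next ranks well above the APC noise floor, the planted conserved
columns 6 and 21 lead the conservation ranking, and spectral analysis
recovers the sector as a single residue community — exactly the planted
five residues. `02_function_prediction.py`
and `03_functional_sites.py` continue the pipeline: training the network
on a synthetic labeled dataset and localizing each predicted function onto
its causal residues.

There is also a thin CLI (`evograph signatures | simulate | train |
predict | sites | eval`) for running the same steps from a shell; every
subcommand takes `--seed` and writes 1-based residue indices.

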