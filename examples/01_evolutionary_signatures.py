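"""Evolutionary signatures from an alignment: couplings, communities,
conservation.

Builds a synthetic alignment of 500 sequences x 40 columns with a planted
five-residue coevolving sector, one planted covarying column pair and two
strongly conserved positions, then runs the full statistics pipeline: gap
trimming, redundancy reweighting, frequency estimation, mean-field
coupling inference with average product correction, per-protein
normalization, and spectral community detection.

Run:  python examples/01_evolutionary_signatures.py
"""

import numpy as np

from evograph import (
    SyntheticMsaSpec,
    compute_weights,
    conservation,
    detect_communities,
    frequencies,
    generate_msa,
    infer_couplings,
    normalize_couplings,
    rc_adjacency,
    threshold_adjacency,
    trim_msa,
)

SECTOR = [2, 9, 23, 31, 36]  # a coevolving group, the signature of an RC
PAIRS = [(3, 17, 0.95)]

spec = SyntheticMsaSpec(
    L=40,
    M=500,
    planted_pairs=PAIRS,
    planted_groups=[(SECTOR, 0.9)],
    conserved_positions=[(5, 0.95), (20, 0.9)],
    gap_rate=0.05,
    seed=7,
)
msa = trim_msa(generate_msa(spec))
weights = compute_weights(msa)
freqs = frequencies(msa, weights)

print(f"alignment: {msa.depth} sequences x {msa.length} columns, "
      f"effective depth {freqs.effective_depth:.1f}")

# conservation from unregularized frequencies (the DCA pseudocount would
# flatten it)
cons = conservation(frequencies(msa, weights, pseudocount=0.0))
top_cons = np.argsort(cons)[::-1][:3]
print("most conserved positions (1-based):",
      [(int(i) + 1, round(float(cons[i]), 3)) for i in top_cons])
# the two planted conserved positions (6 and 21) should lead this list

couplings = normalize_couplings(infer_couplings(freqs))
iu = np.triu_indices(msa.length, 1)
order = np.argsort(couplings.scores[iu])[::-1]
print("top coupled pairs (1-based, score):")
for t in order[:8]:
    i, j = int(iu[0][t]) + 1, int(iu[1][t]) + 1
    print(f"  {i:3d} - {j:3d}  {couplings.scores[i - 1, j - 1]:.3f}")
# the planted pair (4-18) and the sector's mutual pairs should fill the
# top ranks; everything else sits near the APC noise floor

adjacency = threshold_adjacency(couplings, threshold=0.2)
print(f"EVC adjacency at threshold 0.2: {int(adjacency.entries.sum()) // 2} edges")

rcs = detect_communities(couplings, seed=7)
print(f"residue communities found: {len(rcs.communities)}")
for k, comm in enumerate(rcs.communities, 1):
    members = sorted(i + 1 for i in comm.members)
    print(f"  community {k}: residues {members}")
rc = rc_adjacency(rcs, threshold=0.2)
print(f"RC adjacency: {int(rc.entries.sum()) // 2} edges")
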