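"""Fit the directional substitution matrix and compare it to BLOSUM62.

The matrix entry d(i, j) is the mean normalized impact of substituting
residue i with j, pooled over all proteins and positions.  Unlike
symmetric log-odds matrices, it is directional: d(i, j) differs from
d(j, i), and the element-wise difference from the transpose quantifies
that asymmetry.
"""

from dmsimpact import (
    asymmetry,
    compare_matrices_by_row,
    compare_matrices_elementwise,
    fit_matrix,
    load_blosum,
)
from dmsimpact.synthetic import SyntheticSpec, generate_corpus

corpus = generate_corpus(SyntheticSpec(seed=7))
matrix = fit_matrix([p.scores for p in corpus.training_corpus()])

print(f"observed substitution types: {(matrix.counts > 0).sum()} / 380")
print(f"d(P, G) = {matrix['P', 'G']:+.3f}   d(G, P) = {matrix['G', 'P']:+.3f}")
asym = asymmetry(matrix)
print(f"asymmetry d(P,G) - d(G,P) = {asym[12, 5]:+.3f}  (P index 12, G index 5)")

blosum = load_blosum("BLOSUM62")
rho = compare_matrices_elementwise(matrix, blosum)
rows = compare_matrices_by_row(matrix, blosum)
print(f"\nelement-wise Spearman rho vs BLOSUM62 over 400 cells: {rho:+.3f}")
print(f"per-row rho range: {min(rows.values()):+.3f} .. {max(rows.values()):+.3f}")
print(
    "\nOn this synthetic corpus the ground-truth matrix is random, so the"
    "\nBLOSUM correlation is near zero; on real DMS data the fitted matrix"
    "\nrank-correlates strongly with high-numbered BLOSUM matrices."
)
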