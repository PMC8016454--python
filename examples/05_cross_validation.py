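"""Leave-one-out cross-validation over whole proteins.

Each fold removes one protein, refits the substitution matrix and the
regression on the rest, predicts the held-out protein's measured variants
and scores them by Spearman correlation.  Splitting at the protein level
(never the variant level) avoids leaking per-position correlation
structure between train and test.
"""

from dmsimpact import leave_one_out
from dmsimpact.synthetic import SyntheticSpec, generate_corpus

corpus = generate_corpus(SyntheticSpec(seed=7))
report = leave_one_out(corpus.training_corpus())

print("held-out protein   n variants   Spearman rho")
for pid, rho in sorted(report.per_protein.items()):
    print(f"{pid:<18} {report.n_variants[pid]:>10}   {rho:+.4f}")
print(f"\nmedian held-out rho: {sorted(report.per_protein.values())[len(report.per_protein) // 2]:+.4f}")
print(f"per-position correlations computed at {len(report.per_position)} positions")
print(
    "\nBecause this corpus is generated from the model itself with small"
    "\nnoise, held-out correlations near 1 confirm that the refit matrix and"
    "\ncoefficients generalize across proteins; on real data typical values"
    "\nare far lower."
)
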