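"""Train the full model on a synthetic corpus and predict a query protein.

The workflow is the production one: normalize and merge DMS datasets, fit
the directional substitution matrix, assemble (entropy, log2 variant
frequency, matrix entry) features, fit the ordinary least squares
coefficients, then score every possible substitution of a query sequence.
"""

from dmsimpact import fit_matrix, predict, train
from dmsimpact.synthetic import SyntheticSpec, generate_corpus

corpus = generate_corpus(SyntheticSpec(seed=7))
training = corpus.training_corpus()
matrix, coefs = train(training)

print(
    "fitted coefficients: "
    f"intercept={coefs.beta0:+.4f}  entropy={coefs.beta1:+.4f}  "
    f"log2_freq={coefs.beta2:+.4f}  matrix={coefs.beta3:+.4f}"
)
print(
    "generating values:   "
    f"intercept={corpus.true_coefficients.beta0:+.4f}  "
    f"entropy={corpus.true_coefficients.beta1:+.4f}  "
    f"log2_freq={corpus.true_coefficients.beta2:+.4f}  "
    f"matrix={corpus.true_coefficients.beta3:+.4f}"
)

print(
    "(slopes match the generating model closely; the intercept differs"
    "\nbecause rank normalization re-expresses responses on the quantile"
    "\nscale, which shifts the level but barely distorts the ordering)"
)

pid = training[0].protein_id
table = predict(
    corpus.sequences[pid], training[0].profile, matrix, coefs, query_id=pid
)
print(f"\n{len(table)} predictions for {pid} (length {len(corpus.sequences[pid])}):")
print(table.head(5).to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
print(
    "\nscore is the predicted fitness impact in quantile units (0 = neutral,"
    "\nnegative = deleterious); the three contribution columns sum with the"
    "\nintercept to the score exactly, making each prediction decomposable."
)
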