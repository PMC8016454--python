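# Methods

This note documents the models, conventions and numerical choices behind
`dmsimpact`, including the places where the design was genuinely open and
a convention had to be fixed.

## Rank normalization of DMS data

Each dataset's missense variants (nonsense `*` and synonymous records are
removed first) are ranked ascending by raw score, ties receiving the mean
of their tied ranks, and mapped to quantiles `q(r) = (r − 1)/(n − 1)`.
This convention — rather than `r/n` or `(r − ½)/n` — is chosen because it
makes the per-dataset score distribution span exactly `[0, 1]`, i.e. a
range of exactly 1, which downstream contracts rely on.

The wild-type reference score is ranked within the pooled variant scores
under the same convention: if it ties one or more variants it takes their
mean tied-rank quantile; if it falls strictly between two variant scores
its quantile is the linear interpolation of the two neighbouring
quantiles; outside the observed range it clamps to 0 or 1. Subtracting
this wild-type quantile anchors 0 at "no fitness change", so normalized
values lie in `[−1, 1]`. When a dataset carries no explicit wild-type
measurement, the mean of its synonymous-variant scores (captured before
filtering) substitutes; if neither exists the dataset is rejected.

A consequence of the interpolation rule worth knowing: rank
normalization is invariant under strictly monotone transforms of the
assay scale *except* for the interpolated anchor, which is
scale-dependent when the wild-type score falls strictly between two
variant scores. The discrepancy is a single constant shift of all values,
bounded by one quantile step `1/(n − 1)` — negligible for realistic
dataset sizes (≲ 8 × 10⁻⁴ for a full 70-position scan) and exactly zero
whenever the wild-type score ties a variant. Rank-based quantities
(Spearman evaluations, matrix cell orderings within a dataset) are
unaffected.

Datasets covering the same protein are merged **after** normalization by
averaging values for shared variants; merging raw scores would mix assay
scales.

## The directional substitution matrix

Cell `(i, j)` is the arithmetic mean of all normalized scores with wild
type `i` and variant `j`, pooled across proteins with equal per-variant
weight (a merged variant counts once regardless of how many source
datasets contributed to it). The diagonal is fixed at 0 — no
substitution, no impact. Cells with zero observations are stored as
missing (`NaN`, count 0), never as 0, and refuse silent use: predictions
and matrix comparisons raise unless the caller restricts or imputes
explicitly. Units are quantile change, so off-diagonal values lie in
`[−1, 1]`.

Residues are ordered alphabetically by one-letter code
(`ACDEFGHIKLMNPQRSTVWY`) in memory and in all files; property-grouped
orderings seen in figures are presentation only. BLOSUM matrices come
from biopython's bundled copies of the NCBI files (an NCBI-format text
parser is included for files distributed with BLAST+); ambiguity codes
B, Z, X and `*` are dropped. Matrix comparisons use Spearman correlation
over all 400 aligned cells — the diagonal included, and the same choice
is applied to the per-row comparisons for consistency, since nothing in
the comparison's definition distinguishes the diagonal.

## Homolog profiles

Hits are consumed from blastp tabular output
(`-outfmt "6 sseqid pident length gaps evalue bitscore qstart qend qseq sseq"`)
or from a pre-stacked alignment (one length-L row per homolog).
Filtering keeps one HSP per subject (highest bitscore, ties by lower
E-value then subject id), removes hits with identity < 20% or gap
fraction > 10% of the alignment length (the reported `pident` and
`gaps`/`length` fields are trusted, not recomputed), and retains the top
500 survivors by bitscore. The gap-fraction denominator is the alignment
length, not the query span; both thresholds are non-strict at the
boundary (exactly 20% identity or exactly 10% gaps survives).

Stacking walks each HSP along query coordinates: columns where the query
has a gap (subject insertions) map to no query position; columns where
the subject has a gap or a non-standard residue (X, B, Z, J, U, O)
contribute nothing. The query's own residue is always counted once per
position, so every column has at least one observation regardless of the
database searched — a deliberate choice that makes profiles
database-independent (a self-hit would usually supply this count anyway).
A pseudocount of 1e−4 is added to each of the 20 counts (to counts, not
frequencies), counts are normalized to frequencies, and conservation is
the Shannon entropy `H = −Σ f log₂ f` in bits. A position covered only
by the query therefore has entropy ≈ 0.028 bits, not exactly 0: the 19
pseudocounts carry a sliver of probability.

## The linear model

Features per variant: position entropy `H` (bits), `log₂` of the variant
residue's frequency (finite by pseudocount; spans roughly −19 to 0 at
depth 500), and the matrix entry `d(wt, var)` (quantile units).
Coefficients are fit by ordinary least squares — deterministic QR-based
solve, no regularization — over pooled variants with equal weight. A
rank-deficient design (constant or collinear feature) raises an error
naming the offending column. Entropy enters the fit un-negated; the
standalone conservation predictor is exposed as `−H` so that, like the
other two single-feature predictors, larger values mean higher predicted
fitness. Spearman magnitudes are sign-invariant, so this is presentation
only.

Prediction enumerates all 19 substitutions at every standard-residue
position (non-standard query residues are skipped with a warning) and
reports the score together with the three products `β·feature`, which sum
with the intercept to the score exactly. Within a position the ranking
of variants never depends on `β₀` or `β₁` (entropy is constant there).
The matrix argument is pluggable: any 20×20 table (e.g. a BLOSUM matrix)
can replace the DMS-fit matrix to measure how much the directional matrix
itself contributes.

## Evaluation

Spearman's ρ is computed on the intersection of predicted and measured
variant keys, never by imputation. Per-position correlations require at
least three shared variants (fewer yields only trivial ±1 values), and
undefined correlations (zero rank variance) are reported as missing
rather than 0. Leave-one-out cross-validation removes whole proteins —
variants at one position are strongly correlated, so splitting within a
protein would leak — and refits both the matrix and the coefficients in
every fold; folds are processed in a fixed protein-id order so results
are independent of input ordering. Matrix cells left unobserved by a
fold's training data cause the affected held-out variants to be skipped
with a warning.

## Synthetic corpora

The generator emulates exactly the structure the linear model assumes.
Per protein: a random sequence; per position, a residue distribution
mixing a point mass on the wild-type residue with a flat Dirichlet
background, with a mixing weight drawn as `concentration × Exp(1)` so
column sharpness varies across positions (concentration → ∞ gives
perfectly conserved columns, 0 gives near-uniform ones); homolog rows
drawn i.i.d. from these distributions. Responses are computed from the
*realized* profile features (the same `build_profile` code path the
pipeline uses) plus a random directional matrix, via the linear model
with i.i.d. Gaussian noise; raw assay scores are an affine transform of
the response with a per-dataset scale and offset, so rank normalization
has real work to undo, and the wild-type raw score is the offset (the
wild type has response 0 by construction).

Defaults: 8 proteins × 70 positions × 19 variants (10 640 variants — a
desk-scale miniature of a multi-protein training corpus, chosen to keep
the full pipeline under a second), 50 homologs per protein, noise SD
0.05 quantile units (small relative to the unit range of normalized
scores), concentration 5 (most positions fairly conserved, with spread).
Identical specs yield byte-identical files.

Because rank normalization maps responses to quantiles — a monotone but
non-affine distortion — coefficients refit through the full
normalization path match the generating slopes only approximately (and
the intercept shifts with the quantile scale). Exact recovery
identities (zero-noise OLS to ≤ 1e−10) are therefore checked on the
generator's serialized ground-truth responses, while the normalization
path is validated by rank-based criteria: held-out LOO correlations and
monotone-transform invariance. Matrix-cell recovery is exact when the
generating model is matrix-only (β = (0, 0, 0, 1), zero noise), since
each response then equals its matrix cell.

What the generator does **not** emulate: real DMS error structure
(bottlenecking, selection dynamics, sequencing noise), partial coverage,
phylogenetic correlation among homologs, alignment errors, or any
dependence between positions. Green tests on synthetic corpora establish
pipeline correctness, not predictive accuracy on real proteins.

## Known limitations

- The conventions for tie handling, the exact quantile formula and the
  wild-type anchoring rule are declared choices; other reasonable
  conventions differ by at most one quantile step per dataset.
- Whether per-row matrix comparisons should include the diagonal cell is
  a judgment call; including it keeps them consistent with the 400-cell
  element-wise comparison.
- The model treats positions independently; epistasis and
  position-position couplings are out of scope by design.
- Live homolog search requires an external `blastp` and a formatted
  database; the package does not ship or download one.
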