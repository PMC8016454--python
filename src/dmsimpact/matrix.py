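"""Directional amino-acid substitution matrices from DMS data.

The matrix entry ``d(i, j)`` is the mean normalized fitness impact, pooled
across all proteins and positions, of substituting wild-type residue *i*
with variant residue *j*.  Unlike alignment-derived log-odds matrices
(BLOSUM), the matrix is directional: ``d(i, j) != d(j, i)`` in general,
e.g. substitutions *to* proline are typically more damaging than
substitutions *from* it.  Diagonal entries are fixed at 0, representing
no substitution.  Units are quantile change (see :mod:`dmsimpact.normalize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import spearmanr

from ._residues import AA_INDEX, AMINO_ACIDS, N_AA
from .datasets import NormalizedScores
from .errors import MissingCellError

__all__ = [
    "DirectionalMatrix",
    "LogOddsMatrix",
    "fit_matrix",
    "asymmetry",
    "compare_matrices_elementwise",
    "compare_matrices_by_row",
    "load_blosum",
    "read_ncbi_matrix",
]


@dataclass
class DirectionalMatrix:
    """20x20 mean-impact matrix over ordered residue pairs.

    ``values[i, j]`` is the mean normalized impact of substituting residue
    ``AMINO_ACIDS[i]`` with ``AMINO_ACIDS[j]``; NaN marks a cell with no
    observations (distinct from an observed mean of 0).  ``counts`` holds
    the number of contributing observations per cell.
    """

    values: np.ndarray
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_AA, N_AA), dtype=int)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != (N_AA, N_AA) or self.counts.shape != (N_AA, N_AA):
            raise ValueError("matrix and counts must be 20x20")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        wt, var = pair
        return float(self.values[AA_INDEX[wt], AA_INDEX[var]])

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of unobserved off-diagonal cells."""
        return np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def lookup(self, wt: str, var: str) -> float:
        """Value for an observed cell; raises :class:`MissingCellError` if absent."""
        val = self[wt, var]
        if np.isnan(val):
            raise MissingCellError(
                f"substitution {wt}->{var} has no observations in the fitted matrix"
            )
        return val

    def to_frame(self):
        import pandas as pd

        letters = list(AMINO_ACIDS)
        return pd.DataFrame(self.values, index=letters, columns=letters)

    def write(self, path: str | Path) -> None:
        """Write as TSV: header row/column of residue letters, ``NA`` for missing."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, aa in enumerate(AMINO_ACIDS):
                cells = [
                    "NA" if np.isnan(v) else repr(float(v))
                    for v in self.values[i]
                ]
                fh.write(aa + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "DirectionalMatrix":
        """Read a matrix TSV written by :meth:`write` (or any 20x20 TSV)."""
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            cols = [c for c in header if c]
            if cols != list(AMINO_ACIDS):
                raise ValueError(
                    f"matrix file {path}: expected residue columns "
                    f"{AMINO_ACIDS}, got {''.join(cols)}"
                )
            values = np.full((N_AA, N_AA), np.nan)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not parts or parts[0] not in AA_INDEX:
                    continue
                i = AA_INDEX[parts[0]]
                for j, cell in enumerate(parts[1 : N_AA + 1]):
                    values[i, j] = np.nan if cell == "NA" else float(cell)
        counts = (~np.isnan(values)).astype(int)
        np.fill_diagonal(counts, 0)
        return cls(values=values, counts=counts)


@dataclass
class LogOddsMatrix:
    """Symmetric log-odds substitution matrix (e.g. BLOSUM62), half-bit units."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_AA, N_AA):
            raise ValueError("log-odds matrix must be 20x20 over standard residues")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        wt, var = pair
        return float(self.values[AA_INDEX[wt], AA_INDEX[var]])


def _as_logodds(obj) -> LogOddsMatrix:
    """Restrict a biopython substitution matrix to the 20 standard residues."""
    values = np.zeros((N_AA, N_AA))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            values[i, j] = obj[a, b]
    return LogOddsMatrix(values=values)


def load_blosum(name: str) -> LogOddsMatrix:
    """Load a named BLOSUM matrix (e.g. ``"BLOSUM62"``) bundled with biopython."""
    mat = _as_logodds(substitution_matrices.load(name.upper()))
    mat.name = name.upper()
    return mat


def read_ncbi_matrix(path: str | Path) -> LogOddsMatrix:
    """Parse an NCBI-format matrix text file (as distributed with BLAST+).

    Non-standard residue rows/columns (B, Z, X, ``*``) are dropped.
    """
    with open(path) as fh:
        mat = _as_logodds(substitution_matrices.read(fh))
    mat.name = Path(path).stem
    return mat


def fit_matrix(data: list[NormalizedScores]) -> DirectionalMatrix:
    """Fit the directional matrix by per-ordered-pair averaging.

    Cell ``(i, j)``, ``i != j``, is the arithmetic mean of every
    normalized score whose wild type is *i* and variant is *j*, pooled
    across proteins with equal per-variant weight.  Diagonal values are
    set to 0 (no substitution).  Cells with no observations are NaN with
    count 0 — missing, not zero-impact.
    """
    sums = np.zeros((N_AA, N_AA))
    counts = np.zeros((N_AA, N_AA), dtype=int)
    for scores in data:
        for (pos, wt, var), val in scores.entries.items():
            i, j = AA_INDEX[wt], AA_INDEX[var]
            sums[i, j] += val
            counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(counts, 0)
    return DirectionalMatrix(values=values, counts=counts)


def asymmetry(matrix: DirectionalMatrix) -> np.ndarray:
    """Directional asymmetry ``M - M^T`` (antisymmetric, zero diagonal).

    Entry ``(i, j)`` is negative when substituting *i* with *j* is on
    average more detrimental than the reverse substitution.  Missing
    cells propagate as NaN.
    """
    return matrix.values - matrix.values.T


def _require_complete(matrix: DirectionalMatrix) -> None:
    if not matrix.is_complete:
        missing = int(np.isnan(matrix.values).sum())
        raise MissingCellError(
            f"matrix has {missing} unobserved cell(s); restrict the comparison "
            "or impute explicitly before comparing"
        )


def compare_matrices_elementwise(a: DirectionalMatrix, b: LogOddsMatrix) -> float:
    """Spearman rank correlation over all 400 aligned cells (diagonal included)."""
    _require_complete(a)
    rho, _ = spearmanr(a.values.ravel(), b.values.ravel())
    return float(rho)


def compare_matrices_by_row(a: DirectionalMatrix, b: LogOddsMatrix) -> dict[str, float]:
    """Per-wild-type-residue Spearman correlation between matrix rows.

    For each residue, the two aligned 20-element rows (diagonal cell
    included) are rank-correlated.  Returns a mapping residue -> rho.
    """
    _require_complete(a)
    out: dict[str, float] = {}
    for i, aa in enumerate(AMINO_ACIDS):
        rho, _ = spearmanr(a.values[i], b.values[i])
        out[aa] = float(rho)
    return out
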