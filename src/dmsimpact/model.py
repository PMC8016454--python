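"""Linear variant-impact model.

The predicted fitness impact of substituting wild-type residue *wt* with
*var* at position *p* of sequence *s* is

    score = b0 + b1 * H(s, p) + b2 * log2 f(s, p, var) + b3 * d(wt, var)

where H is the position's Shannon entropy across homologs (conservation),
f is the variant residue's pseudocounted frequency across homologs, and d
is the directional substitution-matrix entry fit from DMS data.  The
coefficients are fit by ordinary least squares over pooled training
variants, with equal weight per variant.  Being linear, every prediction
decomposes exactly into three per-feature contributions plus the
intercept, which is what makes the model interpretable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._residues import AA_INDEX, AMINO_ACIDS
from .datasets import NormalizedScores
from .errors import ConsistencyError, SingularDesignError
from .homologs import HomologProfile
from .matrix import DirectionalMatrix

__all__ = [
    "ModelCoefficients",
    "assemble_features",
    "fit_coefficients",
    "predict",
    "single_feature_predictors",
]

FEATURE_COLUMNS = ["entropy", "log2_var_freq", "matrix_value"]
_COEF_LABELS = ["intercept", "entropy", "log2_var_freq", "matrix"]


@dataclass
class ModelCoefficients:
    """Intercept and three slopes of the linear impact model."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        for name in ("beta0", "beta1", "beta2", "beta3"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for label, val in zip(_COEF_LABELS, self.as_array()):
                fh.write(f"{label}\t{float(val)!r}\n")

    @classmethod
    def read(cls, path: str | Path) -> "ModelCoefficients":
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    label, val = line.split("\t")
                    values[label] = float(val)
        missing = [l for l in _COEF_LABELS if l not in values]
        if missing:
            raise ValueError(f"coefficients file {path} lacks {missing}")
        return cls(*(values[l] for l in _COEF_LABELS))


def _matrix_value(matrix, wt: str, var: str) -> float:
    """Cell lookup that raises on unobserved cells of a fitted matrix."""
    if isinstance(matrix, DirectionalMatrix):
        return matrix.lookup(wt, var)
    return float(matrix[wt, var])


def assemble_features(
    scores: NormalizedScores,
    profile: HomologProfile,
    matrix,
) -> pd.DataFrame:
    """Pair each measured variant with its three model features.

    Returns one row per variant with columns ``position``, ``wt``, ``var``,
    the three features (``entropy``, ``log2_var_freq``, ``matrix_value``)
    and the observed normalized impact ``dfitness``.

    Raises
    ------
    ConsistencyError
        If a variant's wild-type residue disagrees with the query sequence
        at that position, or a position exceeds the profile length.
    MissingCellError
        If a required substitution-matrix cell is unobserved.
    """
    rows = []
    for (pos, wt, var), observed in sorted(scores.entries.items()):
        if pos > profile.length:
            raise ConsistencyError(
                f"protein {scores.protein_id!r}: variant position {pos} exceeds "
                f"profile length {profile.length}"
            )
        seq_wt = profile.query_seq[pos - 1]
        if seq_wt != wt:
            raise ConsistencyError(
                f"protein {scores.protein_id!r} position {pos}: dataset says "
                f"wild type {wt!r} but the sequence has {seq_wt!r}"
            )
        rows.append(
            {
                "protein_id": scores.protein_id,
                "position": pos,
                "wt": wt,
                "var": var,
                "entropy": float(profile.entropy[pos - 1]),
                "log2_var_freq": float(np.log2(profile.frequency(pos, var))),
                "matrix_value": _matrix_value(matrix, wt, var),
                "dfitness": observed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "position",
            "wt",
            "var",
            *FEATURE_COLUMNS,
            "dfitness",
        ],
    )


def fit_coefficients(records: pd.DataFrame) -> ModelCoefficients:
    """Ordinary least squares fit of the four model coefficients.

    Deterministic closed-form solve (QR-based least squares); no
    regularization, no stochastic optimization.

    Raises
    ------
    SingularDesignError
        If the design matrix is rank deficient, naming the offending
        column (a constant or collinear feature).
    """
    if len(records) < 4:
        raise ValueError(
            f"need at least 4 records to fit 4 coefficients, got {len(records)}"
        )
    X = np.column_stack(
        [np.ones(len(records))] + [records[c].to_numpy(float) for c in FEATURE_COLUMNS]
    )
    y = records["dfitness"].to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column: smallest |diag(R)| of the QR factor
        _, R = np.linalg.qr(X)
        offender = _COEF_LABELS[int(np.argmin(np.abs(np.diag(R))))]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < 4); "
            f"column {offender!r} is constant or collinear",
            column=offender,
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return ModelCoefficients(*map(float, beta))


def predict(
    query_seq: str,
    profile: HomologProfile,
    matrix,
    coefficients: ModelCoefficients,
    query_id: str = "",
) -> pd.DataFrame:
    """Predict the impact of every possible substitution in a query.

    Returns a table with 19 rows per standard-residue position: predicted
    ``score``, the three feature values, and the three per-feature
    contributions (coefficient times feature).  The identity
    ``score == b0 + contribution_entropy + contribution_freq +
    contribution_matrix`` holds exactly for every row.  Positions whose
    query residue is non-standard (e.g. X) are skipped with a warning.
    """
    if profile.length != len(query_seq):
        raise ConsistencyError(
            f"profile length {profile.length} does not match query length "
            f"{len(query_seq)}"
        )
    b = coefficients
    rows = []
    for p, wt in enumerate(query_seq, start=1):
        if wt not in AA_INDEX:
            warnings.warn(
                f"position {p}: non-standard residue {wt!r} skipped", stacklevel=2
            )
            continue
        h = float(profile.entropy[p - 1])
        c_entropy = b.beta1 * h
        for var in AMINO_ACIDS:
            if var == wt:
                continue
            log2f = float(np.log2(profile.frequency(p, var)))
            d = _matrix_value(matrix, wt, var)
            c_freq = b.beta2 * log2f
            c_mat = b.beta3 * d
            rows.append(
                {
                    "pos": p,
                    "WT": wt,
                    "var": var,
                    "score": b.beta0 + c_entropy + c_freq + c_mat,
                    "entropy": h,
                    "log2f_var": log2f,
                    "matrix": d,
                    "contribution_entropy": c_entropy,
                    "contribution_freq": c_freq,
                    "contribution_matrix": c_mat,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "pos",
            "WT",
            "var",
            "score",
            "entropy",
            "log2f_var",
            "matrix",
            "contribution_entropy",
            "contribution_freq",
            "contribution_matrix",
        ],
    )
    if query_id:
        table.attrs["query_id"] = query_id
    return table


def single_feature_predictors(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """The three component features as standalone predictors.

    Returns ``conservation`` (negated entropy, so that a higher predicted
    value means higher fitness, matching the orientation of the other
    predictors), ``frequency`` (log2 variant frequency, unchanged) and
    ``matrix`` (the directional matrix entry, unchanged).
    """
    return {
        "conservation": -records["entropy"].to_numpy(float),
        "frequency": records["log2_var_freq"].to_numpy(float),
        "matrix": records["matrix_value"].to_numpy(float),
    }
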