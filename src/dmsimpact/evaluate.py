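"""Evaluation of predicted substitution impacts against measured DMS data.

Agreement is always measured with Spearman's rank correlation, per
protein over the intersection of predicted and measured variants, and per
position over each position's variants (positions with fewer than three
shared variants are omitted to avoid trivial correlations of +/-1).
Leave-one-out cross-validation removes whole proteins — never individual
variants, since variants at one position are strongly correlated and must
not straddle the train/test split — and refits both the substitution
matrix and the regression coefficients on each fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datasets import NormalizedScores
from .errors import MissingCellError
from .homologs import HomologProfile
from .matrix import fit_matrix
from .model import ModelCoefficients, assemble_features, fit_coefficients

__all__ = [
    "spearman",
    "evaluate_per_protein",
    "evaluate_per_position",
    "leave_one_out",
    "TrainingProtein",
    "EvaluationReport",
]


def spearman(x, y) -> float:
    """Spearman's rank correlation (Pearson correlation of mean-tie ranks).

    Returns NaN (missing) when either vector has zero rank variance, where
    the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = spearmanr(x, y)
    return float(rho)


def _paired(predictions: pd.DataFrame, measured: NormalizedScores) -> pd.DataFrame:
    pred = {
        (int(row.pos), row.WT, row.var): float(row.score)
        for row in predictions.itertuples(index=False)
    }
    rows = []
    for (pos, wt, var), measured_val in measured.entries.items():
        predicted = pred.get((pos, wt, var))
        if predicted is not None:
            rows.append(
                {
                    "position": pos,
                    "wt": wt,
                    "var": var,
                    "predicted": predicted,
                    "measured": measured_val,
                }
            )
    return pd.DataFrame(rows, columns=["position", "wt", "var", "predicted", "measured"])


def evaluate_per_protein(predictions: pd.DataFrame, measured: NormalizedScores) -> float:
    """Spearman rho between predictions and measurements over shared variants.

    Variants missing from either side are excluded, never imputed.  Raises
    if no variant is shared.
    """
    pairs = _paired(predictions, measured)
    if pairs.empty:
        raise ValueError(
            f"no shared variants between predictions and measurements for "
            f"protein {measured.protein_id!r}"
        )
    return spearman(pairs["predicted"], pairs["measured"])


def evaluate_per_position(
    predictions: pd.DataFrame,
    measured: NormalizedScores,
    min_variants: int = 3,
) -> dict[int, float]:
    """Per-position Spearman rho over each position's shared variants.

    Positions with fewer than ``min_variants`` shared variants are
    omitted; undefined correlations (all-tied ranks) are omitted as well
    rather than reported as 0.
    """
    pairs = _paired(predictions, measured)
    out: dict[int, float] = {}
    for pos, grp in pairs.groupby("position"):
        if len(grp) < min_variants:
            continue
        rho = spearman(grp["predicted"], grp["measured"])
        if not math.isnan(rho):
            out[int(pos)] = rho
    return out


@dataclass
class TrainingProtein:
    """One training protein: merged normalized scores plus its homolog profile."""

    protein_id: str
    scores: NormalizedScores
    profile: HomologProfile


@dataclass
class EvaluationReport:
    """Per-protein and per-position correlation summaries."""

    per_protein: dict[str, float] = field(default_factory=dict)
    per_position: dict[tuple[str, int], float] = field(default_factory=dict)
    n_variants: dict[str, int] = field(default_factory=dict)

    def per_protein_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"protein_id": pid, "n": self.n_variants.get(pid, 0), "rho": rho}
                for pid, rho in sorted(self.per_protein.items())
            ],
            columns=["protein_id", "n", "rho"],
        )

    def per_position_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"protein_id": pid, "pos": pos, "rho": rho}
                for (pid, pos), rho in sorted(self.per_position.items())
            ],
            columns=["protein_id", "pos", "rho"],
        )


def _predict_measured_variants(
    protein: TrainingProtein,
    matrix,
    coefficients: ModelCoefficients,
) -> pd.DataFrame:
    """Predictions restricted to the held-out protein's measured variants.

    Variants whose substitution-matrix cell went unobserved in the fold's
    training data are skipped with a warning.
    """
    b = coefficients
    rows = []
    skipped = 0
    for (pos, wt, var) in sorted(protein.scores.entries):
        try:
            d = matrix.lookup(wt, var)
        except MissingCellError:
            skipped += 1
            continue
        h = float(protein.profile.entropy[pos - 1])
        log2f = float(np.log2(protein.profile.frequency(pos, var)))
        rows.append(
            {
                "pos": pos,
                "WT": wt,
                "var": var,
                "score": b.beta0 + b.beta1 * h + b.beta2 * log2f + b.beta3 * d,
            }
        )
    if skipped:
        warnings.warn(
            f"protein {protein.protein_id!r}: {skipped} variant(s) skipped due to "
            "matrix cells unobserved in this training fold",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["pos", "WT", "var", "score"])


def leave_one_out(corpus: list[TrainingProtein]) -> EvaluationReport:
    """Whole-protein leave-one-out cross-validation.

    For each protein, the substitution matrix and the regression
    coefficients are refit from the remaining proteins, the held-out
    protein's measured variants are predicted, and the per-protein
    Spearman rho is recorded.  Fold results do not depend on corpus order.
    """
    if len(corpus) < 2:
        raise ValueError("leave-one-out requires at least 2 training proteins")
    report = EvaluationReport()
    for held_out in corpus:
        # fixed fold order so results are independent of corpus ordering
        rest = sorted(
            (p for p in corpus if p.protein_id != held_out.protein_id),
            key=lambda p: p.protein_id,
        )
        fold_matrix = fit_matrix([p.scores for p in rest])
        features = pd.concat(
            [assemble_features(p.scores, p.profile, fold_matrix) for p in rest],
            ignore_index=True,
        )
        coefs = fit_coefficients(features)
        preds = _predict_measured_variants(held_out, fold_matrix, coefs)
        report.per_protein[held_out.protein_id] = evaluate_per_protein(
            preds, held_out.scores
        )
        report.n_variants[held_out.protein_id] = len(preds)
        for pos, rho in evaluate_per_position(preds, held_out.scores).items():
            report.per_position[(held_out.protein_id, pos)] = rho
    return report
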