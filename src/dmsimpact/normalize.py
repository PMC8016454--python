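"""Rank normalization of DMS fitness scores.

Raw DMS measurements are incomparable across assays (growth rates,
enrichment ratios, fluorescence...).  Each dataset is therefore reduced to
ranks: scores are mapped to quantiles ``(rank - 1) / (n - 1)`` (mean rank
for ties), so the per-dataset score distribution is uniform with a range
of exactly 1, and the wild-type quantile is subtracted so that 0 means
"no fitness change".  The result is invariant under any strictly monotone
transform of the assay scale.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .datasets import DmsDataset, NormalizedScores
from .errors import ConsistencyError, DegenerateDatasetError

__all__ = ["filter_variants", "rank_normalize", "merge_datasets", "normalize_dataset"]


def filter_variants(dataset: DmsDataset) -> DmsDataset:
    """Remove nonsense (``var == '*'``) and synonymous (``var == wt``) records.

    If the dataset has no ``wt_score``, the mean of the synonymous-variant
    scores (captured here, before they are discarded) is used in its place.

    Raises
    ------
    DegenerateDatasetError
        If the input is empty, if no missense records remain, or if
        ``wt_score`` is absent and there are no synonymous variants to
        estimate it from.
    """
    if not dataset.records:
        raise DegenerateDatasetError(f"dataset {dataset.dataset_id!r} is empty")
    wt_score = dataset.wt_score
    if wt_score is None:
        syn = dataset.synonymous_scores()
        if not syn:
            raise DegenerateDatasetError(
                f"dataset {dataset.dataset_id!r} has no wt_score and no "
                "synonymous variants to estimate it from"
            )
        wt_score = float(np.mean(syn))
    kept = [r for r in dataset.records if r.var != "*" and r.var != r.wt]
    if not kept:
        raise DegenerateDatasetError(
            f"dataset {dataset.dataset_id!r} has no missense records after "
            "removing nonsense and synonymous variants"
        )
    return dataset.with_records(kept, wt_score=wt_score)


def _wt_quantile(scores: np.ndarray, quantiles: np.ndarray, wt_score: float) -> float:
    """Quantile of ``wt_score`` within the variant score distribution.

    Ties with variant scores take the mean tied-rank quantile; a score
    strictly between two variant scores takes the linear interpolation of
    the neighbouring quantiles; a score outside the range clamps to 0 or 1.
    All three cases are realized by linear interpolation over the unique
    scores against their (tie-averaged) quantiles.
    """
    uniq, inverse = np.unique(scores, return_inverse=True)
    # mean quantile per unique value (handles ties exactly)
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, quantiles)
    np.add.at(counts, inverse, 1.0)
    uniq_q = sums / counts
    return float(np.interp(wt_score, uniq, uniq_q))


def rank_normalize(dataset: DmsDataset) -> NormalizedScores:
    """Rank-normalize a filtered dataset and anchor at the wild type.

    Each raw score is replaced by ``(rank - 1) / (n - 1)`` (ascending
    ranks, mean rank for ties) minus the wild-type quantile, computed by
    ranking ``wt_score`` within the variant scores under the same
    convention.  With at least two distinct scores the normalized values
    span a range of exactly 1.

    Raises
    ------
    DegenerateDatasetError
        If fewer than two records are present.
    ValueError
        If ``wt_score`` is unset (run :func:`filter_variants` first).
    """
    n = len(dataset.records)
    if n < 2:
        raise DegenerateDatasetError(
            f"dataset {dataset.dataset_id!r} has {n} record(s); "
            "at least 2 are required for rank normalization"
        )
    if dataset.wt_score is None:
        raise ValueError("dataset has no wt_score; apply filter_variants first")
    scores = np.array([r.score for r in dataset.records], dtype=float)
    ranks = rankdata(scores, method="average")
    quantiles = (ranks - 1.0) / (n - 1.0)
    wt_q = _wt_quantile(scores, quantiles, dataset.wt_score)
    anchored = quantiles - wt_q
    entries = {
        rec.key: float(val) for rec, val in zip(dataset.records, anchored)
    }
    return NormalizedScores(protein_id=dataset.protein_id, entries=entries)


def normalize_dataset(dataset: DmsDataset) -> NormalizedScores:
    """Convenience composition: :func:`filter_variants` then :func:`rank_normalize`."""
    return rank_normalize(filter_variants(dataset))


def merge_datasets(datasets: list[NormalizedScores]) -> NormalizedScores:
    """Merge normalized datasets for one protein by averaging shared variants.

    Each ``(position, wt, var)`` key maps to the arithmetic mean of its
    values across the datasets in which it appears; keys present in only
    one dataset pass through unchanged.

    Raises
    ------
    ValueError
        If no datasets are given or they name different proteins.
    ConsistencyError
        If two datasets disagree on the wild-type residue at a position.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    protein_ids = {d.protein_id for d in datasets}
    if len(protein_ids) != 1:
        raise ValueError(f"datasets name different proteins: {sorted(protein_ids)}")

    wt_at: dict[int, str] = {}
    for d in datasets:
        for pos, wt in d.wt_at().items():
            prev = wt_at.setdefault(pos, wt)
            if prev != wt:
                raise ConsistencyError(
                    f"protein {d.protein_id!r}: conflicting wild-type residues "
                    f"{prev!r} and {wt!r} at position {pos} across datasets"
                )

    sums: dict[tuple[int, str, str], float] = {}
    counts: dict[tuple[int, str, str], int] = {}
    for d in datasets:
        for key, val in d.entries.items():
            sums[key] = sums.get(key, 0.0) + val
            counts[key] = counts.get(key, 0) + 1
    merged = {key: sums[key] / counts[key] for key in sums}
    return NormalizedScores(protein_id=datasets[0].protein_id, entries=merged)
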