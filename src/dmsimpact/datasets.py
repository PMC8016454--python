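"""Containers for deep mutational scanning (DMS) variant data.

A DMS experiment measures a fitness proxy (growth rate, binding,
fluorescence, ...) for many single-residue variants of one protein.  Raw
scores live on an arbitrary assay scale; downstream code only ever
consumes their rank-normalized form (see :mod:`dmsimpact.normalize`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from ._residues import AA_INDEX, STOP
from .errors import ConsistencyError

__all__ = ["VariantRecord", "DmsDataset", "NormalizedScores"]


@dataclass(frozen=True)
class VariantRecord:
    """One measured single-residue substitution.

    Attributes
    ----------
    protein_id : str
        Identifier of the protein the variant belongs to.
    position : int
        1-based residue position in the protein sequence.
    wt : str
        Wild-type residue (one of the 20 standard single letters).
    var : str
        Variant residue; ``'*'`` denotes a nonsense (stop) mutation and
        ``var == wt`` a synonymous one.
    score : float
        Raw fitness measurement in assay units.
    """

    protein_id: str
    position: int
    wt: str
    var: str
    score: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt not in AA_INDEX:
            raise ValueError(f"wild-type residue {self.wt!r} is not standard")
        if self.var != STOP and self.var not in AA_INDEX:
            raise ValueError(f"variant residue {self.var!r} is not standard")
        if not math.isfinite(self.score):
            raise ValueError(f"raw score must be finite, got {self.score!r}")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.wt, self.var)


@dataclass
class DmsDataset:
    """All variant records from one DMS assay of one protein.

    ``wt_score`` is the raw fitness of the unmutated protein on the same
    assay scale.  It may be absent on construction, in which case
    :func:`dmsimpact.normalize.filter_variants` fills it with the mean of
    the synonymous-variant scores (captured before those are discarded).
    """

    dataset_id: str
    protein_id: str
    records: list[VariantRecord] = field(default_factory=list)
    wt_score: float | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ConsistencyError(
                    f"duplicate variant {rec.wt}{rec.position}{rec.var} "
                    f"in dataset {self.dataset_id!r}"
                )
            seen.add(rec.key)
        if self.wt_score is not None and not math.isfinite(self.wt_score):
            raise ValueError("wt_score must be finite")

    def __len__(self) -> int:
        return len(self.records)

    def synonymous_scores(self) -> list[float]:
        """Raw scores of synonymous (wt == var) records."""
        return [r.score for r in self.records if r.var == r.wt]

    def with_records(self, records: list[VariantRecord], **kw) -> "DmsDataset":
        return replace(self, records=records, **kw)


@dataclass
class NormalizedScores:
    """Rank-normalized, wild-type-anchored impact scores for one protein.

    ``entries`` maps ``(position, wt, var)`` to the normalized impact in
    quantile units: values lie in [-1, 1] and 0 means no fitness change
    relative to the wild type.
    """

    protein_id: str
    entries: dict[tuple[int, str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def wt_at(self) -> dict[int, str]:
        """Mapping position -> wild-type residue, checking consistency."""
        out: dict[int, str] = {}
        for (pos, wt, _var) in self.entries:
            prev = out.setdefault(pos, wt)
            if prev != wt:
                raise ConsistencyError(
                    f"protein {self.protein_id!r}: conflicting wild-type "
                    f"residues {prev!r} and {wt!r} at position {pos}"
                )
        return out
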