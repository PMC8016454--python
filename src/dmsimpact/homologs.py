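"""Homolog search output -> per-position frequency profiles and entropies.

Homologs of a query protein are found with blastp (UniRef90 is the
database used for the distributed model, but any protein database works).
Each retained hit contributes its aligned subject residues, stacked onto
query coordinates, to a per-position count over the 20 standard residues.
The query sequence itself is always counted once per position, so no
column is ever empty.  A pseudocount of 1e-4 is added to each of the 20
counts before converting to frequencies; gaps are excluded so frequencies
sum to 1.  Conservation is the Shannon entropy of each position's
frequency vector, in bits: 0 for a perfectly conserved column, log2(20)
for a uniform one.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._residues import AA_INDEX, AMINO_ACIDS, N_AA
from .errors import BlastEnvironmentError, BlastParseError, ConsistencyError

__all__ = [
    "PairwiseHit",
    "HomologProfile",
    "parse_blast_tabular",
    "run_blastp",
    "filter_hits",
    "build_profile",
    "read_stacked_alignment",
]

#: blastp output format used by :func:`run_blastp` and expected by the parser
BLAST_OUTFMT = "6 sseqid pident length gaps evalue bitscore qstart qend qseq sseq"

PSEUDOCOUNT = 1e-4
DEFAULT_EVALUE = 1e-5
DEFAULT_MAX_HITS = 500


@dataclass(frozen=True)
class PairwiseHit:
    """One blastp HSP between the query and a subject sequence."""

    subject_id: str
    percent_identity: float
    alignment_length: int
    gap_count: int
    evalue: float
    bitscore: float
    query_start: int
    query_end: int
    aligned_query: str
    aligned_subject: str

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError(
                f"hit {self.subject_id!r}: aligned query and subject strings "
                "differ in length"
            )
        ungapped = len(self.aligned_query) - self.aligned_query.count("-")
        if ungapped != self.query_end - self.query_start + 1:
            raise ValueError(
                f"hit {self.subject_id!r}: ungapped query length {ungapped} does "
                f"not match coordinates {self.query_start}-{self.query_end}"
            )

    @property
    def gap_fraction(self) -> float:
        return self.gap_count / self.alignment_length


@dataclass
class HomologProfile:
    """Per-position residue frequencies and Shannon entropies for a query.

    Attributes
    ----------
    query_id : str
    query_seq : str
        The query sequence (length L).
    frequencies : ndarray of shape (L, 20)
        Pseudocounted, gap-excluded residue fractions; each row sums to 1.
    entropy : ndarray of shape (L,)
        Shannon entropy in bits, in [0, log2 20].
    depth : ndarray of shape (L,)
        Number of non-gap standard-residue observations per position
        (homologs plus the query itself).
    """

    query_id: str
    query_seq: str
    frequencies: np.ndarray
    entropy: np.ndarray
    depth: np.ndarray

    @property
    def length(self) -> int:
        return len(self.query_seq)

    def frequency(self, position: int, aa: str) -> float:
        """Frequency of residue *aa* at 1-based *position*."""
        return float(self.frequencies[position - 1, AA_INDEX[aa]])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "pos\twt\tentropy\tdepth\t" + "\t".join(AMINO_ACIDS) + "\n"
            )
            for p in range(self.length):
                freqs = "\t".join(repr(float(f)) for f in self.frequencies[p])
                fh.write(
                    f"{p + 1}\t{self.query_seq[p]}\t{float(self.entropy[p])!r}\t"
                    f"{int(self.depth[p])}\t{freqs}\n"
                )

    @classmethod
    def read(cls, path: str | Path, query_id: str = "") -> "HomologProfile":
        rows = []
        seq = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["pos", "wt", "entropy", "depth"]:
                raise ValueError(f"unrecognized profile header in {path}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                seq.append(parts[1])
                rows.append(parts)
        freqs = np.array([[float(x) for x in r[4 : 4 + N_AA]] for r in rows])
        entropy = np.array([float(r[2]) for r in rows])
        depth = np.array([int(r[3]) for r in rows])
        return cls(
            query_id=query_id or Path(path).stem,
            query_seq="".join(seq),
            frequencies=freqs,
            entropy=entropy,
            depth=depth,
        )


def parse_blast_tabular(source: str | Path) -> list[PairwiseHit]:
    """Parse blastp tabular output (``-outfmt "6 sseqid pident length gaps
    evalue bitscore qstart qend qseq sseq"``) into hits.

    Raises :class:`BlastParseError` naming the offending line number on a
    malformed line.
    """
    hits: list[PairwiseHit] = []
    path = Path(source)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise BlastParseError(
                    f"{path}:{lineno}: expected 10 tab-separated fields, "
                    f"got {len(parts)}",
                    line_number=lineno,
                )
            try:
                hits.append(
                    PairwiseHit(
                        subject_id=parts[0],
                        percent_identity=float(parts[1]),
                        alignment_length=int(parts[2]),
                        gap_count=int(parts[3]),
                        evalue=float(parts[4]),
                        bitscore=float(parts[5]),
                        query_start=int(parts[6]),
                        query_end=int(parts[7]),
                        aligned_query=parts[8],
                        aligned_subject=parts[9],
                    )
                )
            except ValueError as exc:
                raise BlastParseError(
                    f"{path}:{lineno}: {exc}", line_number=lineno
                ) from exc
    return hits


def run_blastp(
    query_fasta: str | Path,
    database: str | Path,
    evalue: float = DEFAULT_EVALUE,
    extra_args: list[str] | None = None,
) -> list[PairwiseHit]:
    """Run the external ``blastp`` against a formatted protein database.

    Uses an E-value cutoff of 1e-5 by default and the tabular output
    format carrying aligned sequence strings; returns one hit per HSP.
    """
    exe = shutil.which("blastp")
    if exe is None:
        raise BlastEnvironmentError(
            "blastp executable not found on PATH; install NCBI BLAST+ or "
            "provide pre-computed tabular hits / a stacked alignment instead"
        )
    with tempfile.NamedTemporaryFile(suffix=".tsv", mode="r") as out:
        cmd = [
            exe,
            "-query",
            str(query_fasta),
            "-db",
            str(database),
            "-evalue",
            str(evalue),
            "-outfmt",
            BLAST_OUTFMT,
            "-out",
            out.name,
        ] + (extra_args or [])
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BlastEnvironmentError(
                f"blastp failed (exit {proc.returncode}): {proc.stderr.strip()}; "
                "check that the database was built with makeblastdb"
            )
        hits = parse_blast_tabular(out.name)
    if not hits:
        warnings.warn("blastp returned no hits for the query", stacklevel=2)
    return hits


def _hit_order(h: PairwiseHit) -> tuple:
    # descending bitscore, then ascending evalue, then subject id
    return (-h.bitscore, h.evalue, h.subject_id)


def filter_hits(
    hits: list[PairwiseHit],
    min_identity: float = 20.0,
    max_gap_fraction: float = 0.10,
    max_hits: int = DEFAULT_MAX_HITS,
) -> list[PairwiseHit]:
    """Apply the homolog retention rules.

    Keeps one HSP per subject (highest bitscore; ties broken by lower
    E-value then subject id), removes hits with identity below 20% or
    more than 10% gap columns in the alignment, then retains the top 500
    survivors by bitscore.  The result is independent of input order.
    """
    best: dict[str, PairwiseHit] = {}
    for h in hits:
        prev = best.get(h.subject_id)
        if prev is None or _hit_order(h) < _hit_order(prev):
            best[h.subject_id] = h
    survivors = [
        h
        for h in best.values()
        if h.percent_identity >= min_identity and h.gap_fraction <= max_gap_fraction
    ]
    survivors.sort(key=_hit_order)
    if not survivors:
        warnings.warn("no hits survive identity/gap filtering", stacklevel=2)
    return survivors[:max_hits]


def _stack_hit(counts: np.ndarray, depth: np.ndarray, hit: PairwiseHit, length: int) -> None:
    if hit.query_end > length:
        raise ConsistencyError(
            f"hit {hit.subject_id!r} ends at query position {hit.query_end} "
            f"but the query is only {length} residues long"
        )
    pos = hit.query_start - 1  # 0-based index of next query column
    for qc, sc in zip(hit.aligned_query, hit.aligned_subject):
        if qc == "-":
            continue  # subject insertion relative to the query: no query column
        if sc in AA_INDEX:
            counts[pos, AA_INDEX[sc]] += 1.0
            depth[pos] += 1
        pos += 1


def build_profile(
    query_id: str,
    query_seq: str,
    hits: list[PairwiseHit] | None = None,
    alignment_rows: list[str] | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> HomologProfile:
    """Build the frequency/entropy profile for a query sequence.

    Counts come either from filtered pairwise ``hits`` (stacked onto query
    coordinates) or from pre-stacked ``alignment_rows`` (length-L strings
    over residues and ``-``, one per homolog).  In both cases the query's
    own residue is counted once at every position, subject gap columns and
    non-standard residues (X, B, Z, J, U, O) contribute nothing, and a
    pseudocount is added to each of the 20 counts before normalization.
    """
    length = len(query_seq)
    counts = np.zeros((length, N_AA))
    depth = np.zeros(length, dtype=int)

    # the query itself is one observation per position
    for p, aa in enumerate(query_seq):
        if aa in AA_INDEX:
            counts[p, AA_INDEX[aa]] += 1.0
            depth[p] += 1

    for hit in hits or []:
        _stack_hit(counts, depth, hit, length)
    for row in alignment_rows or []:
        if len(row) != length:
            raise ConsistencyError(
                f"stacked alignment row length {len(row)} does not match "
                f"query length {length}"
            )
        for p, aa in enumerate(row):
            if aa in AA_INDEX:
                counts[p, AA_INDEX[aa]] += 1.0
                depth[p] += 1

    counts += pseudocount
    freqs = counts / counts.sum(axis=1, keepdims=True)
    entropy = -(freqs * np.log2(freqs)).sum(axis=1)
    return HomologProfile(
        query_id=query_id,
        query_seq=query_seq,
        frequencies=freqs,
        entropy=entropy,
        depth=depth,
    )


def read_stacked_alignment(path: str | Path) -> list[str]:
    """Read a pre-stacked alignment: one length-L homolog row per line.

    Blank lines and ``#`` comments are ignored.  Rows use the 20 residue
    letters, non-standard codes and ``-`` for gaps.
    """
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                rows.append(line)
    return rows
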