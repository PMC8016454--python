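"""Readers and writers for the package's plain-text interchange formats.

All tables are TSV.  DMS variant tables carry ``position``, ``wt``,
``var``, ``score``; a YAML manifest groups dataset files by protein and
records each dataset's wild-type reference score and each protein's
sequence (FASTA) and homolog alignment.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from Bio import SeqIO

from .datasets import DmsDataset, NormalizedScores, VariantRecord

__all__ = [
    "read_dms_table",
    "write_dms_table",
    "read_normalized_scores",
    "write_normalized_scores",
    "read_fasta",
    "read_manifest",
]


def read_dms_table(
    path: str | Path,
    dataset_id: str,
    protein_id: str,
    wt_score: float | None = None,
) -> DmsDataset:
    """Read a per-variant DMS table (columns position, wt, var, score)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            idx = [header.index(c) for c in ("position", "wt", "var", "score")]
        except ValueError as exc:
            raise ValueError(f"{path}: missing required column: {exc}") from exc
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            records.append(
                VariantRecord(
                    protein_id=protein_id,
                    position=int(parts[idx[0]]),
                    wt=parts[idx[1]],
                    var=parts[idx[2]],
                    score=float(parts[idx[3]]),
                )
            )
    return DmsDataset(
        dataset_id=dataset_id,
        protein_id=protein_id,
        records=records,
        wt_score=wt_score,
    )


def write_dms_table(dataset: DmsDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\twt\tvar\tscore\n")
        for r in dataset.records:
            fh.write(f"{r.position}\t{r.wt}\t{r.var}\t{float(r.score)!r}\n")


def write_normalized_scores(scores: NormalizedScores, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\twt\tvar\tnormalized_score\n")
        for (pos, wt, var), val in sorted(scores.entries.items()):
            fh.write(f"{pos}\t{wt}\t{var}\t{float(val)!r}\n")


def read_normalized_scores(path: str | Path, protein_id: str) -> NormalizedScores:
    entries = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["position", "wt", "var", "normalized_score"]:
            raise ValueError(f"unrecognized normalized-scores header in {path}")
        for line in fh:
            if line.strip():
                pos, wt, var, val = line.rstrip("\n").split("\t")
                entries[(int(pos), wt, var)] = float(val)
    return NormalizedScores(protein_id=protein_id, entries=entries)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered mapping id -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_manifest(path: str | Path) -> dict:
    """Read a corpus manifest (YAML).

    Expected structure::

        datasets:
          - dataset_id: yap1_2012
            protein_id: YAP1
            path: yap1_2012.tsv      # relative to the manifest
            wt_score: 1.0            # optional
        proteins:
          - protein_id: YAP1
            fasta: sequences.fasta   # record id == protein_id
            alignment: YAP1.aln      # pre-stacked homolog alignment

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "datasets" not in manifest:
        raise ValueError(f"{path}: manifest must be a mapping with a 'datasets' list")
    base = path.parent
    for entry in manifest.get("datasets", []):
        entry["path"] = str((base / entry["path"]).resolve())
    for entry in manifest.get("proteins", []) or []:
        for key in ("fasta", "alignment", "hits"):
            if key in entry:
                entry[key] = str((base / entry[key]).resolve())
    return manifest
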