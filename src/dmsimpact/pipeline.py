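"""End-to-end training and prediction built from the module primitives.

``load_training_corpus`` turns a manifest (DMS tables + sequences +
homolog alignments) into per-protein merged normalized scores and
profiles; ``train`` fits the directional substitution matrix and the
linear-model coefficients from such a corpus.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd

from . import io
from .datasets import DmsDataset
from .errors import ConsistencyError
from .evaluate import TrainingProtein
from .homologs import build_profile, filter_hits, parse_blast_tabular, read_stacked_alignment
from .matrix import DirectionalMatrix, fit_matrix
from .model import ModelCoefficients, assemble_features, fit_coefficients
from .normalize import merge_datasets, normalize_dataset

__all__ = ["load_training_corpus", "train", "profile_from_manifest_entry"]


def profile_from_manifest_entry(entry: dict, sequences: dict[str, str]):
    """Build a protein's homolog profile from its manifest entry."""
    protein_id = entry["protein_id"]
    if protein_id not in sequences:
        raise ConsistencyError(
            f"protein {protein_id!r} has no record in its FASTA file"
        )
    seq = sequences[protein_id]
    if "alignment" in entry:
        rows = read_stacked_alignment(entry["alignment"])
        return build_profile(protein_id, seq, alignment_rows=rows)
    if "hits" in entry:
        hits = filter_hits(parse_blast_tabular(entry["hits"]))
        return build_profile(protein_id, seq, hits=hits)
    raise ValueError(
        f"protein {protein_id!r}: manifest entry needs an 'alignment' or 'hits' path"
    )


def load_training_corpus(manifest_path: str | Path) -> list[TrainingProtein]:
    """Load, normalize and merge a manifest's datasets; build profiles.

    Datasets covering the same protein are rank-normalized independently
    and then merged by averaging shared variants.
    """
    manifest = io.read_manifest(manifest_path)
    by_protein: dict[str, list[DmsDataset]] = defaultdict(list)
    for entry in manifest["datasets"]:
        by_protein[entry["protein_id"]].append(
            io.read_dms_table(
                entry["path"],
                dataset_id=entry["dataset_id"],
                protein_id=entry["protein_id"],
                wt_score=entry.get("wt_score"),
            )
        )

    protein_entries = {e["protein_id"]: e for e in manifest.get("proteins", []) or []}
    corpus: list[TrainingProtein] = []
    for protein_id in sorted(by_protein):
        merged = merge_datasets(
            [normalize_dataset(d) for d in by_protein[protein_id]]
        )
        if protein_id not in protein_entries:
            raise ValueError(
                f"manifest lists datasets for {protein_id!r} but no protein entry"
            )
        entry = protein_entries[protein_id]
        sequences = io.read_fasta(entry["fasta"])
        profile = profile_from_manifest_entry(entry, sequences)
        corpus.append(
            TrainingProtein(protein_id=protein_id, scores=merged, profile=profile)
        )
    return corpus


def train(
    corpus: list[TrainingProtein],
    matrix: DirectionalMatrix | None = None,
) -> tuple[DirectionalMatrix, ModelCoefficients]:
    """Fit the substitution matrix (unless given) and the OLS coefficients.

    Passing a pre-built ``matrix`` (e.g. a rescaled log-odds matrix)
    swaps the matrix feature while keeping the rest of the fit identical,
    which supports matrix-ablation experiments.
    """
    if matrix is None:
        matrix = fit_matrix([p.scores for p in corpus])
    features = pd.concat(
        [assemble_features(p.scores, p.profile, matrix) for p in corpus],
        ignore_index=True,
    )
    return matrix, fit_coefficients(features)
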