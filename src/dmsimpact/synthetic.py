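"""Synthetic DMS corpora with known ground truth.

The generator emulates the statistical structure the linear impact model
assumes: each protein position gets a residue distribution of controlled
sharpness, homolog alignment columns are drawn from it (yielding entropy
and variant-frequency features), a true directional substitution matrix
and true coefficients define the model response for every substitution,
and the raw assay score handed to the normalization stage is an affine
transform of that response (a different scale and offset per dataset, so
rank normalization has real work to undo).  The wild type has response 0
by construction, so the raw wild-type score equals the dataset offset.

What it does *not* emulate: real DMS error structure (bottlenecking,
sequencing noise), partial mutational coverage, phylogenetic correlation
between homologs, or alignment errors.  Passing tests on this corpus
demonstrates pipeline correctness, not real-data accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from ._residues import AMINO_ACIDS, N_AA
from .datasets import DmsDataset, NormalizedScores, VariantRecord
from .evaluate import TrainingProtein
from .homologs import HomologProfile, build_profile
from .matrix import DirectionalMatrix
from .model import ModelCoefficients
from .normalize import normalize_dataset

__all__ = ["SyntheticSpec", "SyntheticCorpus", "generate_corpus", "random_matrix"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic corpus; identical specs yield identical output.

    Defaults give 8 proteins x 70 positions x 19 variants = 10 640
    variants — a desk-scale miniature of a multi-protein DMS training
    corpus.  ``noise_sd`` (quantile units) is small relative to the unit
    range of normalized scores; ``column_concentration`` controls how
    sharply homolog columns concentrate on the wild-type residue (0 =
    uniform columns, large = perfectly conserved, entropies -> 0).
    """

    seed: int = 0
    n_proteins: int = 8
    protein_length: int = 70
    true_coefficients: ModelCoefficients = field(
        default_factory=lambda: ModelCoefficients(-0.1, 0.05, 0.02, 0.9)
    )
    true_matrix: DirectionalMatrix | None = None
    noise_sd: float = 0.05
    homolog_depth: int = 50
    column_concentration: float = 5.0


@dataclass
class SyntheticCorpus:
    """In-memory view of a generated corpus plus its ground truth."""

    spec: SyntheticSpec
    sequences: dict[str, str]
    datasets: list[DmsDataset]
    truth_scores: dict[str, NormalizedScores]
    profiles: dict[str, HomologProfile]
    alignments: dict[str, list[str]]
    true_matrix: DirectionalMatrix
    true_coefficients: ModelCoefficients
    out_dir: Path | None = None

    def training_corpus(self, use_truth_scores: bool = False) -> list[TrainingProtein]:
        """Per-protein corpus for training/evaluation.

        With ``use_truth_scores`` the exact model responses are used as
        the scores (zero-residual route); otherwise the raw datasets go
        through filtering and rank normalization like real data.
        """
        corpus = []
        for ds in self.datasets:
            scores = (
                self.truth_scores[ds.protein_id]
                if use_truth_scores
                else normalize_dataset(ds)
            )
            corpus.append(
                TrainingProtein(
                    protein_id=ds.protein_id,
                    scores=scores,
                    profile=self.profiles[ds.protein_id],
                )
            )
        return corpus


def random_matrix(rng: np.random.Generator) -> DirectionalMatrix:
    """A random directional matrix with mostly-deleterious mean impacts."""
    values = rng.uniform(-0.7, 0.05, size=(N_AA, N_AA))
    np.fill_diagonal(values, 0.0)
    counts = np.ones((N_AA, N_AA), dtype=int)
    np.fill_diagonal(counts, 0)
    return DirectionalMatrix(values=values, counts=counts)


def _column_distributions(
    rng: np.random.Generator, wt_idx: np.ndarray, concentration: float
) -> np.ndarray:
    """Per-position residue distributions of controlled sharpness.

    Each position mixes a point mass on its wild-type residue with a
    random Dirichlet background; the mixing weight is an exponential draw
    scaled by ``concentration``, so sharpness varies across positions and
    the concentration -> infinity limit gives perfectly conserved columns.
    """
    length = len(wt_idx)
    background = rng.dirichlet(np.ones(N_AA), size=length)
    weight = concentration * rng.exponential(1.0, size=length)
    onehot = np.zeros((length, N_AA))
    onehot[np.arange(length), wt_idx] = 1.0
    pi = (weight[:, None] * onehot + background) / (weight[:, None] + 1.0)
    return pi


def generate_corpus(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> SyntheticCorpus:
    """Generate a synthetic corpus; optionally write it to disk.

    When ``out_dir`` is given, writes the file set the pipeline consumes
    (``manifest.yaml``, per-protein DMS tables and stacked alignments, a
    FASTA of the query sequences) plus a ``ground_truth/`` directory with
    the true matrix, coefficients and exact model responses.  Identical
    specs produce byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    coefs = spec.true_coefficients
    matrix = spec.true_matrix if spec.true_matrix is not None else random_matrix(rng)

    sequences: dict[str, str] = {}
    datasets: list[DmsDataset] = []
    truth_scores: dict[str, NormalizedScores] = {}
    profiles: dict[str, HomologProfile] = {}
    alignments: dict[str, list[str]] = {}

    length = spec.protein_length
    for k in range(spec.n_proteins):
        pid = f"SYN{k + 1:02d}"
        wt_idx = rng.integers(0, N_AA, size=length)
        seq = "".join(AMINO_ACIDS[i] for i in wt_idx)
        pi = _column_distributions(rng, wt_idx, spec.column_concentration)
        columns = np.stack(
            [
                rng.choice(N_AA, size=spec.homolog_depth, p=pi[p])
                for p in range(length)
            ]
        )  # (length, depth)
        rows = [
            "".join(AMINO_ACIDS[columns[p, d]] for p in range(length))
            for d in range(spec.homolog_depth)
        ]
        profile = build_profile(pid, seq, alignment_rows=rows)

        records: list[VariantRecord] = []
        entries: dict[tuple[int, str, str], float] = {}
        noise = rng.normal(0.0, spec.noise_sd, size=length * (N_AA - 1))
        scale = rng.uniform(0.5, 3.0)
        offset = rng.uniform(-2.0, 2.0)
        i = 0
        for p in range(1, length + 1):
            wt = seq[p - 1]
            h = float(profile.entropy[p - 1])
            for var in AMINO_ACIDS:
                if var == wt:
                    continue
                log2f = float(np.log2(profile.frequency(p, var)))
                response = (
                    coefs.beta0
                    + coefs.beta1 * h
                    + coefs.beta2 * log2f
                    + coefs.beta3 * matrix[wt, var]
                    + float(noise[i])
                )
                i += 1
                entries[(p, wt, var)] = response
                records.append(
                    VariantRecord(
                        protein_id=pid,
                        position=p,
                        wt=wt,
                        var=var,
                        score=scale * response + offset,
                    )
                )
        sequences[pid] = seq
        alignments[pid] = rows
        profiles[pid] = profile
        truth_scores[pid] = NormalizedScores(protein_id=pid, entries=entries)
        datasets.append(
            DmsDataset(
                dataset_id=f"{pid}_dms",
                protein_id=pid,
                records=records,
                wt_score=offset,  # the wild type has response 0 by construction
            )
        )

    corpus = SyntheticCorpus(
        spec=spec,
        sequences=sequences,
        datasets=datasets,
        truth_scores=truth_scores,
        profiles=profiles,
        alignments=alignments,
        true_matrix=matrix,
        true_coefficients=coefs,
    )
    if out_dir is not None:
        corpus.out_dir = Path(out_dir)
        _write_corpus(corpus)
    return corpus


def _write_corpus(corpus: SyntheticCorpus) -> None:
    out = corpus.out_dir
    assert out is not None
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "ground_truth"
    truth_dir.mkdir(exist_ok=True)

    with open(out / "sequences.fasta", "w") as fh:
        for pid in sorted(corpus.sequences):
            fh.write(f">{pid}\n{corpus.sequences[pid]}\n")

    manifest = {"datasets": [], "proteins": []}
    for ds in corpus.datasets:
        table = f"{ds.protein_id}.dms.tsv"
        io.write_dms_table(ds, out / table)
        manifest["datasets"].append(
            {
                "dataset_id": ds.dataset_id,
                "protein_id": ds.protein_id,
                "path": table,
                "wt_score": float(ds.wt_score),
            }
        )
        aln = f"{ds.protein_id}.aln"
        with open(out / aln, "w") as fh:
            fh.write("\n".join(corpus.alignments[ds.protein_id]) + "\n")
        manifest["proteins"].append(
            {
                "protein_id": ds.protein_id,
                "fasta": "sequences.fasta",
                "alignment": aln,
            }
        )
        io.write_normalized_scores(
            corpus.truth_scores[ds.protein_id],
            truth_dir / f"{ds.protein_id}.scores.tsv",
        )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    corpus.true_matrix.write(truth_dir / "matrix.tsv")
    corpus.true_coefficients.write(truth_dir / "coefficients.tsv")
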