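"""Synthetic benchmark data with planted block structure.

The generator emulates the statistical assumption the prediction model
rests on — functionally similar miRNAs tend to associate with similar
diseases — by assigning miRNAs and diseases to latent groups and planting
both the association matrix and the similarity tables on the same blocks:

* associations appear with probability ``p_in`` when a miRNA and a disease
  share a group and ``p_out`` otherwise;
* similarity scores are drawn around ``s_in`` within a group and ``s_out``
  across groups, perturbed by truncated-Gaussian noise, symmetrized, and
  clipped to [0, 1];
* only a ``fs_coverage`` fraction of miRNA pairs carries an observed
  functional-similarity score, mimicking the partial coverage of published
  score tables;
* a forest of MeSH-style dotted tree numbers places each disease in its
  group's tree, so same-group diseases share ancestors and cross-group
  diseases share none.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph_data import (
    AssociationMatrix,
    PartialSimilarity,
    ValidationError,
    write_associations,
)


@dataclass
class BlockModelParams:
    """Parameters of the planted block model.

    Defaults describe a moderately sparse benchmark with clear block
    signal: four groups over 60 miRNAs x 40 diseases, within-group
    association probability 0.3 against a 0.02 background (overall density
    ~0.09), well-separated similarity levels (0.8 vs 0.1, noise sd 0.05),
    and 70% functional-similarity coverage.
    """

    nm: int = 60
    nd: int = 40
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    s_in: float = 0.8
    s_out: float = 0.1
    sim_noise: float = 0.05
    fs_coverage: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_blocks <= min(self.nm, self.nd)):
            raise ValidationError("need nm, nd >= n_blocks >= 1")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValidationError("need 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.s_out < self.s_in <= 1.0:
            raise ValidationError("need 0 <= s_out < s_in <= 1")
        if not 0.0 <= self.fs_coverage <= 1.0:
            raise ValidationError("fs_coverage must lie in [0, 1]")
        if self.sim_noise < 0:
            raise ValidationError("sim_noise must be nonnegative")


def _block_similarity(
    labels: np.ndarray,
    params: BlockModelParams,
    rng: np.random.Generator,
    ids: list[str],
    coverage: float,
) -> PartialSimilarity:
    """Symmetric similarity around s_in/s_out with truncated-Gaussian noise."""
    n = len(labels)
    mean = np.where(
        labels[:, None] == labels[None, :], params.s_in, params.s_out
    )
    noise = rng.normal(0.0, params.sim_noise, size=(n, n))
    values = np.clip(mean + np.triu(noise) + np.triu(noise, 1).T, 0.0, 1.0)
    observed = rng.random((n, n)) < coverage
    observed = np.triu(observed) | np.triu(observed, 1).T
    np.fill_diagonal(values, 1.0)
    np.fill_diagonal(observed, True)
    return PartialSimilarity(ids, values, observed)


def simulate_block_dataset(
    params: BlockModelParams | None = None,
) -> tuple[
    AssociationMatrix,
    PartialSimilarity,
    PartialSimilarity,
    tuple[np.ndarray, np.ndarray],
]:
    """Draw one planted-block benchmark instance.

    Returns the association matrix, the partially observed miRNA similarity,
    the (fully observed) disease similarity, and the ground-truth group
    labels as a (miRNA labels, disease labels) pair.  Group assignment is
    round-robin, so blocks are balanced and reproducible.
    """
    params = params or BlockModelParams()
    rng = np.random.default_rng(params.seed)
    m_labels = np.arange(params.nm) % params.n_blocks
    d_labels = np.arange(params.nd) % params.n_blocks
    mirna_ids = [f"mir-{i + 1}" for i in range(params.nm)]
    disease_ids = [f"disease-{j + 1}" for j in range(params.nd)]

    prob = np.where(
        m_labels[:, None] == d_labels[None, :], params.p_in, params.p_out
    )
    values = (rng.random((params.nm, params.nd)) < prob).astype(float)
    assoc = AssociationMatrix(mirna_ids, disease_ids, values)

    fs = _block_similarity(m_labels, params, rng, mirna_ids, params.fs_coverage)
    ss = _block_similarity(d_labels, params, rng, disease_ids, 1.0)
    return assoc, fs, ss, (m_labels, d_labels)


def shuffle_associations(
    assoc: AssociationMatrix, seed: int
) -> AssociationMatrix:
    """Destroy the block signal by permuting all entries of A.

    Keeps the number of known associations (and hence the density) while
    decoupling them from the similarity structure; a negative control for
    the end-to-end benchmark.
    """
    rng = np.random.default_rng(seed)
    flat = assoc.values.flatten()
    rng.shuffle(flat)
    return AssociationMatrix(
        list(assoc.mirna_ids),
        list(assoc.disease_ids),
        flat.reshape(assoc.values.shape),
    )


def simulate_dag_forest(
    n_diseases: int, n_blocks: int, depth: int, seed: int
) -> list[tuple[str, str]]:
    """MeSH-style tree-number table over a forest of per-block trees.

    One root per block (C01, C02, ...).  Each block grows a random tree of
    dotted numbers to at most ``depth`` levels below its root; each disease
    is placed at a distinct random node of its block's tree.  Diseases of
    the same block therefore share ancestor structure while cross-block
    pairs share nothing (their semantic similarity is exactly zero).

    Returns (term, tree number) rows parseable by
    :func:`mdinfer.graph_data.read_mesh_tree_numbers`.
    """
    if n_diseases < 1 or n_blocks < 1 or depth < 1:
        raise ValidationError("n_diseases, n_blocks, depth must be positive")
    rng = np.random.default_rng(seed)
    d_labels = np.arange(n_diseases) % n_blocks
    rows: list[tuple[str, str]] = []
    for b in range(n_blocks):
        members = np.flatnonzero(d_labels == b)
        root = f"C{b + 1:02d}"
        nodes = [root]
        # grow until every member disease can sit on its own node
        while len(nodes) < max(2 * len(members), 4):
            parent = nodes[rng.integers(len(nodes))]
            if parent.count(".") >= depth:
                continue
            child = f"{parent}.{rng.integers(100, 1000)}"
            if child not in nodes:
                nodes.append(child)
        chosen = rng.choice(len(nodes), size=len(members), replace=False)
        for disease_idx, node_idx in zip(members, chosen):
            rows.append((f"disease-{disease_idx + 1}", nodes[node_idx]))
    return rows


def write_dataset(params: BlockModelParams, outdir: str | Path) -> dict[str, Path]:
    """Write one benchmark draw as the three standard TSV inputs.

    Produces ``associations.tsv`` (edge list), ``functional_similarity.tsv``
    (observed miRNA pairs only), and ``mesh_tree_numbers.tsv`` (DAG forest
    aligned with the disease blocks), ready for the command-line pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assoc, fs, _, _ = simulate_block_dataset(params)
    paths = {
        "associations": outdir / "associations.tsv",
        "functional_similarity": outdir / "functional_similarity.tsv",
        "mesh_tree_numbers": outdir / "mesh_tree_numbers.tsv",
    }
    write_associations(assoc, paths["associations"])
    with open(paths["functional_similarity"], "w", encoding="utf-8") as fh:
        for i in range(fs.values.shape[0]):
            for j in range(i + 1, fs.values.shape[0]):
                if fs.observed[i, j]:
                    fh.write(
                        f"{fs.ids[i]}\t{fs.ids[j]}\t{fs.values[i, j]:.6f}\n"
                    )
    forest = simulate_dag_forest(
        params.nd, params.n_blocks, depth=3, seed=params.seed
    )
    with open(paths["mesh_tree_numbers"], "w", encoding="utf-8") as fh:
        for term, number in forest:
            fh.write(f"{term}\t{number}\n")
    return paths
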