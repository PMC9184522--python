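"""Readers and writers for the standard on-disk formats.

Expression data travels as a Matrix Market triplet (1-based indices, per the
format standard) plus ``genes.tsv`` / ``barcodes.tsv`` / ``clusters.tsv``
side tables, or as one dense CSV whose first row carries the cluster
assignment.  All tabular outputs carry a ``#``-prefixed header block
recording the package version, the seed, and a configuration hash, so runs
are auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .cluster_stats import ExpressionDataset, normalize_counts

__all__ = [
    "read_expression",
    "write_expression",
    "read_expression_csv",
    "write_expression_csv",
    "write_table",
    "read_table",
]


def _collapse_duplicate_genes(counts: np.ndarray, gene_ids: list[str]):
    if len(set(gene_ids)) == len(gene_ids):
        return counts, gene_ids
    warnings.warn("duplicate gene symbols collapsed by summing counts")
    df = pd.DataFrame(counts, index=gene_ids)
    df = df.groupby(level=0, sort=False).sum()
    return df.to_numpy(), list(df.index)


def read_expression(path, target_sum: float = 1e4) -> ExpressionDataset:
    """Read a Matrix Market directory (matrix.mtx + genes/barcodes/clusters).

    ``clusters.tsv`` maps cell_id to cluster label; a cell missing from it is
    an error.  Matrix indices are 1-based in the file, 0-based in memory.
    """
    path = Path(path)
    m = spio.mmread(path / "matrix.mtx")
    counts = np.asarray(m.todense()) if sparse.issparse(m) else np.asarray(m)
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    cl = pd.read_csv(path / "clusters.tsv", sep="\t", header=None, names=["cell_id", "cluster"])
    mapping = dict(zip(cl["cell_id"].astype(str), cl["cluster"].astype(str)))
    missing = [c for c in cells if c not in mapping]
    if missing:
        raise ValueError(f"cells without a cluster assignment: {missing[:5]}")
    clusters = [mapping[c] for c in cells]
    if np.any(counts < 0):
        raise ValueError("negative counts in matrix")
    counts, genes = _collapse_duplicate_genes(counts, genes)
    return ExpressionDataset.from_counts(counts, genes, cells, clusters, target_sum=target_sum)


def write_expression(dataset: ExpressionDataset, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(dataset.counts))
    pd.Series(dataset.gene_ids).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(dataset.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame({"cell_id": dataset.cell_ids, "cluster": dataset.clusters}).to_csv(
        path / "clusters.tsv", sep="\t", index=False, header=False
    )


def read_expression_csv(path, target_sum: float = 1e4) -> ExpressionDataset:
    """Dense CSV: genes x cells with a leading ``cluster`` row."""
    df = pd.read_csv(path, index_col=0)
    if "cluster" not in df.index:
        raise ValueError("dense CSV must contain a 'cluster' row")
    clusters = df.loc["cluster"].astype(str).tolist()
    body = df.drop(index="cluster").astype(float)
    counts = body.to_numpy()
    if np.any(counts < 0):
        raise ValueError("negative counts in matrix")
    counts, genes = _collapse_duplicate_genes(counts, list(body.index.astype(str)))
    return ExpressionDataset.from_counts(
        counts, genes, list(body.columns.astype(str)), clusters, target_sum=target_sum
    )


def write_expression_csv(dataset: ExpressionDataset, path) -> None:
    body = pd.DataFrame(dataset.counts, index=dataset.gene_ids, columns=dataset.cell_ids)
    head = pd.DataFrame([list(dataset.clusters)], index=["cluster"], columns=dataset.cell_ids)
    pd.concat([head, body]).to_csv(path)


def config_hash(config: Mapping) -> str:
    payload = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed: int | None = None,
                config: Mapping | None = None, index: bool = False) -> None:
    """Write a TSV with a ``#`` header block (version, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# ccckit version: {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
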