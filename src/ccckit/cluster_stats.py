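"""Per-gene, per-cluster summary statistics.

Every scoring system consumes the same cluster-level summaries computed here:
cluster means of the normalized (log1p) layer and of its de-logged values,
fractions of expressing cells, one-vs-rest log2 fold changes, z-scores of the
cluster means, and Wilcoxon one-vs-rest differential-expression p-values.
Heteromeric complexes are reduced to the subunit with the minimum mean
expression in the relevant cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .resources import ProteinEntity

__all__ = [
    "ExpressionDataset",
    "ClusterStatTable",
    "EntitySummary",
    "normalize_counts",
    "summarize_clusters",
    "entity_cluster_summary",
]


@dataclass
class ExpressionDataset:
    """Counts plus a normalized layer and a cell → cluster assignment.

    ``counts`` and ``norm`` are dense genes x cells arrays aligned with
    ``gene_ids`` / ``cell_ids``; ``clusters`` holds one label per cell.
    """

    counts: np.ndarray
    norm: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    clusters: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.norm = np.asarray(self.norm, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.clusters = np.asarray([str(c) for c in self.clusters], dtype=object)
        n_genes, n_cells = self.counts.shape
        if self.norm.shape != (n_genes, n_cells):
            raise ValueError("counts and norm shapes differ")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match counts columns")
        if len(self.clusters) != n_cells:
            raise ValueError("cluster labels do not cover all cells")
        if any(c == "" or c == "nan" for c in self.clusters):
            bad = [self.cell_ids[i] for i, c in enumerate(self.clusters) if c in ("", "nan")]
            raise ValueError(f"unlabelled cells: {bad[:5]}")
        if np.any(self.counts < 0):
            raise ValueError("negative values in count matrix")
        if len(set(self.clusters)) < 2:
            raise ValueError("at least two clusters required")

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
        clusters: Sequence[str],
        target_sum: float = 1e4,
    ) -> "ExpressionDataset":
        norm = normalize_counts(np.asarray(counts), target_sum=target_sum, cell_ids=cell_ids)
        return cls(np.asarray(counts), norm, list(gene_ids), list(cell_ids), np.asarray(clusters))

    @property
    def cluster_labels(self) -> list[str]:
        return sorted(set(self.clusters))

    def cells_of(self, cluster: str) -> np.ndarray:
        return np.flatnonzero(self.clusters == str(cluster))

    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return ExpressionDataset(
            self.counts[:, index],
            self.norm[:, index],
            self.gene_ids,
            [self.cell_ids[i] for i in index],
            self.clusters[index],
        )

    def with_clusters(self, clusters: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(
            self.counts, self.norm, self.gene_ids, self.cell_ids, np.asarray(clusters)
        )


def normalize_counts(
    counts: np.ndarray, target_sum: float = 1e4, cell_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Library-size normalize to ``target_sum`` per cell, then ln(1 + x)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative values in count matrix")
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [cell_ids[i] for i in zero] if cell_ids is not None else list(zero)
        raise ValueError(f"cells with zero total counts: {names[:5]}")
    return np.log1p(counts / totals * target_sum)


@dataclass
class ClusterStatTable:
    """Gene x cluster summary tables plus the dataset-wide scalar mu.

    Each attribute is a DataFrame indexed by gene with one column per
    cluster.  ``de_p`` may cover only a subset of genes (rows absent for the
    rest) when differential expression was computed on demand.  ``mu`` is the
    mean over all entries of the normalized layer (zeros included) and feeds
    the regularised LRscore.
    """

    mean_lin: pd.DataFrame
    mean_log: pd.DataFrame
    prop: pd.DataFrame
    log2fc: pd.DataFrame
    zscore: pd.DataFrame
    de_p: pd.DataFrame
    mu: float
    cluster_sizes: pd.Series
    dataset: ExpressionDataset | None = field(default=None, repr=False)

    @property
    def clusters(self) -> list[str]:
        return list(self.mean_log.columns)

    @property
    def genes(self) -> pd.Index:
        return self.mean_log.index


def _wilcoxon_one_vs_rest(
    norm: np.ndarray, masks: dict[str, np.ndarray], gene_index: np.ndarray
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p, per gene and cluster, on norm values."""
    sub = norm[gene_index]
    out = np.ones((len(gene_index), len(masks)))
    for j, mask in enumerate(masks.values()):
        x = sub[:, mask]
        y = sub[:, ~mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = mannwhitneyu(x, y, alternative="two-sided", axis=1, method="auto")
        p = np.asarray(res.pvalue, dtype=float)
        # Constant data across both groups gives an undefined statistic; no
        # evidence of a shift, so p = 1.
        out[:, j] = np.where(np.isfinite(p), p, 1.0)
    return np.clip(out, 0.0, 1.0)


def summarize_clusters(
    dataset: ExpressionDataset,
    de_genes: Sequence[str] | None = None,
    compute_de: bool = True,
) -> ClusterStatTable:
    """Compute all per-(gene, cluster) summaries.

    ``de_genes`` restricts the (comparatively expensive) Wilcoxon tests to a
    gene subset; other tables always cover all genes.  Clusters with fewer
    than 3 cells trigger a warning but are still summarised.
    """
    labels = dataset.cluster_labels
    masks = {c: dataset.clusters == c for c in labels}
    sizes = pd.Series({c: int(m.sum()) for c, m in masks.items()})
    small = sizes[sizes < 3]
    if len(small):
        warnings.warn(f"clusters with fewer than 3 cells: {list(small.index)}")

    norm = dataset.norm
    lin = np.expm1(norm)
    n_cells = norm.shape[1]

    mean_log = np.column_stack([norm[:, m].mean(axis=1) for m in masks.values()])
    mean_lin = np.column_stack([lin[:, m].mean(axis=1) for m in masks.values()])
    prop = np.column_stack([(dataset.counts[:, m] > 0).mean(axis=1) for m in masks.values()])

    # One-vs-rest fold change on de-logged means with pseudocount 1.
    lin_total = lin.sum(axis=1)
    rest_mean = np.empty_like(mean_lin)
    for j, m in enumerate(masks.values()):
        n_in = m.sum()
        rest = n_cells - n_in
        rest_mean[:, j] = (lin_total - mean_lin[:, j] * n_in) / rest if rest else 0.0
    log2fc = np.log2((mean_lin + 1.0) / (rest_mean + 1.0))

    # z-score of each cluster mean within the gene's vector of cluster means.
    mu_g = mean_log.mean(axis=1, keepdims=True)
    sd_g = mean_log.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        zscore = np.where(sd_g > 0, (mean_log - mu_g) / sd_g, 0.0)

    genes = pd.Index(dataset.gene_ids, name="gene")
    if compute_de:
        if de_genes is None:
            gene_index = np.arange(len(genes))
        else:
            wanted = set(de_genes)
            gene_index = np.flatnonzero([g in wanted for g in dataset.gene_ids])
        de = _wilcoxon_one_vs_rest(norm, masks, gene_index)
        de_p = pd.DataFrame(de, index=genes[gene_index], columns=labels)
    else:
        de_p = pd.DataFrame(index=pd.Index([], name="gene"), columns=labels, dtype=float)

    return ClusterStatTable(
        mean_lin=pd.DataFrame(mean_lin, index=genes, columns=labels),
        mean_log=pd.DataFrame(mean_log, index=genes, columns=labels),
        prop=pd.DataFrame(prop, index=genes, columns=labels),
        log2fc=pd.DataFrame(log2fc, index=genes, columns=labels),
        zscore=pd.DataFrame(zscore, index=genes, columns=labels),
        de_p=de_p,
        mu=float(norm.mean()),
        cluster_sizes=sizes,
        dataset=dataset,
    )


@dataclass(frozen=True)
class EntitySummary:
    """Cluster-level summary of a (possibly heteromeric) entity."""

    mean_lin: float
    mean_log: float
    prop: float
    log2fc: float
    zscore: float
    detected: bool
    representative: str | None


def entity_cluster_summary(
    entity: ProteinEntity, cluster: str, stats: ClusterStatTable
) -> EntitySummary:
    """Reduce an entity to its minimally expressed subunit in a cluster.

    All fields come from the subunit with the minimum ``mean_log`` in that
    cluster (lexicographic tie-break), except ``prop`` which is the minimum
    across subunits.  A subunit missing from the table marks the whole entity
    undetected.
    """
    genes = stats.mean_log.index
    if any(s not in genes for s in entity.subunits):
        return EntitySummary(0.0, 0.0, 0.0, 0.0, 0.0, False, None)
    col = str(cluster)
    means = {s: stats.mean_log.at[s, col] for s in entity.subunits}
    rep = min(sorted(means), key=lambda s: means[s])
    return EntitySummary(
        mean_lin=float(stats.mean_lin.at[rep, col]),
        mean_log=float(means[rep]),
        prop=float(min(stats.prop.at[s, col] for s in entity.subunits)),
        log2fc=float(stats.log2fc.at[rep, col]),
        zscore=float(stats.zscore.at[rep, col]),
        detected=True,
        representative=rep,
    )


def entity_matrices(
    entities: Iterable[ProteinEntity], stats: ClusterStatTable
) -> dict[str, pd.DataFrame]:
    """Entity x cluster matrices of min-subunit summaries, plus helpers.

    Returns mean_lin / mean_log / prop / log2fc / zscore frames indexed by
    canonical entity name, a ``detected`` boolean Series, a ``representative``
    frame of the chosen subunit per cluster, and ``de_p_max`` (the maximum
    differential-expression p across subunits, NaN where unavailable).
    """
    entities = list({e.name: e for e in entities}.values())
    clusters = stats.clusters
    fields = ["mean_lin", "mean_log", "prop", "log2fc", "zscore"]
    data = {f: pd.DataFrame(0.0, index=[e.name for e in entities], columns=clusters) for f in fields}
    rep = pd.DataFrame("", index=[e.name for e in entities], columns=clusters, dtype=object)
    de_max = pd.DataFrame(np.nan, index=[e.name for e in entities], columns=clusters)
    detected = pd.Series(False, index=[e.name for e in entities])
    de_genes = set(stats.de_p.index)
    for e in entities:
        name = e.name
        if any(s not in stats.mean_log.index for s in e.subunits):
            continue
        detected[name] = True
        sub_mean = stats.mean_log.loc[list(e.subunits)]
        order = np.argsort(sub_mean.index)  # lexicographic tie-break base
        sorted_idx = sub_mean.index[order]
        sm = sub_mean.loc[sorted_idx].to_numpy()
        rep_pos = sm.argmin(axis=0)
        reps = [sorted_idx[i] for i in rep_pos]
        rep.loc[name] = reps
        for f in fields[:2] + ["log2fc", "zscore"]:
            frame = getattr(stats, f)
            data[f].loc[name] = [frame.at[r, c] for r, c in zip(reps, clusters)]
        data["prop"].loc[name] = stats.prop.loc[list(e.subunits)].min(axis=0).to_numpy()
        if all(s in de_genes for s in e.subunits):
            de_max.loc[name] = stats.de_p.loc[list(e.subunits)].max(axis=0).to_numpy()
    data["representative"] = rep
    data["de_p_max"] = de_max
    data["detected"] = detected
    return data
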