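"""The six ligand-receptor scoring systems.

Each method scores every ordered cluster pair (autocrine pairs included) for
every interaction in the resource, producing a magnitude and/or a
cluster-pair-specificity score:

* ``cellphonedb`` — mean of ligand and receptor cluster means, with an
  empirical one-sided p-value from global cluster-label permutations.
* ``connectome``  — product of cluster means (weight_norm) and mean of the
  ligand/receptor z-scores (weight_scale), after a Wilcoxon DE filter.
* ``natmi``       — product of cluster means, and a specificity weight that
  divides each mean by the entity's summed means across all clusters.
* ``sca``         — the regularised LRscore sqrt(l*r) / (mu + sqrt(l*r)).
* ``logfc``       — mean of the ligand and receptor one-vs-rest log2FC.
* ``crosstalk``   — product of min-max-scaled preferential expression (PEM)
  and non-self-talk (NST, mutual-information-based) components.

All methods share the 10%-of-cells expression filter, score both paracrine
and autocrine pairs, and reduce heteromeric complexes to the minimally
expressed subunit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cluster_stats import ClusterStatTable, ExpressionDataset, entity_matrices, summarize_clusters
from .resources import InteractionRecord, ProteinEntity

__all__ = [
    "MethodConfig",
    "METHODS",
    "score_cellphonedb",
    "score_connectome",
    "score_natmi",
    "score_sca",
    "score_logfc_mean",
    "score_crosstalk",
    "score_methods",
]

logger = logging.getLogger("ccckit")

METHODS = ("cellphonedb", "connectome", "logfc", "natmi", "sca", "crosstalk")

SCORE_COLUMNS = [
    "source",
    "target",
    "ligand_complex",
    "receptor_complex",
    "score_magnitude",
    "score_specificity",
    "p_value",
]


@dataclass(frozen=True)
class MethodConfig:
    """Shared knobs for all scoring systems.

    ``prop_threshold`` is the minimum fraction of expressing cells for both
    entities; ``sca_*`` control the LRscore filters; ``crosstalk_bins`` is
    the number of equal-frequency bins for mutual information.
    """

    prop_threshold: float = 0.10
    n_permutations: int = 1000
    seed: int = 0
    de_p_threshold: float = 0.05
    sca_lr_threshold: float = 0.5
    sca_apply_lr_threshold: bool = True
    sca_logfc_threshold: float = 1.5
    sca_apply_logfc_filter: bool = True
    crosstalk_bins: int = 4
    eps: float = 1e-9

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")
        if not 0.0 <= self.prop_threshold <= 1.0:
            raise ValueError("prop_threshold must be in [0, 1]")
        if self.crosstalk_bins < 2:
            raise ValueError("crosstalk_bins must be at least 2")


# ---------------------------------------------------------------------------
# Shared scaffolding
# ---------------------------------------------------------------------------


class _PairFrame:
    """All (interaction, source, target) rows passing the shared filters."""

    def __init__(self, stats: ClusterStatTable, resource: Iterable[InteractionRecord],
                 config: MethodConfig):
        interactions = sorted(
            {rec.identity: rec for rec in resource}.values(), key=lambda r: r.identity
        )
        self.ligands = list({r.transmitter.name: r.transmitter for r in interactions}.values())
        self.receptors = list({r.receiver.name: r.receiver for r in interactions}.values())
        self.lig_idx = {e.name: i for i, e in enumerate(self.ligands)}
        self.rec_idx = {e.name: i for i, e in enumerate(self.receptors)}
        self.L = entity_matrices(self.ligands, stats)
        self.R = entity_matrices(self.receptors, stats)
        self.clusters = stats.clusters
        self.stats = stats
        self.config = config

        C = len(self.clusters)
        n_int = len(interactions)
        # Row layout: interaction-major, then source, then target.
        li = np.array([self.lig_idx[r.transmitter.name] for r in interactions])
        ri = np.array([self.rec_idx[r.receiver.name] for r in interactions])
        self.row_lig = np.repeat(li, C * C)
        self.row_rec = np.repeat(ri, C * C)
        self.row_src = np.tile(np.repeat(np.arange(C), C), n_int)
        self.row_tgt = np.tile(np.arange(C), n_int * C)
        self.interactions = interactions

        det = (
            self.L["detected"].to_numpy()[self.row_lig]
            & self.R["detected"].to_numpy()[self.row_rec]
        )
        lp = self.L["prop"].to_numpy()[self.row_lig, self.row_src]
        rp = self.R["prop"].to_numpy()[self.row_rec, self.row_tgt]
        self.base_mask = det & (lp >= config.prop_threshold) & (rp >= config.prop_threshold)
        logger.info(
            "prop filter (>= %.0f%% expressing): %d of %d candidate rows kept",
            100 * config.prop_threshold, int(self.base_mask.sum()), len(self.base_mask),
        )

    def gather(self, frame_key: str, side: str) -> np.ndarray:
        mats = self.L if side == "lig" else self.R
        rows = self.row_lig if side == "lig" else self.row_rec
        cols = self.row_src if side == "lig" else self.row_tgt
        return mats[frame_key].to_numpy()[rows, cols]

    def emit(self, mask: np.ndarray, magnitude: np.ndarray, specificity: np.ndarray,
             p_value: np.ndarray | None = None) -> pd.DataFrame:
        idx = np.flatnonzero(mask)
        clusters = np.asarray(self.clusters, dtype=object)
        lig_names = np.array([e.name for e in self.ligands], dtype=object)
        rec_names = np.array([e.name for e in self.receptors], dtype=object)
        out = pd.DataFrame(
            {
                "source": clusters[self.row_src[idx]],
                "target": clusters[self.row_tgt[idx]],
                "ligand_complex": lig_names[self.row_lig[idx]],
                "receptor_complex": rec_names[self.row_rec[idx]],
                "score_magnitude": np.asarray(magnitude)[idx],
                "score_specificity": np.asarray(specificity)[idx],
                "p_value": np.asarray(p_value)[idx] if p_value is not None else np.nan,
            }
        )
        return out.reset_index(drop=True)


def _entity_min_rows(entities: Sequence[ProteinEntity], gene_pos: dict[str, int]) -> list:
    return [np.array([gene_pos[s] for s in e.subunits]) for e in entities]


def _entity_means(M: np.ndarray, entity_rows: list) -> np.ndarray:
    """Min-subunit reduction of a gene x cluster mean matrix."""
    return np.vstack([M[rows].min(axis=0) for rows in entity_rows])


# ---------------------------------------------------------------------------
# Methods
# ---------------------------------------------------------------------------


def score_cellphonedb(
    stats: ClusterStatTable,
    resource: Iterable[InteractionRecord],
    config: MethodConfig = MethodConfig(),
) -> pd.DataFrame:
    """Truncated-mean score with a label-permutation empirical p-value.

    The magnitude is the mean of the ligand's cluster mean (source) and the
    receptor's cluster mean (target), on the normalized log layer with the
    min-subunit rule.  Cluster labels are reshuffled globally
    ``n_permutations`` times and the one-sided p-value is the fraction of
    permutations whose magnitude is at least the observed one (no
    pseudocount).  Specificity is 1 - p.
    """
    pf = _PairFrame(stats, resource, config)
    if stats.dataset is None:
        raise ValueError("cellphonedb scoring needs the dataset attached to the stats table")
    dataset = stats.dataset

    mask = pf.base_mask
    idx = np.flatnonzero(mask)
    # Restrict the permutation machinery to genes that can matter.
    genes_needed = sorted(
        {s for e in pf.ligands if pf.L["detected"][e.name] for s in e.subunits}
        | {s for e in pf.receptors if pf.R["detected"][e.name] for s in e.subunits}
    )
    gene_row = {g: i for i, g in enumerate(dataset.gene_ids)}
    genes_needed = [g for g in genes_needed if g in gene_row]
    X = dataset.norm[[gene_row[g] for g in genes_needed]]
    gene_pos = {g: i for i, g in enumerate(genes_needed)}

    def rows_or_empty(e):
        try:
            return np.array([gene_pos[s] for s in e.subunits])
        except KeyError:
            return np.array([0])  # undetected entities never pass base_mask

    lig_rows = [rows_or_empty(e) for e in pf.ligands]
    rec_rows = [rows_or_empty(e) for e in pf.receptors]

    codes = pd.Categorical(dataset.clusters, categories=pf.clusters).codes
    C = len(pf.clusters)
    n = len(codes)
    sizes = np.bincount(codes, minlength=C).astype(float)
    onehot = np.zeros((n, C))
    onehot[np.arange(n), codes] = 1.0 / sizes[codes]

    def magnitudes(weights: np.ndarray) -> np.ndarray:
        M = X @ weights
        Lm = _entity_means(M, lig_rows)
        Rm = _entity_means(M, rec_rows)
        return (Lm[pf.row_lig[idx], pf.row_src[idx]] + Rm[pf.row_rec[idx], pf.row_tgt[idx]]) / 2.0

    observed = magnitudes(onehot)
    rng = np.random.default_rng(config.seed)
    ge = np.zeros(observed.shape, dtype=np.int64)
    tol = 1e-12
    for _ in range(config.n_permutations):
        perm = rng.permutation(n)
        ge += magnitudes(onehot[perm]) >= observed - tol
    p = ge / config.n_permutations

    magnitude = np.zeros(len(mask))
    pvals = np.ones(len(mask))
    magnitude[idx] = observed
    pvals[idx] = p
    return pf.emit(mask, magnitude, 1.0 - pvals, pvals)


def score_connectome(
    stats: ClusterStatTable,
    resource: Iterable[InteractionRecord],
    config: MethodConfig = MethodConfig(),
) -> pd.DataFrame:
    """Product of cluster means plus a z-score-based specificity weight.

    Rows survive only when every subunit of both entities is differentially
    expressed (two-sided Wilcoxon one-vs-rest p <= threshold) in its cluster.
    weight_norm multiplies the two cluster means; weight_scale averages the
    two z-scores of the cluster means.
    """
    pf = _PairFrame(stats, resource, config)
    lde = pf.gather("de_p_max", "lig")
    rde = pf.gather("de_p_max", "rec")
    if np.isnan(lde[pf.base_mask]).any() or np.isnan(rde[pf.base_mask]).any():
        warnings.warn(
            "differential-expression p-values missing for some resource genes; "
            "those rows are dropped"
        )
    with np.errstate(invalid="ignore"):
        mask = pf.base_mask & (lde <= config.de_p_threshold) & (rde <= config.de_p_threshold)
    logger.info("connectome DE filter: %d rows kept", int(mask.sum()))
    lm = pf.gather("mean_log", "lig")
    rm = pf.gather("mean_log", "rec")
    weight_norm = lm * rm
    weight_scale = (pf.gather("zscore", "lig") + pf.gather("zscore", "rec")) / 2.0
    return pf.emit(mask, weight_norm, weight_scale)


def score_natmi(
    stats: ClusterStatTable,
    resource: Iterable[InteractionRecord],
    config: MethodConfig = MethodConfig(),
) -> pd.DataFrame:
    """Mean-expression and specificity edge weights.

    The specificity weight divides each entity's cluster mean by the sum of
    that entity's means across *all* clusters, and multiplies the ligand and
    receptor fractions; a zero denominator yields specificity 0.
    """
    pf = _PairFrame(stats, resource, config)
    Lm = pf.L["mean_log"].to_numpy()
    Rm = pf.R["mean_log"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        Lfrac = np.where(Lm.sum(axis=1, keepdims=True) > 0, Lm / Lm.sum(axis=1, keepdims=True), 0.0)
        Rfrac = np.where(Rm.sum(axis=1, keepdims=True) > 0, Rm / Rm.sum(axis=1, keepdims=True), 0.0)
    magnitude = pf.gather("mean_log", "lig") * pf.gather("mean_log", "rec")
    specificity = (
        Lfrac[pf.row_lig, pf.row_src] * Rfrac[pf.row_rec, pf.row_tgt]
    )
    return pf.emit(pf.base_mask, magnitude, specificity)


def score_sca(
    stats: ClusterStatTable,
    resource: Iterable[InteractionRecord],
    config: MethodConfig = MethodConfig(),
) -> pd.DataFrame:
    """Regularised LRscore: sqrt(l * r) / (mu + sqrt(l * r)).

    ``mu`` is the dataset-wide mean of the normalized layer.  By default rows
    additionally require |log2FC| >= 1.5 for both entities and LRscore >= 0.5
    (both filters can be switched off in the config).  Magnitude-only: the
    specificity column is NaN.
    """
    if stats.mu <= 0:
        raise ValueError("dataset mean expression mu must be positive")
    pf = _PairFrame(stats, resource, config)
    lm = pf.gather("mean_log", "lig")
    rm = pf.gather("mean_log", "rec")
    root = np.sqrt(lm * rm)
    lrscore = root / (stats.mu + root)
    mask = pf.base_mask.copy()
    if config.sca_apply_logfc_filter:
        mask &= np.abs(pf.gather("log2fc", "lig")) >= config.sca_logfc_threshold
        mask &= np.abs(pf.gather("log2fc", "rec")) >= config.sca_logfc_threshold
        logger.info("sca log2FC filter: %d rows kept", int(mask.sum()))
    if config.sca_apply_lr_threshold:
        mask &= lrscore >= config.sca_lr_threshold
        logger.info("sca LRscore >= %.2f filter: %d rows kept",
                    config.sca_lr_threshold, int(mask.sum()))
    return pf.emit(mask, lrscore, np.full_like(lrscore, np.nan))


def score_logfc_mean(
    stats: ClusterStatTable,
    resource: Iterable[InteractionRecord],
    config: MethodConfig = MethodConfig(),
) -> pd.DataFrame:
    """Mean of the ligand and receptor one-vs-rest log2 fold changes."""
    pf = _PairFrame(stats, resource, config)
    score = (pf.gather("log2fc", "lig") + pf.gather("log2fc", "rec")) / 2.0
    return pf.emit(pf.base_mask, score, score)


def _minmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _mutual_information_bits(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """MI of two vectors after equal-frequency binning, in bits."""
    n = len(x)
    bins = min(bins, n)
    if bins < 2:
        return 0.0

    def digitize(v):
        edges = np.unique(np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1]))
        return np.digitize(v, edges, right=True)

    xi, yi = digitize(x), digitize(y)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    return float(np.nansum(terms))


def score_crosstalk(
    stats: ClusterStatTable,
    resource: Iterable[InteractionRecord],
    config: MethodConfig = MethodConfig(),
) -> pd.DataFrame:
    """Crosstalk score: min-max-scaled PEM times min-max-scaled NST.

    PEM (preferential expression measure) of gene g in cluster c is
    max(0, log10(S_gc / E_gc)) where S sums normalized expression per
    gene x cluster and E is the independence expectation from the margins;
    PEM is 0 where S is 0.  The pair PEM averages the ligand (source) and
    receptor (target) PEMs.  NST (non-self-talk) penalises ligand-receptor
    co-expression within the source cluster via their mutual information
    after equal-frequency binning; for autocrine pairs (source = target) the
    inverse transform 1 / (1 - minmax(MI) + eps) is used instead, min-max
    rescaled across autocrine rows.  Rows whose ligand or receptor PEM is 0
    score exactly 0.
    """
    pf = _PairFrame(stats, resource, config)
    if stats.dataset is None:
        raise ValueError("crosstalk scoring needs the dataset attached to the stats table")
    dataset = stats.dataset

    clusters = pf.clusters
    S = np.column_stack(
        [dataset.norm[:, dataset.cells_of(c)].sum(axis=1) for c in clusters]
    )
    grand = S.sum()
    E = np.outer(S.sum(axis=1), S.sum(axis=0)) / grand if grand > 0 else np.zeros_like(S)
    with np.errstate(divide="ignore", invalid="ignore"):
        pem = np.where((S > 0) & (E > 0), np.log10(np.where(S > 0, S, 1.0) / np.where(E > 0, E, 1.0)), 0.0)
    pem = np.maximum(pem, 0.0)
    pem_df = pd.DataFrame(pem, index=dataset.gene_ids, columns=clusters)

    def entity_pem(side: str) -> np.ndarray:
        mats = pf.L if side == "lig" else pf.R
        rows = pf.row_lig if side == "lig" else pf.row_rec
        cols = pf.row_src if side == "lig" else pf.row_tgt
        rep = mats["representative"].to_numpy()
        out = np.zeros(len(rows))
        cl = np.asarray(clusters, dtype=object)
        for i in np.flatnonzero(pf.base_mask):
            g = rep[rows[i], cols[i]]
            if g:
                out[i] = pem_df.at[g, cl[cols[i]]]
        return out

    pem_l = entity_pem("lig")
    pem_r = entity_pem("rec")
    pair_pem = (pem_l + pem_r) / 2.0

    # Mutual information of ligand vs receptor within the source cluster.
    small = [c for c in clusters if stats.cluster_sizes[c] < config.crosstalk_bins]
    if small:
        warnings.warn(
            f"clusters smaller than {config.crosstalk_bins} cells; "
            f"reducing bin count there: {small}"
        )
    cell_idx = {c: dataset.cells_of(c) for c in clusters}
    gene_row = {g: i for i, g in enumerate(dataset.gene_ids)}
    rep_l = pf.L["representative"].to_numpy()
    rep_r = pf.R["representative"].to_numpy()
    cl = np.asarray(clusters, dtype=object)
    mi = np.zeros(len(pf.base_mask))
    cache: dict[tuple, float] = {}
    for i in np.flatnonzero(pf.base_mask):
        s = pf.row_src[i]
        gl = rep_l[pf.row_lig[i], s]
        gr = rep_r[pf.row_rec[i], s]
        if not gl or not gr:
            continue
        key = (gl, gr, s)
        if key not in cache:
            cells = cell_idx[cl[s]]
            cache[key] = _mutual_information_bits(
                dataset.norm[gene_row[gl], cells],
                dataset.norm[gene_row[gr], cells],
                config.crosstalk_bins,
            )
        mi[i] = cache[key]

    mask = pf.base_mask
    mm_mi = np.zeros_like(mi)
    if mask.any():
        mm_mi[mask] = _minmax(mi[mask])
    nst = 1.0 - mm_mi
    auto = mask & (pf.row_src == pf.row_tgt)
    if auto.any():
        inv = 1.0 / (1.0 - mm_mi[auto] + config.eps)
        nst[auto] = _minmax(inv)

    score = np.zeros_like(nst)
    if mask.any():
        score[mask] = _minmax(pair_pem[mask]) * _minmax(nst[mask])
    score[(pem_l == 0) | (pem_r == 0)] = 0.0
    return pf.emit(mask, score, score)


# ---------------------------------------------------------------------------
# Pipeline entry point
# ---------------------------------------------------------------------------

_DISPATCH = {
    "cellphonedb": score_cellphonedb,
    "connectome": score_connectome,
    "natmi": score_natmi,
    "sca": score_sca,
    "logfc": score_logfc_mean,
    "crosstalk": score_crosstalk,
}


def score_methods(
    dataset_or_stats: ExpressionDataset | ClusterStatTable,
    resource: Iterable[InteractionRecord],
    methods: Sequence[str] | str = "all",
    config: MethodConfig = MethodConfig(),
) -> pd.DataFrame:
    """Run the requested scoring systems and return one long-format table.

    Accepts either a dataset (summaries are computed, with the Wilcoxon
    tests restricted to resource genes) or a pre-computed stat table.
    """
    resource = list(resource)
    if isinstance(dataset_or_stats, ExpressionDataset):
        genes = sorted(
            {s for rec in resource for s in rec.transmitter.subunits}
            | {s for rec in resource for s in rec.receiver.subunits}
        )
        stats = summarize_clusters(dataset_or_stats, de_genes=genes)
    else:
        stats = dataset_or_stats
    if methods == "all":
        methods = METHODS
    elif isinstance(methods, str):
        methods = [methods]
    unknown = [m for m in methods if m not in _DISPATCH]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}; choose from {sorted(_DISPATCH)}")
    frames = []
    for m in methods:
        df = _DISPATCH[m](stats, resource, config)
        df.insert(0, "method", m)
        logger.info("method %s: %d scored rows", m, len(df))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
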