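"""Seeded synthetic-data generators with planted ground truth.

The generator emulates a cluster-annotated scRNA-seq experiment: negative
binomial counts with log-normal library-size factors, a configurable number
of planted ligand-receptor pairs (the ligand upregulated in its source
cluster, the receptor in its target cluster, optionally as a two-subunit
complex), decoy interactions among untouched genes, and matching auxiliary
modalities — spatial spot proportions with correlated planted pairs,
orthogonal cytokine signatures whose activity is planted into designated
clusters, and receptor protein abundances elevated for planted receptors.

All draws flow from the single ``seed`` in ``ScenarioConfig`` through named
substreams, so every artifact is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster_stats import ExpressionDataset, normalize_counts
from .resources import InteractionRecord, ProteinEntity

__all__ = ["ScenarioConfig", "GroundTruth", "generate_dataset", "generate_resource",
           "generate_modalities"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    ``effect_size`` multiplies the planted ligand's mean in its source
    cluster (and the receptor's in its target); ``dispersion`` is the
    negative binomial size parameter theta (variance m + m^2/theta);
    ``library_size_cv`` is the coefficient of variation of the per-cell
    log-normal library factor.
    """

    seed: int
    n_genes: int = 2000
    n_clusters: int = 20
    cells_per_cluster: int = 100
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    n_planted_pairs: int = 20
    effect_size: float = 8.0
    n_decoy_interactions: int = 300
    complex_fraction: float = 0.25
    library_size_cv: float = 0.3
    n_spots: int = 200
    n_cytokines: int = 8
    signature_genes_per_cytokine: int = 30
    activity_effect: float = 3.0
    n_coloc_pairs: int = 6

    def __post_init__(self):
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.n_clusters < 2:
            raise ValueError("need at least two clusters")
        if self.n_cytokines > self.n_planted_pairs:
            raise ValueError("cannot plant more cytokines than ligand-receptor pairs")


@dataclass
class GroundTruth:
    """What was planted: interactions, colocalization, activities, proteins."""

    planted: list[tuple[str, str, str, str]]  # (source, target, ligand, receptor)
    coloc_pairs: list[tuple[str, str]]
    active_cytokines: list[tuple[str, str]]  # (cytokine, cluster)
    specific_receptors: list[tuple[str, str]]  # (receptor, cluster)
    ligand_entities: list[ProteinEntity]
    receptor_entities: list[ProteinEntity]
    signature_genes: dict[str, list[str]]
    decoy_gene_pool: list[str]

    @property
    def planted_ids(self) -> frozenset:
        return frozenset(self.planted)


def _blueprint(config: ScenarioConfig):
    """Deterministic assignment of genes and clusters to planted structure."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    clusters = [f"C{i:02d}" for i in range(config.n_clusters)]

    pool = iter(genes)
    ligands, receptors, planted = [], [], []
    complex_draws = rng.random(config.n_planted_pairs)
    needed = config.n_planted_pairs * 3 + config.n_cytokines * config.signature_genes_per_cytokine
    if needed > config.n_genes:
        raise ValueError(
            f"gene budget too small: need up to {needed} genes for plantings, "
            f"have {config.n_genes}"
        )
    for i in range(config.n_planted_pairs):
        lig = ProteinEntity([next(pool)])
        if complex_draws[i] < config.complex_fraction:
            rec = ProteinEntity([next(pool), next(pool)])
        else:
            rec = ProteinEntity([next(pool)])
        source = clusters[i % config.n_clusters]
        target = clusters[(i + config.n_clusters // 2) % config.n_clusters]
        ligands.append(lig)
        receptors.append(rec)
        planted.append((source, target, lig.name, rec.name))

    cytokines = [ligands[k].name for k in range(config.n_cytokines)]
    signature_genes = {}
    active = []
    for k, cyt in enumerate(cytokines):
        sig = [next(pool) for _ in range(config.signature_genes_per_cytokine)]
        signature_genes[cyt] = sig
        active.append((cyt, planted[k][1]))  # active in the pair's target cluster

    used = {g for e in ligands + receptors for g in e.subunits}
    used |= {g for sig in signature_genes.values() for g in sig}
    decoy_pool = [g for g in genes if g not in used]

    coloc = []
    for source, target, _, _ in planted:
        pair = tuple(sorted((source, target)))
        if pair not in coloc and source != target:
            coloc.append(pair)
        if len(coloc) >= config.n_coloc_pairs:
            break

    specific = [(rec.name, planted[i][1]) for i, rec in enumerate(receptors)]

    truth = GroundTruth(
        planted=planted,
        coloc_pairs=coloc,
        active_cytokines=active,
        specific_receptors=specific,
        ligand_entities=ligands,
        receptor_entities=receptors,
        signature_genes=signature_genes,
        decoy_gene_pool=decoy_pool,
    )
    return genes, clusters, truth


def generate_dataset(config: ScenarioConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate counts with planted ligand-receptor and activity structure."""
    genes, clusters, truth = _blueprint(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    C, n_per = config.n_clusters, config.cells_per_cluster

    mean = np.full((config.n_genes, C), config.baseline_mean)
    cl_pos = {c: j for j, c in enumerate(clusters)}
    for (source, target, _, _), lig, rec in zip(
        truth.planted, truth.ligand_entities, truth.receptor_entities
    ):
        for g in lig.subunits:
            mean[gene_pos[g], cl_pos[source]] *= config.effect_size
        for g in rec.subunits:
            mean[gene_pos[g], cl_pos[target]] *= config.effect_size
    for cyt, cluster in truth.active_cytokines:
        for g in truth.signature_genes[cyt]:
            mean[gene_pos[g], cl_pos[cluster]] *= config.activity_effect

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    sigma2 = np.log1p(config.library_size_cv**2)
    n_cells = C * n_per
    lib = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n_cells)

    cell_clusters = np.repeat(clusters, n_per)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    mu = mean[:, np.repeat(np.arange(C), n_per)] * lib[None, :]
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    dataset = ExpressionDataset(
        counts=counts,
        norm=normalize_counts(counts, cell_ids=cell_ids),
        gene_ids=genes,
        cell_ids=cell_ids,
        clusters=cell_clusters,
    )
    return dataset, truth


def generate_resource(config: ScenarioConfig, truth: GroundTruth) -> set[InteractionRecord]:
    """Planted interactions plus decoy pairs among untouched genes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    records = {
        InteractionRecord(lig, rec, resource_name="synthetic")
        for lig, rec in zip(truth.ligand_entities, truth.receptor_entities)
    }
    existing = {r.identity for r in records}
    pool = truth.decoy_gene_pool
    if len(pool) * (len(pool) - 1) < 2 * config.n_decoy_interactions:
        raise ValueError(
            f"decoy gene pool of {len(pool)} genes cannot host "
            f"{config.n_decoy_interactions} distinct decoy interactions"
        )
    while len(records) < len(existing) + config.n_decoy_interactions:
        a, b = rng.choice(len(pool), size=2, replace=False)
        rec = InteractionRecord(
            ProteinEntity([pool[a]]), ProteinEntity([pool[b]]), resource_name="synthetic"
        )
        if rec.identity not in existing:
            records.add(rec)
    return records


def generate_modalities(
    config: ScenarioConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spot proportions, cytokine signature matrix, and protein abundances.

    Returns ``(proportions, signatures, abundance)``: spots x clusters
    proportions whose planted colocalized pairs share a latent factor,
    a genes x cytokines 0/1 weight matrix with disjoint (orthogonal)
    signature gene sets, and a receptor x cluster abundance matrix elevated
    for planted receptors in their target clusters.
    """
    all_clusters = [f"C{i:02d}" for i in range(config.n_clusters)]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    base = rng.gamma(shape=2.0, scale=1.0, size=(config.n_spots, config.n_clusters))
    props = pd.DataFrame(base, columns=all_clusters)
    for a, b in truth.coloc_pairs:
        factor = rng.gamma(shape=2.0, scale=2.0, size=config.n_spots)
        props[a] += factor
        props[b] += factor
    props = props.div(props.sum(axis=1), axis=0)
    props.index = [f"spot{i:04d}" for i in range(config.n_spots)]

    # A zero-weight background block keeps the regression design full rank
    # (with only signature genes the indicator columns would sum to the
    # intercept).
    sig_genes = sorted({g for sig in truth.signature_genes.values() for g in sig})
    n_background = min(4 * config.signature_genes_per_cytokine, len(truth.decoy_gene_pool))
    background = truth.decoy_gene_pool[-n_background:]
    signatures = pd.DataFrame(
        0.0,
        index=pd.Index(sig_genes + background, name="gene"),
        columns=list(truth.signature_genes),
    )
    for cyt, sig in truth.signature_genes.items():
        signatures.loc[sig, cyt] = 1.0

    receptors = sorted({r.name for r in truth.receptor_entities})
    abund = pd.DataFrame(
        rng.gamma(shape=100.0, scale=0.1, size=(len(receptors), config.n_clusters)),
        index=pd.Index(receptors, name="receptor"),
        columns=all_clusters,
    )
    for rec, cluster in truth.specific_receptors:
        abund.loc[rec, cluster] += 8.0
    return props, signatures, abund
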