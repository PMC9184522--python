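"""Noise-injection robustness analyses.

Four perturbations measure the stability of each method's top-ranked
interactions against a fixed baseline: per-cluster cell subsampling,
partial reshuffling of cluster labels, and selective / non-selective
replacement of resource interactions with spurious pairs drawn from the
dataset's most variable genes.  The baseline is the tie-inclusive top-250
per method on the unmodified inputs, and stability is the fraction of the
baseline recovered after each manipulation.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cluster_stats import ExpressionDataset
from .consensus import rank_interactions
from .rank_analysis import TopSet, top_ranked
from .resources import InteractionRecord, ProteinEntity
from .scoring import MethodConfig, METHODS, score_methods

__all__ = [
    "subsample_cells",
    "shuffle_labels",
    "corrupt_resource",
    "robustness_sweep",
    "ANALYSES",
]

logger = logging.getLogger("ccckit")

ANALYSES = ("subsample_cells", "shuffle_labels", "resource_selective", "resource_nonselective")

DEFAULT_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)
BASELINE_TOP_K = 250


def subsample_cells(dataset: ExpressionDataset, keep_fraction: float, seed: int) -> ExpressionDataset:
    """Subsample each cluster independently (without replacement)."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return dataset
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in dataset.cluster_labels:
        cells = dataset.cells_of(c)
        n_keep = int(round(keep_fraction * len(cells)))
        if n_keep < 3:
            raise ValueError(
                f"cluster {c!r} would drop below the 3-cell floor ({n_keep} cells)"
            )
        keep.append(rng.choice(cells, size=n_keep, replace=False))
    index = np.sort(np.concatenate(keep))
    return dataset.subset_cells(index)


def shuffle_labels(dataset: ExpressionDataset, fraction: float, seed: int) -> ExpressionDataset:
    """Permute the cluster labels of a random subset of cells.

    A subset of size fraction * n is drawn and its labels are permuted among
    themselves, preserving the overall label multiset.  Self-assignments can
    occur, so the share of actually mislabeled cells is slightly below the
    fraction.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0:
        return dataset
    rng = np.random.default_rng(seed)
    n = len(dataset.cell_ids)
    m = int(round(fraction * n))
    chosen = rng.choice(n, size=m, replace=False)
    new_labels = dataset.clusters.copy()
    new_labels[chosen] = new_labels[rng.permutation(chosen)]
    return dataset.with_clusters(new_labels)


def _variable_genes(dataset: ExpressionDataset, n: int = 2000) -> list[str]:
    if len(dataset.gene_ids) < n:
        warnings.warn(
            f"dataset has {len(dataset.gene_ids)} genes (< {n}); using all genes"
        )
        return list(dataset.gene_ids)
    var = dataset.norm.var(axis=1)
    order = np.argsort(var)[::-1][:n]
    return [dataset.gene_ids[i] for i in order]


def corrupt_resource(
    resource: Iterable[InteractionRecord],
    dataset: ExpressionDataset,
    fraction: float,
    mode: str = "nonselective",
    baseline_topset: TopSet | None = None,
    seed: int = 0,
) -> set[InteractionRecord]:
    """Replace a fraction of the resource with spurious interactions.

    Fake interactions are random ordered pairs of the dataset's 2000 most
    variable genes (by variance of the normalized layer), never colliding
    with existing records.  ``selective`` mode protects records underlying
    ``baseline_topset`` from replacement; ``nonselective`` replaces records
    uniformly.  Resource size is preserved.
    """
    if not 0 <= fraction <= 0.40:
        raise ValueError("fraction must be in [0, 0.40]")
    if mode not in {"selective", "nonselective"}:
        raise ValueError("mode must be 'selective' or 'nonselective'")
    records = sorted(set(resource), key=lambda r: r.identity)
    n_replace = int(np.floor(fraction * len(records)))
    if n_replace == 0:
        return set(records)
    rng = np.random.default_rng(seed)
    genes = _variable_genes(dataset)
    existing = {r.identity for r in records}

    if mode == "selective":
        if baseline_topset is None:
            raise ValueError("selective mode needs the baseline topset")
        protected_pairs = {
            (ls, rs)
            for _, _, lig, rec in baseline_topset.ids
            for ls in ProteinEntity(lig).subunits
            for rs in ProteinEntity(rec).subunits
        }
        replaceable = [
            i
            for i, r in enumerate(records)
            if not any(
                (ls, rs) in protected_pairs
                for ls in r.transmitter.subunits
                for rs in r.receiver.subunits
            )
        ]
        if len(replaceable) < n_replace:
            raise ValueError(
                f"only {len(replaceable)} replaceable records for "
                f"{n_replace} requested replacements"
            )
    else:
        replaceable = list(range(len(records)))
    victims = set(rng.choice(replaceable, size=n_replace, replace=False).tolist())

    fakes: set[tuple[str, str]] = set()
    while len(fakes) < n_replace:
        a, b = rng.choice(len(genes), size=2, replace=False)
        pair = (genes[a], genes[b])
        if pair not in existing and pair not in fakes:
            fakes.add(pair)
    fake_records = [
        InteractionRecord(ProteinEntity([t]), ProteinEntity([r]), resource_name="spurious")
        for t, r in sorted(fakes)
    ]
    out = {r for i, r in enumerate(records) if i not in victims}
    out.update(fake_records)
    return out


def _top_per_method(scored_long: pd.DataFrame, k: int) -> dict[str, TopSet]:
    out = {}
    for m in scored_long["method"].unique():
        ranked = rank_interactions(scored_long, m)
        out[m] = top_ranked(ranked, k=min(k, len(ranked)), method=m)
    return out


def robustness_sweep(
    dataset: ExpressionDataset,
    resource: Iterable[InteractionRecord],
    methods: Sequence[str] = METHODS,
    analyses: Sequence[str] = ANALYSES,
    grid: Sequence[float] = DEFAULT_GRID,
    reps: int = 5,
    seed: int = 0,
    config: MethodConfig | None = None,
    top_k: int = BASELINE_TOP_K,
) -> pd.DataFrame:
    """Run the four noise analyses over a manipulation grid.

    Returns a tidy frame (analysis, method, fraction, rep, overlap) where
    overlap is the fraction of each method's baseline top-250 recovered on
    the perturbed inputs.  Zero-fraction rows reuse the deterministic
    baseline, so their overlap is exactly 1.  A method failing on a
    perturbed input is recorded as NaN rather than aborting the sweep.
    """
    if any(f < 0 or f > 0.40 for f in grid):
        raise ValueError("manipulation fractions must lie in [0, 0.40]")
    unknown = set(analyses) - set(ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")
    resource = set(resource)
    config = config or MethodConfig(seed=seed)
    baseline_scores = score_methods(dataset, resource, methods, config)
    baseline = _top_per_method(baseline_scores, top_k)

    rows = []
    ss = np.random.SeedSequence(seed)
    zero_cache: dict[str, dict] = {}
    for analysis in analyses:
        for fraction in grid:
            for rep in range(reps):
                sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                if fraction == 0 and analysis in zero_cache:
                    # zero manipulation is seed-independent; one real run suffices
                    tops = zero_cache[analysis]
                else:
                    try:
                        pert_data, pert_resource = dataset, resource
                        if analysis == "subsample_cells":
                            pert_data = subsample_cells(dataset, 1.0 - fraction, sub_seed)
                        elif analysis == "shuffle_labels":
                            pert_data = shuffle_labels(dataset, fraction, sub_seed)
                        elif analysis == "resource_selective":
                            union_top = TopSet(
                                method="union",
                                resource="",
                                ids=frozenset().union(*(t.ids for t in baseline.values())),
                                nominal_k=top_k,
                            )
                            pert_resource = corrupt_resource(
                                resource, dataset, fraction, "selective", union_top, sub_seed
                            )
                        else:
                            pert_resource = corrupt_resource(
                                resource, dataset, fraction, "nonselective", seed=sub_seed
                            )
                        scored = score_methods(pert_data, pert_resource, methods, config)
                        tops = _top_per_method(scored, top_k)
                        if fraction == 0:
                            zero_cache[analysis] = tops
                    except Exception as exc:  # record, don't crash the sweep
                        logger.warning(
                            "%s at %.0f%% rep %d failed: %s", analysis, 100 * fraction, rep, exc
                        )
                        tops = {}
                for m in methods:
                    if m in tops and m in baseline and baseline[m].ids:
                        overlap = len(tops[m].ids & baseline[m].ids) / len(baseline[m].ids)
                    else:
                        overlap = np.nan
                    rows.append(
                        {
                            "analysis": analysis,
                            "method": m,
                            "fraction": fraction,
                            "rep": rep,
                            "overlap": overlap,
                        }
                    )
    return pd.DataFrame(rows)
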