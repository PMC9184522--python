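"""Top-k extraction and overlap analysis across method x resource runs.

Runs are compared on interaction *identities* — (source, target, ligand,
receptor) tuples after complex dissociation — so that complex-aware and
simple resources land in the same universe.  Provides tie-inclusive top-k
sets, pairwise Jaccard matrices with per-group medians, per-cell-type edge
frequencies, and relative interaction strength.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import IDENTITY_COLUMNS, RANK_KEYS, rank_interactions
from .resources import ProteinEntity

__all__ = [
    "TopSet",
    "top_ranked",
    "presence_absence",
    "jaccard_matrix",
    "celltype_frequencies",
    "relative_strength",
]


@dataclass(frozen=True)
class TopSet:
    """Tie-inclusive top-k interaction identities from one run."""

    method: str
    resource: str
    ids: frozenset
    nominal_k: int
    rows: tuple = ()  # the (source, target, ligand, receptor) rows kept, pre-dissociation

    @property
    def actual_size(self) -> int:
        return len(self.ids)


def _dissociated_ids(rows: Iterable[tuple]) -> frozenset:
    out = set()
    for src, tgt, lig, rec in rows:
        for ls in ProteinEntity(lig).subunits:
            for rs in ProteinEntity(rec).subunits:
                out.add((src, tgt, ls, rs))
    return frozenset(out)


def top_ranked(
    ranking: pd.DataFrame,
    k: int | None = None,
    fraction: float | None = None,
    method: str = "",
    resource: str = "",
    dissociate: bool = True,
) -> TopSet:
    """Keep the best-ranked interactions, including ties at the boundary.

    ``ranking`` must carry a ``rank`` column (see ``rank_interactions``).
    Either ``k`` or ``fraction`` (of the ranking's size, rounded up) must be
    given.  All rows whose rank does not exceed the k-th best rank are kept.
    """
    n = len(ranking)
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        k = ceil(fraction * n)
    if k is None or k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        warnings.warn(f"k={k} exceeds the universe size {n}; returning everything")
        k = n
    ranks = ranking["rank"].to_numpy()
    boundary = np.sort(ranks)[k - 1]
    kept = ranking[ranking["rank"] <= boundary]
    rows = tuple(map(tuple, kept[IDENTITY_COLUMNS].to_numpy()))
    ids = _dissociated_ids(rows) if dissociate else frozenset(rows)
    return TopSet(method=method, resource=resource, ids=ids, nominal_k=k, rows=rows)


def presence_absence(topsets: Sequence[TopSet]) -> pd.DataFrame:
    """Boolean interaction-identity x run matrix over the union of topsets."""
    labels = [f"{t.method}|{t.resource}" for t in topsets]
    universe = sorted(set().union(*(t.ids for t in topsets)))
    data = {
        label: [i in t.ids for i in universe] for label, t in zip(labels, topsets)
    }
    index = pd.MultiIndex.from_tuples(
        universe, names=["source", "target", "ligand", "receptor"]
    )
    return pd.DataFrame(data, index=index)


def jaccard_matrix(
    topsets: Sequence[TopSet], group_by: str | None = None
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Pairwise Jaccard matrix over topsets, with per-group medians.

    ``group_by`` ("method" or "resource") groups runs sharing that label and
    summarises each group by the median of its off-diagonal pairwise Jaccard
    indices — e.g. grouping by resource measures how much the *methods*
    disagree on a fixed resource.
    """
    if len(topsets) < 2:
        raise ValueError("need at least two topsets")
    labels = [f"{t.method}|{t.resource}" for t in topsets]
    n = len(topsets)
    mat = pd.DataFrame(np.eye(n), index=labels, columns=labels)
    for i, j in itertools.combinations(range(n), 2):
        a, b = topsets[i].ids, topsets[j].ids
        union = len(a | b)
        jac = len(a & b) / union if union else 0.0
        mat.iloc[i, j] = mat.iloc[j, i] = jac
    if group_by is None:
        return mat, None
    if group_by not in {"method", "resource"}:
        raise ValueError("group_by must be 'method' or 'resource'")
    medians = {}
    keys = sorted({getattr(t, group_by) for t in topsets})
    for key in keys:
        idx = [i for i, t in enumerate(topsets) if getattr(t, group_by) == key]
        vals = [mat.iloc[i, j] for i, j in itertools.combinations(idx, 2)]
        medians[key] = float(np.median(vals)) if vals else float("nan")
    return mat, pd.Series(medians, name="median_jaccard")


def celltype_frequencies(topset: TopSet, role: str = "source") -> pd.Series:
    """Share of top edges stemming from (or leading to) each cluster."""
    if role not in {"source", "target"}:
        raise ValueError("role must be 'source' or 'target'")
    if not topset.rows:
        raise ValueError("empty topset")
    pos = 0 if role == "source" else 1
    counts = pd.Series([r[pos] for r in topset.rows]).value_counts()
    return (counts / counts.sum()).sort_index()


def relative_strength(scored: pd.DataFrame, method: str) -> pd.DataFrame:
    """Relative interaction strength per cluster and role.

    The method's recommended score is min-max scaled to [0, 1]; each
    cluster's mean scaled score over its edges (as source, resp. target) is
    divided by the mean scaled score of all predictions.  Constant scores
    scale to 0.5 everywhere (with a warning).
    """
    if method not in RANK_KEYS:
        raise ValueError(f"unknown method {method!r}")
    col = RANK_KEYS[method][0]
    df = scored
    if "method" in df.columns:
        df = df[df["method"] == method]
    if df.empty:
        raise ValueError(f"no scores for method {method!r}")
    x = df[col].to_numpy(dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn("constant scores; min-max scaling undefined, using 0.5")
        scaled = np.full_like(x, 0.5)
    else:
        scaled = (x - lo) / (hi - lo)
    overall = scaled.mean()
    rows = []
    for role, key in (("source", "source"), ("target", "target")):
        groups = pd.Series(scaled).groupby(df[key].to_numpy()).mean()
        for cluster, m in groups.items():
            rows.append({"cluster": cluster, "role": role, "rel_strength": m / overall})
    return pd.DataFrame(rows)
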