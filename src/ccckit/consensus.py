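"""Per-method ranking and robust rank aggregation (RRA) consensus.

Each method ranks its surviving interactions by its recommended score.  The
aggregate builds a rank matrix over the universe of all predictions (missing
entries imputed as the maximum normalized rank, 1), and for each interaction
computes rho — the minimum over k of the Beta(k, K-k+1) CDF evaluated at the
k-th smallest normalized rank — i.e. the smallest order-statistic p-value
against a uniform-rank null.  A Bonferroni-style correction multiplies rho
by the number of methods K (capped at 1); the consensus ranking ascends by
this corrected score.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta, rankdata

__all__ = [
    "RANK_KEYS",
    "rank_interactions",
    "build_rank_matrix",
    "aggregate_rra",
    "add_consensus",
]

IDENTITY_COLUMNS = ["source", "target", "ligand_complex", "receptor_complex"]

#: Recommended ranking key per method: (column, direction, tiebreak column,
#: tiebreak direction).  ``ascending`` ranks small values best.
RANK_KEYS: dict[str, tuple[str, str, str | None, str | None]] = {
    "cellphonedb": ("p_value", "ascending", "score_magnitude", "descending"),
    "connectome": ("score_specificity", "descending", None, None),
    "natmi": ("score_specificity", "descending", None, None),
    "sca": ("score_magnitude", "descending", None, None),
    "logfc": ("score_specificity", "descending", None, None),
    "crosstalk": ("score_specificity", "descending", None, None),
    "consensus": ("score_specificity", "descending", None, None),
}


def _composite_rank(primary: np.ndarray, secondary: np.ndarray | None) -> np.ndarray:
    """Average-tie ranks by primary key, breaking ties with the secondary.

    Both keys are oriented so that *smaller is better* before the call.
    """
    if secondary is None:
        return rankdata(primary, method="average")
    # Dense primary ranks are integers; adding a secondary rank squeezed into
    # (0, 1) reorders only within primary ties.
    dense = rankdata(primary, method="dense").astype(float)
    sec = rankdata(secondary, method="average")
    sec = sec / (len(sec) + 1.0)
    return rankdata(dense + sec, method="average")


def rank_interactions(
    scored: pd.DataFrame, method: str, direction: str | None = None
) -> pd.DataFrame:
    """Attach a ``rank`` column (1 = most preferred, average ties).

    ``direction`` overrides the method's recommended orientation ("ascending"
    ranks small score values first).
    """
    if method not in RANK_KEYS:
        raise ValueError(f"unknown method {method!r}; known: {sorted(RANK_KEYS)}")
    col, default_dir, tb_col, tb_dir = RANK_KEYS[method]
    direction = direction or default_dir
    if direction not in {"ascending", "descending"}:
        raise ValueError("direction must be 'ascending' or 'descending'")
    df = scored.copy()
    if "method" in df.columns:
        df = df[df["method"] == method].copy()
    primary = df[col].to_numpy(dtype=float)
    if direction == "descending":
        primary = -primary
    secondary = None
    if tb_col is not None:
        secondary = df[tb_col].to_numpy(dtype=float)
        if tb_dir == "descending":
            secondary = -secondary
    df["rank"] = _composite_rank(primary, secondary)
    return df.sort_values("rank").reset_index(drop=True)


def build_rank_matrix(scored_long: pd.DataFrame) -> pd.DataFrame:
    """Normalized-rank matrix (interactions x methods) from a long table.

    The universe is the union of interaction identities surviving any
    method's filters; each method's ranks are divided by the universe size,
    and identities a method did not score are imputed at 1 (the maximum
    normalized rank).
    """
    methods = [m for m in scored_long["method"].unique() if m != "consensus"]
    ranked = {m: rank_interactions(scored_long, m) for m in methods}
    universe = pd.MultiIndex.from_frame(
        scored_long.loc[scored_long["method"] != "consensus", IDENTITY_COLUMNS].drop_duplicates()
    )
    n = len(universe)
    mat = pd.DataFrame(1.0, index=universe, columns=methods)
    for m, df in ranked.items():
        keys = pd.MultiIndex.from_frame(df[IDENTITY_COLUMNS])
        mat.loc[keys, m] = (df["rank"] / n).to_numpy()
    return mat


def aggregate_rra(matrix: pd.DataFrame) -> pd.DataFrame:
    """Beta order-statistic aggregation of a normalized-rank matrix.

    For each row with sorted normalized ranks r(1) <= ... <= r(K),
    rho = min_k BetaCDF(r(k); k, K - k + 1) and the corrected score is
    min(rho * K, 1).  Rows outside (0, 1] are rejected.
    """
    vals = matrix.to_numpy(dtype=float)
    if vals.size and (np.nanmin(vals) <= 0 or np.nanmax(vals) > 1):
        raise ValueError("normalized ranks must lie in (0, 1]")
    K = vals.shape[1]
    if K < 1:
        raise ValueError("at least one method required")
    sorted_ranks = np.sort(vals, axis=1)
    ks = np.arange(1, K + 1)
    cdf = beta.cdf(sorted_ranks, ks[None, :], (K - ks + 1)[None, :])
    rho = cdf.min(axis=1)
    corrected = np.minimum(rho * K, 1.0)
    out = pd.DataFrame(
        {"rho": rho, "corrected_score": corrected}, index=matrix.index
    )
    return out.sort_values("corrected_score")


def add_consensus(scored_long: pd.DataFrame) -> pd.DataFrame:
    """Append the RRA consensus as method ``"consensus"``.

    The consensus row's specificity is 1 - corrected_score (so descending
    specificity reproduces the ascending corrected-score order); magnitude
    mirrors it and the p-value column is left empty.
    """
    mat = build_rank_matrix(scored_long)
    agg = aggregate_rra(mat)
    idf = agg.index.to_frame(index=False)
    cons = pd.DataFrame(
        {
            "method": "consensus",
            "source": idf["source"],
            "target": idf["target"],
            "ligand_complex": idf["ligand_complex"],
            "receptor_complex": idf["receptor_complex"],
            "score_magnitude": 1.0 - agg["corrected_score"].to_numpy(),
            "score_specificity": 1.0 - agg["corrected_score"].to_numpy(),
            "p_value": np.nan,
        }
    )
    return pd.concat(
        [scored_long[scored_long["method"] != "consensus"], cons], ignore_index=True
    )
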