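"""Agreement of predictions with auxiliary modalities.

Three binary "calls" are derived from independent data: active cytokines per
target cluster (multivariate linear model on pseudobulk profiles against
cytokine expression signatures), spatially colocalized cluster pairs
(correlated deconvolution proportions, or neighborhood-enrichment z-scores,
at z >= 1.645), and specifically abundant receptor proteins (per-receptor
z-scores across clusters at the same threshold).  Predictions are then
evaluated by Fisher odds ratios over sequential rank intervals, or by
AUROC / downsampled AUPRC for receptor specificity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModalityCalls",
    "build_pseudobulk",
    "mlm_activities",
    "cluster_activities",
    "call_active_cytokines",
    "colocalization_from_proportions",
    "colocalization_from_zscores",
    "odds_ratio_curve",
    "receptor_specificity_eval",
    "clr_transform",
]

Z_THRESHOLD = 1.645  # one-sided 95th normal percentile

DEFAULT_CUTOFFS = (100, 250, 500, 1000, 2500, 5000, 10000)


@dataclass(frozen=True)
class ModalityCalls:
    """Binary positive/negative calls over a key universe."""

    positives: frozenset
    negatives: frozenset

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValueError("positive and negative call sets overlap")

    @property
    def universe(self) -> frozenset:
        return self.positives | self.negatives


# ---------------------------------------------------------------------------
# Cytokine activities
# ---------------------------------------------------------------------------

def build_pseudobulk(dataset, min_prop: float = 0.10, min_sum: int = 5) -> pd.DataFrame:
    """Per-cluster log2(1 + summed counts) profiles with expression filters.

    A gene enters a cluster's profile only when it is expressed in at least
    ``min_prop`` of the cluster's cells *and* its summed raw count is
    strictly above ``min_sum``; entries failing either filter are NaN.
    """
    clusters = dataset.cluster_labels
    out = pd.DataFrame(np.nan, index=pd.Index(dataset.gene_ids, name="gene"), columns=clusters)
    for c in clusters:
        cells = dataset.cells_of(c)
        if cells.size == 0:
            raise ValueError(f"cluster {c!r} has no cells")
        sub = dataset.counts[:, cells]
        sums = sub.sum(axis=1)
        prop = (sub > 0).mean(axis=1)
        keep = (prop >= min_prop) & (sums > min_sum)
        vals = np.log2(1.0 + sums.astype(float))
        out.loc[keep, c] = vals[keep]
    return out


def mlm_activities(profile: pd.Series, signatures: pd.DataFrame,
                   min_genes: int = 5) -> pd.DataFrame:
    """Multivariate linear model of one expression profile on all signatures.

    The profile (genes, NaN = filtered out) is regressed jointly on every
    signature column with an intercept; the activity score is the
    coefficient t-value, with two-sided p-values corrected per profile by
    Benjamini-Hochberg.
    """
    if signatures.shape[1] < 2:
        raise ValueError("need at least two signature columns")
    y = profile.dropna()
    genes = y.index.intersection(signatures.index)
    if len(genes) < min_genes:
        raise ValueError(
            f"only {len(genes)} genes shared between profile and signatures "
            f"(need >= {min_genes})"
        )
    X = signatures.loc[genes]
    design = sm.add_constant(X.to_numpy())
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = []
        for j, col in enumerate(X.columns):
            rest = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                collinear.append(col)
        raise ValueError(f"signature design is rank-deficient; collinear: {collinear}")
    model = sm.OLS(y.loc[genes].to_numpy(), design).fit()
    t = model.tvalues[1:]
    p = model.pvalues[1:]
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"cytokine": signatures.columns, "t": t, "p": p, "fdr": fdr}
    )


def cluster_activities(pseudobulk: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    """mlm activities for every cluster column of a pseudobulk matrix."""
    frames = []
    for c in pseudobulk.columns:
        df = mlm_activities(pseudobulk[c], signatures)
        df.insert(0, "cluster", c)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def call_active_cytokines(activities: pd.DataFrame, fdr_threshold: float = 0.05) -> ModalityCalls:
    """Positive (cytokine, cluster) pairs: positive score and FDR <= 0.05."""
    pos = {
        (row.cytokine, row.cluster)
        for row in activities.itertuples()
        if row.t > 0 and row.fdr <= fdr_threshold
    }
    universe = {(row.cytokine, row.cluster) for row in activities.itertuples()}
    return ModalityCalls(frozenset(pos), frozenset(universe - pos))


# ---------------------------------------------------------------------------
# Spatial colocalization
# ---------------------------------------------------------------------------

def colocalization_from_proportions(
    proportions: pd.DataFrame, z_threshold: float = Z_THRESHOLD
) -> ModalityCalls:
    """Colocalized cluster pairs from per-spot cell-type proportions.

    Pearson correlations between cluster proportion vectors across spots are
    z-scaled over the off-diagonal coefficient distribution; an unordered
    pair is positive when its z-score reaches the threshold.
    """
    if len(proportions) < 10:
        raise ValueError("need at least 10 spots")
    row_sums = proportions.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=0.05):
        warnings.warn("spot proportions do not sum to 1; interpreting as given")
    const = [c for c in proportions.columns if proportions[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant proportion columns (called negative): {const}")
    corr = proportions.corr()
    clusters = list(proportions.columns)
    pairs = list(itertools.combinations(clusters, 2))
    vals = np.array([corr.loc[a, b] for a, b in pairs], dtype=float)
    finite = np.isfinite(vals)
    mean = vals[finite].mean()
    sd = vals[finite].std(ddof=1)
    z = np.where(finite & (sd > 0), (vals - mean) / (sd if sd > 0 else 1.0), -np.inf)
    pos = {tuple(sorted(p)) for p, zz in zip(pairs, z) if zz >= z_threshold}
    universe = {tuple(sorted(p)) for p in pairs}
    return ModalityCalls(frozenset(pos), frozenset(universe - pos))


def colocalization_from_zscores(
    zmatrix: pd.DataFrame, z_threshold: float = Z_THRESHOLD
) -> ModalityCalls:
    """Colocalization calls from a neighborhood-enrichment z-score matrix.

    An unordered pair is positive when either orientation reaches the
    threshold; the matrix must be square over clusters.
    """
    if zmatrix.shape[0] != zmatrix.shape[1] or list(zmatrix.index) != list(zmatrix.columns):
        raise ValueError("z-score matrix must be square with matching labels")
    clusters = list(zmatrix.index)
    pos, universe = set(), set()
    for a, b in itertools.combinations(clusters, 2):
        key = tuple(sorted((a, b)))
        universe.add(key)
        if max(zmatrix.loc[a, b], zmatrix.loc[b, a]) >= z_threshold:
            pos.add(key)
    return ModalityCalls(frozenset(pos), frozenset(universe - pos))


# ---------------------------------------------------------------------------
# Rank-interval odds ratios
# ---------------------------------------------------------------------------

def fisher_or(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Odds ratio (Haldane-corrected on zero cells) and two-sided Fisher p."""
    table = np.array([[a, b], [c, d]])
    degenerate = table.min() == 0
    if degenerate:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    p = fisher_exact(table, alternative="two-sided")[1]
    return float(odds), float(p), bool(degenerate)


def odds_ratio_curve(
    ranking: pd.DataFrame,
    calls: ModalityCalls,
    key_of_interaction: Callable[[pd.Series], object],
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Fisher odds ratios of positive calls among top-N predictions.

    The ranking (with a ``rank`` column) is first restricted to predictions
    whose key maps into the calls' universe; at each cutoff N a 2x2 table of
    (within top-N vs below) x (positive vs negative call) yields an odds
    ratio (Haldane-corrected when any cell is zero) and a two-sided exact
    p-value.
    """
    cutoffs = sorted(set(int(c) for c in cutoffs))
    keys = ranking.apply(key_of_interaction, axis=1)
    in_universe = keys.isin(calls.universe)
    df = ranking[in_universe].copy()
    if df.empty:
        raise ValueError("no predictions map into the calls' universe")
    df["_key"] = keys[in_universe]
    df = df.sort_values("rank").reset_index(drop=True)
    positive = df["_key"].isin(calls.positives).to_numpy()
    n = len(df)
    rows = []
    for N in cutoffs:
        top = np.zeros(n, dtype=bool)
        top[: min(N, n)] = True
        a = int((top & positive).sum())
        b = int((top & ~positive).sum())
        c = int((~top & positive).sum())
        d = int((~top & ~positive).sum())
        odds, p, degenerate = fisher_or(a, b, c, d)
        rows.append(
            {
                "cutoff": N,
                "odds_ratio": odds,
                "fisher_p": p,
                "n_top": int(top.sum()),
                "n_top_positive": a,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Receptor protein specificity
# ---------------------------------------------------------------------------

def clr_transform(abundance: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform per profile (column): ln(x+1) - mean."""
    logged = np.log1p(abundance)
    return logged - logged.mean(axis=0)


def receptor_specificity_eval(
    predictions: pd.DataFrame,
    abundance: pd.DataFrame,
    score_column: str = "score_specificity",
    z_threshold: float = Z_THRESHOLD,
    n_draws: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """AUROC and mean downsampled AUPRC for receptor-specificity calls.

    Positives are (receptor, cluster) pairs whose protein abundance z-score
    across clusters reaches the threshold.  Every universe key gets the
    maximum prediction score among matching predictions (receptor_complex,
    target); unpredicted keys score below every prediction.  The AUPRC
    averages 100 seeded draws with the negative class downsampled to the
    number of positives, binding the random expectation to 0.5.
    """
    vals = abundance.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mean) / sd, 0.0)
    keys, labels = [], []
    for i, rec in enumerate(abundance.index):
        for j, c in enumerate(abundance.columns):
            keys.append((rec, c))
            labels.append(z[i, j] >= z_threshold)
    labels = np.array(labels)
    if labels.sum() < 2:
        raise ValueError("fewer than 2 positive receptor-cluster pairs")

    scores_by_key = (
        predictions.groupby(["receptor_complex", "target"])[score_column].max()
    )
    floor = float(scores_by_key.min()) - 1.0 if len(scores_by_key) else -1.0
    scores = np.array([scores_by_key.get(k, floor) for k in keys], dtype=float)

    auroc = float(roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    n_pos = len(pos_idx)
    auprcs = []
    for _ in range(n_draws):
        draw = rng.choice(neg_idx, size=min(n_pos, len(neg_idx)), replace=False)
        sel = np.concatenate([pos_idx, draw])
        auprcs.append(average_precision_score(labels[sel], scores[sel]))
    return auroc, float(np.mean(auprcs))
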