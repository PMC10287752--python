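"""Gene-set activity scoring for single-nucleus expression data.

Within one cell cluster, marker genes are selected by a per-gene Wilcoxon
rank-sum test between two conditions (p <= 0.05, up to 15 genes per
direction, ranked by ascending p).  Each marker's expression is min-max
rescaled across the scored cells to [0, 1]; a cell's activity score is
the mean of its rescaled values over the gene set.  Scanning a threshold
over [0, 1] yields per-condition "percent of cells above threshold"
curves; the critical threshold is the first grid value at which the
condition with downregulated activity drops below 50% active cells.
Pairwise distances between cells in the plane of the first two principal
components summarize how far each condition sits from a reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .exceptions import ParameterError

logger = logging.getLogger("editaudit")


@dataclass
class CellMatrix:
    """Genes x cells expression with per-cell condition and cluster labels.

    Expression is assumed log-normalized upstream; values must be
    non-negative and identifiers unique.
    """

    expression: pd.DataFrame  # genes x cells
    condition: pd.Series  # per cell
    cluster: pd.Series  # per cell

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates or self.expression.columns.has_duplicates:
            raise ValueError("duplicate gene or cell identifiers")
        cells = self.expression.columns
        self.condition = self.condition.reindex(cells)
        self.cluster = self.cluster.reindex(cells)
        if self.condition.isna().any() or self.cluster.isna().any():
            raise ValueError("every cell needs exactly one condition and cluster")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @classmethod
    def from_frames(cls, expression: pd.DataFrame, metadata: pd.DataFrame) -> "CellMatrix":
        return cls(expression, metadata["condition"], metadata["cluster"])

    def subset_cluster(self, cluster: str) -> "CellMatrix":
        cells = self.cluster.index[self.cluster == cluster]
        return CellMatrix(self.expression[cells], self.condition[cells],
                         self.cluster[cells])


def select_markers(
    matrix: CellMatrix,
    cluster: str,
    condition_a: str,
    condition_b: str,
    p_max: float = 0.05,
    top_k: int = 15,
) -> tuple[list[str], list[str]]:
    """Up- and downregulated marker genes of ``condition_a`` vs ``condition_b``.

    Per gene, a two-sided Wilcoxon rank-sum test between the two
    conditions within the cluster; genes with p <= p_max are split by the
    sign of the mean difference (a - b) and the top ``top_k`` per
    direction are kept, ranked by ascending p with |mean difference| as
    the tie-break.
    """
    sub = matrix.subset_cluster(cluster)
    in_a = sub.condition == condition_a
    in_b = sub.condition == condition_b
    if not in_a.any() or not in_b.any():
        logger.warning("cluster %r lacks condition %r or %r; skipped",
                       cluster, condition_a, condition_b)
        return [], []
    xa = sub.expression.loc[:, in_a.to_numpy()].to_numpy()
    xb = sub.expression.loc[:, in_b.to_numpy()].to_numpy()
    res = stats.ranksums(xa, xb, axis=1)
    pvals = np.asarray(res.pvalue)
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    genes = sub.expression.index.to_numpy()
    table = pd.DataFrame({"gene": genes, "p": pvals, "diff": diff})
    sig = table[table["p"] <= p_max]
    up = (sig[sig["diff"] > 0]
          .sort_values(["p", "diff"], ascending=[True, False],
                       key=lambda s: s.abs() if s.name == "diff" else s)
          .head(top_k)["gene"].tolist())
    down = (sig[sig["diff"] < 0]
            .sort_values(["p", "diff"], ascending=[True, False],
                         key=lambda s: s.abs() if s.name == "diff" else s)
            .head(top_k)["gene"].tolist())
    logger.info("select_markers(%s): %d up, %d down (of %d tested)",
                cluster, len(up), len(down), len(genes))
    return up, down


def score_cells(matrix: CellMatrix, gene_set: list[str]) -> pd.Series:
    """Per-cell activity score: mean of min-max rescaled expression.

    Each gene is rescaled to [0, 1] across the scored cells (1 = maximum
    activation, 0 = minimum/non-expression); the score averages the
    rescaled values over the set.  Constant genes are dropped with a
    warning; an all-constant set is an error.
    """
    missing = [g for g in gene_set if g not in matrix.expression.index]
    if missing:
        raise ParameterError(f"genes not in matrix: {missing[:5]}")
    expr = matrix.expression.loc[gene_set]
    lo = expr.min(axis=1)
    hi = expr.max(axis=1)
    constant = hi == lo
    if constant.all():
        raise ParameterError("all genes in the set are constant across cells")
    if constant.any():
        logger.warning("dropping %d constant genes from the set",
                       int(constant.sum()))
        expr = expr[~constant]
        lo, hi = lo[~constant], hi[~constant]
    rescaled = expr.sub(lo, axis=0).div(hi - lo, axis=0)
    return rescaled.mean(axis=0)


@dataclass
class ActivityResult:
    """Threshold-scan curves and the critical threshold for one gene set."""

    scores: pd.Series
    condition: pd.Series
    threshold_grid: np.ndarray
    percent_above: pd.DataFrame  # conditions x grid
    critical_threshold: float | None = None
    percent_at_critical: dict[str, float] | None = None


def threshold_scan(
    scores: pd.Series, condition: pd.Series, grid_step: float = 0.01
) -> ActivityResult:
    """Percent of cells per condition with score strictly above each threshold."""
    condition = condition.reindex(scores.index)
    conditions = sorted(condition.unique())
    if len(conditions) < 2:
        raise ParameterError("need at least two conditions")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    rows = {}
    for cond in conditions:
        vals = scores[condition == cond].to_numpy()
        rows[cond] = [(vals > t).mean() * 100.0 for t in grid]
    percent = pd.DataFrame(rows, index=grid).T
    return ActivityResult(scores=scores, condition=condition,
                          threshold_grid=grid, percent_above=percent)


def critical_threshold(
    result: ActivityResult, downregulated_condition: str | None = None
) -> ActivityResult:
    """First grid threshold where the downregulated condition drops below 50%.

    The downregulated condition defaults to the one with the lowest mean
    score.  The per-condition percentages at that threshold are recorded;
    if the curve never drops below 50% the threshold is left unset with a
    warning.
    """
    if downregulated_condition is None:
        means = result.scores.groupby(result.condition).mean()
        downregulated_condition = means.idxmin()
    curve = result.percent_above.loc[downregulated_condition].to_numpy()
    below = np.nonzero(curve < 50.0)[0]
    if below.size == 0:
        logger.warning("condition %r never drops below 50%% active cells",
                       downregulated_condition)
        result.critical_threshold = None
        result.percent_at_critical = None
        return result
    t = float(result.threshold_grid[below[0]])
    result.critical_threshold = t
    result.percent_at_critical = {
        cond: float(result.percent_above.loc[cond].iloc[below[0]])
        for cond in result.percent_above.index
    }
    return result


def pc_pairwise_distances(
    matrix: CellMatrix,
    reference_condition: str,
    n_components: int = 2,
    all_pairs: bool = False,
) -> dict[str, np.ndarray]:
    """Euclidean distances to reference cells in the first-two-PC plane.

    Principal components are computed on the pooled (all-condition)
    expression by eigendecomposition of the cell-cell covariance of
    centered expression; component signs are fixed so the
    largest-magnitude loading is positive.  By default each non-reference
    cell is paired with every reference cell; ``all_pairs`` pools every
    within-set pair instead.
    """
    x = matrix.expression.to_numpy().T  # cells x genes
    n_cells = x.shape[0]
    if n_cells < n_components:
        raise ParameterError("fewer cells than components")
    xc = x - x.mean(axis=0, keepdims=True)
    cov = np.cov(xc, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    idx = np.argsort(evals)[::-1][:n_components]
    comps = evecs[:, idx]
    for k in range(comps.shape[1]):
        j = np.argmax(np.abs(comps[:, k]))
        if comps[j, k] < 0:
            comps[:, k] = -comps[:, k]
    proj = xc @ comps  # cells x n_components
    cond = matrix.condition.to_numpy()
    ref = proj[cond == reference_condition]
    out: dict[str, np.ndarray] = {}
    for c in sorted(set(cond)):
        sel = proj[cond == c]
        if all_pairs or c == reference_condition:
            d = cdist(sel, ref)
            if c == reference_condition:
                d = d[np.triu_indices_from(d, k=1)]
            else:
                d = d.ravel()
        else:
            d = cdist(sel, ref).ravel()
        out[c] = np.sort(d)
    return out


__all__ = [
    "CellMatrix", "ActivityResult",
    "select_markers", "score_cells", "threshold_scan", "critical_threshold",
    "pc_pairwise_distances",
]
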