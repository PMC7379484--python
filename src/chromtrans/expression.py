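"""Expression integration: DEG filtering, tissue-preferential calls,
multi-mark k-means clustering, and mark x expression overlap tables.

Two-condition differential expression uses the bare fold-change filter
(ratio > 2 with a pseudocount so the rule is defined at zero).  Preferential
expression on a multi-tissue panel (emulating a 45-array, 13-tissue
compendium) quantile-normalizes the samples, then scores each gene with
Z = (mean_target - mean_others) / sd_others and an upper-tail normal p-value
at the 0.05 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import KMeans

from .marks import DifferentialMarkResult
from .metagene import HeatmapMatrix

__all__ = [
    "call_deg",
    "quantile_normalize",
    "preferential_expression",
    "ClusterAssignment",
    "cluster_by_marks",
    "integrate_marks_expression",
]


def call_deg(
    expr_a: pd.Series,
    expr_b: pd.Series,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Differentially expressed genes by strict fold-change (> fold).

    Returns (A-higher, B-higher) gene sets; a gene is A-higher iff
    (expr_A + c) / (expr_B + c) > fold.  The sets are disjoint for fold > 1.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    expr_b = expr_b.reindex(expr_a.index)
    if expr_a.min() < 0 or expr_b.min() < 0:
        raise ValueError("negative expression values")
    ratio = (expr_a + pseudocount) / (expr_b + pseudocount)
    return set(expr_a.index[ratio > fold]), set(expr_a.index[ratio < 1.0 / fold])


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common mean quantile profile.

    The standard array-panel normalization: rank each column, replace each
    value by the cross-sample mean of its rank's sorted values (ties get the
    mean of the tied quantiles via average ranks).
    """
    ranks = matrix.rank(method="average")
    sorted_means = np.sort(matrix.values, axis=0).mean(axis=1)
    grid = np.arange(1, len(matrix) + 1, dtype=float)
    out = {
        col: np.interp(ranks[col].values, grid, sorted_means)
        for col in matrix.columns
    }
    return pd.DataFrame(out, index=matrix.index)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shift every sample so all medians equal the panel-wide mean median."""
    med = matrix.median(axis=0)
    return matrix - med + med.mean()


def preferential_expression(
    matrix: pd.DataFrame,
    sample_tissue: pd.Series,
    target: str,
    p_cutoff: float = 0.05,
    normalize: str | bool = "median",
    robust: bool = False,
) -> pd.DataFrame:
    """Call genes preferentially expressed in the target tissue.

    ``matrix`` is gene x sample; ``sample_tissue`` maps sample -> tissue.
    ``normalize`` brings the samples onto a common level first: ``"median"``
    (default) shifts each sample to the common median and is robust to a
    large fraction of genuinely tissue-specific genes; ``"quantile"`` forces
    identical distributions and is stricter but suppresses real signal when
    many genes change in one tissue; ``False`` (off) is for testing.
    After normalization, each gene gets
    Z = (mean over target samples - mean over other samples) / sd of other
    samples (ddof=1; median/MAD with ``robust=True``), and the upper-tail
    standard-normal p.  A gene is preferential iff Z > 0 and p < p_cutoff.
    Genes whose non-target samples are constant (sd 0) are flagged
    ``degenerate`` and called preferential iff the target mean exceeds that
    constant, with the smallest positive float standing in for p.
    """
    sample_tissue = sample_tissue.reindex(matrix.columns)
    if sample_tissue.isna().any():
        raise ValueError("every sample needs a tissue label")
    target_cols = list(matrix.columns[sample_tissue == target])
    other_cols = list(matrix.columns[sample_tissue != target])
    if not target_cols:
        raise ValueError(f"no samples for target tissue {target!r}")
    if len(other_cols) < 3:
        raise ValueError("need at least 3 non-target samples")
    if (matrix.values < 0).any():
        raise ValueError("negative expression values")
    if normalize == "median":
        matrix = median_center(matrix)
    elif normalize == "quantile" or normalize is True:
        matrix = quantile_normalize(matrix)
    elif normalize not in (False, None, "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    t = matrix[target_cols].mean(axis=1)
    if robust:
        center = matrix[other_cols].median(axis=1)
        # 1.4826 * MAD estimates the normal sd
        spread = 1.4826 * (
            (matrix[other_cols].sub(center, axis=0)).abs().median(axis=1)
        )
    else:
        center = matrix[other_cols].mean(axis=1)
        spread = matrix[other_cols].std(axis=1, ddof=1)
    degenerate = spread == 0
    z = (t - center) / spread.where(~degenerate, np.nan)
    p = pd.Series(norm.sf(z.values), index=matrix.index)
    tiny = np.nextafter(0, 1)
    z = z.where(~degenerate, np.sign(t - center) * np.inf)
    p = p.where(~degenerate, pd.Series(np.where(t > center, tiny, 1.0), index=matrix.index))
    flag = (z > 0) & (p < p_cutoff)
    return pd.DataFrame(
        {"z": z, "p": p, "preferential": flag, "degenerate": degenerate}
    )


@dataclass
class ClusterAssignment:
    """k-means result: 1-based cluster index per gene plus centroids."""

    labels: pd.Series
    centroids: np.ndarray
    inertia: float

    @property
    def k(self) -> int:
        return len(self.centroids)

    def to_tsv(self, path) -> None:
        self.labels.rename("cluster").to_csv(path, sep="\t", index_label="gene_id")


def cluster_by_marks(
    matrices: list[HeatmapMatrix | pd.DataFrame],
    k: int,
    seed: int,
    n_restarts: int = 10,
    log_transform: bool = True,
) -> ClusterAssignment:
    """k-means over concatenated per-mark TSS-bin features.

    Bins are log1p-transformed by default (ChIP-style signal is heavy-tailed;
    the log keeps presence/absence patterns from being drowned by amplitude
    spread), then each matrix's bins are standardized to zero mean / unit
    variance (constant bins become zeros) before concatenation so no single
    mark's amplitude dominates.  Deterministic given ``seed``.
    """
    frames = [m.values if isinstance(m, HeatmapMatrix) else m for m in matrices]
    if not frames:
        raise ValueError("no matrices given")
    index = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(index):
            raise ValueError("matrices must share the same gene set and order")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(index):
        raise ValueError(f"k={k} exceeds the {len(index)} genes")
    blocks = []
    for f in frames:
        x = f.values.astype(float)
        if log_transform:
            x = np.log1p(x)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        blocks.append((x - mu) / sd)
    features = np.hstack(blocks)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    fit = km.fit(features)
    return ClusterAssignment(
        labels=pd.Series(fit.labels_ + 1, index=index, name="cluster"),
        centroids=fit.cluster_centers_,
        inertia=float(fit.inertia_),
    )


def integrate_marks_expression(
    mark_result: DifferentialMarkResult,
    deg_a: set[str],
    deg_b: set[str],
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Cross-tabulate differential mark deposition against DEG direction.

    Returns the 2x2 overlap counts (mark-preferential tissue x
    expression-higher tissue) and the gene lists behind each cell.  With a
    repressive mark the anti-diagonal cells (mark up in one tissue, expression
    up in the other) are the biologically expected majority.
    """
    a, b = mark_result.tissue_a, mark_result.tissue_b
    cells = {
        (a, a): mark_result.a_preferential & deg_a,
        (a, b): mark_result.a_preferential & deg_b,
        (b, a): mark_result.b_preferential & deg_a,
        (b, b): mark_result.b_preferential & deg_b,
    }
    counts = pd.DataFrame(
        [[len(cells[(a, a)]), len(cells[(a, b)])], [len(cells[(b, a)]), len(cells[(b, b)])]],
        index=pd.Index([a, b], name=f"{mark_result.mark}_preferential"),
        columns=pd.Index([a, b], name="expression_higher"),
    )
    lists = {f"mark_{ma}__expr_{ex}": genes for (ma, ex), genes in cells.items()}
    return counts, lists
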