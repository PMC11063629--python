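"""Expression pipeline: TMM normalization, genome binning, Z-scoring,
median smoothing, winsorization, cell-cycle scoring, PCA and community
detection on a KNN cell graph.

The stage order is fixed: normalize -> bin -> Z -> smooth -> winsorize.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, rand_score
from sklearn.neighbors import NearestNeighbors

from tumorevo.core import BinnedExpression, CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.4, 1.61, 0.2), 2))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def tmm_factor(
    cell: np.ndarray,
    reference: np.ndarray,
    *,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """Trimmed-mean-of-M scale factor mapping ``cell`` onto ``reference``.

    M = log2(cell/ref) over genes expressed in both; the top and bottom
    ``trim_m`` of M values and ``trim_a`` of A values are discarded and the
    remaining M values averaged with inverse-variance weights (delta-method
    1/cell + 1/ref).  Returns 2**(-trimmed mean), i.e. the multiplier that
    rescales the cell to the reference.
    """
    both = (cell > 0) & (reference > 0)
    y, r = cell[both].astype(float), reference[both].astype(float)
    m = np.log2(y) - np.log2(r)
    a = 0.5 * (np.log2(y) + np.log2(r))
    lo_m, hi_m = np.quantile(m, [trim_m, 1.0 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1.0 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        keep = np.ones_like(m, dtype=bool)
    w = 1.0 / (1.0 / y[keep] + 1.0 / r[keep])
    mean_m = float(np.sum(w * m[keep]) / np.sum(w))
    return float(2.0**-mean_m)


def normalize_to_reference(
    counts: CountMatrix,
    reference: str | np.ndarray | None = None,
    *,
    min_shared_genes: int = 50,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> CountMatrix:
    """Rescale every cell by a TMM factor against a reference expression.

    ``reference`` is a cell id, an explicit per-gene vector, or None for
    the per-gene mean pseudo-cell.  Cells sharing fewer than
    ``min_shared_genes`` expressed genes with the reference are dropped
    with a warning.
    """
    if reference is None:
        ref = counts.counts.mean(axis=1)
    elif isinstance(reference, str):
        ref = counts.counts[:, counts.cell_ids.index(reference)].astype(float)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (counts.n_genes,):
            raise ValueError("reference vector length must match gene count")
    if (ref > 0).sum() < min_shared_genes:
        raise ValueError(
            f"reference expresses fewer than {min_shared_genes} genes"
        )
    keep_cols, out = [], []
    for j, cell_id in enumerate(counts.cell_ids):
        col = counts.counts[:, j].astype(float)
        shared = int(((col > 0) & (ref > 0)).sum())
        if shared < min_shared_genes:
            logger.warning(
                "dropping cell %s: only %d genes shared with reference (< %d)",
                cell_id, shared, min_shared_genes,
            )
            continue
        out.append(col * tmm_factor(col, ref, trim_m=trim_m, trim_a=trim_a))
        keep_cols.append(j)
    if not out:
        raise ValueError("no cells survived normalization")
    return CountMatrix(
        np.column_stack(out),
        counts.genes.reset_index(drop=True),
        [counts.cell_ids[j] for j in keep_cols],
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_genes(
    matrix: CountMatrix, min_mean_expression: float = 1.0
) -> BinnedExpression:
    """Merge consecutive same-chromosome genes into expression bins.

    Greedy left-to-right: genes accumulate until the summed per-gene mean
    (across cells) reaches ``min_mean_expression``, closing the bin.  An
    under-threshold remnant at a chromosome end merges into the previous
    bin on that chromosome, or stands alone if the chromosome has none.
    """
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValueError("empty matrix")
    if not matrix.is_position_sorted():
        raise ValueError("genes must be sorted by genome position")
    gene_means = matrix.counts.mean(axis=1)
    chroms = matrix.genes["chrom"].to_numpy()
    bins: list[dict] = []
    i = 0
    while i < matrix.n_genes:
        chrom = chroms[i]
        chrom_first_bin = len(bins)
        j = i
        while j < matrix.n_genes and chroms[j] == chrom:
            acc = 0.0
            first = j
            while j < matrix.n_genes and chroms[j] == chrom:
                acc += gene_means[j]
                j += 1
                if acc >= min_mean_expression:
                    break
            if acc < min_mean_expression and len(bins) > chrom_first_bin:
                bins[-1]["last_gene"] = j - 1  # trailing remnant merges left
            else:
                bins.append({"chrom": chrom, "first_gene": first, "last_gene": j - 1})
        i = j
    for b in bins:
        b["start"] = int(matrix.genes["start"].iloc[b["first_gene"]])
        end_col = "end" if "end" in matrix.genes.columns else "start"
        b["end"] = int(matrix.genes[end_col].iloc[b["last_gene"]])
    bin_df = pd.DataFrame(bins)
    values = np.vstack(
        [
            matrix.counts[b["first_gene"] : b["last_gene"] + 1, :].sum(axis=0)
            for b in bins
        ]
    )
    return BinnedExpression(values, bin_df, list(matrix.cell_ids))


# ---------------------------------------------------------------------------
# Z-score, smoothing, winsorization
# ---------------------------------------------------------------------------


def zscore_bins(
    binned: BinnedExpression,
    *,
    baseline_mean: np.ndarray | None = None,
    baseline_sd: np.ndarray | None = None,
) -> BinnedExpression:
    """Standardize each bin across cells (sample sd, n-1).

    Zero-variance bins map to Z = 0.  A baseline mean/sd (e.g. from normal
    cells) may be supplied instead of the cross-cell statistics.
    """
    if baseline_mean is None:
        if binned.n_cells < 2:
            raise ValueError("need at least 2 cells for Z-scores")
        baseline_mean = binned.values.mean(axis=1)
        baseline_sd = binned.values.std(axis=1, ddof=1)
    baseline_mean = np.asarray(baseline_mean, dtype=float)
    baseline_sd = np.asarray(baseline_sd, dtype=float)
    sd = np.where((baseline_sd > 0) & np.isfinite(baseline_sd), baseline_sd, np.inf)
    z = (binned.values - baseline_mean[:, None]) / sd[:, None]
    return BinnedExpression(z, binned.bins.copy(), list(binned.cell_ids))


def rolling_median_smooth(z: BinnedExpression, window: int = 5) -> BinnedExpression:
    """Replace each bin by the median over a centered window on its chromosome.

    The window shrinks at chromosome edges (no padding); a window of 1 is
    the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    out = np.empty_like(z.values)
    for _, idx in z.chrom_blocks():
        block = z.values[idx, :]
        n = len(idx)
        for k in range(n):
            lo, hi = max(0, k - half), min(n, k + half + 1)
            out[idx[k], :] = np.median(block[lo:hi, :], axis=0)
    return BinnedExpression(out, z.bins.copy(), list(z.cell_ids))


def winsorize(
    z: BinnedExpression, lo: float = -3.0, hi: float = 3.0
) -> BinnedExpression:
    """Clip values into [lo, hi]; idempotent."""
    if lo >= hi:
        raise ValueError("lo must be smaller than hi")
    return BinnedExpression(
        np.clip(z.values, lo, hi), z.bins.copy(), list(z.cell_ids)
    )


def prepare_smoothed_z(
    counts: CountMatrix,
    *,
    reference=None,
    min_mean_expression: float = 1.0,
    window: int = 5,
    winsorize_bound: float = 3.0,
    baseline_mean=None,
    baseline_sd=None,
) -> tuple[BinnedExpression, CountMatrix]:
    """normalize -> bin -> Z -> smooth -> winsorize; returns (Z, normalized)."""
    normalized = normalize_to_reference(counts.sorted_by_position(), reference)
    binned = bin_genes(normalized, min_mean_expression)
    z = zscore_bins(binned, baseline_mean=baseline_mean, baseline_sd=baseline_sd)
    z = rolling_median_smooth(z, window)
    return winsorize(z, -winsorize_bound, winsorize_bound), normalized


# ---------------------------------------------------------------------------
# cell-cycle scoring
# ---------------------------------------------------------------------------


def score_cell_cycle(
    matrix: CountMatrix,
    g1s_genes: list[str],
    g2m_genes: list[str],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Phase calls from standardized marker-set scores.

    Per-cell score of a set = mean over its genes of the cross-cell
    standardized expression.  A cell cycles iff max(G1S, G2M) > threshold;
    phase is G1 when not cycling, S when G1S >= G2M, else G2M.
    """
    gene_index = {g: i for i, g in enumerate(matrix.genes["gene_id"])}
    idx_g1s = [gene_index[g] for g in g1s_genes if g in gene_index]
    idx_g2m = [gene_index[g] for g in g2m_genes if g in gene_index]
    if not idx_g1s or not idx_g2m:
        raise ValueError("a cell-cycle gene set has no genes in the matrix")
    x = matrix.counts.astype(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        zx = np.where(sd > 0, (x - mean) / sd, 0.0)
    score_g1s = zx[idx_g1s, :].mean(axis=0)
    score_g2m = zx[idx_g2m, :].mean(axis=0)
    cycling = np.maximum(score_g1s, score_g2m) > threshold
    phase = np.where(cycling, np.where(score_g1s >= score_g2m, "S", "G2M"), "G1")
    return pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "score_g1s": score_g1s,
            "score_g2m": score_g2m,
            "cycling": cycling,
            "phase": phase,
        }
    )


# ---------------------------------------------------------------------------
# PCA and KNN graph
# ---------------------------------------------------------------------------


@dataclass
class CellEmbedding:
    scores: np.ndarray  # cells x components
    cycling: np.ndarray  # bool per cell
    n_components: int
    cell_ids: list[str]


def pca_project(
    z: BinnedExpression,
    cycling: np.ndarray,
    n_components: int = 20,
) -> CellEmbedding:
    """Fit PCA on non-cycling cells (bins as features) and project all cells."""
    cycling = np.asarray(cycling, dtype=bool)
    n_noncycling = int((~cycling).sum())
    if n_noncycling < n_components:
        raise ValueError(
            f"need >= {n_components} non-cycling cells, have {n_noncycling}"
        )
    k = min(n_components, z.n_bins)
    x = z.values.T  # cells x bins
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(x[~cycling, :])
    scores = pca.transform(x)
    return CellEmbedding(scores, cycling, k, list(z.cell_ids))


def build_knn_graph(embedding: CellEmbedding, k: int | None = None) -> nx.Graph:
    """Union-symmetrized KNN graph in PC space, edge weight 1/(1 + D)."""
    n = embedding.scores.shape[0]
    if k is None:
        k = min(100, n // 3)
    if k <= 0:
        raise ValueError("K must be positive")
    if k >= n:
        raise ValueError("K must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.scores)
    dist, idx = nn.kneighbors(embedding.scores)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            graph.add_edge(i, int(j), weight=1.0 / (1.0 + float(d)))
    return graph


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------


@dataclass
class CommunityPartition:
    labels: np.ndarray  # community id per cell, contiguous from 1
    gamma: float
    stats: pd.DataFrame  # gamma, mean_rand, var_rand

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())


def _to_igraph(graph: nx.Graph):
    import igraph as ig

    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    h = ig.Graph(n=len(nodes), edges=edges)
    h.es["weight"] = [graph.edges[u, v].get("weight", 1.0) for u, v in graph.edges()]
    return h


def _louvain_labels(graph, gamma: float, seed: int) -> np.ndarray:
    """One seeded Louvain run; community ids contiguous from 1.

    Ids are assigned by each community's smallest member so relabeling is
    deterministic.  ``graph`` may be a networkx graph or a pre-converted
    igraph graph.
    """
    import random as _random

    import igraph as ig

    h = _to_igraph(graph) if isinstance(graph, nx.Graph) else graph
    ig.set_random_number_generator(_random.Random(int(seed)))
    membership = np.asarray(
        h.community_multilevel(weights="weight", resolution=float(gamma)).membership
    )
    labels = np.empty(len(membership), dtype=int)
    order = sorted(
        np.unique(membership), key=lambda c: int(np.flatnonzero(membership == c)[0])
    )
    for cid, c in enumerate(order, start=1):
        labels[membership == c] = cid
    return labels


def detect_communities(
    graph: nx.Graph,
    gamma_grid=DEFAULT_GAMMA_GRID,
    n_runs: int = 10,
    seed=None,
    *,
    adjusted: bool = False,
) -> CommunityPartition:
    """Louvain partition at the resolution with the most stable runs.

    For each gamma, Louvain runs ``n_runs`` times with distinct sub-seeds;
    the mean and variance of the pairwise Rand index across runs pick gamma
    (max mean, then min variance, then smaller gamma) and the run with the
    highest modularity at that gamma is returned.  Resolutions whose runs
    all collapse to a single community are trivially stable and carry no
    structure, so they are only eligible when every resolution collapses.
    """
    gamma_grid = list(gamma_grid)
    if not gamma_grid:
        raise ValueError("gamma_grid must not be empty")
    if n_runs < 2:
        raise ValueError("need at least 2 runs per gamma")
    score = adjusted_rand_score if adjusted else rand_score
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(len(gamma_grid), n_runs))
    h = _to_igraph(graph)
    rows, runs_per_gamma = [], []
    for gi, gamma in enumerate(gamma_grid):
        runs = [_louvain_labels(h, gamma, s) for s in sub_seeds[gi]]
        rand = [score(a, b) for a, b in itertools.combinations(runs, 2)]
        rows.append(
            {
                "gamma": float(gamma),
                "mean_rand": float(np.mean(rand)),
                "var_rand": float(np.var(rand)),
                "degenerate": all(lab.max() == 1 for lab in runs),
            }
        )
        runs_per_gamma.append(runs)
    stats = pd.DataFrame(rows)
    eligible = [i for i in range(len(gamma_grid)) if not rows[i]["degenerate"]]
    if not eligible:
        eligible = list(range(len(gamma_grid)))
    best = min(
        eligible,
        key=lambda i: (-rows[i]["mean_rand"], rows[i]["var_rand"], rows[i]["gamma"]),
    )
    best_runs = runs_per_gamma[best]
    gamma = float(gamma_grid[best])
    modularities = [
        h.modularity(list(lab - 1), weights="weight", resolution=gamma)
        for lab in best_runs
    ]
    labels = best_runs[int(np.argmax(modularities))]
    return CommunityPartition(labels=labels, gamma=gamma, stats=stats)
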