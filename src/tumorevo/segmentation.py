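"""Per-community copy-number segmentation via meta-cells and a 3-state HMM,
segment significance testing, and community x cluster enrichment.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tumorevo.core import BinnedExpression, CountMatrix
from tumorevo.cna import (
    bin_genes,
    normalize_to_reference,
    rolling_median_smooth,
    winsorize,
    zscore_bins,
)

logger = logging.getLogger(__name__)

STATE_LOSS, STATE_NEUTRAL, STATE_GAIN = -1, 0, 1
STATE_NAMES = {STATE_LOSS: "loss", STATE_NEUTRAL: "neutral", STATE_GAIN: "gain"}


# ---------------------------------------------------------------------------
# meta-cells
# ---------------------------------------------------------------------------


@dataclass
class MetaCellSet:
    """Processed Z for all meta-cells, plus membership for reproducibility.

    ``meta`` has one row per meta-cell: community (community id or
    "baseline") and members (list of cell indices).  Columns of ``z.values``
    align with ``meta`` rows.
    """

    z: BinnedExpression
    meta: pd.DataFrame

    def community_z(self, community) -> np.ndarray:
        cols = np.flatnonzero((self.meta["community"] == community).to_numpy())
        return self.z.values[:, cols]

    def communities(self) -> list:
        return [c for c in self.meta["community"].unique() if c != "baseline"]


def make_metacells(
    counts: CountMatrix,
    partition_labels: np.ndarray,
    baseline_cells: np.ndarray,
    *,
    n_meta: int = 5,
    frac: float = 0.5,
    seed=None,
    min_community_size: int = 10,
    min_mean_expression: float = 1.0,
    window: int = 5,
    winsorize_bound: float = 3.0,
) -> MetaCellSet:
    """Build meta-cells per community and reprocess them against a baseline.

    Each meta-cell sums the raw counts of ceil(frac * community size) cells
    sampled without replacement.  Baseline meta-cells are drawn the same way
    from ``baseline_cells`` (cell indices); all pseudo-cells then pass
    through normalize -> bin -> Z -> smooth -> winsorize with the Z computed
    against the baseline meta-cells' per-bin mean and standard deviation.
    Communities smaller than ``min_community_size`` are skipped with a
    warning.
    """
    partition_labels = np.asarray(partition_labels)
    baseline_cells = np.asarray(baseline_cells)
    if baseline_cells.size == 0:
        raise ValueError("baseline_cells must not be empty")
    rng = np.random.default_rng(seed)
    matrix = counts.sorted_by_position()

    pseudo_cols, meta_rows = [], []

    def add_group(tag, members: np.ndarray) -> None:
        size = max(1, math.ceil(frac * len(members)))
        for m in range(n_meta):
            chosen = rng.choice(members, size=size, replace=False)
            pseudo_cols.append(matrix.counts[:, chosen].sum(axis=1))
            meta_rows.append({"community": tag, "members": sorted(int(c) for c in chosen)})

    add_group("baseline", baseline_cells)
    for community in np.unique(partition_labels):
        if isinstance(community, (int, np.integer)) and community < 0:
            continue  # sentinel for cells outside any community
        members = np.flatnonzero(partition_labels == community)
        if len(members) < min_community_size:
            logger.warning(
                "skipping community %s: %d cells < %d",
                community, len(members), min_community_size,
            )
            continue
        add_group(community, members)

    pseudo = CountMatrix(
        np.column_stack(pseudo_cols),
        matrix.genes,
        [f"meta{m:03d}" for m in range(len(pseudo_cols))],
    )
    reference = pseudo.counts.mean(axis=1)
    normalized = normalize_to_reference(pseudo, reference)
    binned = bin_genes(normalized, min_mean_expression)
    meta = pd.DataFrame(meta_rows)

    # Baseline statistics come from the individual baseline cells, TMM-scaled
    # to the same pseudo-cell reference and summed into the same bins: a
    # meta-cell of k cells then carries ~sd_cell/sqrt(k) noise per bin, so
    # neutral bins sit well inside one baseline sd while arm-scale dosage
    # shifts stand out.
    base_cells = CountMatrix(
        matrix.counts[:, baseline_cells],
        matrix.genes,
        [f"base{c:05d}" for c in range(len(baseline_cells))],
    )
    base_norm = normalize_to_reference(base_cells, reference)
    first = binned.bins["first_gene"].to_numpy()
    last = binned.bins["last_gene"].to_numpy()
    base_binned = np.vstack(
        [base_norm.counts[f : l + 1, :].sum(axis=0) for f, l in zip(first, last)]
    )
    # Location from the baseline meta-cells (same normalization path as the
    # community meta-cells — single-cell TMM is biased by zero truncation);
    # noise scale from the baseline cells, ratio-calibrated onto the
    # meta-cell scale per bin.
    base_meta_cols = np.flatnonzero((meta["community"] == "baseline").to_numpy())
    base_meta_mean = binned.values[:, base_meta_cols].mean(axis=1)
    cell_mean = base_binned.mean(axis=1)
    cell_sd = base_binned.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(cell_mean > 0, base_meta_mean / cell_mean, 1.0)
    z = zscore_bins(
        binned,
        baseline_mean=base_meta_mean,
        baseline_sd=cell_sd * scale,
    )
    z = winsorize(rolling_median_smooth(z, window), -winsorize_bound, winsorize_bound)
    return MetaCellSet(z=z, meta=meta)


# ---------------------------------------------------------------------------
# HMM segmentation
# ---------------------------------------------------------------------------


@dataclass
class HmmParams:
    """3-state Gaussian HMM on the winsorized Z scale.

    States neutral/loss/gain have means 0, -delta, +delta and a shared
    emission sigma (estimated from the data when None); tau is the per-step
    switch probability to each other state.
    """

    delta: float = 0.5
    sigma: float | None = None
    tau: float = 1e-3


def estimate_sigma(meta_z: np.ndarray, floor: float = 0.05) -> float:
    """Robust emission sigma: MAD of all (bin, meta-cell) Z values.

    Non-neutral bins are a minority, so the median absolute deviation
    tracks the neutral noise scale while ignoring the winsorized signal
    tails; meta-cells of one community share member cells, which makes the
    naive per-bin sd across meta-cells a large underestimate of the
    meta-cell-vs-baseline comparison noise.
    """
    z = np.asarray(meta_z, dtype=float).ravel()
    sd = 1.4826 * float(np.median(np.abs(z - np.median(z))))
    return max(sd, floor)


def hmm_segment(
    meta_z: np.ndarray,
    chroms: np.ndarray,
    params: HmmParams | None = None,
) -> np.ndarray:
    """Viterbi-decode one shared loss/neutral/gain path over genome bins.

    ``meta_z`` is bins x n_meta; the emission at a bin under a state is the
    product over meta-cells of Normal(z; mu_state, sigma).  Decoding
    restarts on each chromosome with a uniform initial state.  Returns an
    int array with -1 = loss, 0 = neutral, +1 = gain.
    """
    params = params or HmmParams()
    meta_z = np.atleast_2d(np.asarray(meta_z, dtype=float))
    if meta_z.ndim != 2:
        raise ValueError("meta_z must be bins x n_meta")
    if not np.isfinite(meta_z).all():
        raise ValueError("meta_z contains non-finite values")
    chroms = np.asarray(chroms)
    if len(chroms) != meta_z.shape[0]:
        raise ValueError("chrom labels must match bin count")
    sigma = params.sigma if params.sigma is not None else estimate_sigma(meta_z)
    mus = np.array([-params.delta, 0.0, params.delta])  # loss, neutral, gain
    # bins x 3 emission log-likelihood, summed over meta-cells
    emit = stats.norm.logpdf(
        meta_z[:, :, None], loc=mus[None, None, :], scale=sigma
    ).sum(axis=1)
    log_stay = math.log1p(-2.0 * params.tau)
    log_switch = math.log(params.tau)
    trans = np.full((3, 3), log_switch)
    np.fill_diagonal(trans, log_stay)
    path = np.empty(len(chroms), dtype=int)
    start = 0
    for end in _chrom_block_ends(chroms):
        path[start:end] = _viterbi(emit[start:end], trans)
        start = end
    return path - 1  # map {0,1,2} -> {-1,0,1}


def _chrom_block_ends(chroms: np.ndarray) -> list[int]:
    ends = []
    for i in range(1, len(chroms)):
        if chroms[i] != chroms[i - 1]:
            ends.append(i)
    ends.append(len(chroms))
    return ends


def _viterbi(emit: np.ndarray, trans: np.ndarray) -> np.ndarray:
    n, k = emit.shape
    delta = emit[0] + math.log(1.0 / k)
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k)] + emit[t]
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    return states


def filter_short_segments(
    path: np.ndarray,
    chroms: np.ndarray,
    min_seg_bins: int = 5,
) -> np.ndarray:
    """Set non-neutral runs shorter than ``min_seg_bins`` to neutral.

    Runs are measured on the input path in a single left-to-right pass;
    neutral runs created by the filtering are not re-examined.
    """
    path = np.asarray(path).copy()
    chroms = np.asarray(chroms)
    i = 0
    while i < len(path):
        j = i
        while j < len(path) and path[j] == path[i] and chroms[j] == chroms[i]:
            j += 1
        if path[i] != STATE_NEUTRAL and (j - i) < min_seg_bins:
            path[i:j] = STATE_NEUTRAL
        i = j
    return path


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------


@dataclass
class CNASegment:
    chrom: str
    first_bin: int  # global bin indices, inclusive
    last_bin: int
    state: str  # loss | neutral | gain
    n_bins: int
    start_bp: int | None = None
    end_bp: int | None = None
    p_value: float | None = None
    q_value: float | None = None


@dataclass
class CommunityCNAProfile:
    community: object
    segments: list[CNASegment]
    hmm_params: HmmParams = field(default_factory=HmmParams)


def segments_from_path(
    path: np.ndarray, bins: pd.DataFrame
) -> list[CNASegment]:
    """Maximal constant-state runs per chromosome, tiling the genome."""
    chroms = bins["chrom"].to_numpy()
    segments = []
    i = 0
    while i < len(path):
        j = i
        while j < len(path) and path[j] == path[i] and chroms[j] == chroms[i]:
            j += 1
        segments.append(
            CNASegment(
                chrom=str(chroms[i]),
                first_bin=i,
                last_bin=j - 1,
                state=STATE_NAMES[int(path[i])],
                n_bins=j - i,
                start_bp=int(bins["start"].iloc[i]) if "start" in bins else None,
                end_bp=int(bins["end"].iloc[j - 1]) if "end" in bins else None,
            )
        )
        i = j
    return segments


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum segment test
# ---------------------------------------------------------------------------


def rank_sum_test(x: np.ndarray, y: np.ndarray, *, exact_max: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration of all rank assignments when the total sample
    size is <= ``exact_max`` (handles ties by averaged ranks); otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    n = nx + ny
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    if n <= exact_max:
        dev_obs = abs(w_obs - mu)
        count = total = 0
        for combo in itertools.combinations(range(n), nx):
            w = sum(ranks[list(combo)])
            total += 1
            if abs(w - mu) >= dev_obs - 1e-9:
                count += 1
        return count / total
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = max(abs(w_obs - mu) - 0.5, 0.0) / math.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def test_segment(
    meta_z: np.ndarray,
    segment: CNASegment,
    segments: list[CNASegment],
    *,
    exact_max: int = 20,
    flank_bins: int | None = None,
) -> float | None:
    """p-value of a non-neutral segment vs neutral bins on its chromosome.

    All (bin, meta-cell) Z values inside the segment are compared against
    the Z values of neutral segments on the same chromosome (optionally
    restricted to ``flank_bins`` bins on each side).  Returns None when the
    chromosome has no neutral bins.
    """
    if segment.state == "neutral":
        raise ValueError("test applies to non-neutral segments")
    meta_z = np.atleast_2d(meta_z)
    neutral_bins: list[int] = []
    for other in segments:
        if other.chrom != segment.chrom or other.state != "neutral":
            continue
        neutral_bins.extend(range(other.first_bin, other.last_bin + 1))
    if flank_bins is not None:
        lo = segment.first_bin - flank_bins
        hi = segment.last_bin + flank_bins
        neutral_bins = [b for b in neutral_bins if lo <= b <= hi]
    if not neutral_bins:
        logger.warning(
            "segment %s:%d-%d has no neutral bins on its chromosome",
            segment.chrom, segment.first_bin, segment.last_bin,
        )
        return None
    inside = meta_z[segment.first_bin : segment.last_bin + 1, :].ravel()
    outside = meta_z[neutral_bins, :].ravel()
    return rank_sum_test(inside, outside, exact_max=exact_max)


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = val
        prev = val
    return q.tolist()


def call_community_profile(
    metacells: MetaCellSet,
    community,
    params: HmmParams | None = None,
    *,
    min_seg_bins: int = 5,
    exact_max: int = 20,
    flank_bins: int | None = None,
) -> CommunityCNAProfile:
    """Full per-community segmentation: HMM -> short-run filter -> tests."""
    params = params or HmmParams()
    meta_z = metacells.community_z(community)
    chroms = metacells.z.bins["chrom"].to_numpy()
    path = hmm_segment(meta_z, chroms, params)
    path = filter_short_segments(path, chroms, min_seg_bins)
    segments = segments_from_path(path, metacells.z.bins)
    tested = [s for s in segments if s.state != "neutral"]
    for seg in tested:
        seg.p_value = test_segment(
            meta_z, seg, segments, exact_max=exact_max, flank_bins=flank_bins
        )
    with_p = [s for s in tested if s.p_value is not None]
    for seg, q in zip(with_p, bh_adjust([s.p_value for s in with_p])):
        seg.q_value = q
    return CommunityCNAProfile(community=community, segments=segments, hmm_params=params)


# ---------------------------------------------------------------------------
# community x cluster enrichment
# ---------------------------------------------------------------------------


def enrich_communities(
    community_labels: np.ndarray, cluster_labels: np.ndarray
) -> pd.DataFrame:
    """Hypergeometric enrichment of communities in expression clusters.

    fold = (overlap / community size) / (cluster size / n);
    p_enrich = P(X >= overlap), p_deplete = P(X <= overlap) drawing
    |community| cells from a population with |cluster| successes.
    """
    community_labels = np.asarray(community_labels)
    cluster_labels = np.asarray(cluster_labels)
    if community_labels.shape != cluster_labels.shape:
        raise ValueError("label vectors must cover the same cells")
    n = len(community_labels)
    if n == 0:
        raise ValueError("empty labelings")
    rows = []
    for community in np.unique(community_labels):
        in_comm = community_labels == community
        for cluster in np.unique(cluster_labels):
            in_clus = cluster_labels == cluster
            k = int((in_comm & in_clus).sum())
            size_comm, size_clus = int(in_comm.sum()), int(in_clus.sum())
            background = size_clus / n
            fold = (k / size_comm) / background
            hg = stats.hypergeom(n, size_clus, size_comm)
            rows.append(
                {
                    "community": community,
                    "cluster": cluster,
                    "overlap": k,
                    "community_size": size_comm,
                    "cluster_size": size_clus,
                    "background_fraction": background,
                    "fold": fold,
                    "p_enrich": float(hg.sf(k - 1)),
                    "p_deplete": float(hg.cdf(k)),
                }
            )
    return pd.DataFrame(rows)
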