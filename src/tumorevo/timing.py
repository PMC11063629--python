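"""Mutation-time timing of copy-number gains and WGD, and cohort event ordering.

Timing is expressed as a fraction pi in [0, 1] of a segment's clonal
mutational history elapsed before the gain (or WGD).  The data are counts
of clonal SNVs per multiplicity class on allele-specific copy-number
segments; the accrual model places mutations uniformly in time on each
extant chromosomal copy, so the probability a clonal SNV sits at a given
multiplicity is a ratio of copy-time masses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

SIMPLE_ROUTES = ("gain_2+1", "gain_2+0", "wgd_2+2")
WGD_ROUTES = ("pre_wgd", "post_wgd")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AlleleSegment:
    """Allele-specific copy-number segment (half-open bp coordinates)."""

    segment_id: str
    chrom: str
    start_bp: int
    end_bp: int
    major_cn: int
    minor_cn: int
    n_snvs: int

    def __post_init__(self) -> None:
        if not (self.major_cn >= self.minor_cn >= 0):
            raise ValueError(
                f"{self.segment_id}: require major_cn >= minor_cn >= 0, "
                f"got {self.major_cn}+{self.minor_cn}"
            )


@dataclass
class MultiplicityCounts:
    """Clonal SNV counts per multiplicity class for one segment.

    n1/n2 are the classes the simple routes produce; n3/n4 only occur on
    pre/post-WGD routes for major copy number 3 and 4 segments.
    """

    segment_id: str
    n1: int
    n2: int
    n3: int = 0
    n4: int = 0

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3, self.n4) < 0:
            raise ValueError("multiplicity counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4])


@dataclass
class TimingPosterior:
    """Pooled post-burn-in MCMC samples of a timing parameter."""

    samples: np.ndarray
    chains: int = 1
    steps: int = 0
    burnin: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    def interval(self, level: float = 0.9) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.samples, [alpha, 1.0 - alpha])
        return float(lo), float(hi)


@dataclass
class TimelineEvent:
    event_id: str
    event_type: str = "gain"  # loss | gain | WGD | driver SNV
    clonality: str = "clonal"  # clonal | subclonal
    posterior: TimingPosterior | None = None
    order_index: int | None = None


@dataclass
class TumorTimeline:
    tumor_id: str
    events: list[TimelineEvent]

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate event ids in tumor {self.tumor_id}")

    def event_ids(self) -> set[str]:
        return {e.event_id for e in self.events}

    def get(self, event_id: str) -> TimelineEvent:
        for e in self.events:
            if e.event_id == event_id:
                return e
        raise KeyError(event_id)


@dataclass
class LeagueRanking:
    """Rank distribution per event over scoring repetitions."""

    event_ids: list[str]
    rank_samples: np.ndarray  # n_iter x n_events, rank 1 = earliest
    mean_scores: np.ndarray
    prevalence: np.ndarray  # fraction of tumors containing each event

    def mean_ranks(self) -> np.ndarray:
        return self.rank_samples.mean(axis=0)

    def ordering(self) -> list[str]:
        """Events sorted earliest-first by mean rank."""
        order = np.argsort(self.mean_ranks(), kind="stable")
        return [self.event_ids[i] for i in order]


# ---------------------------------------------------------------------------
# WGD call
# ---------------------------------------------------------------------------


def call_wgd(
    ploidy: float,
    loh_fraction: float,
    *,
    intercept: float = 2.9,
    slope: float = 2.0,
) -> bool:
    """Call whole-genome doubling from ploidy vs genome LOH fraction.

    WGD iff ploidy > intercept - slope * loh_fraction (strict).
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if not 0.0 <= loh_fraction <= 1.0:
        raise ValueError("loh_fraction must be in [0, 1]")
    return ploidy > intercept - slope * loh_fraction


# ---------------------------------------------------------------------------
# multiplicity accrual model
# ---------------------------------------------------------------------------


def multiplicity2_fraction(pi, route: str):
    """Expected fraction of clonal SNVs at multiplicity 2 for simple routes.

    gain_2+1: pi / (3 - pi); gain_2+0 and wgd_2+2: pi / (2 - pi).
    Derivation (copy-time masses, mutation rate proportional to the number
    of extant copies): a gained allele holds mass pi at multiplicity 2 and
    2(1 - pi) at multiplicity 1; an untouched allele adds mass 1 at
    multiplicity 1 per copy.
    """
    pi = np.asarray(pi, dtype=float)
    if route == "gain_2+1":
        return pi / (3.0 - pi)
    if route in ("gain_2+0", "wgd_2+2"):
        return pi / (2.0 - pi)
    raise ValueError(f"unknown route {route!r}")


def invert_multiplicity2_fraction(f: float, route: str) -> float:
    """MLE of pi from an observed multiplicity-2 fraction (clipped to [0,1])."""
    if route == "gain_2+1":
        pi = 3.0 * f / (1.0 + f)
    elif route in ("gain_2+0", "wgd_2+2"):
        pi = 2.0 * f / (1.0 + f)
    else:
        raise ValueError(f"unknown route {route!r}")
    return float(np.clip(pi, 0.0, 1.0))


def wgd_route_masses(route: str, major_cn: int, g, w):
    """Copy-time masses per multiplicity class (1..4) for pre/post-WGD routes.

    g = gain time, w = WGD time, both in mutation time.  The minor allele is
    fixed at copy number 2 (doubled by the WGD at w).  Major-allele histories:

    post_wgd, major 3 (w <= g):  1 -> 2 at w -> 3 at g (one copy duplicated)
    pre_wgd,  major 3 (g <= w):  1 -> 2 at g -> 3 at w (one copy duplicated)
    pre_wgd,  major 4 (g <= w):  1 -> 2 at g -> 4 at w
    post_wgd, major 4 (w <= g):  1 -> 2 at w -> 4 at g (both copies at once;
        g stands for the average time of the two post-WGD gains, which are
        not separately identifiable)
    """
    g = np.asarray(g, dtype=float)
    w = np.asarray(w, dtype=float)
    zero = np.zeros(np.broadcast(g, w).shape)
    if route == "post_wgd" and major_cn == 3:
        m3 = w + zero
        m2 = g + zero  # (g - w) on the duplicated copy + w on the minor allele
        m1 = (g - w) + 3.0 * (1.0 - g) + 2.0 * (1.0 - w)
        m4 = zero
    elif route == "pre_wgd" and major_cn == 3:
        m3 = g + zero
        m2 = (w - g) + w
        m1 = (w - g) + 3.0 * (1.0 - w) + 2.0 * (1.0 - w)
        m4 = zero
    elif route == "pre_wgd" and major_cn == 4:
        m4 = g + zero
        m2 = 2.0 * (w - g) + w
        m1 = 4.0 * (1.0 - w) + 2.0 * (1.0 - w)
        m3 = zero
    elif route == "post_wgd" and major_cn == 4:
        m4 = w + zero
        m2 = 2.0 * (g - w) + w
        m1 = 4.0 * (1.0 - g) + 2.0 * (1.0 - w)
        m3 = zero
    else:
        raise ValueError(f"unknown WGD route {route!r} for major_cn {major_cn}")
    return np.stack([m1, m2, m3, m4], axis=-1)


def route_log_likelihood(counts: MultiplicityCounts, route: str):
    """Return a vectorized log-likelihood function of pi for a simple route.

    L(pi) = Binomial(n2 | n1 + n2, p_route(pi)).
    """
    if route not in SIMPLE_ROUTES:
        raise ValueError(f"unknown route {route!r}")
    n = counts.n1 + counts.n2
    if n < 1:
        raise ValueError("need at least one SNV (n1 + n2 >= 1)")
    n2 = counts.n2

    def loglik(pi):
        p = multiplicity2_fraction(np.clip(pi, 0.0, 1.0), route)
        return stats.binom.logpmf(n2, n, p)

    return loglik


# ---------------------------------------------------------------------------
# MCMC sampler
# ---------------------------------------------------------------------------


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Reflect proposals back into [0, 1]."""
    y = np.remainder(np.abs(x), 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def _metropolis_unit_interval(
    loglik,
    *,
    chains: int,
    steps: int,
    burnin: int,
    seed,
    proposal_sd: float = 0.1,
) -> TimingPosterior:
    """Reflecting random-walk Metropolis on [0,1] with a uniform prior."""
    if burnin >= steps:
        raise ValueError("burnin must be smaller than steps")
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=chains)
    ll = np.asarray(loglik(x), dtype=float)
    # restart chains stuck at zero-likelihood starting points
    bad = ~np.isfinite(ll)
    for _ in range(100):
        if not bad.any():
            break
        x[bad] = rng.uniform(size=bad.sum())
        ll[bad] = loglik(x[bad])
        bad = ~np.isfinite(ll)
    kept = np.empty((steps - burnin, chains))
    for step in range(steps):
        prop = _reflect_unit(x + proposal_sd * rng.standard_normal(chains))
        ll_prop = np.asarray(loglik(prop), dtype=float)
        accept = np.log(rng.uniform(size=chains)) < ll_prop - ll
        x = np.where(accept, prop, x)
        ll = np.where(accept, ll_prop, ll)
        if step >= burnin:
            kept[step - burnin] = x
    chain_means = kept.mean(axis=0)
    within = kept.var(axis=0, ddof=1).mean()
    between = chain_means.var(ddof=1) * kept.shape[0]
    if within > 0:
        n = kept.shape[0]
        rhat = np.sqrt((n - 1) / n + between / (within * n))
        logger.info("timing MCMC split statistic: %.4f", rhat)
        if rhat > 1.1:
            logger.warning("timing MCMC may not have converged (%.3f > 1.1)", rhat)
    return TimingPosterior(
        samples=kept.T.ravel(), chains=chains, steps=steps, burnin=burnin
    )


def sample_gain_timing(
    counts: MultiplicityCounts,
    route: str,
    *,
    chains: int = 30,
    steps: int = 2000,
    burnin: int = 1000,
    seed=None,
    proposal_sd: float = 0.1,
) -> TimingPosterior:
    """Posterior over a single gain's timing under a uniform prior on [0,1]."""
    loglik = route_log_likelihood(counts, route)
    return _metropolis_unit_interval(
        loglik,
        chains=chains,
        steps=steps,
        burnin=burnin,
        seed=seed,
        proposal_sd=proposal_sd,
    )


def wgd_segment_route(segment: AlleleSegment) -> str | None:
    """Route by which a major-CN-2 segment times the WGD, or None."""
    if segment.major_cn != 2:
        return None
    if segment.minor_cn == 2:
        return "wgd_2+2"
    if segment.minor_cn == 0:
        return "gain_2+0"
    return None  # 2+1 does not result from a WGD


def time_wgd(
    segments: list[AlleleSegment],
    counts: dict[str, MultiplicityCounts],
    *,
    chains: int = 30,
    steps: int = 2000,
    burnin: int = 1000,
    seed=None,
    proposal_sd: float = 0.1,
) -> TimingPosterior:
    """Jointly time the WGD from all gains with a major copy number of two.

    The joint posterior over one shared pi multiplies per-segment route
    likelihoods (wgd_2+2 for 2+2 segments, gain_2+0 for 2+0 segments).
    """
    logliks = []
    for seg in segments:
        route = wgd_segment_route(seg)
        if route is None:
            continue
        if seg.segment_id not in counts:
            continue
        logliks.append(route_log_likelihood(counts[seg.segment_id], route))
    if not logliks:
        raise ValueError("no WGD-eligible segments (major_cn == 2, minor 0 or 2)")

    def joint(pi):
        return sum(f(pi) for f in logliks)

    return _metropolis_unit_interval(
        joint, chains=chains, steps=steps, burnin=burnin, seed=seed,
        proposal_sd=proposal_sd,
    )


# ---------------------------------------------------------------------------
# pre/post-WGD route classification
# ---------------------------------------------------------------------------


def _histogram_density(samples: np.ndarray, n_bins: int) -> np.ndarray:
    h, _ = np.histogram(samples, bins=n_bins, range=(0.0, 1.0))
    total = h.sum()
    return h / total if total > 0 else np.full(n_bins, 1.0 / n_bins)


def bhattacharyya_coefficient(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sqrt(np.asarray(p) * np.asarray(q)).sum())


def overlap_coefficient(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.minimum(np.asarray(p), np.asarray(q)).sum())


def _wgd_route_grid_posterior(
    counts: MultiplicityCounts, route: str, major_cn: int, n_grid: int
):
    """Joint posterior over (gain time g, WGD time w) on a grid.

    Returns (g_grid, w_grid, posterior) with posterior normalized over the
    valid ordering region (g <= w for pre, w <= g for post).
    """
    grid = (np.arange(n_grid) + 0.5) / n_grid
    gg, ww = np.meshgrid(grid, grid, indexing="ij")
    masses = wgd_route_masses(route, major_cn, gg, ww)
    total = masses.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(masses > 0, np.log(masses) - np.log(total)[..., None], -np.inf)
    n_k = counts.as_array()
    loglik = (n_k * np.where(n_k > 0, logp, 0.0)).sum(axis=-1)  # 0 * -inf := 0
    valid = gg <= ww if route == "pre_wgd" else ww <= gg
    loglik = np.where(valid, loglik, -np.inf)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()
    return grid, post


def classify_gain_route(
    segment: AlleleSegment,
    counts: MultiplicityCounts,
    sample_wgd_posterior: TimingPosterior,
    *,
    wgd: bool = True,
    n_grid: int = 100,
    similarity: str = "bhattacharyya",
    n_samples: int = 2000,
    seed=None,
) -> tuple[float, float, TimingPosterior]:
    """Weigh pre- vs post-WGD routes for a gained segment in a WGD tumor.

    Each route implies a WGD-timing distribution (the marginal over w of the
    grid posterior); its weight is 0.5 (equal route prior) times the
    similarity of that marginal to the sample-wide WGD posterior, then
    normalized.  Returns (P(pre), P(post), gain-timing posterior under the
    more probable route; for major CN 4 post-WGD this is the average timing
    of the two post-WGD gains).
    """
    if not wgd:
        raise ValueError("route classification requires a WGD tumor")
    if segment.major_cn not in (3, 4):
        raise ValueError("route classification applies to major_cn 3 or 4")
    sim = {
        "bhattacharyya": bhattacharyya_coefficient,
        "overlap": overlap_coefficient,
    }[similarity]
    wgd_hist = _histogram_density(sample_wgd_posterior.samples, n_grid)
    weights, marginals = {}, {}
    for route in WGD_ROUTES:
        grid, post = _wgd_route_grid_posterior(counts, route, segment.major_cn, n_grid)
        implied_w = post.sum(axis=0)  # marginal over WGD time
        marginals[route] = (grid, post)
        weights[route] = 0.5 * sim(implied_w, wgd_hist)
    total = weights["pre_wgd"] + weights["post_wgd"]
    if total == 0:
        p_pre = p_post = 0.5
    else:
        p_pre = weights["pre_wgd"] / total
        p_post = weights["post_wgd"] / total
    best = "pre_wgd" if p_pre >= p_post else "post_wgd"
    grid, post = marginals[best]
    g_marginal = post.sum(axis=1)
    rng = np.random.default_rng(seed)
    draws = rng.choice(grid, size=n_samples, p=g_marginal)
    draws = draws + (rng.uniform(size=n_samples) - 0.5) / n_grid
    posterior = TimingPosterior(np.clip(draws, 0.0, 1.0))
    return float(p_pre), float(p_post), posterior


# ---------------------------------------------------------------------------
# eligibility and PDX refinement
# ---------------------------------------------------------------------------


def filter_timeable_segments(
    segments: list[AlleleSegment],
    wgd: bool,
    *,
    min_snvs: int = 10,
    max_minor: int = 2,
) -> list[AlleleSegment]:
    """Keep gained segments eligible for timing.

    Requires n_snvs >= 10, minor_cn <= 2, and major_cn <= 4 in WGD tumors
    or <= 2 otherwise (all bounds inclusive as printed).
    """
    max_major = 4 if wgd else 2
    return [
        s
        for s in segments
        if s.n_snvs >= min_snvs and s.minor_cn <= max_minor and s.major_cn <= max_major
    ]


def refine_clonality_with_pdx(
    pt_timeline: TumorTimeline, pdx_events: set[str]
) -> TumorTimeline:
    """Reclassify PT-clonal events absent from the matched PDX as subclonal."""
    events = []
    for e in pt_timeline.events:
        if e.clonality == "clonal" and e.event_id not in pdx_events:
            events.append(replace(e, clonality="subclonal"))
        else:
            events.append(replace(e))
    return TumorTimeline(pt_timeline.tumor_id, events)


# ---------------------------------------------------------------------------
# league model
# ---------------------------------------------------------------------------


def _draw_event_value(event: TimelineEvent, rng) -> tuple[str, float]:
    """(kind, value) used to compare two events within one tumor."""
    if event.posterior is not None and len(event.posterior.samples):
        return "timing", float(rng.choice(event.posterior.samples))
    if event.order_index is not None:
        return "order", float(event.order_index)
    return "none", np.nan


def league_rank(
    timelines: list[TumorTimeline],
    *,
    n_iter: int = 100,
    seed=None,
) -> LeagueRanking:
    """Aggregate event order across tumors by repeated pairwise scoring.

    Per repetition every event starts at score 0; for each unordered event
    pair one tumor containing both is drawn uniformly, one timing sample is
    drawn per event from that tumor, and the earlier event gains +1 while
    the later loses 1.  Indistinguishable pairs (equal draws, incomparable
    information, or no shared tumor) leave both scores unchanged.  Events
    are then ranked by descending score (ties share the averaged rank).
    """
    event_ids = sorted({e.event_id for t in timelines for e in t.events})
    if not event_ids:
        raise ValueError("no events in cohort")
    rng = np.random.default_rng(seed)
    n_events = len(event_ids)
    shared: dict[tuple[str, str], list[TumorTimeline]] = {}
    for a, b in itertools.combinations(event_ids, 2):
        shared[(a, b)] = [
            t for t in timelines if a in t.event_ids() and b in t.event_ids()
        ]
    rank_samples = np.empty((n_iter, n_events))
    score_sum = np.zeros(n_events)
    index = {e: i for i, e in enumerate(event_ids)}
    for it in range(n_iter):
        scores = np.zeros(n_events)
        for (a, b), tumors in shared.items():
            if not tumors:
                continue
            tumor = tumors[int(rng.integers(len(tumors)))]
            kind_a, va = _draw_event_value(tumor.get(a), rng)
            kind_b, vb = _draw_event_value(tumor.get(b), rng)
            if kind_a != kind_b or kind_a == "none" or va == vb:
                continue
            if va < vb:
                scores[index[a]] += 1
                scores[index[b]] -= 1
            else:
                scores[index[b]] += 1
                scores[index[a]] -= 1
        rank_samples[it] = stats.rankdata(-scores, method="average")
        score_sum += scores
    n_tumors = len(timelines)
    prevalence = np.array(
        [sum(e in t.event_ids() for t in timelines) / n_tumors for e in event_ids]
    )
    return LeagueRanking(
        event_ids=event_ids,
        rank_samples=rank_samples,
        mean_scores=score_sum / n_iter,
        prevalence=prevalence,
    )
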