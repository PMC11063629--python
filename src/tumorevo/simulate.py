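"""Synthetic-data generators with known ground truth.

Three simulators feed the pipeline: clone-structured expression matrices
with planted chromosome-arm copy-number events on top of a normal-cell
baseline, clonal-SNV accrual on allele-specific copy-number histories with
known gain/WGD times, and cohorts of per-tumor event timelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tumorevo.core import CountMatrix, chrom_sort_key
from tumorevo.timing import (
    MultiplicityCounts,
    TimelineEvent,
    TimingPosterior,
    TumorTimeline,
    multiplicity2_fraction,
    wgd_route_masses,
)

SAMPLES = ("PT_bulk", "PDX_bulk", "SCS12", "SCS34")


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


@dataclass
class ArmEvent:
    chrom: str
    arm: str  # "p" | "q"
    state: str  # "loss" | "gain"

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.state not in ("loss", "gain"):
            raise ValueError(f"state must be 'loss' or 'gain', got {self.state!r}")

    @property
    def copy_number(self) -> int:
        return 1 if self.state == "loss" else 3


@dataclass
class CloneSpec:
    clone_id: str
    n_cells: int
    events: list[ArmEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [
            e if isinstance(e, ArmEvent) else ArmEvent(*e) for e in self.events
        ]
        if self.n_cells < 1:
            raise ValueError(f"clone {self.clone_id}: cell count must be >= 1")


@dataclass
class ExpressionSimConfig:
    genes_per_chrom: dict[str, int]
    clones: list[CloneSpec]
    dosage_effect: float = 1.0
    n_normal_cells: int = 0
    frac_cycling: float = 0.0
    library_size_lognorm: tuple[float, float] = (0.0, 0.2)
    gene_mean_lognorm: tuple[float, float] = (0.5, 0.5)
    overdispersion: float | None = None  # negative-binomial dispersion if set
    g2m_factor: float = 3.0
    n_marker_genes: int = 30
    gene_spacing_bp: int = 1_000_000
    gene_length_bp: int = 1_000
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return sum(self.genes_per_chrom.values())

    def validate(self) -> None:
        if not self.clones:
            raise ValueError("config must declare at least one clone")
        if self.dosage_effect < 0:
            raise ValueError("dosage_effect must be >= 0")
        if not 0.0 <= self.frac_cycling <= 1.0:
            raise ValueError("frac_cycling must be in [0, 1]")
        for clone in self.clones:
            for ev in clone.events:
                if ev.chrom not in self.genes_per_chrom:
                    raise ValueError(
                        f"clone {clone.clone_id}: event chromosome {ev.chrom!r} "
                        "not in genes_per_chrom"
                    )


@dataclass
class ExpressionGroundTruth:
    cells: pd.DataFrame  # cell_id, clone, cycling
    genes: pd.DataFrame  # gene_id, chrom, start, end, arm
    clone_cn: dict[str, np.ndarray]  # clone -> per-gene integer CN ("normal" incl.)
    g1s_genes: list[str]
    g2m_genes: list[str]


def _gene_table(config: ExpressionSimConfig) -> pd.DataFrame:
    rows = []
    chroms = sorted(config.genes_per_chrom, key=chrom_sort_key)
    for chrom in chroms:
        n = config.genes_per_chrom[chrom]
        half = n // 2
        for i in range(n):
            start = i * config.gene_spacing_bp
            rows.append(
                {
                    "gene_id": f"{chrom}_g{i:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + config.gene_length_bp,
                    "arm": "p" if i < half else "q",
                }
            )
    return pd.DataFrame(rows)


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[CountMatrix, ExpressionGroundTruth]:
    """Draw a gene x cell count matrix with planted arm-scale CNAs.

    Counts are Poisson (negative binomial if ``overdispersion`` is set) with
    rate = library_factor * gene_mean * (CN / 2) ** dosage_effect; cycling
    cells additionally scale a designated G2/M marker gene set by
    ``g2m_factor``.  Normal cells carry copy number 2 everywhere.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config)
    n_genes = len(genes)

    # marker sets: evenly spread, disjoint, recorded in the ground truth
    n_mark = min(config.n_marker_genes, n_genes // 4)
    marker_idx = np.linspace(0, n_genes - 1, 2 * n_mark, dtype=int)
    g2m_idx, g1s_idx = marker_idx[0::2], marker_idx[1::2]

    clone_cn: dict[str, np.ndarray] = {"normal": np.full(n_genes, 2, dtype=int)}
    for clone in config.clones:
        cn = np.full(n_genes, 2, dtype=int)
        for ev in clone.events:
            mask = (genes["chrom"] == ev.chrom) & (genes["arm"] == ev.arm)
            cn[mask.to_numpy()] = ev.copy_number
        clone_cn[clone.clone_id] = cn

    labels = [("normal", i) for i in range(config.n_normal_cells)]
    for clone in config.clones:
        labels += [(clone.clone_id, i) for i in range(clone.n_cells)]
    n_cells = len(labels)
    cell_ids = [f"{clone}_c{i:04d}" for clone, i in labels]

    mu, sigma = config.gene_mean_lognorm
    gene_mean = rng.lognormal(mu, sigma, size=n_genes)
    lib_mu, lib_sigma = config.library_size_lognorm
    lib = rng.lognormal(lib_mu, lib_sigma, size=n_cells)
    cycling = rng.uniform(size=n_cells) < config.frac_cycling

    rates = np.empty((n_genes, n_cells))
    for j, (clone, _) in enumerate(labels):
        cn_ratio = clone_cn[clone] / 2.0
        rate = lib[j] * gene_mean * cn_ratio**config.dosage_effect
        if cycling[j]:
            rate = rate.copy()
            rate[g2m_idx] *= config.g2m_factor
        rates[:, j] = rate
    if config.overdispersion is None:
        counts = rng.poisson(rates)
    else:
        # NB via Gamma-Poisson; dispersion alpha: var = m + alpha * m^2
        alpha = config.overdispersion
        shape = 1.0 / alpha
        counts = rng.poisson(rng.gamma(shape, rates * alpha))

    truth = ExpressionGroundTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "clone": [c for c, _ in labels],
                "cycling": cycling,
            }
        ),
        genes=genes,
        clone_cn=clone_cn,
        g1s_genes=list(genes["gene_id"].iloc[g1s_idx]),
        g2m_genes=list(genes["gene_id"].iloc[g2m_idx]),
    )
    return CountMatrix(counts, genes, cell_ids), truth


def default_scenario(
    *,
    cells_per_clone: int = 200,
    n_normal_cells: int = 150,
    dosage_effect: float = 1.0,
    frac_cycling: float = 0.1,
    seed: int = 0,
) -> ExpressionSimConfig:
    """Three clones with two arm events each over a normal baseline."""
    genes_per_chrom = {f"chr{i}": 120 for i in range(1, 7)}
    clones = [
        CloneSpec(
            "clone1",
            cells_per_clone,
            [ArmEvent("chr4", "p", "loss"), ArmEvent("chr1", "q", "gain")],
        ),
        CloneSpec(
            "clone2",
            cells_per_clone,
            [ArmEvent("chr4", "p", "loss"), ArmEvent("chr2", "p", "loss")],
        ),
        CloneSpec(
            "clone3",
            cells_per_clone,
            [ArmEvent("chr5", "q", "gain"), ArmEvent("chr3", "p", "loss")],
        ),
    ]
    return ExpressionSimConfig(
        genes_per_chrom=genes_per_chrom,
        clones=clones,
        dosage_effect=dosage_effect,
        n_normal_cells=n_normal_cells,
        frac_cycling=frac_cycling,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# clonal SNV simulation
# ---------------------------------------------------------------------------


@dataclass
class SegmentSpec:
    segment_id: str
    chrom: str
    start_bp: int
    end_bp: int
    route: str  # gain_2+1 | gain_2+0 | wgd_2+2 | pre_wgd | post_wgd
    true_pi: float
    true_wgd_pi: float | None = None  # WGD time for pre/post-WGD routes
    major_cn: int = 4  # only used by pre/post-WGD routes (3 or 4)

    def validate(self) -> None:
        if not 0.0 <= self.true_pi <= 1.0:
            raise ValueError(f"{self.segment_id}: true_pi must be in [0, 1]")
        if self.route in ("pre_wgd", "post_wgd"):
            if self.true_wgd_pi is None:
                raise ValueError(
                    f"{self.segment_id}: {self.route} requires true_wgd_pi"
                )
            if self.route == "pre_wgd" and self.true_pi > self.true_wgd_pi:
                raise ValueError(f"{self.segment_id}: pre_wgd requires gain <= WGD")
            if self.route == "post_wgd" and self.true_pi < self.true_wgd_pi:
                raise ValueError(f"{self.segment_id}: post_wgd requires WGD <= gain")
            if self.major_cn not in (3, 4):
                raise ValueError(f"{self.segment_id}: major_cn must be 3 or 4")
        elif self.route not in ("gain_2+1", "gain_2+0", "wgd_2+2"):
            raise ValueError(f"{self.segment_id}: unknown route {self.route!r}")


@dataclass
class CloneNode:
    clone_id: str
    parent_id: str | None
    samples: tuple[str, ...] = SAMPLES


@dataclass
class EvolutionSimConfig:
    segments: list[SegmentSpec]
    n_snvs_per_segment: int = 100
    clone_tree: list[CloneNode] = field(
        default_factory=lambda: [CloneNode("root", None, SAMPLES)]
    )
    false_negative_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        roots = [c for c in self.clone_tree if c.parent_id is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        by_chrom: dict[str, list[SegmentSpec]] = {}
        for seg in self.segments:
            seg.validate()
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start_bp)
            for a, b in zip(segs, segs[1:]):
                if a.end_bp > b.start_bp:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"{a.segment_id} and {b.segment_id}"
                    )


def route_multiplicity_masses(spec: SegmentSpec) -> np.ndarray:
    """Copy-time mass per multiplicity class (1..4) for one segment spec.

    Simple routes (gained allele reaches copy number 2 at time pi):
      gain_2+1: mult2 mass pi, mult1 mass 2(1-pi) + 1 (untouched minor)
      gain_2+0: mult2 mass pi, mult1 mass 2(1-pi)
      wgd_2+2:  both alleles gained: mult2 mass 2 pi, mult1 mass 4(1-pi)
    The implied mult2 fractions are pi/(3-pi) and pi/(2-pi) respectively.
    """
    pi = spec.true_pi
    if spec.route == "gain_2+1":
        return np.array([2.0 * (1.0 - pi) + 1.0, pi, 0.0, 0.0])
    if spec.route == "gain_2+0":
        return np.array([2.0 * (1.0 - pi), pi, 0.0, 0.0])
    if spec.route == "wgd_2+2":
        return np.array([4.0 * (1.0 - pi), 2.0 * pi, 0.0, 0.0])
    if spec.route in ("pre_wgd", "post_wgd"):
        return wgd_route_masses(spec.route, spec.major_cn, pi, spec.true_wgd_pi)
    raise ValueError(f"unknown route {spec.route!r}")


@dataclass
class EvolutionGroundTruth:
    segments: list[SegmentSpec]
    snv_clones: pd.DataFrame  # snv_id, clone
    clone_tree: list[CloneNode]


def _clone_sample_presence(clone_tree: list[CloneNode]) -> dict[str, set[str]]:
    """Samples an SNV born in each clone appears in: its subtree's samples."""
    children: dict[str, list[CloneNode]] = {}
    for node in clone_tree:
        if node.parent_id is not None:
            children.setdefault(node.parent_id, []).append(node)
    presence: dict[str, set[str]] = {}

    def collect(node: CloneNode) -> set[str]:
        samples = set(node.samples)
        for child in children.get(node.clone_id, []):
            samples |= collect(child)
        presence[node.clone_id] = samples
        return samples

    root = next(c for c in clone_tree if c.parent_id is None)
    collect(root)
    for node in clone_tree:  # unreachable nodes (defensive)
        presence.setdefault(node.clone_id, set(node.samples))
    return presence


def simulate_clonal_snvs(
    config: EvolutionSimConfig,
) -> tuple[list[MultiplicityCounts], pd.DataFrame, EvolutionGroundTruth]:
    """Draw per-segment multiplicity counts and a per-sample presence table.

    Each SNV lands on a chromosomal copy-lineage with probability
    proportional to the lineage's extant time (uniform mutation time at a
    rate proportional to the number of copies); its multiplicity is the
    number of final copies descending from that point.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    presence_map = _clone_sample_presence(config.clone_tree)
    clone_ids = [c.clone_id for c in config.clone_tree]

    counts_out: list[MultiplicityCounts] = []
    rows = []
    snv_clone_rows = []
    for spec in config.segments:
        masses = route_multiplicity_masses(spec)
        probs = masses / masses.sum()
        mults = rng.choice(4, size=config.n_snvs_per_segment, p=probs) + 1
        n = np.bincount(mults, minlength=5)
        counts_out.append(
            MultiplicityCounts(spec.segment_id, int(n[1]), int(n[2]), int(n[3]), int(n[4]))
        )
        for k in range(config.n_snvs_per_segment):
            clone = clone_ids[int(rng.integers(len(clone_ids)))]
            snv_id = f"{spec.segment_id}_snv{k:05d}"
            snv_clone_rows.append({"snv_id": snv_id, "clone": clone})
            flags = {}
            for sample in SAMPLES:
                present = sample in presence_map[clone]
                if present and config.false_negative_rate > 0:
                    present = rng.uniform() >= config.false_negative_rate
                flags[sample] = int(present)
            rows.append(
                {
                    "snv_id": snv_id,
                    **flags,
                    "tlod": float(np.round(20.0 + rng.exponential(40.0), 2)),
                    "is_indel": bool(rng.uniform() < 0.1),
                    "n_cells_genotyped": int(rng.poisson(30)),
                }
            )
    presence = pd.DataFrame(
        rows,
        columns=["snv_id", *SAMPLES, "tlod", "is_indel", "n_cells_genotyped"],
    )
    truth = EvolutionGroundTruth(
        segments=list(config.segments),
        snv_clones=pd.DataFrame(snv_clone_rows, columns=["snv_id", "clone"]),
        clone_tree=list(config.clone_tree),
    )
    return counts_out, presence, truth


def expected_multiplicity2_fraction(spec: SegmentSpec) -> float:
    """Closed-form expected n2 / (n1 + n2) for a simple-route segment."""
    return float(multiplicity2_fraction(spec.true_pi, spec.route))


# ---------------------------------------------------------------------------
# cohort timeline simulation
# ---------------------------------------------------------------------------


def simulate_cohort_timelines(
    true_order: list[str],
    n_tumors: int,
    timing_noise_sd: float,
    dropout: float,
    seed: int = 0,
    *,
    n_samples: int = 50,
) -> list[TumorTimeline]:
    """Per-tumor timelines with events centered on their true rank position.

    Each tumor contains each event with probability 1 - dropout; a present
    event's timing samples are its true position (rank-proportional in
    (0, 1)) plus Gaussian noise, truncated to [0, 1].
    """
    if len(true_order) < 2:
        raise ValueError("need at least 2 events")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1) — dropout 1 leaves no data")
    rng = np.random.default_rng(seed)
    n_events = len(true_order)
    positions = {e: (i + 1) / (n_events + 1) for i, e in enumerate(true_order)}
    timelines = []
    for t in range(n_tumors):
        events = []
        for i, event_id in enumerate(true_order):
            if rng.uniform() < dropout:
                continue
            samples = positions[event_id] + timing_noise_sd * rng.standard_normal(
                n_samples
            )
            events.append(
                TimelineEvent(
                    event_id=event_id,
                    posterior=TimingPosterior(np.clip(samples, 0.0, 1.0)),
                    order_index=i,
                )
            )
        timelines.append(TumorTimeline(f"tumor{t:03d}", events))
    return timelines
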