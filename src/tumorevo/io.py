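"""Readers/writers for the pipeline's on-disk formats, run configuration,
and the end-to-end pipeline driver.

TSV dialect: tab-separated, header row, UTF-8, '.' for missing values.
BED-style outputs use 0-based half-open coordinates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from tumorevo.core import BinnedExpression, CountMatrix
from tumorevo.segmentation import CNASegment, CommunityCNAProfile

logger = logging.getLogger(__name__)

NA = "."

SEGMENT_COLUMNS = [
    "chrom", "start", "end", "community", "state", "n_bins", "p_value", "q_value",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage sub-seed from the global seed and the stage name."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % 2**32


# ---------------------------------------------------------------------------
# count matrices (MTX + gene/cell TSV)
# ---------------------------------------------------------------------------


def read_counts(mtx_path, genes_path, cells_path) -> CountMatrix:
    """Load an MTX count matrix with gene/cell annotations, genome-sorted.

    The gene TSV needs gene_id, chrom and start columns (end/arm kept when
    present); the cell TSV needs a cell_id column.
    """
    mat = spio.mmread(str(mtx_path))
    counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    for col in ("gene_id", "chrom", "start"):
        if col not in genes.columns:
            raise ValueError(f"gene annotation is missing column {col!r}")
    if "cell_id" not in cells.columns:
        raise ValueError("cell annotation is missing column 'cell_id'")
    matrix = CountMatrix(counts, genes, list(cells["cell_id"].astype(str)))
    return matrix.sorted_by_position()


def write_counts(matrix: CountMatrix, out_dir, *, cells_extra: pd.DataFrame | None = None) -> None:
    """Write MTX + genes.tsv + cells.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.coo_matrix(matrix.counts))
    matrix.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    cells = pd.DataFrame({"cell_id": matrix.cell_ids})
    if cells_extra is not None:
        cells = cells.merge(cells_extra, on="cell_id", how="left")
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrices / partitions / embeddings
# ---------------------------------------------------------------------------


def write_binned_matrix(binned: BinnedExpression, path) -> None:
    df = binned.bins.copy()
    values = pd.DataFrame(
        binned.values, columns=[str(c) for c in binned.cell_ids]
    )
    pd.concat([df.reset_index(drop=True), values], axis=1).to_csv(
        path, sep="\t", index=False
    )


def write_partition(cell_ids, labels, gamma, path) -> None:
    pd.DataFrame(
        {"cell_id": cell_ids, "community": labels, "gamma": gamma}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_embedding(embedding, path) -> None:
    df = pd.DataFrame(
        embedding.scores,
        columns=[f"PC{i+1}" for i in range(embedding.scores.shape[1])],
    )
    df.insert(0, "cell_id", embedding.cell_ids)
    df["cycling"] = embedding.cycling
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segment BED-like TSV
# ---------------------------------------------------------------------------


def write_segments_bed(profiles: list[CommunityCNAProfile], path) -> None:
    """Serialize per-community segment profiles as a BED-like TSV.

    One row per segment; coordinates 0-based half-open from the member
    bins' bp bounds.  Re-reading reproduces the profiles exactly.
    """
    rows = []
    for profile in profiles:
        last_end: dict[str, int] = {}
        for seg in profile.segments:
            start = seg.start_bp if seg.start_bp is not None else seg.first_bin
            end = seg.end_bp if seg.end_bp is not None else seg.last_bin + 1
            if seg.chrom in last_end and start < last_end[seg.chrom]:
                raise ValueError(
                    f"overlapping segments on {seg.chrom} in community "
                    f"{profile.community}"
                )
            last_end[seg.chrom] = end
            rows.append(
                {
                    "chrom": seg.chrom,
                    "start": start,
                    "end": end,
                    "community": profile.community,
                    "state": seg.state,
                    "n_bins": seg.n_bins,
                    "p_value": NA if seg.p_value is None else repr(seg.p_value),
                    "q_value": NA if seg.q_value is None else repr(seg.q_value),
                }
            )
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_segments_bed(path) -> list[CommunityCNAProfile]:
    df = pd.read_csv(
        path, sep="\t", na_values=[NA], keep_default_na=False,
        float_precision="round_trip",
    )
    profiles = []
    if df.empty:
        return profiles
    for community, group in df.groupby("community", sort=False):
        segments = []
        first = 0
        for _, row in group.iterrows():
            n_bins = int(row["n_bins"])
            segments.append(
                CNASegment(
                    chrom=str(row["chrom"]),
                    first_bin=first,
                    last_bin=first + n_bins - 1,
                    state=str(row["state"]),
                    n_bins=n_bins,
                    start_bp=int(row["start"]),
                    end_bp=int(row["end"]),
                    p_value=None if pd.isna(row["p_value"]) else float(row["p_value"]),
                    q_value=None if pd.isna(row["q_value"]) else float(row["q_value"]),
                )
            )
            first += n_bins
        profiles.append(CommunityCNAProfile(community=community, segments=segments))
    return profiles


# ---------------------------------------------------------------------------
# SNV tables
# ---------------------------------------------------------------------------


def read_snv_table(path) -> list:
    """Read the SNV presence TSV into SNVObservation records."""
    from tumorevo.clones import SNVObservation

    df = pd.read_csv(path, sep="\t")
    return [
        SNVObservation(
            snv_id=str(r["snv_id"]),
            pt_bulk=bool(r["PT_bulk"]),
            pdx_bulk=bool(r["PDX_bulk"]),
            scs12=bool(r["SCS12"]),
            scs34=bool(r["SCS34"]),
            tlod=float(r.get("tlod", 0.0)),
            is_indel=bool(r.get("is_indel", False)),
            n_cells_genotyped=int(r.get("n_cells_genotyped", 0)),
        )
        for _, r in df.iterrows()
    ]


def read_allele_profile(path) -> list:
    from tumorevo.clones import AlleleCnPair

    df = pd.read_csv(path, sep="\t")
    return [
        AlleleCnPair(
            segment_id=str(r["segment_id"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            cn_a=int(r["cn_a"]),
            cn_b=int(r["cn_b"]),
        )
        for _, r in df.iterrows()
    ]


def read_allele_segments(path) -> list:
    from tumorevo.timing import AlleleSegment

    df = pd.read_csv(path, sep="\t")
    return [
        AlleleSegment(
            segment_id=str(r["segment_id"]),
            chrom=str(r["chrom"]),
            start_bp=int(r["start"]),
            end_bp=int(r["end"]),
            major_cn=int(r["major_cn"]),
            minor_cn=int(r["minor_cn"]),
            n_snvs=int(r["n_snvs"]),
        )
        for _, r in df.iterrows()
    ]


def read_multiplicity_counts(path) -> dict:
    from tumorevo.timing import MultiplicityCounts

    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        out[str(r["segment_id"])] = MultiplicityCounts(
            segment_id=str(r["segment_id"]),
            n1=int(r["n1"]),
            n2=int(r["n2"]),
            n3=int(r.get("n3", 0)),
            n4=int(r.get("n4", 0)),
        )
    return out


def write_multiplicity_counts(counts: list, path) -> None:
    pd.DataFrame(
        [
            {"segment_id": c.segment_id, "n1": c.n1, "n2": c.n2, "n3": c.n3, "n4": c.n4}
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class CnaParams:
    min_mean_expression: float = 1.0
    window: int = 5
    winsorize_bound: float = 3.0
    n_components: int = 20
    knn_k: int | None = None
    gamma_grid: list[float] = field(
        default_factory=lambda: [round(g, 2) for g in np.arange(0.4, 1.61, 0.2)]
    )
    n_runs: int = 10
    cell_cycle_threshold: float = 1.0


@dataclass
class SegmentationParams:
    n_meta: int = 5
    meta_frac: float = 0.5
    min_community_size: int = 10
    delta: float = 0.5
    sigma: float | None = None
    tau: float = 1.0e-3
    min_seg_bins: int = 5
    flank_bins: int | None = None


@dataclass
class TimingParams:
    chains: int = 30
    steps: int = 2000
    burnin: int = 1000
    proposal_sd: float = 0.1
    league_iters: int = 100
    similarity: str = "bhattacharyya"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "tumorevo_run"
    cna: CnaParams = field(default_factory=CnaParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    timing: TimingParams = field(default_factory=TimingParams)


def _from_dict(cls, data: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config key {sorted(unknown)[0]!r} in {context}")
    return cls(**data)


def load_run_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    nested = {
        "cna": CnaParams,
        "segmentation": SegmentationParams,
        "timing": TimingParams,
    }
    kwargs = {}
    for key, value in data.items():
        if key in nested:
            kwargs[key] = _from_dict(nested[key], value or {}, key)
        elif key in ("seed", "out_dir"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, sim_config=None) -> dict:
    """simulate -> cna -> communities -> segment -> enrich, with a manifest.

    When ``sim_config`` is None the default synthetic scenario is used with
    the configured seed.  Returns the JSON manifest (also written to
    manifest.json in the output directory).
    """
    from tumorevo import cna as cna_mod
    from tumorevo import segmentation as seg_mod
    from tumorevo import simulate as sim_mod

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    # --- simulate ---------------------------------------------------------
    if sim_config is None:
        sim_config = sim_mod.default_scenario(seed=stage_seed(config.seed, "simulate"))
    matrix, truth = sim_mod.simulate_expression(sim_config)
    write_counts(matrix, out / "sim", cells_extra=truth.cells)
    manifest["stages"]["simulate"] = {
        "seed": sim_config.seed,
        "n_genes": matrix.n_genes,
        "n_cells": matrix.n_cells,
    }

    # --- cna prepare ------------------------------------------------------
    p = config.cna
    z, normalized = cna_mod.prepare_smoothed_z(
        matrix,
        min_mean_expression=p.min_mean_expression,
        window=p.window,
        winsorize_bound=p.winsorize_bound,
    )
    write_binned_matrix(z, out / "smoothed_z.tsv")
    cycle = cna_mod.score_cell_cycle(
        normalized, truth.g1s_genes, truth.g2m_genes, p.cell_cycle_threshold
    )
    manifest["stages"]["cna_prepare"] = {
        "n_bins": z.n_bins,
        "window": p.window,
        "min_mean_expression": p.min_mean_expression,
    }

    # --- communities ------------------------------------------------------
    embedding = cna_mod.pca_project(
        z, cycle["cycling"].to_numpy(), n_components=p.n_components
    )
    write_embedding(embedding, out / "embedding.tsv")
    graph = cna_mod.build_knn_graph(embedding, p.knn_k)
    partition = cna_mod.detect_communities(
        graph, p.gamma_grid, p.n_runs, seed=stage_seed(config.seed, "communities")
    )
    write_partition(z.cell_ids, partition.labels, partition.gamma, out / "partition.tsv")
    manifest["stages"]["communities"] = {
        "seed": stage_seed(config.seed, "communities"),
        "gamma": partition.gamma,
        "n_communities": partition.n_communities,
    }

    # --- segmentation -----------------------------------------------------
    s = config.segmentation
    cell_index = {c: i for i, c in enumerate(matrix.cell_ids)}
    baseline = np.array(
        [cell_index[c] for c in truth.cells.loc[truth.cells["clone"] == "normal", "cell_id"]]
    )
    if baseline.size == 0:  # no normal cells simulated: largest community
        sizes = pd.Series(partition.labels).value_counts()
        baseline = np.flatnonzero(partition.labels == sizes.idxmax())
    kept = [cell_index[c] for c in z.cell_ids]
    labels_kept = np.full(matrix.n_cells, -1)
    labels_kept[kept] = partition.labels
    metacells = seg_mod.make_metacells(
        matrix,
        labels_kept,
        baseline,
        n_meta=s.n_meta,
        frac=s.meta_frac,
        seed=stage_seed(config.seed, "metacells"),
        min_community_size=s.min_community_size,
        min_mean_expression=p.min_mean_expression,
        window=p.window,
        winsorize_bound=p.winsorize_bound,
    )
    params = seg_mod.HmmParams(delta=s.delta, sigma=s.sigma, tau=s.tau)
    profiles = [
        seg_mod.call_community_profile(
            metacells, c, params, min_seg_bins=s.min_seg_bins, flank_bins=s.flank_bins
        )
        for c in metacells.communities()
    ]
    write_segments_bed(profiles, out / "segments.tsv")
    manifest["stages"]["segmentation"] = {
        "seed": stage_seed(config.seed, "metacells"),
        "n_meta": s.n_meta,
        "delta": s.delta,
        "tau": s.tau,
    }

    # --- enrichment -------------------------------------------------------
    clone_of = dict(zip(truth.cells["cell_id"], truth.cells["clone"]))
    clusters = np.array([clone_of[c] for c in z.cell_ids])
    enrichment = seg_mod.enrich_communities(partition.labels, clusters)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    manifest["outputs"] = {
        f.name: _checksum(f)
        for f in sorted(out.rglob("*"))
        if f.is_file() and f.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", out)
    return manifest
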