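"""Shared genome-ordered matrix containers.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "arm"]


def chrom_sort_key(chrom: str):
    """Natural ordering for chromosome names: chr2 < chr10 < chrX."""
    m = re.match(r"(?:chr)?(\d+)$", str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom))


@dataclass
class CountMatrix:
    """Genes x cells matrix with genomic gene annotations.

    ``genes`` must carry at least ``gene_id``, ``chrom`` and ``start``
    columns; ``end`` and ``arm`` are optional but preserved.
    """

    counts: np.ndarray
    genes: pd.DataFrame
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if self.counts.shape[0] != len(self.genes):
            raise ValueError(
                f"gene annotation rows ({len(self.genes)}) do not match "
                f"matrix rows ({self.counts.shape[0]})"
            )
        if self.counts.shape[1] != len(self.cell_ids):
            raise ValueError(
                f"cell ids ({len(self.cell_ids)}) do not match matrix "
                f"columns ({self.counts.shape[1]})"
            )
        dup_genes = self.genes["gene_id"][self.genes["gene_id"].duplicated()]
        if len(dup_genes):
            raise ValueError(f"duplicate gene id: {dup_genes.iloc[0]!r}")
        ids = pd.Series(self.cell_ids)
        dup_cells = ids[ids.duplicated()]
        if len(dup_cells):
            raise ValueError(f"duplicate cell id: {dup_cells.iloc[0]!r}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def sorted_by_position(self) -> "CountMatrix":
        """Return a copy with genes sorted by (chrom, start) in genome order."""
        keys = [chrom_sort_key(c) for c in self.genes["chrom"]]
        order = sorted(
            range(self.n_genes),
            key=lambda i: (keys[i], int(self.genes["start"].iloc[i])),
        )
        genes = self.genes.iloc[order].reset_index(drop=True)
        return CountMatrix(self.counts[order, :], genes, list(self.cell_ids))

    def is_position_sorted(self) -> bool:
        keys = list(
            zip(
                (chrom_sort_key(c) for c in self.genes["chrom"]),
                self.genes["start"].astype(int),
            )
        )
        return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))


@dataclass
class BinnedExpression:
    """Genome-ordered bins x cells matrix.

    Bins never span two chromosomes; ``bins`` has columns chrom,
    first_gene, last_gene (inclusive gene indices), start, end.
    The same container holds raw binned values, Z scores and smoothed /
    winsorized Z scores as the pipeline progresses.
    """

    values: np.ndarray
    bins: pd.DataFrame
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.bins):
            raise ValueError("bin annotation rows do not match matrix rows")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def chrom_blocks(self) -> list[tuple[str, np.ndarray]]:
        """Contiguous runs of bins per chromosome, in genome order."""
        chroms = self.bins["chrom"].to_numpy()
        blocks: list[tuple[str, np.ndarray]] = []
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            blocks.append((chroms[i], np.arange(i, j)))
            i = j
        return blocks
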