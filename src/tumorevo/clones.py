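"""SNV quality filters, clone assignment over the PT/PDX/single-cell sample
quartet, and MRCA allele-specific copy-number reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SAMPLES = ("PT_bulk", "PDX_bulk", "SCS12", "SCS34")

CLONAL = "clonal"
SUBCLONE1 = "subclone1"
SUBCLONE2 = "subclone2"
SUBCLONE3 = "subclone3"
UNASSIGNED = "unassigned"


@dataclass
class SNVObservation:
    snv_id: str
    pt_bulk: bool
    pdx_bulk: bool
    scs12: bool
    scs34: bool
    tlod: float = 0.0
    is_indel: bool = False
    n_cells_genotyped: int = 0


def filter_somatic_for_fishing(
    snvs: list[SNVObservation],
    *,
    min_tlod: float = 40.0,
    min_cells: int = 10,
) -> list[SNVObservation]:
    """Keep non-indel SNVs with TLOD >= 40 genotyped in >= 10 cells (inclusive)."""
    return [
        s
        for s in snvs
        if not s.is_indel and s.tlod >= min_tlod and s.n_cells_genotyped >= min_cells
    ]


def assign_snv_clone(obs: SNVObservation) -> str:
    """Assign an SNV to a clone from its presence pattern across samples.

    Rules in order, first match wins:
      1. present in all four datasets -> clonal
      2. PT_bulk and SCS12, absent from PDX_bulk and SCS34 -> subclone 1
      3. PT_bulk, PDX_bulk and SCS34, absent from SCS12 -> subclone 2
      4. only PDX_bulk and SCS34 -> subclone 3
    Any other pattern is left unassigned.
    """
    pt, pdx, s12, s34 = obs.pt_bulk, obs.pdx_bulk, obs.scs12, obs.scs34
    if pt and pdx and s12 and s34:
        return CLONAL
    if pt and s12 and not s34 and not pdx:
        return SUBCLONE1
    if pt and pdx and s34 and not s12:
        return SUBCLONE2
    if pdx and s34 and not pt and not s12:
        return SUBCLONE3
    return UNASSIGNED


def assign_table(snvs: list[SNVObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {"snv_id": [s.snv_id for s in snvs], "label": [assign_snv_clone(s) for s in snvs]}
    )


# ---------------------------------------------------------------------------
# MRCA copy-number reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AlleleCnPair:
    """Haplotype-specific copy number of one segment in one subclone."""

    segment_id: str
    chrom: str
    start: int
    end: int
    cn_a: int
    cn_b: int

    def __post_init__(self) -> None:
        if self.cn_a < 0 or self.cn_b < 0:
            raise ValueError(f"{self.segment_id}: allele copy numbers must be >= 0")


def _check_profiles(p1: list[AlleleCnPair], p2: list[AlleleCnPair]) -> None:
    if len(p1) != len(p2) or any(
        a.segment_id != b.segment_id for a, b in zip(p1, p2)
    ):
        raise ValueError("profiles must cover the same segments in the same order")


def _neighbor_match(
    idx: int,
    allele: str,
    p1: list[AlleleCnPair],
    p2: list[AlleleCnPair],
    max_distance: int | None,
) -> int | None:
    """Nearest same-chromosome segment whose allele CN is shared between the
    subclones and equals one of the two discordant values; left before right
    at each distance."""
    v1, v2 = getattr(p1[idx], allele), getattr(p2[idx], allele)
    chrom = p1[idx].chrom
    d = 1
    while True:
        candidates = [idx - d, idx + d]
        in_range = False
        for j in candidates:
            if 0 <= j < len(p1) and p1[j].chrom == chrom:
                in_range = True
                shared1, shared2 = getattr(p1[j], allele), getattr(p2[j], allele)
                if shared1 == shared2 and shared1 in (v1, v2):
                    return shared1
        if not in_range:
            return None
        d += 1
        if max_distance is not None and d > max_distance:
            return None


def infer_mrca_cn(
    seg_index: int,
    profile1: list[AlleleCnPair],
    profile2: list[AlleleCnPair],
    *,
    max_neighbor_distance: int | None = None,
) -> tuple[int, int, tuple[str, str]]:
    """MRCA (cn_a, cn_b) for one segment, with the rule used per allele.

    Per allele, in order: (1) equal in both subclones -> that value;
    (2) LOH in exactly one subclone -> the retained (non-zero) value;
    (3) a nearest same-chromosome neighbor with shared allele CN matching
    one of the discordant values -> that value; (4) the minimum of the two.
    """
    _check_profiles(profile1, profile2)
    result, rules = [], []
    for allele in ("cn_a", "cn_b"):
        v1 = getattr(profile1[seg_index], allele)
        v2 = getattr(profile2[seg_index], allele)
        if v1 == v2:
            result.append(v1)
            rules.append("equal")
        elif (v1 == 0) != (v2 == 0):
            result.append(max(v1, v2))
            rules.append("loh")
        else:
            match = _neighbor_match(
                seg_index, allele, profile1, profile2, max_neighbor_distance
            )
            if match is not None:
                result.append(match)
                rules.append("neighbor")
            else:
                result.append(min(v1, v2))
                rules.append("minimum")
    return result[0], result[1], (rules[0], rules[1])


def infer_mrca_profile(
    profile1: list[AlleleCnPair],
    profile2: list[AlleleCnPair],
    *,
    max_neighbor_distance: int | None = None,
) -> pd.DataFrame:
    """Apply the MRCA heuristics to every segment of two aligned profiles."""
    _check_profiles(profile1, profile2)
    rows = []
    for i, seg in enumerate(profile1):
        cn_a, cn_b, (rule_a, rule_b) = infer_mrca_cn(
            i, profile1, profile2, max_neighbor_distance=max_neighbor_distance
        )
        rows.append(
            {
                "segment_id": seg.segment_id,
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "cn_a": cn_a,
                "cn_b": cn_b,
                "rule_a": rule_a,
                "rule_b": rule_b,
            }
        )
    return pd.DataFrame(rows)
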