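"""Assignment of SNPs to gene neighborhoods.

A SNP belongs to a gene's set when it lies on the same chromosome within
``window`` bp of the gene body, boundaries inclusive on both ends:
``start - window <= pos <= end + window`` (default window 500 kb).  Distance
is measured from the gene body boundaries, not the midpoint or TSS.  A SNP
inside two overlapping neighborhoods is kept in both sets — no nearest-gene
tie-break; collinearity between overlapping sets is handled and reported by
the modelling stage.  All coordinates are 1-based inclusive internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneSnpSet",
    "AssignmentReport",
    "AssignmentError",
    "assign_snps_to_genes",
    "summarize_assignment",
]


class AssignmentError(ValueError):
    """Raised when SNPs cannot be assigned (e.g. unknown chromosome label)."""


@dataclass(frozen=True)
class GeneSnpSet:
    """An ordered SNP set treated downstream as one composite genotype.

    ``snp_ids`` are ordered by ascending position (ties by id), which fixes
    the token order of the composite labels.
    """

    gene: str
    snp_ids: tuple[str, ...]

    @property
    def empty(self) -> bool:
        return len(self.snp_ids) == 0

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class AssignmentReport:
    """Counts summarizing one SNP-to-gene assignment."""

    n_distinct_snps: int
    per_gene: dict[str, int]
    shared_snps: tuple[str, ...]  # SNPs belonging to >= 2 genes
    empty_genes: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.per_gene),
             "n_snps": list(self.per_gene.values()),
             "empty": [g in set(self.empty_genes) for g in self.per_gene]}
        )


def assign_snps_to_genes(
    snp_map: pd.DataFrame,
    regions: pd.DataFrame,
    window: int = 500_000,
) -> list[GeneSnpSet]:
    """Collate each gene's SNPs within ``window`` bp of the gene body.

    Parameters
    ----------
    snp_map
        DataFrame with columns ``snp_id, chrom, pos`` (1-based).
    regions
        DataFrame with columns ``gene, chrom, start, end`` (1-based
        inclusive, ``start <= end``).
    window
        Neighborhood half-width in bp (>= 0); both boundary ends inclusive.

    Returns
    -------
    One :class:`GeneSnpSet` per region row, in region order.  Genes whose
    neighborhood contains no SNP are returned with empty sets (callers
    flag/skip them); an unknown chromosome label raises
    :class:`AssignmentError`.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if regions["start"].gt(regions["end"]).any():
        bad = regions[regions["start"] > regions["end"]].iloc[0]
        raise AssignmentError(f"region {bad['gene']!r} has start > end")
    known = set(snp_map["chrom"].unique())
    out = []
    by_chrom = {c: grp.sort_values(["pos", "snp_id"], kind="mergesort")
                for c, grp in snp_map.groupby("chrom", sort=False)}
    for _, r in regions.iterrows():
        if r["chrom"] not in known:
            raise AssignmentError(
                f"unknown chromosome label {r['chrom']!r} for gene {r['gene']!r}")
        grp = by_chrom[r["chrom"]]
        pos = grp["pos"].to_numpy()
        lo, hi = r["start"] - window, r["end"] + window
        sel = grp["snp_id"].to_numpy()[(pos >= lo) & (pos <= hi)]
        out.append(GeneSnpSet(gene=str(r["gene"]), snp_ids=tuple(sel)))
    return out


def summarize_assignment(gene_sets: list[GeneSnpSet]) -> AssignmentReport:
    """Tally distinct SNPs, per-gene counts, shared SNPs and empty genes."""
    per_gene = {gs.gene: len(gs) for gs in gene_sets}
    counts: dict[str, int] = {}
    for gs in gene_sets:
        for s in gs.snp_ids:
            counts[s] = counts.get(s, 0) + 1
    shared = tuple(sorted(s for s, c in counts.items() if c >= 2))
    empty = tuple(gs.gene for gs in gene_sets if gs.empty)
    return AssignmentReport(
        n_distinct_snps=len(counts),
        per_gene=per_gene,
        shared_snps=shared,
        empty_genes=empty,
    )
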