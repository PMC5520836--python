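"""Per-gene SNP tabulation: gene DNA span versus mRNA (exonic) SNP counts.

For a user-supplied list of named gene loci, counts SNPs falling in the
gene's genomic span (optionally extended by a flank) and in its mRNA —
the exon union by default, or the CDS only in ``cds_only`` mode (the
stricter "coding regions" reading).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import GeneModel, SnpRecord

MRNA_MODES = ("exon_union", "cds_only")


@dataclass
class GeneVariationReport:
    """SNP counts for one gene locus."""

    name: str
    gene_id: str
    dna_count: int  # SNPs in [tx_start - flank, tx_end + flank]
    mrna_count: int  # SNPs in exon union (or CDS only)


@dataclass
class GeneVariationResult:
    reports: list
    not_found: list  # requested names that resolved to no model

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Gene": [r.name for r in self.reports],
                "DNA": [r.dna_count for r in self.reports],
                "mRNA": [r.mrna_count for r in self.reports],
            }
        )


def count_gene_variants(
    snps: Sequence[SnpRecord],
    models: Sequence[GeneModel],
    gene_list: Sequence[str],
    flank: int = 0,
    mrna_mode: str = "exon_union",
) -> GeneVariationResult:
    """Count SNPs per named gene, in gene-list order.

    ``gene_list`` entries resolve against model ``gene_id`` first, then
    ``name``; unresolved entries are collected in ``not_found`` rather
    than raising.
    """
    if mrna_mode not in MRNA_MODES:
        raise ValueError(f"unknown mrna_mode {mrna_mode!r}; choose from {MRNA_MODES}")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_key: dict[str, GeneModel] = {}
    for m in models:
        by_key.setdefault(m.gene_id, m)
    for m in models:
        if m.name:
            by_key.setdefault(m.name, m)

    positions: dict[str, list[int]] = {}
    for r in snps:
        positions.setdefault(r.chrom, []).append(r.pos)
    for chrom in positions:
        positions[chrom].sort()

    reports, not_found = [], []
    for entry in gene_list:
        model = by_key.get(entry)
        if model is None:
            not_found.append(entry)
            continue
        pos = positions.get(model.chrom, [])
        dna = _count_in(pos, max(1, model.tx_start - flank), model.tx_end + flank)
        intervals = model.cds if mrna_mode == "cds_only" else model.exons
        mrna = sum(_count_in(pos, s, e) for s, e in intervals)
        reports.append(
            GeneVariationReport(
                name=entry, gene_id=model.gene_id, dna_count=dna, mrna_count=mrna
            )
        )
    return GeneVariationResult(reports=reports, not_found=not_found)


def _count_in(sorted_positions: list[int], start: int, end: int) -> int:
    return bisect_right(sorted_positions, end) - bisect_left(sorted_positions, start)


def read_gene_list(path) -> list[str]:
    """Read a one- or two-column gene list (name [tab gene_id]); returns the
    identifiers to resolve, preferring the second column when present."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            out.append(fields[1] if len(fields) > 1 else fields[0])
    return out
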