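"""Identification of focal-line-specific SNPs against N comparison lines.

A focal SNP locus is *specific* when the comparison lines' genotypes at
that locus are mutually identical (as allele sets) and differ from the
focal genotype.  All call sets must share one reference.  Two policies
govern loci where a comparison line has no call: ``absent_as_reference``
imputes the homozygous reference genotype; ``require_covered`` drops loci
uncovered in any comparison line (counting them separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .records import CoverageMask, SnpRecord, natural_sort_key

POLICIES = ("absent_as_reference", "require_covered")


@dataclass
class SpecificityResult:
    """Focal-specific loci plus bookkeeping."""

    specific: list  # [(chrom, pos, frozenset focal alleles)]
    policy: str
    n_comparison_lines: int
    excluded_uncovered: int = 0  # loci dropped under require_covered

    @property
    def loci(self) -> set:
        return {(c, p) for c, p, _ in self.specific}

    def per_chromosome(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for chrom, _, _ in self.specific:
            counts[chrom] = counts.get(chrom, 0) + 1
        return counts


def _index_by_locus(records: Sequence[SnpRecord], refs: dict) -> dict:
    table = {}
    for r in records:
        key = (r.chrom, r.pos)
        prev = refs.get(key)
        if prev is not None and prev != r.ref_base:
            raise ValueError(
                f"reference mismatch at {r.chrom}:{r.pos}: {prev} vs {r.ref_base} "
                "(tables were not called against the same reference)"
            )
        refs[key] = r.ref_base
        table[key] = r
    return table


def identify_specific_snps(
    focal: Sequence[SnpRecord],
    others: Sequence[Sequence[SnpRecord]],
    masks: Optional[Sequence[Optional[CoverageMask]]] = None,
    policy: str = "absent_as_reference",
    must_match_reference: bool = False,
) -> SpecificityResult:
    """Return the focal line's specific SNP loci.

    ``others`` is a sequence of N >= 1 comparison call sets;
    ``masks`` optionally gives each comparison line's coverage mask (same
    order), used by the ``require_covered`` policy — a line without a mask
    is treated as fully covered.  ``must_match_reference`` additionally
    requires the comparison lines to carry the reference genotype, not
    merely to agree with each other.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if not others:
        raise ValueError("need at least one comparison line")
    if masks is not None and len(masks) != len(others):
        raise ValueError("masks must parallel the comparison tables")

    refs: dict = {}
    other_tables = [_index_by_locus(table, refs) for table in others]
    focal_table = _index_by_locus(focal, refs)

    specific = []
    excluded = 0
    for (chrom, pos), rec in sorted(
        focal_table.items(), key=lambda kv: (natural_sort_key(kv[0][0]), kv[0][1])
    ):
        ref_set = frozenset({rec.ref_base})
        focal_set = rec.alleles
        other_sets = []
        drop = False
        for i, table in enumerate(other_tables):
            other_rec = table.get((chrom, pos))
            if other_rec is not None:
                other_sets.append(other_rec.alleles)
                continue
            covered = (
                masks is None
                or masks[i] is None
                or masks[i].is_covered(chrom, pos)
            )
            if policy == "require_covered" and not covered:
                drop = True
                break
            other_sets.append(ref_set)  # no call at a covered locus => reference
        if drop:
            excluded += 1
            continue
        first = other_sets[0]
        if any(s != first for s in other_sets[1:]):
            continue
        if must_match_reference and first != ref_set:
            continue
        if first != focal_set:
            specific.append((chrom, pos, focal_set))

    return SpecificityResult(
        specific=specific,
        policy=policy,
        n_comparison_lines=len(others),
        excluded_uncovered=excluded,
    )


def summarize_specific_by_chromosome(
    result: SpecificityResult, chroms: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-chromosome specific-SNP counts plus a genome total row.

    Chromosomes are listed in natural sort order; ``chroms`` may supply
    the full chromosome set so that zero rows appear.
    """
    counts = result.per_chromosome()
    names = set(counts) | set(chroms or ())
    ordered = sorted(names, key=natural_sort_key)
    df = pd.DataFrame(
        {"specific_snps": [counts.get(c, 0) for c in ordered]},
        index=pd.Index(ordered, name="Chr"),
    )
    df.loc["Total"] = df.sum()
    return df
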