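"""Codon-level functional-effect classification of SNPs against gene models.

Each SNP is assigned a genomic region per overlapping gene model
(intergenic / intron / UTR / CDS) and, for CDS hits, a coding effect under
the standard nuclear genetic code: synonymous, nonsynonymous, or one of
three large-effect classes — premature stop (nonsense), start loss
(initiation-codon change) and stop loss (termination-codon change).  A
change that turns the terminal stop into a *different* stop codon is
synonymous, not stop loss.

Codons are reconstructed in spliced, strand-oriented CDS coordinates
(reverse-complemented for minus-strand models); every non-reference allele
of a (possibly heterozygous) genotype is evaluated and the most severe
effect is reported, ties broken by alphabetical alternate allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .records import GeneModel, SnpRecord, natural_sort_key

logger = logging.getLogger(__name__)

#: codon -> single-letter amino acid, stops as "*"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: effect severity for picking one effect per SNP (large-effect classes tie)
SEVERITY = {
    "none": 0,
    "deferred": 0,
    "synonymous": 1,
    "nonsynonymous": 2,
    "premature_stop": 3,
    "start_loss": 3,
    "stop_loss": 3,
}

LARGE_EFFECT = ("premature_stop", "start_loss", "stop_loss")


@dataclass
class EffectAnnotation:
    """Region + coding-effect call for one SNP against one gene model."""

    chrom: str
    pos: int
    gene_id: Optional[str]
    region: str  # intergenic | intron | utr | cds
    coding_effect: str = "none"  # none | deferred | synonymous | ... (see SEVERITY)
    alt_allele: Optional[str] = None
    codon_index: Optional[int] = None  # 1-based codon number in the CDS
    codon_position: Optional[int] = None  # 1-based position within the codon
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None


def classify_codon_change(
    codon_index0: int, n_codons: int, ref_codon: str, alt_codon: str
) -> str:
    """Name the effect of one codon substitution (0-based codon index)."""
    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
    if codon_index0 == 0:
        # any change away from the annotated ATG abolishes initiation
        return "start_loss" if alt_codon != "ATG" else "synonymous"
    if codon_index0 == n_codons - 1:
        if ref_aa == "*" and alt_aa != "*":
            return "stop_loss"
        return "synonymous" if alt_aa == ref_aa else "nonsynonymous"
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "premature_stop"
    return "nonsynonymous"


def annotate_effect(
    snp: SnpRecord,
    models: Sequence[GeneModel],
    genome: dict[str, str],
) -> list[EffectAnnotation]:
    """Annotate one SNP against every overlapping gene model.

    Returns one annotation per overlapping model, or a single intergenic
    annotation when none overlaps.  The SNP's stated reference base must
    equal the genome base at its position.  Invalid (flagged) models yield
    region calls only, with ``coding_effect="deferred"`` for CDS hits.
    """
    genome_base = genome[snp.chrom][snp.pos - 1]
    if genome_base != snp.ref_base:
        raise ValueError(
            f"{snp.chrom}:{snp.pos}: record ref_base {snp.ref_base} does not match "
            f"genome base {genome_base}"
        )
    annotations = []
    for model in models:
        if model.chrom != snp.chrom or not (model.tx_start <= snp.pos <= model.tx_end):
            continue
        annotations.append(_annotate_in_model(snp, model, genome))
    if not annotations:
        annotations.append(
            EffectAnnotation(
                chrom=snp.chrom, pos=snp.pos, gene_id=None, region="intergenic"
            )
        )
    return annotations


def _annotate_in_model(
    snp: SnpRecord, model: GeneModel, genome: dict[str, str]
) -> EffectAnnotation:
    region = model.region_of(snp.pos)
    ann = EffectAnnotation(
        chrom=snp.chrom, pos=snp.pos, gene_id=model.gene_id, region=region
    )
    if region != "cds":
        return ann
    if not model.valid:
        ann.coding_effect = "deferred"
        logger.warning(
            "SNP %s:%d falls in flagged-invalid model %s; effect deferred",
            snp.chrom, snp.pos, model.gene_id,
        )
        return ann

    spliced = model.spliced_cds(genome)
    n_codons = len(spliced) // 3
    cds_index = model.cds_index_of(snp.pos)
    codon_i0, codon_pos0 = divmod(cds_index, 3)
    ref_codon = spliced[3 * codon_i0 : 3 * codon_i0 + 3]

    best = None
    for alt in snp.alt_alleles:  # alphabetical => deterministic tie-break
        oriented = alt if model.strand == "+" else _COMP[alt]
        alt_codon = (
            ref_codon[:codon_pos0] + oriented + ref_codon[codon_pos0 + 1 :]
        )
        effect = classify_codon_change(codon_i0, n_codons, ref_codon, alt_codon)
        if best is None or SEVERITY[effect] > SEVERITY[best[0]]:
            best = (effect, alt, alt_codon)
    if best is None:  # genotype carried only the reference allele
        return ann
    effect, alt, alt_codon = best
    ann.coding_effect = effect
    ann.alt_allele = alt
    ann.codon_index = codon_i0 + 1
    ann.codon_position = codon_pos0 + 1
    ann.ref_codon = ref_codon
    ann.alt_codon = alt_codon
    ann.ref_aa = CODON_TABLE[ref_codon]
    ann.alt_aa = CODON_TABLE[alt_codon]
    return ann


def annotate_all(
    snps: Sequence[SnpRecord],
    models: Sequence[GeneModel],
    genome: dict[str, str],
) -> list[EffectAnnotation]:
    """Annotate many SNPs; returns the concatenated annotation list."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: list[EffectAnnotation] = []
    for snp in snps:
        out.extend(annotate_effect(snp, by_chrom.get(snp.chrom, ()), genome))
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_MRNA_REGIONS = {"utr", "intron", "cds"}


def _most_severe_per_snp(
    annotations: Sequence[EffectAnnotation],
) -> dict[tuple, EffectAnnotation]:
    """Collapse SNP x gene annotations to one per SNP (most severe;
    among equal severities the one in mRNA wins, then first seen)."""
    best: dict[tuple, EffectAnnotation] = {}
    for ann in annotations:
        key = (ann.chrom, ann.pos)
        cur = best.get(key)
        if cur is None:
            best[key] = ann
            continue
        rank = (SEVERITY[ann.coding_effect], ann.region in _MRNA_REGIONS)
        cur_rank = (SEVERITY[cur.coding_effect], cur.region in _MRNA_REGIONS)
        if rank > cur_rank:
            best[key] = ann
    return best


def summarize_effects(
    annotations: Sequence[EffectAnnotation],
    chroms: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chromosome-level effect summaries, each SNP counted once.

    Returns ``(coding_summary, large_effect_summary)``: the first has
    columns Syn_CDS / Non-syn_CDS / mRNA (mRNA = SNPs anywhere in the
    transcript span: UTR, intron or CDS), the second one column per
    large-effect class.  Both carry a totals row equal to the column sums.
    """
    best = _most_severe_per_snp(annotations)
    names = set(chroms or ()) | {c for c, _ in best}
    ordered = sorted(names, key=natural_sort_key)
    idx = {c: i for i, c in enumerate(ordered)}

    coding = pd.DataFrame(
        0, index=pd.Index(ordered, name="Chr"),
        columns=["Syn_CDS", "Non-syn_CDS", "mRNA"],
    )
    large = pd.DataFrame(
        0, index=pd.Index(ordered, name="Chr"), columns=list(LARGE_EFFECT)
    )
    for (chrom, _), ann in best.items():
        if ann.region in _MRNA_REGIONS:
            coding.loc[chrom, "mRNA"] += 1
        if ann.coding_effect == "synonymous":
            coding.loc[chrom, "Syn_CDS"] += 1
        elif ann.coding_effect == "nonsynonymous":
            coding.loc[chrom, "Non-syn_CDS"] += 1
        elif ann.coding_effect in LARGE_EFFECT:
            large.loc[chrom, ann.coding_effect] += 1
    coding.loc["Total"] = coding.sum()
    large.loc["Total"] = large.sum()
    return coding, large


def annotations_to_frame(annotations: Sequence[EffectAnnotation]) -> pd.DataFrame:
    """Per-SNP annotation table (one row per SNP x gene)."""
    return pd.DataFrame(
        {
            "chrom": [a.chrom for a in annotations],
            "pos": [a.pos for a in annotations],
            "gene_id": [a.gene_id or "." for a in annotations],
            "region": [a.region for a in annotations],
            "effect": [a.coding_effect for a in annotations],
            "alt": [a.alt_allele or "." for a in annotations],
            "codon": [
                f"{a.ref_codon}>{a.alt_codon}" if a.ref_codon else "."
                for a in annotations
            ],
            "aa": [
                f"{a.ref_aa}{a.codon_index}{a.alt_aa}" if a.ref_aa else "."
                for a in annotations
            ],
        }
    )
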