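"""Readers and writers for the variant-analysis file formats.

Three custom whitespace-delimited variant tables (18-column SNP consensus,
9-column InDel, 10-column SV), plus the surrounding standard formats:
reference FASTA, GFF3 gene models, BED coverage masks (0-based half-open,
converted to the package's 1-based inclusive convention on read) and VCF 4.2
export of SNP calls.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CoverageMask,
    GeneModel,
    IndelRecord,
    SnpRecord,
    SvRecord,
    natural_sort_key,
)

logger = logging.getLogger(__name__)


class TableReadResult(list):
    """A list of parsed records carrying a ``skipped`` line count
    (populated in lenient mode)."""

    def __init__(self, records=(), skipped: int = 0):
        super().__init__(records)
        self.skipped = skipped


# ---------------------------------------------------------------------------
# 18-column SNP consensus table
# ---------------------------------------------------------------------------

_SNP_FIELDS = 18


def _parse_snp_line(fields: list[str]) -> SnpRecord:
    if len(fields) != _SNP_FIELDS:
        raise ValueError(f"expected {_SNP_FIELDS} fields, got {len(fields)}")
    rec = SnpRecord(
        chrom=fields[0],
        pos=int(fields[1]),
        ref_base=fields[2].upper(),
        genotype=fields[3].upper(),
        quality=int(fields[4]),
        best_base=fields[5].upper(),
        best_quality=int(fields[6]),
        best_unique_reads=int(fields[7]),
        best_all_reads=int(fields[8]),
        second_base=fields[9].upper(),
        second_quality=int(fields[10]),
        second_unique_reads=int(fields[11]),
        second_all_reads=int(fields[12]),
        total_reads=int(fields[13]),
        rank_field=fields[14],
        copy_number=float(fields[15]),
        in_dbsnp=int(fields[16]),
        nearest_snp_distance=int(fields[17]),
    )
    rec.validate()
    return rec


def read_snp_table(path, strict: bool = True) -> TableReadResult:
    """Read an 18-column SNP consensus table.

    In strict mode any malformed line raises ``ValueError`` naming the line
    number; in lenient mode malformed lines are skipped with a logged
    warning and counted in the result's ``skipped`` attribute.
    """
    return _read_table(path, _parse_snp_line, strict, "SNP")


def write_snp_table(path, records: Sequence[SnpRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.chrom, r.pos, r.ref_base, r.genotype, r.quality,
                        r.best_base, r.best_quality, r.best_unique_reads,
                        r.best_all_reads, r.second_base, r.second_quality,
                        r.second_unique_reads, r.second_all_reads,
                        r.total_reads, r.rank_field, r.copy_number,
                        r.in_dbsnp, r.nearest_snp_distance,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# 9-column InDel table
# ---------------------------------------------------------------------------


def _parse_indel_type(field: str) -> tuple[str, int]:
    """Parse the combined "indel type and number" field.

    Primary dialect is a letter I/D followed by the length ("I2", "D3");
    "+2"/"-3" is accepted as a tolerated dialect.
    """
    field = field.strip()
    if not field:
        raise ValueError("empty indel type field")
    head, rest = field[0], field[1:]
    kind = {"I": "insertion", "+": "insertion", "D": "deletion", "-": "deletion"}.get(
        head.upper() if head.isalpha() else head
    )
    if kind is None or not rest.isdigit():
        raise ValueError(f"cannot parse indel type field {field!r}")
    return kind, int(rest)


def _format_indel_type(kind: str, length: int) -> str:
    return ("I" if kind == "insertion" else "D") + str(length)


def _parse_indel_line(fields: list[str]) -> IndelRecord:
    if len(fields) != 9:
        raise ValueError(f"expected 9 fields, got {len(fields)}")
    kind, length = _parse_indel_type(fields[2])
    rec = IndelRecord(
        chrom=fields[0],
        pos=int(fields[1]),
        indel_kind=kind,
        indel_length=length,
        bases=fields[3].upper(),
        strand=fields[4],
        zygosity=fields[5].lower(),
        mean_quality=float(fields[6]),
        support_pairs=int(fields[7]),
        crossing_pairs=int(fields[8]),
    )
    rec.validate()
    return rec


def read_indel_table(path, strict: bool = True) -> TableReadResult:
    """Read a 9-column InDel table (see :func:`read_snp_table` for modes)."""
    return _read_table(path, _parse_indel_line, strict, "InDel")


def write_indel_table(path, records: Sequence[IndelRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.chrom, r.pos,
                        _format_indel_type(r.indel_kind, r.indel_length),
                        r.bases, r.strand, r.zygosity, r.mean_quality,
                        r.support_pairs, r.crossing_pairs,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# 10-column SV table
# ---------------------------------------------------------------------------

_MISSING = "."


def _parse_sv_line(fields: list[str]) -> SvRecord:
    if len(fields) != 10:
        raise ValueError(f"expected 10 fields, got {len(fields)}")
    breakpoint_field = fields[7]
    breakpoint = None if breakpoint_field == _MISSING else int(breakpoint_field)
    rec = SvRecord(
        chrom=fields[0],
        sv_type=fields[1],
        cluster_start_min=int(fields[2]),
        cluster_end_max=int(fields[3]),
        est_start=int(fields[4]),
        est_end=int(fields[5]),
        sv_length=int(fields[6]),
        insertion_breakpoint=breakpoint,
        match_mode=fields[8],
        support_pairs=int(fields[9]),
    )
    rec.validate()
    return rec


def read_sv_table(path, strict: bool = True) -> TableReadResult:
    """Read a 10-column SV table.  The breakpoint column (8) holds "." for
    every SV type except insertion."""
    return _read_table(path, _parse_sv_line, strict, "SV")


def write_sv_table(path, records: Sequence[SvRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            bp = _MISSING if r.insertion_breakpoint is None else r.insertion_breakpoint
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.chrom, r.sv_type, r.cluster_start_min,
                        r.cluster_end_max, r.est_start, r.est_end,
                        r.sv_length, bp, r.match_mode, r.support_pairs,
                    )
                )
                + "\n"
            )


def _read_table(path, parse_line, strict: bool, what: str) -> TableReadResult:
    path = Path(path)
    result = TableReadResult()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()  # any run of tabs/spaces
            try:
                result.append(parse_line(fields))
            except (ValueError, IndexError) as exc:
                if strict:
                    raise ValueError(
                        f"{path}:{lineno}: malformed {what} line: {exc}"
                    ) from exc
                logger.warning("%s:%d: skipping malformed %s line: %s", path, lineno, what, exc)
                result.skipped += 1
    return result


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a {name: uppercase sequence} map."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, genome: dict[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(
    path,
    genome: Optional[dict[str, str]] = None,
    strict: bool = False,
) -> list[GeneModel]:
    """Read gene models from a GFF3 gene -> mRNA -> exon/CDS hierarchy.

    One :class:`GeneModel` is built per mRNA.  Models failing validation
    (overlapping exons, CDS length not divisible by 3, and — when
    ``genome`` is given — a spliced CDS not starting with ATG or not
    ending in a stop) are flagged invalid and logged; in strict mode they
    raise instead.
    """
    mrna_meta: dict[str, dict] = {}
    gene_names: dict[str, str] = {}
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line (need 9 columns): {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attrs = _gff3_attributes(attrs)
            ival = (int(start), int(end))
            if ftype == "gene":
                gid = attrs.get("ID", "")
                if "Name" in attrs:
                    gene_names[gid] = attrs["Name"]
            elif ftype == "mRNA":
                mid = attrs["ID"]
                mrna_meta[mid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "span": ival,
                    "parent": attrs.get("Parent", mid),
                    "name": attrs.get("Name"),
                }
            elif ftype == "exon":
                exons.setdefault(attrs["Parent"], []).append(ival)
            elif ftype == "CDS":
                cds.setdefault(attrs["Parent"], []).append(ival)
    models = []
    for mid, meta in mrna_meta.items():
        model = GeneModel(
            gene_id=meta["parent"],
            chrom=meta["chrom"],
            strand=meta["strand"],
            tx_start=meta["span"][0],
            tx_end=meta["span"][1],
            exons=sorted(exons.get(mid, [])),
            cds=sorted(cds.get(mid, [])),
            name=meta["name"] or gene_names.get(meta["parent"]),
        )
        model.validate(genome=genome, strict=strict)
        if not model.valid:
            logger.warning(
                "gene model %s flagged invalid: %s", model.gene_id, model.invalid_reason
            )
        models.append(model)
    models.sort(key=lambda m: (natural_sort_key(m.chrom), m.tx_start))
    return models


def write_gff3(path, models: Sequence[GeneModel], chrom_lengths: Optional[dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom in sorted(chrom_lengths, key=natural_sort_key):
                fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for m in models:
            name_attr = f";Name={m.name}" if m.name else ""
            fh.write(
                f"{m.chrom}\tricevar\tgene\t{m.tx_start}\t{m.tx_end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}{name_attr}\n"
            )
            mid = f"{m.gene_id}.1"
            fh.write(
                f"{m.chrom}\tricevar\tmRNA\t{m.tx_start}\t{m.tx_end}\t.\t{m.strand}\t.\t"
                f"ID={mid};Parent={m.gene_id}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tricevar\texon\t{s}\t{e}\t.\t{m.strand}\t.\tParent={mid}\n"
                )
            for s, e in m.cds:
                fh.write(
                    f"{m.chrom}\tricevar\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\tParent={mid}\n"
                )


# ---------------------------------------------------------------------------
# BED coverage masks
# ---------------------------------------------------------------------------


def read_bed_mask(path) -> CoverageMask:
    """Read a BED file (0-based half-open) into a 1-based inclusive mask.

    BED ``chrom 0 100`` covers 1-based positions 1..100.
    """
    intervals: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"empty/negative BED interval: {line!r}")
            intervals.setdefault(chrom, []).append((start + 1, end))
    return CoverageMask(intervals)


def write_bed_mask(path, mask: CoverageMask) -> None:
    with open(path, "w") as fh:
        for chrom in mask.chroms:
            for s, e in mask.intervals(chrom):
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------


def export_vcf(
    snps: Sequence[SnpRecord],
    reference: Optional[dict[str, str]] = None,
    sample: str = "SAMPLE",
) -> str:
    """Render SNP records as VCF 4.2 text.

    ALT alleles are the non-reference bases expanded from the IUPAC
    genotype; GT is 1/1 for a homozygous non-reference call, 0/1 for a het
    containing the reference and 1/2 for a het of two non-reference
    alleles.  Records whose genotype equals the reference base carry no
    ALT and are skipped with a warning.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    ]
    if reference:
        for chrom in sorted(reference, key=natural_sort_key):
            lines.append(f"##contig=<ID={chrom},length={len(reference[chrom])}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    n_skipped = 0
    for r in sorted(snps, key=lambda r: (natural_sort_key(r.chrom), r.pos)):
        alts = list(r.alt_alleles)
        if not alts:
            logger.warning(
                "%s:%d genotype %s identical to reference; skipped from VCF",
                r.chrom, r.pos, r.genotype,
            )
            n_skipped += 1
            continue
        if r.ref_base in r.alleles:
            gt = "0/1"
        elif len(alts) == 1:
            gt = "1/1"
        else:
            gt = "1/2"
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref_base}\t{','.join(alts)}\t{r.quality}"
            f"\tPASS\tDP={r.total_reads}\tGT\t{gt}"
        )
    if n_skipped:
        logger.warning("export_vcf skipped %d reference-genotype records", n_skipped)
    return "\n".join(lines) + "\n"
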