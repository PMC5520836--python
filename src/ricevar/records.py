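"""Domain types for re-sequencing variant analysis.

All genomic coordinates are 1-based inclusive throughout the package
(SOAPsnp-style consensus convention); BED input/output is converted at the
boundary by :mod:`ricevar.variant_io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

#: IUPAC nucleotide code -> frozenset of concrete bases it denotes.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}

#: frozenset of one or two bases -> IUPAC code (inverse of the above,
#: restricted to the diploid-genotype cases this package emits).
BASES_TO_IUPAC: dict[frozenset[str], str] = {
    bases: code for code, bases in IUPAC_TO_BASES.items() if len(bases) <= 2
}

VALID_BASES = frozenset("ACGT")


def expand_iupac(code: str) -> frozenset[str]:
    """Expand an IUPAC nucleotide code into its set of concrete bases.

    ``R`` -> ``{A, G}``; plain bases map to singletons.  Raises
    ``ValueError`` for anything that is not a valid code.
    """
    try:
        return IUPAC_TO_BASES[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def iupac_for(bases: frozenset[str] | set[str]) -> str:
    """Return the IUPAC code for a set of one or two bases."""
    return BASES_TO_IUPAC[frozenset(bases)]


_NATSORT_RE = re.compile(r"(\d+)")


def natural_sort_key(name: str) -> tuple:
    """Sort key putting chr2 before chr10 (digit runs compared numerically)."""
    return tuple(
        int(part) if part.isdigit() else part.lower()
        for part in _NATSORT_RE.split(name)
    )


# ---------------------------------------------------------------------------
# variant records (the three custom table formats)
# ---------------------------------------------------------------------------


@dataclass
class SnpRecord:
    """One consensus SNP call (18-column SOAPsnp-style consensus line).

    ``genotype`` may be an IUPAC ambiguity code encoding a heterozygous
    call; ``rank_field`` (column 15, "order and quality value") is carried
    as opaque text and never interpreted.
    """

    chrom: str
    pos: int
    ref_base: str
    genotype: str
    quality: int
    best_base: str
    best_quality: int
    best_unique_reads: int
    best_all_reads: int
    second_base: str
    second_quality: int
    second_unique_reads: int
    second_all_reads: int
    total_reads: int
    rank_field: str
    copy_number: float
    in_dbsnp: int
    nearest_snp_distance: int

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base not in VALID_BASES:
            raise ValueError(f"ref_base must be A/C/G/T, got {self.ref_base!r}")
        expand_iupac(self.genotype)  # raises on invalid code
        for fname in (
            "best_unique_reads",
            "best_all_reads",
            "second_unique_reads",
            "second_all_reads",
            "total_reads",
        ):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0")
        if self.best_unique_reads > self.best_all_reads:
            raise ValueError("best_unique_reads > best_all_reads")
        if self.in_dbsnp not in (0, 1):
            raise ValueError(f"in_dbsnp must be 0 or 1, got {self.in_dbsnp}")

    @property
    def alleles(self) -> frozenset[str]:
        """Concrete allele set encoded by the genotype."""
        return expand_iupac(self.genotype)

    @property
    def alt_alleles(self) -> tuple[str, ...]:
        """Non-reference alleles, alphabetically ordered."""
        return tuple(sorted(self.alleles - {self.ref_base}))


@dataclass
class IndelRecord:
    """One short insertion/deletion call (9-column format)."""

    chrom: str
    pos: int
    indel_kind: str  # "insertion" | "deletion"
    indel_length: int
    bases: str
    strand: str  # + | - | *
    zygosity: str  # hom | het
    mean_quality: float
    support_pairs: int
    crossing_pairs: int

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.indel_kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel_kind {self.indel_kind!r}")
        if self.indel_length < 1:
            raise ValueError("indel_length must be >= 1")
        if len(self.bases) != self.indel_length:
            raise ValueError(
                f"bases length {len(self.bases)} != indel_length {self.indel_length}"
            )
        if self.strand not in ("+", "-", "*"):
            raise ValueError(f"strand must be +/-/*, got {self.strand!r}")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity must be hom/het, got {self.zygosity!r}")
        if self.support_pairs > self.crossing_pairs:
            raise ValueError("support_pairs > crossing_pairs")


@dataclass
class SvRecord:
    """One structural-variant call (10-column format).

    ``insertion_breakpoint`` is populated only when ``sv_type`` is
    ``insertion``; ``match_mode`` is a string over {F, R} describing the
    unusual read-pair orientation.
    """

    chrom: str
    sv_type: str
    cluster_start_min: int
    cluster_end_max: int
    est_start: int
    est_end: int
    sv_length: int
    insertion_breakpoint: Optional[int]
    match_mode: str
    support_pairs: int

    def validate(self) -> None:
        if not (
            self.cluster_start_min <= self.est_start <= self.est_end <= self.cluster_end_max
        ):
            raise ValueError(
                "require cluster_start_min <= est_start <= est_end <= cluster_end_max"
            )
        if self.sv_length < 0:
            raise ValueError("sv_length must be >= 0")
        if self.insertion_breakpoint is not None and self.sv_type != "insertion":
            raise ValueError("insertion_breakpoint only valid for sv_type=insertion")
        if self.match_mode and set(self.match_mode) - set("FR"):
            raise ValueError(f"match_mode must be over {{F,R}}, got {self.match_mode!r}")
        if self.support_pairs < 0:
            raise ValueError("support_pairs must be >= 0")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 1-based inclusive


def _check_sorted_disjoint(intervals: list[Interval], what: str) -> None:
    prev_end = 0
    for s, e in intervals:
        if s > e:
            raise ValueError(f"{what} interval start > end: ({s}, {e})")
        if s <= prev_end:
            raise ValueError(f"{what} intervals overlap or are unsorted at ({s}, {e})")
        prev_end = e


@dataclass
class GeneModel:
    """A stranded transcript: exon and CDS intervals on one chromosome.

    This is the coordinate frame for every coding-effect call.  ``valid``
    is False when the model failed validation (e.g. CDS length not a
    multiple of 3); such models are excluded from effect classification.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[Interval]
    cds: list[Interval]
    name: Optional[str] = None
    valid: bool = True
    invalid_reason: Optional[str] = None

    def validate(self, genome: Optional[dict[str, str]] = None, strict: bool = False) -> None:
        """Check structural invariants; mark (or raise, when strict) on failure.

        With ``genome`` provided, additionally checks that the spliced CDS
        begins with ATG and ends with a stop codon.
        """
        try:
            if self.strand not in ("+", "-"):
                raise ValueError(f"strand must be + or -, got {self.strand!r}")
            if self.tx_start > self.tx_end:
                raise ValueError("tx_start > tx_end")
            _check_sorted_disjoint(self.exons, "exon")
            _check_sorted_disjoint(self.cds, "CDS")
            for s, e in self.exons + self.cds:
                if s < self.tx_start or e > self.tx_end:
                    raise ValueError(f"interval ({s}, {e}) outside transcript span")
            if self.cds_length % 3 != 0:
                raise ValueError(f"CDS length {self.cds_length} not divisible by 3")
            if genome is not None and self.cds:
                spliced = self.spliced_cds(genome)
                if not spliced.startswith("ATG"):
                    raise ValueError("spliced CDS does not start with ATG")
                if spliced[-3:] not in ("TAA", "TAG", "TGA"):
                    raise ValueError("spliced CDS does not end with a stop codon")
        except ValueError as exc:
            self.valid = False
            self.invalid_reason = str(exc)
            if strict:
                raise

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def spliced_cds(self, genome: dict[str, str]) -> str:
        """Spliced, strand-oriented CDS sequence (5'->3' of the mRNA)."""
        seq = "".join(genome[self.chrom][s - 1 : e] for s, e in self.cds)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq.upper()

    def cds_index_of(self, pos: int) -> Optional[int]:
        """0-based index of genomic position ``pos`` in the spliced,
        strand-oriented CDS, or None when ``pos`` is not coding."""
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                plus_index = offset + (pos - s)
                if self.strand == "+":
                    return plus_index
                return self.cds_length - 1 - plus_index
            offset += e - s + 1
        return None

    def region_of(self, pos: int) -> Optional[str]:
        """'cds' | 'utr' | 'intron' for a position inside the transcript
        span, None outside it.  UTR is exon-minus-CDS; a model without CDS
        has no 'cds'/'utr' calls (exonic positions report 'utr')."""
        if pos < self.tx_start or pos > self.tx_end:
            return None
        for s, e in self.cds:
            if s <= pos <= e:
                return "cds"
        for s, e in self.exons:
            if s <= pos <= e:
                return "utr"
        return "intron"


_COMPLEMENT = str.maketrans("ACGTRYKMBVDHacgtrykmbvdh", "TGCAYRMKVBHDtgcayrmkvbhd")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# coverage mask
# ---------------------------------------------------------------------------


class CoverageMask:
    """Per-chromosome sorted, non-overlapping covered intervals.

    Stored 1-based inclusive.  Overlapping or abutting input intervals are
    merged on construction.
    """

    def __init__(self, intervals: Optional[dict[str, list[Interval]]] = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivals in intervals.items():
                self.add_chrom(chrom, ivals)

    def add_chrom(self, chrom: str, intervals: list[Interval]) -> None:
        merged: list[list[int]] = []
        for s, e in sorted(intervals):
            if s > e:
                raise ValueError(f"interval start > end: ({s}, {e})")
            if s < 1:
                raise ValueError(f"interval start < 1: ({s}, {e})")
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([s for s, _ in merged], dtype=np.int64)
        ends = np.array([e for _, e in merged], dtype=np.int64)
        self._starts[chrom] = starts
        self._ends[chrom] = ends
        lengths = ends - starts + 1
        self._cum[chrom] = np.concatenate([[0], np.cumsum(lengths)])

    @classmethod
    def full(cls, chrom_lengths: dict[str, int]) -> "CoverageMask":
        """Mask covering every base of every chromosome."""
        return cls({c: [(1, n)] for c, n in chrom_lengths.items()})

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts, key=natural_sort_key)

    def intervals(self, chrom: str) -> list[Interval]:
        return list(
            zip(self._starts[chrom].tolist(), self._ends[chrom].tolist())
        )

    def covered_bases(self, chrom: str) -> int:
        if chrom not in self._cum:
            return 0
        return int(self._cum[chrom][-1])

    def extent(self, chrom: str) -> int:
        """Largest covered coordinate (used as the chromosome extent when no
        explicit length is known)."""
        ends = self._ends.get(chrom)
        return int(ends[-1]) if ends is not None and len(ends) else 0

    def is_covered(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None or not len(starts):
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos <= self._ends[chrom][i]

    def covered_in(self, chrom: str, start: int, end: int) -> int:
        """Number of covered bases in the 1-based inclusive window [start, end]."""
        starts = self._starts.get(chrom)
        if starts is None or not len(starts) or end < start:
            return 0
        ends = self._ends[chrom]
        cum = self._cum[chrom]
        # intervals fully to the left of `start` / overlapping region
        lo = int(np.searchsorted(ends, start, side="left"))
        hi = int(np.searchsorted(starts, end, side="right"))
        if lo >= hi:
            return 0
        total = int(cum[hi] - cum[lo])
        # trim partial overlap at both edges
        total -= max(0, start - int(starts[lo]))
        total -= max(0, int(ends[hi - 1]) - end)
        return total

    def subtract(self, chrom: str, remove: list[Interval]) -> None:
        """Remove intervals from a chromosome's covered set (in place)."""
        pieces = []
        for s, e in self.intervals(chrom):
            cuts = sorted((max(s, rs), min(e, re_)) for rs, re_ in remove)
            cur = s
            for rs, re_ in cuts:
                if re_ < cur or rs > e:
                    continue
                if rs > cur:
                    pieces.append((cur, rs - 1))
                cur = max(cur, re_ + 1)
            if cur <= e:
                pieces.append((cur, e))
        self.add_chrom(chrom, pieces)

    def __eq__(self, other: object) -> bool:
        """Equal iff the covered sets coincide (a chromosome with no covered
        interval is indistinguishable from an absent one)."""
        if not isinstance(other, CoverageMask):
            return NotImplemented
        mine = {c for c in self._starts if len(self._starts[c])}
        theirs = {c for c in other._starts if len(other._starts[c])}
        if mine != theirs:
            return False
        return all(
            np.array_equal(self._starts[c], other._starts[c])
            and np.array_equal(self._ends[c], other._ends[c])
            for c in mine
        )

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{c}: {len(self._starts[c])} ivals/{self.covered_bases(c)} bp"
            for c in self.chroms
        )
        return f"CoverageMask({parts})"
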