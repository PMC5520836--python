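"""Synthetic re-sequencing variant data with planted, fully known truth.

Emulates the study design this package analyses: four related inbred rice
lines called against one shared reference, where the focal line carries a
controllable number of line-specific SNPs, a handful of planted large-effect
coding SNPs (premature stop / start loss / stop loss) inside simulated gene
models, localized variant-density hotspots, and per-line coverage gaps.

Everything downstream (window scanning, line-specificity, effect
annotation, phylogeny) can be validated against the returned
:class:`TruthSet` without any external data.

Design notes that matter for exact truth recovery:

* Heterozygosity is decided per *locus*, not per line-call, so a shared SNP
  carries the same genotype in every line that has it; otherwise genuine
  (but unplanted) allele-set differences would appear between lines.
* Shared SNPs are never placed where all comparison lines are uncovered
  (reference imputation would otherwise manufacture an unplanted
  focal-specific locus), and focal-specific SNPs are only placed where the
  focal line is covered.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .records import (
    CoverageMask,
    GeneModel,
    IndelRecord,
    SnpRecord,
    SvRecord,
    iupac_for,
    revcomp,
)
from . import variant_io

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
LARGE_EFFECT_CLASSES = ("premature_stop", "start_loss", "stop_loss")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic four-line design.

    Defaults describe a desk-scale genome (two 1-Mb chromosomes) with a
    background SNP density of 8e-4 per bp (the genome-wide density of the
    focal line's call set relative to its reference), one 10-fold SNP
    hotspot block, ~17% of each line's genome uncovered, and a 5% rate of
    heterozygous (IUPAC-coded) calls, matching mostly-homozygous inbred
    lines.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 20
    exons_per_gene: int = 3
    background_snp_rate: float = 8e-4
    background_indel_rate: float = 1.5e-4
    background_sv_rate: float = 8e-6
    specific_snp_count: int = 300
    large_effect_counts: dict = field(
        default_factory=lambda: {"premature_stop": 6, "start_loss": 3, "stop_loss": 4}
    )
    hotspot_blocks: list = field(
        default_factory=lambda: [("chr01", 300_001, 400_000, 10.0)]
    )
    uncovered_fraction: float = 0.17
    het_fraction: float = 0.05
    focal_name: str = "focal"
    comparison_names: tuple = ("comp1", "comp2", "comp3")

    def validate(self) -> None:
        for fname in ("background_snp_rate", "background_indel_rate",
                      "background_sv_rate", "uncovered_fraction", "het_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fname} must be in [0, 1], got {v}")
        for k in self.large_effect_counts:
            if k not in LARGE_EFFECT_CLASSES:
                raise ValueError(f"unknown large-effect class {k!r}")
        for chrom, start, end, fold in self.hotspot_blocks:
            if not (1 <= start <= end <= self.chrom_length):
                raise ValueError(
                    f"hotspot block ({chrom}, {start}, {end}) outside chromosome bounds"
                )
            if fold < 0:
                raise ValueError("hotspot fold must be >= 0")
        if self.specific_snp_count < 0 or self.n_genes < 0:
            raise ValueError("counts must be >= 0")

    @property
    def line_names(self) -> tuple:
        return (self.focal_name,) + tuple(self.comparison_names)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["comparison_names"] = list(data["comparison_names"])
        data["hotspot_blocks"] = [list(b) for b in data["hotspot_blocks"]]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["comparison_names"] = tuple(data.get("comparison_names", ()))
        data["hotspot_blocks"] = [tuple(b) for b in data.get("hotspot_blocks", [])]
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class TruthSet:
    """Ground truth planted by :func:`simulate_lines`.

    ``specific_loci`` holds every focal-line-only locus, including the
    planted large-effect loci (which are focal-specific by construction);
    ``large_effect_loci`` additionally records those by class with the gene
    they hit.
    """

    specific_loci: set = field(default_factory=set)  # {(chrom, pos)}
    shared_loci: set = field(default_factory=set)
    large_effect_loci: dict = field(default_factory=dict)  # class -> {(chrom,pos,gene_id)}
    hotspot_regions: list = field(default_factory=list)

    def __post_init__(self):
        overlap = self.specific_loci & self.shared_loci
        if overlap:
            raise ValueError(f"specific and shared loci overlap: {sorted(overlap)[:3]}")

    def to_json(self, path) -> None:
        data = {
            "specific_loci": sorted(list(t) for t in self.specific_loci),
            "shared_loci": sorted(list(t) for t in self.shared_loci),
            "large_effect_loci": {
                cls: sorted(list(t) for t in loci)
                for cls, loci in self.large_effect_loci.items()
            },
            "hotspot_regions": [list(b) for b in self.hotspot_regions],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            specific_loci={tuple(t) for t in data["specific_loci"]},
            shared_loci={tuple(t) for t in data["shared_loci"]},
            large_effect_loci={
                k: {tuple(t) for t in v} for k, v in data["large_effect_loci"].items()
            },
            hotspot_regions=[tuple(b) for b in data["hotspot_regions"]],
        )


@dataclass
class SimulatedLines:
    """All per-line outputs of :func:`simulate_lines`."""

    snp_tables: dict  # line -> list[SnpRecord]
    indel_tables: dict
    sv_tables: dict
    masks: dict  # line -> CoverageMask
    truth: TruthSet
    focal_name: str
    comparison_names: tuple


# ---------------------------------------------------------------------------
# reference + gene models
# ---------------------------------------------------------------------------


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def simulate_reference(config: SimulationConfig):
    """Generate a random reference genome and clean gene models.

    Returns ``(genome, models)``.  Every gene's spliced CDS starts with
    ATG, ends with a stop codon, has length divisible by 3 and contains no
    internal stop; genes are non-overlapping and alternate strand.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    L = config.chrom_length
    raw = {
        _chrom_name(i): bytearray(
            BASES[rng.integers(0, 4, size=L)].tobytes()
        )
        for i in range(config.n_chroms)
    }
    chrom_names = list(raw)
    models: list[GeneModel] = []
    if config.n_genes:
        cursors = {c: 1000 for c in chrom_names}
        for k in range(config.n_genes):
            chrom = chrom_names[k % len(chrom_names)]
            strand = "+" if k % 2 == 0 else "-"
            model, cds_seq = _layout_gene(
                rng, f"gene{k + 1:03d}", chrom, strand,
                cursors[chrom] + int(rng.integers(2_000, 20_000)),
                config.exons_per_gene,
            )
            if model.tx_end > L - 1000:
                raise ValueError(
                    f"cannot place {config.n_genes} genes without overlap on "
                    f"{config.n_chroms} x {L} bp chromosomes; increase chrom_length"
                )
            _paste_cds(raw[chrom], model, cds_seq)
            cursors[chrom] = model.tx_end
            models.append(model)
    genome = {c: bytes(seq).decode("ascii") for c, seq in raw.items()}
    for m in models:
        m.validate(genome=genome, strict=True)
    return genome, models


def _layout_gene(rng, gene_id, chrom, strand, start, n_exons):
    """Lay out exon/CDS intervals left to right and draw a coding sequence."""
    utr = 30  # non-coding bp kept at each end of the exon union
    exon_lens = [int(rng.integers(60, 181)) + (2 * utr if n_exons == 1 else 0)
                 for _ in range(n_exons)]
    if n_exons > 1:
        exon_lens[0] += utr
        exon_lens[-1] += utr
    intron_lens = [int(rng.integers(60, 201)) for _ in range(n_exons - 1)]
    exons, cds = [], []
    pos = start
    for i, elen in enumerate(exon_lens):
        s, e = pos, pos + elen - 1
        exons.append((s, e))
        cs = s + utr if i == 0 else s
        ce = e - utr if i == n_exons - 1 else e
        cds.append((cs, ce))
        pos = e + 1 + (intron_lens[i] if i < n_exons - 1 else 0)
    cds_len = sum(e - s + 1 for s, e in cds)
    trim = cds_len % 3  # shave the last CDS piece to a codon boundary
    if trim:
        s, e = cds[-1]
        cds[-1] = (s, e - trim)
        exons[-1] = (exons[-1][0], exons[-1][1])  # exon keeps its span
        cds_len -= trim
    n_codons = cds_len // 3
    if n_codons < 10:
        raise ValueError("gene layout produced a CDS shorter than 10 codons")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    cds_seq = (
        "ATG"
        + "".join(SENSE_CODONS[i] for i in body)
        + STOP_CODONS[int(rng.integers(0, 3))]
    )
    model = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        tx_start=exons[0][0], tx_end=exons[-1][1],
        exons=exons, cds=cds, name=gene_id.upper(),
    )
    return model, cds_seq


def _paste_cds(raw: bytearray, model: GeneModel, cds_seq: str) -> None:
    """Write the strand-oriented coding sequence into the chromosome."""
    genomic = cds_seq if model.strand == "+" else revcomp(cds_seq)
    offset = 0
    for s, e in model.cds:
        n = e - s + 1
        raw[s - 1 : e] = genomic[offset : offset + n].encode("ascii")
        offset += n


def genomic_position_of(model: GeneModel, cds_index: int) -> int:
    """Genomic 1-based position of a 0-based spliced-CDS index."""
    plus_index = (
        cds_index if model.strand == "+" else model.cds_length - 1 - cds_index
    )
    offset = 0
    for s, e in model.cds:
        n = e - s + 1
        if plus_index < offset + n:
            return s + (plus_index - offset)
        offset += n
    raise IndexError(f"CDS index {cds_index} outside model {model.gene_id}")


# ---------------------------------------------------------------------------
# four-line variant simulation
# ---------------------------------------------------------------------------


def simulate_lines(
    config: SimulationConfig,
    genome: dict[str, str],
    models: Sequence[GeneModel],
) -> SimulatedLines:
    """Simulate the four lines' SNP/InDel/SV call sets plus coverage masks.

    Shared SNPs carry identical genotypes in all four lines; specific and
    planted large-effect SNPs appear only in the focal line.  Hotspot
    blocks multiply the local background rate for all three variant
    classes.  No call is emitted inside a line's uncovered intervals.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    masks = {
        line: _simulate_mask(rng, chrom_lengths, config.uncovered_fraction)
        for line in config.line_names
    }
    focal_mask = masks[config.focal_name]
    comp_masks = [masks[n] for n in config.comparison_names]

    used: set = set()
    truth = TruthSet(hotspot_regions=list(config.hotspot_blocks))

    # planted large-effect SNPs (focal-specific by construction)
    large_effect_calls = []  # (chrom, pos, alt_base)
    valid_models = [m for m in models if m.valid and m.cds]
    for cls in LARGE_EFFECT_CLASSES:
        count = int(config.large_effect_counts.get(cls, 0))
        loci = set()
        for _ in range(count):
            planted = _plant_large_effect(
                rng, cls, valid_models, genome, focal_mask, used
            )
            if planted is None:
                raise ValueError(
                    f"large_effect_counts[{cls!r}] exceeds available eligible "
                    "codon positions in the simulated gene models"
                )
            chrom, pos, alt, gene_id = planted
            used.add((chrom, pos))
            loci.add((chrom, pos, gene_id))
            large_effect_calls.append((chrom, pos, alt))
        truth.large_effect_loci[cls] = loci

    # focal-specific background SNPs
    specific_calls = []
    chrom_names = list(genome)
    attempts = 0
    while len(specific_calls) < config.specific_snp_count:
        attempts += 1
        if attempts > 200 * max(1, config.specific_snp_count):
            raise ValueError("cannot place specific SNPs; genome too small or masked")
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
        if (chrom, pos) in used or not focal_mask.is_covered(chrom, pos):
            continue
        ref = genome[chrom][pos - 1]
        alt = _random_alt(rng, ref)
        used.add((chrom, pos))
        specific_calls.append((chrom, pos, alt))
    truth.specific_loci = {(c, p) for c, p, _ in specific_calls} | {
        (c, p) for c, p, _ in large_effect_calls
    }

    # shared background SNPs (hotspot-weighted)
    shared_calls = []
    for chrom in chrom_names:
        for pos in _draw_positions(
            rng, chrom, chrom_lengths[chrom], config.background_snp_rate,
            config.hotspot_blocks,
        ):
            if (chrom, pos) in used:
                continue
            if not any(m.is_covered(chrom, pos) for m in comp_masks):
                continue  # would alias a focal-specific locus under imputation
            ref = genome[chrom][pos - 1]
            alt = _random_alt(rng, ref)
            used.add((chrom, pos))
            shared_calls.append((chrom, pos, alt))
    truth.shared_loci = {(c, p) for c, p, _ in shared_calls}

    # per-locus genotype (het status shared by every carrier line)
    genotypes = {}
    for chrom, pos, alt in specific_calls + large_effect_calls + shared_calls:
        ref = genome[chrom][pos - 1]
        if rng.random() < config.het_fraction:
            genotypes[(chrom, pos)] = iupac_for({ref, alt})
        else:
            genotypes[(chrom, pos)] = alt

    snp_tables = {}
    focal_loci = shared_calls + specific_calls + large_effect_calls
    snp_tables[config.focal_name] = _emit_snp_records(
        rng, genome, focal_loci, genotypes, focal_mask
    )
    for name in config.comparison_names:
        snp_tables[name] = _emit_snp_records(
            rng, genome, shared_calls, genotypes, masks[name]
        )

    indel_tables = {
        line: _simulate_indels(rng, genome, chrom_lengths, config, masks[line])
        for line in config.line_names
    }
    sv_tables = {
        line: _simulate_svs(rng, genome, chrom_lengths, config, masks[line])
        for line in config.line_names
    }

    return SimulatedLines(
        snp_tables=snp_tables,
        indel_tables=indel_tables,
        sv_tables=sv_tables,
        masks=masks,
        truth=truth,
        focal_name=config.focal_name,
        comparison_names=tuple(config.comparison_names),
    )


def _simulate_mask(rng, chrom_lengths, uncovered_fraction) -> CoverageMask:
    mask = CoverageMask.full(chrom_lengths)
    if uncovered_fraction <= 0:
        return mask
    for chrom, L in chrom_lengths.items():
        target = int(round(L * uncovered_fraction))
        if target == 0:
            continue
        n_gaps = max(1, target // 25_000)
        lengths = rng.multinomial(target, np.full(n_gaps, 1.0 / n_gaps))
        remove = []
        for glen in lengths:
            glen = int(glen)
            if glen < 1:
                continue
            s = int(rng.integers(1, max(2, L - glen + 1)))
            remove.append((s, min(L, s + glen - 1)))
        mask.subtract(chrom, remove)
    return mask


def _draw_positions(rng, chrom, length, rate, hotspot_blocks) -> list[int]:
    """Per-base Bernoulli positions with hotspot fold multipliers applied."""
    if rate <= 0:
        return []
    rates = np.full(length, rate)
    for hchrom, s, e, fold in hotspot_blocks:
        if hchrom == chrom:
            rates[s - 1 : e] = np.minimum(1.0, rates[s - 1 : e] * fold)
    hits = np.nonzero(rng.random(length) < rates)[0] + 1
    return hits.tolist()


def _random_alt(rng, ref: str) -> str:
    alts = [b for b in "ACGT" if b != ref]
    return alts[int(rng.integers(0, 3))]


def _plant_large_effect(rng, cls, valid_models, genome, focal_mask, used):
    """Find (chrom, pos, genomic alt base, gene_id) creating the asked class."""
    order = rng.permutation(len(valid_models))
    for mi in order:
        model = valid_models[mi]
        spliced = model.spliced_cds(genome)
        n_codons = len(spliced) // 3
        hit = _find_edit(rng, cls, spliced, n_codons)
        if hit is None:
            continue
        cds_index, alt = hit
        pos = genomic_position_of(model, cds_index)
        if (model.chrom, pos) in used or not focal_mask.is_covered(model.chrom, pos):
            continue
        genomic_alt = alt if model.strand == "+" else _COMP[alt]
        return model.chrom, pos, genomic_alt, model.gene_id
    return None


def _find_edit(rng, cls, spliced, n_codons):
    """One (spliced CDS index, strand-oriented alt base) realizing the class."""
    if cls == "start_loss":
        p = int(rng.integers(0, 3))
        alt = _random_alt(rng, spliced[p])
        return p, alt  # any change to the ATG destroys it
    if cls == "stop_loss":
        base = 3 * (n_codons - 1)
        codon = spliced[base : base + 3]
        choices = []
        for p in range(3):
            for alt in "ACGT":
                if alt == codon[p]:
                    continue
                mutated = codon[:p] + alt + codon[p + 1 :]
                if mutated not in STOP_CODONS:
                    choices.append((base + p, alt))
        if not choices:
            return None
        return choices[int(rng.integers(0, len(choices)))]
    # premature_stop: internal codon turned into a stop by one substitution
    codon_order = rng.permutation(n_codons - 2) + 1
    for ci in codon_order:
        base = 3 * int(ci)
        codon = spliced[base : base + 3]
        choices = []
        for p in range(3):
            for alt in "ACGT":
                if alt == codon[p]:
                    continue
                if codon[:p] + alt + codon[p + 1 :] in STOP_CODONS:
                    choices.append((base + p, alt))
        if choices:
            return choices[int(rng.integers(0, len(choices)))]
    return None


def _emit_snp_records(rng, genome, calls, genotypes, mask) -> list[SnpRecord]:
    """Materialize full 18-column records for the loci a line carries."""
    carried = [
        (chrom, pos, alt)
        for chrom, pos, alt in calls
        if mask.is_covered(chrom, pos)
    ]
    carried.sort(key=lambda t: (t[0], t[1]))
    # nearest-SNP distance within this line's own call set, per chromosome
    nearest = {}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos, _ in carried:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, positions in by_chrom.items():
        for i, pos in enumerate(positions):
            gaps = []
            if i > 0:
                gaps.append(pos - positions[i - 1])
            if i < len(positions) - 1:
                gaps.append(positions[i + 1] - pos)
            nearest[(chrom, pos)] = min(gaps) if gaps else 0
    records = []
    for chrom, pos, alt in carried:
        ref = genome[chrom][pos - 1]
        genotype = genotypes[(chrom, pos)]
        het = len(genotype) == 1 and genotype not in "ACGT"
        total = int(rng.integers(8, 31))
        quality = int(rng.integers(30, 51))
        if het:
            best_all = max(1, total // 2)
            second_all = max(1, total - best_all - int(rng.integers(0, 3)))
            second_base = ref
        else:
            best_all = max(1, total - int(rng.integers(0, 3)))
            second_all = total - best_all
            second_base = ref
        best_unique = int(rng.integers(max(1, best_all // 2), best_all + 1))
        second_unique = int(rng.integers(0, second_all + 1))
        records.append(
            SnpRecord(
                chrom=chrom, pos=pos, ref_base=ref, genotype=genotype,
                quality=quality, best_base=alt, best_quality=quality,
                best_unique_reads=best_unique, best_all_reads=best_all,
                second_base=second_base,
                second_quality=int(rng.integers(10, quality + 1)),
                second_unique_reads=second_unique, second_all_reads=second_all,
                total_reads=total, rank_field=f"1&{quality}",
                copy_number=1.0, in_dbsnp=int(rng.random() < 0.3),
                nearest_snp_distance=nearest[(chrom, pos)],
            )
        )
    return records


def _simulate_indels(rng, genome, chrom_lengths, config, mask) -> list[IndelRecord]:
    records = []
    for chrom, L in chrom_lengths.items():
        for pos in _draw_positions(
            rng, chrom, L, config.background_indel_rate, config.hotspot_blocks
        ):
            if not mask.is_covered(chrom, pos):
                continue
            length = int(rng.integers(1, 7))
            kind = "insertion" if rng.random() < 0.5 else "deletion"
            if kind == "deletion":
                end = min(len(genome[chrom]), pos + length - 1)
                bases = genome[chrom][pos - 1 : end]
                length = len(bases)
            else:
                bases = "".join(
                    "ACGT"[int(i)] for i in rng.integers(0, 4, size=length)
                )
            crossing = int(rng.integers(4, 25))
            records.append(
                IndelRecord(
                    chrom=chrom, pos=pos, indel_kind=kind, indel_length=length,
                    bases=bases, strand="+-*"[int(rng.integers(0, 3))],
                    zygosity="het" if rng.random() < config.het_fraction else "hom",
                    mean_quality=round(float(rng.uniform(25, 45)), 1),
                    support_pairs=int(rng.integers(2, crossing + 1)),
                    crossing_pairs=crossing,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def _simulate_svs(rng, genome, chrom_lengths, config, mask) -> list[SvRecord]:
    records = []
    for chrom, L in chrom_lengths.items():
        for pos in _draw_positions(
            rng, chrom, L, config.background_sv_rate, config.hotspot_blocks
        ):
            if not mask.is_covered(chrom, pos):
                continue
            sv_type = ("deletion", "insertion", "inversion")[int(rng.integers(0, 3))]
            length = int(rng.integers(100, 5001))
            est_start = pos
            est_end = min(L, pos + length - 1)
            pad_l = int(rng.integers(0, 51))
            pad_r = int(rng.integers(0, 51))
            records.append(
                SvRecord(
                    chrom=chrom, sv_type=sv_type,
                    cluster_start_min=max(1, est_start - pad_l),
                    cluster_end_max=min(L, est_end + pad_r),
                    est_start=est_start, est_end=est_end,
                    sv_length=est_end - est_start + 1,
                    insertion_breakpoint=pos if sv_type == "insertion" else None,
                    match_mode=("FR", "FF", "RR")[int(rng.integers(0, 3))],
                    support_pairs=int(rng.integers(2, 21)),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.est_start))
    return records


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_simulation(
    outdir,
    config: SimulationConfig,
    genome: dict[str, str],
    models: Sequence[GeneModel],
    lines: SimulatedLines,
) -> Path:
    """Write the full simulated dataset in the formats variant_io reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    variant_io.write_fasta(outdir / "reference.fa", genome)
    variant_io.write_gff3(
        outdir / "genes.gff3", models, {c: len(s) for c, s in genome.items()}
    )
    for line in config.line_names:
        variant_io.write_snp_table(outdir / f"{line}.snp.tsv", lines.snp_tables[line])
        variant_io.write_indel_table(outdir / f"{line}.indel.tsv", lines.indel_tables[line])
        variant_io.write_sv_table(outdir / f"{line}.sv.tsv", lines.sv_tables[line])
        variant_io.write_bed_mask(outdir / f"{line}.covered.bed", lines.masks[line])
    lines.truth.to_json(outdir / "truth.json")
    return outdir


def simulate_all(config: SimulationConfig):
    """Convenience wrapper: reference + lines in one call."""
    genome, models = simulate_reference(config)
    lines = simulate_lines(config, genome, models)
    return genome, models, lines
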