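"""Summary tables, packaged reference-table fixtures, and the pipeline runner.

The fixtures are per-chromosome count tables transcribed from the
published study this pipeline re-implements (variant counts, high/low
region counts, specific-SNP annotation counts, large-effect class counts);
:func:`verify_fixture_totals` re-adds each column and compares it with the
printed total, which is the only genome-scale check that is reproducible
without the unreleased sequencing data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from . import variant_io
from .records import natural_sort_key
from . import simulate as sim
from . import window_scan
from . import line_specificity
from . import effect_annotation
from . import gene_variation
from . import phylogeny

logger = logging.getLogger(__name__)

FIXTURE_IDS = ("table2", "table3", "table4", "largeeffect")
_FIXTURE_FILES = {
    "table2": "table2.tsv",
    "table3": "table3.tsv",
    "table4": "table4.tsv",
    "largeeffect": "largeeffect.tsv",
}
_CHROM_FIXTURES = ("table2", "table3", "table4")
N_RICE_CHROMOSOMES = 12


@dataclass
class PaperTableFixture:
    """A transcribed published count table with its printed totals."""

    table_id: str
    rows: pd.DataFrame  # data rows only (no totals row)
    printed_totals: dict  # column -> printed total

    def validate(self) -> None:
        if self.table_id in _CHROM_FIXTURES and len(self.rows) != N_RICE_CHROMOSOMES:
            raise ValueError(
                f"{self.table_id}: expected {N_RICE_CHROMOSOMES} chromosome rows, "
                f"got {len(self.rows)}"
            )
        missing = set(self.printed_totals) - set(self.rows.columns)
        if missing:
            raise ValueError(f"{self.table_id}: totals for unknown columns {missing}")


def load_fixture(table_id: str) -> PaperTableFixture:
    """Load one packaged fixture by id (table2 | table3 | table4 | largeeffect)."""
    if table_id not in FIXTURE_IDS:
        raise ValueError(f"unknown fixture {table_id!r}; choose from {FIXTURE_IDS}")
    ref = resources.files("ricevar.data") / _FIXTURE_FILES[table_id]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    totals = df.loc["Total"].astype(int).to_dict()
    rows = df.drop(index="Total").astype(int)
    fixture = PaperTableFixture(table_id=table_id, rows=rows, printed_totals=totals)
    fixture.validate()
    return fixture


def verify_fixture_totals(fixture: PaperTableFixture) -> pd.DataFrame:
    """Sum each column over the data rows and compare with the printed total.

    Returns a frame with columns (column, sum, printed_total, match);
    exact integer arithmetic.
    """
    fixture.validate()
    if fixture.rows.empty:
        raise ValueError(f"{fixture.table_id}: fixture has no data rows")
    records = []
    for col, printed in fixture.printed_totals.items():
        s = int(fixture.rows[col].sum())
        records.append(
            {"column": col, "sum": s, "printed_total": int(printed), "match": s == int(printed)}
        )
    return pd.DataFrame(records)


def verify_all_fixtures() -> pd.DataFrame:
    """Totals check for every packaged fixture, concatenated."""
    frames = []
    for table_id in FIXTURE_IDS:
        df = verify_fixture_totals(load_fixture(table_id))
        df.insert(0, "table", table_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# chromosome-level variant summary
# ---------------------------------------------------------------------------


def summarize_variants_by_chromosome(
    snps: Sequence = (),
    indels: Sequence = (),
    svs: Sequence = (),
    chroms: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-chromosome SNP/InDel/SV counts with a totals row."""
    names = set(chroms or ())
    counts = {"SNP": {}, "InDel": {}, "SV": {}}
    for cls, records in (("SNP", snps), ("InDel", indels), ("SV", svs)):
        for r in records:
            counts[cls][r.chrom] = counts[cls].get(r.chrom, 0) + 1
            names.add(r.chrom)
    ordered = sorted(names, key=natural_sort_key)
    df = pd.DataFrame(
        {cls: [counts[cls].get(c, 0) for c in ordered] for cls in counts},
        index=pd.Index(ordered, name="Chr"),
    )
    df.loc["Total"] = df.sum()
    return df


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> Path:
    """Run simulate -> parse -> windows -> specificity -> effects -> genes
    -> phylogeny from a single config mapping and write every stage's
    outputs plus a manifest into ``outdir``.

    Config keys (all optional except none): ``seed`` (int, default 0);
    ``simulate`` (mapping of :class:`~ricevar.simulate.SimulationConfig`
    overrides); ``windows`` (window_size / step / alpha / method);
    ``genes`` (list of gene names to tabulate; default every simulated
    gene); ``min_quality`` (SNP quality filter for the phylogeny).
    Any stage failure raises, naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("ricevar")
    old_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"version": __version__, "stages": {}, "files": {}}
    stage = "configure"
    try:
        sim_overrides = dict(config.get("simulate", {}))
        sim_overrides.setdefault("seed", int(config.get("seed", 0)))
        cfg = sim.SimulationConfig(**sim_overrides)
        cfg.validate()
        manifest["seed"] = cfg.seed

        stage = "simulate"
        genome, models, lines = sim.simulate_all(cfg)
        data_dir = sim.write_simulation(outdir / "data", cfg, genome, models, lines)
        root.info("simulate: %d chroms, %d gene models, %d lines",
                  len(genome), len(models), len(cfg.line_names))

        stage = "parse"
        genome = variant_io.read_fasta(data_dir / "reference.fa")
        models = variant_io.read_gff3(data_dir / "genes.gff3", genome=genome)
        snp_tables, masks = {}, {}
        indels, svs = {}, {}
        for line in cfg.line_names:
            snp_tables[line] = variant_io.read_snp_table(data_dir / f"{line}.snp.tsv")
            indels[line] = variant_io.read_indel_table(data_dir / f"{line}.indel.tsv")
            svs[line] = variant_io.read_sv_table(data_dir / f"{line}.sv.tsv")
            masks[line] = variant_io.read_bed_mask(data_dir / f"{line}.covered.bed")
        focal = cfg.focal_name
        root.info("parse: %s", {k: len(v) for k, v in snp_tables.items()})

        stage = "report"
        summary = summarize_variants_by_chromosome(
            snp_tables[focal], indels[focal], svs[focal], chroms=list(genome)
        )
        summary.to_csv(outdir / "variant_counts.tsv", sep="\t")

        stage = "windows"
        wcfg = config.get("windows", {})
        window_size = int(wcfg.get("window_size", 100_000))
        step = int(wcfg.get("step", 50_000))
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        regions_by_class = {}
        for cls, records, key in (
            ("SNP", snp_tables[focal], lambda r: (r.chrom, r.pos)),
            ("InDel", indels[focal], lambda r: (r.chrom, r.pos)),
            ("SV", svs[focal], lambda r: (r.chrom, r.est_start)),
        ):
            stats = window_scan.compute_window_frequencies(
                [key(r) for r in records], masks[focal],
                window_size=window_size, step=step, chrom_lengths=chrom_lengths,
            )
            window_scan.windows_to_frame(stats).to_csv(
                outdir / f"windows_{cls.lower()}.tsv", sep="\t", index=False
            )
            regions = window_scan.call_extreme_regions(
                stats,
                method=wcfg.get("method", "quantile"),
                alpha=float(wcfg.get("alpha", 0.025)),
            )
            (outdir / f"regions_{cls.lower()}.bed").write_text(
                window_scan.regions_to_bed(regions)
            )
            regions_by_class[cls] = regions
            root.info("windows[%s]: %d windows, %d regions", cls, len(stats), len(regions))
        window_scan.region_summary(regions_by_class, list(genome)).to_csv(
            outdir / "region_counts.tsv", sep="\t"
        )

        stage = "specificity"
        comp = list(cfg.comparison_names)
        spec = line_specificity.identify_specific_snps(
            snp_tables[focal],
            [snp_tables[c] for c in comp],
            masks=[masks[c] for c in comp],
            policy=config.get("policy", "absent_as_reference"),
        )
        spec_records = [
            r for r in snp_tables[focal] if (r.chrom, r.pos) in spec.loci
        ]
        variant_io.write_snp_table(outdir / "specific.snp.tsv", spec_records)
        (outdir / "specific.vcf").write_text(
            variant_io.export_vcf(spec_records, genome, sample=focal)
        )
        line_specificity.summarize_specific_by_chromosome(
            spec, chroms=list(genome)
        ).to_csv(outdir / "specific_counts.tsv", sep="\t")
        root.info("specificity: %d specific loci", len(spec.specific))

        stage = "effects"
        annotations = effect_annotation.annotate_all(spec_records, models, genome)
        effect_annotation.annotations_to_frame(annotations).to_csv(
            outdir / "effects.tsv", sep="\t", index=False
        )
        coding, large = effect_annotation.summarize_effects(
            annotations, chroms=list(genome)
        )
        coding.to_csv(outdir / "effect_counts.tsv", sep="\t")
        large.to_csv(outdir / "large_effect_counts.tsv", sep="\t")
        root.info("effects: %d annotations", len(annotations))

        stage = "genes"
        gene_list = config.get("genes") or [m.name or m.gene_id for m in models]
        gene_variation.count_gene_variants(
            snp_tables[focal], models, gene_list
        ).to_frame().to_csv(outdir / "gene_variation.tsv", sep="\t", index=False)

        stage = "phylogeny"
        dm = phylogeny.pairwise_distance(
            snp_tables, min_quality=config.get("min_quality")
        )
        (outdir / "distances.tsv").write_text(dm.to_tsv())
        tree = phylogeny.nj_tree(dm)
        (outdir / "tree.nwk").write_text(phylogeny.write_newick(tree))
        root.info("phylogeny: %d lines, %d clamped branches",
                  len(dm.labels), tree.clamped_branches)

        stage = "manifest"
        for path in sorted(outdir.rglob("*")):
            if path.is_file() and path.name not in ("pipeline.log", "manifest.json"):
                manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
        manifest["stages"] = {
            "snp_records": {k: len(v) for k, v in snp_tables.items()},
            "specific_loci": len(spec.specific),
            "annotations": len(annotations),
            "regions": {k: len(v) for k, v in regions_by_class.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    return outdir
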