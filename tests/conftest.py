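import pytest

from ricevar import simulate as sim


@pytest.fixture(scope="session")
def default_sim():
    """One full default-condition simulation shared across the suite:
    (config, genome, models, lines)."""
    cfg = sim.SimulationConfig(seed=1)
    genome, models, lines = sim.simulate_all(cfg)
    return cfg, genome, models, lines


@pytest.fixture(scope="session")
def five_gene_genome():
    """A small genome with five clean gene models (both strands) used by
    the exhaustive translate-and-compare oracle."""
    cfg = sim.SimulationConfig(
        seed=7, n_chroms=1, chrom_length=150_000, n_genes=5, exons_per_gene=3,
        background_snp_rate=0.0, specific_snp_count=0,
        large_effect_counts={}, hotspot_blocks=[], uncovered_fraction=0.0,
    )
    genome, models = sim.simulate_reference(cfg)
    return genome, models


def make_snp(chrom="chr01", pos=100, ref="A", genotype="G", quality=40, **kw):
    """A minimally plausible 18-column SNP record for tests."""
    from ricevar.records import SnpRecord

    defaults = dict(
        chrom=chrom, pos=pos, ref_base=ref, genotype=genotype, quality=quality,
        best_base=genotype if genotype in "ACGT" else ref, best_quality=quality,
        best_unique_reads=8, best_all_reads=10, second_base=ref,
        second_quality=20, second_unique_reads=1, second_all_reads=2,
        total_reads=12, rank_field="1&40", copy_number=1.0, in_dbsnp=0,
        nearest_snp_distance=350,
    )
    defaults.update(kw)
    rec = SnpRecord(**defaults)
    rec.validate()
    return rec
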