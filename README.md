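# ricevar

Downstream genome-variation analysis for re-sequenced inbred rice lines
called against a shared reference genome.

Re-sequencing studies of closely related rice lines (e.g. an improved
restorer line compared against the established lines it was bred from)
produce per-line call sets — SNP consensus tables, short InDels and
structural variants — from which the biology is read off downstream: where
variation clusters along the genome, which SNPs are private to the focal
line, which of those disrupt proteins, and how the lines relate to each
other.  `ricevar` implements that downstream layer as a tested library and
CLI:

* **variant_io** — readers/writers for the caller's custom table formats
  (18-column SOAPsnp-style SNP consensus, 9-column InDel, 10-column SV),
  plus FASTA, GFF3 gene models, BED coverage masks and VCF 4.2 export.
* **window_scan** — sliding-window variant frequency *f* = (variants in
  window) / (covered bases in window), default 100-kb windows with 50-kb
  step, and merged high/low-frequency region calls from two-sided
  empirical quantiles.
* **line_specificity** — focal-line-specific SNPs: loci where N comparison
  lines' allele sets agree with each other but differ from the focal line,
  with configurable handling of no-call loci.
* **effect_annotation** — strand-aware codon reconstruction in spliced CDS
  coordinates and classification as synonymous, nonsynonymous, premature
  stop, start loss or stop loss under the standard genetic code.
* **gene_variation** — per-gene SNP counts in the gene's DNA span vs its
  mRNA (exon union or CDS-only).
* **phylogeny** — allele-sharing distances (0 / 0.5 / 1 per locus, averaged
  over the union of called loci) and a deterministic neighbor-joining tree
  written as Newick.
* **simulate** — a synthetic-data generator producing four related lines
  with planted, exactly recoverable truth (specific loci, large-effect
  SNPs, density hotspots, coverage gaps), so every stage is testable
  without external data.
* **reports / CLI** — chromosome-level summary tables, transcribed
  published count-table fixtures with arithmetic consistency checks, and a
  one-command end-to-end pipeline.

See `docs/methods.md` for the model, conventions and design decisions.

## Worked example

```python
from ricevar import simulate as sim, line_specificity as ls
from ricevar import effect_annotation as ea, phylogeny as ph

cfg = sim.SimulationConfig(seed=1)          # 2 x 1 Mb genome, 4 lines
genome, models, lines = sim.simulate_all(cfg)

comp = list(cfg.comparison_names)
result = ls.identify_specific_snps(
    lines.snp_tables[cfg.focal_name],
    [lines.snp_tables[c] for c in comp],
    masks=[lines.masks[c] for c in comp],
)
print("focal calls:", len(lines.snp_tables["focal"]))
print("specific SNPs:", len(result.specific))

specific = [r for r in lines.snp_tables["focal"] if (r.chrom, r.pos) in result.loci]
coding, large = ea.summarize_effects(
    ea.annotate_all(specific, models, genome), chroms=list(genome))
print(large.to_string())

dm = ph.pairwise_distance(lines.snp_tables)
print(ph.write_newick(ph.nj_tree(dm)))
```

prints

```
focal calls: 2268
specific SNPs: 313
       premature_stop  start_loss  stop_loss
Chr
chr01               5           2          3
chr02               1           1          1
Total               6           3          4
(comp1:0.165928,comp2:0.191182,(focal:0.223703,comp3:0.092854):0.019420);
```

The focal line carries 2,268 SNP calls, of which 313 are line-specific —
exactly the simulator's planted specific set (300 background-specific plus
13 planted large-effect SNPs), recovered with no false positives or
negatives.  The large-effect summary recovers the planted 6 premature
stops, 3 start losses and 4 stop losses on their chromosomes, and the
neighbor-joining tree places the focal line on the longest terminal branch
(0.224), as expected for the line carrying ~300 private SNPs.

The same pipeline runs from the shell:

```bash
ricevar simulate --seed 1 --out sim/          # write FASTA/GFF3/tables/BED + truth
ricevar run --seed 1 --out run/               # full end-to-end pipeline
ricevar verify-fixtures                       # published-table arithmetic checks
```

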