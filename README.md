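# ricircle

Transcriptome-wide discovery of circular RNAs (circRNAs) from stranded
paired-end RNA-seq, built around the backsplice-junction strategy used for
the rice (*Oryza sativa*) transcriptome: chiastic anchor mapping, per-read
pseudo-genome spliced alignment, and stringent mate / read-support /
splice-signal filters, together with the simulation-testing harness that
measures the pipeline's sensitivity and false-discovery rate on designed
backsplice reads.

## Who this is for

Anyone who wants to (a) call backsplice junctions from stranded 2x100 bp
libraries with a fully transparent, desk-scale implementation, (b) study
the behaviour of the published filtering rules (>= 2 independent
junction-spanning reads, GU/AG intron signal, mate consistency) under
controlled synthetic conditions, or (c) reuse the downstream analyses —
genomic-origin classification, alternative backsplicing, flanking
inverted repeats, MITE overlap, rule-based miRNA target-mimic prediction.

## The method

A read spanning a backsplice cannot be explained by a colinear alignment:
its 5' end maps *downstream* of its 3' end on the same strand. The
pipeline proceeds in stages:

1. **Colinear prefilter.** Reads with a single ungapped genomic placement
   covering them at >= 95% identity are discarded (they are ordinary
   linear reads).
2. **Chiastic candidate selection.** The terminal 20-bp anchors of each
   remaining read are matched exactly against both genome strands. A read
   is a candidate iff both anchors hit uniquely, on one chromosome and
   strand, in permuted (chiastic) order, with an anchor footprint
   <= 15 kb.
3. **Pseudo-genome spliced alignment.** For each candidate, 5.1 kb of
   genomic sequence downstream of the head anchor and 5.1 kb upstream of
   the tail anchor are reverse-assembled (downstream block first) into a
   10.2-kb pseudo-genome, turning the backsplice into a forward splice.
   A two-segment aligner scans every split of the read, maximizing
   matched bases; ties from junction homology are resolved toward the
   GT..AG-consistent split. Junction coordinates are mapped back through
   the invertible block descriptors.
4. **Filters and calling.** A junction read is dropped when its mate is
   confidently placed even partly outside the circle span. Junctions are
   grouped by exact coordinates; calls require >= 2 independent
   supporting reads and the canonical GU/AG (GT..AG in DNA) intron signal
   flanking the backsplice.

The **simulation harness** regenerates the published benchmark design:
chimeric reads built by reverse-assembling 20-80 bp terminal segments of
two exons of one transcript, five independent data sets, with the truth
set recorded at generation time. Sensitivity is the fraction of designed
sites recovered; FDR the fraction of calls matching no designed site.

The **synthetic-data module** makes all of this testable offline: random
multi-chromosome genomes, non-overlapping multi-exon gene models whose
introns are rewritten to GT..AG, linear + circular stranded 2x100 bp
libraries with configurable error rate, strand-orientation accuracy and
circular fraction.

## Worked example

```python
from ricircle import (SimConfig, PipelineConfig, GenomeIndex,
                      generate_genome, generate_gene_models,
                      run_simulation_study)

sim = SimConfig(n_chroms=2, chrom_len=2_000_000, n_genes=300,
                n_designed_sites=1_500, n_datasets=5, rng_seed=1)
genome = generate_genome(sim)
genome, models = generate_gene_models(genome, sim)
res = run_simulation_study(models, genome, sim, PipelineConfig(),
                           index=GenomeIndex(genome, 20))
print(f"sensitivity {res.sensitivity:.4f}  fdr {res.fdr:.4f}")
```

prints

```
sensitivity 1.0000  fdr 0.0000
```

i.e. all 7,500 designed backsplice sites (5 x 1,500, two error-free reads
each) are recovered exactly and no spurious junction survives the
filters. The numbered scripts under `analysis/` run the same machinery as
a narrative: `01` simulates a 100k-pair mixed linear/circular library,
`02` detects (on one such run: 14 calls, all 14 matching a circular
template, zero false calls), `03` annotates them (e.g. 12 CDS-CDS + 2
ncRNA), `04` screens flanks/MITEs/mimics against planted positives, and
`05` sweeps the per-base error rate (sensitivity 0.9999 at 0 errors
falling to 0.19 at 2% substitutions, FDR 0 throughout).

There is also a CLI: `ricircle simulate|detect|annotate|flanks|mimics|evaluate`
(see `ricircle --help`).

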