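# xenosplit

Host-xenograft read deconvolution and absolute exRNA quantification for
liquid-biopsy RNA-seq from human-tumour xenograft models.

In a xenograft mouse, tumour RNA is human and host RNA is murine, so every
sequencing read can in principle be assigned to its genome of origin.
`xenosplit` implements both assignment strategies on top of aligner output
(SAM/BAM with `NH`/`NM` tags):

- **Combined route** — reads aligned to one concatenated human+mouse
  reference (mouse contigs prefixed `m`, spike and rDNA contigs appended)
  are uniqueness-filtered (`NH:i:1`) and classified by contig.
- **Parallel route** — reads aligned separately to each genome are assigned
  to the species with the smaller pair edit distance (`NM` + CIGAR soft-clip,
  summed over both mates); ties are kept in an explicit ambiguous bucket.

On top of deconvolution it provides:

- **Masking** (`maskkit`) — learn the footprint of misalignable sequence from
  pure-species control samples and drop any read pair overlapping it.
  Applying a mask built from a read set to that same set removes every read
  (the closure property).
- **Counting** (`countquant`) — union-mode, strand-aware (`reverse` protocol)
  paired-end gene counting against union-exon models, robust-detection
  filtering (≥ 5 counts), TPM / log2(TPM+1), biotype summaries, and
  between-sample normalisation by Sequin spike-in count sums.
- **Absolute quantification** (`spikequant`) — spike-in mass bookkeeping
  (length × 321.47 g/mol per nucleotide, molarity × volume × dilution)
  converting species-split counts into pg/mL concentrations and a tumour
  fraction percentage.
- **Simulation** (`simfix`) — fully deterministic two-species toy genomes
  with homology blocks of controlled identity, truth-labelled paired-end
  SAM alignments with exact NM/soft-clip bookkeeping, spike reads, and a
  count-level plasma fraction series (host counts scale with platelet level,
  tumour counts constant).

## CLI

```sh
xenosplit build-ref --human human.fa --mouse mouse.fa --spikes spikes.fa \
    --human-gtf human.gtf --mouse-gtf mouse.gtf --prefix m --out-dir ref/ --parallel
xenosplit split-combined --bam combined.bam --classes ref/contig_classes.tsv --out-dir split/
xenosplit deconv-parallel --human-bam h.bam --mouse-bam m.bam \
    --classes ref/contig_classes.tsv --out-dir par/
xenosplit build-mask --control-bam ctrl1.bam --control-bam ctrl2.bam --out-bed mask.bed
xenosplit apply-mask --bam split/human.sam --mask-bed mask.bed --out-sam human.masked.sam
xenosplit count --bam human.masked.sam --gtf ref/combined.gtf --out counts.tsv
xenosplit quantify --counts sample_counts.tsv --spike-panel panel.tsv --out quant.tsv
xenosplit simulate --seed 3 --out-dir sim/
xenosplit run --config pipeline.yaml --samples samples.tsv --out-dir run/
```

All alignment inputs must be queryname-sorted with primary records carrying
`NH` and `NM` tags. `run` executes the configured route end to end
(deconvolution → masking → counting → quantification) per sample sheet row;
one sample's failure is recorded in `report.json` without stopping the rest.

Pipeline config (YAML) keys: `route` (`combined`/`parallel`),
`contig_classes`, `spike_panel`, optional `protocol` (YAML:
`volume_added_ul`, `dilution_factor`, `input_volume_ml`), optional `masks`
(`human:`/`mouse:` BED paths), optional `gtf`, `strandedness`,
`robust_threshold`. Sample sheet columns: `sample_id`, `bam` (combined) or
`human_bam`/`mouse_bam` (parallel), optional `input_volume_ml`.

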