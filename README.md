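# rrnpipe

A desk-scale pipeline for multiplexed long-read **rrn operon** (16S–ITS–23S,
~4.5 kb) amplicon sequencing: split concatenated reads on internal adapter
occurrences, filter by mean read quality, demultiplex on dual 16 nt barcodes,
excise degenerate primers, extract pseudo-V3V4 sub-regions in silico,
estimate per-sample taxonomic relative abundances by
expectation–maximization, and export crosstalk/prevalence-filtered,
phyloseq-ready tables.

It is aimed at microbiome researchers who want the full processing chain of
an rrn nanopore experiment as a tested, inspectable library — every stage is
exercised end to end against a built-in synthetic read generator with a
ground-truth manifest, so no flow cell or curated reference database is
needed to validate the machinery.

## The model in brief

**Quality arithmetic.** A read's mean quality is the Phred transform of its
mean per-base error probability,
`Q̄ = −10·log₁₀( (1/L) Σᵢ 10^(−Qᵢ/10) )`, and per-base accuracy is
`100·(1 − 10^(−Q/10))` — so Q12 ⇒ 93.7 %, Q20 ⇒ 99.0 %, and a 4,500 bp read
at Q20 carries 45 expected errors.

**Demultiplexing and crosstalk.** Reads are assigned when exactly one
(forward, reverse) barcode pair matches within a Hamming tolerance
(default 0) at the read ends, in exactly one orientation; minus-strand
matches are reverse complemented. Barcode combinations not mapped to a
sample are *null controls*: the fraction of demultiplexed reads landing in
them estimates the barcode-crosstalk rate (e.g. 73 null reads among 1.00×10⁶
⇒ 0.0073 %), which is then applied as a per-sample relative-abundance floor
on the final table.

**EM abundance estimation.** Candidate references come from shared-k-mer
seeding followed by glocal edit-distance alignment. With per-read
likelihoods `L(r|k) = identity^aln_len`, EM iterates

    E:  P(k|r) = aₖ·L(r|k) / Σⱼ aⱼ·L(r|j)        M:  aₖ ← (1/N) Σᵣ P(k|r)

until the abundance vector is stable; taxa below a pruning threshold are
zeroed and the mass renormalized. Hard per-read calls take the
maximum-responsibility taxon, ties going to the longer alignment.

## Worked example

Simulate a small 2-sample mock run (8 taxa at the theoretical mock
proportions, 1 % error, concatemer artifacts), then run every stage from the
shell:

```console
$ rrnpipe simulate --n-taxa 8 --n-samples 2 --reads-per-sample 40 --seed 4 --out-dir sim
wrote 78 reads to sim
$ rrnpipe split sim/reads.fastq split.fastq --report split.tsv
78 reads in, 80 out (2 recovered in 2 rounds)
$ rrnpipe filter split.fastq filt.fastq --min-q 10
retained 80/80 reads at Q>=10.0
$ rrnpipe demux filt.fastq --barcodes sim/barcodes.tsv --samples sim/samples.tsv --out-dir dm
assigned 53, null 0 (crosstalk 0.0000%), unassigned 27
$ rrnpipe trim dm/S01.fastq trimmed.fastq
trimmed 31 reads; 0 lacked a primer site
$ rrnpipe classify trimmed.fastq --reference sim/reference.fasta \
      --taxonomy sim/taxonomy.tsv --out abund.tsv
7 taxa, 0 unclassified reads, 2 EM iterations
```

Reading the numbers: the simulator emitted 78 reads because two pairs of the
80 molecules were stitched into concatemers; `split` detects the internal
adapters and restores all 80. At a 1 % error rate roughly a quarter of reads
carry at least one error inside a 16 nt barcode, so the stringent
zero-mismatch demultiplexer assigns 53 of 80 (the rest are `no_barcode` or
outside the 3–7 kb window) — rerunning with `--mismatches 1` recovers most
of them. All 31 reads of sample S01 had both primer sites and were trimmed
to the biological amplicon; classification found 7 of the 8 mock taxa in
this very shallow sample (the rarest taxon drew no reads), with estimated
abundances and counts written to `abund.tsv`. `rrnpipe extract-region`
cuts the pseudo-V3V4 insert out of the trimmed reads, and `rrnpipe tables`
aggregates per-sample abundance files to species level, rarefies, applies
the prevalence (>5 reads in ≥3 samples) and crosstalk filters, and writes
`otu_table.csv` / `tax_table.csv` / `sample_data.csv` for
`scripts/build_phyloseq.R`.

The same flow is available as a library; see `rrnpipe.pipeline.
run_synthetic_pipeline`, which runs the full study-condition benchmark
(3 samples × 2,000 reads at 1 % error) in ~20 s.

## Layout

| module | role |
|---|---|
| `rrnpipe.seqio` | FASTQ/FASTA I/O, Phred arithmetic, per-stage run statistics |
| `rrnpipe.synthetic` | reference + read simulator with truth manifest |
| `rrnpipe.splitcat` | concatemer splitting on internal adapters |
| `rrnpipe.qc_filter` | mean-quality filtering |
| `rrnpipe.demux` | dual-barcode demultiplexing, crosstalk estimation |
| `rrnpipe.trim_extract` | IUPAC primer trimming, pseudo-V3V4 extraction |
| `rrnpipe.classify_em` | k-mer seeded alignment, EM abundances, pairwise identity |
| `rrnpipe.tables_export` | species aggregation, rarefaction, filters, phyloseq CSVs |
| `rrnpipe.pipeline` | end-to-end orchestration |
| `scripts/build_phyloseq.R` | CSVs → phyloseq object |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and known limitations.
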