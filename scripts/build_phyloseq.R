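#!/usr/bin/env Rscript
# Build a phyloseq object from the pipeline's exported CSVs.
# Usage: Rscript build_phyloseq.R <otu.csv> <tax.csv> <samples.csv> <out.rds>

suppressPackageStartupMessages(library(phyloseq))

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 4) {
  stop("usage: build_phyloseq.R <otu.csv> <tax.csv> <samples.csv> <out.rds>")
}
otu_csv <- args[1]; tax_csv <- args[2]; sample_csv <- args[3]; out_rds <- args[4]

otu <- read.csv(otu_csv, row.names = 1, check.names = FALSE)
tax <- read.csv(tax_csv, row.names = 1, check.names = FALSE,
                colClasses = "character")
samp <- read.csv(sample_csv, row.names = 1, check.names = FALSE,
                 comment.char = "")

missing_tax <- setdiff(rownames(otu), rownames(tax))
if (length(missing_tax) > 0) {
  stop(sprintf("taxa present in counts but missing from taxonomy: %s",
               paste(missing_tax, collapse = ", ")))
}
tax <- tax[rownames(otu), , drop = FALSE]

if (ncol(samp) == 0) samp$sample_id <- rownames(samp)

ps <- phyloseq(
  otu_table(as.matrix(otu), taxa_are_rows = TRUE),
  tax_table(as.matrix(tax)),
  sample_data(samp)
)
saveRDS(ps, out_rds)
cat(sprintf("phyloseq object: %d taxa x %d samples -> %s\n",
            ntaxa(ps), nsamples(ps), out_rds))
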