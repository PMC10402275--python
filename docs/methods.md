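# Methods

This note documents the models, defaults, and numerical choices behind
rrnpipe, and what the synthetic benchmark does and does not demonstrate
about real data.

## The processing model

The pipeline treats a multiplexed long-amplicon nanopore run as a sequence
of well-defined transformations on reads:

1. **Concatemer splitting.** Molecules traversing a pore in quick
   succession can be emitted as one artificial read with the ligation
   adapter at each junction. Reads are scanned for internal adapter
   occurrences (semi-global edit-distance search with edlib, both strands);
   all occurrences in a read are split in a single pass and passes iterate
   to a fixpoint (a `max_rounds=10` cap guards pathological inputs; in
   practice round 2 finds nothing). Occurrences within 20 bp of a read end
   are terminal adapter remnants, not junctions, and are left alone;
   fragments under 50 bp are discarded.
2. **Quality filtering.** Reads below mean quality Q10 are removed. "Mean
   quality" is the error-probability average
   `−10·log₁₀(mean(10^(−Qᵢ/10)))`, the convention of standard long-read
   filters; it equals Q for constant-quality reads and is otherwise below
   the arithmetic mean of the scores (Jensen).
3. **Demultiplexing.** Dual 16 nt barcodes (8 forward × 12 reverse = 96
   combinations) are sought within 150 bp of each read end at the
   best-scoring offset, using substitution-only (Hamming) distance —
   barcodes are short, and the mismatch tolerance is discussed in the
   field in substitution terms. Default tolerance is zero mismatches on
   both barcodes. A read is assigned only when exactly one (fwd, rev) pair
   matches across both orientations; any second pair within tolerance
   discards the read as ambiguous, favouring crosstalk control over yield.
   Minus-strand matches reverse complement the read, so downstream stages
   see plus-oriented reads only. Barcodes are excised and the excised
   length must lie in [3,000, 7,000] bp (applied post-barcode,
   pre-primer excision).
4. **Crosstalk floor.** Combinations not mapped to a sample are null
   controls. The crosstalk rate is `null reads / all demultiplexed reads`;
   as a percentage it becomes the per-sample relative-abundance floor
   applied to the final table. It is always computed from the run at hand,
   never hard-coded.
5. **Primer trimming / sub-region extraction.** The degenerate outer
   primers (27F `AGRRTTYGATYHTDGYTYAG`, U2428R `CCRAMCTGTCTCACGACG`) are
   located IUPAC-aware within 100 bp of the read ends, allowing
   `⌈0.1 × primer length⌉` mismatches (the convention of standard trimming
   tools). Everything outside and including the primer sites is removed;
   reads missing either site are flagged and excluded. Re-trimming a
   trimmed read therefore flags it — the product no longer contains primer
   sites. The same machinery extracts a "pseudo-V3V4" insert between inner
   primer sites anywhere in the read (default 341F/805R; the inner pair is
   configuration, and the defaults are stand-ins for whatever short-read
   primers a study used).
6. **Classification and EM.** Candidate references are found by shared
   15-mer seeding (read k-mers sampled every 7 bp vote for references;
   candidates need at least half the best vote count, capped at 20) and
   scored by glocal alignment of the full read against each candidate,
   allowing up to 0.35 edits/base. Identity is matched columns over
   alignment columns. The per-read likelihood is geometric per base,
   `L(r|k) = identity^aln_len`, computed in log space. EM starts uniform
   over hit taxa and stops when `max|Δaₖ| < 1e−6` (cap 1,000 iterations).
   Pruning (default 1e−5) is applied **once after convergence**, followed
   by renormalization and a final E-step — pruning inside the loop could
   break the monotonicity of the observed-data log-likelihood, which the
   tests assert per iteration. Reads with no hits are reported as
   unclassified and never redistributed. Hard per-read assignments take
   the maximum-responsibility taxon, ties broken by longer alignment, then
   smaller taxid.
7. **Tables.** Per-sample estimated counts form a taxa × samples table.
   Default filter order: aggregate to (genus, species) — blank genus rows
   dropped, blank species renamed "Unclassified" — then rarefaction
   (seeded multivariate hypergeometric; EM counts are rounded to integers
   first; samples under the depth are dropped with a warning), then the
   prevalence rule (keep taxa with strictly more than 5 reads in at least
   3 samples), then the crosstalk floor (strictly-below cells zeroed
   per sample; rows zeroed everywhere are dropped). Every operation is
   appended to a `filter_log`, and replaying the log on the raw table
   reproduces the final table exactly. The order is configurable; both
   comparators in the prevalence rule are read strictly (">5 in ≥3"),
   which is the conservative reading of an ambiguous phrasing.

## Pairwise identity

Global percent identity is defined canonically as `100·M/(M+d)`, where `d`
is the unit-cost edit distance and `M` the maximum number of matched
columns among all minimum-distance alignments. Any such alignment has
exactly `M+d` columns, so the value is independent of traceback
tie-breaking — unlike "matches over columns" read off an arbitrary
co-optimal alignment, which is not well defined (e.g. `AC` vs `CA` admits
co-optimal alignments with identity 0 % or 33 %). The implementation is a
single dynamic program over the combined integer weight
`2²¹·cost − matches` with vectorized rows (the in-row gap recurrence
reduces to a prefix minimum), and the tests verify it cell-for-cell
against an independent tuple-valued DP oracle.

## The synthetic generator

The generator emulates the read population of a multiplexed rrn run, and
its defaults are the benchmark's study conditions:

| parameter | default | meaning |
|---|---|---|
| `rrn_len` | 4,500 bp | amplicon length (16S-like head, ITS-like middle at 3× divergence, 23S-like tail) |
| `divergence` | 0.05 | per-base substitution rate from a common ancestor, per taxon |
| `error_rate` | 0.01 | per-base read error (≈Q20 chemistry) |
| `concatemer_fraction` | 0.02 | fraction of molecules stitched into concatemers |
| `n_samples` / `reads_per_sample` | 3 / 2,000 | mock replicates at the 8-species theoretical composition |
| barcodes | 16 nt, pairwise Hamming ≥ 7 | mirrors the substitution separation of real primer sets |
| adapter | fixed 24-mer | the kit adapter is run configuration; this is the generator's default |

Reads are assembled as
`adapter + fwd barcode + primer site + amplicon + rc(rev primer site) +
rc(rev barcode) + adapter`; per-base Phred scores are drawn around the
quality implied by `error_rate` (Normal jitter, σ = 2) and substitutions
are then drawn per base at the Phred-implied probability, so quality
strings and error process are mutually consistent. Errors hit the entire
construct — barcodes and adapters included — which is what makes the
demultiplexer's mismatch-tolerance behaviour measurable. Roughly half the
reads are emitted reverse complemented. Taxon counts per sample are one
multinomial draw from the configured composition. All randomness flows
from a single seed; identical configs give byte-identical runs. Inner
V3V4 primer sites are embedded at fixed positions and held invariant
across taxa so sub-region extraction has well-defined targets; taxon
lengths vary by a tail indel drawn Normal(0, 3 % of length), capped at
±10 %.

What the generator does **not** model: homopolymer-biased or
signal-level nanopore error profiles (substitution-only by default; an
optional uniform 1 bp indel mode exists for robustness tests), chimeras
other than adapter-joined concatemers, PCR amplification bias, and
real-database phenomena such as shared or misannotated reference
sequences. Passing the benchmark therefore demonstrates the correctness
of the pipeline's logic under idealized errors, not classifier
performance on real flow-cell data against curated databases.

## Numerical choices

- **Adapter scan tolerance** defaults to `⌊L/8⌋` edits (3 for the 24 nt
  default adapter). At `⌊L/4⌋` a 24-mer chance-matches inside 4.5 kb of
  random sequence often enough to split a noticeable fraction of clean
  reads (and systematically so, since a chance match in a reference
  recurs in every read of that taxon); at `⌊L/8⌋` chance hits were absent
  in 600 simulated reference-length windows while a junction adapter at a
  1 % error rate still exceeds 3 errors with probability ~1e−5.
- **Overlapping adapter hits** are resolved greedily by lowest edit
  distance, ties leftmost, masking each accepted span before re-searching.
- **Split boundaries** may shift by a base or two when the junction
  adapter carries errors (co-optimal alignments); junction-adjacent
  terminal adapter copies of the joined molecules are consumed with the
  junction.
- **Degenerate-base matching** uses 4-bit base sets; N in a read matches
  any primer symbol, and N read characters keep their stated quality.
- **Rarefaction** uses seed 42 by default and records seed and depth in
  the filter log. The end-to-end benchmark rarefies at 1,000 reads: with
  2,000 reads/sample and zero-mismatch dual-barcode demultiplexing,
  ~72 % of error-bearing reads survive to the table
  (0.99³² ≈ 0.725 of reads have error-free barcodes), so ~1,450
  reads/sample reach the table and a 1,900-read depth would drop every
  sample.
- **Benchmark comparison**: recovered abundances are compared per taxon
  after averaging over the replicate mock samples, against the configured
  composition. A single 2,000-read multinomial draw carries ~1 % sampling
  noise per taxon; averaging replicates compares the estimator rather
  than the draw.
- **EM likelihood** uses `identity^aln_len` rather than a full
  per-transition error model — a deliberate desk-scale simplification;
  with ≥5 % inter-taxon divergence and ~1 % read error the posterior is
  effectively concentrated on the source taxon, which is also why EM
  converges in a handful of iterations on the benchmark.

## Known limitations

- The demultiplexer's windowed search (150 bp) assumes barcodes near the
  read ends; heavily truncated reads fall out as `no_barcode`.
- `align_candidates` aligns the full read glocally; a read whose minority
  segment stems from a different taxon (undetected chimera) is scored as
  a whole.
- The 8×12 plate layout is fixed by design; other multiplexing geometries
  are out of scope.
- Fractional EM counts are rounded before rarefaction, which can shift a
  sample total by a few reads.
- `pairwise_identity` is exact but O(n·m); it is intended for
  amplicon-scale comparisons (hundreds of bp to a few kb), not genomes.
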