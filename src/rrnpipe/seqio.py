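"""FASTQ/FASTA I/O, Phred arithmetic, and per-stage run statistics.

The unit flowing through every pipeline stage is :class:`Read`: a DNA string
with one integer Phred score per base.  Quality arithmetic follows the
error-probability convention: a read's "mean quality" is the Phred transform
of the mean per-base error probability, not the arithmetic mean of the
scores.  This matches the behaviour of the standard long-read filtering
tools and is the quantity thresholded by the Q10 filter downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtnRYSWKMBDHVryswkmbdhv",
                            "TGCANtgcanYRSWMKVHDByrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R<->Y, M<->K, B<->V, D<->H)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records (names the offending record)."""


@dataclass
class Read:
    """A single sequencing read.

    Attributes
    ----------
    read_id : str
        Non-empty identifier, unique within a file.
    bases : str
        DNA over {A,C,G,T,N}.
    quals : np.ndarray
        Integer Phred scores, one per base, each >= 0.
    annotations : dict
        Optional provenance (sample, orientation, stage, ...).
    """

    read_id: str
    bases: str
    quals: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if len(self.quals) and self.quals.min() < 0:
            raise ValueError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int, new_id: str | None = None) -> "Read":
        """Sub-read with quals kept in register with bases."""
        return Read(
            new_id or self.read_id,
            self.bases[start:stop],
            self.quals[start:stop].copy(),
            dict(self.annotations),
        )

    def reverse_complement(self) -> "Read":
        return Read(
            self.read_id,
            revcomp(self.bases),
            self.quals[::-1].copy(),
            dict(self.annotations),
        )


def read_fastq(path) -> list[Read]:
    """Parse a 4-line-record, Phred+33 FASTQ file into Reads.

    Malformed records (sequence/quality length mismatch) raise
    :class:`FastqFormatError` naming the record.
    """
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                Read(rec.id, str(rec.seq).upper(),
                     np.asarray(rec.letter_annotations["phred_quality"],
                                dtype=np.int16))
            )
    except ValueError as exc:  # Biopython names the record in its message
        raise FastqFormatError(f"malformed FASTQ in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    """Write reads as Phred+33 FASTQ; round-trips exactly through read_fastq."""
    with open(path, "w") as fh:
        for r in reads:
            qline = "".join(chr(int(q) + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qline}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Phred arithmetic


def phred_to_error_prob(q) -> np.ndarray:
    return np.power(10.0, -np.asarray(q, dtype=float) / 10.0)


def mean_read_quality(read: Read) -> float:
    """Error-probability-averaged read quality.

    Returns -10*log10(mean_i 10^(-Q_i/10)).  Equals Q exactly for a
    constant-Q read and is <= the arithmetic mean otherwise (Jensen).
    """
    if len(read) == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    return float(-10.0 * np.log10(phred_to_error_prob(read.quals).mean()))


def phred_accuracy(q: float) -> float:
    """Percent per-base accuracy implied by a Phred score.

    100*(1 - 10^(-q/10)): Q12 -> 93.7%, Q20 -> 99.0%.
    """
    if q < 0:
        raise ValueError("Phred score must be >= 0")
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))


def expected_errors(q: float, read_length: int) -> float:
    """Expected error count on a read of the given length at mean quality q."""
    return read_length * (1.0 - phred_accuracy(q) / 100.0)


# ---------------------------------------------------------------------------
# Run statistics


@dataclass
class RunStats:
    """Per-stage summary: read/base counts, length and quality distribution."""

    stage_label: str
    n_reads: int
    n_bases: int
    avg_len: float
    med_len: float
    avg_q: float
    med_q: float
    pct_ge_q12: float
    pct_ge_q15: float

    HEADER = ("stage\tn_reads\tn_bases\tavg_len\tmed_len\t"
              "avg_q\tmed_q\tpct_ge_q12\tpct_ge_q15")

    def to_row(self) -> str:
        return (f"{self.stage_label}\t{self.n_reads}\t{self.n_bases}\t"
                f"{self.avg_len:.1f}\t{self.med_len:.1f}\t{self.avg_q:.2f}\t"
                f"{self.med_q:.2f}\t{self.pct_ge_q12:.1f}\t{self.pct_ge_q15:.1f}")


def summarize_run(reads: Sequence[Read], stage_label: str) -> RunStats:
    """Compute the run-statistics row for one pipeline stage.

    Per-read quality is :func:`mean_read_quality`; the >=Q12 / >=Q15
    percentages threshold that per-read mean.  Empty input yields zero
    counts with NaN summary fields.
    """
    n = len(reads)
    if n == 0:
        nan = float("nan")
        return RunStats(stage_label, 0, 0, nan, nan, nan, nan, nan, nan)
    lengths = np.array([len(r) for r in reads], dtype=float)
    mean_qs = np.array([mean_read_quality(r) for r in reads])
    return RunStats(
        stage_label=stage_label,
        n_reads=n,
        n_bases=int(lengths.sum()),
        avg_len=float(lengths.mean()),
        med_len=float(np.median(lengths)),
        avg_q=float(mean_qs.mean()),
        med_q=float(np.median(mean_qs)),
        pct_ge_q12=float(100.0 * (mean_qs >= 12).mean()),
        pct_ge_q15=float(100.0 * (mean_qs >= 15).mean()),
    )


def write_stats_tsv(stats: Sequence[RunStats], path) -> None:
    with open(path, "w") as fh:
        fh.write(RunStats.HEADER + "\n")
        for s in stats:
            fh.write(s.to_row() + "\n")
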