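"""IUPAC-aware primer location/removal and in-silico sub-region extraction.

The rrn amplicons are framed by the degenerate 27F / U2428R primer pair;
after demultiplexing these non-biological bases are excised.  The same
machinery extracts internal sub-regions ("pseudo-V3V4"): given the binding
sites of a short-read primer pair, the insert between them is cut out of
the long read to mimic a short-read amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import yaml

from .seqio import Read, revcomp

# IUPAC nucleotide codes as A/C/G/T bit masks
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
_BASE_BITS = np.zeros(128, dtype=np.uint8)
for _sym, _bits in _IUPAC_BITS.items():
    _BASE_BITS[ord(_sym)] = _bits

# default inner pair for pseudo-V3V4 extraction (341F / 805R); the real
# short-read primers are run configuration — these widely used sequences
# are stand-ins
V3V4_FORWARD = "CCTACGGGNGGCWGCAG"
V3V4_REVERSE = "GACTACHVGGGTATCTAATCC"

# the rrn outer primer pair (27F / U2428R)
RRN_FORWARD = "AGRRTTYGATYHTDGYTYAG"
RRN_REVERSE = "CCRAMCTGTCTCACGACG"


@dataclass
class PrimerPair:
    """A degenerate primer pair, both sequences written 5'->3'."""

    name: str
    forward: str
    reverse: str
    max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not 10 <= len(seq) <= 40:
                raise ValueError(f"primer length {len(seq)} outside 10..40")
            if set(seq) - set(_IUPAC_BITS):
                raise ValueError(f"non-IUPAC character in primer {seq!r}")

    def max_mismatches(self, pattern: str) -> int:
        return ceil(self.max_error_rate * len(pattern))

    @classmethod
    def from_yaml(cls, path) -> "PrimerPair":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(cfg["name"], cfg["forward"], cfg["reverse"],
                   float(cfg.get("max_error_rate", 0.1)))


def rrn_primers(**kwargs) -> PrimerPair:
    return PrimerPair("27F-U2428R", RRN_FORWARD, RRN_REVERSE, **kwargs)


def v3v4_primers(**kwargs) -> PrimerPair:
    return PrimerPair("341F-805R", V3V4_FORWARD, V3V4_REVERSE, **kwargs)


def iupac_match_count(pattern: str, window: str) -> int:
    """Mismatches between a degenerate pattern and a concrete window.

    A position matches when the window base is in the pattern symbol's
    allowed set (R={A,G}, H={A,C,T}, N=any, ...).
    """
    if len(pattern) != len(window):
        raise ValueError("pattern and window lengths differ")
    pbits = _BASE_BITS[np.frombuffer(pattern.encode(), dtype=np.uint8)]
    wbits = _BASE_BITS[np.frombuffer(window.upper().encode(), dtype=np.uint8)]
    return int(((pbits & wbits) == 0).sum())


def find_primer(seq: str, pattern: str, max_mismatches: int,
                start: int = 0, stop: int | None = None) -> tuple[int, int] | None:
    """Best occurrence of a degenerate pattern in seq[start:stop].

    Returns (position, mismatches) of the lowest-mismatch offset (ties:
    leftmost) if within tolerance, else None.
    """
    stop = len(seq) if stop is None else min(stop, len(seq))
    region = seq[start:stop]
    L = len(pattern)
    if len(region) < L:
        return None
    pbits = _BASE_BITS[np.frombuffer(pattern.encode(), dtype=np.uint8)]
    sbits = _BASE_BITS[np.frombuffer(region.encode(), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(sbits, L)
    mism = ((windows & pbits[None, :]) == 0).sum(axis=1)
    off = int(np.argmin(mism))
    if mism[off] > max_mismatches:
        return None
    return start + off, int(mism[off])


def trim_primers(read: Read, primers: PrimerPair,
                 search_window: int = 100) -> Read | None:
    """Excise everything outside and including the outer primer sites.

    The forward primer is sought within the first ``search_window`` bases
    and the reverse complement of the reverse primer within the last.
    Returns the interior read (quals in register) or None when either
    primer is missing within tolerance — such reads are flagged by the
    caller and excluded.  Idempotent: a trimmed read lacks primer sites,
    so a second trim returns None.
    """
    fwd = find_primer(read.bases, primers.forward,
                      primers.max_mismatches(primers.forward),
                      0, search_window)
    rc_rev = revcomp(primers.reverse)
    rev = find_primer(read.bases, rc_rev, primers.max_mismatches(rc_rev),
                      max(0, len(read) - search_window))
    if fwd is None or rev is None:
        return None
    start = fwd[0] + len(primers.forward)
    stop = rev[0]
    if stop <= start:
        return None
    out = read.slice(start, stop)
    out.annotations["trimmed"] = primers.name
    return out


def trim_reads(reads: Sequence[Read], primers: PrimerPair,
               search_window: int = 100) -> tuple[list[Read], int]:
    """Trim a batch; returns (trimmed reads, number flagged as missing a primer)."""
    kept: list[Read] = []
    flagged = 0
    for r in reads:
        t = trim_primers(r, primers, search_window)
        if t is None:
            flagged += 1
        else:
            kept.append(t)
    return kept, flagged


def extract_subregion(read: Read, inner: PrimerPair) -> Read | None:
    """Cut out the insert between an internal primer pair (primers excluded).

    Emulates a short-read amplicon drawn from the long read: the inner
    forward site is located anywhere in the read, the reverse-complemented
    inner reverse site anywhere downstream of it.  Returns None when
    either site is absent within tolerance.
    """
    fwd = find_primer(read.bases, inner.forward,
                      inner.max_mismatches(inner.forward))
    if fwd is None:
        return None
    start = fwd[0] + len(inner.forward)
    rc_rev = revcomp(inner.reverse)
    rev = find_primer(read.bases, rc_rev, inner.max_mismatches(rc_rev), start)
    if rev is None or rev[0] <= start:
        return None
    out = read.slice(start, rev[0])
    out.annotations["subregion"] = inner.name
    return out
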