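"""Mean-quality read filtering between pipeline stages.

The split reads are re-filtered by average Phred >= 10 before
demultiplexing; "average" is the error-probability-averaged read quality
(see :func:`rrnpipe.seqio.mean_read_quality`).  Length filtering is
deliberately not done here — the 3-7 kb window belongs to the
demultiplexing stage.
"""

from __future__ import annotations

from typing import Sequence

from .seqio import Read, mean_read_quality


def filter_by_quality(reads: Sequence[Read], min_mean_q: float = 10.0) -> list[Read]:
    """Retain exactly the reads with mean quality >= threshold, in order.

    The threshold is inclusive; filtering is idempotent and monotone in
    ``min_mean_q`` (retained sets are nested as the threshold rises).
    """
    if min_mean_q < 0:
        raise ValueError("min_mean_q must be >= 0")
    return [r for r in reads if mean_read_quality(r) >= min_mean_q]
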