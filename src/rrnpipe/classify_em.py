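"""Read classification against an rrn reference and EM abundance estimation.

Candidate references for each read are found by shared-k-mer seeding and
scored with a glocal (infix) edit-distance alignment (edlib).  Community
relative abundances are then estimated by expectation-maximization over
the per-read hit sets, the standard treatment when long reads map
ambiguously to several close references.  The per-read likelihood model is
geometric per-base: L(r|k) = identity^aln_len, i.e. an independent
per-column match probability equal to the observed alignment identity.

Final hard per-read assignments take the maximum-responsibility taxon,
with ties broken by the longer alignment and then the smaller taxid — the
"longest alignment wins" convention of long-read classifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .seqio import Read, read_fasta, write_fasta

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class RefEntry:
    taxid: int
    sequence: str
    taxonomy: dict[str, str]  # 7 ranks, values may be blank

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"taxid {self.taxid}: empty sequence")
        self.taxonomy = {r: self.taxonomy.get(r, "") for r in RANKS}


@dataclass
class ReferenceDB:
    """rrn sequences keyed to a 7-rank taxonomy (species may be blank)."""

    entries: list[RefEntry]

    def __post_init__(self) -> None:
        ids = [e.taxid for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("taxids must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def taxonomy_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([e.taxonomy for e in self.entries],
                          index=[e.taxid for e in self.entries])
        df.index.name = "taxid"
        return df

    def to_files(self, fasta_path, taxonomy_path) -> None:
        """FASTA with taxid headers + taxonomy TSV (taxid, 7 ranks)."""
        write_fasta({str(e.taxid): e.sequence for e in self.entries}, fasta_path)
        self.taxonomy_frame().to_csv(taxonomy_path, sep="\t")

    @classmethod
    def from_files(cls, fasta_path, taxonomy_path) -> "ReferenceDB":
        seqs = read_fasta(fasta_path)
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col="taxid",
                          dtype=str, keep_default_na=False)
        entries = [
            RefEntry(int(tid), seq, dict(tax.loc[int(tid)]))
            for tid, seq in seqs.items()
        ]
        return cls(entries)


@dataclass
class AlignmentHit:
    read_id: str
    taxid: int
    aln_len: int
    score: int  # matched columns
    identity: float  # matches / alignment columns


_CIG = re.compile(r"(\d+)([=XIDM])")


def _cigar_identity(cigar: str, dist: int) -> tuple[int, int, int]:
    """(matches, columns, query_len) from an edlib cigar."""
    counts = {"=": 0, "X": 0, "I": 0, "D": 0, "M": 0}
    for n, op in _CIG.findall(cigar):
        counts[op] += int(n)
    cols = sum(counts.values())
    if counts["="] or counts["X"]:
        matches = counts["="]
    else:  # standard cigar: mismatches folded into M
        matches = counts["M"] - (dist - counts["I"] - counts["D"])
    qlen = counts["="] + counts["X"] + counts["M"] + counts["I"]
    return matches, cols, qlen


def _kmer_index(db: ReferenceDB, k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for idx, entry in enumerate(db.entries):
        seq = entry.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], set()).add(idx)
    return index


def align_candidates(reads: Sequence[Read], db: ReferenceDB, k: int = 15,
                     max_hits: int = 20, seed_stride: int = 7,
                     seed_frac: float = 0.5,
                     max_divergence: float = 0.35) -> list[AlignmentHit]:
    """Seed-and-extend candidate alignments for each read.

    Read k-mers (sampled every ``seed_stride`` positions) vote for
    references; references with at least ``seed_frac`` of the best vote
    count (capped at ``max_hits``) are aligned glocally with edlib, the
    read as query against the full reference, allowing up to
    ``max_divergence`` edits per read base.  Reads with no seed or no
    alignment within the edit budget produce no hits (unclassified).
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    if k > min(len(e.sequence) for e in db.entries):
        raise ValueError("k exceeds the shortest reference sequence")
    index = _kmer_index(db, k)
    hits: list[AlignmentHit] = []
    for read in reads:
        seq = read.bases
        votes = np.zeros(len(db), dtype=int)
        for i in range(0, max(1, len(seq) - k + 1), seed_stride):
            for ridx in index.get(seq[i:i + k], ()):
                votes[ridx] += 1
        best = votes.max() if votes.size else 0
        if best == 0:
            continue
        cand = np.nonzero(votes >= max(1, seed_frac * best))[0]
        cand = cand[np.argsort(-votes[cand], kind="stable")][:max_hits]
        budget = int(max_divergence * len(seq))
        for ridx in cand:
            res = edlib.align(seq, db.entries[ridx].sequence,
                              mode="HW", task="path", k=budget)
            if res["editDistance"] < 0:
                continue
            matches, cols, _ = _cigar_identity(res["cigar"], res["editDistance"])
            hits.append(AlignmentHit(
                read_id=read.read_id,
                taxid=db.entries[ridx].taxid,
                aln_len=len(seq),
                score=matches,
                identity=matches / cols if cols else 0.0,
            ))
    return hits


@dataclass
class AbundanceEstimate:
    """EM output: relative abundances, est. counts, per-read assignments."""

    abundances: dict[int, float]
    est_counts: dict[int, float]
    n_iterations: int
    converged: bool
    log_likelihoods: list[float] = field(default_factory=list)
    read_assignments: dict[str, int] = field(default_factory=dict)


def em_abundances(hits: Sequence[AlignmentHit], tol: float = 1e-6,
                  max_iter: int = 1000, prune: float = 1e-5) -> AbundanceEstimate:
    """Estimate relative abundances by EM over per-read hit sets.

    E-step: P(k|r) = a_k L(r|k) / sum_j a_j L(r|j) with
    L(r|k) = identity^aln_len (computed in log space).  M-step:
    a_k <- mean_r P(k|r).  Initialization is uniform over taxa with at
    least one hit.  After convergence, taxa below ``prune`` are zeroed and
    the remaining mass renormalized; a final E-step yields hard per-read
    assignments (ties: larger aln_len, then smaller taxid).
    """
    if not hits:
        raise ValueError("no alignment hits to estimate from")
    taxids = sorted({h.taxid for h in hits})
    tax_idx = {t: i for i, t in enumerate(taxids)}
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    read_ids = sorted(by_read)
    n_reads, n_tax = len(read_ids), len(taxids)

    # log-likelihood matrix, -inf where a read has no hit on a taxon
    loglik = np.full((n_reads, n_tax), -np.inf)
    aln_lens = np.zeros((n_reads, n_tax), dtype=int)
    for ri, rid in enumerate(read_ids):
        for h in by_read[rid]:
            ll = h.aln_len * np.log(max(h.identity, 1e-12))
            ti = tax_idx[h.taxid]
            if ll > loglik[ri, ti]:  # keep best hit per (read, taxon)
                loglik[ri, ti] = ll
                aln_lens[ri, ti] = h.aln_len

    a = np.full(n_tax, 1.0 / n_tax)
    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            joint = loglik + np.log(a)[None, :]
        norm = logsumexp(joint, axis=1)
        ll_trace.append(float(norm.sum()))
        resp = np.exp(joint - norm[:, None])
        a_new = resp.mean(axis=0)
        if np.max(np.abs(a_new - a)) < tol:
            a = a_new
            converged = True
            break
        a = a_new

    # prune-and-renormalize once, then final responsibilities
    a[a < prune] = 0.0
    if a.sum() == 0:
        raise ValueError("all taxa pruned; lower the prune threshold")
    a /= a.sum()
    with np.errstate(divide="ignore"):
        joint = loglik + np.where(a > 0, np.log(np.where(a > 0, a, 1.0)),
                                  -np.inf)[None, :]
    norm = logsumexp(joint, axis=1)
    orphan = ~np.isfinite(norm)  # every hit taxon pruned: use raw likelihoods
    joint[orphan] = loglik[orphan]
    norm[orphan] = logsumexp(loglik[orphan], axis=1)
    resp = np.exp(joint - norm[:, None])
    resp[orphan] = 0.0  # orphans keep a hard assignment but no soft mass

    assignments: dict[str, int] = {}
    for ri, rid in enumerate(read_ids):
        row = resp[ri]
        best = row.max()
        tie = np.nonzero(row >= best - 1e-12)[0]
        if len(tie) > 1:  # longer alignment wins, then smaller taxid
            order = sorted(tie, key=lambda ti: (-aln_lens[ri, ti], taxids[ti]))
            choice = order[0]
        else:
            choice = int(tie[0])
        assignments[rid] = taxids[choice]

    counts = resp.sum(axis=0)
    return AbundanceEstimate(
        abundances={t: float(a[tax_idx[t]]) for t in taxids},
        est_counts={t: float(counts[tax_idx[t]]) for t in taxids},
        n_iterations=it,
        converged=converged,
        log_likelihoods=ll_trace,
        read_assignments=assignments,
    )


def classify_sample(reads: Sequence[Read], db: ReferenceDB,
                    **kwargs) -> tuple[AbundanceEstimate, int]:
    """Align then EM for one sample; returns (estimate, n_unclassified).

    Unclassified reads (no hit within the edit budget) are counted
    separately and never redistributed among taxa.
    """
    em_keys = {"tol", "max_iter", "prune"}
    em_kwargs = {k: v for k, v in kwargs.items() if k in em_keys}
    aln_kwargs = {k: v for k, v in kwargs.items() if k not in em_keys}
    hits = align_candidates(reads, db, **aln_kwargs)
    hit_reads = {h.read_id for h in hits}
    n_unclassified = sum(1 for r in reads if r.read_id not in hit_reads)
    estimate = em_abundances(hits, **em_kwargs)
    return estimate, n_unclassified


# ---------------------------------------------------------------------------
# Pairwise identity (global alignment)


def _pair_identity(a: str, b: str) -> float:
    """Percent identity of a global alignment of a and b.

    Identity is matches / alignment columns x 100 under the canonical
    alignment: minimum unit-cost edit distance d, ties resolved toward the
    maximum number of matched columns M.  Every such alignment has exactly
    M + d columns, so the value is traceback-independent.

    Implemented as a single DP over the combined integer weight
    BIG*cost - matches (lexicographic minimization); rows are vectorized,
    the in-row gap recurrence resolved with a prefix-minimum.
    """
    n, m = len(a), len(b)
    BIG = np.int64(1) << 21
    if max(n, m) >= BIG:
        raise ValueError("sequences too long for pairwise identity DP")
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    idx = np.arange(m + 1, dtype=np.int64)
    prev = idx * BIG  # first row: j gaps
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], np.int64(-1), BIG)  # match: -1, mismatch: +BIG
        cand = np.empty(m + 1, dtype=np.int64)
        cand[0] = prev[0] + BIG  # gap up only
        cand[1:] = np.minimum(prev[:-1] + sub, prev[1:] + BIG)
        # left-gap closure: cur[j] = min_{i<=j} cand[i] + (j-i)*BIG
        cur = np.minimum.accumulate(cand - idx * BIG) + idx * BIG
        prev = cur
    comb = int(prev[m])
    q, r = divmod(comb, int(BIG))
    cost, matches = (q, 0) if r == 0 else (q + 1, int(BIG) - r)
    cols = matches + cost
    return 100.0 * matches / cols if cols else 100.0


def pairwise_identity(seqs: dict[str, str]) -> pd.DataFrame:
    """All-vs-all percent identity matrix (symmetric, 100 on the diagonal)."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for name, s in seqs.items():
        if not s:
            raise ValueError(f"sequence {name!r} is empty")
    names = list(seqs)
    mat = np.full((len(names), len(names)), 100.0)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ident = _pair_identity(seqs[names[i]], seqs[names[j]])
            mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=names, columns=names)


def write_abundance_tsv(estimate: AbundanceEstimate, db: ReferenceDB, path) -> None:
    tax = db.taxonomy_frame()
    rows = []
    for taxid, ab in sorted(estimate.abundances.items()):
        row = {"taxid": taxid, "abundance": ab,
               "est_counts": estimate.est_counts[taxid]}
        row.update(tax.loc[taxid])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
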