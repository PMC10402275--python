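"""Ground-truthed synthetic rrn sequencing runs.

Generates a toy rrn (16S-ITS-23S) reference database and barcoded,
adapter-flanked, error-bearing reads with a truth manifest, emulating the
read population of a multiplexed long-amplicon nanopore run: ~4.5 kb
amplicons carrying dual 16 nt barcodes, flanking adapters, per-base
Phred-consistent substitution errors, and a configurable fraction of
concatemer artifacts.  Known-composition samples stand in for commercial
mock communities as classification ground truth.

Every stage of the pipeline is testable against the manifest without any
external data.  All randomness flows from the single ``SimConfig.seed``:
identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify_em import RANKS, RefEntry, ReferenceDB
from .demux import BARCODE_LEN, N_FORWARD, N_REVERSE, BarcodeScheme
from .seqio import Read, revcomp
from .trim_extract import RRN_FORWARD, RRN_REVERSE, V3V4_FORWARD, V3V4_REVERSE

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed synthetic ligation adapter (the sequencing-kit adapter is run
# configuration; this 24-mer is the generator's default)
DEFAULT_ADAPTER = "TGCTGATCGTCAGCAACGTCTAGA"

# concrete binding sites compatible with the degenerate rrn primers
# (27F: AGRRTTYGATYHTDGYTYAG; U2428R: CCRAMCTGTCTCACGACG)
FWD_PRIMER_SITE = "AGAGTTTGATCATGGCTCAG"
REV_PRIMER_SITE_RC = revcomp("CCAAACTGTCTCACGACG")

# concrete inner V3V4 sites embedded in the 16S segment so pseudo-V3V4
# extraction has targets (341F: CCTACGGGNGGCWGCAG; 805R: GACTACHVGGGTATCTAATCC)
V3V4_FWD_SITE = "CCTACGGGAGGCAGCAG"
V3V4_REV_SITE_RC = revcomp("GACTACCAGGGTATCTAATCC")
_V3V4_FWD_POS = 340   # site start within the amplicon
_V3V4_REV_POS = 764   # rc(805R) site start -> ~390 bp insert between sites

# theoretical composition of the 8-species commercial mock standard (%)
MOCK_COMPOSITION = {
    "Lactiplantibacillus fermentum": 18.4,
    "Bacillus subtilis": 17.4,
    "Staphylococcus aureus": 15.5,
    "Listeria monocytogenes": 14.1,
    "Salmonella enterica": 10.4,
    "Escherichia coli": 10.1,
    "Enterococcus faecalis": 9.9,
    "Pseudomonas aeruginosa": 4.2,
}


@dataclass
class SimConfig:
    """Study conditions for a synthetic run.

    Defaults emulate the real read population: 4.5 kb amplicons, ~5%
    inter-taxon divergence (tripled in the ITS segment), 1% read error
    (Q20 chemistry), 2% concatemer contamination.
    """

    n_taxa: int = 12
    rrn_len: int = 4500
    divergence: float = 0.05
    n_samples: int = 3
    reads_per_sample: int = 2000
    error_rate: float = 0.01
    concatemer_fraction: float = 0.02
    adapter: str = DEFAULT_ADAPTER
    indel_rate: float = 0.0  # optional; substitution-only by default
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 <= self.concatemer_fraction <= 0.5:
            raise ValueError("concatemer_fraction must be in [0, 0.5]")
        if self.n_samples > N_FORWARD * N_REVERSE:
            raise ValueError("n_samples exceeds the number of barcode combinations")


# ---------------------------------------------------------------------------
# Barcode scheme generation


def _random_barcodes(n: int, rng: np.random.Generator,
                     existing: list[str], min_dist: int = 7) -> list[str]:
    out: list[str] = []
    pool = list(existing)
    while len(out) < n:
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, BARCODE_LEN))
        if all(sum(a != b for a, b in zip(cand, other)) >= min_dist
               for other in pool):
            out.append(cand)
            pool.append(cand)
    return out


def make_scheme(n_samples: int, seed: int = 0) -> BarcodeScheme:
    """An 8x12 dual-barcode scheme with the first ``n_samples`` combinations
    mapped to samples (row-major) and the rest left as null controls.

    Barcodes are 16 nt with pairwise Hamming distance >= 7, mirroring the
    substitution separation of the real primer sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBC]))
    fwd_seqs = _random_barcodes(N_FORWARD, rng, [])
    rev_seqs = _random_barcodes(N_REVERSE, rng, fwd_seqs)
    forward = {f"F{i+1:02d}": s for i, s in enumerate(fwd_seqs)}
    reverse = {f"R{i+1:02d}": s for i, s in enumerate(rev_seqs)}
    combos = [(f, r) for f in forward for r in reverse]
    sample_map = {combos[i]: f"S{i+1:02d}" for i in range(n_samples)}
    return BarcodeScheme(forward, reverse, sample_map)


# ---------------------------------------------------------------------------
# Reference database


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def _mutate(seq: np.ndarray, rate: np.ndarray | float,
            rng: np.random.Generator,
            protected: np.ndarray | None = None) -> np.ndarray:
    """Substitute bases at the given per-position rate(s)."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if protected is not None:
        hit &= ~protected
    idx = np.nonzero(hit)[0]
    if len(idx):
        # draw a base different from the current one
        shift = rng.integers(1, 4, len(idx))
        cur = np.searchsorted(_BASES, out[idx])  # A,C,G,T are sorted
        out[idx] = _BASES[(cur + shift) % 4]
    return out


def build_reference(config: SimConfig,
                    species_names: Sequence[str] | None = None) -> ReferenceDB:
    """Simulate an rrn reference: n_taxa sequences from one ancestor.

    The amplicon mimics the operon's structure: a 16S-like head, a short
    ITS-like middle with 3x the substitution rate (the spacer is the
    fastest-evolving part of the operon), and a 23S-like tail.  Inner
    V3V4 primer sites are embedded in the head and held invariant so
    sub-region extraction has well-defined targets.  Taxa come in
    congeneric pairs (shared ranks above species); sequence lengths vary
    by up to +/-10% via tail indels.
    """
    if config.n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if config.divergence == 0 and config.n_taxa > 1:
        raise ValueError("divergence 0 with n_taxa > 1: taxa indistinguishable")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDB]))
    L = config.rrn_len
    ancestor = _random_seq(rng, L)
    # embed invariant inner primer sites
    fsite = np.frombuffer(V3V4_FWD_SITE.encode(), dtype=np.uint8)
    rsite = np.frombuffer(V3V4_REV_SITE_RC.encode(), dtype=np.uint8)
    ancestor[_V3V4_FWD_POS:_V3V4_FWD_POS + len(fsite)] = fsite
    ancestor[_V3V4_REV_POS:_V3V4_REV_POS + len(rsite)] = rsite
    protected = np.zeros(L, dtype=bool)
    protected[_V3V4_FWD_POS:_V3V4_FWD_POS + len(fsite)] = True
    protected[_V3V4_REV_POS:_V3V4_REV_POS + len(rsite)] = True

    # per-position substitution rate: 3x in the ITS-like middle segment
    seg16 = L // 3
    its_len = max(1, round(0.09 * L))
    rates = np.full(L, config.divergence)
    rates[seg16:seg16 + its_len] = min(0.75, 3 * config.divergence)

    entries: list[RefEntry] = []
    for i in range(config.n_taxa):
        seq = _mutate(ancestor, rates, rng, protected)
        # length variation via a tail indel (typically a few %, capped at
        # +/-10%), keeping inner sites intact
        delta = int(np.clip(round(rng.normal(0.0, 0.03 * L)), -L // 10, L // 10))
        if delta > 0:
            seq = np.concatenate([seq, _random_seq(rng, delta)])
        elif delta < 0:
            seq = seq[:delta]
        if species_names and i < len(species_names):
            genus, species = species_names[i].split(" ", 1)
        else:
            genus = f"Synthbacter{i // 2 + 1}"  # congeneric pairs
            species = f"Synthbacter{i // 2 + 1} taxon{i + 1}"
        taxonomy = dict(zip(RANKS, (
            "Bacteria", "Synthphyla", "Synthclassia", f"Synthorder{i // 4 + 1}",
            f"Synthfamily{i // 4 + 1}", genus, species)))
        entries.append(RefEntry(1000 + i, seq.tobytes().decode("ascii"), taxonomy))
    db = ReferenceDB(entries)
    if config.n_taxa > 1:
        pairs_identical = any(
            entries[i].sequence == entries[j].sequence
            for i in range(len(entries)) for j in range(i + 1, len(entries)))
        if pairs_identical:
            raise RuntimeError("degenerate simulation: identical taxa generated")
    return db


# ---------------------------------------------------------------------------
# Read simulation


def _phred_consistent_quals(n: int, error_rate: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Per-base Phred scores whose implied mean error prob ~ error_rate."""
    if error_rate <= 0:
        return np.full(n, 60, dtype=np.int16)
    q0 = -10.0 * np.log10(error_rate)
    q = np.clip(np.rint(q0 + rng.normal(0.0, 2.0, n)), 2, 60)
    return q.astype(np.int16)


def simulate_reads(db: ReferenceDB, scheme: BarcodeScheme,
                   composition: dict[str, dict[int, float]],
                   config: SimConfig) -> tuple[list[Read], pd.DataFrame]:
    """Simulate one multiplexed run with a truth manifest.

    Each read is assembled as
    ``adapter + fwd_barcode + fwd_primer_site + amplicon + rc(rev_primer_site)
    + rc(rev_barcode) + adapter``; substitution errors at the
    Phred-implied per-base rate are applied over the whole construct, and
    ~half the reads are emitted reverse complemented.  Per-sample taxon
    counts are one seeded multinomial draw from the configured
    composition.

    ``composition`` maps sample_id -> {taxid: proportion} (each sample
    summing to 1).  The manifest has one row per source molecule:
    read_id, source_taxon, sample_id, fwd_id/rev_id, orientation,
    concat_group (NA until concatemers are injected), pre_error_seq (the
    amplicon interior before errors).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EAD]))
    by_taxid = {e.taxid: e for e in db.entries}
    pair_for_sample = {s: p for p, s in scheme.sample_map.items()}
    refs_enc = {t: np.frombuffer(e.sequence.encode(), dtype=np.uint8)
                for t, e in by_taxid.items()}

    reads: list[Read] = []
    rows: list[dict] = []
    for sample_id, taxa_props in composition.items():
        if sample_id not in pair_for_sample:
            raise ValueError(f"sample {sample_id!r} not in the barcode scheme")
        unknown = set(taxa_props) - set(by_taxid)
        if unknown:
            raise ValueError(f"unknown taxa in composition: {sorted(unknown)}")
        props = np.array(list(taxa_props.values()), dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions for {sample_id!r} sum to {props.sum()}")
        taxids = list(taxa_props)
        counts = rng.multinomial(config.reads_per_sample, props)
        fwd_id, rev_id = pair_for_sample[sample_id]
        fwd_bc = scheme.forward[fwd_id]
        rev_bc_rc = revcomp(scheme.reverse[rev_id])
        head = (config.adapter + fwd_bc + FWD_PRIMER_SITE)
        tail = (REV_PRIMER_SITE_RC + rev_bc_rc + config.adapter)
        head_enc = np.frombuffer(head.encode(), dtype=np.uint8)
        tail_enc = np.frombuffer(tail.encode(), dtype=np.uint8)
        for taxid, n_reads in zip(taxids, counts):
            amplicon = refs_enc[taxid]
            for _ in range(n_reads):
                rid = f"{sample_id}_r{len(rows):06d}"
                construct = np.concatenate([head_enc, amplicon, tail_enc])
                quals = _phred_consistent_quals(len(construct),
                                               config.error_rate, rng)
                if config.error_rate > 0:
                    per_base = np.power(10.0, -quals / 10.0)
                    construct = _mutate(construct, per_base, rng)
                if config.indel_rate > 0:
                    construct, quals = _apply_indels(
                        construct, quals, config.indel_rate, rng)
                orientation = "+" if rng.random() < 0.5 else "-"
                bases = construct.tobytes().decode("ascii")
                if orientation == "-":
                    bases = revcomp(bases)
                    quals = quals[::-1]
                reads.append(Read(rid, bases, quals,
                                  {"sample": sample_id, "taxid": taxid}))
                rows.append({
                    "read_id": rid, "source_taxon": taxid,
                    "sample_id": sample_id, "fwd_id": fwd_id,
                    "rev_id": rev_id, "orientation": orientation,
                    "concat_group": pd.NA,
                    "pre_error_seq": by_taxid[taxid].sequence,
                })
    manifest = pd.DataFrame(rows)
    if not manifest.empty:
        manifest["final_read_id"] = manifest["read_id"]
    return reads, manifest


def _apply_indels(seq: np.ndarray, quals: np.ndarray, rate: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Optional indel mode for robustness tests: equal-rate 1 bp ins/del."""
    keep = rng.random(len(seq)) >= rate / 2.0
    seq, quals = seq[keep], quals[keep]
    ins_mask = rng.random(len(seq)) < rate / 2.0
    if ins_mask.any():
        pos = np.nonzero(ins_mask)[0]
        ins_bases = _random_seq(rng, len(pos))
        seq = np.insert(seq, pos, ins_bases)
        quals = np.insert(quals, pos, quals[pos])
    return seq, quals


def inject_concatemers(reads: Sequence[Read], manifest: pd.DataFrame,
                       fraction: float, seed: int,
                       adapter: str = DEFAULT_ADAPTER,
                       adapter_q: int = 20) -> tuple[list[Read], pd.DataFrame]:
    """Artificially stitch a fraction of reads into concatemers.

    ``round(fraction * n)`` joins are performed; each join appends one
    read to a growing group (so some groups become triples and larger),
    with the adapter retained at each junction.  Biological bases are
    conserved.  The manifest keeps one row per source molecule; joined
    rows share a ``concat_group`` id and a ``final_read_id``.
    """
    if not 0 <= fraction <= 0.5:
        raise ValueError("fraction must be in [0, 0.5]")
    reads = list(reads)
    n = len(reads)
    n_joins = round(fraction * n)
    manifest = manifest.copy()
    if n_joins == 0 or n < 2:
        return reads, manifest
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA7]))
    order = rng.permutation(n)
    # the first n_joins+? reads in the shuffled order are grouped: each join
    # merges the next victim into the current group
    groups: list[list[int]] = []
    victims = list(order[: 2 * n_joins])  # 2 members for the 1st join, +1 each after
    g: list[int] = []
    joins_left = n_joins
    for idx in victims:
        g.append(idx)
        if len(g) >= 2:
            joins_left -= 1
            # randomly close the group (bias to pairs, some triples+)
            if joins_left == 0 or rng.random() < 0.7:
                groups.append(g)
                g = []
            if joins_left == 0:
                break
    if len(g) >= 2:
        groups.append(g)
    grouped = {i for grp in groups for i in grp}

    adapter_quals = np.full(len(adapter), adapter_q, dtype=np.int16)
    out: list[Read] = [r for i, r in enumerate(reads) if i not in grouped]
    id_map: dict[str, tuple[str, int]] = {}
    for gid, grp in enumerate(groups):
        members = [reads[i] for i in grp]
        bases = members[0].bases
        quals = [members[0].quals]
        for m in members[1:]:
            bases += adapter + m.bases
            quals.extend([adapter_quals, m.quals])
        cat_id = f"cat{gid:05d}_" + members[0].read_id
        out.append(Read(cat_id, bases, np.concatenate(quals),
                        {"concatemer": True}))
        for m in members:
            id_map[m.read_id] = (cat_id, gid)
    mapped = manifest["read_id"].map(lambda r: id_map.get(r))
    has = mapped.notna()
    manifest.loc[has, "final_read_id"] = mapped[has].map(lambda t: t[0])
    manifest.loc[has, "concat_group"] = mapped[has].map(lambda t: t[1])
    return out, manifest


def write_truth_tsv(manifest: pd.DataFrame, path) -> None:
    """Truth TSV (sequence column omitted: it is derivable from the reference)."""
    cols = ["read_id", "final_read_id", "source_taxon", "sample_id",
            "fwd_id", "rev_id", "orientation", "concat_group"]
    manifest[cols].to_csv(path, sep="\t", index=False)
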