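"""Candidate alignment, EM abundance estimation, pairwise identity."""

import numpy as np
import pytest

from rrnpipe import synthetic
from rrnpipe.classify_em import (AlignmentHit, ReferenceDB, RefEntry,
                                 align_candidates, classify_sample,
                                 em_abundances, pairwise_identity,
                                 _pair_identity)
from rrnpipe.seqio import Read


def nw_oracle(a, b):
    """Independent DP: lexicographic (edit cost, -matches) optimum.

    Returns percent identity = 100*M/(M+d) with d the unit-cost edit
    distance and M the maximum match count among minimum-cost alignments.
    """
    n, m = len(a), len(b)
    INF = (10**9, 0)
    prev = [(j, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(i, 0)] + [INF] * m
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                diag = (prev[j - 1][0], prev[j - 1][1] - 1)
            else:
                diag = (prev[j - 1][0] + 1, prev[j - 1][1])
            up = (prev[j][0] + 1, prev[j][1])
            left = (cur[j - 1][0] + 1, cur[j - 1][1])
            cur[j] = min(diag, up, left)
        prev = cur
    d, neg_m = prev[m]
    matches = -neg_m
    cols = matches + d
    return 100.0 * matches / cols if cols else 100.0


def _hit(rid, taxid, aln_len=1000, identity=0.99):
    return AlignmentHit(rid, taxid, aln_len, int(identity * aln_len), identity)


@pytest.fixture(scope="module")
def toy_db():
    cfg = synthetic.SimConfig(n_taxa=8, divergence=0.05, seed=21)
    return synthetic.build_reference(cfg)


class TestAlignCandidates:
    def test_exact_substring_read_hits_source(self, toy_db):
        src = toy_db.entries[2]
        read = Read("r", src.sequence[500:2500],
                    np.full(2000, 40, dtype=np.int16))
        hits = align_candidates([read], toy_db)
        best = max(hits, key=lambda h: h.identity)
        assert best.taxid == src.taxid
        assert best.identity == pytest.approx(1.0)

    def test_foreign_sequence_no_hits(self, toy_db):
        rng = np.random.default_rng(4)
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        read = Read("r", bases, np.full(60, 40, dtype=np.int16))
        # 60 bp of random sequence shares no seeded 15-mer with the db
        assert align_candidates([read], toy_db) == []

    def test_k_larger_than_reference_rejected(self):
        db = ReferenceDB([RefEntry(1, "ACGTACGTAC",
                                   dict.fromkeys(["genus"], "G"))])
        read = Read("r", "ACGT", np.full(4, 40, dtype=np.int16))
        with pytest.raises(ValueError):
            align_candidates([read], db, k=15)

    def test_noisy_reads_recover_source_taxon(self, toy_db):
        """1% error reads against >=5%-diverged taxa: top hit is the source."""
        rng = np.random.default_rng(5)
        n_reads, correct = 300, 0
        entries = toy_db.entries
        for i in range(n_reads):
            src = entries[i % len(entries)]
            seq = np.frombuffer(src.sequence.encode(), dtype=np.uint8).copy()
            errs = rng.random(len(seq)) < 0.01
            idx = np.nonzero(errs)[0]
            seq[idx] = np.frombuffer(b"ACGT", dtype=np.uint8)[
                rng.integers(0, 4, len(idx))]
            read = Read(f"r{i}", seq.tobytes().decode(),
                        np.full(len(seq), 20, dtype=np.int16))
            hits = align_candidates([read], toy_db)
            best = max(hits, key=lambda h: h.identity)
            correct += best.taxid == src.taxid
        assert correct / n_reads >= 0.99


class TestEM:
    def test_unique_mapping_fixed_point(self):
        hits = [_hit(f"a{i}", 1) for i in range(60)] + \
               [_hit(f"b{i}", 2) for i in range(40)]
        est = em_abundances(hits)
        assert est.abundances[1] == pytest.approx(0.6, abs=1e-9)
        assert est.abundances[2] == pytest.approx(0.4, abs=1e-9)

    def test_single_taxon(self):
        est = em_abundances([_hit("r1", 7), _hit("r2", 7)])
        assert est.abundances == {7: 1.0}

    def test_symmetric_shared_reads_split_evenly(self):
        """50 unique to A, 50 unique to B, 100 equal-likelihood shared
        -> 0.5/0.5 (the symmetric fixed point)."""
        hits = [_hit(f"a{i}", 1) for i in range(50)] + \
               [_hit(f"b{i}", 2) for i in range(50)]
        for i in range(100):
            hits += [_hit(f"s{i}", 1), _hit(f"s{i}", 2)]
        est = em_abundances(hits, tol=1e-9)
        assert est.abundances[1] == pytest.approx(0.5, abs=1e-6)
        assert est.abundances[2] == pytest.approx(0.5, abs=1e-6)

    def test_loglik_monotone(self, mock_pipeline_result):
        for est in mock_pipeline_result.estimates.values():
            ll = est.log_likelihoods
            assert all(b >= a - 1e-8 for a, b in zip(ll, ll[1:]))

    def test_abundances_sum_to_one(self, mock_pipeline_result):
        for est in mock_pipeline_result.estimates.values():
            assert sum(est.abundances.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(a >= 0 for a in est.abundances.values())

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        hits = []
        for i in range(200):
            taxa = rng.choice(5, size=rng.integers(1, 4), replace=False)
            for t in taxa:
                hits.append(_hit(f"r{i}", int(t) + 1, 2000,
                                 0.9 + 0.1 * rng.random()))
        est1 = em_abundances(hits)
        perm = [hits[i] for i in rng.permutation(len(hits))]
        est2 = em_abundances(perm)
        for t in est1.abundances:
            assert est2.abundances[t] == pytest.approx(
                est1.abundances[t], abs=1e-9)

    def test_hard_assignment_tie_breaks(self):
        # perfect-identity hits have likelihood 1 regardless of length, so
        # with symmetric abundances the responsibilities tie exactly
        base = [_hit("x", 1), _hit("y", 2)]  # keeps abundances symmetric
        longer_wins = base + [AlignmentHit("r", 1, 500, 500, 1.0),
                              AlignmentHit("r", 2, 800, 800, 1.0)]
        assert em_abundances(longer_wins).read_assignments["r"] == 2
        equal_lengths = base + [AlignmentHit("r", 1, 500, 500, 1.0),
                                AlignmentHit("r", 2, 500, 500, 1.0)]
        assert em_abundances(equal_lengths).read_assignments["r"] == 1

    def test_no_hits_rejected(self):
        with pytest.raises(ValueError):
            em_abundances([])

    def test_unclassified_counted_separately(self, toy_db):
        rng = np.random.default_rng(9)
        good = Read("g", toy_db.entries[0].sequence[:2000],
                    np.full(2000, 30, dtype=np.int16))
        junk = Read("j", "".join("ACGT"[i] for i in rng.integers(0, 4, 500)),
                    np.full(500, 30, dtype=np.int16))
        est, n_uncl = classify_sample([good, junk], toy_db)
        assert n_uncl == 1
        assert "j" not in est.read_assignments


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        m = pairwise_identity({"a": "ACGT" * 100, "b": "ACGT" * 100})
        assert m.loc["a", "b"] == 100.0
        assert (np.diag(m.values) == 100.0).all()

    def test_single_substitution(self):
        a = "A" * 50 + "C" + "G" * 49
        b = "A" * 50 + "T" + "G" * 49
        assert pairwise_identity({"a": a, "b": b}).loc["a", "b"] == \
            pytest.approx(99.0)

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        seqs = {f"s{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 120))
                for i in range(4)}
        m = pairwise_identity(seqs)
        assert np.allclose(m.values, m.values.T)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity({"a": "ACGT", "b": ""})

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity({"a": "ACGT"})

    def test_agrees_with_bruteforce_dp(self):
        """Implementation vs independent DP oracle on random short pairs."""
        rng = np.random.default_rng(11)
        for _ in range(150):
            n1, n2 = rng.integers(1, 51, 2)
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, n1))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, n2))
            assert _pair_identity(a, b) == nw_oracle(a, b)
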