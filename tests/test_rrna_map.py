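"""Seed-and-extend mapping: decomposition, alignment, statistics, merge."""

import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import mutate_with_indels, optimal_local_score, random_dna
from pmeta.io_formats import SequenceRecord, TabularHit
from pmeta.rrna_map import (ReferenceIndex, ScoringScheme, align, best_hit,
                            decompose, karlin_altschul_params, parallel_map)


def _recs(lengths, prefix="q"):
    return [SequenceRecord(id=f"{prefix}{i}", residues="A" * n)
            for i, n in enumerate(lengths)]


# --- problem decomposition ---------------------------------------------------

def test_decompose_equal_queries_into_thread_count_chunks():
    # 240 equal-length queries over 24 chunks: 24 chunks of 10
    plan = decompose(_recs([100] * 240), 24)
    assert len(plan) == 24
    assert all(len(c) == 10 for c in plan)


def test_decompose_degenerate_and_identity_cases():
    plan = decompose(_recs([50] * 5), 24)
    assert len(plan) == 5
    single = decompose(_recs([10, 20, 30]), 1)
    assert len(single) == 1 and single.chunks[0] == [0, 1, 2]
    assert len(decompose([], 4)) == 0


@given(n=st.integers(1, 200), k=st.integers(1, 24))
def test_decompose_partitions_in_order_and_balances(n, k):
    queries = _recs([100] * n)
    plan = decompose(queries, k)
    flat = [i for chunk in plan for i in chunk]
    assert flat == list(range(n))  # partition preserving order
    assert len(plan) == min(k, n)
    loads = [sum(100 for _ in chunk) for chunk in plan]
    assert max(loads) <= 2 * min(loads)


# --- Karlin-Altschul statistics ----------------------------------------------

def test_lambda_satisfies_characteristic_equation():
    lam, K = karlin_altschul_params(1, -2)
    residual = 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1.0
    assert abs(residual) < 1e-12
    assert K > 0


def test_evalue_monotone_in_score_and_linear_in_database(scheme):
    e_low = scheme.evalue(40, 100, 1500)
    e_high = scheme.evalue(50, 100, 1500)
    assert e_high < e_low
    assert scheme.evalue(40, 100, 3000) == pytest.approx(2 * e_low)


def test_bit_score_increases_with_raw_score(scheme):
    assert scheme.bit_score(50) > scheme.bit_score(40)


# --- alignment ---------------------------------------------------------------

def test_exact_substring_gives_perfect_hit(reference5, index5, scheme):
    ref = reference5[0][0]
    query = SequenceRecord(id="q", residues=ref.residues[50:150])
    hits = align(query, index5, scheme)
    top = hits[0]
    assert top.sseqid == ref.id
    assert top.pident == 100.0
    assert top.length == 100 and top.mismatch == 0 and top.gapopen == 0
    assert (top.qstart, top.qend) == (0, 100)
    assert (top.sstart, top.send) == (50, 150)
    assert top.strand == "+"


def test_query_without_shared_word_yields_nothing(index5, scheme, rng):
    # a 20-mer of pure background is exceedingly unlikely to share a
    # 16-mer with the references; construct one that provably does not
    while True:
        q = random_dna(rng, 20)
        if all(q[i:i + 16] not in index5.kmer_index for i in range(5)):
            break
    assert align(SequenceRecord(id="q", residues=q), index5, scheme) == []


def test_query_shorter_than_word_yields_nothing(index5, scheme):
    assert align(SequenceRecord(id="q", residues="ACGTACGTAC"),
                 index5, scheme) == []


def test_banded_score_bounded_by_exhaustive_optimum(scheme, rng):
    """Reported raw score is >= the seed's ungapped score by construction
    and <= the exhaustive local optimum; equality in >=90% of trials."""
    eq = n = 0
    for _ in range(50):
        ref = random_dna(rng, 300)
        start = int(rng.integers(0, 200))
        length = int(rng.integers(40, 100))
        core = mutate_with_indels(rng, ref[start:start + length], 0.05, 0.01)
        query = random_dna(rng, int(rng.integers(0, 25))) + core \
            + random_dna(rng, int(rng.integers(0, 25)))
        index = ReferenceIndex.build(
            [SequenceRecord(id="r", residues=ref)], w=16)
        hits = align(SequenceRecord(id="q", residues=query), index, scheme,
                     max_evalue=1e30)
        if not hits:
            continue
        n += 1
        raw = max(h.raw_score for h in hits)
        opt = optimal_local_score(scheme, query, ref)
        assert raw <= opt
        if raw == opt:
            eq += 1
    assert n >= 40
    assert eq / n >= 0.90


def test_minus_strand_query_maps_with_descending_subject(reference5, index5,
                                                         scheme):
    from pmeta.rrna_extract import reverse_complement

    ref = reference5[0][0]
    query = SequenceRecord(id="q",
                           residues=reverse_complement(ref.residues[50:150]))
    top = align(query, index5, scheme)[0]
    assert top.strand == "-"
    assert top.pident == 100.0
    assert (top.sstart, top.send) == (50, 150)
    assert top.qstart < top.qend  # query coordinates always ascending


# --- parallel mapping and merge ---------------------------------------------

def test_parallel_map_identical_for_all_chunk_counts(small_sample, reference5,
                                                     index5, scheme, hmm5):
    from pmeta.rrna_extract import extract_fragments, scan_reads

    reads, _ = small_sample
    hits = scan_reads(reads[:120], hmm5, 20.0)
    frags = extract_fragments(reads[:120], hits)
    assert len(frags) >= 30
    reference = parallel_map(frags, index5, scheme, n_chunks=1)
    for c in range(2, 9):
        assert parallel_map(frags, index5, scheme, n_chunks=c) == reference


def test_merge_is_independent_of_chunk_completion_order(small_sample, index5,
                                                        scheme, hmm5):
    from pmeta.rrna_extract import extract_fragments, scan_reads

    reads, _ = small_sample
    hits = scan_reads(reads[:80], hmm5, 20.0)
    frags = extract_fragments(reads[:80], hits)
    serial = parallel_map(frags, index5, scheme, n_chunks=1)
    order = list(range(6))
    random.Random(5).shuffle(order)
    shuffled = parallel_map(frags, index5, scheme, n_chunks=6,
                            _chunk_order=order)
    assert shuffled == serial


def test_process_pool_matches_serial(small_sample, index5, scheme, hmm5):
    from pmeta.rrna_extract import extract_fragments, scan_reads

    reads, _ = small_sample
    hits = scan_reads(reads[:60], hmm5, 20.0)
    frags = extract_fragments(reads[:60], hits)
    serial = parallel_map(frags, index5, scheme, n_chunks=4, n_workers=1)
    pooled = parallel_map(frags, index5, scheme, n_chunks=4, n_workers=3)
    assert pooled == serial


# --- best hit ----------------------------------------------------------------

def _hit(sseqid="s1", bitscore=100.0, evalue=1e-30):
    return TabularHit(qseqid="q", sseqid=sseqid, pident=99.0, length=100,
                      mismatch=1, gapopen=0, qstart=0, qend=100, sstart=0,
                      send=100, evalue=evalue, bitscore=bitscore)


def test_best_hit_selection_and_tie_breaks():
    assert best_hit([]) is None
    assert best_hit([_hit(bitscore=100), _hit(bitscore=90)]).bitscore == 100
    tie = best_hit([_hit(sseqid="gg010"), _hit(sseqid="gg002")])
    assert tie.sseqid == "gg002"
    by_evalue = best_hit([_hit(evalue=1e-10), _hit(evalue=1e-20)])
    assert by_evalue.evalue == 1e-20


def test_query_identical_to_reference_is_its_own_best_hit(reference5, index5,
                                                          scheme):
    for ref in reference5[0]:
        query = SequenceRecord(id="q", residues=ref.residues)
        top = best_hit(align(query, index5, scheme))
        assert top.sseqid == ref.id
        assert top.pident == 100.0
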