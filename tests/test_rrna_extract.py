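"""Profile-HMM scanning: Viterbi correctness, strand handling, extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import enumerate_viterbi, random_dna, random_profile_hmm
from pmeta.io_formats import SequenceRecord
from pmeta.rrna_extract import (HmmHit, ProfileHMM, extract_fragments,
                                length_distribution, read_profile_hmm,
                                reverse_complement, scan_reads, viterbi,
                                write_profile_hmm)


# --- reverse complement -----------------------------------------------------

@pytest.mark.parametrize("seq,expected", [
    ("ACGT", "ACGT"),
    ("AAAC", "GTTT"),
    ("AN", "NT"),
    ("RYK", "MRY"),
])
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


@given(st.text(alphabet="ACGTN", min_size=1, max_size=50))
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_reverse_complement_rejects_non_iupac():
    with pytest.raises(ValueError):
        reverse_complement("ACXGT")


# --- Viterbi ----------------------------------------------------------------

def _single_match_model():
    return ProfileHMM(
        name="one",
        match_lo=np.array([[2.0, -np.inf, -np.inf, -np.inf]]),
        insert_lo=np.zeros((0, 4)),
        trans_lo=np.zeros((0, 9)),
    )


def test_viterbi_single_match_state_forced_score():
    # emitting A with probability 1 over a 0.25 background: log2(4) bits
    score, path = viterbi(_single_match_model(), "A")
    assert score == pytest.approx(2.0)
    assert path == [("M", 0, 0)]


def test_viterbi_all_n_scores_transitions_only(rng):
    # N emits at background (log-odds 0) in every state, so the best
    # local path is a single match state with zero total score
    hmm = random_profile_hmm(rng, max_states=4)
    score, _ = viterbi(hmm, "NNNNN")
    assert score == pytest.approx(0.0)


def test_viterbi_matches_path_enumeration_oracle(rng):
    for _ in range(60):
        hmm = random_profile_hmm(rng, max_states=5)
        seq = random_dna(rng, int(rng.integers(1, 9)))
        score, path = viterbi(hmm, seq)
        assert score == pytest.approx(enumerate_viterbi(hmm, seq), abs=1e-9)
        # the returned path must itself realize the returned score
        assert path[0][0] == "M" and path[-1][0] == "M"


def test_viterbi_rejects_empty_sequence(hmm5):
    with pytest.raises(ValueError):
        viterbi(hmm5, "")


# --- model construction and file format ------------------------------------

def test_seed_alignment_pseudocount_emissions():
    hmm = ProfileHMM.from_seed_alignment(["AC", "AC", "AC", "AG"], name="t")
    # column 0: 4 A's + 1 pseudocount over 8 -> p(A) = 5/8
    assert hmm.match_lo[0, 0] == pytest.approx(np.log2((5 / 8) / 0.25))
    assert hmm.match_lo[0, 1] == pytest.approx(np.log2((1 / 8) / 0.25))
    # column 1: 3 C, 1 G
    assert hmm.match_lo[1, 1] == pytest.approx(np.log2((4 / 8) / 0.25))


def test_profile_hmm_rejects_bad_emissions():
    with pytest.raises(ValueError):
        ProfileHMM(name="bad", match_lo=np.array([[1.0, 1.0, 1.0, 1.0]]),
                   insert_lo=np.zeros((0, 4)), trans_lo=np.zeros((0, 9)))


def test_model_file_roundtrip(tmp_path, hmm5):
    p = tmp_path / "m.phmm"
    write_profile_hmm(hmm5, p)
    back = read_profile_hmm(p)
    assert back.name == hmm5.name
    np.testing.assert_array_equal(back.match_lo, hmm5.match_lo)
    np.testing.assert_array_equal(back.insert_lo, hmm5.insert_lo)
    np.testing.assert_array_equal(back.trans_lo, hmm5.trans_lo)
    # second serialization is byte-identical
    p2 = tmp_path / "m2.phmm"
    write_profile_hmm(back, p2)
    assert p2.read_text() == p.read_text()


def test_model_file_rejects_wrong_magic(tmp_path):
    p = tmp_path / "m.phmm"
    p.write_text("NOTPHMM\n")
    with pytest.raises(ValueError):
        read_profile_hmm(p)


# --- read scanning ----------------------------------------------------------

def test_scan_is_chunk_invariant(small_sample, hmm5):
    reads, _ = small_sample
    reads = reads[:100]
    h1 = scan_reads(reads, hmm5, 20.0, chunks=1)
    h7 = scan_reads(reads, hmm5, 20.0, chunks=7)
    assert h1 == h7 and len(h1) > 0


def test_scan_worker_processes_match_serial(small_sample, hmm5):
    reads, _ = small_sample
    reads = reads[:60]
    serial = scan_reads(reads, hmm5, 20.0, chunks=4, n_workers=1)
    parallel = scan_reads(reads, hmm5, 20.0, chunks=4, n_workers=3)
    assert serial == parallel


def test_scan_finds_planted_fragment_and_strand(reference5, hmm5, rng):
    ref = reference5[0][0].residues
    frag = ref[100:190]
    read_plus = SequenceRecord(id="p", residues=random_dna(rng, 5) + frag
                               + random_dna(rng, 5))
    (hit,) = scan_reads([read_plus], hmm5, 20.0)
    assert hit.strand == "+"
    assert hit.start <= 6 and hit.end >= len(frag) + 4  # covers the plant
    read_minus = SequenceRecord(
        id="m", residues=reverse_complement(read_plus.residues))
    (hit_m,) = scan_reads([read_minus], hmm5, 20.0)
    assert hit_m.strand == "-"
    assert hit_m.score == pytest.approx(hit.score)


def test_scan_recall_and_specificity_on_synthetic_reads(small_sample, hmm5):
    reads, truth = small_sample
    hits = {h.read_id: h for h in scan_reads(reads, hmm5, 20.0)}
    planted = set(truth.read_id)
    found = 0
    for row in truth.itertuples():
        h = hits.get(row.read_id)
        if h is None:
            continue
        s, e = h.start, h.end
        if h.strand == "-":
            n = 100
            s, e = n - h.end, n - h.start
        overlap = max(0, min(e, row.read_end) - max(s, row.read_start))
        if h.strand == row.strand and overlap >= 0.5 * (row.read_end - row.read_start):
            found += 1
    assert found / len(planted) >= 0.95
    assert not set(hits) - planted  # no hit on fragment-free reads


# --- extraction and length distribution -------------------------------------

def test_extract_fragment_plus_strand_slice():
    read = SequenceRecord(id="r1", residues="TTACGTACGT")
    hit = HmmHit(read_id="r1", strand="+", start=2, end=8,
                 model_start=0, model_end=6, score=30.0)
    (frag,) = extract_fragments([read], [hit])
    assert frag.residues == "ACGTAC"
    assert frag.id == "r1|+|2-8"


def test_extract_minus_strand_is_sense_oriented(rng):
    sense = random_dna(rng, 40)
    read = SequenceRecord(id="r", residues=reverse_complement(sense))
    hit = HmmHit(read_id="r", strand="-", start=0, end=40,
                 model_start=0, model_end=40, score=30.0)
    (frag,) = extract_fragments([read], [hit])
    assert frag.residues == sense


def test_extract_rejects_bad_hits():
    read = SequenceRecord(id="r1", residues="ACGT")
    bad_interval = HmmHit(read_id="r1", strand="+", start=2, end=9,
                          model_start=0, model_end=3, score=30.0)
    with pytest.raises(ValueError):
        extract_fragments([read], [bad_interval])
    unknown = HmmHit(read_id="zz", strand="+", start=0, end=2,
                     model_start=0, model_end=2, score=30.0)
    with pytest.raises(ValueError):
        extract_fragments([read], [unknown])


def test_length_distribution_counts_and_mean(rng):
    frags = [SequenceRecord(id=f"f{i}", residues=random_dna(rng, n))
             for i, n in enumerate([90, 90, 100])]
    dist = length_distribution(frags)
    assert dist.histogram == {90: 2, 100: 1}
    assert dist.n == 3 and sum(dist.histogram.values()) == dist.n
    assert dist.mean == pytest.approx(93.333, abs=1e-3)
    empty = length_distribution([])
    assert empty.n == 0 and empty.histogram == {}
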