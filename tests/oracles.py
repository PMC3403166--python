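"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic programs: the Viterbi
oracle enumerates every legal state path explicitly, and the alignment
oracle is Biopython's exhaustive local pairwise aligner.
"""

from __future__ import annotations

import numpy as np

from pmeta._kernels import DD, DI, DM, ID, II, IM, MD, MI, MM

_CODE = {c: i for i, c in enumerate("ACGT")}


def enumerate_viterbi(hmm, residues: str) -> float:
    """Maximum local-alignment log-odds by explicit path enumeration.

    Walks every path that starts in any match state at any sequence
    position and ends in any match state (free entry/exit, zero-cost
    flanks).  Exponential; only usable for tiny models and sequences.
    """
    x = [_CODE.get(c, 4) for c in residues]
    n = len(x)
    L = hmm.length
    t = hmm.trans_lo

    def m_emit(k, i):
        return hmm.match_lo[k, x[i]] if x[i] < 4 else 0.0

    def i_emit(k, i):
        return hmm.insert_lo[k, x[i]] if x[i] < 4 else 0.0

    best = [-np.inf]

    def walk(state: str, k: int, i: int, score: float):
        # `score` includes the emission/transitions up to and including
        # the current state; i is the next unconsumed sequence index.
        if state == "M":
            if score > best[0]:
                best[0] = score  # free exit after any match state
            if k + 1 < L:
                if i < n:
                    walk("M", k + 1, i + 1,
                         score + t[k, MM] + m_emit(k + 1, i))
                    walk("I", k, i + 1, score + t[k, MI] + i_emit(k, i))
                walk("D", k + 1, i, score + t[k, MD])
        elif state == "I":
            if k + 1 < L:
                if i < n:
                    walk("M", k + 1, i + 1,
                         score + t[k, IM] + m_emit(k + 1, i))
                    walk("I", k, i + 1, score + t[k, II] + i_emit(k, i))
                walk("D", k + 1, i, score + t[k, ID])
        else:  # D
            if k + 1 < L:
                if i < n:
                    walk("M", k + 1, i + 1,
                         score + t[k, DM] + m_emit(k + 1, i))
                    walk("I", k, i + 1, score + t[k, DI] + i_emit(k, i))
                walk("D", k + 1, i, score + t[k, DD])

    for i0 in range(n):
        for k0 in range(L):
            walk("M", k0, i0 + 1, m_emit(k0, i0))
    return float(best[0])


def random_profile_hmm(rng: np.random.Generator, max_states: int = 5):
    """A random small ProfileHMM with Dirichlet emissions/transitions."""
    from pmeta.rrna_extract import ProfileHMM

    L = int(rng.integers(1, max_states + 1))
    match_p = rng.dirichlet([1.0] * 4, size=L)
    insert_p = rng.dirichlet([1.0] * 4, size=max(L - 1, 0)) \
        if L > 1 else np.zeros((0, 4))
    match_lo = np.log2(match_p / 0.25)
    insert_lo = np.log2(insert_p / 0.25) if L > 1 else np.zeros((0, 4))
    trans = np.zeros((max(L - 1, 0), 9))
    for k in range(L - 1):
        for cols in ((MM, MI, MD), (IM, II, ID), (DM, DI, DD)):
            p = rng.dirichlet([2.0, 1.0, 1.0])
            for pv, col in zip(p, cols):
                trans[k, col] = np.log2(pv)
    return ProfileHMM(name="rand", match_lo=match_lo, insert_lo=insert_lo,
                      trans_lo=trans)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_local_aligner(scheme):
    """Biopython exhaustive local aligner under the package's scheme."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    # first gap residue costs open + extend under the package's model
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def optimal_local_score(scheme, query: str, subject: str) -> float:
    """Exhaustive optimal local alignment score over both query strands."""
    from pmeta.rrna_extract import reverse_complement

    aligner = make_local_aligner(scheme)
    return max(aligner.score(subject, query),
               aligner.score(subject, reverse_complement(query)))


def mutate_with_indels(rng: np.random.Generator, s: str, sub_rate: float,
                       indel_rate: float) -> str:
    out = []
    for c in s:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(c)
            out.append("ACGT"[rng.integers(0, 4)])
            continue
        if r < indel_rate + sub_rate:
            out.append("ACGT"[rng.integers(0, 4)])
        else:
            out.append(c)
    return "".join(out)
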