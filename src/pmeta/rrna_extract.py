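"""Step 1 of the pipeline: find and excise 16S rRNA fragments in reads.

A profile hidden Markov model of the 16S gene (match/insert/delete
states with position-specific emissions) is scanned over every read and
its reverse complement with the Viterbi algorithm under local-alignment
semantics: entry into any match state and exit after any match state are
free, flanking read residues are ignored at zero cost.  The better
scoring strand is kept, and reads whose best score reaches the reporting
threshold have the matching interval excised in rRNA sense orientation.

The model file format is a versioned plain-text layout (see
:func:`write_profile_hmm`); :meth:`ProfileHMM.from_seed_alignment`
builds a model from an ungapped seed alignment with maximum-likelihood
emission estimates (+1 pseudocount) and global transition priors.

Scanning is chunk-parallel: reads are cut into contiguous chunks
balanced by residue count and results are merged back in read order, so
output is identical for every chunk count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from ._kernels import DD, DI, DM, ID, II, IM, MD, MI, MM, viterbi_fill
from .io_formats import IUPAC_DNA, SequenceRecord
from .rrna_map import decompose, encode

__all__ = [
    "ProfileHMM",
    "HmmHit",
    "LengthDistribution",
    "reverse_complement",
    "viterbi",
    "scan_reads",
    "extract_fragments",
    "length_distribution",
    "read_profile_hmm",
    "write_profile_hmm",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

FORMAT_MAGIC = "PHMM1"
_BACKGROUND = 0.25


def reverse_complement(residues: str) -> str:
    """Watson-Crick complement of the reversed string (IUPAC-aware)."""
    bad = set(residues) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC residues: {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class ProfileHMM:
    """Profile HMM over {A,C,G,T} with log-odds scores in bits.

    ``match_lo[k]`` and ``insert_lo[k]`` are log2(p / 0.25) per residue;
    ``trans_lo`` holds log2 transition probabilities for the nine moves
    (MM MI MD IM II ID DM DI DD) out of position ``k`` (insert state
    ``k`` sits between match states ``k`` and ``k+1``).  Emission
    probabilities underlying each state's log-odds must sum to one
    (checked to 1e-9).  Entry/exit for local alignment is handled by the
    scanner, not by the model.
    """

    name: str
    match_lo: np.ndarray
    insert_lo: np.ndarray
    trans_lo: np.ndarray

    def __post_init__(self):
        self.match_lo = np.asarray(self.match_lo, dtype=np.float64)
        self.insert_lo = np.asarray(self.insert_lo, dtype=np.float64)
        self.trans_lo = np.asarray(self.trans_lo, dtype=np.float64)
        L = self.match_lo.shape[0]
        if L < 1 or self.match_lo.shape != (L, 4):
            raise ValueError("match_lo must have shape (L, 4), L >= 1")
        if self.insert_lo.shape != (max(L - 1, 0), 4):
            raise ValueError("insert_lo must have shape (L-1, 4)")
        if self.trans_lo.shape != (max(L - 1, 0), 9):
            raise ValueError("trans_lo must have shape (L-1, 9)")
        for lo in (self.match_lo, self.insert_lo):
            if lo.shape[0] == 0:
                continue
            psum = (_BACKGROUND * np.exp2(lo)).sum(axis=1)
            if not np.allclose(psum, 1.0, atol=1e-9):
                raise ValueError("emission probabilities must sum to 1 (1e-9)")
        if L > 1:
            probs = np.exp2(self.trans_lo)
            for trio in ((MM, MI, MD), (IM, II, ID), (DM, DI, DD)):
                tsum = probs[:, list(trio)].sum(axis=1)
                if not np.allclose(tsum, 1.0, atol=1e-6):
                    raise ValueError("transition probabilities must sum to 1")

    @property
    def length(self) -> int:
        return self.match_lo.shape[0]

    @classmethod
    def from_seed_alignment(cls, rows: Sequence[str], name: str,
                            match_trans: Tuple[float, float, float] = (0.9, 0.05, 0.05),
                            insert_trans: Tuple[float, float, float] = (0.8, 0.15, 0.05),
                            delete_trans: Tuple[float, float, float] = (0.8, 0.05, 0.15),
                            ) -> "ProfileHMM":
        """Build a model from an ungapped seed alignment.

        Match emissions are per-column maximum-likelihood estimates with
        a +1 pseudocount per residue; insert states emit at background;
        transitions use the global priors (out of M / I / D).
        """
        if not rows:
            raise ValueError("empty seed alignment")
        L = len(rows[0])
        if L == 0 or any(len(r) != L for r in rows):
            raise ValueError("seed alignment rows must be non-empty, equal length")
        counts = np.zeros((L, 4))
        order = {c: i for i, c in enumerate("ACGT")}
        for row in rows:
            for k, c in enumerate(row.upper()):
                idx = order.get(c)
                if idx is not None:
                    counts[k, idx] += 1.0
        probs = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 4.0)
        match_lo = np.log2(probs / _BACKGROUND)
        insert_lo = np.zeros((max(L - 1, 0), 4))
        trans = np.empty((max(L - 1, 0), 9))
        if L > 1:
            for trio, cols in ((match_trans, (MM, MI, MD)),
                               (insert_trans, (IM, II, ID)),
                               (delete_trans, (DM, DI, DD))):
                if abs(sum(trio) - 1.0) > 1e-9:
                    raise ValueError("transition priors must sum to 1")
                for p, col in zip(trio, cols):
                    trans[:, col] = math.log2(p)
        return cls(name=name, match_lo=match_lo, insert_lo=insert_lo,
                   trans_lo=trans)


@dataclass
class HmmHit:
    """One per-read detection: interval on the reported strand's sequence."""

    read_id: str
    strand: str
    start: int
    end: int
    model_start: int
    model_end: int
    score: float

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError("empty hit interval")


# ---------------------------------------------------------------------------
# model file format


def write_profile_hmm(hmm: ProfileHMM, path) -> None:
    """Write the versioned plain-text model format.

    Layout: magic line, NAME, LENGTH, then one MATCH/INSERT/TRANS line
    per state block with full-precision floats (bits / log2
    probabilities), terminated by END.
    """
    with open(path, "wt") as fh:
        fh.write(f"{FORMAT_MAGIC}\n")
        fh.write(f"NAME {hmm.name}\n")
        fh.write(f"LENGTH {hmm.length}\n")
        for k in range(hmm.length):
            vals = " ".join(repr(float(v)) for v in hmm.match_lo[k])
            fh.write(f"MATCH {k} {vals}\n")
        for k in range(hmm.length - 1):
            vals = " ".join(repr(float(v)) for v in hmm.insert_lo[k])
            fh.write(f"INSERT {k} {vals}\n")
        for k in range(hmm.length - 1):
            vals = " ".join(repr(float(v)) for v in hmm.trans_lo[k])
            fh.write(f"TRANS {k} {vals}\n")
        fh.write("END\n")


def read_profile_hmm(path) -> ProfileHMM:
    from .io_formats import ParseError

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != FORMAT_MAGIC:
        raise ParseError(f"not a {FORMAT_MAGIC} model file", path, 1)
    name = None
    L = None
    match_lo = insert_lo = trans_lo = None
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line == "END":
            continue
        tag, rest = line.split(None, 1)
        if tag == "NAME":
            name = rest.strip()
        elif tag == "LENGTH":
            L = int(rest)
            match_lo = np.zeros((L, 4))
            insert_lo = np.zeros((max(L - 1, 0), 4))
            trans_lo = np.zeros((max(L - 1, 0), 9))
        elif tag in ("MATCH", "INSERT", "TRANS"):
            if L is None:
                raise ParseError("state line before LENGTH", path, lineno)
            parts = rest.split()
            k = int(parts[0])
            vals = [float(v) for v in parts[1:]]
            try:
                if tag == "MATCH":
                    match_lo[k] = vals
                elif tag == "INSERT":
                    insert_lo[k] = vals
                else:
                    trans_lo[k] = vals
            except (IndexError, ValueError) as exc:
                raise ParseError(str(exc), path, lineno) from exc
        else:
            raise ParseError(f"unknown record tag {tag!r}", path, lineno)
    if name is None or L is None:
        raise ParseError("missing NAME or LENGTH", path, None)
    return ProfileHMM(name=name, match_lo=match_lo, insert_lo=insert_lo,
                      trans_lo=trans_lo)


# ---------------------------------------------------------------------------
# Viterbi + traceback


def warmup_kernels() -> None:
    """Trigger JIT compilation once (before forking workers)."""
    x = np.zeros(1, dtype=np.int8)
    viterbi_fill(x, np.zeros((1, 4)), np.zeros((0, 4)), np.zeros((0, 9)))
    from ._kernels import banded_sw_fill

    banded_sw_fill(x, x, 0, 2, 1, -2, -5, -2)


def _traceback(x: np.ndarray, hmm: ProfileHMM, VM, VI, VD, i: int, k: int) -> list:
    """Reconstruct one maximizing path ending at match cell (i, k).

    Tie-break: predecessors are tried in the order M, D, I (then local
    entry), so equal-scoring paths resolve deterministically.
    """
    t = hmm.trans_lo
    tol = 1e-9
    path = []
    state = "M"
    while True:
        path.append((state, k, i))
        if state == "M":
            e = hmm.match_lo[k, x[i]] if x[i] < 4 else 0.0
            target = VM[i, k] - e
            if i > 0 and k > 0:
                if abs(VM[i - 1, k - 1] + t[k - 1, MM] - target) <= tol:
                    state, i, k = "M", i - 1, k - 1
                    continue
                if abs(VD[i - 1, k - 1] + t[k - 1, DM] - target) <= tol:
                    state, i, k = "D", i - 1, k - 1
                    continue
                if abs(VI[i - 1, k - 1] + t[k - 1, IM] - target) <= tol:
                    state, i, k = "I", i - 1, k - 1
                    continue
            if abs(target) <= tol:
                break  # local entry
            raise RuntimeError("traceback failed to find a predecessor")
        elif state == "I":
            e = hmm.insert_lo[k, x[i]] if x[i] < 4 else 0.0
            target = VI[i, k] - e
            if abs(VM[i - 1, k] + t[k, MI] - target) <= tol:
                state, i = "M", i - 1
            elif abs(VD[i - 1, k] + t[k, DI] - target) <= tol:
                state, i = "D", i - 1
            elif abs(VI[i - 1, k] + t[k, II] - target) <= tol:
                state, i = "I", i - 1
            else:
                raise RuntimeError("traceback failed in insert state")
        else:  # D
            target = VD[i, k]
            if abs(VM[i, k - 1] + t[k - 1, MD] - target) <= tol:
                state, k = "M", k - 1
            elif abs(VD[i, k - 1] + t[k - 1, DD] - target) <= tol:
                state, k = "D", k - 1
            elif abs(VI[i, k - 1] + t[k - 1, ID] - target) <= tol:
                state, k = "I", k - 1
            else:
                raise RuntimeError("traceback failed in delete state")
    path.reverse()
    return path


def viterbi(hmm: ProfileHMM, residues: str) -> Tuple[float, list]:
    """Maximum log-odds (bits) over all local state paths, plus one
    maximizing path as a list of (state, model_index, seq_index)."""
    if not residues:
        raise ValueError("empty sequence")
    x = encode(residues)
    VM, VI, VD = viterbi_fill(x, hmm.match_lo, hmm.insert_lo, hmm.trans_lo)
    flat = int(np.argmax(VM))  # first maximum in row-major order
    i, k = divmod(flat, hmm.length)
    score = float(VM[i, k])
    path = _traceback(x, hmm, VM, VI, VD, i, k)
    return score, path


# ---------------------------------------------------------------------------
# read scanning


def _scan_chunk(args) -> list:
    reads, hmm, min_score = args
    hits = []
    for read in reads:
        hit = _scan_one(read, hmm, min_score)
        if hit is not None:
            hits.append(hit)
    return hits


def _scan_one(read: SequenceRecord, hmm: ProfileHMM,
              min_score: float) -> Optional[HmmHit]:
    fwd = read.residues
    rev = reverse_complement(fwd)
    xf = encode(fwd)
    xr = encode(rev)
    Mf = viterbi_fill(xf, hmm.match_lo, hmm.insert_lo, hmm.trans_lo)
    Mr = viterbi_fill(xr, hmm.match_lo, hmm.insert_lo, hmm.trans_lo)
    sf = float(Mf[0].max())
    sr = float(Mr[0].max())
    if max(sf, sr) < min_score:
        return None
    if sf >= sr:  # tie prefers the forward strand
        strand, x, (VM, VI, VD), score = "+", xf, Mf, sf
    else:
        strand, x, (VM, VI, VD), score = "-", xr, Mr, sr
    flat = int(np.argmax(VM))
    i, k = divmod(flat, hmm.length)
    path = _traceback(x, hmm, VM, VI, VD, i, k)
    emitting = [si for st, _, si in path if st in ("M", "I")]
    model = [mk for st, mk, _ in path if st == "M"]
    return HmmHit(
        read_id=read.id,
        strand=strand,
        start=min(emitting),
        end=max(emitting) + 1,
        model_start=min(model),
        model_end=max(model) + 1,
        score=score,
    )


def scan_reads(reads: Sequence[SequenceRecord], hmm: ProfileHMM,
               min_score: float = 20.0, chunks: int = 1,
               n_workers: int = 1) -> List[HmmHit]:
    """Scan reads (both strands) and report per-read best hits.

    The better-scoring strand is kept for each read; reads below
    ``min_score`` produce nothing.  Output is in read order and is
    identical for every value of ``chunks`` / ``n_workers``.
    """
    if not math.isfinite(min_score):
        raise ValueError("min_score must be finite")
    plan = decompose(reads, chunks)
    tasks = [([reads[i] for i in chunk], hmm, min_score) for chunk in plan]
    results: List[Optional[list]] = [None] * len(tasks)
    if n_workers > 1 and len(tasks) > 1:
        from .parallel import run_tasks

        warmup_kernels()  # compile before forking
        for idx, res in run_tasks(_scan_chunk, tasks, n_workers):
            results[idx] = res
    else:
        for idx, task in enumerate(tasks):
            results[idx] = _scan_chunk(task)
    merged: List[HmmHit] = []
    for res in results:
        merged.extend(res or [])
    return merged


# ---------------------------------------------------------------------------
# fragment extraction and length distribution


def extract_fragments(reads: Sequence[SequenceRecord],
                      hits: Sequence[HmmHit]) -> List[SequenceRecord]:
    """Excise hit intervals; minus-strand fragments are emitted in rRNA
    sense orientation (the hit interval indexes the reverse complement
    of the read)."""
    by_id = {r.id: r for r in reads}
    fragments = []
    for hit in hits:
        read = by_id.get(hit.read_id)
        if read is None:
            raise ValueError(f"hit refers to unknown read {hit.read_id!r}")
        n = len(read.residues)
        if not (0 <= hit.start < hit.end <= n):
            raise ValueError(
                f"hit interval [{hit.start}, {hit.end}) outside read "
                f"{hit.read_id!r} of length {n}"
            )
        source = read.residues if hit.strand == "+" else reverse_complement(read.residues)
        fragments.append(
            SequenceRecord(
                id=f"{hit.read_id}|{hit.strand}|{hit.start}-{hit.end}",
                residues=source[hit.start : hit.end],
                description=f"score={hit.score:.2f}",
            )
        )
    return fragments


@dataclass
class LengthDistribution:
    histogram: dict
    n: int
    min: Optional[int]
    max: Optional[int]
    mean: Optional[float]

    def to_tsv(self) -> str:
        lines = ["length\tcount"]
        for length in sorted(self.histogram):
            lines.append(f"{length}\t{self.histogram[length]}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        if self.n == 0:
            return "fragments: 0\n"
        return (
            f"fragments: {self.n}\nmin length: {self.min}\n"
            f"max length: {self.max}\nmean length: {self.mean:.2f}\n"
        )


def length_distribution(fragments: Sequence[SequenceRecord]) -> LengthDistribution:
    hist: dict = {}
    for frag in fragments:
        hist[len(frag)] = hist.get(len(frag), 0) + 1
    if not fragments:
        return LengthDistribution(histogram={}, n=0, min=None, max=None, mean=None)
    lengths = [len(f) for f in fragments]
    return LengthDistribution(
        histogram=hist,
        n=len(lengths),
        min=min(lengths),
        max=max(lengths),
        mean=sum(lengths) / len(lengths),
    )
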