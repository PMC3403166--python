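"""Synthetic reference databases and read sets with known ground truth.

Every stage of the pipeline is testable without downloads: the generator
emulates a small annotated 16S reference set (a star phylogeny around a
random ancestor), and shotgun samples in which a known fraction of reads
carries a planted 16S fragment drawn from a community of known
composition.  The truth table written alongside each sample is the
oracle for recall and composition-recovery checks.

Defaults mirror the scale of a short-read shotgun survey: 100 nt reads,
planted fragments of 60-100 nt cut from ~300 nt reference segments (one
variable-region-sized stretch of the gene), per-read substitution noise
of 1%, and uniform-random background DNA for non-16S reads.  Everything
is fully determined by the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord, TaxonomyMap
from .rrna_extract import reverse_complement

__all__ = ["CommunitySpec", "generate_reference", "generate_sample"]

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, residues: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions (always to a
    different base)."""
    seq = list(residues)
    if n_subs == 0:
        return residues
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def _lineage_string(names: Dict[str, str]) -> str:
    return "; ".join(
        f"{p}__{names[r]}"
        for p, r in zip("kpcofgs",
                        ("kingdom", "phylum", "class_", "order", "family",
                         "genus", "species"))
    )


def generate_reference(n_taxa: int = 8, seq_length: int = 300,
                       seed: int = 7,
                       divergence_range: Tuple[float, float] = (0.02, 0.15),
                       ) -> Tuple[List[SequenceRecord], TaxonomyMap, List[str]]:
    """Reference 16S set evolved from one ancestor on a star topology.

    Each taxon diverges from the random ancestor by a per-taxon
    substitution fraction drawn from ``divergence_range`` and gets a
    distinct full 7-rank lineage over a generated nomenclature (taxa are
    split between two phyla, with nested groups below).  The rows of the
    taxa themselves (all the same length, indel-free) double as the
    ungapped seed alignment for the profile HMM.  Deterministic given
    ``seed``.
    """
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    rng = np.random.default_rng(seed)
    ancestor = _random_dna(rng, seq_length)
    records: List[SequenceRecord] = []
    entries: Dict[str, str] = {}
    lo, hi = divergence_range
    for t in range(n_taxa):
        div = rng.uniform(lo, hi)
        n_subs = int(round(div * seq_length))
        seq = _mutate(rng, ancestor, n_subs)
        # nested nomenclature: 2 phyla, 4-way classes, binary below
        phylum = t % 2
        klass = t % 4
        order_ = t % 4
        family = t % 8
        names = {
            "kingdom": "Bacteria",
            "phylum": f"Phylum{phylum:02d}",
            "class_": f"Class{klass:02d}",
            "order": f"Order{order_:02d}",
            "family": f"Family{family:02d}",
            "genus": f"Genus{t:02d}",
            "species": f"species{t:02d}",
        }
        ref_id = f"ref{t:03d}"
        records.append(
            SequenceRecord(
                id=ref_id,
                residues=seq,
                description=f"synthetic 16S, divergence={div:.4f}",
            )
        )
        entries[ref_id] = _lineage_string(names)
    seed_alignment = [r.residues for r in records]
    return records, TaxonomyMap(entries=entries), seed_alignment


@dataclass
class CommunitySpec:
    """Conditions for one synthetic shotgun sample.

    ``taxa`` holds (lineage string, reference sequence, relative
    abundance) triples; abundances must sum to 1 (1e-9).
    """

    taxa: List[Tuple[str, str, float]]
    n_reads: int = 2000
    read_length: int = 100
    fragment_length: Tuple[int, int] = (60, 100)
    substitution_rate: float = 0.01
    planted_fraction: float = 0.5
    strand_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if abs(sum(a for _, _, a in self.taxa) - 1.0) > 1e-9:
            raise ValueError("taxon abundances must sum to 1")
        for rate in (self.substitution_rate, self.planted_fraction,
                     self.strand_probability):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate out of [0, 1]: {rate}")
        if self.fragment_length[0] > self.fragment_length[1]:
            raise ValueError("bad fragment length range")
        if self.fragment_length[1] > self.read_length:
            raise ValueError("fragments must fit within reads")

    def to_json(self) -> str:
        return json.dumps(
            {
                "taxa": [
                    {"lineage": l, "abundance": a} for l, _, a in self.taxa
                ],
                "n_reads": self.n_reads,
                "read_length": self.read_length,
                "fragment_length": list(self.fragment_length),
                "substitution_rate": self.substitution_rate,
                "planted_fraction": self.planted_fraction,
                "strand_probability": self.strand_probability,
                "seed": self.seed,
            },
            indent=2,
        )


def generate_sample(spec: CommunitySpec, read_prefix: str = "read",
                    ) -> Tuple[List[SequenceRecord], pd.DataFrame]:
    """One synthetic sample: reads plus a ground-truth table.

    Background reads are i.i.d. uniform ACGT.  A planted read carries a
    contiguous fragment of one reference (taxon drawn by abundance,
    interval uniform, strand by ``strand_probability``) with
    substitutions applied at ``substitution_rate``, embedded at a random
    offset.  The truth table records read id, taxon index, lineage, the
    fragment interval on the read, the source interval on the reference,
    strand and substitution count.
    """
    rng = np.random.default_rng(spec.seed)
    abundances = np.array([a for _, _, a in spec.taxa])
    reads: List[SequenceRecord] = []
    truth_rows = []
    for i in range(spec.n_reads):
        read_id = f"{read_prefix}{i:06d}"
        background = _random_dna(rng, spec.read_length)
        planted = rng.random() < spec.planted_fraction
        if not planted:
            reads.append(SequenceRecord(
                id=read_id, residues=background,
                qualities=(40,) * spec.read_length,
            ))
            continue
        taxon = int(rng.choice(len(spec.taxa), p=abundances))
        lineage, ref_seq, _ = spec.taxa[taxon]
        flen = int(rng.integers(spec.fragment_length[0],
                                spec.fragment_length[1] + 1))
        flen = min(flen, len(ref_seq))
        ref_start = int(rng.integers(0, len(ref_seq) - flen + 1))
        fragment = ref_seq[ref_start : ref_start + flen]
        n_subs = int(rng.binomial(flen, spec.substitution_rate))
        fragment = _mutate(rng, fragment, n_subs)
        strand = "-" if rng.random() < spec.strand_probability else "+"
        if strand == "-":
            fragment = reverse_complement(fragment)
        offset = int(rng.integers(0, spec.read_length - flen + 1))
        residues = background[:offset] + fragment + background[offset + flen :]
        reads.append(SequenceRecord(
            id=read_id, residues=residues, qualities=(40,) * spec.read_length,
        ))
        truth_rows.append({
            "read_id": read_id,
            "taxon": taxon,
            "lineage": lineage,
            "read_start": offset,
            "read_end": offset + flen,
            "ref_start": ref_start,
            "ref_end": ref_start + flen,
            "strand": strand,
            "n_substitutions": n_subs,
        })
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "taxon", "lineage", "read_start", "read_end",
                 "ref_start", "ref_end", "strand", "n_substitutions"],
    )
    return reads, truth
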