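"""Step 3: taxonomic assignment of mapped fragments and per-sample profiles.

Each fragment is classified by its single best mapping hit: if the hit's
percent identity reaches ``min_identity`` and its subject carries a
taxonomy entry, the fragment inherits that lineage; otherwise it is
counted as unclassified.  Lineages follow the rank-prefixed,
semicolon-delimited dialect (``k__Bacteria; p__Firmicutes; ...``); ranks
must be filled prefix-first, so a lineage is truncated at its first
empty rank.  Counts are accumulated along the lineage path at each of
the six tree ranks (phylum through species; kingdom is collapsed into
the tree root by the comparison step).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .io_formats import SequenceRecord, TabularHit, TaxonomyMap
from .rrna_map import best_hit

__all__ = [
    "RANKS",
    "TREE_RANKS",
    "Lineage",
    "SampleProfile",
    "parse_lineage",
    "assign",
    "classification_report",
    "profile_to_json",
    "profile_from_json",
]

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")
TREE_RANKS = ("phylum", "class_", "order", "family", "genus", "species")
_PREFIXES = "kpcofgs"
_TOKEN_RE = re.compile(r"^(?:([a-zA-Z])__)?(.*)$")


@dataclass
class Lineage:
    """Ordered rank-prefixed taxonomy path, kingdom through species.

    Ranks are filled prefix-first: a filled genus implies a filled
    family, order, class, phylum and kingdom.
    """

    kingdom: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None
    raw: str = ""

    def __post_init__(self):
        seen_gap = False
        for rank in RANKS:
            name = getattr(self, rank)
            if name is not None and ";" in name:
                raise ValueError(f"taxon name contains ';': {name!r}")
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise ValueError(f"lineage fills {rank} below an empty rank: {self.raw!r}")

    def depth(self) -> int:
        """Number of filled ranks (kingdom counts)."""
        return sum(getattr(self, r) is not None for r in RANKS)

    def path(self, rank: str) -> Optional[Tuple[str, ...]]:
        """Names from phylum down to ``rank``, or None if unfilled."""
        idx = TREE_RANKS.index(rank)
        names = [getattr(self, r) for r in TREE_RANKS[: idx + 1]]
        if any(n is None for n in names):
            return None
        return tuple(names)


def parse_lineage(raw: str) -> Lineage:
    """Parse a semicolon-delimited, optionally rank-prefixed lineage.

    Rank prefixes (``k__`` .. ``s__``) are stripped; an empty field
    (``g__`` with nothing after) is unfilled, and the lineage is
    truncated at the first gap so the prefix-first invariant holds.
    """
    tokens = [tok.strip() for tok in raw.split(";")]
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]  # tolerate a trailing separator
    if len(tokens) > len(RANKS):
        raise ValueError(f"more than {len(RANKS)} lineage fields: {raw!r}")
    names: List[Optional[str]] = []
    for pos, tok in enumerate(tokens):
        m = _TOKEN_RE.match(tok)
        prefix, name = m.group(1), m.group(2)
        if prefix is not None:
            if prefix.lower() not in _PREFIXES:
                raise ValueError(f"unknown rank prefix {prefix!r}__ in {raw!r}")
            if _PREFIXES.index(prefix.lower()) != pos:
                raise ValueError(
                    f"rank prefix {prefix!r}__ out of order at position {pos} in {raw!r}"
                )
        elif "__" in tok:
            raise ValueError(f"unparseable lineage token {tok!r} in {raw!r}")
        names.append(name if name else None)
    # truncate at the first gap
    filled: Dict[str, Optional[str]] = {}
    for rank, name in zip(RANKS, names):
        if name is None:
            break
        filled[rank] = name
    return Lineage(raw=raw, **filled)


@dataclass
class SampleProfile:
    """Per-sample classification outcome.

    ``assignments`` maps fragment id to a :class:`Lineage` (or None for
    unclassified fragments); ``counts`` maps (rank, taxon path tuple) to
    the number of fragments whose lineage reaches that path.
    """

    sample_id: str
    assignments: Dict[str, Optional[Lineage]] = field(default_factory=dict)
    counts: Dict[Tuple[str, Tuple[str, ...]], int] = field(default_factory=dict)
    total_classified: int = 0
    total_unclassified: int = 0

    @property
    def total(self) -> int:
        return self.total_classified + self.total_unclassified

    def rank_counts(self, rank: str) -> Dict[Tuple[str, ...], int]:
        return {p: c for (r, p), c in self.counts.items() if r == rank}


def assign(fragments: Sequence[SequenceRecord], hits: Iterable[TabularHit],
           taxonomy: TaxonomyMap, min_identity: float = 90.0,
           sample_id: str = "sample") -> SampleProfile:
    """Classify each fragment by its best hit.

    A fragment is classified when its best hit has percent identity >=
    ``min_identity`` and the subject is annotated; otherwise it counts
    as unclassified (a missing taxonomy entry is logged as a warning).
    """
    by_query: Dict[str, List[TabularHit]] = {}
    for h in hits:
        by_query.setdefault(h.qseqid, []).append(h)
    profile = SampleProfile(sample_id=sample_id)
    for frag in fragments:
        best = best_hit(by_query.get(frag.id, ()))
        lineage: Optional[Lineage] = None
        if best is not None and best.pident >= min_identity:
            raw = taxonomy.get(best.sseqid)
            if raw is None:
                logger.warning(
                    "subject %s (best hit of %s) missing from taxonomy; "
                    "fragment counted unclassified", best.sseqid, frag.id,
                )
            else:
                lineage = parse_lineage(raw)
        profile.assignments[frag.id] = lineage
        if lineage is None:
            profile.total_unclassified += 1
            continue
        profile.total_classified += 1
        for rank in TREE_RANKS:
            path = lineage.path(rank)
            if path is None:
                break
            key = (rank, path)
            profile.counts[key] = profile.counts.get(key, 0) + 1
    return profile


def profile_to_json(profile: SampleProfile) -> str:
    """Serialize a profile (counts and totals; assignments stay in the
    per-fragment TSV) for the multi-sample comparison step."""
    import json

    return json.dumps(
        {
            "sample_id": profile.sample_id,
            "total_classified": profile.total_classified,
            "total_unclassified": profile.total_unclassified,
            "counts": [
                {"rank": r, "path": list(p), "count": c}
                for (r, p), c in profile.counts.items()
            ],
        },
        indent=2,
    )


def profile_from_json(text: str) -> SampleProfile:
    import json

    data = json.loads(text)
    return SampleProfile(
        sample_id=data["sample_id"],
        total_classified=data["total_classified"],
        total_unclassified=data["total_unclassified"],
        counts={
            (e["rank"], tuple(e["path"])): e["count"] for e in data["counts"]
        },
    )


def classification_report(profile: SampleProfile) -> Tuple[str, Dict[str, pd.DataFrame]]:
    """Human-readable summary plus one count/percentage table per rank.

    Percentages are over classified fragments; the unclassified share is
    reported separately as a fraction of all fragments.
    """
    total = profile.total
    unclass_pct = 100.0 * profile.total_unclassified / total if total else 0.0
    lines = [
        f"sample: {profile.sample_id}",
        f"fragments: {total}",
        f"classified: {profile.total_classified}",
        f"unclassified: {profile.total_unclassified} ({unclass_pct:.1f}%)",
        "",
    ]
    tables: Dict[str, pd.DataFrame] = {}
    for rank in TREE_RANKS:
        counts = profile.rank_counts(rank)
        rows = []
        denom = profile.total_classified
        for path in sorted(counts, key=lambda p: (-counts[p], p)):
            pct = 100.0 * counts[path] / denom if denom else 0.0
            rows.append({
                "rank": rank.rstrip("_"),
                "taxon": ";".join(path),
                "count": counts[path],
                "percent_of_rank": round(
                    100.0 * counts[path] / sum(counts.values()), 2
                ) if counts else 0.0,
                "percent_of_classified": round(pct, 2),
            })
        tables[rank] = pd.DataFrame(
            rows,
            columns=["rank", "taxon", "count", "percent_of_rank",
                     "percent_of_classified"],
        )
        lines.append(f"{rank.rstrip('_')}: {len(rows)} taxa, "
                     f"{sum(counts.values())} fragments")
    return "\n".join(lines) + "\n", tables
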