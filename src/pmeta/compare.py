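"""Step 4: the multi-sample consensus taxonomy tree and its renderings.

All samples are mapped onto one rank-structured tree: each level below
the root is one biological level (phylum, class, order, family, genus,
species -- kingdom is collapsed into the root), a node exists iff some
sample observed a nonzero count on that path, and every node carries one
count and one normalized proportion per sample.  Proportions are
normalized per sample over its classified fragments, which makes bars
comparable between samples of very different sequencing depth.

Renderings: an SVG with a per-sample bar chart after each node name
(bars scaled per node to the largest proportion at that node), a Newick
string with proportions in bracketed comments, and a TSV comparison
table with one proportion column per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
from xml.sax.saxutils import escape

from .classify import SampleProfile, TREE_RANKS

__all__ = [
    "TreeNode",
    "ConsensusTree",
    "build_consensus_tree",
    "render_tree_newick",
    "render_tree_svg",
    "comparison_table",
]

_PALETTE = [
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f",
    "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
]


@dataclass
class TreeNode:
    name: str
    rank: str  # "root" or one of the six tree ranks
    counts: Dict[str, int] = field(default_factory=dict)
    proportions: Dict[str, float] = field(default_factory=dict)
    children: List["TreeNode"] = field(default_factory=list)

    def pooled_count(self) -> int:
        return sum(self.counts.values())

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class ConsensusTree:
    root: TreeNode
    samples: List[str]

    def depth(self) -> int:
        """Number of ranked levels below the root."""

        def _d(node: TreeNode) -> int:
            if not node.children:
                return 0
            return 1 + max(_d(c) for c in node.children)

        return _d(self.root)


def build_consensus_tree(profiles: Sequence[SampleProfile]) -> ConsensusTree:
    """Union of all observed lineage paths with per-sample proportions.

    A node's proportion for a sample is that sample's count at the node
    divided by the sample's total classified count (0 for samples absent
    at the node).  Children are ordered by descending pooled count, ties
    alphabetical.
    """
    if not profiles:
        raise ValueError("need at least one sample profile")
    samples = [p.sample_id for p in profiles]
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample ids: {samples}")
    totals = {p.sample_id: p.total_classified for p in profiles}
    root = TreeNode(name="root", rank="root")
    for p in profiles:
        root.counts[p.sample_id] = p.total_classified
    nodes: Dict[Tuple[str, ...], TreeNode] = {}
    for profile in profiles:
        for (rank, path), count in profile.counts.items():
            node = nodes.get(path)
            if node is None:
                node = TreeNode(name=path[-1], rank=rank)
                nodes[path] = node
            node.counts[profile.sample_id] = (
                node.counts.get(profile.sample_id, 0) + count
            )
    # attach children
    for path, node in nodes.items():
        parent = root if len(path) == 1 else nodes[path[:-1]]
        parent.children.append(node)
    for node in list(nodes.values()) + [root]:
        node.children.sort(key=lambda c: (-c.pooled_count(), c.name))
        for sid in samples:
            total = totals[sid]
            node.proportions[sid] = (
                node.counts.get(sid, 0) / total if total else 0.0
            )
    tree = ConsensusTree(root=root, samples=samples)
    assert tree.depth() <= len(TREE_RANKS)
    return tree


# ---------------------------------------------------------------------------
# renderings


def _newick_label(name: str) -> str:
    out = []
    for ch in name:
        out.append("_" if ch in " \t()[]:;,'" else ch)
    return "".join(out)


def render_tree_newick(tree: ConsensusTree) -> str:
    """Newick with node names and per-sample proportions in comments."""

    def _fmt(node: TreeNode) -> str:
        props = ",".join(
            f"{_newick_label(s)}={node.proportions.get(s, 0.0):.6f}"
            for s in tree.samples
        )
        label = f"{_newick_label(node.name)}[&{props}]"
        if not node.children:
            return label
        inner = ",".join(_fmt(c) for c in node.children)
        return f"({inner}){label}"

    return _fmt(tree.root) + ";"


def comparison_table(tree: ConsensusTree) -> str:
    """TSV: rank, taxon path, one normalized-proportion column per sample."""
    header = ["rank", "taxon_path"] + list(tree.samples)
    lines = ["\t".join(header)]

    def _rows(node: TreeNode, path: Tuple[str, ...]):
        if node.rank != "root":
            cols = [node.rank.rstrip("_"), ";".join(path)] + [
                f"{node.proportions.get(s, 0.0):.6f}" for s in tree.samples
            ]
            lines.append("\t".join(cols))
        for child in node.children:
            _rows(child, path + (child.name,))

    _rows(tree.root, ())
    return "\n".join(lines) + "\n"


def render_tree_svg(tree: ConsensusTree, bar_width: int = 60,
                    row_height: int = 16, col_width: int = 170) -> str:
    """Left-to-right tree drawing with one bar per sample at each node.

    Bars are scaled per node: the largest per-sample proportion at a
    node fills the full bar width.  A shared legend maps colors to
    sample ids.
    """
    samples = tree.samples
    bar_h = max(2, row_height // max(len(samples), 1) - 1)
    node_h = max(row_height, (bar_h + 1) * len(samples) + 4)

    positions: Dict[int, Tuple[float, float]] = {}
    next_y = [40.0]

    def _layout(node: TreeNode, depth: int) -> float:
        if not node.children:
            y = next_y[0]
            next_y[0] += node_h + 6
        else:
            ys = [_layout(c, depth + 1) for c in node.children]
            y = sum(ys) / len(ys)
        positions[id(node)] = (20.0 + depth * col_width, y)
        return y

    _layout(tree.root, 0)
    width = 20 + (tree.depth() + 1) * col_width + bar_width + 200
    height = next_y[0] + 30 + 14 * len(samples)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" font-family="sans-serif" font-size="10">'
    ]
    # edges
    for node in tree.root.walk():
        x, y = positions[id(node)]
        for child in node.children:
            cx, cy = positions[id(child)]
            parts.append(
                f'<path d="M {x:.1f} {y:.1f} H {(x + cx) / 2:.1f} '
                f'V {cy:.1f} H {cx:.1f}" fill="none" stroke="#999"/>'
            )
    # nodes: label + per-sample bars
    for node in tree.root.walk():
        x, y = positions[id(node)]
        scale = max((node.proportions.get(s, 0.0) for s in samples), default=0.0)
        parts.append(f'<g class="node" transform="translate({x:.1f},{y:.1f})">')
        parts.append(
            f'<text x="2" y="-2" class="label">{escape(node.name)}</text>'
        )
        for si, sid in enumerate(samples):
            prop = node.proportions.get(sid, 0.0)
            w = bar_width * (prop / scale) if scale > 0 else 0.0
            by = si * (bar_h + 1)
            parts.append(
                f'<rect class="bar" x="2" y="{by}" width="{w:.2f}" '
                f'height="{bar_h}" fill="{_PALETTE[si % len(_PALETTE)]}">'
                f"<title>{escape(sid)}: {prop:.4f}</title></rect>"
            )
        parts.append("</g>")
    # legend
    ly = next_y[0] + 10
    parts.append('<g class="legend">')
    for si, sid in enumerate(samples):
        parts.append(
            f'<rect x="20" y="{ly + si * 14:.1f}" width="10" height="10" '
            f'fill="{_PALETTE[si % len(_PALETTE)]}"/>'
            f'<text x="34" y="{ly + si * 14 + 9:.1f}">{escape(sid)}</text>'
        )
    parts.append("</g></svg>")
    return "\n".join(parts)
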