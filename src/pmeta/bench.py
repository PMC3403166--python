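"""Weighted-average summaries for chunk-level timing reports.

When the same pipeline runs over several inputs of very different size,
a plain mean of per-input speed-ups over-weights the small inputs.  The
summary used here weights each input's speed-up ``S_i`` by its workload
``N_i`` (sequence count for the extraction stage, 16S fragment count for
the mapping stage):

    weighted_average = sum_i N_i * S_i / sum_i N_i

Wall-clock numbers are reported, never asserted: they depend on the
hardware the pipeline happens to run on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

__all__ = ["SpeedupSummary", "weighted_average"]


def weighted_average(weights: Sequence[float], values: Sequence[float]) -> float:
    """``sum(w_i * v_i) / sum(w_i)``; weights must be nonnegative with a
    positive sum and match ``values`` in length."""
    if len(weights) != len(values):
        raise ValueError(
            f"length mismatch: {len(weights)} weights vs {len(values)} values"
        )
    if len(weights) == 0:
        raise ValueError("need at least one (weight, value) pair")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    total = float(sum(weights))
    if total <= 0:
        raise ValueError("weights sum to zero")
    return sum(w * v for w, v in zip(weights, values)) / total


@dataclass
class SpeedupSummary:
    """Per-input (weight, speed-up) pairs plus their weighted average."""

    weights: List[float]
    values: List[float]
    weighted: float = 0.0

    def __post_init__(self):
        if any(v <= 0 for v in self.values):
            raise ValueError("speed-ups must be positive ratios")
        self.weighted = weighted_average(self.weights, self.values)
        assert min(self.values) <= self.weighted <= max(self.values)

    def report(self) -> str:
        lines = ["input\tweight\tspeedup"]
        for i, (w, v) in enumerate(zip(self.weights, self.values), start=1):
            lines.append(f"{i}\t{w:g}\t{v:g}")
        lines.append(f"weighted average\t\t{self.weighted:.2f}")
        return "\n".join(lines) + "\n"
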