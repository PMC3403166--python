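"""Process-based chunk execution with order-independent collection.

Workers receive whole chunks; results are collected keyed by chunk
index, so the merged output never depends on completion order.  The
``fork`` start method is used so that already-JIT-compiled kernels are
inherited by the workers.
"""

from __future__ import annotations

import multiprocessing as mp
from concurrent.futures import ProcessPoolExecutor, as_completed
from typing import Callable, Iterator, Sequence


def run_tasks(worker: Callable, tasks: Sequence, n_workers: int) -> Iterator[tuple]:
    """Run ``worker(task)`` for each task; yield ``(index, result)`` pairs.

    Pairs are yielded as tasks complete (arbitrary order); callers must
    place results by index.
    """
    ctx = mp.get_context("fork")
    n_workers = min(n_workers, len(tasks))
    with ProcessPoolExecutor(max_workers=n_workers, mp_context=ctx) as ex:
        futures = {ex.submit(worker, t): i for i, t in enumerate(tasks)}
        for fut in as_completed(futures):
            yield futures[fut], fut.result()
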