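"""Deterministic parallel map over independent tasks.

Results are returned in task order regardless of the worker count, and a
failure in one task is isolated and reported rather than aborting the
whole run.  Worker functions must be picklable (module-level) when more
than one worker is requested.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

log = logging.getLogger("pocketmotif")

__all__ = ["TaskResult", "parallel_map"]


@dataclass
class TaskResult:
    """Outcome of one task: either a value or an error message."""

    ok: bool
    value: object = None
    error: str = ""


def _guard(func, task):
    try:
        return TaskResult(True, func(task))
    except Exception as exc:  # noqa: BLE001 - isolation is the point
        return TaskResult(False, None, f"{type(exc).__name__}: {exc}")


def parallel_map(func, tasks, workers: int = 1,
                 initializer=None, initargs=()) -> list[TaskResult]:
    """Apply ``func`` to every task, optionally across processes.

    Raises ``RuntimeError`` when every task failed (and there was at least
    one task); otherwise per-task failures are reported in the results.
    """
    tasks = list(tasks)
    if not tasks:
        return []
    if workers <= 1:
        if initializer is not None:
            initializer(*initargs)
        results = [_guard(func, t) for t in tasks]
    else:
        with ProcessPoolExecutor(max_workers=workers, initializer=initializer,
                                 initargs=initargs) as pool:
            chunk = max(1, len(tasks) // (workers * 8))
            results = list(pool.map(_guard, [func] * len(tasks), tasks,
                                    chunksize=chunk))
    failures = [r for r in results if not r.ok]
    if len(failures) == len(results):
        raise RuntimeError(
            f"all {len(results)} tasks failed; first error: {failures[0].error}")
    for r in failures:
        log.warning("task failed: %s", r.error)
    return results
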