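"""Benchmark instrumentation: stage timings and resident-memory sampling.

Resident set size (RSS) is sampled from ``/proc/<pid>/statm`` on a short
fixed interval (default 15 ms) in a background thread; a resting baseline
collected before the workload is subtracted from the in-flight peak, so
the reported figure is the memory attributable to the computation, not
the interpreter.  Wall-clock RSS is hardware- and allocator-dependent, so
downstream checks assert only qualitative properties (flatness across
cube sizes, monotonicity in batch size), never absolute values.

:func:`tracemalloc_peak` offers a deterministic, allocator-level
alternative used for the memory-contract assertions.
"""

from __future__ import annotations

import os
import threading
import time
import tracemalloc
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Callable, Iterator

__all__ = ["MemoryTrace", "StageTimer", "memory_trace", "trace_callable", "tracemalloc_peak"]

_PAGE = os.sysconf("SC_PAGE_SIZE")


def _rss_bytes(pid: int | str = "self") -> int:
    with open(f"/proc/{pid}/statm") as fh:
        return int(fh.read().split()[1]) * _PAGE


@dataclass
class MemoryTrace:
    """RSS time series plus resting / peak / attributable-peak summary."""

    samples: list[tuple[float, int]]  # (seconds since start, RSS bytes)
    resting: float  # baseline RSS, bytes
    interval: float
    complete: bool = True  # False if the traced process exited mid-trace

    @property
    def peak(self) -> int:
        return max(r for _, r in self.samples) if self.samples else 0

    @property
    def peak_minus_resting(self) -> float:
        return max(self.peak - self.resting, 0.0)

    @property
    def duration(self) -> float:
        return self.samples[-1][0] if self.samples else 0.0


class _Sampler(threading.Thread):
    def __init__(self, pid: int | str, interval: float):
        super().__init__(daemon=True)
        self.pid = pid
        self.interval = interval
        self.samples: list[tuple[float, int]] = []
        self.complete = True
        self._halt = threading.Event()

    def run(self) -> None:
        t0 = time.perf_counter()
        next_t = t0
        while not self._halt.is_set():
            try:
                rss = _rss_bytes(self.pid)
            except (FileNotFoundError, ProcessLookupError):
                self.complete = False  # process exited; return partial trace
                return
            now = time.perf_counter()
            self.samples.append((now - t0, rss))
            next_t += self.interval
            delay = next_t - time.perf_counter()
            if delay > 0:
                self._halt.wait(delay)

    def stop(self) -> None:
        self._halt.set()
        self.join()


@contextmanager
def memory_trace(
    pid: int | str = "self",
    interval: float = 0.015,
    baseline_duration: float = 0.06,
) -> Iterator[MemoryTrace]:
    """Sample RSS of ``pid`` every ``interval`` seconds around the with-block.

    A resting baseline is averaged over ``baseline_duration`` before the
    block starts; the yielded :class:`MemoryTrace` fills in after exit.
    """
    baseline: list[int] = []
    t_end = time.perf_counter() + baseline_duration
    while time.perf_counter() < t_end:
        baseline.append(_rss_bytes(pid))
        time.sleep(interval)
    sampler = _Sampler(pid, interval)
    trace = MemoryTrace(samples=sampler.samples, resting=float(sum(baseline)) / max(len(baseline), 1), interval=interval)
    sampler.start()
    try:
        yield trace
    finally:
        sampler.stop()
        trace.complete = sampler.complete


def trace_callable(
    fn: Callable[[], object], interval: float = 0.015
) -> tuple[object, MemoryTrace]:
    """Run ``fn`` under an RSS trace of the current process."""
    with memory_trace("self", interval=interval) as trace:
        result = fn()
    return result, trace


def tracemalloc_peak(fn: Callable[[], object]) -> tuple[object, int]:
    """Run ``fn`` and return (result, peak Python-allocated bytes).

    Deterministic measure of the peak additional allocations of a
    computation; used to verify that fit memory scales with batch size
    and is flat in cube length.
    """
    tracemalloc.start()
    tracemalloc.reset_peak()
    try:
        result = fn()
        _, peak = tracemalloc.get_traced_memory()
    finally:
        tracemalloc.stop()
    return result, peak


@dataclass
class StageTimer:
    """Named wall-clock stage durations (batch-size calc, reader, fit, ...)."""

    durations: dict[str, float] = field(default_factory=dict)

    @contextmanager
    def stage(self, name: str) -> Iterator[None]:
        t0 = time.perf_counter()
        try:
            yield
        finally:
            self.durations[name] = self.durations.get(name, 0.0) + (
                time.perf_counter() - t0
            )

    def as_log_lines(self) -> list[str]:
        return [f"stage {name}: {dt:.4f} s" for name, dt in self.durations.items()]
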