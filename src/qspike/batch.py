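"""Embarrassingly parallel per-channel batch execution.

One channel = one job.  Jobs are pure functions of their own channel's input,
so the worker pool may run them in any order on any number of workers and the
scientific outputs are bitwise identical — the central contract that makes
parallelization safe.  The pool collects per-job stdout/stderr, wall-clock
times and worker attribution into an execution log; ``run_batch`` returns
only when every job has reached a terminal state, which is the dependency
barrier consolidation relies on.
"""

from __future__ import annotations

import io
import math
import os
import time
import traceback
from concurrent.futures import ProcessPoolExecutor
from contextlib import redirect_stderr, redirect_stdout
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

__all__ = [
    "BatchPlan",
    "JobRecord",
    "ExecutionLog",
    "BenchmarkResult",
    "plan_jobs",
    "run_batch",
    "compute_efficiency",
]


@dataclass
class BatchPlan:
    """Decomposition of one recording into per-channel jobs."""

    job_ids: list[int]  # one entry per channel
    n_workers: int

    @property
    def n_jobs(self) -> int:
        return len(self.job_ids)

    @property
    def load_per_worker(self) -> int:
        return math.ceil(self.n_jobs / self.n_workers)


@dataclass
class JobRecord:
    job_id: int
    status: str  # done | failed
    start: float
    end: float
    worker: str
    stdout: str = ""
    stderr: str = ""

    @property
    def elapsed_s(self) -> float:
        return self.end - self.start


@dataclass
class ExecutionLog:
    """Run-level provenance: per-job records plus queue-level timing."""

    queue_name: str
    n_workers: int
    start: float
    end: float = 0.0
    jobs: list[JobRecord] = field(default_factory=list)

    @property
    def total_time_s(self) -> float:
        return self.end - self.start

    @property
    def status(self) -> str:
        return "done" if all(j.status == "done" for j in self.jobs) else "failed"

    def to_dict(self) -> dict:
        return {
            "queue_name": self.queue_name,
            "n_workers": self.n_workers,
            "start": self.start,
            "end": self.end,
            "status": self.status,
            "jobs": [vars(j) for j in self.jobs],
        }


@dataclass
class BenchmarkResult:
    """Parallel efficiency relative to the slowest (single-worker) run."""

    t_max_s: float
    delta_t_s: float

    @property
    def efficiency_pct(self) -> float:
        return compute_efficiency(self.t_max_s, self.delta_t_s)


def plan_jobs(n_channels: int, n_workers: int) -> BatchPlan:
    """One job per channel; e.g. 60 channels on 12 workers -> 5 jobs/worker."""
    if n_channels < 1 or n_workers < 1:
        raise ValueError("n_channels and n_workers must be >= 1")
    return BatchPlan(job_ids=list(range(n_channels)), n_workers=n_workers)


def _run_one(job: Callable[[Any], Any], arg: Any, job_id: int) -> tuple[JobRecord, Any]:
    out, err = io.StringIO(), io.StringIO()
    start = time.time()
    result = None
    try:
        with redirect_stdout(out), redirect_stderr(err):
            result = job(arg)
        status = "done"
    except Exception:
        err.write(traceback.format_exc())
        status = "failed"
    rec = JobRecord(
        job_id=job_id,
        status=status,
        start=start,
        end=time.time(),
        worker=f"pid-{os.getpid()}",
        stdout=out.getvalue(),
        stderr=err.getvalue(),
    )
    return rec, result


def run_batch(
    plan: BatchPlan,
    job: Callable[[Any], Any],
    job_args: Sequence[Any],
    queue_name: str = "default",
) -> tuple[dict[int, Any], ExecutionLog]:
    """Execute every job on the pool; barrier on full completion.

    ``job`` must be a picklable pure function of its single argument (one per
    channel).  A failing job marks the run failed but never aborts the
    others; its traceback is captured in the job's stderr.  Returns results
    of the successful jobs keyed by job id, plus the execution log.
    """
    if len(job_args) != plan.n_jobs:
        raise ValueError("one argument per planned job required")
    log = ExecutionLog(queue_name=queue_name, n_workers=plan.n_workers, start=time.time())
    results: dict[int, Any] = {}
    records: dict[int, JobRecord] = {}
    if plan.n_workers == 1:
        for jid, arg in zip(plan.job_ids, job_args):
            rec, res = _run_one(job, arg, jid)
            records[jid] = rec
            if rec.status == "done":
                results[jid] = res
    else:
        with ProcessPoolExecutor(max_workers=plan.n_workers) as pool:
            futures = {
                jid: pool.submit(_run_one, job, arg, jid)
                for jid, arg in zip(plan.job_ids, job_args)
            }
            for jid, fut in futures.items():
                rec, res = fut.result()  # barrier: wait for every job
                records[jid] = rec
                if rec.status == "done":
                    results[jid] = res
    log.jobs = [records[jid] for jid in plan.job_ids]
    log.end = time.time()
    return results, log


def compute_efficiency(t_max: float, delta_t: float) -> float:
    """Parallel efficiency E = T_max / dT x 100 (%).

    T_max is the slowest (single-worker) execution time, dT the time at the
    worker count under test; E = 100% at one worker and grows sublinearly
    with the pool size.
    """
    if t_max <= 0 or delta_t <= 0:
        raise ValueError("execution times must be positive")
    return t_max / delta_t * 100.0
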