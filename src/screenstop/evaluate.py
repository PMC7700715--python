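"""Per-run metrics and benchmark aggregation for stopping criteria.

For each criterion in a completed screening trace: *actual recall* at its
stopping point, *work saved* (fraction of the corpus left unscreened when
it fired, WS-SC) and *additional burden* — work saved at the moment the
recall target was truly reached minus work saved at the stop, so positive
values mean screening continued past the target and negative values mean
the criterion fired too early.  A criterion that never fires saves no work
and, since screening then ran to exhaustion, attains recall 1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import ScreeningTrace

__all__ = [
    "CriterionMetrics",
    "metrics_from_trace",
    "metrics_frame",
    "summarize_benchmark",
]


@dataclass(frozen=True)
class CriterionMetrics:
    criterion_name: str
    actual_recall: float
    work_saved: float
    additional_burden: float
    stopped: bool


def metrics_from_trace(
    trace: ScreeningTrace, criterion_name: str, tau_tar: float
) -> CriterionMetrics:
    """Evaluate one criterion's stopping decision against ground truth.

    The identity ``work_saved_at_target = work_saved + additional_burden``
    holds exactly for every criterion, fired or not.
    """
    if trace.rho_total == 0:
        raise ValueError("recall undefined for a corpus with no relevant documents")
    if criterion_name not in trace.stop_indices:
        raise KeyError(f"criterion {criterion_name!r} not recorded in trace")
    stop = trace.stop_indices[criterion_name]
    ws_target = trace.work_saved_at(trace.target_recall_index(tau_tar))
    if stop is None:
        return CriterionMetrics(
            criterion_name=criterion_name,
            actual_recall=1.0,
            work_saved=0.0,
            additional_burden=ws_target,
            stopped=False,
        )
    ws = trace.work_saved_at(stop)
    return CriterionMetrics(
        criterion_name=criterion_name,
        actual_recall=trace.recall_at(stop),
        work_saved=ws,
        additional_burden=ws_target - ws,
        stopped=True,
    )


def metrics_frame(
    traces: Iterable[ScreeningTrace],
    tau_tar: float,
    dataset_name: str = "dataset",
) -> pd.DataFrame:
    """Metrics for every criterion of every trace, one row per pair."""
    rows = []
    for run_id, trace in enumerate(traces):
        for name in trace.stop_indices:
            m = metrics_from_trace(trace, name, tau_tar)
            rows.append(
                {
                    "dataset": dataset_name,
                    "run": run_id,
                    "seed": trace.seed,
                    "criterion": name,
                    "actual_recall": m.actual_recall,
                    "ws_sc": m.work_saved,
                    "additional_burden": m.additional_burden,
                    "stopped": m.stopped,
                }
            )
    return pd.DataFrame(rows)


def summarize_benchmark(metrics: pd.DataFrame, tau_tar: float) -> pd.DataFrame:
    """Aggregate run-level metrics per dataset and criterion.

    Returns one row per (dataset, criterion) with the mean work saved, the
    recall-miss rate (fraction of runs with ``actual_recall < tau_tar``,
    pooled over runs) and the 5th/95th percentiles of work saved.  The
    result is invariant to the ordering of the input rows.
    """
    required = {"dataset", "criterion", "actual_recall", "ws_sc", "additional_burden"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics frame lacks columns: {sorted(missing)}")

    def agg(group: pd.DataFrame) -> pd.Series:
        ws = group["ws_sc"].to_numpy()
        return pd.Series(
            {
                "n_runs": len(group),
                "mean_ws_sc": ws.mean(),
                "mean_actual_recall": group["actual_recall"].mean(),
                "mean_additional_burden": group["additional_burden"].mean(),
                "miss_rate": float((group["actual_recall"] < tau_tar).mean()),
                "ws_sc_p5": float(np.percentile(ws, 5)),
                "ws_sc_p95": float(np.percentile(ws, 95)),
            }
        )

    out = (
        metrics.groupby(["dataset", "criterion"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n_runs"] = out["n_runs"].astype(int)
    return out
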