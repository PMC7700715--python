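"""Baseline stopping criteria: inclusion-rate sampling and irrelevance runs.

The baseline-inclusion-rate (BIR) procedure estimates the total number of
relevant documents from an initial random sample and stops screening once a
target fraction of that estimate has been found.  The estimate carries
sampling error that the procedure ignores: underestimates end screening
before the recall target is truly met, while overestimates set a stop count
that can never be reached, forcing exhaustive screening with no savings.
``bir_error_partition`` quantifies both failure modes exactly.

The consecutive-irrelevant heuristic stops after a fixed number of
irrelevant records in a row, ignoring both uncertainty and the size of the
unseen pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "BIRResult",
    "BIRErrorPartition",
    "estimate_bir",
    "bir_criterion",
    "bir_error_partition",
    "bir_error_curve",
    "consecutive_irrelevant_criterion",
]


@dataclass(frozen=True)
class BIRResult:
    """Baseline-inclusion-rate estimate from an initial random sample."""

    n_s: int
    relevant_in_sample: int
    estimated_total_relevant: float
    stop_count: float


@dataclass(frozen=True)
class BIRErrorPartition:
    """Outcome probabilities of the BIR procedure over the sample draw."""

    p_recall_miss: float
    p_no_savings: float
    p_ok: float


def estimate_bir(
    n_s: int, relevant_in_sample: int, N_total: int, tau_tar: float
) -> BIRResult:
    """Project the sample inclusion rate onto the whole corpus.

    ``estimated_total_relevant = (relevant_in_sample / n_s) * N_total`` and
    ``stop_count = tau_tar * estimated_total_relevant``.  Both are kept
    real-valued; the screener stops once the running count of relevant
    documents reaches ``stop_count``.  A sample with no relevant documents
    yields a stop count of zero, which fires immediately.
    """
    if n_s < 1:
        raise ValueError("sample size must be positive")
    if not 0 <= relevant_in_sample <= n_s:
        raise ValueError("need 0 <= relevant_in_sample <= n_s")
    if n_s > N_total:
        raise ValueError("sample larger than corpus")
    est = relevant_in_sample / n_s * N_total
    return BIRResult(
        n_s=n_s,
        relevant_in_sample=relevant_in_sample,
        estimated_total_relevant=est,
        stop_count=tau_tar * est,
    )


def bir_criterion(labels: Sequence[int], bir: BIRResult, tau_tar: float) -> bool:
    """True once the running relevant count reaches the BIR stop count.

    The comparison is real-valued (``>=`` against ``tau_tar`` times the
    estimate, no rounding), so the firing document is always one at which
    the cumulative relevant count is an integer at or above the stop count.
    """
    if bir.n_s < 1:
        raise ValueError("BIR estimate requires a non-empty sample")
    return sum(labels) >= tau_tar * bir.estimated_total_relevant


def bir_error_partition(
    N_total: int,
    K_pop: int,
    n_s: int,
    tau_tar: float,
    no_savings_bound: str = "symmetric",
) -> BIRErrorPartition:
    """Exact outcome probabilities of the BIR procedure.

    Enumerates the sample's relevant count ``k ~ Hypergeometric(N_total,
    K_pop, n_s)`` and classifies each value by where its stop count
    ``s = tau_tar * (k / n_s) * N_total`` lands:

    - *recall miss*: stopping at ``s`` yields fewer than ``tau_tar * K_pop``
      relevant documents (the first integer count at or above ``s`` falls
      short of the target; exact attainment counts as ok);
    - *no savings*: ``s`` is so large that screening cannot end early;
    - *ok*: work is saved and the recall target met.

    ``no_savings_bound`` selects the upper classification boundary.
    ``"symmetric"`` (default) classes a draw as no-savings when
    ``s > K_pop / tau_tar``, mirroring the recall-miss bound at
    ``tau_tar * K_pop`` so the acceptable stop counts form the band
    ``[tau_tar * K_pop, K_pop / tau_tar]``; this is the convention behind
    the published partition of this error distribution.  ``"unreachable"``
    uses the strict feasibility bound ``s > K_pop`` (the stop count exceeds
    the relevant documents that exist), which is the classification an
    end-to-end simulation of the procedure reproduces.
    """
    if not 0 <= K_pop <= N_total:
        raise ValueError("need 0 <= K_pop <= N_total")
    if not 1 <= n_s <= N_total:
        raise ValueError("need 1 <= n_s <= N_total")
    if not 0.0 < tau_tar < 1.0:
        raise ValueError(f"tau_tar must lie in (0, 1), got {tau_tar}")
    if no_savings_bound not in ("symmetric", "unreachable"):
        raise ValueError("no_savings_bound must be 'symmetric' or 'unreachable'")

    k = np.arange(n_s + 1)
    pmf = hypergeom.pmf(k, N_total, K_pop, n_s)
    stop_count = tau_tar * (k / n_s) * N_total
    target = tau_tar * K_pop
    # Relevant count at stop is the first integer >= stop_count.
    at_stop = np.ceil(stop_count)
    miss = at_stop < target
    if no_savings_bound == "symmetric":
        no_savings = stop_count > K_pop / tau_tar
    else:
        no_savings = stop_count > K_pop
    no_savings &= ~miss
    ok = ~miss & ~no_savings
    return BIRErrorPartition(
        p_recall_miss=float(pmf[miss].sum()),
        p_no_savings=float(pmf[no_savings].sum()),
        p_ok=float(pmf[ok].sum()),
    )


def bir_error_curve(
    N_total: int,
    K_pop: int,
    sample_sizes: Iterable[int],
    tau_tar: float,
    no_savings_bound: str = "symmetric",
) -> list[BIRErrorPartition]:
    """:func:`bir_error_partition` evaluated over a range of sample sizes."""
    return [
        bir_error_partition(N_total, K_pop, n_s, tau_tar, no_savings_bound)
        for n_s in sample_sizes
    ]


def consecutive_irrelevant_criterion(labels: Sequence[int], h: int) -> bool:
    """True iff the last ``h`` screened records exist and are all irrelevant."""
    if h < 1:
        raise ValueError("window must be a positive integer")
    tail = np.asarray(labels[-h:], dtype=np.int64) if len(labels) >= h else None
    if tail is None:
        return False
    return bool((tail == 0).all())
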