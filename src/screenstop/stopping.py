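"""Hypergeometric stopping test for screening with a recall target.

The screening problem: a corpus of ``N_tot`` documents contains an unknown
number of relevant ones.  After a prioritised (active-learning) phase has
seen ``N_AL`` documents and found ``rho_AL`` relevant, screening switches to
uniform random sampling without replacement from the ``N = N_tot - N_AL``
unseen documents.  Let ``K`` be the unknown number of relevant documents
among those ``N``.  After ``n`` random draws containing ``k`` relevant, the
null hypothesis that recall is still below the target ``tau_tar`` is
equivalent to ``K >= K_tar`` where ``K_tar`` is the smallest remaining
relevant count that would leave recall under the target.  Because the
cumulative mass ``P(X <= k)`` of ``Hypergeometric(N, K, n)`` is decreasing
in ``K``, evaluating it at ``K_tar`` bounds the p-value over the whole null
region; screening stops when that bound falls below ``1 - alpha``.

The ranked quasi-sampling variant applies the same test retrospectively to
every trailing window of the prioritised screening sequence, treating the
window as if it were a random sample, and takes the minimum p-value.  On
ranked sequences the windows are biased toward relevance, which makes the
resulting criterion conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "StoppingConfig",
    "SamplingState",
    "HypergeomTestResult",
    "compute_k_tar",
    "stopping_p_value",
    "evaluate_random_sampling_criterion",
    "quasi_sampling_p_sequence",
    "p_min",
    "switch_decision",
    "quasi_sampling_stop_decision",
]


@dataclass(frozen=True)
class StoppingConfig:
    """Targets and thresholds governing a screening run.

    Parameters
    ----------
    tau_tar : float
        Target recall, in (0, 1).
    alpha : float
        Confidence level, in (0, 1).  The null hypothesis of having missed
        the target is rejected when its p-value drops below ``1 - alpha``.
    heuristic_window : int
        Number of consecutive irrelevant records that fires the heuristic
        baseline criterion.
    seed_sample_size : int
        Size of the initial random seed sample that bootstraps the
        classifier (and the baseline-inclusion-rate estimate).
    batch_size : int
        Number of top-ranked documents screened between classifier refits.
    """

    tau_tar: float = 0.95
    alpha: float = 0.95
    heuristic_window: int = 50
    seed_sample_size: int = 200
    batch_size: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_tar < 1.0:
            raise ValueError(f"tau_tar must lie in (0, 1), got {self.tau_tar}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.heuristic_window < 1:
            raise ValueError("heuristic_window must be a positive integer")
        if self.seed_sample_size < 1:
            raise ValueError("seed_sample_size must be a positive integer")
        if self.batch_size < 1:
            raise ValueError("batch_size must be a positive integer")

    @property
    def stop_threshold(self) -> float:
        """Significance level: stop once the p-value is below ``1 - alpha``.

        Rounded to 12 decimals so a p-value exactly at the threshold's
        printed precision counts as a tie and screening continues.
        """
        return round(1.0 - self.alpha, 12)

    @property
    def switch_threshold(self) -> float:
        """Laxer threshold ``1 - alpha/2`` ending the active-learning phase."""
        return round(1.0 - self.alpha / 2.0, 12)


@dataclass(frozen=True)
class SamplingState:
    """Document accounting at a point during the random-sampling phase.

    ``N_total`` is the corpus size; ``N_AL`` documents were screened before
    random sampling began, ``rho_AL`` of them relevant; ``n`` documents have
    been drawn at random since, ``k`` of them relevant.
    """

    N_total: int
    N_AL: int
    rho_AL: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.rho_AL <= self.N_AL <= self.N_total:
            raise ValueError("need 0 <= rho_AL <= N_AL <= N_total")
        if not 0 <= self.k <= self.n <= self.N_total - self.N_AL:
            raise ValueError("need 0 <= k <= n <= N_total - N_AL")

    @property
    def N(self) -> int:
        """Documents unseen at the start of random sampling."""
        return self.N_total - self.N_AL

    @property
    def rho_seen(self) -> int:
        """Relevant documents seen so far (both phases)."""
        return self.rho_AL + self.k


@dataclass(frozen=True)
class HypergeomTestResult:
    """Outcome of one evaluation of the stopping test."""

    k_tar: int
    p_value: float
    reject: bool


def compute_k_tar(rho_seen: int, rho_al: int, tau_tar: float) -> int:
    """Minimum remaining relevant count consistent with recall < ``tau_tar``.

    Computed as ``floor(rho_seen / tau_tar - rho_al + 1)``, which equals the
    smallest integer ``K`` such that ``rho_seen / (rho_al + K) < tau_tar``:
    if ``K`` or more relevant documents remained unseen when sampling
    started, the final recall would fall short of the target.  Recall
    exactly equal to the target counts as achieved, so ties favour the
    alternative hypothesis.

    The quotient is evaluated in exact rational arithmetic so the floor is
    never perturbed by floating-point rounding.
    """
    if not 0.0 < tau_tar < 1.0:
        raise ValueError(f"tau_tar must lie in (0, 1), got {tau_tar}")
    if not 0 <= rho_al <= rho_seen:
        raise ValueError("need 0 <= rho_al <= rho_seen")
    return math.floor(Fraction(rho_seen) / Fraction(tau_tar) - rho_al + 1)


def stopping_p_value(N: int, k_tar: int, n: int, k: int) -> float:
    """Upper bound on ``P(data | recall below target)``.

    Returns ``P(X <= k)`` for ``X ~ Hypergeometric(N, k_tar, n)``: the
    probability of drawing at most ``k`` relevant documents in ``n`` draws
    without replacement from ``N`` documents of which ``k_tar`` are
    relevant.  Degenerate nulls — ``k_tar <= 0`` (the target provably
    already met) or ``k_tar > N`` (more relevant posited than documents
    exist) — have an empty parameter region and return 0.
    """
    if not 0 <= k <= n <= N:
        raise ValueError("need 0 <= k <= n <= N")
    if k_tar <= 0 or k_tar > N:
        return 0.0
    return float(hypergeom.cdf(k, N, k_tar, n))


def evaluate_random_sampling_criterion(
    state: SamplingState, config: StoppingConfig
) -> HypergeomTestResult:
    """Apply the stopping test to the current random-sampling state."""
    k_tar = compute_k_tar(state.rho_seen, state.rho_AL, config.tau_tar)
    p = stopping_p_value(state.N, k_tar, state.n, state.k)
    return HypergeomTestResult(k_tar=k_tar, p_value=p, reject=p < config.stop_threshold)


def _quasi_components(
    labels: np.ndarray, N_total: int, tau_tar: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (N, K_tar, n, k) for look-back starts i = 1..len-1."""
    t = labels.size
    cum = np.cumsum(labels, dtype=np.int64)
    total = int(cum[-1])
    # K_tar(i) = floor(total/tau - rho_al(i) + 1); rho_al is an integer so the
    # floor separates: K_tar(i) = floor(total/tau + 1) - rho_al(i), exactly.
    base = math.floor(Fraction(total) / Fraction(tau_tar) + 1)
    i = np.arange(1, t)
    rho_al = cum[:-1]
    n = t - i
    k = total - rho_al
    N = N_total - i
    k_tar = base - rho_al
    return N, k_tar, n, k


def quasi_sampling_p_sequence(
    labels: Sequence[int], N_total: int, tau_tar: float
) -> np.ndarray:
    """p-values from treating every trailing window as a random sample.

    For each look-back start ``i`` in ``1..len(labels)-1`` the first ``i``
    screened documents are treated as the pre-sampling phase and the rest as
    a quasi-random sample from the ``N_total - i`` documents not yet seen at
    that point.  Entry ``j`` of the result is the p-value for ``i = j + 1``.
    An empty or length-1 sequence yields an empty array.
    """
    arr = np.asarray(labels, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    if arr.size > N_total:
        raise ValueError("more labels than documents in the corpus")
    if np.any((arr != 0) & (arr != 1)):
        raise ValueError("labels must be binary")
    if arr.size <= 1:
        return np.empty(0, dtype=float)
    N, k_tar, n, k = _quasi_components(arr, N_total, tau_tar)
    p = np.zeros(arr.size - 1, dtype=float)
    live = (k_tar > 0) & (k_tar <= N)  # degenerate windows keep p = 0
    if np.any(live):
        p[live] = hypergeom.cdf(k[live], N[live], k_tar[live], n[live])
    return p


def p_min(labels: Sequence[int], N_total: int, tau_tar: float) -> float:
    """Minimum of :func:`quasi_sampling_p_sequence`; 1.0 if it is empty."""
    seq = quasi_sampling_p_sequence(labels, N_total, tau_tar)
    return float(seq.min()) if seq.size else 1.0


def switch_decision(p_min_value: float, config: StoppingConfig) -> bool:
    """End active learning and begin random sampling once ``p_min < 1 - alpha/2``."""
    return p_min_value < config.switch_threshold


def quasi_sampling_stop_decision(p_min_value: float, config: StoppingConfig) -> bool:
    """Standalone ranked quasi-sampling stop rule: ``p_min < 1 - alpha``."""
    return p_min_value < config.stop_threshold
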