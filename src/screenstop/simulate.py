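"""Screening workflow simulation and the random-sampling calibration experiment.

``run_screening`` executes the full workflow on a labelled corpus: an
initial random seed sample, active-learning batches ranked by a linear SVM,
a switch to uniform random sampling once the quasi-sampling heuristic says
the end is near, and screening to exhaustion.  Every enabled stopping
criterion is evaluated after each revealed label and the index at which it
first fires is recorded, so one pass yields the stopping behaviour of all
criteria plus the index at which the recall target was truly reached.

``run_sampling_accuracy_experiment`` strips the workflow down to what the
hypergeometric test actually sees — a stream of labels drawn without
replacement from a residual population — and measures how often the test
stops before the recall target is truly met.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.stats import hypergeom
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .baselines import BIRResult, estimate_bir
from .corpus import ScreeningDataset, featurize
from .stopping import StoppingConfig, compute_k_tar, stopping_p_value

__all__ = [
    "ScreeningTrace",
    "ScenarioSpec",
    "ScenarioResult",
    "train_and_rank",
    "run_screening",
    "run_iterations",
    "run_sampling_accuracy_experiment",
    "default_calibration_scenarios",
    "DEFAULT_CRITERIA",
]

DEFAULT_CRITERIA = ("random_sampling", "quasi_sampling", "bir", "heuristic")


@dataclass
class ScreeningTrace:
    """Chronological record of one screening run.

    ``order`` is the screening sequence as indices into the dataset;
    ``labels_seen`` the aligned true labels.  ``seed_end`` is the number of
    documents screened when the random seed phase (including any cold-start
    extension) ended; ``switch_index`` the count at which active learning
    gave way to random sampling (None if it never did).  ``stop_indices``
    maps criterion names to the count at which each first fired (None if
    never).  Ground truth ``N_total`` and ``rho_total`` make recall at any
    index computable.
    """

    order: np.ndarray
    labels_seen: np.ndarray
    seed_end: int
    switch_index: int | None
    stop_indices: dict[str, int | None]
    N_total: int
    rho_total: int
    seed: int
    config: StoppingConfig

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.labels_seen = np.asarray(self.labels_seen, dtype=np.int64)
        if self.order.size != self.N_total or self.labels_seen.size != self.N_total:
            raise ValueError("trace must cover the whole corpus")
        if int(self.labels_seen.sum()) != self.rho_total:
            raise ValueError("labels_seen inconsistent with rho_total")

    @property
    def cumulative_relevant(self) -> np.ndarray:
        """Relevant documents seen after each screening step (length N_total)."""
        return np.cumsum(self.labels_seen)

    def recall_at(self, index: int) -> float:
        """Recall after ``index`` documents have been screened."""
        if self.rho_total == 0:
            raise ValueError("recall undefined for a corpus with no relevant documents")
        if index == 0:
            return 0.0
        return float(self.cumulative_relevant[index - 1]) / self.rho_total

    def work_saved_at(self, index: int) -> float:
        """Fraction of the corpus unscreened after ``index`` documents."""
        return (self.N_total - index) / self.N_total

    def target_recall_index(self, tau_tar: float) -> int:
        """First screening count at which recall reaches ``tau_tar``."""
        needed = self.rho_total * tau_tar
        cum = self.cumulative_relevant
        hits = np.nonzero(cum >= needed)[0]
        if hits.size == 0:  # only possible through float round-up at tau ~ 1
            return self.N_total
        return int(hits[0]) + 1


def train_and_rank(
    features: sparse.csr_matrix,
    screened_idx: np.ndarray,
    labels_screened: np.ndarray,
    unscreened_idx: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rank unscreened documents by predicted relevance.

    Fits a linear max-margin classifier on the screened documents and
    orders the unscreened ones by decreasing decision-function score, ties
    broken by stable document order.  A single-class training set cannot be
    fit; the ranking then falls back to a random order (with a warning),
    drawn from ``rng``.
    """
    labels_screened = np.asarray(labels_screened)
    if np.unique(labels_screened).size < 2:
        warnings.warn(
            "single-class training set: falling back to random ranking",
            stacklevel=2,
        )
        rng = rng if rng is not None else np.random.default_rng(0)
        return unscreened_idx[rng.permutation(unscreened_idx.size)]
    model = LinearSVC(C=1.0, tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(features[screened_idx], labels_screened)
    scores = model.decision_function(features[unscreened_idx])
    return unscreened_idx[np.argsort(-scores, kind="stable")]


class _QuasiMonitor:
    """Incremental minimum quasi-sampling p-value over a growing sequence.

    Re-deriving the full look-back vector after every document is
    quadratic in corpus size.  Absorbing an irrelevant document into the
    look-back prefix never lowers the window's p-value (the quasi-sample
    shrinks by one irrelevant member, weakening the evidence), so the
    minimum over all look-back starts is always attained at a window that
    begins directly after a relevant document (or at the very first
    window).  Only those candidate windows are evaluated, which keeps the
    per-document cost proportional to the number of relevant documents
    seen.  Equivalence with the full vector is covered by tests.
    """

    def __init__(self, N_total: int, tau_tar: float):
        self.N_total = N_total
        self.tau = Fraction(tau_tar)
        self.t = 0
        self.total = 0
        self.cum: list[int] = [0]  # cum[i] = relevant among first i docs
        self.starts: list[int] = []  # candidate look-back starts i

    def push(self, label: int) -> None:
        self.t += 1
        self.total += label
        self.cum.append(self.total)
        if label and self.t < self.N_total:
            self.starts.append(self.t)

    def p_min(self) -> float:
        t = self.t
        if t <= 1:
            return 1.0
        base = math.floor(Fraction(self.total) / self.tau + 1)
        # A window with more posited relevant than members has p = 0; the
        # longest-prefix window maximises i - rho_al so it decides this.
        if (t - 1) - self.cum[t - 2] > self.N_total - base:
            return 0.0
        cand = [i for i in ([1] + self.starts) if i <= t - 1]
        i = np.asarray(cand, dtype=np.int64)
        rho_al = np.asarray([self.cum[j] for j in cand], dtype=np.int64)
        k_tar = base - rho_al
        N = self.N_total - i
        n = t - i
        k = self.total - rho_al
        p = np.zeros(i.size)
        live = k_tar <= N  # k_tar >= 1 always, since rho_al <= total < total/tau
        if live.any():
            p[live] = hypergeom.cdf(k[live], N[live], k_tar[live], n[live])
        return float(p.min())


def _normalise_criteria(
    criteria: Sequence[str], config: StoppingConfig
) -> dict[str, int | None]:
    """Map user criterion names to canonical keys (heuristics keyed ``ih<h>``)."""
    keys: dict[str, int | None] = {}
    for name in criteria:
        if name in ("random_sampling", "quasi_sampling", "bir"):
            keys[name] = None
        elif name == "heuristic":
            keys[f"ih{config.heuristic_window}"] = config.heuristic_window
        elif name.startswith("ih") and name[2:].isdigit():
            keys[name] = int(name[2:])
        else:
            raise ValueError(f"unknown criterion: {name!r}")
    return keys


def run_screening(
    dataset: ScreeningDataset,
    config: StoppingConfig,
    criteria: Sequence[str] = DEFAULT_CRITERIA,
    seed: int = 0,
    weighting: str = "tf",
    features: sparse.csr_matrix | None = None,
) -> ScreeningTrace:
    """Simulate one screening run to exhaustion, recording criterion firings.

    Workflow: reveal a random seed sample of ``config.seed_sample_size``
    labels (extended randomly if it contains a single class, since the
    classifier needs both); then screen active-learning batches of
    ``config.batch_size`` ranked by the classifier, refitting after each
    batch; once the quasi-sampling heuristic signals the target may be
    near (``p_min`` below ``1 - alpha/2``), abandon the ranking — mid-batch
    if need be — and draw the remaining documents uniformly without
    replacement.  Criteria are evaluated after every revealed label; the
    first firing index of each is recorded and screening continues to the
    last document so all criteria and the true target-recall index are
    observed in one pass.

    ``features`` may carry a precomputed document-feature matrix to avoid
    refeaturising the corpus across repeated runs.
    """
    N = dataset.N_total
    if N == 0:
        raise ValueError("dataset is empty")
    if config.seed_sample_size >= N:
        raise ValueError("seed sample must be smaller than the corpus")
    keys = _normalise_criteria(criteria, config)
    need_quasi = "quasi_sampling" in keys or "random_sampling" in keys
    rng = np.random.default_rng(seed)
    X = features if features is not None else featurize(dataset, weighting=weighting)
    y = dataset.labels

    order = np.empty(N, dtype=np.int64)
    labels_seen = np.empty(N, dtype=np.int64)
    stop_indices: dict[str, int | None] = {key: None for key in keys}
    monitor = _QuasiMonitor(N, config.tau_tar) if need_quasi else None

    pending: list[int] = list(rng.permutation(N)[: config.seed_sample_size])
    phase = "seed"
    seed_end: int | None = None
    switch_index: int | None = None
    switch_rho = 0
    bir: BIRResult | None = None
    zero_run = 0
    cum_rel = 0
    t = 0

    while t < N:
        if not pending:
            screened = order[:t]
            mask = np.zeros(N, dtype=bool)
            mask[screened] = True
            unscreened = np.nonzero(~mask)[0]
            if phase == "seed":
                # cold start: classifier needs both classes before ranking
                if cum_rel in (0, t):
                    pending = [int(unscreened[rng.integers(unscreened.size)])]
                else:
                    seed_end = t
                    phase = "al"
            if phase == "al" and not pending:
                ranked = train_and_rank(X, screened, labels_seen[:t], unscreened, rng)
                pending = list(ranked[: config.batch_size])
            elif phase == "random" and not pending:
                pending = list(rng.permutation(unscreened))

        doc = pending.pop(0)
        order[t] = doc
        label = int(y[doc])
        labels_seen[t] = label
        cum_rel += label
        zero_run = 0 if label else zero_run + 1
        t += 1
        if monitor is not None:
            monitor.push(label)
        if bir is None and t == config.seed_sample_size:
            bir = estimate_bir(
                config.seed_sample_size,
                int(labels_seen[:t].sum()),
                N,
                config.tau_tar,
            )

        # --- evaluate criteria after this document ---
        pmin = None
        if monitor is not None and (
            ("quasi_sampling" in keys and stop_indices["quasi_sampling"] is None)
            or phase == "al"
        ):
            pmin = monitor.p_min()
        if (
            "quasi_sampling" in keys
            and stop_indices["quasi_sampling"] is None
            and pmin is not None
            and pmin < config.stop_threshold
        ):
            stop_indices["quasi_sampling"] = t
        if (
            "random_sampling" in keys
            and phase == "random"
            and stop_indices["random_sampling"] is None
        ):
            k_tar = compute_k_tar(cum_rel, switch_rho, config.tau_tar)
            p = stopping_p_value(
                N - switch_index, k_tar, t - switch_index, cum_rel - switch_rho
            )
            if p < config.stop_threshold:
                stop_indices["random_sampling"] = t
        if "bir" in keys and stop_indices["bir"] is None and bir is not None:
            if cum_rel >= config.tau_tar * bir.estimated_total_relevant:
                stop_indices["bir"] = t
        for key, window in keys.items():
            if window is not None and stop_indices[key] is None and zero_run >= window:
                stop_indices[key] = t

        # --- phase transition: end active learning, begin random sampling ---
        if phase == "al" and pmin is not None and pmin < config.switch_threshold:
            phase = "random"
            switch_index = t
            switch_rho = cum_rel
            pending = []  # truncate the current batch

    if seed_end is None:
        seed_end = t
    return ScreeningTrace(
        order=order,
        labels_seen=labels_seen,
        seed_end=seed_end,
        switch_index=switch_index,
        stop_indices=stop_indices,
        N_total=N,
        rho_total=dataset.rho_total,
        seed=seed,
        config=config,
    )


def run_iterations(
    dataset: ScreeningDataset,
    config: StoppingConfig,
    iterations: int,
    base_seed: int = 0,
    criteria: Sequence[str] = DEFAULT_CRITERIA,
    weighting: str = "tf",
) -> list[ScreeningTrace]:
    """Repeat :func:`run_screening` with per-iteration seeds ``base_seed + i``."""
    X = featurize(dataset, weighting=weighting)
    return [
        run_screening(
            dataset, config, criteria=criteria, seed=base_seed + i, features=X
        )
        for i in range(iterations)
    ]


@dataclass(frozen=True)
class ScenarioSpec:
    """One configuration of the pure random-sampling calibration experiment.

    ``rho_al`` relevant documents (of ``rho_total``) and ``n_al`` documents
    overall were screened before sampling starts, fixing the starting
    recall at ``rho_al / rho_total`` and the residual population at
    ``N_total - n_al`` documents containing ``rho_total - rho_al`` relevant.
    """

    N_total: int
    rho_total: int
    rho_al: int
    n_al: int
    tau_tar: float = 0.95
    alpha: float = 0.95
    replications: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_al <= self.rho_total <= self.N_total:
            raise ValueError("need 0 <= rho_al <= rho_total <= N_total")
        if not self.rho_al <= self.n_al <= self.N_total - 1:
            raise ValueError("need rho_al <= n_al < N_total")
        if self.rho_total - self.rho_al > self.N_total - self.n_al:
            raise ValueError("residual relevant exceed residual documents")
        if self.replications < 1:
            raise ValueError("replications must be positive")

    @property
    def starting_recall(self) -> float:
        return self.rho_al / self.rho_total if self.rho_total else 1.0


@dataclass(frozen=True)
class ScenarioResult:
    """Calibration measurements for one scenario."""

    spec: ScenarioSpec
    false_stop_rate: float
    recall_5th_percentile: float
    mean_recall: float
    flagged: bool  # starting recall already at or above the target


def _stop_boundary(N: int, K: int, rho_al: int, tau_tar: float, alpha: float) -> np.ndarray:
    """Smallest sample size at which the test rejects, per relevant count.

    For each possible relevant-draw count ``j`` the p-value is decreasing
    in the sample size ``n``, so the rejection region is ``n >= n_min[j]``;
    each ``n_min`` is found by bisection on the hypergeometric CDF.
    """
    sig = round(1.0 - alpha, 12)  # ties at the printed precision continue
    n_min = np.full(K + 1, N + 1, dtype=np.int64)
    for j in range(K + 1):
        kt = compute_k_tar(rho_al + j, rho_al, tau_tar)
        if kt <= 0 or kt > N:  # degenerate null: p = 0, rejected at once
            n_min[j] = max(j, 1)
            continue
        if hypergeom.cdf(j, N, kt, N) >= sig:
            continue
        lo, hi = max(j, 1), N
        while lo < hi:
            mid = (lo + hi) // 2
            if hypergeom.cdf(j, N, kt, mid) < sig:
                hi = mid
            else:
                lo = mid + 1
        n_min[j] = lo
    return n_min


def run_sampling_accuracy_experiment(
    scenarios: Iterable[ScenarioSpec],
) -> list[ScenarioResult]:
    """Monte-Carlo calibration of the random-sampling stopping test.

    Each replication draws the residual population in uniform random order
    and stops at the first draw where the test rejects (which is guaranteed
    to happen by exhaustion).  Reported per scenario: the fraction of
    replications stopping while true recall was still below the target,
    and the 5th percentile and mean of recall at stopping.  Scenarios whose
    starting recall already meets the target are flagged — the null is then
    impossible a priori and a "false" stop cannot occur.
    """
    results = []
    for spec in scenarios:
        N = spec.N_total - spec.n_al
        K = spec.rho_total - spec.rho_al
        flagged = spec.starting_recall >= spec.tau_tar
        n_min = _stop_boundary(N, K, spec.rho_al, spec.tau_tar, spec.alpha)
        rng = np.random.default_rng(spec.seed)
        reps = spec.replications
        stop_j = np.empty(reps, dtype=np.int64)
        for r in range(reps):
            pos = np.sort(rng.choice(N, size=K, replace=False)) + 1 if K else None
            if K == 0:
                stop_j[r] = 0
                continue
            seg_start = np.concatenate(([0], pos))
            seg_end = np.concatenate((pos - 1, [N]))
            cand = np.maximum(seg_start, n_min)
            ok = cand <= seg_end
            stop_j[r] = int(np.argmax(ok)) if ok.any() else K
        recalls = (spec.rho_al + stop_j) / spec.rho_total
        false_rate = float(np.mean(recalls < spec.tau_tar))
        results.append(
            ScenarioResult(
                spec=spec,
                false_stop_rate=false_rate,
                recall_5th_percentile=float(np.percentile(recalls, 5)),
                mean_recall=float(recalls.mean()),
                flagged=flagged,
            )
        )
    return results


def default_calibration_scenarios(
    replications: int = 100_000, seed: int = 0
) -> list[ScenarioSpec]:
    """Six scenarios varying recall at the start of sampling.

    A 20,000-document corpus with 500 relevant, 4,000 documents screened
    before sampling, and starting recalls from 50% to 90% — the span a
    reasonable active-learning phase leaves when it hands over to random
    sampling below a 95% target.
    """
    starts = (0.50, 0.60, 0.70, 0.80, 0.85, 0.90)
    return [
        ScenarioSpec(
            N_total=20_000,
            rho_total=500,
            rho_al=int(round(s * 500)),
            n_al=4_000,
            replications=replications,
            seed=seed + i,
        )
        for i, s in enumerate(starts)
    ]
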