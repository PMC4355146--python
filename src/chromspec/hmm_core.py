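"""Exact HMM inference and EM refinement.

All recursions use per-position scaling constants (not log space), which is
numerically safe for chromosome-length sequences; the log-likelihood is
accumulated from the scalings.  Conventions follow the rest of the package:
column-stochastic A (A[i,j] = Pr[next=i | current=j]) and O (O[x,j] =
Pr[obs=x | state=j]), so one forward step is ``alpha' = O[x] * (A @ alpha)``.

In exact arithmetic the sequence likelihood equals the observable-operator
product ``1^T B_{x_T} ... B_{x_1} pi`` with ``B_x = A O_x`` — the identity
the spectral estimator is built on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .spectral import HMMParams, fix_probabilities
from .tracks_io import ObservationSequence

logger = logging.getLogger(__name__)


@dataclass
class PosteriorSet:
    """Per-segment state posteriors for a batch of chromosomes."""

    gamma: np.ndarray  # (T_total, K), rows sum to 1
    log_likelihood: float
    boundaries: list[int]  # start offset of each chromosome in gamma

    def per_chromosome(self) -> list[np.ndarray]:
        bounds = self.boundaries + [self.gamma.shape[0]]
        return [self.gamma[lo:hi] for lo, hi in zip(bounds[:-1], bounds[1:])]


@dataclass
class StateAnnotation:
    """Hidden-state labels (1-based) per segment, per chromosome."""

    labels: dict[str, np.ndarray]  # chromosome -> (T_c,) int labels in [1, K]
    segment_width: int = 200

    @property
    def n_states(self) -> int:
        return int(max(lab.max() for lab in self.labels.values() if lab.size))

    def state_intervals(self) -> list[tuple[str, int, int, int]]:
        """Merged (chromosome, start, end, state) runs partitioning the genome."""
        out = []
        w = self.segment_width
        for chrom in self.labels:
            lab = self.labels[chrom]
            if lab.size == 0:
                continue
            changes = np.flatnonzero(np.diff(lab)) + 1
            starts = np.r_[0, changes]
            ends = np.r_[changes, lab.size]
            for s, e in zip(starts, ends):
                out.append((chrom, int(s) * w, int(e) * w, int(lab[s])))
        return out

    def to_bed(self, path, state_prefix: str = "E") -> None:
        with open(path, "w") as fh:
            for chrom, start, end, state in self.state_intervals():
                fh.write(f"{chrom}\t{start}\t{end}\t{state_prefix}{state}\n")

    @staticmethod
    def from_bed(path, segment_width: int = 200, state_prefix: str = "E") -> "StateAnnotation":
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                chrom, start, end, name = line.split("\t")[:4]
                state = int(name.removeprefix(state_prefix))
                per_chrom.setdefault(chrom, []).append((int(start), int(end), state))
        labels = {}
        for chrom, runs in per_chrom.items():
            runs.sort()
            total = runs[-1][1] // segment_width
            lab = np.zeros(total, dtype=np.int64)
            for start, end, state in runs:
                lab[start // segment_width: end // segment_width] = state
            labels[chrom] = lab
        return StateAnnotation(labels, segment_width)


class ZeroProbabilityError(RuntimeError):
    """An observation has zero emission probability under every state."""


def _forward(params: HMMParams, codes: np.ndarray):
    """Scaled forward pass; returns (alpha, scalings)."""
    T = codes.size
    K = params.K
    alpha = np.empty((T, K))
    c = np.empty(T)
    emis = params.O[codes]  # (T, K)
    a = params.pi * emis[0]
    c[0] = a.sum()
    if c[0] == 0:
        raise ZeroProbabilityError(
            "first observation has probability 0 under every state"
        )
    alpha[0] = a / c[0]
    A = params.A
    for t in range(1, T):
        a = emis[t] * (A @ alpha[t - 1])
        c[t] = a.sum()
        if c[t] == 0:
            raise ZeroProbabilityError(
                f"observation at position {t} has probability 0 under every "
                "reachable state"
            )
        alpha[t] = a / c[t]
    return alpha, c


def _backward(params: HMMParams, codes: np.ndarray, c: np.ndarray) -> np.ndarray:
    T = codes.size
    K = params.K
    beta = np.empty((T, K))
    beta[-1] = 1.0
    emis = params.O[codes]
    At = params.A.T
    for t in range(T - 2, -1, -1):
        beta[t] = At @ (emis[t + 1] * beta[t + 1]) / c[t + 1]
    return beta


def log_likelihood(params: HMMParams, seq: ObservationSequence) -> float:
    """Log P(x_{1:T} | theta) via the scaled forward recursion.

    Returns ``-inf`` (with a log entry) if some observation is impossible
    under every state — the observable-operator product is exactly zero then.
    """
    try:
        _, c = _forward(params, seq.codes)
    except ZeroProbabilityError as exc:
        logger.warning("log-likelihood is -inf: %s", exc)
        return float("-inf")
    return float(np.log(c).sum())


def operator_log_likelihood(params: HMMParams, seq: ObservationSequence) -> float:
    """Likelihood as the raw observable-operator product 1^T B_xT ... B_x1 pi.

    Unscaled, so only usable for short sequences; serves as an independent
    check of the forward recursion.
    """
    v = params.pi.copy()
    for x in seq.codes:
        v = params.A @ (params.O[x] * v)
    total = float(v.sum())
    return float(np.log(total)) if total > 0 else float("-inf")


def forward_backward(
    params: HMMParams, seqs: ObservationSequence | Sequence[ObservationSequence]
) -> PosteriorSet:
    """Posterior state probabilities gamma for one or more chromosomes."""
    if isinstance(seqs, ObservationSequence):
        seqs = [seqs]
    gammas = []
    boundaries = []
    ll = 0.0
    offset = 0
    for seq in seqs:
        alpha, c = _forward(params, seq.codes)
        beta = _backward(params, seq.codes, c)
        g = alpha * beta
        g /= g.sum(axis=1, keepdims=True)
        gammas.append(g)
        boundaries.append(offset)
        offset += len(seq)
        ll += float(np.log(c).sum())
    return PosteriorSet(np.vstack(gammas), ll, boundaries)


def _viterbi(params: HMMParams, codes: np.ndarray) -> np.ndarray:
    T, K = codes.size, params.K
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logO = np.log(params.O[codes])
        logpi = np.log(params.pi)
    delta = logpi + logO[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        # score[i, j] = delta[j] + logA[i, j]; ties -> lower previous index
        score = delta[None, :] + logA
        back[t] = np.argmax(score, axis=1)
        delta = score[np.arange(K), back[t]] + logO[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode(
    params: HMMParams,
    seqs: ObservationSequence | Sequence[ObservationSequence],
    method: Literal["posterior", "viterbi"] = "posterior",
    segment_width: int = 200,
) -> StateAnnotation:
    """Segment the genome into hidden-state labels (1-based).

    ``posterior`` (default) takes the per-segment argmax of the
    forward-backward posteriors; ``viterbi`` the single best path.  Ties
    break toward the lower state index.
    """
    if isinstance(seqs, ObservationSequence):
        seqs = [seqs]
    labels: dict[str, np.ndarray] = {}
    if method == "posterior":
        post = forward_backward(params, seqs)
        for seq, g in zip(seqs, post.per_chromosome()):
            labels[seq.chromosome] = np.argmax(g, axis=1) + 1
    elif method == "viterbi":
        for seq in seqs:
            labels[seq.chromosome] = _viterbi(params, seq.codes) + 1
    else:
        raise ValueError(f"unknown decoding method {method!r}")
    return StateAnnotation(labels, segment_width)


def baum_welch_refine(
    params_init: HMMParams,
    seqs: Sequence[ObservationSequence],
    max_iter: int = 200,
    tol: float = 1e-3,
    emission_floor: float = 0.0,
) -> tuple[HMMParams, list[float]]:
    """EM (Baum-Welch) refinement from any initializer.

    Chromosomes are independent sequences sharing parameters, each starting
    from pi.  Stops when the total log-likelihood improves by less than
    ``tol`` or after ``max_iter`` iterations (the convergence rule of the
    EM-based annotators this estimator is benchmarked against).  Returns the
    refined parameters and the per-iteration log-likelihood trace.

    Raises ``RuntimeError`` if the log-likelihood decreases by more than 1e-8
    — EM guarantees monotonicity, so a decrease indicates an update bug.
    """
    if isinstance(seqs, ObservationSequence):
        seqs = [seqs]
    params = HMMParams(params_init.A.copy(), params_init.O.copy(), params_init.pi.copy())
    if emission_floor > 0:
        O = np.maximum(params.O, emission_floor)
        params = HMMParams(params.A, O / O.sum(axis=0), params.pi)
    K, N = params.K, params.N
    trace: list[float] = []
    prev_ll = -np.inf
    for it in range(max_iter):
        A_num = np.zeros((K, K))
        O_num = np.zeros((N, K))
        pi_num = np.zeros(K)
        ll = 0.0
        for seq in seqs:
            codes = seq.codes
            alpha, c = _forward(params, codes)
            beta = _backward(params, codes, c)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            ll += float(np.log(c).sum())
            pi_num += gamma[0]
            np.add.at(O_num, codes, gamma)
            if codes.size >= 2:
                # xi[i, j] summed over t = A[i,j] * sum_t w_{t+1}[i] alpha_t[j]
                w = params.O[codes[1:]] * beta[1:] / c[1:, None]
                A_num += params.A * (w.T @ alpha[:-1])
        trace.append(ll)
        if ll < prev_ll - 1e-8:
            raise RuntimeError(
                f"log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        if it > 0 and ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll

        A = A_num / np.where(A_num.sum(axis=0) == 0, 1.0, A_num.sum(axis=0))
        zero_cols = A_num.sum(axis=0) == 0
        if zero_cols.any():
            A[:, zero_cols] = 1.0 / K
        O = O_num / np.where(O_num.sum(axis=0) == 0, 1.0, O_num.sum(axis=0))
        zero_cols = O_num.sum(axis=0) == 0
        if zero_cols.any():
            O[:, zero_cols] = 1.0 / N
        pi = pi_num / pi_num.sum()
        params = HMMParams(A, O, pi)
    logger.info("EM stopped after %d iteration(s), log-likelihood %.6f", len(trace), trace[-1])
    return params, trace
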