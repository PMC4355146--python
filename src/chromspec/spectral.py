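"""Spectral (method-of-moments) recovery of HMM parameters.

The estimator works on the moment statistics alone, with no likelihood
optimization and no initialization:

1.  ``U`` = top-K left singular vectors of the two-step co-occurrence P31.
2.  Observable matrices ``C_x = (U^T P3_{.,x,.}) (U^T P31)^+``; in the
    population limit ``C_x = (U^T O A) O_x (U^T O A)^{-1}``, so every C_x
    shares the eigenvector matrix ``R = U^T O A`` and its eigenvalues are a
    row of the emission matrix.
3.  Each state contributes one eigenvector, extracted from the observable
    matrix of that state's *major observation* (the code maximizing
    ``U[x, i]**2``), or from a U-weighted sum of all C_x.
4.  Emissions from ``diag(R^{-1} C_x R)``; the initial distribution from
    ``pi = O^+ P1_init``; transitions from ``A = (O^+ P31)(O^+ P21)^+``,
    which avoids dividing by near-zero entries of pi.
5.  Negative entries produced by noise are repaired by absolute value plus
    column renormalization.

Everything is deterministic given the input moments and options.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .moments import MomentSet, compute_moments, smooth_moments, _to_dense
from .tracks_io import ObservationSequence

logger = logging.getLogger(__name__)

#: Dense SVD is used up to this alphabet size, iterative sparse SVD above.
DENSE_SVD_LIMIT = 1024


class SpectralError(RuntimeError):
    """Numerical failure in the moment-based recovery, with stage context."""


@dataclass
class HMMParams:
    """HMM parameters in the column-stochastic convention.

    ``A[i, j]`` is the probability of moving from state j to state i;
    ``O[x, j]`` the probability of emitting combination code x in state j;
    ``pi[i]`` the probability that a chromosome starts in state i.
    """

    A: np.ndarray  # (K, K)
    O: np.ndarray  # (N, K)
    pi: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.O = np.asarray(self.O, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)

    @property
    def K(self) -> int:
        return self.A.shape[0]

    @property
    def N(self) -> int:
        return self.O.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        assert self.A.shape == (self.K, self.K)
        assert self.O.shape == (self.N, self.K)
        assert self.pi.shape == (self.K,)
        for name, arr in (("A", self.A), ("O", self.O), ("pi", self.pi)):
            assert (arr >= 0).all(), f"{name} has negative entries"
        assert np.allclose(self.A.sum(axis=0), 1.0, atol=atol), "A columns != 1"
        assert np.allclose(self.O.sum(axis=0), 1.0, atol=atol), "O columns != 1"
        assert abs(self.pi.sum() - 1.0) < atol, "pi does not sum to 1"

    def permuted(self, perm: np.ndarray) -> "HMMParams":
        """Relabel states: new state i is old state perm[i]."""
        perm = np.asarray(perm)
        return HMMParams(self.A[np.ix_(perm, perm)], self.O[:, perm], self.pi[perm])


@dataclass
class SpectralBasis:
    """Top-K left singular subspace of the two-step co-occurrence matrix."""

    K: int
    U: np.ndarray  # (N, K)
    singular_values: np.ndarray  # (K,), nonincreasing


@dataclass
class ObservableSet:
    """Observable matrices C_x plus the shared eigenvector estimate R."""

    C: dict[int, np.ndarray]
    R: np.ndarray  # (K, K)
    major_obs: list[int]


def compute_basis(ms: MomentSet, K: int) -> SpectralBasis:
    """Top-K left singular vectors of P31 (surrogate for the emission range)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ms.N:
        raise ValueError(f"K={K} exceeds alphabet size N={ms.N}")
    n_observed = int((np.asarray(ms.P1) > 0).sum())
    if K > n_observed:
        raise ValueError(f"K={K} exceeds number of observed codes ({n_observed})")
    P31 = ms.P31
    if not sp.issparse(P31) and ms.N <= DENSE_SVD_LIMIT:
        U, s, _ = np.linalg.svd(np.asarray(P31), full_matrices=False)
        U, s = U[:, :K], s[:K]
    else:
        if not sp.issparse(P31):
            P31 = sp.csr_matrix(P31)
        k = min(K, min(P31.shape) - 1)
        if k < K:
            raise ValueError("iterative SVD requires K < N")
        U, s, _ = spla.svds(P31, k=K, random_state=0)
        order = np.argsort(s)[::-1]
        U, s = U[:, order], s[order]
    # Deterministic sign convention: largest-|.| entry of each vector positive.
    for j in range(K):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            U[:, j] = -U[:, j]
    if s[0] > 0 and s[K - 1] / s[0] < 1e-10:
        logger.warning(
            "P31 near rank deficiency: sigma_K/sigma_1 = %.3e", s[K - 1] / s[0]
        )
    return SpectralBasis(K=K, U=U, singular_values=s)


def observable_matrices(
    ms: MomentSet, basis: SpectralBasis, pinv_rtol: float | None = None
) -> dict[int, np.ndarray]:
    """C_x = (U^T P3_slices[x]) (U^T P31)^+ for every observed middle code.

    Codes with no observed triple slice are implicitly the zero matrix.
    """
    U = basis.U
    G = U.T @ _to_dense(ms.P31) if not sp.issparse(ms.P31) else U.T @ ms.P31
    G = np.asarray(G)
    rtol = pinv_rtol if pinv_rtol is not None else max(G.shape) * np.finfo(float).eps
    s = np.linalg.svd(G, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < rtol:
        raise SpectralError(
            "U^T P31 is numerically rank deficient; consider moment smoothing "
            "or a smaller K"
        )
    Gp = np.linalg.pinv(G, rcond=rtol)
    C: dict[int, np.ndarray] = {}
    for x, slc in ms.P3_slices.items():
        proj = U.T @ slc if sp.issparse(slc) else U.T @ _to_dense(slc)
        C[int(x)] = np.asarray(proj) @ Gp
    return C


def _leading_eigvec(M: np.ndarray, imag_tol: float = 1e-8) -> np.ndarray:
    """Eigenvector of the leading eigenvalue with a deterministic gauge."""
    w, v = np.linalg.eig(M)
    radius = max(np.abs(w).max(), np.finfo(float).tiny)
    if np.abs(w.imag).max() <= imag_tol * radius:
        idx = int(np.argmax(w.real))
    else:
        warnings.warn(
            "observable matrix has a markedly complex spectrum; "
            "selecting by eigenvalue modulus",
            RuntimeWarning,
            stacklevel=2,
        )
        idx = int(np.argmax(np.abs(w)))
    vec = np.real(v[:, idx])
    vec /= np.linalg.norm(vec)
    lead = np.argmax(np.abs(vec))
    if vec[lead] < 0:
        vec = -vec
    return vec


def major_observations(
    basis: SpectralBasis,
    C: Mapping[int, np.ndarray],
    strategy: Literal["max", "weighted"] = "max",
) -> ObservableSet:
    """Build the shared eigenvector matrix R, one column per hidden state.

    ``max``: state i uses the single observable matrix of its major
    observation ``x' = argmax_x U[x, i]**2`` (collisions resolved greedily by
    the next-best unused code, in state order).  ``weighted``: state i instead
    eigendecomposes ``sum_x U[x, i]**2 C_x`` — nearly identical whenever the
    major observation carries most of the singular-vector mass.
    """
    K, U = basis.K, basis.U
    cols = []
    chosen: list[int] = []
    for i in range(K):
        if strategy == "max":
            order = np.argsort(U[:, i] ** 2)[::-1]
            xprime = next(int(x) for x in order if int(x) not in chosen)
            chosen.append(xprime)
            M = C.get(xprime)
            if M is None:
                raise SpectralError(
                    f"major observation {xprime} for state {i} has no "
                    "observed triple slice"
                )
        elif strategy == "weighted":
            M = None
            for x, Cx in C.items():
                w = U[x, i] ** 2
                M = w * Cx if M is None else M + w * Cx
            chosen.append(int(np.argmax(U[:, i] ** 2)))
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        cols.append(_leading_eigvec(M))
    R = np.column_stack(cols)
    cond = np.linalg.cond(R)
    logger.info("eigenvector matrix condition number: %.3e", cond)
    if not np.isfinite(cond):
        raise SpectralError(
            "eigenvector matrix R is singular; try strategy='weighted' or "
            "moment smoothing"
        )
    return ObservableSet(C=dict(C), R=R, major_obs=chosen)


def recover_emissions(
    obs: ObservableSet, N: int, return_diagnostics: bool = False
):
    """Emission matrix from the simultaneous diagonalization diag(R^-1 C_x R).

    Rows for codes never observed as a triple middle stay zero; negative
    artifacts are left for :func:`fix_probabilities`.  The off-diagonal
    Frobenius mass of each D_x (0 for exact moments) is the returned
    diagnostic.
    """
    K = obs.R.shape[0]
    try:
        Rinv = np.linalg.inv(obs.R)
    except np.linalg.LinAlgError as exc:
        raise SpectralError(
            "R is singular; try the weighted strategy or smoothing"
        ) from exc
    O = np.zeros((N, K))
    off_mass = 0.0
    for x, Cx in obs.C.items():
        D = Rinv @ Cx @ obs.R
        O[x] = np.diag(D)
        off = D - np.diag(np.diag(D))
        off_mass += float(np.linalg.norm(off, "fro") ** 2)
    off_mass = float(np.sqrt(off_mass))
    if return_diagnostics:
        return O, {"off_diagonal_mass": off_mass}
    return O


def recover_pi(O: np.ndarray, ms: MomentSet) -> np.ndarray:
    """Initial state distribution pi = O^+ P1_init (raw, pre-repair)."""
    return np.linalg.pinv(O) @ ms.P1_init


def recover_pi_legacy(O: np.ndarray, ms: MomentSet) -> np.ndarray:
    """Original recovery pi = O^+ P1 from the all-positions marginal.

    Noisier than the first-segment variant when chromosomes are long and the
    chain mixes; kept for comparison.
    """
    return np.linalg.pinv(O) @ ms.P1


def recover_transitions(O: np.ndarray, ms: MomentSet) -> np.ndarray:
    """Transition matrix A = (O^+ P31)(O^+ P21)^+ (raw, pre-repair).

    This form never divides by pi, so it stays stable when most initial-state
    mass sits on one background state.
    """
    Op = np.linalg.pinv(O)
    lhs = np.asarray(Op @ ms.P31)
    rhs = np.asarray(Op @ ms.P21)
    s = np.linalg.svd(rhs, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < max(rhs.shape) * np.finfo(float).eps:
        raise SpectralError("O^+ P21 is rank deficient; transitions unrecoverable")
    return lhs @ np.linalg.pinv(rhs)


def recover_transitions_legacy(
    O: np.ndarray, ms: MomentSet, pi: np.ndarray
) -> np.ndarray:
    """Original recovery A = O^+ P21 (O^+)^T diag(pi)^-1.

    Requires every entry of pi bounded away from zero; agrees with the
    pi-free form on exact moments.
    """
    Op = np.linalg.pinv(O)
    if (pi <= 0).any():
        raise SpectralError("legacy transition recovery needs strictly positive pi")
    return np.asarray(Op @ ms.P21) @ Op.T @ np.diag(1.0 / pi)


def fix_probabilities(params: HMMParams) -> HMMParams:
    """Repair sign-flip artifacts: absolute value, then column renormalization.

    An all-zero column (no mass survives) is replaced by the uniform
    distribution with a warning.
    """

    def _fix_cols(M: np.ndarray) -> np.ndarray:
        M = np.abs(np.asarray(M, dtype=float))
        sums = M.sum(axis=0)
        zero = sums == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} all-zero column(s) replaced by uniform",
                RuntimeWarning,
                stacklevel=3,
            )
            M[:, zero] = 1.0 / M.shape[0]
            sums = M.sum(axis=0)
        return M / sums

    pi = np.abs(np.asarray(params.pi, dtype=float))
    if pi.sum() == 0:
        warnings.warn("all-zero pi replaced by uniform", RuntimeWarning, stacklevel=2)
        pi = np.ones_like(pi)
    return HMMParams(_fix_cols(params.A), _fix_cols(params.O), pi / pi.sum())


def spectral_learn(
    seqs: Sequence[ObservationSequence] | None,
    K: int,
    smooth_weight: float = 0.0,
    strategy: Literal["max", "weighted"] = "max",
    legacy_recovery: bool = False,
    moments: MomentSet | None = None,
    pinv_rtol: float | None = None,
) -> HMMParams:
    """Full moment-based estimation pipeline.

    Runs compute_moments -> [smooth] -> compute_basis -> observable_matrices
    -> major_observations -> recover_emissions -> recover_pi ->
    recover_transitions -> fix_probabilities.  Passing ``moments`` skips the
    counting stage (exact-moment injection).  Deterministic given inputs.
    """
    stage = "compute_moments"
    try:
        ms = moments if moments is not None else compute_moments(seqs)
        if smooth_weight:
            stage = "smooth_moments"
            ms = smooth_moments(ms, smooth_weight)
        stage = "compute_basis"
        basis = compute_basis(ms, K)
        stage = "observable_matrices"
        C = observable_matrices(ms, basis, pinv_rtol=pinv_rtol)
        stage = "major_observations"
        obs = major_observations(basis, C, strategy=strategy)
        stage = "recover_emissions"
        O_raw = recover_emissions(obs, ms.N)
        O_fixed = fix_probabilities(HMMParams(np.eye(K), O_raw, np.full(K, 1.0 / K))).O
        stage = "recover_pi"
        pi_raw = (
            recover_pi_legacy(O_fixed, ms)
            if legacy_recovery
            else recover_pi(O_fixed, ms)
        )
        pi_tmp = np.abs(pi_raw)
        pi_tmp = pi_tmp / pi_tmp.sum() if pi_tmp.sum() else np.full(K, 1.0 / K)
        stage = "recover_transitions"
        A_raw = (
            recover_transitions_legacy(O_fixed, ms, pi_tmp)
            if legacy_recovery
            else recover_transitions(O_fixed, ms)
        )
        stage = "fix_probabilities"
        params = fix_probabilities(HMMParams(A_raw, O_raw, pi_raw))
    except SpectralError as exc:
        raise SpectralError(f"[{stage}] {exc}") from exc
    params.validate()
    return params
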