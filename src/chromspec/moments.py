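"""Empirical singleton/pair/triple probabilities — the method-of-moments inputs.

For observation codes x_t over an alphabet of size N the moment statistics are

    P1[i]        = Pr[x_t = i]
    P21[i, j]    = Pr[x_{t+1} = i, x_t = j]
    P3_slices[x] = Pr[x_{t+2} = i, x_{t+1} = x, x_t = j]   (N x N slice per x)
    P31[i, j]    = Pr[x_{t+2} = i, x_t = j] = sum_x P3_slices[x]

estimated by pooled counts over all chromosomes (each chromosome weighted by
its number of pairs/triples).  Pairs and triples never span chromosome
boundaries or mask-induced breaks.  ``P1_init`` is the empirical distribution
of the first segment of each chromosome, the quantity the modified initial
state recovery consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .tracks_io import ObservationSequence

#: Above this alphabet size the N x N pair matrices are stored sparsely.
DENSE_ALPHABET_LIMIT = 2048

_ATOL = 1e-12


class InsufficientDataError(ValueError):
    """No sequence long enough to contribute the required moment order."""


def _to_dense(mat) -> np.ndarray:
    return mat.toarray() if sp.issparse(mat) else np.asarray(mat)


@dataclass
class MomentSet:
    """Singleton, initial, pair and triple-slice probability estimates.

    ``P3_slices`` is keyed by observed middle codes only; absent slices are
    implicitly zero.  Matrices are dense ndarrays for small alphabets and
    scipy CSR above :data:`DENSE_ALPHABET_LIMIT`.
    """

    N: int
    P1: np.ndarray
    P1_init: np.ndarray
    P21: np.ndarray | sp.spmatrix
    P3_slices: dict[int, np.ndarray | sp.spmatrix]
    P31: np.ndarray | sp.spmatrix
    n_singletons: int = 0
    n_pairs: int = 0
    n_triples: int = 0

    def validate(self, atol: float = 1e-9) -> None:
        """Raise AssertionError if any probability-mass invariant is violated."""
        for name, vec in (("P1", self.P1), ("P1_init", self.P1_init)):
            assert vec.shape == (self.N,), f"{name} has wrong shape"
            assert (vec >= -_ATOL).all(), f"{name} has negative entries"
            assert abs(vec.sum() - 1.0) < atol, f"{name} does not sum to 1"
        for name, mat in (("P21", self.P21), ("P31", self.P31)):
            dense_sum = mat.sum()
            assert abs(dense_sum - 1.0) < atol, f"{name} total mass != 1"
            mn = mat.min() if not sp.issparse(mat) else mat.data.min(initial=0.0)
            assert mn >= -_ATOL, f"{name} has negative entries"
        recon = None
        for mat in self.P3_slices.values():
            recon = mat if recon is None else recon + mat
        if recon is not None:
            diff = abs(_to_dense(self.P31) - _to_dense(recon)).max()
            assert diff < max(atol, _ATOL), "P31 != sum of triple slices"


def compute_moments(seqs: Sequence[ObservationSequence]) -> MomentSet:
    """Count singletons, first segments, pairs and triple slices.

    Requires at least one sequence of length >= 3 (otherwise the triple
    moments, and hence the whole spectral pipeline, are undefined).
    """
    if not seqs:
        raise InsufficientDataError("no observation sequences given")
    N = seqs[0].alphabet_size
    for s in seqs:
        if s.alphabet_size != N:
            raise ValueError("sequences have mismatched alphabet sizes")
    if max(len(s) for s in seqs) < 3:
        raise InsufficientDataError("all sequences shorter than 3 segments")

    dense = N <= DENSE_ALPHABET_LIMIT
    p1 = np.zeros(N)
    p1_init = np.zeros(N)
    pair_rows: list[np.ndarray] = []
    pair_cols: list[np.ndarray] = []
    tri_rows: list[np.ndarray] = []
    tri_mid: list[np.ndarray] = []
    tri_cols: list[np.ndarray] = []
    n_single = n_pair = n_triple = 0

    for s in seqs:
        c = s.codes
        if c.size == 0:
            continue
        np.add.at(p1, c, 1.0)
        p1_init[c[0]] += 1.0
        n_single += c.size
        if c.size >= 2:
            pair_rows.append(c[1:])
            pair_cols.append(c[:-1])
            n_pair += c.size - 1
        if c.size >= 3:
            tri_rows.append(c[2:])
            tri_mid.append(c[1:-1])
            tri_cols.append(c[:-2])
            n_triple += c.size - 2

    p1 /= n_single
    p1_init /= p1_init.sum()

    def _count_matrix(rows, cols, total):
        coo = sp.coo_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(N, N)
        ).tocsr()
        coo = coo / total
        return coo.toarray() if dense else coo

    rows = np.concatenate(pair_rows)
    cols = np.concatenate(pair_cols)
    P21 = _count_matrix(rows, cols, n_pair)

    t_rows = np.concatenate(tri_rows)
    t_mid = np.concatenate(tri_mid)
    t_cols = np.concatenate(tri_cols)
    slices: dict[int, np.ndarray | sp.spmatrix] = {}
    order = np.argsort(t_mid, kind="stable")
    t_rows, t_mid, t_cols = t_rows[order], t_mid[order], t_cols[order]
    uniq, starts = np.unique(t_mid, return_index=True)
    bounds = np.r_[starts, t_mid.size]
    for x, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
        slices[int(x)] = _count_matrix(t_rows[lo:hi], t_cols[lo:hi], n_triple)
    P31 = sum(slices.values())
    if dense:
        P31 = np.asarray(P31)

    return MomentSet(
        N=N,
        P1=p1,
        P1_init=p1_init,
        P21=P21,
        P3_slices=slices,
        P31=P31,
        n_singletons=n_single,
        n_pairs=n_pair,
        n_triples=n_triple,
    )


def smooth_moments(ms: MomentSet, weight: float) -> MomentSet:
    """Shrink pair/triple matrices toward the product of singleton marginals.

    Similar in spirit to pseudocounts, except the pseudo-mass follows the
    marginal frequencies of the observations rather than a uniform prior:

        P21      <- (1 - w) P21      + w * P1 P1^T
        slice_x  <- (1 - w) slice_x  + w * P1[x] * P1 P1^T

    which preserves all mass invariants and the identity
    ``P31 = sum_x slice_x`` exactly (for x observed; unseen codes keep their
    implicit zero slice so total triple mass shrinks onto observed middles).
    ``weight=0`` is the identity.
    """
    if not (0.0 <= weight < 1.0):
        raise ValueError(f"smoothing weight must be in [0, 1), got {weight}")
    if weight == 0.0:
        return ms
    outer = np.outer(ms.P1, ms.P1)
    # Renormalize the middle-marginal over the observed slices so the
    # smoothed triples keep total mass exactly 1.
    mid_mass = sum(ms.P1[x] for x in ms.P3_slices)
    slices = {
        x: (1.0 - weight) * _to_dense(m) + weight * (ms.P1[x] / mid_mass) * outer
        for x, m in ms.P3_slices.items()
    }
    P31 = sum(slices.values())
    P21 = (1.0 - weight) * _to_dense(ms.P21) + weight * outer
    return MomentSet(
        N=ms.N,
        P1=ms.P1.copy(),
        P1_init=ms.P1_init.copy(),
        P21=P21,
        P3_slices=slices,
        P31=np.asarray(P31),
        n_singletons=ms.n_singletons,
        n_pairs=ms.n_pairs,
        n_triples=ms.n_triples,
    )


def population_moments(params, pi_init: np.ndarray | None = None) -> MomentSet:
    """Exact (infinite-data) moments implied by HMM parameters.

    With column-stochastic transition ``A`` (A[i,j] = Pr[next=i | cur=j]) and
    emission ``O`` (O[x,j] = Pr[obs=x | state=j]), and ``pi_s`` the stationary
    distribution of A, the time-invariant moments are

        P1   = O pi_s
        P21  = O A diag(pi_s) O^T
        P3x1 = O A O_x A diag(pi_s) O^T
        P31  = O A A diag(pi_s) O^T

    ``P1_init = O pi`` uses the chain's actual initial distribution (``params.pi``
    unless ``pi_init`` overrides it) — the first segment of a chromosome is the
    one position whose state is drawn from pi rather than the stationary law.

    ``params`` needs only ``A``, ``O`` and ``pi`` array attributes.
    """
    A = np.asarray(params.A, dtype=float)
    O = np.asarray(params.O, dtype=float)
    pi = np.asarray(params.pi if pi_init is None else pi_init, dtype=float)
    pi_s = stationary_distribution(A)
    N = O.shape[0]
    D = np.diag(pi_s)
    P1 = O @ pi_s
    P21 = O @ A @ D @ O.T
    slices = {}
    base = A @ D @ O.T  # K x N
    for x in range(N):
        Ox = np.diag(O[x])
        slices[x] = O @ A @ Ox @ base
    P31 = O @ A @ A @ D @ O.T
    return MomentSet(
        N=N,
        P1=P1,
        P1_init=O @ pi,
        P21=P21,
        P3_slices=slices,
        P31=P31,
    )


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary vector of a column-stochastic transition matrix."""
    w, v = np.linalg.eig(A)
    idx = np.argmin(abs(w - 1.0))
    vec = np.real(v[:, idx])
    vec = np.abs(vec)
    return vec / vec.sum()
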