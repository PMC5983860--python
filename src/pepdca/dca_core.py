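"""Mean-field direct coupling analysis.

Pipeline: sequence reweighting -> pseudocount-regularized frequency
estimation -> inversion of the connected-correlation matrix in the reduced
(q-1)-state gauge -> per-pair direct information from a marginal-matched
two-site model -> separation-filtered pair ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from pepdca.alignment_io import MSA


@dataclass
class SequenceWeights:
    """Redundancy-based sequence weights.

    ``m[a]`` counts the sequences (self included) whose identity with row
    ``a`` reaches the threshold; ``w = 1/m``; ``meff = sum(w)``.
    """

    m: np.ndarray
    identity_threshold: float

    @property
    def w(self) -> np.ndarray:
        return 1.0 / self.m

    @property
    def meff(self) -> float:
        return float(self.w.sum())


@dataclass
class FrequencyModel:
    """Reweighted, pseudocount-regularized single and pairwise frequencies.

    ``fi`` has shape ``(L, q)``; ``fij`` has shape ``(L, L, q, q)`` with the
    diagonal blocks closed as ``f_ii(A, B) = delta_AB * f_i(A)``.
    """

    fi: np.ndarray
    fij: np.ndarray
    q: int
    pseudocount: float
    meff: float

    @property
    def n_columns(self) -> int:
        return self.fi.shape[0]


@dataclass
class CouplingModel:
    """Pair couplings ``e[i, j]`` on the reduced (q-1)-state alphabet.

    The gauged-out state is ``gauge_state`` (the gap, by default); coupling
    blocks are zero-padded on that state when exponentiated downstream.
    ``e[i, i]`` is identically zero.
    """

    e: np.ndarray  # (L, L, q-1, q-1)
    q: int
    gauge_state: int

    @property
    def n_columns(self) -> int:
        return self.e.shape[0]

    def pair_matrix(self, i: int, j: int) -> np.ndarray:
        """Full q x q coupling block for pair (i, j), zero on the gauge state."""
        full = np.zeros((self.q, self.q))
        red = [s for s in range(self.q) if s != self.gauge_state]
        full[np.ix_(red, red)] = self.e[i, j]
        return full


@dataclass
class PairScoreMatrix:
    """Symmetric direct-information scores with an optional block partition."""

    di: np.ndarray  # (L, L), zero diagonal
    protein_len: int | None = None
    non_converged: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.di.shape[0]


@dataclass
class RankedPairs:
    """Pairs ``(i, j, score)`` with ``i < j``, sorted by descending score."""

    pairs: list[tuple[int, int, float]]
    min_separation: int

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, k):
        return self.pairs[k]


class SingularCorrelationError(np.linalg.LinAlgError):
    """Correlation matrix not invertible; carries a condition-number hint."""


def compute_weights(msa: MSA, identity_threshold: float = 0.8) -> SequenceWeights:
    """Count, per sequence, its neighbors at or above the identity threshold.

    Identity is the fraction of columns carrying identical symbols, gaps
    compared like any other symbol.  The comparison uses ``>=`` so that the
    self-count guarantees ``m >= 1`` and exact duplicates always collapse.
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must be in (0, 1)")
    X = msa.matrix
    M, L = X.shape
    # identity counts via per-state one-hot matmuls: avoids the M^2*L boolean
    # tensor while staying exact for integer alignments.
    counts = np.zeros((M, M), dtype=np.int64)
    for state in range(msa.q):
        S = (X == state)
        if S.any():
            Sf = S.astype(np.float64)
            counts += np.rint(Sf @ Sf.T).astype(np.int64)
    identity = counts / L
    m = (identity >= identity_threshold).sum(axis=1)
    return SequenceWeights(m=m.astype(np.int64), identity_threshold=identity_threshold)


def frequencies_from_rows(
    matrix: np.ndarray,
    row_weights: np.ndarray,
    q: int,
    pseudocount: float,
    meff: float | None = None,
) -> FrequencyModel:
    """Weighted frequency model from integer rows with arbitrary row weights.

    This is the shared kernel for plain alignments (one row per sequence,
    weight ``1/m_a``) and joint protein+ligand alignments (one row per
    (sequence, ligand), weight ``w_a / N_a``).

    ``f_i(A)   = [lam/q   + sum_r w_r d(A, x_ri)]            / (meff + lam)``
    ``f_ij(A,B)= [lam/q^2 + sum_r w_r d(A, x_ri) d(B, x_rj)] / (meff + lam)``

    with diagonal blocks ``f_ii(A,B) = d_AB f_i(A)``.
    """
    matrix = np.asarray(matrix, dtype=np.int64)
    w = np.asarray(row_weights, dtype=np.float64)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    R, L = matrix.shape
    if meff is None:
        meff = float(w.sum())
    lam = float(pseudocount)
    norm = meff + lam

    onehot = np.zeros((R, L * q), dtype=np.float64)
    flat_cols = np.arange(L) * q
    onehot[np.arange(R)[:, None], flat_cols[None, :] + matrix] = 1.0

    fi = (onehot * w[:, None]).sum(axis=0).reshape(L, q)
    fi = (lam / q + fi) / norm

    fij = (onehot * w[:, None]).T @ onehot  # (L*q, L*q) weighted pair counts
    fij = fij.reshape(L, q, L, q).transpose(0, 2, 1, 3)
    fij = (lam / q**2 + fij) / norm
    # diagonal closure
    for i in range(L):
        fij[i, i] = np.diag(fi[i])
    return FrequencyModel(fi=fi, fij=fij, q=q, pseudocount=lam, meff=meff)


def compute_frequencies(
    msa: MSA,
    weights: SequenceWeights | None = None,
    pseudocount: float | str = "meff",
    identity_threshold: float = 0.8,
) -> FrequencyModel:
    """Frequency model for a plain alignment.

    ``pseudocount='meff'`` (the default) sets the pseudocount mass equal to
    the effective number of sequences after reweighting.
    """
    if weights is None:
        weights = compute_weights(msa, identity_threshold)
    meff = weights.meff
    lam = meff if pseudocount == "meff" else float(pseudocount)
    return frequencies_from_rows(msa.matrix, weights.w, msa.q, lam, meff=meff)


def mean_field_couplings(freqs: FrequencyModel, gauge_state: int | None = None) -> CouplingModel:
    """Invert the connected-correlation matrix in the reduced gauge.

    One alphabet state per column (the gap, i.e. the last state, unless
    overridden) is gauged out, giving the ``(L*(q-1))^2`` matrix whose
    negative inverse blocks are the couplings.
    """
    L, q = freqs.fi.shape
    if gauge_state is None:
        gauge_state = q - 1
    red = np.array([s for s in range(q) if s != gauge_state])
    qr = q - 1
    fi_r = freqs.fi[:, red]  # (L, qr)
    fij_r = freqs.fij[:, :, red[:, None], red[None, :]]
    C = fij_r - fi_r[:, None, :, None] * fi_r[None, :, None, :]
    C = C.transpose(0, 2, 1, 3).reshape(L * qr, L * qr)
    try:
        Cinv = scipy.linalg.inv(C)
    except scipy.linalg.LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise SingularCorrelationError(
            f"correlation matrix is singular (cond={cond:.3e}); "
            "a positive pseudocount prevents this"
        ) from exc
    e = -Cinv.reshape(L, qr, L, qr).transpose(0, 2, 1, 3)
    # enforce exact block symmetry e_ij(A,B) = e_ji(B,A)
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))
    idx = np.arange(L)
    e[idx, idx] = 0.0
    return CouplingModel(e=e, q=q, gauge_state=gauge_state)


def _two_site_model(
    W: np.ndarray,
    fi: np.ndarray,
    fj: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool]:
    """Fixed-point fields for the two-site model P ~ W * h_i h_j.

    Multiplicative updates on the auxiliary fields until both marginals of P
    match (fi, fj) within ``tol``.  Returns (P, converged).
    """
    q = W.shape[0]
    mu1 = np.full(q, 1.0 / q)
    mu2 = np.full(q, 1.0 / q)
    converged = False
    for _ in range(max_iter):
        new1 = fi / (W @ mu2)
        new1 /= new1.sum()
        new2 = fj / (W.T @ new1)
        new2 /= new2.sum()
        mu1, mu2 = new1, new2
        P = mu1[:, None] * W * mu2[None, :]
        P /= P.sum()
        if max(
            np.abs(P.sum(axis=1) - fi).max(),
            np.abs(P.sum(axis=0) - fj).max(),
        ) < tol:
            converged = True
            break
    else:
        P = mu1[:, None] * W * mu2[None, :]
        P /= P.sum()
    return P, converged


def direct_information(
    couplings: CouplingModel,
    freqs: FrequencyModel,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> PairScoreMatrix:
    """Direct information for every column pair.

    For each pair the two-site distribution ``P_ij ~ exp(e_ij) h_i h_j`` is
    fitted so its marginals match the single-site frequencies, and
    ``DI = sum P_ij log(P_ij / (f_i f_j))``.  Pairs that fail to converge are
    recorded and reported via a warning.
    """
    L, q = freqs.fi.shape
    di = np.zeros((L, L))
    non_converged: list[tuple[int, int]] = []
    red = [s for s in range(q) if s != couplings.gauge_state]
    red_ix = np.ix_(red, red)
    for i in range(L - 1):
        fi = freqs.fi[i]
        for j in range(i + 1, L):
            W = np.ones((q, q))
            W[red_ix] = np.exp(couplings.e[i, j])
            P, ok = _two_site_model(W, fi, freqs.fi[j], tol, max_iter)
            if not ok:
                non_converged.append((i, j))
            indep = fi[:, None] * freqs.fi[j][None, :]
            val = float(np.sum(P * np.log(P / indep)))
            di[i, j] = di[j, i] = max(val, 0.0)
    if non_converged:
        warnings.warn(
            f"direct information: {len(non_converged)} pairs did not converge "
            f"within {max_iter} iterations (first: {non_converged[0]})",
            RuntimeWarning,
            stacklevel=2,
        )
    return PairScoreMatrix(di=di, non_converged=non_converged)


def rank_pairs(
    scores: PairScoreMatrix | np.ndarray,
    min_separation: int = 4,
    top_k: int | None = None,
) -> RankedPairs:
    """Rank column pairs by descending score.

    Pairs closer than ``min_separation + 1`` columns (``|i-j| <=
    min_separation``) are excluded; ties are broken by ascending ``(i, j)``
    for reproducibility.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    di = scores.di if isinstance(scores, PairScoreMatrix) else np.asarray(scores)
    L = di.shape[0]
    pairs = [
        (i, j, float(di[i, j]))
        for i in range(L - 1)
        for j in range(i + 1, L)
        if j - i > min_separation
    ]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    if top_k is not None:
        pairs = pairs[:top_k]
    return RankedPairs(pairs=pairs, min_separation=min_separation)


def top_fraction_count(n_columns: int, fraction: float = 0.25) -> int:
    """Pair-count helper: ``floor(fraction * L)`` (25% of a 178-column domain
    gives 44)."""
    return math.floor(fraction * n_columns)
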