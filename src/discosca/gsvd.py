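"""Generalized singular value decomposition (GSVD) of two linked blocks.

The GSVD jointly factorizes two matrices sharing their column mode,

    X_1 = U_1 S_1 V',   X_2 = U_2 S_2 V',

with U_1, U_2 column-orthogonal, S_1 = diag(c), S_2 = diag(s) satisfying
c_q^2 + s_q^2 = 1, and a full-column-rank V (J x Q) shared by both blocks,
Q = rank([X_1' X_2']').  Because c_q^2 is the proportion of component q's
variation falling in block 1, the pair (c_q^2, s_q^2) classifies each
component: both near 0.5 -> common to the blocks; c_q^2 near 1 ->
distinctive for block 1; near 0 -> distinctive for block 2.

Two estimation modes are provided.  :func:`gsvd` is the *full* (naive)
decomposition — it reproduces the data exactly but its leading components
are not a least-squares approximation, so in noisy data with common
structure they can account for surprisingly little variation.
:func:`adapted_gsvd` first replaces the concatenated data by its rank-R
truncated-SVD (i.e. simultaneous component) approximation and then
decomposes that, which restores least-squares optimality: its total VAF per
block equals the rank-R SCA total by construction.

Computation follows the CS-decomposition route: thin SVD X_c = P Sigma W'
at rank Q; split P row-wise into P_1, P_2; SVD P_1 = U_1 C Z'; then
P_2 Z has orthogonal columns with norms s_q = sqrt(1 - c_q^2) (since
P_1'P_1 + P_2'P_2 = I), giving U_2 by column normalization; and
V = W Sigma Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .blocks import LinkedBlocks

__all__ = [
    "GSVDResult",
    "VAFTable",
    "gsvd",
    "adapted_gsvd",
    "gsvd_vaf",
    "classify_components",
    "numerical_rank",
    "fix_signs",
]


def numerical_rank(X: np.ndarray, eps: float | None = None) -> int:
    """Rank of ``X`` as the number of singular values above
    eps * sigma_max * max(n, m); eps defaults to machine precision."""
    s = scipy.linalg.svdvals(X)
    if s.size == 0 or s[0] == 0:
        return 0
    if eps is None:
        eps = np.finfo(float).eps
    return int((s > eps * s[0] * max(X.shape)).sum())


def fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention for an SVD pair: the largest-magnitude
    element of each right singular vector is made positive."""
    flip = np.empty(Vt.shape[0])
    for q in range(Vt.shape[0]):
        v = Vt[q]
        flip[q] = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
    return U * flip, Vt * flip[:, None]


@dataclass
class VAFTable:
    """Variation-accounted-for bookkeeping, all values proportions of SS.

    Per-component per-block entries are exact rank-1 shares; for the GSVD
    the shared structure V is not column-orthogonal, so partial sums of
    *reconstruction* SS over a component subset need not equal the sum of
    the per-component entries (they do for SCA/DISCO, whose shared factor
    is orthonormal).
    """

    per_component_per_block: np.ndarray  # (components, blocks)
    per_component_concatenated: np.ndarray
    block_totals: np.ndarray
    overall_total: float

    def __post_init__(self) -> None:
        eps = 1e-9
        if (self.per_component_per_block < -eps).any() or \
           (self.per_component_per_block > 1 + eps).any():
            raise ValueError("per-component VAF outside [0, 1]")


@dataclass
class GSVDResult:
    """GSVD factors; components ordered by descending concatenated VAF.

    ``c`` and ``s`` hold the diagonals of S_1 and S_2 (c_q^2 + s_q^2 = 1).
    ``stability_flags`` marks components whose c_q^2 ties another
    component's within 1e-6 — the corresponding U vectors are then not
    unique (any rotation within the tied pair fits equally well).
    """

    U1: np.ndarray
    U2: np.ndarray
    c: np.ndarray
    s: np.ndarray
    V: np.ndarray
    Q: int
    order: np.ndarray = field(default=None)
    stability_flags: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.order is None:
            self.order = np.arange(self.Q)
        if self.stability_flags is None:
            c2 = np.sort(self.c**2)
            flags = np.zeros(self.Q, dtype=bool)
            close = np.abs(np.diff(c2)) < 1e-6
            flags[:-1] |= close
            flags[1:] |= close
            # map back from sorted order
            inv = np.argsort(np.argsort(self.c**2))
            self.stability_flags = flags[inv]

    def reconstruct(self, k: int) -> np.ndarray:
        if k == 0:
            return self.U1 @ (self.c[:, None] * self.V.T)
        return self.U2 @ (self.s[:, None] * self.V.T)


def _order_by_concat_vaf(U1, U2, c, s, V):
    vaf = (V**2).sum(axis=0)  # ||v_q||^2; c^2+s^2 = 1 absorbs both blocks
    order = np.argsort(-vaf, kind="stable")
    return U1[:, order], U2[:, order], c[order], s[order], V[:, order], order


def gsvd(blocks: LinkedBlocks, rank_eps: float | None = None) -> GSVDResult:
    """Full GSVD of two linked blocks (no rank reduction).

    This is an exact decomposition at Q = rank(X_c); it is *not* a
    least-squares rank-R approximation — use :func:`adapted_gsvd` for that.
    """
    if blocks.K != 2:
        raise ValueError("the GSVD is defined for exactly two blocks")
    X1 = blocks.blocks[0].values
    X2 = blocks.blocks[1].values
    Xc = np.vstack([X1, X2])
    if not np.any(Xc):
        raise ValueError("zero concatenated matrix has no GSVD")
    Q = numerical_rank(Xc, rank_eps)
    P, sig, Wt = scipy.linalg.svd(Xc, full_matrices=False)
    P, sig, Wt = P[:, :Q], sig[:Q], Wt[:Q]
    return _gsvd_of_orthofactors(P, sig, Wt, X1.shape[0], X2.shape[0])


def _tied_groups(values: np.ndarray, tol: float = 1e-8):
    """Maximal runs of (sorted-descending) values tied within ``tol``."""
    groups, start = [], 0
    for i in range(1, values.size + 1):
        if i == values.size or abs(values[i] - values[i - 1]) > tol:
            if i - start > 1:
                groups.append(np.arange(start, i))
            start = i
    return groups


def _gsvd_of_orthofactors(P, sig, Wt, I1, I2) -> GSVDResult:
    """CS-decomposition core given a thin SVD X_c = P diag(sig) Wt."""
    Q = sig.size
    P1, P2 = P[:I1], P[I1:]
    # SVD of the top row-block of the orthonormal P: P1 = U1 C Z'
    U1s, cvals, Zt = scipy.linalg.svd(P1, full_matrices=False)
    r1 = min(I1, Q)
    if r1 < Q:
        # complete Z to a full Q x Q orthogonal basis; extra columns have c=0
        Z = scipy.linalg.null_space(Zt).T
        Zt = np.vstack([Zt, Z])
        cvals = np.concatenate([cvals, np.zeros(Q - r1)])
        U1s = np.pad(U1s, ((0, 0), (0, Q - r1)))
    cvals = np.clip(cvals, 0.0, 1.0)
    Zmat = Zt.T
    U1 = U1s
    # Exactly tied (c, s) pairs leave the factors non-unique (any rotation
    # within the tied group fits); canonicalize by rotating each group so
    # its shared-structure columns are orthogonal with descending norm
    # (each component in turn explains maximal concatenated variation).
    for g in _tied_groups(cvals):
        _, _, Bt = scipy.linalg.svd(sig[:, None] * Zmat[:, g],
                                    full_matrices=False)
        Zmat[:, g] = Zmat[:, g] @ Bt.T
        U1[:, g] = U1[:, g] @ Bt.T
    G = P2 @ Zmat                       # columns orthogonal, norms s_q
    # column norms of G are numerically stabler than sqrt(1 - c^2)
    svals = np.clip(np.linalg.norm(G, axis=0), 0.0, 1.0) if I2 else \
        np.zeros(Q)
    U2 = np.zeros((I2, Q))
    tol = 1e-10
    nonzero = svals > tol
    if nonzero.any():
        # QR re-orthonormalization: G's columns are orthogonal only to
        # machine precision; signs keep each column aligned with G's
        Qf, Rf = scipy.linalg.qr(G[:, nonzero], mode="economic")
        U2[:, nonzero] = Qf * np.sign(np.diag(Rf))
    n_missing = int((~nonzero).sum())
    if n_missing and I2 >= int(nonzero.sum()) + n_missing:
        # s_q = 0 leaves u_2q arbitrary: complete orthonormally
        basis = scipy.linalg.null_space(U2[:, nonzero].T) if nonzero.any() \
            else np.eye(I2)
        U2[:, ~nonzero] = basis[:, :n_missing]
    # zero c columns leave u_1q arbitrary: same completion for U1
    zero_c = cvals <= tol
    if zero_c.any() and I1 >= Q:
        basis = scipy.linalg.null_space(U1[:, ~zero_c].T)
        U1[:, zero_c] = basis[:, :int(zero_c.sum())]
    V = Wt.T @ (sig[:, None] * Zmat)
    # sign convention: largest-magnitude element of each v_q positive
    for q in range(Q):
        if V[np.argmax(np.abs(V[:, q])), q] < 0:
            V[:, q] *= -1
            U1[:, q] *= -1
            U2[:, q] *= -1
    U1, U2, cvals, svals, V, order = _order_by_concat_vaf(U1, U2, cvals, svals, V)
    return GSVDResult(U1=U1, U2=U2, c=cvals, s=svals, V=V, Q=Q, order=order)


def adapted_gsvd(blocks: LinkedBlocks, R: int) -> GSVDResult:
    """Least-squares GSVD: decompose the rank-R truncated-SVD approximation
    of the concatenated data instead of the raw data.

    The first step is exactly a simultaneous component analysis, so the
    total VAF per block equals the rank-R SCA total; the result has Q = R
    components.
    """
    if blocks.K != 2:
        raise ValueError("the GSVD is defined for exactly two blocks")
    Xc = blocks.concatenated()
    rank = numerical_rank(Xc)
    if not 1 <= R <= rank:
        raise ValueError(f"R={R} outside [1, rank(X_c)={rank}]")
    P, sig, Wt = scipy.linalg.svd(Xc, full_matrices=False)
    I1 = blocks.blocks[0].n_rows
    I2 = blocks.blocks[1].n_rows
    return _gsvd_of_orthofactors(P[:, :R], sig[:R], Wt[:R], I1, I2)


def gsvd_vaf(result: GSVDResult, blocks: LinkedBlocks) -> VAFTable:
    """VAF accounting for a GSVD.

    Component q accounts for c_q^2 ||v_q||^2 of block-1 SS and
    s_q^2 ||v_q||^2 of block-2 SS (the SS of its rank-1 term; exact because
    U_1, U_2 have orthonormal columns), hence ||v_q||^2 of the concatenated
    SS.  Denominators are the SS of the blocks passed in, so for the
    adapted GSVD the proportions refer to the original, untruncated data.
    """
    if result.V.shape[0] != blocks.n_cols:
        raise ValueError("result and blocks have mismatched column mode")
    ss1 = blocks.blocks[0].ss
    ss2 = blocks.blocks[1].ss
    v2 = (result.V**2).sum(axis=0)
    per_block = np.stack([result.c**2 * v2 / ss1, result.s**2 * v2 / ss2], axis=1)
    per_concat = v2 / (ss1 + ss2)
    return VAFTable(
        per_component_per_block=per_block,
        per_component_concatenated=per_concat,
        block_totals=per_block.sum(axis=0),
        overall_total=float(per_concat.sum()),
    )


DEFAULT_COMMON_BAND = (0.4, 0.6)
DEFAULT_DISTINCT_BAND = (0.95, 1.0)  # mirrored as (0, 0.05) for block 2


def classify_components(result: GSVDResult,
                        common_band: tuple[float, float] = DEFAULT_COMMON_BAND,
                        distinct_band: tuple[float, float] = DEFAULT_DISTINCT_BAND,
                        ) -> list[str]:
    """Label each component from c_q^2: 'common' inside ``common_band``,
    'distinctive_block1' inside ``distinct_band`` (near 1),
    'distinctive_block2' inside its mirror near 0, else 'undetermined'."""
    lo_c, hi_c = common_band
    lo_d, hi_d = distinct_band
    if not (0 <= lo_c <= hi_c <= 1 and 0 <= lo_d <= hi_d <= 1):
        raise ValueError("bands must be sub-intervals of [0, 1]")
    mirror = (1 - hi_d, 1 - lo_d)
    if max(lo_c, mirror[0]) <= min(hi_c, mirror[1]) or \
       max(lo_c, lo_d) <= min(hi_c, hi_d):
        raise ValueError("common and distinctive bands overlap")
    labels = []
    for c2 in result.c**2:
        if lo_c <= c2 <= hi_c:
            labels.append("common")
        elif lo_d <= c2 <= hi_d:
            labels.append("distinctive_block1")
        elif mirror[0] <= c2 <= mirror[1]:
            labels.append("distinctive_block2")
        else:
            labels.append("undetermined")
    return labels
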