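"""Recovery scoring for component models.

Tucker's coefficient of congruence phi(a, b) = a'b / (||a|| ||b||) is the
cosine between two component vectors: it behaves like a correlation
(-1 <= phi <= 1), is sensitive to rotation but not to (positive) scaling,
and is the standard measure for agreement between an estimated and a true
component.  Because a fitted model identifies components only up to column
permutation and reflection (sign), estimates are first matched to the truth
by the permutation and signs maximizing mean |phi|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "tucker_congruence",
    "congruence_matrix",
    "match_components",
    "MatchResult",
    "recovery_report",
    "label_separation",
]


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine congruence between two nonzero vectors of equal length."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("congruence undefined for a zero vector")
    return float(a @ b / (na * nb))


def congruence_matrix(truth: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """Matrix of phi values between columns of ``truth`` and ``estimate``."""
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    tn = t / np.linalg.norm(t, axis=0, keepdims=True)
    en = e / np.linalg.norm(e, axis=0, keepdims=True)
    return tn.T @ en


@dataclass
class MatchResult:
    """Optimal pairing of estimated to true components.

    ``permutation[i]`` is the estimate column paired with truth column ``i``;
    ``signs[i]`` the reflection applied to it so the matched phi is >= 0.
    """

    permutation: list[int]
    signs: list[int]
    per_column_phi: np.ndarray
    mean_phi: float


def match_components(truth: np.ndarray, estimate: np.ndarray) -> MatchResult:
    """Match estimate columns to truth columns maximizing mean |phi|.

    Solved as an optimal assignment on the |phi| matrix (deterministic and
    globally optimal, unlike greedy matching); signs are then chosen so each
    matched congruence is nonnegative.
    """
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape[1] != estimate.shape[1]:
        raise ValueError(
            f"column count mismatch: truth has {truth.shape[1]}, "
            f"estimate has {estimate.shape[1]}"
        )
    phi = congruence_matrix(truth, estimate)
    rows, cols = linear_sum_assignment(-np.abs(phi))
    perm = np.empty(truth.shape[1], dtype=int)
    perm[rows] = cols
    matched = phi[np.arange(truth.shape[1]), perm]
    signs = np.where(matched < 0, -1, 1)
    per_col = matched * signs
    return MatchResult(permutation=perm.tolist(), signs=signs.tolist(),
                       per_column_phi=per_col, mean_phi=float(per_col.mean()))


def recovery_report(truth: dict[str, np.ndarray],
                    estimates: dict[str, np.ndarray],
                    exclude_zero_signal: dict[str, np.ndarray] | None = None,
                    ) -> dict[str, float]:
    """Mean matched congruence per structure (e.g. 'V', 'U1', 'U2').

    Each structure is matched separately, mirroring how recovery is
    usually tabulated per factor matrix.  ``exclude_zero_signal[name]`` may
    give a boolean column mask selecting the truth components with nonzero
    signal in that structure; columns excluded there are arbitrary in the
    truth (a zero singular value leaves the basis vector undetermined) and
    are left out of the calculation.  Scale-invariance of phi makes the
    report identical for U_k and U_k S_k estimates.
    """
    out: dict[str, float] = {}
    for name, t in truth.items():
        e = estimates[name]
        if exclude_zero_signal is not None and name in exclude_zero_signal:
            keep = np.asarray(exclude_zero_signal[name], dtype=bool)
            t = t[:, keep]
        if t.shape[1] < e.shape[1]:
            # truth subset matched against the best-fitting estimate columns
            phi = np.abs(congruence_matrix(t, e))
            rows, cols = linear_sum_assignment(-phi)
            out[name] = float(phi[rows, cols].mean())
        else:
            out[name] = match_components(t, e).mean_phi
    return out


def label_separation(loadings: np.ndarray, labels,
                     return_parts: bool = False):
    """Correlation between loading-space closeness of labelled row pairs and
    a same(0)/different(1) label indicator.

    Closeness of a pair is the cross product (inner product) of the two
    rows' loading vectors in the R-dimensional solution space.  Tight,
    well-separated label clusters make closeness high exactly for same-label
    pairs, so the raw Pearson correlation with the 0/1 indicator is then
    *negative*; both the signed value and its magnitude are of interest and
    ``return_parts=True`` returns ``(signed, |signed|)``.
    """
    L = np.asarray(loadings, dtype=float)
    labels = np.asarray(labels)
    if L.shape[0] != labels.size:
        raise ValueError("one label per loading row required")
    if L.shape[0] < 3:
        raise ValueError("need at least 3 labelled rows")
    if np.unique(labels).size < 2:
        raise ValueError("need at least two distinct labels")
    iu, ju = np.triu_indices(L.shape[0], k=1)
    closeness = np.einsum("ij,ij->i", L[iu], L[ju])
    different = (labels[iu] != labels[ju]).astype(float)
    r = float(np.corrcoef(closeness, different)[0, 1])
    if return_parts:
        return r, abs(r)
    return r
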