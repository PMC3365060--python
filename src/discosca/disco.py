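"""DISCO: rotation of simultaneous components to common/distinctive targets.

A fitted SCA model is only identified up to an orthogonal rotation B:
(T B, P B) fits the data exactly as well as (T, P).  DISCO spends that
rotational freedom to reveal structure: a *distinctive* component should
have all-zero block-factor rows in the blocks it does not underlie, a
*common* component is present everywhere.  Writing W for the binary mask
with ones exactly on the entries targeted to be zero, the rotation solves

    min_B  || W o (T B) ||_F^2      subject to  B'B = I,

(o = elementwise product) so only the targeted entries contribute.  The
minimization iterates a majorization step: with Z = (1-W) o (T B0), the
orthogonal-Procrustes update B = polar(T'Z) never increases the objective.
Components sharing a status give identical target columns, leaving a
rotational indeterminacy within the group; it is resolved by re-rotating
each group so its first component explains maximal variation in the block
factor and each next one the maximum of the residual (as in an SVD).

When the numbers of common and distinctive components are unknown, every
possible assignment is tried and scored by how far the rotated solution
deviates from its target: per component, a distinctive one deviates by the
proportion of variation it accounts for in the block where it should be
absent, a common one by the absolute difference of its VAF proportions
between blocks; the target with the smallest maximal componentwise
deviation is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import scipy.linalg

from .sca import SCAModel

__all__ = [
    "TargetSpec",
    "DiscoResult",
    "DeviationReport",
    "build_target",
    "enumerate_targets",
    "disco_rotate",
    "target_deviation",
    "select_target",
]


@dataclass(frozen=True)
class TargetSpec:
    """Status assignment for R components over K blocks.

    ``statuses[r]`` is the frozenset of (0-based) block indices component r
    underlies: all blocks for a common component, a single block for a
    distinctive one.  ``mask`` is the binary matrix W over the concatenated
    block factor with ones exactly where the rotated factor is targeted to
    vanish (the block rows a component should be absent from).
    """

    statuses: tuple[frozenset, ...]
    mask: np.ndarray = field(compare=False)
    K: int

    @property
    def R(self) -> int:
        return len(self.statuses)

    def counts(self) -> tuple[int, ...]:
        """(d_1, ..., d_K, n_common): distinctive count per block, then common."""
        d = [0] * self.K
        common = 0
        for st in self.statuses:
            if len(st) == self.K:
                common += 1
            elif len(st) == 1:
                d[next(iter(st))] += 1
        return (*d, common)

    def label(self) -> str:
        parts = [f"d{k + 1}={n}" for k, n in enumerate(self.counts()[:-1])]
        parts.append(f"common={self.counts()[-1]}")
        return ",".join(parts)


def build_target(statuses, blocks_or_offsets) -> TargetSpec:
    """Construct the zero mask W for a list of component statuses.

    ``statuses`` is a sequence of nonempty collections of block indices;
    ``blocks_or_offsets`` is a LinkedBlocks or an explicit row-offset list
    (length K+1) giving the block partition of the concatenated factor.
    """
    offsets = (blocks_or_offsets if isinstance(blocks_or_offsets, (list, tuple))
               else blocks_or_offsets.row_offsets)
    K = len(offsets) - 1
    statuses = tuple(frozenset(int(b) for b in st) for st in statuses)
    for r, st in enumerate(statuses):
        if not st:
            raise ValueError(f"component {r}: empty status (must underlie "
                             "at least one block)")
        if not st <= set(range(K)):
            raise ValueError(f"component {r}: block index outside 0..{K - 1}")
    R = len(statuses)
    mask = np.zeros((offsets[-1], R))
    for r, st in enumerate(statuses):
        for k in range(K):
            if k not in st:
                mask[offsets[k]:offsets[k + 1], r] = 1.0
    return TargetSpec(statuses=statuses, mask=mask, K=K)


def enumerate_targets(R: int, K: int = 2, blocks_or_offsets=None) -> list:
    """All unordered assignments of R components to {common, distinctive for
    block k}; for K=2 there are (R+1)(R+2)/2 of them.

    Returns status tuples, or full TargetSpecs when ``blocks_or_offsets``
    is given.  Distinctive-for-a-subset statuses (1 < |set| < K) are not
    enumerated: with K=2 they do not exist, and for K>2 the combinatorial
    blow-up is rarely wanted — build such targets explicitly instead.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    kinds = [frozenset(range(K))] + [frozenset({k}) for k in range(K)]
    assignments = []
    for combo in combinations_with_replacement(range(len(kinds)), R):
        # sorted combo: common components first, then d1, d2, ...
        assignments.append(tuple(kinds[i] for i in combo))
    if blocks_or_offsets is None:
        return assignments
    return [build_target(st, blocks_or_offsets) for st in assignments]


@dataclass
class DeviationReport:
    """Componentwise deviations of a rotated solution from its target."""

    per_component: np.ndarray
    max_deviation: float
    statuses: tuple
    vaf_per_block: np.ndarray  # (R, K) proportions, for reporting


@dataclass
class DiscoResult:
    B: np.ndarray
    rotated: SCAModel
    target: TargetSpec
    objective_trajectory: list[float]
    converged: bool
    n_restarts_used: int
    deviations: DeviationReport | None = None

    @property
    def objective(self) -> float:
        return self.objective_trajectory[-1]


def _polar_orthogonal(M: np.ndarray) -> np.ndarray:
    """Orthogonal polar factor of M; rank-deficient M is completed to a
    full orthogonal matrix via the SVD's full factors."""
    U, _, Vt = scipy.linalg.svd(M, full_matrices=True)
    return U @ Vt


def _masked_ss(T: np.ndarray, B: np.ndarray, W: np.ndarray) -> float:
    return float(((W * (T @ B)) ** 2).sum())


def _rerotate_within_groups(T: np.ndarray, B: np.ndarray,
                            statuses: tuple) -> np.ndarray:
    """Resolve within-group rotational freedom: components with identical
    status are rotated so each successive one maximizes VAF in the block
    factor (principal axes of the group's subspace)."""
    B = B.copy()
    seen: dict[frozenset, list[int]] = {}
    for r, st in enumerate(statuses):
        seen.setdefault(st, []).append(r)
    for idx in seen.values():
        if len(idx) < 2:
            continue
        cols = np.asarray(idx)
        G = T @ B[:, cols]
        # principal axes: G = U S V' -> G V has decreasing column SS
        _, _, Vt = scipy.linalg.svd(G, full_matrices=False)
        B[:, cols] = B[:, cols] @ Vt.T
    # deterministic signs: largest-|.| entry of each rotated column positive
    TB = T @ B
    for r in range(B.shape[1]):
        if TB[np.argmax(np.abs(TB[:, r])), r] < 0:
            B[:, r] *= -1
    return B


def disco_rotate(model: SCAModel, target: TargetSpec,
                 tol: float = 1e-10, max_iter: int = 1000,
                 n_restarts: int = 10, seed: int | None = 0) -> DiscoResult:
    """Rotate an SCA model to a partially specified common/distinctive
    target by iterative majorization.

    Starts from B = I plus ``n_restarts`` random orthogonal matrices (the
    objective is non-convex); the best local optimum is kept.  The
    objective trajectory of the winning start is recorded and is
    guaranteed nonincreasing.
    """
    T = model.block_factor
    W = target.mask
    if W.shape != T.shape[:1] + (model.R,):
        raise ValueError(
            f"target mask shape {W.shape} does not match block factor "
            f"{(T.shape[0], model.R)}")
    rng = np.random.default_rng(seed)
    starts = [np.eye(model.R)]
    for _ in range(n_restarts):
        starts.append(_polar_orthogonal(rng.standard_normal((model.R, model.R))))

    best = None
    for i_start, B0 in enumerate(starts):
        B = B0
        traj = [_masked_ss(T, B, W)]
        converged = False
        for _ in range(max_iter):
            Z = (1.0 - W) * (T @ B)
            B_new = _polar_orthogonal(T.T @ Z)
            f_new = _masked_ss(T, B_new, W)
            # majorization guarantees f_new <= traj[-1] up to roundoff
            if f_new > traj[-1] + 1e-12 * max(1.0, traj[0]):
                break
            B = B_new
            drop = traj[-1] - f_new
            traj.append(f_new)
            scale = max(traj[0], 1e-300)
            # a genuinely nonzero optimum: stop once the decrease is
            # negligible relative to the starting value; an optimum heading
            # to zero (target exactly attainable): polish to numerical zero
            if f_new <= 1e-15 * scale or drop <= 1e-16 * scale or \
                    (f_new > 1e-8 * scale and drop <= tol * scale):
                converged = True
                break
        if best is None or traj[-1] < best[1][-1] - 1e-15:
            best = (B, traj, converged, i_start)

    B, traj, converged, i_start = best
    if not converged:
        warnings.warn(
            f"DISCO rotation did not converge in {max_iter} iterations "
            f"(final objective {traj[-1]:.3e})", stacklevel=2)
    B = _rerotate_within_groups(T, B, target.statuses)
    result = DiscoResult(
        B=B,
        rotated=model.rotated(B),
        target=target,
        objective_trajectory=traj,
        converged=converged,
        n_restarts_used=len(starts) - 1,
    )
    result.deviations = target_deviation(result)
    return result


def target_deviation(result: DiscoResult) -> DeviationReport:
    """Componentwise deviation of a rotated solution from its target.

    Distinctive component: maximal proportion of variation it accounts for
    over the blocks it should be absent from (each block's own SS as
    denominator).  Common component: for K=2 the absolute difference of
    its two VAF proportions; for K>2 the maximal pairwise difference over
    the blocks it is present in (an extension — the measure is defined in
    the two-block setting).
    """
    rotated = result.rotated
    denom = np.asarray(rotated.block_ss)
    vaf = np.divide(rotated.component_block_ss(), denom,
                    out=np.zeros((rotated.R, rotated.K)), where=denom > 0)
    devs = np.empty(rotated.R)
    for r, st in enumerate(result.target.statuses):
        present = sorted(st)
        absent = [k for k in range(rotated.K) if k not in st]
        if absent:  # distinctive (or present-in-subset) component
            devs[r] = vaf[r, absent].max()
        else:  # common component
            p = vaf[r, present]
            devs[r] = float(p.max() - p.min())
    return DeviationReport(per_component=devs, max_deviation=float(devs.max()),
                           statuses=result.target.statuses,
                           vaf_per_block=vaf)


def select_target(model: SCAModel, tol: float = 1e-10, max_iter: int = 1000,
                  n_restarts: int = 10, seed: int | None = 0,
                  tie_tol: float = 1e-9):
    """Try every enumerated target and retain the solution deviating least.

    Returns ``(best DiscoResult, table)`` where the table lists, per
    target, its status counts and maximal deviation (the curve usually
    plotted against the number of distinctive components).  Ties within
    ``tie_tol`` prefer fewer distinctive components, then the
    lexicographically smaller distinctive-count vector.
    """
    targets = enumerate_targets(model.R, model.K, model.block_row_offsets)
    rows = []
    results = []
    for t in targets:
        # deliberately misfit targets often crawl toward flat optima; their
        # convergence status goes in the table instead of a warning each
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="DISCO rotation did not")
            res = disco_rotate(model, t, tol=tol, max_iter=max_iter,
                               n_restarts=n_restarts, seed=seed)
        counts = t.counts()
        n_dist = sum(counts[:-1])
        rows.append({
            "target": t.label(),
            "n_distinctive": n_dist,
            "max_deviation": res.deviations.max_deviation,
            "objective": res.objective,
            "converged": res.converged,
        })
        results.append(res)

    devs = [res.deviations.max_deviation for res in results]
    min_dev = min(devs)
    tied = [i for i, d in enumerate(devs) if d <= min_dev + tie_tol]
    best_i = min(tied, key=lambda i: (sum(targets[i].counts()[:-1]),
                                      targets[i].counts()[:-1]))
    return results[best_i], rows
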