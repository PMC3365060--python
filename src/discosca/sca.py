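"""Simultaneous component analysis (SCA) of linked blocks.

SCA generalizes PCA to K blocks sharing one mode by constraining them to a
single factor on the shared mode: X_k ~ T_k P' with the same P (J x R) for
every block.  The least-squares rank-R solution is the truncated SVD of the
row-wise concatenation X_c = U S V': the shared factor is P = V_R (kept
column-orthonormal) and the block factor is the corresponding rows of
U_R S_R, so all scale sits on the block factor.  With P orthonormal the sum
of squares a component accounts for within block k is simply the squared
norm of that block's column of the block factor — the additivity the DISCO
deviation measure relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .blocks import LinkedBlocks
from .gsvd import VAFTable, fix_signs, numerical_rank

__all__ = ["SCAModel", "sca", "sca_scree"]


@dataclass
class SCAModel:
    """Rank-R simultaneous component model of K linked blocks.

    ``block_factor`` stacks the block-specific factors T_k ((sum I_k) x R,
    carrying the scale); ``shared_factor`` is the column-orthonormal shared
    factor (J x R); ``singvals`` are the concatenated-data singular values.
    """

    block_factor: np.ndarray
    shared_factor: np.ndarray
    singvals: np.ndarray
    R: int
    block_row_offsets: list[int]
    block_ss: list[float]
    total_ss: float
    degenerate: bool = False  # singular-value tie across the R-th boundary
    vaf: VAFTable | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return len(self.block_row_offsets) - 1

    def block_rows(self, k: int) -> np.ndarray:
        """Rows of the block factor belonging to block ``k`` (0-based)."""
        offs = self.block_row_offsets
        return self.block_factor[offs[k]:offs[k + 1]]

    def fitted_concatenated(self) -> np.ndarray:
        return self.block_factor @ self.shared_factor.T

    def fitted_ss(self) -> float:
        return float((self.singvals**2).sum())

    def component_block_ss(self) -> np.ndarray:
        """SS accounted for per component (rows) per block (columns)."""
        return np.stack([(self.block_rows(k) ** 2).sum(axis=0)
                         for k in range(self.K)], axis=1)

    def vaf_table(self) -> VAFTable:
        denom = np.asarray(self.block_ss)
        per_block = np.divide(self.component_block_ss(), denom,
                              out=np.zeros((self.R, self.K)),
                              where=denom > 0)
        per_concat = (self.block_factor**2).sum(axis=0) / self.total_ss
        return VAFTable(
            per_component_per_block=per_block,
            per_component_concatenated=per_concat,
            block_totals=per_block.sum(axis=0),
            overall_total=float(per_concat.sum()),
        )

    def rotated(self, B: np.ndarray) -> "SCAModel":
        """Counter-rotated copy: (T B, P B) fits the data identically for
        any orthogonal B."""
        m = SCAModel(
            block_factor=self.block_factor @ B,
            shared_factor=self.shared_factor @ B,
            singvals=self.singvals.copy(),
            R=self.R,
            block_row_offsets=list(self.block_row_offsets),
            block_ss=list(self.block_ss),
            total_ss=self.total_ss,
            degenerate=self.degenerate,
        )
        m.vaf = m.vaf_table()
        return m


def sca(blocks: LinkedBlocks, R: int, tie_tol: float = 1e-9) -> SCAModel:
    """Fit the rank-R simultaneous component model by truncated SVD of the
    concatenated data.

    Warns (and flags the model) when the R-th and (R+1)-th singular values
    tie within ``tie_tol`` relative — the retained subspace is then not
    unique.
    """
    Xc = blocks.concatenated()
    rank = numerical_rank(Xc)
    if not 1 <= R <= rank:
        raise ValueError(f"R={R} outside [1, rank(X_c)={rank}]")
    U, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    U, Vt = fix_signs(U, Vt)
    degenerate = False
    if R < len(s) and s[0] > 0 and (s[R - 1] - s[R]) <= tie_tol * s[0]:
        degenerate = True
        warnings.warn(
            f"singular values {R} and {R + 1} are tied; the rank-{R} "
            "subspace is not unique", stacklevel=2)
    model = SCAModel(
        block_factor=U[:, :R] * s[:R],
        shared_factor=Vt[:R].T,
        singvals=s[:R].copy(),
        R=R,
        block_row_offsets=blocks.row_offsets,
        block_ss=[b.ss for b in blocks.blocks],
        total_ss=blocks.concatenated_ss,
        degenerate=degenerate,
    )
    model.vaf = model.vaf_table()
    return model


def sca_scree(blocks: LinkedBlocks, R_max: int) -> VAFTable:
    """Per-component per-block VAF for components 1..R_max, ordered by
    concatenated VAF — the multiblock generalization of the scree graph
    used to choose the number of components.

    ``R_max`` may exceed the numerical rank of the concatenation (unlike
    :func:`sca`); components beyond it simply show zero VAF.
    """
    if R_max > min(sum(b.n_rows for b in blocks.blocks), blocks.n_cols):
        raise ValueError(f"R_max={R_max} exceeds the matrix dimensions")
    rank = numerical_rank(blocks.concatenated())
    table = sca(blocks, min(R_max, rank)).vaf_table()
    pad = R_max - min(R_max, rank)
    if pad == 0:
        return table
    return VAFTable(
        per_component_per_block=np.vstack(
            [table.per_component_per_block, np.zeros((pad, blocks.K))]),
        per_component_concatenated=np.concatenate(
            [table.per_component_concatenated, np.zeros(pad)]),
        block_totals=table.block_totals,
        overall_total=table.overall_total,
    )
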