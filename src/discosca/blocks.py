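"""Linked data blocks: container, delimited I/O and preprocessing.

Several data blocks (matrices) are *linked* when they share one mode — here
always the columns (e.g. the same culture samples measured on two platforms,
or the same aligned time points for two organisms).  The row mode is block
specific (metabolites, genes).  All decomposition methods in this package
consume a :class:`LinkedBlocks`, the row-wise concatenation
``X_c = [X_1^T ... X_K^T]^T``.

Preprocessing follows common practice for component analysis of omics
blocks: per-row mean centering and scaling to unit sum of squares (so no
variable dominates through sheer abundance), an elementwise square-root
transform for skewed peak intensities, imputation of below-detection values
by half the smallest detected value, and block weighting so that no block
dominates the joint fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockMatrix",
    "LinkedBlocks",
    "read_linked_blocks",
    "write_block",
    "center_scale_rows",
    "sqrt_transform",
    "impute_below_detection",
    "weight_block",
]

#: values treated as missing on input (in addition to empty fields)
MISSING_SENTINELS = ("", "NA", "NaN", "nan")


class AlignmentError(ValueError):
    """Column identifiers of the blocks cannot be aligned."""


@dataclass
class BlockMatrix:
    """A single data block: ``I_k`` rows (block-specific entities) by ``J``
    shared columns.

    Parameters
    ----------
    values : ndarray, shape (I_k, J)
    block_id : str
    row_ids, col_ids : sequences of unique identifiers
    """

    values: np.ndarray
    block_id: str
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"block {self.block_id!r}: values must be 2-D")
        n_rows, n_cols = self.values.shape
        if not self.row_ids:
            self.row_ids = [f"{self.block_id}_r{i}" for i in range(n_rows)]
        if not self.col_ids:
            self.col_ids = [f"c{j}" for j in range(n_cols)]
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(self.row_ids) != n_rows:
            raise ValueError(f"block {self.block_id!r}: {len(self.row_ids)} row ids for {n_rows} rows")
        if len(self.col_ids) != n_cols:
            raise ValueError(f"block {self.block_id!r}: {len(self.col_ids)} col ids for {n_cols} columns")
        if len(set(self.row_ids)) != n_rows:
            raise ValueError(f"block {self.block_id!r}: duplicate row ids")
        if len(set(self.col_ids)) != n_cols:
            raise ValueError(f"block {self.block_id!r}: duplicate column ids")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def ss(self) -> float:
        """Total sum of squares of the block (NaNs excluded)."""
        return float(np.nansum(self.values**2))

    def with_values(self, values: np.ndarray) -> "BlockMatrix":
        """Copy of this block with new values, same identifiers."""
        return BlockMatrix(np.asarray(values, dtype=float), self.block_id,
                           list(self.row_ids), list(self.col_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class LinkedBlocks:
    """An ordered collection of ``K >= 2`` blocks sharing their column mode."""

    blocks: list[BlockMatrix]

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError("LinkedBlocks needs at least two blocks")
        ref = self.blocks[0].col_ids
        for blk in self.blocks[1:]:
            if blk.col_ids != ref:
                raise AlignmentError(
                    f"block {blk.block_id!r}: column ids differ from block "
                    f"{self.blocks[0].block_id!r}"
                )

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def n_cols(self) -> int:
        return self.blocks[0].n_cols

    @property
    def row_offsets(self) -> list[int]:
        """Start row of each block within the concatenation (plus the end)."""
        offs = [0]
        for blk in self.blocks:
            offs.append(offs[-1] + blk.n_rows)
        return offs

    @property
    def concatenated_ss(self) -> float:
        return float(sum(b.ss for b in self.blocks))

    def concatenated(self) -> np.ndarray:
        """The row-wise concatenation ``X_c``."""
        return np.vstack([b.values for b in self.blocks])

    def block_rows(self, concatenated: np.ndarray, k: int) -> np.ndarray:
        """Rows of a concatenated-shape array belonging to block ``k`` (0-based)."""
        offs = self.row_offsets
        return concatenated[offs[k]:offs[k + 1]]

    def map(self, fn) -> "LinkedBlocks":
        return LinkedBlocks([fn(b) for b in self.blocks])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_one(path, delimiter: str, block_id: str) -> BlockMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False)
    values = np.empty(df.shape, dtype=float)
    for i, row_id in enumerate(df.index):
        for j, col_id in enumerate(df.columns):
            cell = df.iat[i, j].strip()
            if cell in MISSING_SENTINELS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {row_id!r}, "
                    f"column {col_id!r}"
                ) from exc
    return BlockMatrix(values, block_id, list(df.index.astype(str)),
                       list(df.columns.astype(str)))


def read_linked_blocks(paths: Sequence, delimiter: str = "\t",
                       block_ids: Iterable[str] | None = None,
                       transpose: bool = False) -> LinkedBlocks:
    """Read delimited matrices and align them on the first file's columns.

    Each file must have one header row of column ids and a leading column of
    row ids.  Blocks whose columns are a permutation of the first file's are
    reordered to match; a differing column *set* raises
    :class:`AlignmentError`.  ``transpose=True`` transposes each matrix
    after reading (for files whose *rows* are the shared mode).
    """
    paths = list(paths)
    if block_ids is None:
        block_ids = [f"X{i + 1}" for i in range(len(paths))]
    blocks = [_read_one(p, delimiter, bid) for p, bid in zip(paths, block_ids)]
    if transpose:
        blocks = [BlockMatrix(b.values.T, b.block_id, b.col_ids, b.row_ids)
                  for b in blocks]
    ref = blocks[0].col_ids
    aligned = [blocks[0]]
    for blk in blocks[1:]:
        if blk.col_ids == ref:
            aligned.append(blk)
            continue
        if set(blk.col_ids) != set(ref):
            missing = sorted(set(ref) - set(blk.col_ids))
            extra = sorted(set(blk.col_ids) - set(ref))
            raise AlignmentError(
                f"block {blk.block_id!r}: column ids do not match the first "
                f"block (missing {missing[:5]}, unexpected {extra[:5]})"
            )
        order = [blk.col_ids.index(c) for c in ref]
        aligned.append(BlockMatrix(blk.values[:, order], blk.block_id,
                                   blk.row_ids, list(ref)))
    return LinkedBlocks(aligned)


def write_block(block: BlockMatrix, path, delimiter: str = "\t") -> None:
    """Write a block as a delimited matrix with ids, 10 significant digits."""
    df = block.to_frame()
    df.to_csv(path, sep=delimiter, float_format="%.10g")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def center_scale_rows(block: BlockMatrix) -> BlockMatrix:
    """Mean-center and scale every row to sum of squares one.

    Raises if any row is constant (its centered sum of squares is zero);
    such rows must be filtered by the caller first, because silently
    dropping them would desynchronize row identifiers between runs.
    """
    vals = block.values
    if np.isnan(vals).any():
        raise ValueError(f"block {block.block_id!r}: missing values; impute first")
    centered = vals - vals.mean(axis=1, keepdims=True)
    ss = (centered**2).sum(axis=1)
    bad = np.flatnonzero(ss <= 0)
    if bad.size:
        ids = [block.row_ids[i] for i in bad]
        raise ValueError(
            f"block {block.block_id!r}: constant rows cannot be scaled: {ids}"
        )
    return block.with_values(centered / np.sqrt(ss)[:, None])


def sqrt_transform(block: BlockMatrix) -> BlockMatrix:
    """Elementwise square root (for right-skewed nonnegative intensities)."""
    vals = block.values
    if np.nanmin(vals) < 0:
        raise ValueError(f"block {block.block_id!r}: negative values, sqrt undefined")
    return block.with_values(np.sqrt(vals))


def impute_below_detection(block: BlockMatrix,
                           missing_code: float | None = None) -> BlockMatrix:
    """Replace missing (below-detection) cells by half the smallest detected
    value of the whole block.

    Missing cells are NaN (what empty/"NA" fields parse to); an additional
    numeric ``missing_code`` (e.g. 0 for zero-filled peak tables) may be
    given.  A single detection threshold per platform motivates taking the
    minimum over the entire block rather than per row.
    """
    vals = block.values
    mask = np.isnan(vals)
    if missing_code is not None:
        mask |= vals == missing_code
    if not mask.any():
        return block.with_values(vals.copy())
    detected = vals[~mask]
    detected = detected[detected > 0]
    if detected.size == 0:
        raise ValueError(
            f"block {block.block_id!r}: no detected (positive) values to impute from"
        )
    out = vals.copy()
    out[mask] = detected.min() / 2.0
    return block.with_values(out)


def weight_block(block: BlockMatrix, mode: str = "none") -> BlockMatrix:
    """Down-weight a block so it cannot dominate a joint decomposition.

    mode='sqrt_rows' divides by the square root of the number of rows;
    mode='unit_ss' scales the block to total sum of squares one;
    mode='none' is the identity.
    """
    if mode == "none":
        return block.with_values(block.values.copy())
    if mode == "sqrt_rows":
        return block.with_values(block.values / np.sqrt(block.n_rows))
    if mode == "unit_ss":
        norm = np.sqrt(block.ss)
        if norm == 0:
            raise ValueError(f"block {block.block_id!r}: zero block cannot be scaled to unit SS")
        return block.with_values(block.values / norm)
    raise ValueError(f"unknown weighting mode {mode!r}")
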