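"""Buffered spatial block cross-validation for the growth model.

Forest census data are spatially autocorrelated, so leave-one-tree-out
resampling leaks information between training and test sets and yields
optimistic error estimates.  Instead the plot is gridded into square blocks
(default 100 m); each block in turn is the test set, the blocks touching it
(queen adjacency: shared edge or corner) are dropped as a buffer, and the
model is fit to the remaining blocks.  Per-block RMSEs are averaged,
unweighted, into a single cross-validated RMSE.

Only focal growth observations are partitioned.  Competitor stems are never
removed: a focal tree's BA covariates describe its real neighborhood in
every fold.  With cell size >= twice the neighborhood radius, the buffer
guarantees no training tree's neighborhood touches any test tree's
neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .bayes import NIGParams, nig_update, predictive_marginals, rmse
from .census import GrowthDataset
from .neighborhood import build_design

__all__ = ["SpatialBlocks", "CVFold", "CVResult", "assign_blocks", "make_fold", "spatial_cv"]


@dataclass
class SpatialBlocks:
    """Grid-cell assignment of trees to spatial blocks.

    Blocks are half-open squares [x0+c*s, x0+(c+1)*s) x [y0+r*s, y0+(r+1)*s).
    Only occupied blocks take part in the fold rotation; block ids number
    them sequentially in (col, row) order.
    """

    cell_size: float
    origin: Tuple[float, float]
    assignment: np.ndarray  # per-tree block id, aligned with input coords
    block_index: Dict[int, Tuple[int, int]]

    @property
    def n_blocks(self) -> int:
        return len(self.block_index)

    @property
    def block_ids(self) -> List[int]:
        return sorted(self.block_index)

    def trees_in(self, block_id: int) -> np.ndarray:
        return np.where(self.assignment == block_id)[0]


@dataclass
class CVFold:
    """One fold: the held-out test block, its buffer ring, the training blocks."""

    test_block: int
    buffer_blocks: Set[int]
    train_blocks: Set[int]


@dataclass
class CVResult:
    per_block_rmse: Dict[int, float]
    mean_rmse: float
    folds: List[CVFold] = field(default_factory=list)
    pooled_rmse: Optional[float] = None


def assign_blocks(
    coords: np.ndarray,
    cell_size: float = 100.0,
    origin: Optional[Tuple[float, float]] = None,
) -> SpatialBlocks:
    """Bin tree coordinates into half-open grid cells.

    The origin defaults to the minimum coordinate (plot corner); empty cells
    are dropped so irregular plots simply yield fewer blocks.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if origin is None:
        origin = (float(coords[:, 0].min()), float(coords[:, 1].min()))
    col = np.floor((coords[:, 0] - origin[0]) / cell_size).astype(int)
    row = np.floor((coords[:, 1] - origin[1]) / cell_size).astype(int)
    cells = sorted(set(zip(col.tolist(), row.tolist())))
    cell_to_id = {cell: i for i, cell in enumerate(cells)}
    assignment = np.array([cell_to_id[cr] for cr in zip(col, row)], dtype=int)
    return SpatialBlocks(
        cell_size=float(cell_size), origin=origin, assignment=assignment,
        block_index={i: cell for cell, i in cell_to_id.items()},
    )


def make_fold(blocks: SpatialBlocks, test: int) -> CVFold:
    """Partition blocks into test / queen-adjacent buffer / training sets."""
    if test not in blocks.block_index:
        raise KeyError(f"unknown block id {test}")
    tc, tr = blocks.block_index[test]
    buffer_ids = {
        b for b, (c, r) in blocks.block_index.items()
        if b != test and max(abs(c - tc), abs(r - tr)) <= 1
    }
    train_ids = set(blocks.block_index) - buffer_ids - {test}
    return CVFold(test_block=test, buffer_blocks=buffer_ids, train_blocks=train_ids)


def spatial_cv(
    dataset: GrowthDataset,
    blocks: Optional[SpatialBlocks] = None,
    cell_size: float = 100.0,
    prior: Optional[NIGParams] = None,
    mu0=0.0,
    V0=100.0,
    a0: float = 0.01,
    b0: float = 0.01,
) -> CVResult:
    """Buffered spatial block CV of the growth model on a prepared dataset.

    For each occupied block: fit on training-block focal trees, predict the
    test block's focal trees via posterior-predictive means, record the
    block RMSE.  ``mean_rmse`` is the unweighted average over blocks;
    ``pooled_rmse`` additionally pools squared errors over all trees.
    """
    coords = dataset.frame[["x", "y_coord"]].to_numpy(dtype=float)
    if blocks is None:
        blocks = assign_blocks(coords, cell_size=cell_size)
    if blocks.n_blocks < 3:
        raise ValueError(
            f"only {blocks.n_blocks} occupied block(s); spatial CV needs >= 3 "
            "(every fold must retain a nonempty training set)"
        )

    design = build_design(dataset)
    X = np.asarray(design.X, dtype=float)
    y = dataset.y
    p = X.shape[1]
    if prior is None:
        mu0_arr = np.asarray(mu0, dtype=float)
        if mu0_arr.ndim == 0:
            mu0_arr = np.full(p, float(mu0_arr))
        prior = NIGParams(mu0_arr, V0, a0, b0)

    per_block: Dict[int, float] = {}
    folds: List[CVFold] = []
    sq_err_sum, n_total = 0.0, 0
    train_tags_seen: Dict[int, set] = {}
    for test in blocks.block_ids:
        fold = make_fold(blocks, test)
        folds.append(fold)
        train_mask = np.isin(blocks.assignment, sorted(fold.train_blocks))
        test_mask = blocks.assignment == test
        if not train_mask.any():
            raise ValueError(
                f"fold with test block {test} has an empty training set; "
                "use a larger plot or smaller cells"
            )
        post = nig_update(prior, X[train_mask], y[train_mask])
        yhat, _, _ = predictive_marginals(post, X[test_mask])
        per_block[test] = rmse(y[test_mask], yhat)
        sq_err_sum += float(np.sum((y[test_mask] - yhat) ** 2))
        n_total += int(test_mask.sum())
        train_tags_seen[test] = set(design.row_tags[train_mask])
        # leakage audit: no test-block focal observation in this training set
        assert not (set(design.row_tags[test_mask]) & train_tags_seen[test])

    return CVResult(
        per_block_rmse=per_block,
        mean_rmse=float(np.mean(list(per_block.values()))),
        folds=folds,
        pooled_rmse=float(np.sqrt(sq_err_sum / n_total)),
    )
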