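"""Neighborhood competition covariates and the group-blocked design matrix.

The competition load on focal tree *i* from competitor group *k* is the summed
basal area of all competitor stems of group *k* within a fixed radius (default
7.5 m) of the focal stem, the focal stem itself excluded by tag.  The growth
regression is one joint model over all focal groups: each focal group *j* has
its own intercept, its own DBH slope, and its own row of competition
coefficients lambda_{j,1..K}, but a single shared error variance.  The design
is therefore block structured with p = 2J + J*K columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "NeighborhoodConfig",
    "DesignMatrix",
    "basal_area",
    "neighbor_contributions",
    "group_ba",
    "ba_matrix",
    "build_design",
    "count_parameters",
]

_UNIT_SCALE = {"cm2": 1.0, "m2": 1e-4}


@dataclass
class NeighborhoodConfig:
    """Neighborhood definition: radius in meters, basal-area units.

    ``include_boundary_equal`` keeps competitors at exactly the radius
    (distance <= radius); fixed for determinism.
    """

    radius: float = 7.5
    ba_units: str = "cm2"
    include_boundary_equal: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.ba_units not in _UNIT_SCALE:
            raise ValueError(f"ba_units must be one of {sorted(_UNIT_SCALE)}")


def basal_area(dbh, units: str = "cm2"):
    """Cross-sectional stem area pi*(dbh/2)^2; dbh in cm, area in cm2 or m2."""
    dbh_arr = np.asarray(dbh, dtype=float)
    if np.any(dbh_arr < 0):
        raise ValueError("dbh must be non-negative")
    if units not in _UNIT_SCALE:
        raise ValueError(f"units must be one of {sorted(_UNIT_SCALE)}")
    out = np.pi * (dbh_arr / 2.0) ** 2 * _UNIT_SCALE[units]
    return float(out) if np.isscalar(dbh) or dbh_arr.ndim == 0 else out


def count_parameters(J: int, K: int) -> int:
    """Number of model parameters: J intercepts + J DBH slopes + sigma^2 + J*K lambdas."""
    if J < 1 or K < 1:
        raise ValueError("J and K must be >= 1")
    return 2 * J + 1 + J * K


def neighbor_contributions(
    focal_xy: np.ndarray,
    focal_tags: Sequence,
    comp_xy: np.ndarray,
    comp_tags: Sequence,
    comp_dbh: np.ndarray,
    cfg: Optional[NeighborhoodConfig] = None,
) -> sparse.csr_matrix:
    """Sparse (n_focal x n_competitor) matrix of within-radius basal areas.

    Entry (i, c) is the basal area of competitor stem c if it lies within the
    neighborhood of focal i and is not the focal stem itself (same tag);
    zero otherwise.  This factorisation lets the per-group BA matrix be
    rebuilt for any (permuted) labelling with a single sparse product.
    """
    cfg = cfg or NeighborhoodConfig()
    focal_xy = np.asarray(focal_xy, dtype=float)
    comp_xy = np.asarray(comp_xy, dtype=float)
    comp_dbh = np.asarray(comp_dbh, dtype=float)
    n_f, n_c = focal_xy.shape[0], comp_xy.shape[0]
    if n_f == 0 or n_c == 0:
        return sparse.csr_matrix((n_f, n_c))

    ba = basal_area(comp_dbh, cfg.ba_units)
    tree = cKDTree(comp_xy)
    # cKDTree uses <=, matching the include-boundary convention; for strict <
    # shrink by one ulp.
    r = cfg.radius if cfg.include_boundary_equal else np.nextafter(cfg.radius, 0.0)
    hits = tree.query_ball_point(focal_xy, r)

    comp_tag_arr = np.asarray(comp_tags)
    focal_tag_arr = np.asarray(focal_tags)
    rows, cols, vals = [], [], []
    for i, idx in enumerate(hits):
        for c in idx:
            if comp_tag_arr[c] == focal_tag_arr[i]:
                continue  # self-exclusion by tag only
            rows.append(i)
            cols.append(c)
            vals.append(ba[c])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n_f, n_c))


def group_ba(contrib: sparse.csr_matrix, comp_group_idx: np.ndarray, K: int) -> np.ndarray:
    """Collapse per-stem contributions to the n x K per-group BA matrix."""
    comp_group_idx = np.asarray(comp_group_idx, dtype=int)
    n_c = contrib.shape[1]
    onehot = sparse.csr_matrix(
        (np.ones(n_c), (np.arange(n_c), comp_group_idx)), shape=(n_c, K)
    )
    return np.asarray((contrib @ onehot).todense())


def ba_matrix(
    focal_xy: np.ndarray,
    focal_tags: Sequence,
    competitors,
    grouping,
    cfg: Optional[NeighborhoodConfig] = None,
) -> np.ndarray:
    """Per-focal-tree, per-competitor-group summed basal area within radius.

    ``competitors`` is a DataFrame with tag, species, x, y, dbh columns;
    ``grouping`` a GroupingScheme assigning each competitor species a group.
    Columns follow ``grouping.labels`` order.
    """
    cfg = cfg or NeighborhoodConfig()
    comp_xy = competitors[["x", "y"]].to_numpy(dtype=float)
    contrib = neighbor_contributions(
        focal_xy, focal_tags, comp_xy, competitors["tag"].to_numpy(),
        competitors["dbh"].to_numpy(dtype=float), cfg,
    )
    idx = grouping.group_indices(competitors["species"])
    return group_ba(contrib, idx, grouping.J)


@dataclass
class DesignMatrix:
    """Group-blocked regression design.

    Column order: intercept_<g> for each focal group, dbh_<g> for each group,
    then lambda_<g>,<k> for every focal-group / competitor-group pair.  Each
    row is nonzero only inside its focal group's blocks.
    """

    X: object  # ndarray or scipy.sparse
    columns: list
    row_tags: np.ndarray
    group_labels: list
    comp_labels: list
    focal_group_idx: np.ndarray = field(repr=False, default=None)

    @property
    def J(self) -> int:
        return len(self.group_labels)

    @property
    def K(self) -> int:
        return len(self.comp_labels)

    @property
    def shape(self):
        return self.X.shape

    def toarray(self) -> np.ndarray:
        if sparse.issparse(self.X):
            return np.asarray(self.X.todense())
        return np.asarray(self.X)


def design_columns(group_labels: Sequence, comp_labels: Sequence) -> list:
    cols = [f"beta0[{g}]" for g in group_labels]
    cols += [f"beta_dbh[{g}]" for g in group_labels]
    for g in group_labels:
        cols += [f"lambda[{g},{k}]" for k in comp_labels]
    return cols


def assemble_design(
    dbh0: np.ndarray,
    ba: np.ndarray,
    focal_group_idx: np.ndarray,
    J: int,
    as_sparse: bool = False,
):
    """Raw design assembly from focal DBH, BA matrix and group indices."""
    dbh0 = np.asarray(dbh0, dtype=float)
    ba = np.atleast_2d(np.asarray(ba, dtype=float))
    g = np.asarray(focal_group_idx, dtype=int)
    n, K = ba.shape
    p = 2 * J + J * K
    rows = np.arange(n)
    if as_sparse:
        r = np.concatenate([rows, rows] + [rows] * K)
        c = np.concatenate(
            [g, J + g] + [2 * J + g * K + k for k in range(K)]
        )
        v = np.concatenate([np.ones(n), dbh0] + [ba[:, k] for k in range(K)])
        return sparse.csr_matrix((v, (r, c)), shape=(n, p))
    X = np.zeros((n, p))
    X[rows, g] = 1.0
    X[rows, J + g] = dbh0
    for k in range(K):
        X[rows, 2 * J + g * K + k] = ba[:, k]
    return X


def build_design(dataset, as_sparse: bool = False) -> DesignMatrix:
    """Build the full block design from a GrowthDataset.

    One joint regression with a shared sigma^2: p = 2J + J*K columns, so the
    parameter count is p + 1.
    """
    group_labels = dataset.group_labels
    comp_labels = dataset.ba_columns
    J, K = len(group_labels), len(comp_labels)
    if dataset.ba.shape[1] != K:
        raise ValueError("BA matrix width does not match competitor group count")
    label_to_idx = {lab: i for i, lab in enumerate(group_labels)}
    try:
        g = np.array([label_to_idx[lab] for lab in dataset.frame["focal_group"]])
    except KeyError as exc:
        raise ValueError(f"focal group label {exc} not in grouping scheme") from exc
    X = assemble_design(
        dataset.frame["dbh0"].to_numpy(dtype=float), dataset.ba, g, J, as_sparse
    )
    return DesignMatrix(
        X=X,
        columns=design_columns(group_labels, comp_labels),
        row_tags=dataset.frame["focal_tag"].to_numpy(),
        group_labels=list(group_labels),
        comp_labels=list(comp_labels),
        focal_group_idx=g,
    )
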