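"""End-to-end assembly: censuses -> growth dataset -> fitted growth model.

``assemble`` wires the census, grouping and neighborhood modules together and
keeps the per-stem contribution matrix around so that permutation tests can
rebuild the per-group BA covariates for relabelled competitors without
re-running the spatial search.

``NeighborhoodGrowthModel`` is the user-facing estimator: given a grouping
scheme and prior hyperparameters it fits the joint group-blocked growth
regression by exact conjugate update and exposes fitted values, in-sample
RMSE and the coefficient table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .bayes import (
    BayesianLinearRegression,
    FitResult,
    NIGParams,
    nig_update,
    predictive_marginals,
    rmse,
)
from .census import CensusTable, GrowthDataset, annual_growth, select_competitors, select_focal
from .grouping import GroupingScheme
from .neighborhood import (
    DesignMatrix,
    NeighborhoodConfig,
    build_design,
    group_ba,
    neighbor_contributions,
)

__all__ = ["AssembledData", "assemble", "build_growth_dataset", "fit_growth_model",
           "NeighborhoodGrowthModel"]


@dataclass
class AssembledData:
    """A GrowthDataset plus the raw focal x competitor-stem links behind it."""

    dataset: GrowthDataset
    contrib: sparse.csr_matrix
    comp_species: np.ndarray
    comp_tags: np.ndarray
    grouping: GroupingScheme
    config: NeighborhoodConfig

    def ba_for_labels(self, comp_group_idx: np.ndarray) -> np.ndarray:
        """Rebuild the n x K BA matrix for an arbitrary competitor labelling."""
        return group_ba(self.contrib, comp_group_idx, self.grouping.J)


def _main_stems(alive: pd.DataFrame) -> pd.DataFrame:
    """One growth observation per individual: keep the largest-DBH stem.

    Multi-stemmed individuals (shared ``tree_id``) contribute every stem to
    competition but only their main stem as a focal observation.  Ties break
    on tag for determinism.
    """
    if "tree_id" not in alive.columns or alive["tree_id"].isna().all():
        return alive
    key = alive["tree_id"].fillna(alive["tag"])
    order = alive.assign(_k=key).sort_values(
        ["_k", "dbh", "tag"], ascending=[True, False, True]
    )
    return order.drop_duplicates("_k").drop(columns="_k").sort_index()


def assemble(
    c1: CensusTable,
    c2: CensusTable,
    grouping: GroupingScheme,
    cfg: Optional[NeighborhoodConfig] = None,
    edge_buffer: float = 0.0,
) -> AssembledData:
    """Build the model-ready dataset from a census pair and a grouping.

    Focal trees are stems alive in both censuses (main stem per individual);
    competitors are all stems alive at the first census.  ``edge_buffer > 0``
    drops focal trees within that distance of the plot boundary; the default
    keeps them with truncated neighborhoods.
    """
    cfg = cfg or NeighborhoodConfig()
    focal_tags = select_focal(c1, c2)
    comp_tags = select_competitors(c1)

    d1 = c1.data.set_index("tag")
    alive1 = c1.alive()
    focal_rows = _main_stems(alive1[alive1["tag"].isin(focal_tags)])
    if edge_buffer > 0:
        xmin, xmax, ymin, ymax = c1.plot_extent
        keep = (
            (focal_rows["x"] >= xmin + edge_buffer)
            & (focal_rows["x"] <= xmax - edge_buffer)
            & (focal_rows["y"] >= ymin + edge_buffer)
            & (focal_rows["y"] <= ymax - edge_buffer)
        )
        focal_rows = focal_rows[keep]
    focal_rows = focal_rows.sort_values("tag").reset_index(drop=True)

    growth = annual_growth(c1, c2, focal_rows["tag"])
    y = growth.loc[focal_rows["tag"]].to_numpy()

    comp = alive1[alive1["tag"].isin(comp_tags)].reset_index(drop=True)
    contrib = neighbor_contributions(
        focal_rows[["x", "y"]].to_numpy(dtype=float),
        focal_rows["tag"].to_numpy(),
        comp[["x", "y"]].to_numpy(dtype=float),
        comp["tag"].to_numpy(),
        comp["dbh"].to_numpy(dtype=float),
        cfg,
    )
    comp_idx = grouping.group_indices(comp["species"])
    ba = group_ba(contrib, comp_idx, grouping.J)

    frame = pd.DataFrame(
        {
            "focal_tag": focal_rows["tag"].to_numpy(),
            "y": y,
            "dbh0": focal_rows["dbh"].to_numpy(dtype=float),
            "focal_group": [grouping.group_of(s) for s in focal_rows["species"]],
            "x": focal_rows["x"].to_numpy(dtype=float),
            "y_coord": focal_rows["y"].to_numpy(dtype=float),
        }
    )
    dataset = GrowthDataset(
        frame=frame, ba=ba, ba_columns=grouping.labels, group_labels=grouping.labels
    )
    return AssembledData(
        dataset=dataset, contrib=contrib,
        comp_species=comp["species"].to_numpy(), comp_tags=comp["tag"].to_numpy(),
        grouping=grouping, config=cfg,
    )


def build_growth_dataset(
    c1: CensusTable,
    c2: CensusTable,
    grouping: GroupingScheme,
    cfg: Optional[NeighborhoodConfig] = None,
    edge_buffer: float = 0.0,
) -> GrowthDataset:
    return assemble(c1, c2, grouping, cfg, edge_buffer).dataset


def fit_growth_model(
    dataset: GrowthDataset,
    prior: Optional[NIGParams] = None,
    mu0=0.0,
    V0=100.0,
    a0: float = 0.01,
    b0: float = 0.01,
    as_sparse: bool = False,
) -> FitResult:
    """Fit the joint growth regression; returns posterior + fitted values."""
    design = build_design(dataset, as_sparse=as_sparse)
    p = design.shape[1]
    if prior is None:
        mu0_arr = np.asarray(mu0, dtype=float)
        if mu0_arr.ndim == 0:
            mu0_arr = np.full(p, float(mu0_arr))
        prior = NIGParams(mu0_arr, V0, a0, b0)
    post = nig_update(prior, design.X, dataset.y)
    fitted, _, _ = predictive_marginals(post, design.X)
    return FitResult(
        posterior=post, fitted=fitted,
        rmse_insample=rmse(dataset.y, fitted), columns=design.columns,
    )


class NeighborhoodGrowthModel(BaseEstimator):
    """Neighborhood competition growth model as a sklearn-style estimator.

    fit(dataset) builds the group-blocked design for the dataset's grouping
    and performs the exact conjugate NIG update.  predict(dataset) returns
    posterior-predictive mean growth for (possibly new) focal trees whose
    BA covariates were computed under the same grouping.
    """

    def __init__(self, mu0=0.0, V0=100.0, a0=0.01, b0=0.01):
        self.mu0 = mu0
        self.V0 = V0
        self.a0 = a0
        self.b0 = b0

    def fit(self, dataset: GrowthDataset, y=None):
        result = fit_growth_model(
            dataset, mu0=self.mu0, V0=self.V0, a0=self.a0, b0=self.b0
        )
        self.result_ = result
        self.posterior_ = result.posterior
        self.coef_ = result.posterior.mu
        self.columns_ = result.columns
        self.fitted_ = result.fitted
        self.rmse_insample_ = result.rmse_insample
        self.group_labels_ = list(dataset.group_labels)
        self.ba_columns_ = list(dataset.ba_columns)
        return self

    def predict(self, dataset: GrowthDataset) -> np.ndarray:
        check_is_fitted(self, "posterior_")
        if list(dataset.group_labels) != self.group_labels_:
            raise ValueError("dataset grouping does not match the fitted model")
        design = build_design(dataset)
        loc, _, _ = predictive_marginals(self.posterior_, design.X)
        return loc

    def score(self, dataset: GrowthDataset, y=None) -> float:
        """Negative RMSE (sklearn convention: greater is better)."""
        return -rmse(dataset.y, self.predict(dataset))

    def coef_table(self) -> pd.DataFrame:
        check_is_fitted(self, "result_")
        return self.result_.coef_table()
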