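"""Species grouping schemes: actual species, family, and trait clusters.

A grouping scheme is a total mapping from species codes to group labels; the
model is fit with the same scheme on the focal and competitor side (J = K).
Trait clusters come from agglomerative hierarchical clustering with average
linkage (UPGMA) on the Euclidean distance between species' trait vectors —
plant height, wood density and specific leaf area — with the tree cut at a
chosen number of groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage


def _cut_tree(Z: np.ndarray, n: int, k: int) -> np.ndarray:
    """Cut a linkage matrix into exactly k groups by replaying merges.

    Applying the first n-k merges (in agglomeration order) guarantees exactly
    k groups even with tied merge heights, and makes successive cuts nested:
    moving from k to k+1 splits exactly one group.
    """
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m in range(n - k):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        new = n + m
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    seen: dict = {}
    return np.array([seen.setdefault(r, len(seen)) for r in roots], dtype=int)

__all__ = [
    "GroupingScheme",
    "scheme_species",
    "scheme_family",
    "cluster_traits",
    "read_trait_table",
    "read_family_lookup",
]

TRAIT_COLUMNS = ["height", "wood_density", "sla"]


@dataclass
class GroupingScheme:
    """A partition of species into groups.

    ``mapping`` is total over the species it covers; ``labels`` fixes the
    group (column) ordering used everywhere downstream.
    """

    name: str
    mapping: Dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    @property
    def labels(self) -> list:
        return sorted(set(self.mapping.values()))

    @property
    def J(self) -> int:
        return len(self.labels)

    def group_of(self, species: str) -> str:
        try:
            return self.mapping[str(species)]
        except KeyError:
            raise KeyError(f"species {species!r} not covered by grouping {self.name!r}")

    def group_indices(self, species: Sequence) -> np.ndarray:
        """Integer group index (into ``labels``) for each species code."""
        idx = {lab: i for i, lab in enumerate(self.labels)}
        missing = sorted({str(s) for s in species} - set(self.mapping))
        if missing:
            raise KeyError(
                f"species not covered by grouping {self.name!r}: {missing}"
            )
        return np.array([idx[self.mapping[str(s)]] for s in species], dtype=int)


def scheme_species(species_list: Sequence) -> GroupingScheme:
    """Identity grouping: every distinct species is its own group."""
    species = sorted({str(s) for s in species_list})
    if not species:
        raise ValueError("species list is empty")
    return GroupingScheme("species", {s: s for s in species})


def scheme_family(species_list: Sequence, family_lookup: Mapping[str, str]) -> GroupingScheme:
    """Group species by phylogenetic family via a species -> family lookup."""
    species = sorted({str(s) for s in species_list})
    if not species:
        raise ValueError("species list is empty")
    lookup = {str(k): str(v) for k, v in dict(family_lookup).items()}
    missing = [s for s in species if s not in lookup]
    if missing:
        raise KeyError(f"species missing from family lookup: {missing}")
    return GroupingScheme("family", {s: lookup[s] for s in species})


def cluster_traits(
    traits: pd.DataFrame, k: int, standardize: bool = True, name: str = "trait"
) -> GroupingScheme:
    """Trait-based grouping: UPGMA hierarchical clustering cut into k groups.

    ``traits`` is indexed by species code with columns height, wood_density,
    sla (any three numeric trait columns are accepted).  Distances are
    Euclidean on z-scored trait values by default; ``standardize=False``
    uses the raw scales, where the largest-magnitude trait dominates.

    The result is deterministic in the input: species are processed in
    lexicographic order and cluster labels are assigned by first occurrence.
    """
    if traits.isna().any().any():
        raise ValueError("trait table contains missing values")
    if len(traits) < 2:
        raise ValueError("need at least 2 species to cluster")
    if not (1 <= k <= len(traits)):
        raise ValueError(f"k must be in [1, {len(traits)}], got {k}")

    traits = traits.sort_index()
    values = traits.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd

    Z = linkage(values, method="average", metric="euclidean")
    raw = _cut_tree(Z, len(traits), k)
    # relabel clusters by first occurrence over lexicographically sorted species
    relabel: Dict[int, str] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = f"C{len(relabel) + 1}"
    mapping = {str(sp): relabel[r] for sp, r in zip(traits.index, raw)}
    return GroupingScheme(name, mapping)


def read_trait_table(path) -> pd.DataFrame:
    """Read a species x trait CSV (species, height, wood_density, sla)."""
    tab = pd.read_csv(path)
    if "species" not in tab.columns:
        raise ValueError("trait table must have a 'species' column")
    missing = [c for c in TRAIT_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    return tab.set_index("species")[TRAIT_COLUMNS].astype(float)


def read_family_lookup(path) -> Dict[str, str]:
    """Read a 2-column species -> family CSV."""
    tab = pd.read_csv(path)
    if not {"species", "family"} <= set(tab.columns):
        raise ValueError("family lookup must have 'species' and 'family' columns")
    return dict(zip(tab["species"].astype(str), tab["family"].astype(str)))
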