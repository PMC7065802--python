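import numpy as np
import pandas as pd
import pytest

from treecomp.census import CensusTable
from treecomp.neighborhood import NeighborhoodConfig
from treecomp.pipeline import assemble
from treecomp.synthetic import SyntheticSpec, simulate_forest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_census(rows, extent=(0.0, 100.0, 0.0, 100.0), date=2009.0, label="c",
                min_dbh=0.0):
    """Build a CensusTable from (tag, species, x, y, dbh, status) tuples."""
    frame = pd.DataFrame(rows, columns=["tag", "species", "x", "y", "dbh", "status"])
    return CensusTable(data=frame, plot_extent=extent, census_label=label,
                       census_date=date, min_dbh=min_dbh)


@pytest.fixture
def toy_pair():
    """Five-stem census pair covering alive/dead/resprout fates."""
    c1 = make_census(
        [
            ("A", "sp1", 10.0, 10.0, 10.0, "alive"),
            ("B", "sp1", 20.0, 20.0, 8.0, "alive"),
            ("C", "sp2", 30.0, 30.0, 6.0, "alive"),
            ("D", "sp2", 40.0, 40.0, 12.0, "alive"),
            ("E", "sp1", 50.0, 50.0, 5.0, "alive"),
        ],
        date=2009.0, label="c1",
    )
    c2 = make_census(
        [
            ("A", "sp1", 10.0, 10.0, 12.0, "alive"),
            ("B", "sp1", 20.0, 20.0, 8.0, "dead"),
            ("C", "sp2", 30.0, 30.0, 6.5, "resprout"),
            ("D", "sp2", 40.0, 40.0, 11.9, "alive"),
            ("E", "sp1", 50.0, 50.0, 6.0, "alive"),
        ],
        date=2014.0, label="c2",
    )
    return c1, c2


@pytest.fixture(scope="session")
def small_forest():
    """One simulated 1-ha forest with its assembled dataset (true grouping)."""
    spec = SyntheticSpec(plot_extent=(0.0, 100.0, 0.0, 100.0), J=3, seed=42)
    c1, c2 = simulate_forest(spec)
    asm = assemble(c1, c2, spec.true_grouping(), NeighborhoodConfig())
    return spec, c1, c2, asm
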