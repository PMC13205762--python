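import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import starscale as ss
from starscale.accumulation import CommunityMatrix


@pytest.fixture
def toy_tree() -> TreeNode:
    """((A:1,B:2):3,C:4); — total branch length 10."""
    return TreeNode.read(["((A:1,B:2):3,C:4);"])


@pytest.fixture
def small_design():
    return ss.make_design(1, 2, 9, 6, 3)


@pytest.fixture
def small_matrix(small_design):
    params = ss.SimulationParams(pool_size=80, depth_mean=600, seed=11)
    return ss.simulate_communities(small_design, params)


def random_toy_matrix(rng, n_taxa=6, n_points=3, n_times=3, n_levels=None):
    """A tiny random community + design for brute-force comparisons."""
    n_levels = n_levels or n_points
    design = ss.make_design(1, 1, n_points, n_times, n_levels)
    meta = design.sample_index()
    counts = pd.DataFrame(
        rng.integers(0, 4, size=(len(meta), n_taxa)),
        index=meta.index,
        columns=[f"t{i + 1}" for i in range(n_taxa)],
    )
    return CommunityMatrix(counts, meta), design


def brute_force_surface(matrix, design):
    """Exhaustive set-union oracle for the nested accumulation surface."""
    rows = []
    meta = matrix.meta
    for lvl in design.area_levels:
        for k, t in enumerate(design.time_points, start=1):
            taxa: set = set()
            for p in lvl.point_ids:
                for month in design.time_points[:k]:
                    sel = (meta["point"] == p) & (meta["time"] == month)
                    sub = matrix.counts.loc[sel]
                    for taxon in matrix.taxa:
                        if (sub[taxon] > 0).any():
                            taxa.add(taxon)
            rows.append(
                {"area_level": lvl.level, "time_months": float(t),
                 "richness": float(len(taxa)), "taxa": taxa}
            )
    return pd.DataFrame(rows)
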