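"""Nested spatiotemporal accumulation of richness and phylogenetic diversity.

The central construction mirrors nested species-area sampling in both
dimensions: for each time length T (the union of months 1..T from the start
of the survey) and each nested area level j, diversity is the richness (or
Faith's PD) of the union of taxa observed over the points of levels 1..j and
months 1..T. Two alternative temporal constructions are provided: the
complete-nested method (mean over every consecutive window of each length)
and temporal islands (one point per independent survey).

Faith's PD follows the root-inclusive convention (the path to the tree root
is counted, matching common picante behaviour); this is switchable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import TreeNode

from .design import SamplingDesign

__all__ = [
    "CommunityMatrix",
    "build_accumulation_surface",
    "complete_nested_curve",
    "island_curve",
    "faith_pd",
    "standardize_depth",
    "pool_counts_by_scale",
]

SURFACE_COLUMNS = [
    "site",
    "treatment",
    "area_level",
    "area_m2",
    "time_months",
    "richness",
    "pd",
    "total_sequences",
]


@dataclass
class CommunityMatrix:
    """Taxon counts per sample plus the sample metadata.

    ``counts``: non-negative integer DataFrame, samples x taxa.
    ``meta``: DataFrame indexed like ``counts`` with columns
    ``site``, ``treatment``, ``point``, ``time``.
    """

    counts: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"site", "treatment", "point", "time"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and metadata must share the same sample index")
        if self.counts.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def plot(self, site: str, treatment: str) -> "CommunityMatrix":
        mask = (self.meta["site"] == site) & (self.meta["treatment"] == treatment)
        if not mask.any():
            raise ValueError(f"no samples for plot ({site!r}, {treatment!r})")
        return CommunityMatrix(self.counts.loc[mask], self.meta.loc[mask])

    @property
    def plots(self) -> list[tuple[str, str]]:
        seen = self.meta[["site", "treatment"]].drop_duplicates()
        return [tuple(r) for r in seen.to_numpy()]


class _TreeIndex:
    """Edge-incidence index of a rooted tree for vectorised Faith's PD.

    Each edge (node with a branch length) is marked as covering the tips of
    its subtree; PD of a taxon set is the branch-length total of edges
    covering at least one member — the root-inclusive convention.
    """

    def __init__(self, tree: TreeNode, taxa: "list[str]"):
        tips = {t.name for t in tree.tips()}
        missing = [t for t in taxa if t not in tips]
        if missing:
            raise ValueError(
                f"{len(missing)} taxa absent from the tree, e.g. {missing[:5]}"
            )
        col = {name: i for i, name in enumerate(taxa)}
        edges: list[float] = []
        rows: list[np.ndarray] = []
        stack: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                cover = np.zeros(len(taxa), dtype=bool)
                if node.name in col:
                    cover[col[node.name]] = True
            else:
                cover = np.zeros(len(taxa), dtype=bool)
                for child in node.children:
                    cover |= stack.pop(id(child))
            stack[id(node)] = cover
            if node.length is not None and node.length != 0 and not node.is_root():
                edges.append(float(node.length))
                rows.append(cover)
            elif not node.is_root() and node.length is None:
                raise ValueError("tree has edges without branch lengths")
        self.lengths = np.asarray(edges, dtype=float)
        self.incidence = (
            np.vstack(rows).astype(float) if rows else np.zeros((0, len(taxa)))
        )

    def pd_of(self, presence: np.ndarray) -> np.ndarray:
        """PD for each row of a boolean (n_sets, n_taxa) presence matrix."""
        covered = presence.astype(float) @ self.incidence.T > 0.5
        return covered @ self.lengths


def faith_pd(taxa, tree: TreeNode, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a taxon set.

    Sum of branch lengths on the union of root-to-tip paths of the set
    (``include_root=True``, default), or of the subtree spanned below the
    set's most recent common ancestor (``include_root=False``). The empty
    set has PD 0; PD of all tips equals the tree's total branch length.
    """
    taxa = list(taxa)
    if not taxa:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    unknown = [t for t in taxa if t not in tip_names]
    if unknown:
        raise ValueError(f"unknown tip(s): {unknown}")
    idx = _TreeIndex(tree, taxa)
    total = float(idx.pd_of(np.ones((1, len(taxa)), dtype=bool))[0])
    if include_root:
        return total
    lca = tree.lca(taxa) if len(taxa) > 1 else tree.find(taxa[0])
    above = 0.0
    node = lca
    while not node.is_root():
        above += float(node.length or 0.0)
        node = node.parent
    return total - above


def _plot_cells(
    matrix: CommunityMatrix,
    design: SamplingDesign,
    site: "str | None",
    treatment: "str | None",
    on_missing: str,
):
    """Per-(area level, time) presence and read totals for one plot.

    Returns (site, treatment, presence[L, K, taxa] bool, reads[L, K]) where
    level entries already pool over that level's (nested) point set but NOT
    yet over time.
    """
    plots = matrix.plots
    if site is None or treatment is None:
        if len(plots) != 1:
            raise ValueError(
                "matrix holds several plots; pass site= and treatment= to select one"
            )
        site, treatment = plots[0]
    sub = matrix.plot(site, treatment)

    times = list(design.time_points)
    expected = {(p, t) for p in design.points.index for t in times}
    have = set(zip(sub.meta["point"], sub.meta["time"]))
    missing = expected - have
    if missing:
        if on_missing == "error":
            raise ValueError(
                f"plot ({site}, {treatment}) is missing {len(missing)} "
                f"(point, time) samples, e.g. {sorted(missing)[:3]}"
            )
        elif on_missing == "skip":
            warnings.warn(
                f"plot ({site}, {treatment}): skipping {len(missing)} missing cells",
                stacklevel=3,
            )
        else:
            raise ValueError("on_missing must be 'error' or 'skip'")

    n_taxa = len(sub.taxa)
    L, K = len(design.area_levels), len(times)
    counts = sub.counts.to_numpy()
    pt = list(zip(sub.meta["point"], sub.meta["time"]))
    presence = np.zeros((L, K, n_taxa), dtype=bool)
    reads = np.zeros((L, K), dtype=np.int64)
    tpos = {t: k for k, t in enumerate(times)}
    for j, lvl in enumerate(design.area_levels):
        members = set(lvl.point_ids)
        rows = [i for i, (p, t) in enumerate(pt) if p in members]
        for i in rows:
            k = tpos[pt[i][1]]
            presence[j, k] |= counts[i] > 0
            reads[j, k] += int(counts[i].sum())
    return site, treatment, presence, reads


def _surface_frame(design, site, treatment, richness, pd_vals, reads, method):
    L, K = richness.shape
    jj, kk = np.meshgrid(np.arange(L), np.arange(K), indexing="ij")
    out = pd.DataFrame(
        {
            "site": site,
            "treatment": treatment,
            "area_level": jj.ravel() + 1,
            "area_m2": design.area_sizes[jj.ravel()],
            "time_months": np.asarray(design.time_points, dtype=float)[kk.ravel()]
            if K == len(design.time_points)
            else kk.ravel() + 1.0,
            "richness": richness.ravel().astype(float),
            "pd": pd_vals.ravel() if pd_vals is not None else np.nan,
            "total_sequences": reads.ravel().astype(float)
            if reads is not None
            else np.nan,
        }
    )
    out.attrs["temporal_method"] = method
    return out


def build_accumulation_surface(
    matrix: CommunityMatrix,
    design: SamplingDesign,
    tree: "TreeNode | None" = None,
    temporal_method: str = "nested",
    site: "str | None" = None,
    treatment: "str | None" = None,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Nested richness/PD accumulation surface for one plot.

    Row (j, T): diversity of the taxa observed over area levels 1..j and
    months 1..T; monotone non-decreasing along both axes by construction.
    ``temporal_method='complete_nested'`` instead averages every consecutive
    window of each length (see :func:`complete_nested_curve`).
    """
    if temporal_method == "complete_nested":
        return complete_nested_curve(
            matrix, design, tree, site=site, treatment=treatment, on_missing=on_missing
        )
    if temporal_method == "island":
        raise ValueError(
            "the island method needs a list of independent surveys; use island_curve"
        )
    if temporal_method != "nested":
        raise ValueError(f"unknown temporal_method {temporal_method!r}")

    site, treatment, presence, reads = _plot_cells(
        matrix, design, site, treatment, on_missing
    )
    cum = np.logical_or.accumulate(presence, axis=1)  # over time
    richness = cum.sum(axis=2)
    reads_cum = np.cumsum(reads, axis=1)
    pd_vals = None
    if tree is not None:
        idx = _TreeIndex(tree, matrix.taxa)
        pd_vals = idx.pd_of(cum.reshape(-1, cum.shape[2])).reshape(richness.shape)
    return _surface_frame(design, site, treatment, richness, pd_vals, reads_cum, "nested")


def complete_nested_curve(
    matrix: CommunityMatrix,
    design: SamplingDesign,
    tree: "TreeNode | None" = None,
    site: "str | None" = None,
    treatment: "str | None" = None,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Complete-nested temporal accumulation: mean over consecutive windows.

    For window length T the value is the mean cumulative diversity over all
    K - T + 1 windows of consecutive months; at T = K it equals the nested
    method's terminal value.
    """
    if len(design.time_points) < 2:
        raise ValueError("complete-nested accumulation needs >= 2 timepoints")
    site, treatment, presence, _ = _plot_cells(
        matrix, design, site, treatment, on_missing
    )
    L, K, n_taxa = presence.shape
    idx = _TreeIndex(tree, matrix.taxa) if tree is not None else None
    rich_sum = np.zeros((L, K))
    pd_sum = np.zeros((L, K)) if idx is not None else None
    for start in range(K):
        cum = np.logical_or.accumulate(presence[:, start:, :], axis=1)
        w = cum.shape[1]
        rich_sum[:, :w] += cum.sum(axis=2)
        if idx is not None:
            pd_sum[:, :w] += idx.pd_of(cum.reshape(-1, n_taxa)).reshape(L, w)
    n_windows = np.arange(K, 0, -1, dtype=float)[None, :]
    richness = rich_sum / n_windows
    pd_vals = pd_sum / n_windows if pd_sum is not None else None
    out = _surface_frame(design, site, treatment, richness, pd_vals, None, "complete_nested")
    out["time_months"] = np.tile(np.arange(1, K + 1, dtype=float), L)
    return out


def island_curve(surveys, tree: "TreeNode | None" = None) -> pd.DataFrame:
    """Temporal-island diversity: one (duration, richness[, pd]) per survey.

    ``surveys`` is a list of (duration, counts) where counts is a
    samples x taxa DataFrame (or a CommunityMatrix) pooled over one survey.
    """
    rows = []
    for duration, counts in surveys:
        if isinstance(counts, CommunityMatrix):
            counts = counts.counts
        if counts.shape[0] == 0 or counts.to_numpy().sum() == 0:
            raise ValueError(f"survey of duration {duration} is empty")
        present = counts.sum(axis=0) > 0
        row = {
            "time_months": float(duration),
            "richness": float(present.sum()),
            "pd": np.nan,
            "total_sequences": float(counts.to_numpy().sum()),
        }
        if tree is not None:
            row["pd"] = faith_pd(list(counts.columns[present]), tree)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["temporal_method"] = "island"
    return out


def pool_counts_by_scale(
    matrix: CommunityMatrix,
    design: SamplingDesign,
    axis: str = "time",
    site: "str | None" = None,
    treatment: "str | None" = None,
) -> pd.DataFrame:
    """Pooled taxon counts per nested scale (for depth standardization).

    ``axis='time'``: scale k pools months 1..k over all points;
    ``axis='area'``: scale j pools the points of levels 1..j over all months.
    """
    plots = matrix.plots
    if site is None or treatment is None:
        if len(plots) != 1:
            raise ValueError("pass site= and treatment= to select a plot")
        site, treatment = plots[0]
    sub = matrix.plot(site, treatment)
    rows = {}
    if axis == "time":
        for k, t in enumerate(design.time_points, start=1):
            sel = sub.meta["time"].isin(design.time_points[:k])
            rows[k] = sub.counts.loc[sel].sum(axis=0)
    elif axis == "area":
        for lvl in design.area_levels:
            sel = sub.meta["point"].isin(lvl.point_ids)
            rows[lvl.level] = sub.counts.loc[sel].sum(axis=0)
    else:
        raise ValueError("axis must be 'time' or 'area'")
    out = pd.DataFrame(rows).T
    out.index.name = "scale"
    return out


def _expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form expected richness of a hypergeometric subsample."""
    counts = counts[counts > 0]
    total = counts.sum()

    def ln_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    absent = np.zeros(len(counts))
    ok = total - counts >= depth
    absent[ok] = np.exp(ln_choose(total - counts[ok], depth) - ln_choose(total, depth))
    return float(len(counts) - absent.sum())


def standardize_depth(
    pooled_counts: pd.DataFrame,
    target_depth: int,
    n_reps: int = 100,
    seed: "int | None" = None,
    tree: "TreeNode | None" = None,
) -> pd.DataFrame:
    """Depth-standardized diversity per scale (passive-sampling control).

    For each scale (row of ``pooled_counts``), draws ``n_reps`` subsamples of
    ``target_depth`` reads without replacement and reports the mean rarefied
    richness (and PD when a tree is given) alongside the closed-form
    (hypergeometric) expected richness.
    """
    totals = pooled_counts.sum(axis=1)
    if (totals < target_depth).any():
        low = totals[totals < target_depth].index.tolist()
        raise ValueError(
            f"target_depth {target_depth} exceeds pooled total at scale(s) {low}"
        )
    rng = np.random.default_rng(seed)
    idx = _TreeIndex(tree, list(pooled_counts.columns)) if tree is not None else None
    rows = []
    for scale, row in pooled_counts.iterrows():
        vec = row.to_numpy().astype(np.int64)
        rich, pds = [], []
        for _ in range(n_reps):
            sub = rng.multivariate_hypergeometric(vec, target_depth)
            present = sub > 0
            rich.append(int(present.sum()))
            if idx is not None:
                pds.append(float(idx.pd_of(present[None, :])[0]))
        rows.append(
            {
                "scale": scale,
                "depth": int(vec.sum()),
                "richness_observed": int((vec > 0).sum()),
                "richness_rarefied": float(np.mean(rich)),
                "richness_expected": _expected_rarefied_richness(vec, target_depth),
                "pd_rarefied": float(np.mean(pds)) if pds else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("scale")
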