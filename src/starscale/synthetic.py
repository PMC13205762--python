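"""Synthetic community, tree, trait, and soil-property generators.

These emulate the statistical structure the downstream scaling analysis
assumes: a regional log-normal abundance pool, Gaussian-kernel spatial
similarity decaying with distance between sampling points, Markov taxon
replacement over months, an optional homogenization knob that shrinks
between-point compositional variance (the mechanism attributed to intensive
monoculture cropping), and multinomial read sampling at a controllable depth.

Random streams: each generator consumes a single root seed; plot-level
substreams are derived with ``numpy.random.SeedSequence(seed, spawn_key=...)``
so per-plot data are independently reproducible.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .design import SamplingDesign

__all__ = [
    "SimulationParams",
    "simulate_tree",
    "simulate_communities",
    "simulate_star_surface",
    "simulate_soil_table",
    "assign_rrn_traits",
]


@dataclass
class SimulationParams:
    """Knobs of the community generator.

    Parameters
    ----------
    pool_size : regional pool richness (taxa).
    abundance_sigma : log-normal shape of pool abundances (0 = even pool).
    spatial_decay : per-metre decay rate of between-point composition
        correlation (0 = identical expected composition at all points).
    temporal_turnover : per-month probability that a taxon's local state is
        replaced by a fresh draw (0 = static composition).
    homogenization : in [0, 1]; fraction by which between-point and
        between-month compositional variance is shrunk (1 = all points of a
        plot share one static composition), emulating the loss of spatial
        and temporal environmental heterogeneity under monoculture.
    depth_mean : expected reads per sample (Poisson).
    seed : root seed of the generator.
    spatial_sd, temporal_sd : log-scale magnitudes of the spatial and
        temporal abundance fields.
    """

    pool_size: int = 2000
    abundance_sigma: float = 1.5
    spatial_decay: float = 0.05
    temporal_turnover: float = 0.25
    homogenization: float = 0.0
    depth_mean: float = 10_000.0
    seed: int = 0
    spatial_sd: float = 1.0
    temporal_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        for name in ("temporal_turnover", "homogenization"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spatial_decay < 0:
            raise ValueError("spatial_decay must be >= 0")
        if self.abundance_sigma < 0 or self.spatial_sd < 0 or self.temporal_sd < 0:
            raise ValueError("scale parameters must be >= 0")


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random rooted binary tree with exponential branch lengths.

    Tips are labelled ``t1 .. t<n_taxa>``. Built by a random-join (pure birth
    backwards) process: lineages are merged in random pairs with exponential
    waiting times, so every branch length is strictly positive. The same seed
    yields a byte-identical Newick string.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    active: list[tuple[TreeNode, float]] = [
        (TreeNode(name=f"t{i + 1}"), 0.0) for i in range(n_taxa)
    ]
    height = 0.0
    while len(active) > 1:
        height += rng.exponential(1.0 / len(active))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (a, ha), (b, hb) = active[i], active[j]
        a.length = height - ha
        b.length = height - hb
        parent = TreeNode(children=[a, b])
        active[i] = (parent, height)
        del active[j]
    root = active[0][0]
    root.length = None
    return root


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def _plot_composition(
    design: SamplingDesign, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Latent relative abundances, shape (n_points, n_times, pool_size)."""
    n_p = len(design.points)
    n_t = len(design.time_points)
    n = params.pool_size

    log_pool = params.abundance_sigma * rng.standard_normal(n)

    # Spatially correlated log-abundance field over points (exponential
    # kernel on the point coordinates; decay 0 => perfectly shared field).
    if params.spatial_decay == 0.0 or n_p == 1:
        g = np.tile(rng.standard_normal(n), (n_p, 1))
    else:
        xy = design.points[["x", "y"]].to_numpy()
        d = np.hypot(
            xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1]
        )
        cov = np.exp(-params.spatial_decay * d) + 1e-10 * np.eye(n_p)
        chol = np.linalg.cholesky(cov)
        g = chol @ rng.standard_normal((n_p, n))
    g_mean = g.mean(axis=0, keepdims=True)
    g = g_mean + (1.0 - params.homogenization) * (g - g_mean)

    # Markov temporal field shared by all points of the plot: each month a
    # taxon's state is replaced with probability `temporal_turnover`.
    # Homogenization shrinks this field toward its time-mean too: the knob
    # models loss of environmental heterogeneity in both dimensions.
    e = np.empty((n_t, n))
    e[0] = rng.standard_normal(n)  # stationary initial state of the chain
    for t in range(1, n_t):
        fresh = rng.standard_normal(n)
        replace = rng.random(n) < params.temporal_turnover
        e[t] = np.where(replace, fresh, e[t - 1])
    e_mean = e.mean(axis=0, keepdims=True)
    e = e_mean + (1.0 - params.homogenization) * (e - e_mean)

    logw = (
        log_pool[None, None, :]
        + params.spatial_sd * g[:, None, :]
        + params.temporal_sd * e[None, :, :]
    )
    w = np.exp(logw - logw.max(axis=2, keepdims=True))
    return w / w.sum(axis=2, keepdims=True)


def simulate_communities(
    design: SamplingDesign,
    params: SimulationParams,
    params_by_treatment: "dict[str, SimulationParams] | None" = None,
    return_composition: bool = False,
):
    """Simulate a taxa-count table for every sample of ``design``.

    Returns a :class:`~starscale.accumulation.CommunityMatrix` (counts are
    multinomial reads at Poisson depth around ``depth_mean``). With
    ``return_composition=True`` also returns the latent relative-abundance
    array, a dict mapping (site, treatment) to an array of shape
    (n_points, n_times, pool_size) — compositions are exact, so e.g.
    ``homogenization=1`` gives identical composition at all points.

    ``params_by_treatment`` overrides the generator knobs per treatment label
    (e.g. a homogenized cropping treatment vs. a fallow control); the random
    substreams are still derived from ``params.seed``.
    """
    from .accumulation import CommunityMatrix  # cycle guard

    params_by_treatment = params_by_treatment or {}
    for label in params_by_treatment:
        if label not in design.treatments:
            raise ValueError(f"unknown treatment label {label!r}")

    meta = design.sample_index()
    taxa = [f"t{i + 1}" for i in range(params.pool_size)]
    counts = np.zeros((len(meta), params.pool_size), dtype=np.int64)
    comps: dict[tuple[str, str], np.ndarray] = {}

    point_pos = {p: i for i, p in enumerate(design.points.index)}
    time_pos = {t: i for i, t in enumerate(design.time_points)}

    for k, (site, trt) in enumerate(design.plots):
        p = params_by_treatment.get(trt, params)
        rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(k,)))
        comp = _plot_composition(design, p, rng)
        comps[(site, trt)] = comp
        mask = (meta["site"] == site) & (meta["treatment"] == trt)
        for row in np.flatnonzero(mask.to_numpy()):
            ip = point_pos[meta["point"].iloc[row]]
            it = time_pos[meta["time"].iloc[row]]
            depth = max(1, rng.poisson(p.depth_mean))
            counts[row] = rng.multinomial(depth, comp[ip, it])

    matrix = CommunityMatrix(
        counts=pd.DataFrame(counts, index=meta.index, columns=taxa),
        meta=meta,
    )
    if return_composition:
        return matrix, comps
    return matrix


def simulate_star_surface(
    z: float,
    w: float,
    u: float,
    b: float,
    noise_sd: float,
    area_sizes,
    time_lengths,
    seed: "int | None" = None,
    response: str = "richness",
    site: str = "site1",
    treatment: str = "trt1",
) -> pd.DataFrame:
    """Accumulation surface drawn from the interaction power-law model.

    ln S = z ln A + w ln T + u ln A ln T + b + N(0, noise_sd), reported on the
    natural scale, over the full area x time grid. A noise-free surface is an
    exact fixture: refitting recovers (z, w, u, b) to machine precision.
    """
    area_sizes = np.asarray(area_sizes, dtype=float)
    time_lengths = np.asarray(time_lengths, dtype=float)
    if np.any(area_sizes <= 0) or np.any(time_lengths <= 0):
        raise ValueError("area sizes and time lengths must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if response not in ("richness", "pd"):
        raise ValueError("response must be 'richness' or 'pd'")

    rng = np.random.default_rng(seed)
    la = np.log(area_sizes)[:, None]
    lt = np.log(time_lengths)[None, :]
    ln_s = z * la + w * lt + u * la * lt + b
    if noise_sd > 0:
        ln_s = ln_s + rng.normal(0.0, noise_sd, size=ln_s.shape)

    jj, kk = np.meshgrid(
        np.arange(len(area_sizes)), np.arange(len(time_lengths)), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "site": site,
            "treatment": treatment,
            "area_level": jj.ravel() + 1,
            "area_m2": area_sizes[jj.ravel()],
            "time_months": time_lengths[kk.ravel()],
            "richness": np.nan,
            "pd": np.nan,
            "total_sequences": np.nan,
        }
    )
    df[response] = np.exp(ln_s).ravel()
    df.attrs["temporal_method"] = "nested"
    return df


def simulate_soil_table(
    design: SamplingDesign,
    property_means: dict,
    property_sds: dict,
    treatment_variance_factor: float = 1.0,
    treated_treatment: "str | None" = None,
    seed: int = 0,
    residual_frac: float = 0.2,
) -> pd.DataFrame:
    """Sample x property soil table with treatment-dependent heterogeneity.

    Each value is mean + point effect + time effect + residual; for the
    treated treatment (default: the last treatment in the design) all three
    dispersion components are scaled by ``treatment_variance_factor``, so a
    factor < 1 shrinks both spatial and temporal CV of every property.
    """
    if treatment_variance_factor <= 0:
        raise ValueError("treatment_variance_factor must be > 0")
    if set(property_means) != set(property_sds):
        raise ValueError("property_means and property_sds must share keys")
    if any(sd <= 0 for sd in property_sds.values()):
        raise ValueError("property sds must be positive")
    treated = treated_treatment if treated_treatment is not None else design.treatments[-1]
    if treated not in design.treatments:
        raise ValueError(f"unknown treatment label {treated!r}")

    meta = design.sample_index()
    props = sorted(property_means)
    out = pd.DataFrame(index=meta.index, columns=props, dtype=float)
    n_p, n_t = len(design.points), len(design.time_points)

    for k, (site, trt) in enumerate(design.plots):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        factor = treatment_variance_factor if trt == treated else 1.0
        mask = ((meta["site"] == site) & (meta["treatment"] == trt)).to_numpy()
        sub = meta.loc[mask]
        ip = sub["point"].map({p: i for i, p in enumerate(design.points.index)})
        it = sub["time"].map({t: i for i, t in enumerate(design.time_points)})
        for prop in props:
            sd = property_sds[prop] * factor
            pe = rng.normal(0.0, sd, n_p)
            te = rng.normal(0.0, sd, n_t)
            eps = rng.normal(0.0, residual_frac * sd, mask.sum())
            out.loc[mask, prop] = (
                property_means[prop] + pe[ip.to_numpy()] + te[it.to_numpy()] + eps
            )
    return out


def assign_rrn_traits(
    taxon_ids,
    group_labels,
    group_means: dict,
    seed: int = 0,
    jitter_sd: float = 0.15,
) -> pd.DataFrame:
    """Assign each taxon an rrn copy number near its group's mean.

    Copies are ``max(1, mean * exp(jitter_sd * N(0,1)))``; ``jitter_sd=0``
    yields exactly the group mean. Returns a DataFrame indexed by taxon with
    columns ``group`` and ``copy_number``.
    """
    taxon_ids = list(taxon_ids)
    group_labels = list(group_labels)
    if len(taxon_ids) != len(group_labels):
        raise ValueError("taxon_ids and group_labels must align")
    if any(m < 1 for m in group_means.values()):
        raise ValueError("group mean copy numbers must be >= 1")
    unknown = set(group_labels) - set(group_means)
    if unknown:
        raise KeyError(f"unknown group label(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    means = np.array([group_means[g] for g in group_labels], dtype=float)
    copies = np.maximum(1.0, means * np.exp(jitter_sd * rng.standard_normal(len(means))))
    return pd.DataFrame(
        {"group": group_labels, "copy_number": copies},
        index=pd.Index(taxon_ids, name="taxon"),
    )
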