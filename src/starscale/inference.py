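"""Significance testing and effect sizes for spatiotemporal scaling fits.

Model and exponent significance use restricted block permutations: the
ordered temporal and spatial scale labels are grouped into blocks of three
consecutive scales and permuted as intact units (preserving local
dependence), the interaction model is refit per permutation, and p-values
come from the null distributions of R² (upper tail) and |exponent|
(two-sided magnitude). The permutation acts on the scale labels of the
built accumulation surface, not on raw samples.

Treatment and soil-texture contrasts are estimated on moving-window model
families (every window of 5-14 months, step 1) with linear mixed models,
ln-response ratios, and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .accumulation import CommunityMatrix, _TreeIndex, _plot_cells, build_accumulation_surface
from .design import SamplingDesign
from .scaling import DegenerateDesignError, fit_star_arrays

__all__ = [
    "PermutationResult",
    "EffectSize",
    "block_permutation_test",
    "star_ptar_difference_test",
    "enumerate_windows",
    "fit_window_family",
    "lmm_effect_size",
    "ln_response_ratio",
    "cohens_d",
    "spearman_fdr",
]


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the resulting p-value.

    p = (1 + #{null as-or-more-extreme}) / (1 + n_used), which is always in
    (0, 1]; degenerate null fits are discarded and counted.
    """

    statistic: str
    observed: float
    null: np.ndarray = field(repr=False)
    p_value: float
    n_rand: int
    n_discarded: int
    block_size: int
    seed: "int | None"


@dataclass
class EffectSize:
    """A treatment/soil-texture contrast estimate."""

    method: str
    estimate: float
    se: "float | None"
    p_value: "float | None"
    contrast: str
    converged: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# block permutation machinery
# ---------------------------------------------------------------------------


def _blocks(n: int, block_size: int) -> list[np.ndarray]:
    """Consecutive index blocks; a trailing remainder block is kept intact."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    out = [np.arange(i, min(i + block_size, n)) for i in range(0, n, block_size)]
    if len(out) < 2:
        raise ValueError(
            f"cannot form >= 2 blocks of size {block_size} from {n} scales"
        )
    return out


def _permute_order(blocks: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(len(blocks))
    return np.concatenate([blocks[i] for i in order])


def _surface_grid(surface: pd.DataFrame, response: str):
    """Pivot a complete surface into (ln area levels, ln times, ln S grid)."""
    sub = surface.dropna(subset=[response])
    piv = sub.pivot_table(
        index="area_m2", columns="time_months", values=response, aggfunc="first"
    ).sort_index(axis=0).sort_index(axis=1)
    if piv.isna().any().any():
        raise ValueError("surface is not a complete area x time grid")
    if (piv.to_numpy() <= 0).any():
        raise ValueError(f"non-positive {response} values; cannot take logs")
    la = np.log(piv.index.to_numpy(dtype=float))
    lt = np.log(piv.columns.to_numpy(dtype=float))
    return la, lt, np.log(piv.to_numpy(dtype=float))


def block_permutation_test(
    data,
    design: "SamplingDesign | None" = None,
    tree=None,
    response: str = "richness",
    n_rand: int = 1000,
    block_size: int = 3,
    seed: "int | None" = None,
    site: "str | None" = None,
    treatment: "str | None" = None,
) -> dict[str, PermutationResult]:
    """Block-permutation significance of the interaction model and exponents.

    ``data`` is either a built accumulation surface (DataFrame) or a
    :class:`CommunityMatrix` (then ``design`` is required and the nested
    surface is built first). Returns results keyed by ``"r_squared"``
    (upper-tail test of model fit) and ``"z"``, ``"w"``, ``"u"``
    (two-sided tests on exponent magnitude).
    """
    if isinstance(data, CommunityMatrix):
        if design is None:
            raise ValueError("design is required when passing a CommunityMatrix")
        surface = build_accumulation_surface(
            data, design, tree=tree, site=site, treatment=treatment
        )
    else:
        surface = data
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")

    la, lt, ln_s = _surface_grid(surface, response)
    a_blocks = _blocks(len(la), block_size)
    t_blocks = _blocks(len(lt), block_size)

    la_grid = np.broadcast_to(la[:, None], ln_s.shape)
    lt_grid = np.broadcast_to(lt[None, :], ln_s.shape)
    beta_obs, r2_obs = fit_star_arrays(
        la_grid.ravel(), lt_grid.ravel(), ln_s.ravel()
    )
    obs = {"r_squared": r2_obs, "z": beta_obs[1], "w": beta_obs[2], "u": beta_obs[3]}

    rng = np.random.default_rng(seed)
    nulls = {k: [] for k in obs}
    discarded = 0
    y = ln_s.ravel()
    for _ in range(n_rand):
        pa = _permute_order(a_blocks, rng)
        pt = _permute_order(t_blocks, rng)
        la_p = np.broadcast_to(la[pa][:, None], ln_s.shape).ravel()
        lt_p = np.broadcast_to(lt[pt][None, :], ln_s.shape).ravel()
        try:
            beta, r2 = fit_star_arrays(la_p, lt_p, y)
        except DegenerateDesignError:
            discarded += 1
            continue
        nulls["r_squared"].append(r2)
        nulls["z"].append(beta[1])
        nulls["w"].append(beta[2])
        nulls["u"].append(beta[3])

    out = {}
    for key, observed in obs.items():
        null = np.asarray(nulls[key])
        n_used = len(null)
        if key == "r_squared":
            extreme = int((null >= observed).sum())
        else:
            extreme = int((np.abs(null) >= abs(observed)).sum())
        out[key] = PermutationResult(
            statistic=key,
            observed=float(observed),
            null=null,
            p_value=(1 + extreme) / (1 + n_used),
            n_rand=n_rand,
            n_discarded=discarded,
            block_size=block_size,
            seed=seed,
        )
    return out


def star_ptar_difference_test(
    surface: pd.DataFrame,
    exponent: str = "w",
    n_rand: int = 1000,
    block_size: int = 3,
    seed: "int | None" = None,
) -> PermutationResult:
    """Permutation contrast of a STAR exponent against its PTAR analog.

    Because both models share one log-log design, the exponent difference
    equals the corresponding coefficient of a single fit to the cell-wise
    difference surface ln S - ln PD. Its null is built by restricted
    residual permutation: residuals of the reduced model (the difference
    fit without the tested term) are permuted in intact blocks of
    ``block_size`` consecutive scales along both axes, the full model is
    refit, and the permuted coefficient recorded; the p-value is two-sided
    on the difference magnitude. Identical richness and PD columns give a
    difference of exactly zero in every draw (p = 1).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if exponent not in ("z", "w", "u"):
        raise ValueError("exponent must be 'z', 'w', or 'u'")
    if surface["pd"].isna().all():
        raise ValueError("surface carries no phylogenetic diversity column")

    la, lt, ln_s = _surface_grid(surface, "richness")
    la2, lt2, ln_p = _surface_grid(surface, "pd")
    if not (np.allclose(la, la2) and np.allclose(lt, lt2)):
        raise ValueError("richness and pd grids do not align")
    pos = {"z": 1, "w": 2, "u": 3}[exponent]
    a_blocks = _blocks(len(la), block_size)
    t_blocks = _blocks(len(lt), block_size)

    delta = ln_s - ln_p
    shape = delta.shape
    la_f = np.broadcast_to(la[:, None], shape).ravel()
    lt_f = np.broadcast_to(lt[None, :], shape).ravel()
    X = np.column_stack([np.ones_like(la_f), la_f, lt_f, la_f * lt_f])

    beta_full, _, _, _ = np.linalg.lstsq(X, delta.ravel(), rcond=None)
    observed = float(beta_full[pos])

    X0 = np.delete(X, pos, axis=1)
    beta0, _, _, _ = np.linalg.lstsq(X0, delta.ravel(), rcond=None)
    fitted0 = (X0 @ beta0).reshape(shape)
    resid0 = delta - fitted0

    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    for i in range(n_rand):
        pa = _permute_order(a_blocks, rng)
        pt = _permute_order(t_blocks, rng)
        delta_star = fitted0 + resid0[np.ix_(pa, pt)]
        beta_star, _, _, _ = np.linalg.lstsq(X, delta_star.ravel(), rcond=None)
        null[i] = float(beta_star[pos])

    extreme = int((np.abs(null) >= abs(observed)).sum())
    return PermutationResult(
        statistic=f"star_ptar_{exponent}_difference",
        observed=observed,
        null=null,
        p_value=(1 + extreme) / (1 + n_rand),
        n_rand=n_rand,
        n_discarded=0,
        block_size=block_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# moving windows
# ---------------------------------------------------------------------------


def enumerate_windows(n_times: int, sizes, step: int = 1) -> list[tuple[int, int]]:
    """All (window size, 1-based start) pairs over a series of ``n_times``.

    A window of size s has n_times - s + 1 starts; sizes larger than the
    series emit a warning and contribute no windows.
    """
    out: list[tuple[int, int]] = []
    for s in sorted(set(int(s) for s in sizes)):
        if s < 2:
            raise ValueError(f"window size must be >= 2, got {s}")
        if s > n_times:
            warnings.warn(f"window size {s} exceeds series length {n_times}; skipped")
            continue
        out.extend((s, start) for start in range(1, n_times - s + 2, step))
    return out


def fit_window_family(
    matrix: CommunityMatrix,
    design: SamplingDesign,
    tree=None,
    sizes=range(5, 15),
    step: int = 1,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Interaction-model fits over every moving time window, for every plot.

    Within each window the nested accumulation restarts at the window's
    first month (time lengths 1..s), giving one STAR fit — and one PTAR fit
    when a tree is supplied — per (plot, window size, start). Degenerate
    window fits are recorded with NaN exponents and a reason.
    """
    K = len(design.time_points)
    windows = enumerate_windows(K, sizes, step)
    if not windows:
        raise ValueError("no feasible windows for this series length")
    la = np.log(design.area_sizes)
    idx = _TreeIndex(tree, matrix.taxa) if tree is not None else None

    records = []
    for site, treatment in matrix.plots:
        _, _, presence, _ = _plot_cells(matrix, design, site, treatment, on_missing)
        L = presence.shape[0]
        by_start: dict[int, dict[str, np.ndarray]] = {}
        for start in sorted({w[1] for w in windows}):
            cum = np.logical_or.accumulate(presence[:, start - 1 :, :], axis=1)
            grids = {"richness": cum.sum(axis=2).astype(float)}
            if idx is not None:
                grids["pd"] = idx.pd_of(cum.reshape(-1, cum.shape[2])).reshape(
                    L, cum.shape[1]
                )
            by_start[start] = grids
        for size, start in windows:
            lt = np.log(np.arange(1, size + 1, dtype=float))
            for resp, grid in by_start[start].items():
                sub = grid[:, :size]
                rec = {
                    "site": site,
                    "treatment": treatment,
                    "plot": f"{site}.{treatment}",
                    "response": resp,
                    "window_size": size,
                    "ystart": start,
                }
                try:
                    if (sub <= 0).any():
                        raise DegenerateDesignError("zero diversity in window")
                    la_f = np.broadcast_to(la[:, None], sub.shape).ravel()
                    lt_f = np.broadcast_to(lt[None, :], sub.shape).ravel()
                    beta, r2 = fit_star_arrays(la_f, lt_f, np.log(sub).ravel())
                    rec.update(
                        b=beta[0], z=beta[1], w=beta[2], u=beta[3], r_squared=r2,
                        note="",
                    )
                except DegenerateDesignError as err:
                    rec.update(
                        b=np.nan, z=np.nan, w=np.nan, u=np.nan, r_squared=np.nan,
                        note=f"degenerate: {err}",
                    )
                records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------


def lmm_effect_size(
    family: pd.DataFrame,
    value: str = "w",
    fixed: str = "treatment",
    reference: "str | None" = None,
    random_nesting: tuple = ("window_size", "site", "plot"),
    ar1_on_ystart: bool = True,
) -> EffectSize:
    """Mixed-model contrast of a scaling exponent between two groups.

    Fits ``value ~ fixed`` with nested random intercepts (outermost factor
    as groups, inner factors as nested variance components). An AR(1)
    residual correlation indexed by window start is part of the specified
    structure but is not supported by the backend; when requested it is
    noted and the model falls back to the nested-random-intercepts
    structure. Non-convergence falls back to OLS with a flag.
    """
    df = family.dropna(subset=[value]).copy()
    levels = sorted(df[fixed].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"fixed factor {fixed!r} has a single level: {levels}")
    if len(levels) > 2:
        raise ValueError(f"fixed factor {fixed!r} must have exactly 2 levels")
    if reference is None:
        reference = levels[0]
    other = [l for l in levels if l != reference][0]
    contrast = f"{other} vs {reference} on {value}"
    note = "ar1_on_ystart requested; backend lacks AR(1), nested intercepts only" if ar1_on_ystart else ""

    fml = f"{value} ~ C({fixed}, Treatment(reference='{reference}'))"
    groups = df[random_nesting[0]].astype(str)
    vc: dict[str, str] = {}
    nested = ""
    for factor in random_nesting[1:]:
        if factor in df.columns and df[factor].nunique() > 1:
            nested = f"{nested}:C({factor})" if nested else f"C({factor})"
            vc[factor] = f"0 + {nested}"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            model = smf.mixedlm(fml, df, groups=groups, vc_formula=vc or None)
            res = model.fit(reml=True)
            beta = float(res.fe_params.iloc[1])
            se = float(res.bse_fe.iloc[1])
            p = float(res.pvalues.iloc[1])
            converged = bool(res.converged)
            if not converged:
                raise RuntimeError("mixed model did not converge")
            return EffectSize("lmm", beta, se, p, contrast, converged, note)
        except Exception as err:  # singular fits, small families, etc.
            ols = smf.ols(fml, df).fit()
            return EffectSize(
                "lmm",
                float(ols.params.iloc[1]),
                float(ols.bse.iloc[1]),
                float(ols.pvalues.iloc[1]),
                contrast,
                converged=False,
                note=(note + "; " if note else "") + f"fallback OLS ({err})",
            )


def ln_response_ratio(treat, control) -> EffectSize:
    """ln(mean_treat / mean_control) with its delta-method variance."""
    t = np.asarray(treat, dtype=float)
    c = np.asarray(control, dtype=float)
    mt, mc = t.mean(), c.mean()
    if mt <= 0 or mc <= 0:
        raise ValueError("ln-response ratio requires positive group means")
    lnrr = float(np.log(mt / mc))
    var = 0.0
    if len(t) > 1:
        var += t.var(ddof=1) / (len(t) * mt**2)
    if len(c) > 1:
        var += c.var(ddof=1) / (len(c) * mc**2)
    se = float(np.sqrt(var)) if var > 0 else None
    p = float(2 * stats.norm.sf(abs(lnrr) / se)) if se else None
    return EffectSize("lnRR", lnrr, se, p, "treat vs control")


def cohens_d(group_a, group_b) -> EffectSize:
    """Standardized mean difference (pooled-SD Cohen's d), a minus b."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((a.mean() - b.mean()) / pooled)
    se = float(np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb - 2))))
    return EffectSize("cohens_d", d, se, None, "a vs b")


def spearman_fdr(
    rate_table: pd.DataFrame, heterogeneity_table: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlations (each rate column x each property column) with
    Benjamini-Hochberg adjustment across the whole tested family.

    Rows are paired on the shared index; constant vectors give an
    undefined-rho flagged record excluded from the adjustment family.
    """
    common = rate_table.index.intersection(heterogeneity_table.index)
    if len(common) < 4:
        raise ValueError("need >= 4 paired observations")
    records = []
    for rcol in rate_table.columns:
        for hcol in heterogeneity_table.columns:
            x = rate_table.loc[common, rcol]
            y = heterogeneity_table.loc[common, hcol]
            ok = x.notna() & y.notna()
            if ok.sum() < 4 or x[ok].nunique() == 1 or y[ok].nunique() == 1:
                records.append(
                    dict(rate=rcol, property=hcol, rho=np.nan, p=np.nan,
                         n=int(ok.sum()), undefined=True)
                )
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            records.append(
                dict(rate=rcol, property=hcol, rho=float(rho), p=float(p),
                     n=int(ok.sum()), undefined=False)
            )
    out = pd.DataFrame(records)
    out["p_adjusted"] = np.nan
    mask = ~out["undefined"]
    if mask.any():
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out
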