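"""End-to-end orchestration of the spatiotemporal scaling analysis.

Given either input files (community table, tree, metadata, soil, traits) or
synthetic-mode parameters, the pipeline builds per-plot accumulation
surfaces, fits the single-variable and interaction power-law models with
block-permutation significance, derives time-space equivalence ratios
(native m²/month and converted km²/yr), fits moving-window model families
and treatment/soil effect sizes, computes community rrn traits and their
correlations with group-level scaling rates, heterogeneity profiles and
temporal stability, depth-standardized diversity, and per-timepoint neutral
community model fits. All randomness derives from one root seed.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .accumulation import (
    build_accumulation_surface,
    pool_counts_by_scale,
    standardize_depth,
)
from .design import make_design
from .inference import (
    block_permutation_test,
    cohens_d,
    fit_window_family,
    ln_response_ratio,
    lmm_effect_size,
    spearman_fdr,
    star_ptar_difference_test,
)
from .neutral import fit_ncm, ncm_treatment_effect
from .scaling import equivalence_ratio, fit_power_law, fit_star, rescale_units
from .synthetic import (
    SimulationParams,
    assign_rrn_traits,
    simulate_communities,
    simulate_soil_table,
    simulate_tree,
)
from .traits import heterogeneity_cv, temporal_stability

__all__ = ["AnalysisConfig", "run_pipeline", "write_report"]

_DEFAULT_SOIL = {
    "pH": (6.5, 0.3),
    "moisture": (15.0, 3.0),
    "TC": (1.2, 0.25),
    "TN": (0.10, 0.02),
    "P": (8.0, 2.0),
}
_RRN_GROUP_MEANS = {"g1": 1.5, "g2": 2.5, "g3": 4.0, "g4": 6.0, "g5": 9.0}


@dataclass
class AnalysisConfig:
    """Everything needed for one pipeline run (YAML-serialisable)."""

    # synthetic mode (active when community_path is None)
    n_sites: int = 2
    n_treatments: int = 2
    n_points: int = 21
    n_times: int = 17
    n_area_levels: int = 5
    params: dict = field(default_factory=dict)  # SimulationParams overrides
    treated_homogenization: "float | None" = 0.5
    soil_variance_factor: float = 0.5
    # file mode
    community_path: "str | None" = None
    metadata_path: "str | None" = None
    tree_path: "str | None" = None
    soil_path: "str | None" = None
    traits_path: "str | None" = None
    # analysis settings
    temporal_method: str = "nested"
    window_sizes: tuple = tuple(range(5, 15))
    n_rand: int = 1000
    block_size: int = 3
    with_pd: bool = True
    area_factor_km2: float = 1e6
    time_factor_yr: float = 12.0
    rarefaction_reps: int = 50
    outdir: str = "starscale_out"
    seed: int = 0

    def __post_init__(self) -> None:
        file_mode = self.community_path is not None
        if file_mode and self.metadata_path is None:
            raise ValueError("file mode requires a metadata_path")

    @property
    def synthetic(self) -> bool:
        return self.community_path is None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = sio.read_config(path) or {}
        if "window_sizes" in raw:
            raw["window_sizes"] = tuple(raw["window_sizes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_sizes"] = list(self.window_sizes)
        return d


def _load_or_simulate(config: AnalysisConfig, log: list):
    sub = np.random.SeedSequence(config.seed)
    if not config.synthetic:
        log.append(f"reading inputs from {config.community_path}")
        matrix, tree, soil, traits = sio.read_inputs(
            config.community_path,
            config.metadata_path,
            config.tree_path,
            config.soil_path,
            config.traits_path,
            require_pd=config.with_pd,
        )
        design = _design_from_metadata(matrix.meta)
        return design, matrix, tree, soil, traits

    design = make_design(
        config.n_sites,
        config.n_treatments,
        config.n_points,
        config.n_times,
        config.n_area_levels,
    )
    params = SimulationParams(**{"seed": config.seed, **config.params})
    by_treatment = None
    if config.treated_homogenization is not None and len(design.treatments) > 1:
        treated = dataclasses.replace(
            params, homogenization=config.treated_homogenization
        )
        by_treatment = {design.treatments[-1]: treated}
    log.append(
        f"simulating communities: {design.n_samples} samples, "
        f"{params.pool_size} taxa"
    )
    matrix = simulate_communities(design, params, params_by_treatment=by_treatment)
    tree = (
        simulate_tree(params.pool_size, seed=int(sub.generate_state(1)[0] >> 1))
        if config.with_pd and params.pool_size >= 2
        else None
    )
    soil = simulate_soil_table(
        design,
        {k: v[0] for k, v in _DEFAULT_SOIL.items()},
        {k: v[1] for k, v in _DEFAULT_SOIL.items()},
        treatment_variance_factor=config.soil_variance_factor,
        seed=config.seed + 1,
    )
    groups = [
        list(_RRN_GROUP_MEANS)[i % len(_RRN_GROUP_MEANS)]
        for i in range(params.pool_size)
    ]
    traits = assign_rrn_traits(
        matrix.taxa, groups, _RRN_GROUP_MEANS, seed=config.seed + 2
    )
    return design, matrix, tree, soil, traits


def _design_from_metadata(meta: pd.DataFrame):
    """Reconstruct a nested design from sample metadata (file mode)."""
    sites = sorted(meta["site"].unique())
    treatments = sorted(meta["treatment"].unique())
    points = sorted(meta["point"].unique())
    times = sorted(meta["time"].unique())
    return make_design(
        n_sites=len(sites),
        n_treatments=len(treatments),
        n_points=len(points),
        n_times=len(times),
        n_area_levels=min(5, len(points)),
    )


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns a results bundle of tidy DataFrames."""
    log: list[str] = [f"seed={config.seed}", f"config={config.to_dict()}"]
    t0 = _time.time()
    design, matrix, tree, soil, traits = _load_or_simulate(config, log)
    results: dict = {"config": config.to_dict(), "log": log}

    # --- accumulation surfaces & model fits per plot -----------------------
    surfaces, power_rows, star_rows, perm_rows, ratio_rows, diff_rows = (
        [], [], [], [], [], []
    )
    for site, trt in matrix.plots:
        surf = build_accumulation_surface(
            matrix, design, tree=tree, temporal_method=config.temporal_method,
            site=site, treatment=trt,
        )
        surfaces.append(surf)
        responses = ["richness"] + (["pd"] if tree is not None else [])
        for resp in responses:
            for pred in ("area", "time"):
                f = fit_power_law(surf, predictor=pred, response=resp)
                power_rows.append(
                    dict(site=site, treatment=trt, model=f.model_, response=resp,
                         slope=f.slope_, intercept=f.intercept_,
                         r_squared=f.r_squared_, n=f.n_points_)
                )
            sf = fit_star(surf, response=resp)
            ratio = equivalence_ratio(sf)
            sf_km_yr = rescale_units(
                sf, config.area_factor_km2, config.time_factor_yr, "km2", "yr"
            )
            ratio_km_yr = equivalence_ratio(sf_km_yr)
            star_rows.append(
                dict(site=site, treatment=trt, response=resp, z=sf.z_, w=sf.w_,
                     u=sf.u_, b=sf.b_, r_squared=sf.r_squared_, n=sf.n_points_,
                     area_unit=sf.area_unit_, time_unit=sf.time_unit_)
            )
            ratio_rows.append(
                dict(site=site, treatment=trt, basis=resp,
                     ratio_m2_per_month=ratio.value,
                     ratio_km2_per_yr=ratio_km_yr.value)
            )
            perms = block_permutation_test(
                surf, response=resp, n_rand=config.n_rand,
                block_size=config.block_size, seed=config.seed + 10,
            )
            for key, pr in perms.items():
                perm_rows.append(
                    dict(site=site, treatment=trt, response=resp, statistic=key,
                         observed=pr.observed, p_value=pr.p_value,
                         n_rand=pr.n_rand, n_discarded=pr.n_discarded)
                )
        if tree is not None:
            for exp in ("z", "w", "u"):
                dr = star_ptar_difference_test(
                    surf, exponent=exp, n_rand=config.n_rand,
                    block_size=config.block_size, seed=config.seed + 11,
                )
                diff_rows.append(
                    dict(site=site, treatment=trt, exponent=exp,
                         observed_difference=dr.observed, p_value=dr.p_value)
                )
    results["surfaces"] = pd.concat(surfaces, ignore_index=True)
    results["power_law_fits"] = pd.DataFrame(power_rows)
    results["star_fits"] = pd.DataFrame(star_rows)
    results["permutation_tests"] = pd.DataFrame(perm_rows)
    results["equivalence_ratios"] = pd.DataFrame(ratio_rows)
    results["star_ptar_differences"] = pd.DataFrame(diff_rows)
    log.append(f"surfaces and fits done in {_time.time() - t0:.1f}s")

    # --- moving-window families and effect sizes ---------------------------
    family = fit_window_family(
        matrix, design, tree=tree, sizes=config.window_sizes
    )
    results["window_family"] = family
    effect_rows = []
    control = design.treatments[0]
    if len(design.treatments) > 1:
        for resp in family["response"].unique():
            fam = family[family["response"] == resp]
            for value in ("z", "w"):
                es = lmm_effect_size(
                    fam, value=value, fixed="treatment", reference=control
                )
                effect_rows.append(_effect_row(es, resp, value, "lmm"))
            fam_abs = fam.assign(abs_u=fam["u"].abs())
            es = lmm_effect_size(
                fam_abs, value="abs_u", fixed="treatment", reference=control
            )
            effect_rows.append(_effect_row(es, resp, "abs_u", "lmm"))
            treat_label = design.treatments[-1]
            for value in ("z", "w"):
                tv = fam.loc[fam["treatment"] == treat_label, value].dropna()
                cv = fam.loc[fam["treatment"] == control, value].dropna()
                effect_rows.append(
                    _effect_row(ln_response_ratio(tv, cv), resp, value, "lnRR")
                )
                effect_rows.append(
                    _effect_row(cohens_d(tv, cv), resp, value, "cohens_d")
                )
    if len(design.sites) > 1:
        fam = family[family["response"] == "richness"].rename(
            columns={"site": "soil_type"}
        )
        for value in ("z", "w"):
            es = lmm_effect_size(
                fam, value=value, fixed="soil_type",
                random_nesting=("window_size", "treatment", "plot"),
            )
            effect_rows.append(_effect_row(es, "richness", value, "lmm_soil"))
    results["effect_sizes"] = pd.DataFrame(effect_rows)
    log.append(f"window families and effect sizes done in {_time.time() - t0:.1f}s")

    # --- soil heterogeneity and stability ----------------------------------
    het_rows, stab_rows = [], []
    if soil is not None:
        props = list(soil.columns)
        for site, trt in matrix.plots:
            mask = (matrix.meta["site"] == site) & (matrix.meta["treatment"] == trt)
            sub = soil.loc[mask.reindex(soil.index, fill_value=False)]
            meta = matrix.meta.loc[sub.index]
            for prop in props:
                for t, grp in sub.groupby(meta["time"]):
                    het_rows.append(
                        dict(site=site, treatment=trt, property=prop,
                             mode="spatial", index=int(t),
                             cv=heterogeneity_cv(grp[prop], "spatial"))
                    )
                for p, grp in sub.groupby(meta["point"]):
                    series = grp[prop].to_numpy()[np.argsort(meta.loc[grp.index, "time"])]
                    het_rows.append(
                        dict(site=site, treatment=trt, property=prop,
                             mode="temporal", index=p,
                             cv=heterogeneity_cv(series, "temporal"))
                    )
        het = pd.DataFrame(het_rows)
        results["heterogeneity"] = het
        # Cohen's d of treatment on heterogeneity per property and mode
        d_rows = []
        if len(design.treatments) > 1:
            treat_label = design.treatments[-1]
            for (prop, mode), grp in het.groupby(["property", "mode"]):
                a = grp.loc[grp["treatment"] == treat_label, "cv"]
                b = grp.loc[grp["treatment"] == control, "cv"]
                if len(a) >= 2 and len(b) >= 2:
                    es = cohens_d(a, b)
                    d_rows.append(
                        dict(property=prop, mode=mode, cohens_d=es.estimate,
                             se=es.se)
                    )
        results["heterogeneity_effects"] = pd.DataFrame(d_rows)
    for site, trt in matrix.plots:
        sub = matrix.plot(site, trt)
        series = [
            float((sub.counts.loc[sub.meta["time"] == t].sum(axis=0) > 0).sum())
            for t in design.time_points
        ]
        if len(series) >= 2 and np.std(series) > 0:
            stab_rows.append(
                dict(site=site, treatment=trt,
                     stability=temporal_stability(series))
            )
    results["stability"] = pd.DataFrame(stab_rows)

    # --- rrn traits and group-level scaling correlations -------------------
    if traits is not None:
        copies = traits["copy_number"] if "copy_number" in traits else traits.iloc[:, -1]
        from .traits import community_rrn

        rrn_rows = [
            dict(sample=s, community_rrn=community_rrn(matrix.counts.loc[s], traits))
            for s in matrix.counts.index
        ]
        results["community_rrn"] = pd.DataFrame(rrn_rows).set_index("sample")
        if "group" in getattr(traits, "columns", []):
            rate_rows = []
            for site, trt in matrix.plots:
                for g, members in traits.groupby("group").groups.items():
                    cols = [t for t in members if t in matrix.counts.columns]
                    if not cols:
                        continue
                    sub = type(matrix)(matrix.counts[cols], matrix.meta)
                    try:
                        surf = build_accumulation_surface(
                            sub, design, site=site, treatment=trt
                        )
                        f = fit_star(surf)
                        rate_rows.append(
                            dict(plot=f"{site}.{trt}", group=g, z=f.z_, w=f.w_,
                                 abs_u=abs(f.u_),
                                 rrn=float(copies.loc[cols].mean()))
                        )
                    except ValueError:
                        continue
            if rate_rows:
                rates = pd.DataFrame(rate_rows).set_index(["plot", "group"])
                results["rrn_scaling_correlations"] = spearman_fdr(
                    rates[["z", "w", "abs_u"]], rates[["rrn"]]
                )
    log.append(f"traits and heterogeneity done in {_time.time() - t0:.1f}s")

    # --- passive-sampling depth standardization ----------------------------
    std_rows = []
    for site, trt in matrix.plots:
        for axis in ("time", "area"):
            pooled = pool_counts_by_scale(matrix, design, axis=axis,
                                          site=site, treatment=trt)
            target = int(pooled.sum(axis=1).min())
            std = standardize_depth(
                pooled, target, n_reps=config.rarefaction_reps,
                seed=config.seed + 20,
            )
            std["site"], std["treatment"], std["axis"] = site, trt, axis
            std_rows.append(std.reset_index())
    results["depth_standardized"] = pd.concat(std_rows, ignore_index=True)

    # --- neutral community model -------------------------------------------
    ncm_rows = []
    for site, trt in matrix.plots:
        sub = matrix.plot(site, trt)
        for t in design.time_points:
            cnt = sub.counts.loc[sub.meta["time"] == t]
            try:
                f = fit_ncm(cnt)
                ncm_rows.append(
                    dict(site=site, treatment=trt, timepoint=int(t), m=f.m_,
                         Nm=f.Nm_, r_squared=f.r_squared_, n_taxa=f.n_taxa_)
                )
            except ValueError:
                continue
    ncm = pd.DataFrame(ncm_rows)
    results["ncm_fits"] = ncm
    if len(design.treatments) > 1 and not ncm.empty:
        eff_rows = []
        for site in design.sites:
            sub = ncm[ncm["site"] == site]
            if sub["treatment"].nunique() == 2:
                es = ncm_treatment_effect(sub, reference=control)
                eff_rows.append(
                    dict(site=site, estimate=es.estimate, se=es.se,
                         p_value=es.p_value, converged=es.converged)
                )
        results["ncm_treatment_effects"] = pd.DataFrame(eff_rows)
    log.append(f"pipeline finished in {_time.time() - t0:.1f}s")
    return results


def _effect_row(es, response, value, tag):
    return dict(
        response=response, exponent=value, method=tag, estimate=es.estimate,
        se=es.se, p_value=es.p_value, contrast=es.contrast,
        converged=es.converged, note=es.note,
    )


def _fresh_path(outdir: Path, name: str) -> Path:
    """Versioned, non-clobbering output path."""
    p = outdir / name
    stem, suffix = p.stem, p.suffix
    k = 1
    while p.exists():
        p = outdir / f"{stem}.{k}{suffix}"
        k += 1
    return p


def write_report(results: dict, outdir) -> dict:
    """Write tidy TSVs, a JSON summary, and a run log; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {"seed": results.get("config", {}).get("seed")}
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            path = _fresh_path(outdir, f"{key}.tsv")
            val.to_csv(path, sep="\t", index=not isinstance(val.index, pd.RangeIndex),
                       float_format="%.10g")
            manifest[key] = path.name
            summary[f"n_{key}"] = int(len(val))
    if "star_fits" in results and len(results["star_fits"]):
        summary["star_fits"] = results["star_fits"].to_dict(orient="records")
    if "equivalence_ratios" in results and len(results["equivalence_ratios"]):
        summary["equivalence_ratios"] = results["equivalence_ratios"].to_dict(
            orient="records"
        )
    spath = _fresh_path(outdir, "summary.json")
    with open(spath, "w") as fh:
        json.dump({"manifest": manifest, "summary": summary,
                   "config": results.get("config", {})}, fh, indent=2, default=str)
    manifest["summary"] = spath.name
    lpath = _fresh_path(outdir, "run_log.txt")
    with open(lpath, "w") as fh:
        fh.write("\n".join(results.get("log", [])) + "\n")
    manifest["log"] = lpath.name
    return manifest
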