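"""rrn copy-number traits, environmental heterogeneity, temporal stability.

The 16S rRNA operon (rrn) copy number is a genomic trait indicative of
bacterial growth potential. Per-taxon copies are estimated by matching a
taxon's lineage against an rrnDB-style reference from the lowest rank
upward; the community-level value is the relative-abundance-weighted mean
Σ S_i n_i / Σ S_i over taxa with trait estimates (unmatched taxa are
excluded from numerator and denominator).

Heterogeneity is quantified as a coefficient of variation: spatially the
sd/mean across points at one timepoint; temporally the sd of residuals from
an ordinary linear time regression divided by the series mean (detrended
CV). Sample (n-1) standard deviations are used throughout. Temporal
stability of a richness series is the inverse CV, mean/sd.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "match_rrn",
    "community_rrn",
    "heterogeneity_cv",
    "temporal_stability",
]

RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]


def match_rrn(
    taxonomy: pd.DataFrame,
    reference: pd.DataFrame,
    ranks: "list[str] | None" = None,
) -> pd.DataFrame:
    """Estimate per-taxon rrn copy numbers from an rrnDB-style reference.

    ``taxonomy``: one row per query taxon (index = taxon id), rank-named
    columns with lineage names (NaN where unresolved). ``reference``: rows
    of reference taxa with the same rank columns plus ``copy_number``.

    Matching starts at the query's lowest resolved rank: all reference rows
    carrying that name at that rank are averaged (mode ``child-mean`` — the
    mean over the matched taxon's children in the reference); failing that,
    ranks are ascended and the parent taxon's mean is used (mode
    ``parent-mean``). Queries unmatched at every rank are flagged ``none``
    with a missing copy number.
    """
    if reference.empty:
        raise ValueError("reference table is empty")
    ranks = ranks or [r for r in RANKS if r in taxonomy.columns]
    if not ranks:
        raise ValueError("taxonomy table has no recognised rank columns")
    for r in ranks:
        if r not in reference.columns:
            raise ValueError(f"reference lacks rank column {r!r}")
    if "copy_number" not in reference.columns:
        raise ValueError("reference lacks a copy_number column")

    # Mean copy number per (rank, name) over all reference rows carrying
    # that name at that rank (i.e. the taxon itself and its children).
    lookup: dict[str, pd.Series] = {
        r: reference.dropna(subset=[r]).groupby(r)["copy_number"].mean()
        for r in ranks
    }

    records = []
    for taxon, row in taxonomy.iterrows():
        resolved = [(i, r) for i, r in enumerate(ranks) if pd.notna(row.get(r))]
        copy, matched_rank, mode = np.nan, None, "none"
        for depth, (i, rank) in enumerate(reversed(resolved)):
            name = row[rank]
            if name in lookup[rank].index:
                copy = float(lookup[rank].loc[name])
                matched_rank = rank
                mode = "child-mean" if depth == 0 else "parent-mean"
                break
        records.append(
            {"taxon": taxon, "copy_number": copy, "matched_rank": matched_rank,
             "match_mode": mode}
        )
    return pd.DataFrame(records).set_index("taxon")


def community_rrn(sample_counts: pd.Series, traits: pd.DataFrame) -> float:
    """Community-level rrn copy number: abundance-weighted mean trait.

    Σ S_i n_i / Σ S_i over counted taxa with a trait estimate; taxa without
    a match are dropped from both sums (renormalization). The result is
    bounded by the trait extremes and invariant to count rescaling.
    """
    copies = traits["copy_number"] if "copy_number" in traits else traits
    if isinstance(copies, pd.DataFrame):
        raise ValueError("traits must carry a single copy_number column")
    common = sample_counts.index.intersection(copies.index)
    s = sample_counts.loc[common].astype(float)
    n = copies.loc[common].astype(float)
    ok = (s > 0) & n.notna()
    if not ok.any():
        raise ValueError("no counted taxa carry a trait estimate")
    dropped = int((sample_counts > 0).sum() - ok.sum())
    if dropped:
        warnings.warn(f"{dropped} counted taxa lack trait estimates; excluded")
    return float((s[ok] * n[ok]).sum() / s[ok].sum())


def heterogeneity_cv(values, mode: str = "spatial", time=None) -> float:
    """Coefficient of variation as a heterogeneity measure.

    ``spatial``: sd/mean across points at one timepoint. ``temporal``:
    detrended CV — sd of residuals from an ordinary least-squares regression
    on the time index, divided by the raw series mean (an exactly linear
    series therefore has temporal CV 0).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    if mode == "spatial":
        return float(x.std(ddof=1) / mean)
    if mode == "temporal":
        t = np.arange(len(x), dtype=float) if time is None else np.asarray(time, float)
        if len(t) != len(x):
            raise ValueError("time axis must align with values")
        slope, intercept = np.polyfit(t, x, 1)
        resid = x - (intercept + slope * t)
        return float(resid.std(ddof=1) / mean)
    raise ValueError("mode must be 'spatial' or 'temporal'")


def temporal_stability(series) -> float:
    """Inverse CV of a richness time series (mean/sd); higher = more stable.

    A constant series has undefined (infinite) stability; ``inf`` is
    returned with a warning flag.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; temporal stability is infinite")
        return float("inf")
    return float(x.mean() / sd)
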