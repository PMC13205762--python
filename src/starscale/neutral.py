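"""Sloan neutral community model (NCM) fits.

The NCM predicts, for a set of local communities sampled from a common
source pool, the occurrence frequency of each taxon from its mean relative
abundance: with community size N, migration rate m, and detection limit d,

    E[frequency] = 1 - BetaCDF(d; N m p, N m (1 - p)).

Higher m indicates weaker dispersal limitation. m is estimated by bounded
least squares over taxa; the fit quality is R² = 1 - SSE/SST. By
convention N defaults to the mean per-sample read depth and d to 1/N.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .inference import EffectSize

__all__ = ["SloanNCM", "fit_ncm", "ncm_treatment_effect", "simulate_neutral_counts"]


class SloanNCM(BaseEstimator):
    """Sloan neutral community model estimator.

    Parameters
    ----------
    N : community size; defaults to the mean per-sample read depth.
    detection_limit : abundance threshold d; defaults to 1/N.
    min_samples, min_taxa : preconditions on the input table.

    Fitted attributes: ``m_`` (migration rate in (0, 1]), ``Nm_``,
    ``r_squared_``, ``n_taxa_``, ``N_``, ``detection_limit_``,
    ``boundary_`` (True when every taxon is ubiquitous, f = 1).
    """

    def __init__(
        self,
        N: "float | None" = None,
        detection_limit: "float | None" = None,
        min_samples: int = 5,
        min_taxa: int = 10,
    ):
        self.N = N
        self.detection_limit = detection_limit
        self.min_samples = min_samples
        self.min_taxa = min_taxa

    @staticmethod
    def predicted_frequency(p: np.ndarray, m: float, N: float, d: float) -> np.ndarray:
        """Expected occurrence frequency of taxa with mean rel. abundance p."""
        p = np.asarray(p, dtype=float)
        return stats.beta.sf(d, N * m * p, N * m * (1.0 - p))

    def fit(self, counts: pd.DataFrame) -> "SloanNCM":
        """Fit m from a samples x taxa count table at one timepoint."""
        arr = counts.to_numpy(dtype=float)
        if arr.shape[0] < self.min_samples:
            raise ValueError(f"need >= {self.min_samples} samples")
        depths = arr.sum(axis=1)
        if (depths == 0).any():
            raise ValueError("every sample needs at least one read")
        rel = arr / depths[:, None]
        present = arr > 0
        keep = present.any(axis=0)
        if keep.sum() < self.min_taxa:
            raise ValueError(f"need >= {self.min_taxa} observed taxa")
        p = rel[:, keep].mean(axis=0)
        f = present[:, keep].mean(axis=0)

        self.N_ = float(self.N) if self.N is not None else float(depths.mean())
        self.detection_limit_ = (
            float(self.detection_limit)
            if self.detection_limit is not None
            else 1.0 / self.N_
        )
        self.boundary_ = bool((f == 1.0).all())

        d, N = self.detection_limit_, self.N_

        def sse(m: float) -> float:
            pred = self.predicted_frequency(p, m, N, d)
            return float(((f - pred) ** 2).sum())

        res = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
        self.m_ = float(res.x)
        self.Nm_ = self.m_ * N
        sst = float(((f - f.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - sse(self.m_) / sst if sst > 0 else 0.0
        self.n_taxa_ = int(keep.sum())
        return self


def fit_ncm(counts: pd.DataFrame, **kwargs) -> SloanNCM:
    """Fit the Sloan NCM at one timepoint; thin wrapper over SloanNCM."""
    return SloanNCM(**kwargs).fit(counts)


def ncm_treatment_effect(
    fits: pd.DataFrame,
    treatment_col: str = "treatment",
    reference: "str | None" = None,
) -> EffectSize:
    """Contrast of migration rates between two treatments over timepoints.

    ``fits``: DataFrame with columns ``m``, ``timepoint``, and the treatment
    label; fitted as a mixed model with a random intercept per timepoint.
    With a single timepoint, falls back to a two-sample comparison with a
    warning note.
    """
    import statsmodels.formula.api as smf

    levels = sorted(fits[treatment_col].dropna().unique())
    if len(levels) < 2:
        raise ValueError("both treatments must be present")
    if reference is None:
        reference = levels[0]
    other = [l for l in levels if l != reference][0]
    contrast = f"{other} vs {reference} on m"

    if fits["timepoint"].nunique() < 2:
        a = fits.loc[fits[treatment_col] == other, "m"]
        b = fits.loc[fits[treatment_col] == reference, "m"]
        est = float(a.mean() - b.mean())
        t, p = (stats.ttest_ind(a, b) if min(len(a), len(b)) > 1 else (np.nan, np.nan))
        return EffectSize(
            "lmm", est, None, float(p) if np.isfinite(p) else None, contrast,
            converged=False, note="single timepoint; plain two-sample fallback",
        )

    fml = f"m ~ C({treatment_col}, Treatment(reference='{reference}'))"
    try:
        res = smf.mixedlm(fml, fits, groups=fits["timepoint"].astype(str)).fit(
            reml=True
        )
        return EffectSize(
            "lmm",
            float(res.fe_params.iloc[1]),
            float(res.bse_fe.iloc[1]),
            float(res.pvalues.iloc[1]),
            contrast,
            converged=bool(res.converged),
        )
    except Exception as err:
        ols = smf.ols(fml, fits).fit()
        return EffectSize(
            "lmm", float(ols.params.iloc[1]), float(ols.bse.iloc[1]),
            float(ols.pvalues.iloc[1]), contrast, converged=False,
            note=f"fallback OLS ({err})",
        )


def simulate_neutral_counts(
    m: float,
    N: int,
    n_samples: int,
    source: "np.ndarray | None" = None,
    n_taxa: int = 100,
    abundance_sigma: float = 1.5,
    seed: "int | None" = None,
) -> pd.DataFrame:
    """Generate count tables from the neutral sampling model itself.

    Each taxon's relative abundance in each local community is drawn from
    the model's stationary Beta(N m p, N m (1 - p)) around its source-pool
    abundance p; the community of N individuals then holds floor(N x)
    individuals of that taxon (the Beta already embodies the finite-size
    sampling noise, so no further read-level noise is layered on top).
    Serves as the generative ground truth for migration-rate recovery
    tests.
    """
    rng = np.random.default_rng(seed)
    if source is None:
        w = np.exp(abundance_sigma * rng.standard_normal(n_taxa))
        source = w / w.sum()
    source = np.asarray(source, dtype=float)
    a = N * m * source
    b = N * m * (1.0 - source)
    x = rng.beta(a[None, :], b[None, :], size=(n_samples, len(source)))
    counts = np.floor(N * x).astype(np.int64)
    return pd.DataFrame(
        counts,
        index=[f"s{i + 1}" for i in range(n_samples)],
        columns=[f"t{i + 1}" for i in range(len(source))],
    )
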