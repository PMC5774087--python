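"""Multi-environment phenotype combination: BLUP, heritability, correlations.

Line values for QTL scanning come from the random-effects model

    y_ij = mu + env_j + g_i + e_ij

with environments fixed and lines random.  Variance components are
estimated by REML (statsmodels MixedLM) with a method-of-moments
fallback for degenerate fits; line BLUPs are the shrunken,
environment-adjusted line means, BLUP_i = k_i (ybar_i,adj - mu) with
k_i = sigma2_g / (sigma2_g + sigma2_e / n_i).  Heritability is reported
on an entry-mean basis, h2 = sigma2_g / (sigma2_g + sigma2_e / n_env).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "estimate_variance_components",
    "blup_line_values",
    "heritability",
    "trait_correlations",
]


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    n_env: int

    @property
    def h2(self) -> float:
        return heritability(self.sigma2_g, self.sigma2_e, self.n_env)


def _moments_components(df: pd.DataFrame) -> tuple[float, float]:
    """Method-of-moments variance components from the one-way layout.

    Expected mean squares of the line classification (after removing
    environment means): E[MS_between] = sigma2_e + n0 * sigma2_g,
    E[MS_within] = sigma2_e, with n0 the effective per-line replication.
    """
    adj = df["value"] - df.groupby("environment")["value"].transform("mean")
    groups = adj.groupby(df["line"])
    n_i = groups.size().to_numpy(dtype=float)
    means = groups.mean().to_numpy()
    grand = adj.mean()
    k = n_i.size
    N = n_i.sum()
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(((adj - groups.transform("mean")) ** 2).sum())
    df_within = N - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    ms_between = ss_between / (k - 1)
    sigma2_g = max(0.0, (ms_between - ms_within) / n0)
    return sigma2_g, max(ms_within, 0.0)


def estimate_variance_components(df: pd.DataFrame) -> VarianceComponents:
    """REML variance components for one trait's long table.

    ``df`` needs columns line, environment, value (replicate optional;
    replicates simply add observations).  Falls back to closed-form
    method-of-moments when the REML fit fails or is degenerate.
    """
    n_env = df["environment"].nunique()
    if len(df) < 3 or df["line"].nunique() < 2:
        raise ValueError("need at least 2 lines and 3 observations")
    sigma2_g = sigma2_e = None
    if df.groupby("line").size().max() > 1:
        try:
            import statsmodels.formula.api as smf

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    "value ~ C(environment)", df, groups=df["line"]
                ).fit(reml=True)
            sigma2_g = float(model.cov_re.iloc[0, 0])
            sigma2_e = float(model.scale)
        except Exception:
            sigma2_g = sigma2_e = None
    if sigma2_g is None or not np.isfinite(sigma2_g):
        sigma2_g, sigma2_e = _moments_components(df)
    return VarianceComponents(sigma2_g, sigma2_e, n_env)


def blup_line_values(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, VarianceComponents]]:
    """Per-line BLUPs across environments for every trait.

    ``table`` is long format with columns line, environment, trait,
    value (an optional replicate column is accepted and pooled).
    Returns a wide DataFrame (index line, one column per trait, values
    mu + BLUP_i so they sit on the trait scale) and the variance
    components per trait.
    """
    required = {"line", "environment", "trait", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    out: dict[str, pd.Series] = {}
    comps: dict[str, VarianceComponents] = {}
    for trait, df in table.groupby("trait"):
        df = df.dropna(subset=["value"])
        vc = estimate_variance_components(df)
        comps[str(trait)] = vc
        adj = df["value"] - df.groupby("environment")["value"].transform("mean")
        groups = adj.groupby(df["line"])
        n_i = groups.size()
        line_mean = groups.mean()
        if vc.sigma2_g == 0:
            shrink = pd.Series(0.0, index=line_mean.index)
        else:
            shrink = vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e / n_i)
        grand = float(df["value"].mean())
        out[str(trait)] = grand + shrink * (line_mean - line_mean.mean())
    wide = pd.DataFrame(out)
    wide.index.name = "line"
    return wide, comps


def heritability(sigma2_g: float, sigma2_e: float, n_env: int) -> float:
    """Entry-mean heritability h2 = sigma2_g / (sigma2_g + sigma2_e / n_env)."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    denom = sigma2_g + sigma2_e / n_env
    if denom == 0:
        raise ValueError("heritability undefined with all-zero variance")
    return sigma2_g / denom


def trait_correlations(
    values: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among trait columns, with p-values.

    Uses pairwise-complete observations; pairs with fewer than 3 shared
    values get NaN.
    """
    traits = list(values.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            a = values[traits[i]]
            b = values[traits[j]]
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            rr, pp = stats.pearsonr(a[ok], b[ok])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )
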