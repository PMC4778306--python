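"""Trait statistics, ANOVA variance components and heritability.

Broad-sense heritability on the multi-environment line-mean basis follows
the standard balanced-design formulation

    H^2 = s2_g / (s2_g + s2_ge / e + s2 / (e * r))

with genetic variance ``s2_g``, genotype-by-environment variance ``s2_ge``
and replicate-level error variance ``s2`` estimated from the expected mean
squares of a two-factor ANOVA with replication:

    s2     = MS_error
    s2_ge  = (MS_gxe - MS_error) / r
    s2_g   = (MS_g - MS_gxe) / (e * r)

Negative method-of-moments estimates are clamped to zero with a warning.
Only balanced designs are supported; unbalanced tables raise rather than
silently fall back to a different estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnbalancedDesignError",
    "VarianceComponents",
    "descriptive_stats",
    "line_means",
    "anova_components",
    "heritability",
    "correlations",
    "variance_partition",
]


class UnbalancedDesignError(ValueError):
    """Raised when the phenotype table is not a balanced line x env x rep design."""


@dataclass
class VarianceComponents:
    """Method-of-moments variance components from a balanced two-factor ANOVA."""

    genetic: float  # s2_g
    gxe: float  # s2_ge
    error: float  # s2
    n_environments: int
    n_replicates: int
    n_lines: int

    def __post_init__(self) -> None:
        if self.n_environments < 1 or self.n_replicates < 1:
            raise ValueError("need at least one environment and one replicate")


def descriptive_stats(values: np.ndarray | pd.Series) -> dict:
    """Range, mean, SD, skewness, excess kurtosis and CV% of one trait.

    Skewness and kurtosis are the bias-adjusted sample statistics; kurtosis
    is reported as excess kurtosis (0 for a normal distribution); CV is
    ``100 * SD / mean``.  Degenerate inputs yield NaN for the undefined
    statistics.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need at least 3 values for moment statistics")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        skew = kurt = np.nan
    else:
        skew = float(stats.skew(v, bias=False))
        kurt = float(stats.kurtosis(v, bias=False))
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": mean,
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "cv_pct": cv,
    }


def _balanced_array(table: pd.DataFrame, trait: str) -> np.ndarray:
    """Reshape a long table into a (lines, envs, reps) array or raise."""
    for col in ("ril", "env", "rep", trait):
        if col not in table.columns:
            raise KeyError(f"phenotype table lacks column {col!r}")
    sub = table[["ril", "env", "rep", trait]].dropna()
    lines = sorted(sub["ril"].unique())
    envs = sorted(sub["env"].unique())
    reps = sorted(sub["rep"].unique())
    expected = len(lines) * len(envs) * len(reps)
    if len(sub) != expected or sub.duplicated(["ril", "env", "rep"]).any():
        raise UnbalancedDesignError(
            f"trait {trait!r}: need one observation per line x env x rep "
            f"({expected} cells, found {len(sub)} rows)"
        )
    pivot = sub.set_index(["ril", "env", "rep"])[trait].sort_index()
    return pivot.to_numpy().reshape(len(lines), len(envs), len(reps))


def anova_components(table: pd.DataFrame, trait: str) -> VarianceComponents:
    """Estimate genetic, GxE and error variances from a balanced design.

    ``table`` is long-format with columns ``ril``, ``env``, ``rep`` and the
    trait.  Requires at least two lines, two environments is not required
    but interaction needs e >= 2, and r >= 2 for an error stratum.
    """
    y = _balanced_array(table, trait)
    n, e, r = y.shape
    if n < 2 or e < 2 or r < 2:
        raise UnbalancedDesignError(
            "component estimation needs >= 2 lines, >= 2 environments and >= 2 replicates"
        )
    grand = y.mean()
    line_mean = y.mean(axis=(1, 2))
    env_mean = y.mean(axis=(0, 2))
    cell_mean = y.mean(axis=2)
    ss_g = e * r * np.sum((line_mean - grand) ** 2)
    ss_ge = r * np.sum((cell_mean - line_mean[:, None] - env_mean[None, :] + grand) ** 2)
    ss_err = np.sum((y - cell_mean[:, :, None]) ** 2)
    ms_g = ss_g / (n - 1)
    ms_ge = ss_ge / ((n - 1) * (e - 1))
    ms_err = ss_err / (n * e * (r - 1))
    s2 = ms_err
    s2_ge = (ms_ge - ms_err) / r
    s2_g = (ms_g - ms_ge) / (e * r)
    clamped = []
    if s2_ge < 0:
        clamped.append("s2_ge")
        s2_ge = 0.0
    if s2_g < 0:
        clamped.append("s2_g")
        s2_g = 0.0
    if clamped:
        warnings.warn(
            f"negative variance-component estimate(s) clamped to zero: {', '.join(clamped)}",
            stacklevel=2,
        )
    return VarianceComponents(float(s2_g), float(s2_ge), float(s2), e, r, n)


def heritability(components: VarianceComponents) -> float:
    """Broad-sense heritability on the multi-environment line-mean basis."""
    e, r = components.n_environments, components.n_replicates
    denom = components.genetic + components.gxe / e + components.error / (e * r)
    if denom == 0:
        return np.nan
    h2 = components.genetic / denom
    return float(h2)


def variance_partition(components: VarianceComponents) -> dict:
    """Fractions of line-mean phenotypic variance by factor.

    On the line-mean scale the phenotypic variance decomposes into the
    genetic part ``s2_g`` (fraction = H^2), the interaction part
    ``s2_ge / e`` and the residual part ``s2 / (e r)``; fractions sum to 1.
    """
    e, r = components.n_environments, components.n_replicates
    parts = {
        "genotype": components.genetic,
        "gxe": components.gxe / e,
        "residual": components.error / (e * r),
    }
    total = sum(parts.values())
    if total == 0:
        return {k: np.nan for k in parts}
    return {k: v / total for k, v in parts.items()}


def line_means(table: pd.DataFrame, trait: str, env: str | None = None) -> pd.Series:
    """Per-line trait means, within one environment or pooled over all."""
    sub = table if env is None else table[table["env"] == env]
    return sub.groupby("ril")[trait].mean()


def correlations(
    table: pd.DataFrame, traits: list[str], env: str | None = None
) -> pd.DataFrame:
    """Spearman rank correlations between line means of trait pairs.

    Ties are mid-ranked (the standard Spearman convention); a constant
    trait yields NaN.  Requires at least 5 lines.
    """
    means = pd.DataFrame({t: line_means(table, t, env) for t in traits})
    if len(means) < 5:
        raise ValueError("need at least 5 lines for rank correlations")
    out = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if i < j:
                va, vb = means[a].to_numpy(), means[b].to_numpy()
                if np.std(va) == 0 or np.std(vb) == 0:
                    rho = np.nan
                else:
                    rho = float(stats.spearmanr(va, vb).statistic)
                out.loc[a, b] = out.loc[b, a] = rho
    return out
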