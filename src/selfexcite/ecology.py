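"""State-level ecological incidence analysis.

With a national per-person incident rate ``mu``, the number of incidents
in a state of population ``N_i`` is Binomial(N_i, mu) under geographic
homogeneity; the binomial CDF

    F(k_i | N_i, mu) = sum_{j<=k_i} C(N_i, j) mu^j (1-mu)^(N_i-j)

locates each state in [0, 1], with values near 0 (1) flagging incidence
significantly below (above) the national average.  These F values are
then correlated across states with exogenous covariates: the
firearm-ownership proxy (fraction of all suicides in the state committed
with a firearm — a validated stand-in for ownership prevalence), serious
mental-illness prevalence, and strength-of-legislation rank.  An
ecological correlation describes aggregate units, not individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "national_rate",
    "binomial_cdf_significance",
    "firearm_proxy",
    "state_incidence",
    "incidence_covariate_correlation",
    "critical_pearson_r",
    "CorrelationResult",
]


def national_rate(catalog, populations: pd.Series | pd.DataFrame) -> float:
    """National per-person incident rate over the catalog span,
    ``mu = total incidents / total population``."""
    if isinstance(populations, pd.DataFrame):
        populations = populations["population"]
    total_pop = float(populations.sum())
    if total_pop <= 0:
        raise ValueError("total population must be positive")
    states = catalog.data["state"].dropna().unique()
    missing = [s for s in states if s not in populations.index]
    if missing:
        raise ValueError(f"populations missing for state(s): {missing}")
    return len(catalog) / total_pop


def binomial_cdf_significance(k_i: int, n_i: int, mu: float) -> float:
    """Binomial CDF ``F(k_i | N_i, mu)``, stable for N ~ 1e7, mu ~ 1e-7.

    Delegates to the regularized-incomplete-beta form; agrees with direct
    term-by-term summation on small inputs.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    if not 0 <= k_i <= n_i:
        raise ValueError("need 0 <= k_i <= N_i")
    return float(stats.binom.cdf(k_i, n_i, mu))


def firearm_proxy(suicide_table: pd.DataFrame) -> pd.Series:
    """Per-state fraction of suicides involving firearms.

    Counts are pooled over whatever years the table covers (sums of
    ``suicides_firearm`` and ``suicides_total`` per state, then one
    ratio — not a mean of yearly ratios).
    """
    grouped = suicide_table.groupby(level=0) if suicide_table.index.name == "state" else suicide_table.groupby("state")
    pooled = grouped[["suicides_firearm", "suicides_total"]].sum()
    if (pooled["suicides_total"] <= 0).any():
        raise ValueError("suicides_total must be positive for every state")
    if (pooled["suicides_firearm"] > pooled["suicides_total"]).any():
        raise ValueError("firearm suicides exceed total suicides for some state")
    frac = pooled["suicides_firearm"] / pooled["suicides_total"]
    frac.name = "firearm_proxy"
    return frac


def state_incidence(catalog, populations: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Per-state incidence table: observed count, population, binomial-CDF
    F value at the national rate, and the per-capita rate."""
    if isinstance(populations, pd.DataFrame):
        populations = populations["population"]
    mu = national_rate(catalog, populations)
    counts = catalog.data["state"].value_counts()
    rows = []
    for state, pop in populations.items():
        k = int(counts.get(state, 0))
        rows.append(
            {
                "state": state,
                "k": k,
                "population": int(pop),
                "F": binomial_cdf_significance(k, int(pop), mu),
                "per_capita_rate": k / pop,
            }
        )
    return pd.DataFrame(rows).set_index("state")


def critical_pearson_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| for a Pearson correlation of n pairs
    (t-distribution inversion with n-2 df)."""
    if n < 3:
        raise ValueError("need n >= 3")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str
    covariate: str
    critical_r_05: float
    partialed_out: str | None = None

    def as_dict(self) -> dict:
        return {
            "rho": self.rho,
            "p_value": self.p_value,
            "n": self.n,
            "method": self.method,
            "covariate": self.covariate,
            "critical_r_05": self.critical_r_05,
            "partialed_out": self.partialed_out,
        }


def _residualize(values: np.ndarray, control: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(control), control])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ coef


def incidence_covariate_correlation(
    incidence: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate: str,
    method: str = "pearson",
    incidence_column: str = "F",
    partial_out: str | None = None,
) -> CorrelationResult:
    """Correlate state incidence (binomial-CDF F values by default) with
    one exogenous covariate across states.

    ``partial_out`` names a second covariate (typically the firearm
    proxy) to adjust for: both variables are residualized on it by simple
    linear regression and the residuals correlated.  Alongside the
    two-sided p-value the critical |r| at alpha=0.05 for the achieved n
    is reported (0.28 at n=50).
    """
    wanted = [covariate] + ([partial_out] if partial_out and partial_out != covariate else [])
    joined = incidence[[incidence_column]].join(covariates[wanted], how="inner").dropna()
    n = len(joined)
    if n < 4:
        raise ValueError("need at least 4 states with both values")
    x = joined[incidence_column].to_numpy(dtype=float)
    y = joined[covariate].to_numpy(dtype=float)
    if partial_out:
        z = joined[partial_out].to_numpy(dtype=float)
        x = _residualize(x, z)
        y = _residualize(y, z)
    if method == "pearson":
        rho, p = stats.pearsonr(x, y)
    elif method == "spearman":
        rho, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(
        rho=float(rho),
        p_value=float(p),
        n=n,
        method=method,
        covariate=covariate,
        critical_r_05=critical_pearson_r(n),
        partialed_out=partial_out,
    )
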