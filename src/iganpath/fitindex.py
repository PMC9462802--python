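"""Implied covariance and global fit indices for recursive path models.

The fitted structural equations imply a covariance matrix

    Sigma = (I - B)^-1 (Phi (+) Psi) (I - B)^-T

with B the (strictly lower-triangular in topological order) coefficient
matrix, Phi the sample covariance of the exogenous block, and Psi the
diagonal residual variances.  The maximum-likelihood discrepancy between
Sigma and the sample matrix S,

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p,

yields chi2 = (n - 1) * F_ML (Wishart form; the n-multiplier variant is
exposed as an option) and the usual indices: RMSEA with a 90% CI from
noncentral chi-square inversion, CFI against the mutual-independence
baseline, and SRMSR as the root mean square of residual correlations.

Everything works in the correlation (z-scored) metric, matching the
standardized estimation, so chi2 is invariant to affine rescaling of the
input variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import PathFitResult, PathModelSpec

__all__ = ["FitIndices", "implied_covariance", "fit_indices",
           "check_sample_size", "rmsea_confidence_interval"]


@dataclass
class FitIndices:
    chi2: float
    df: int
    p_chi2: float
    rmsea: float
    rmsea_ci90: tuple          # (low, high)
    cfi: float
    srmsr: float
    baseline_chi2: float
    baseline_df: int
    saturated: bool = False

    def summary(self) -> str:
        """One-line text summary in the reporting style of the field."""
        lo, hi = self.rmsea_ci90
        return (f"chi2({self.df}) = {self.chi2:.2f}, p = {self.p_chi2:.3f}; "
                f"RMSEA = {self.rmsea:.3f} (90% CI {lo:.3f}-{hi:.3f}), "
                f"CFI = {self.cfi:.3f}, SRMSR = {self.srmsr:.3f}")

    def meets_published_thresholds(self) -> bool:
        """RMSEA < 0.05, CFI > 0.90, SRMSR < 0.05."""
        return self.rmsea < 0.05 and self.cfi > 0.90 and self.srmsr < 0.05


def _causal_order(spec: PathModelSpec) -> list:
    """Topological order treating correlational-link partners as preceding
    their host (the host equation regresses on the partner)."""
    g = spec.graph()
    for link in spec.correlational_links:
        other = link.b if link.host == link.a else link.a
        g.add_edge(other, link.host)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("spec with correlational hosts is not orderable")
    return list(nx.topological_sort(g))


def implied_covariance(spec: PathModelSpec, fitresult: PathFitResult,
                       metric: str = "correlation") -> pd.DataFrame:
    """Model-implied covariance matrix in the working metric.

    ``metric='correlation'`` (default) uses the z-scored sample, matching
    the standardized coefficients; ``'covariance'`` rescales to the raw
    sample variances.
    """
    order = _causal_order(spec)
    p = len(order)
    idx = {v: i for i, v in enumerate(order)}
    S = (fitresult.correlation if metric == "correlation"
         else fitresult.covariance).loc[order, order].to_numpy()

    B = np.zeros((p, p))
    E = np.zeros((p, p))  # Phi (+) Psi
    scale = np.sqrt(np.diag(S))
    for v in order:
        i = idx[v]
        if spec.nodes[v] == "exogenous":
            continue
        eq = fitresult.equations[v]
        for parent, est in eq.coefficients.items():
            # standardized coefficient rescaled to the working metric
            B[i, idx[parent]] = est.sc * scale[i] / scale[idx[parent]]
        E[i, i] = eq.epsilon * S[i, i]
    exog = [v for v in order if spec.nodes[v] == "exogenous"]
    for a in exog:
        for b in exog:
            E[idx[a], idx[b]] = S[idx[a], idx[b]]

    inv = np.linalg.inv(np.eye(p) - B)
    sigma = inv @ E @ inv.T
    names = list(spec.nodes)
    out = pd.DataFrame(sigma, index=order, columns=order)
    return out.loc[names, names]


def _count_free_parameters(spec: PathModelSpec) -> int:
    k = len(spec.exogenous())
    n_coef = len(spec.directed_edges) + len(spec.correlational_links)
    n_resid = len(spec.endogenous())
    n_exog_moments = k * (k + 1) // 2
    return n_coef + n_resid + n_exog_moments


def rmsea_confidence_interval(chi2: float, df: int, n: int,
                              level: float = 0.90) -> tuple:
    """RMSEA CI by inverting the noncentral chi-square distribution.

    The lower (upper) bound is the noncentrality lambda at which the
    observed chi2 sits at the (1+level)/2 (respectively (1-level)/2)
    quantile; bounds at zero when no such lambda exists.
    """
    if df <= 0 or n <= 1:
        return (0.0, 0.0)
    upper_tail = (1.0 + level) / 2.0
    lower_tail = (1.0 - level) / 2.0

    def solve(target):
        # find lambda with ncx2.cdf(chi2, df, lambda) = target
        if stats.chi2.cdf(chi2, df) < target:
            return 0.0
        lo, hi = 0.0, max(chi2, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2.0
            if hi > 1e8:
                break
        return float(optimize.brentq(
            lambda lam: stats.ncx2.cdf(chi2, df, lam) - target, lo, hi,
            xtol=1e-10))

    lam_lo = solve(upper_tail)
    lam_hi = solve(lower_tail)
    denom = df * (n - 1)
    return (np.sqrt(lam_lo / denom), np.sqrt(lam_hi / denom))


def fit_indices(
    spec: PathModelSpec,
    fitresult: PathFitResult,
    n: Optional[int] = None,
    discrepancy_multiplier: str = "n-1",
    srmsr_include_diagonal: bool = True,
) -> FitIndices:
    """Global fit of the fitted model against the sample correlation matrix.

    ``discrepancy_multiplier`` selects the Wishart ``"n-1"`` (default) or
    normal-theory ``"n"`` chi-square scaling.  ``srmsr_include_diagonal``
    includes the (generally nonzero for endogenous variables) diagonal
    residuals in the SRMSR average; conventions differ across packages.
    """
    if n is None:
        n = fitresult.n
    names = list(spec.nodes)
    p = len(names)
    S = fitresult.correlation.loc[names, names].to_numpy()
    sigma = implied_covariance(spec, fitresult).loc[names, names].to_numpy()

    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("implied covariance not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    mult = float(n - 1) if discrepancy_multiplier == "n-1" else float(n)
    f_ml = logdet_sigma - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
    chi2 = max(mult * f_ml, 0.0)
    df = p * (p + 1) // 2 - _count_free_parameters(spec)

    # baseline: mutual independence with free variances
    sigma_b = np.diag(np.diag(S))
    f_b = (float(np.sum(np.log(np.diag(S)))) - logdet_s
           + float(np.trace(S @ np.linalg.inv(sigma_b))) - p)
    chi2_b = max(mult * f_b, 0.0)
    df_b = p * (p + 1) // 2 - p

    saturated = df <= 0
    if saturated:
        chi2 = 0.0
        df = max(df, 0)

    p_chi2 = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rmsea = (np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))) if df > 0 else 0.0)
    ci = rmsea_confidence_interval(chi2, df, n)

    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - (max(chi2 - df, 0.0) / denom if denom > 0 else 0.0)

    d = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices(p, k=0 if srmsr_include_diagonal else 1)
    srmsr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    return FitIndices(chi2=float(chi2), df=int(df), p_chi2=p_chi2,
                      rmsea=float(rmsea), rmsea_ci90=ci, cfi=float(cfi),
                      srmsr=srmsr, baseline_chi2=float(chi2_b),
                      baseline_df=int(df_b), saturated=saturated)


def check_sample_size(n: int, n_variables: int) -> tuple:
    """Sample-size adequacy by the 20-observations-per-variable rule.

    Returns ``(passes, minimum)`` with ``minimum = 20 * n_variables``; the
    published analysis counted 19 dummy-level variables, giving a minimum
    cohort of 380.
    """
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    minimum = 20 * n_variables
    return (n >= minimum, minimum)
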