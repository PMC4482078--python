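"""Empirical-Bayes moderated one-sample t-testing of protein ratios.

The per-protein sample variances are shrunk toward a prior (d0, s0²)
estimated across all proteins by moment matching on the log scale, the
moderated statistic is referred to a t distribution with d0 + d_g degrees
of freedom, and significance is controlled by Benjamini-Hochberg
adjustment.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .quantfilter import ProteinRatioMatrix

__all__ = ["VariancePrior", "ModeratedResult", "estimate_variance_prior",
           "moderated_test", "bh_adjust", "fold_change", "concordance",
           "results_frame"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariancePrior:
    """Prior degrees of freedom (may be inf) and prior variance (log2²)."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if self.s0sq <= 0:
            raise ValueError("s0sq must be positive")
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (or inf)")


@dataclass(frozen=True)
class ModeratedResult:
    protein_id: str
    mean_log2: float
    n_reps: int
    sample_var: float
    df: int
    posterior_var: float
    t: float
    p: float
    adj_p: float
    call: str


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(sample_vars, dfs) -> VariancePrior:
    """Moment-match a scaled inverse chi-square prior to observed variances.

    Works on e_g = log s²_g - psi(d_g/2) + log(d_g/2). The excess of the
    empirical variance of e_g over the sampling contribution
    psi'(d_g/2) estimates psi'(d0/2); the mean fixes s0². When there is
    no excess dispersion the prior degrees of freedom are infinite and
    s0² = exp(mean(e_g)).
    """
    s2 = np.asarray(sample_vars, dtype=float)
    d = np.asarray(dfs, dtype=float)
    usable = (s2 > 0) & (d >= 1)
    s2, d = s2[usable], d[usable]
    n = s2.size
    if n < 2:
        raise ValueError("need >= 2 proteins with positive variance and df >= 1")
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = e.mean()
    evar = np.mean((e - ebar) ** 2 * n / (n - 1) - special.polygamma(1, d / 2.0))
    if evar <= 0:
        return VariancePrior(d0=math.inf, s0sq=float(np.exp(ebar)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0sq=s0sq)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def moderated_test(matrix: ProteinRatioMatrix,
                   prior: VariancePrior | str = "estimate",
                   alpha: float = 0.01) -> list[ModeratedResult]:
    """Moderated one-sample t-test of each protein's replicate ratios.

    Proteins with fewer than 2 non-missing replicate ratios are excluded
    (logged, not fatal). Calls: ``down37`` for adj_p <= alpha with a
    positive mean oriented ratio (more abundant at 30°C), ``up37`` for a
    negative one, else ``ns``.
    """
    ratios = matrix.ratios
    values = ratios.to_numpy()
    n_g = (~np.isnan(values)).sum(axis=1)
    excluded = ratios.index[n_g < 2]
    for protein in excluded:
        log.warning("excluding %s: fewer than 2 replicate ratios", protein)
    tested = n_g >= 2
    if not tested.any():
        return []
    vals = values[tested]
    ids = ratios.index[tested]
    n = n_g[tested].astype(float)
    mean = np.nanmean(vals, axis=1)
    s2 = np.nanvar(vals, axis=1, ddof=1)
    d = n - 1.0

    if isinstance(prior, str):
        if prior != "estimate":
            raise ValueError("prior must be a VariancePrior or 'estimate'")
        prior = estimate_variance_prior(s2, d)

    if math.isinf(prior.d0):
        post = np.full_like(s2, prior.s0sq)
        df_total = np.full_like(s2, math.inf)
    else:
        post = (prior.d0 * prior.s0sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    t_stat = mean / np.sqrt(post / n)
    with np.errstate(invalid="ignore"):
        p = np.where(np.isinf(df_total),
                     2.0 * stats.norm.sf(np.abs(t_stat)),
                     2.0 * stats.t.sf(np.abs(t_stat), df_total))
    p = np.clip(p, 0.0, 1.0)
    adj = bh_adjust(p)
    sig = adj <= alpha
    calls = np.where(sig & (mean > 0), "down37",
                     np.where(sig & (mean < 0), "up37", "ns"))

    return [ModeratedResult(protein_id=str(ids[i]), mean_log2=float(mean[i]),
                            n_reps=int(n[i]), sample_var=float(s2[i]),
                            df=int(d[i]), posterior_var=float(post[i]),
                            t=float(t_stat[i]), p=float(p[i]),
                            adj_p=float(adj[i]), call=str(calls[i]))
            for i in range(len(ids))]


def results_frame(results: list[ModeratedResult]) -> pd.DataFrame:
    """Serialize results with the fixed public column order."""
    return pd.DataFrame({
        "protein_id": [r.protein_id for r in results],
        "mean_log2": [r.mean_log2 for r in results],
        "n_reps": [r.n_reps for r in results],
        "sample_var": [r.sample_var for r in results],
        "posterior_var": [r.posterior_var for r in results],
        "t": [r.t for r in results],
        "p": [r.p for r in results],
        "adj_p": [r.adj_p for r in results],
        "call": [r.call for r in results],
    })


def fold_change(log2_ratio: float) -> tuple[float, str]:
    """Linear fold change and direction at 37°C for reporting.

    Returns ``2 ** |log2_ratio|`` rounded to two decimals; direction is
    ``down`` for a positive oriented ratio (more abundant at 30°C) and
    ``up`` for a negative one.
    """
    if not math.isfinite(log2_ratio):
        raise ValueError("log2 ratio must be finite")
    fold = round(2.0 ** abs(log2_ratio), 2)
    direction = "down" if log2_ratio > 0 else "up"
    return fold, direction


def concordance(a: list[ModeratedResult], b: list[ModeratedResult],
                alpha: float = 0.01) -> tuple[int, float | None]:
    """Sign agreement between two result sets.

    Restricted to proteins significant (adj_p <= alpha) in both sets;
    returns the intersection size and the fraction of those whose mean
    log2 ratios carry the same sign (None when the intersection is empty).
    """
    sig_a = {r.protein_id: r for r in a if r.adj_p <= alpha}
    sig_b = {r.protein_id: r for r in b if r.adj_p <= alpha}
    common = sorted(sig_a.keys() & sig_b.keys())
    if not common:
        return 0, None
    agree = sum(np.sign(sig_a[k].mean_log2) == np.sign(sig_b[k].mean_log2)
                for k in common)
    return len(common), agree / len(common)
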