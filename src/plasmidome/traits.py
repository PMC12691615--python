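"""Phylogenetic signal of host-benefit traits and subtype-environment tests.

Pagel's lambda measures how much of a quantitative trait's covariance
structure follows the tree: tip values are modelled as multivariate normal
with covariance sigma2 * C(lambda), where C(lambda) is the Brownian-motion
shared-path matrix with off-diagonal entries multiplied by lambda in
[0, 1].  The mean and sigma2 are profiled analytically (GLS mean, ML
variance), leaving a 1-D bounded likelihood maximisation in lambda; the
test against lambda = 0 is a likelihood-ratio test on chi2 with 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import tree_vcv


@dataclass
class LambdaFit:
    lambda_hat: float
    sigma2_hat: float
    log_likelihood: float
    log_likelihood_0: float
    p_value: float          # LRT vs lambda = 0
    n_tips: int


def _profiled_loglik(lam: float, C: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Log-likelihood at lambda with mu and sigma2 profiled out.

    Returns (logL, sigma2_hat).
    """
    n = y.size
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf, np.nan
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = (one @ Vi @ y) / (one @ Vi @ one)
    r = y - mu
    s2 = (r @ Vi @ r) / n
    if s2 <= 0:
        return -np.inf, np.nan
    logL = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return float(logL), float(s2)


def pagel_lambda_fit(tree: dendropy.Tree, trait: pd.Series) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda for a tip trait on a tree.

    ``trait`` is indexed by tip label and must cover a (sub)set of the
    tree's tips with at least 3 values; lambda is bounded to [0, 1].
    """
    taxa, C = tree_vcv(tree)
    trait = trait.dropna()
    common = [t for t in taxa if t in trait.index]
    if len(common) < 3:
        raise ValueError("need at least 3 tips with trait values")
    if len(common) < 10:
        warnings.warn("fewer than 10 tips: lambda estimate will be unstable",
                      stacklevel=2)
    idx = [taxa.index(t) for t in common]
    C = C[np.ix_(idx, idx)]
    y = trait[common].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant across tips; fit is degenerate")

    def neg(lam: float) -> float:
        return -_profiled_loglik(lam, C, y)[0]

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    # bounded Brent can miss a boundary optimum on flat surfaces; check ends
    cands = [(res.x, -res.fun), (0.0, _profiled_loglik(0.0, C, y)[0]),
             (1.0, _profiled_loglik(1.0, C, y)[0])]
    lam_hat, logL = max(cands, key=lambda c: c[1])
    _, s2 = _profiled_loglik(lam_hat, C, y)
    logL0 = _profiled_loglik(0.0, C, y)[0]
    lrt = max(0.0, 2.0 * (logL - logL0))
    p = float(stats.chi2.sf(lrt, df=1))
    return LambdaFit(float(lam_hat), s2, float(logL), float(logL0), p, len(common))


def subtype_treatment_table(
    subtypes: dict[str, str] | pd.Series,
    metadata: pd.DataFrame,
    strain_col: str = "strain",
    treatment_col: str = "treatment",
) -> tuple[pd.DataFrame, list[str]]:
    """Subtype x treatment strain counts for one focal replicon.

    Strains in the metadata without a subtype (they lack the replicon) are
    excluded from the table and returned separately as a drop log.
    """
    subtypes = dict(subtypes)
    rows = []
    dropped = []
    for _, rec in metadata.iterrows():
        s = rec[strain_col]
        if s in subtypes:
            rows.append((subtypes[s], rec[treatment_col]))
        else:
            dropped.append(s)
    if not rows:
        return pd.DataFrame(), dropped
    df = pd.DataFrame(rows, columns=["subtype", "treatment"])
    table = pd.crosstab(df["subtype"], df["treatment"])
    return table, dropped


def chisq_independence(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    Zero-margin rows/columns are dropped (with a warning) before testing.
    Returns (X2, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a non-negative 2-D count table")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns before chi-squared test",
                      stacklevel=2)
        t = t[np.ix_(keep_r, keep_c)]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2 after pruning")
    x2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(x2), int(df), float(p)
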