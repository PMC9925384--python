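"""Small- vs large-intestine APOBEC-family expression comparison.

Single-cell counts are normalized to relative counts (per-cell total
scaled to 1e4), averaged per tissue group, and compared as small/large
ratios; per-gene negative-binomial regressions test the tissue effect
while controlling per-cell total counts, feature counts and the other
APOBEC family members, with Benjamini-Hochberg correction across genes.
Bulk rows (nTPM) are consumed as given values and only ratioed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

RELATIVE_COUNT_SCALE = 1e4


def relative_counts(matrix: pd.DataFrame, scale: float = RELATIVE_COUNT_SCALE) -> pd.DataFrame:
    """Per-cell normalization: count / cell_total * scale (gene x cell)."""
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"cells with zero total counts: {list(zero.index[:10])}")
    return matrix / totals * scale


def group_mean_ratio(values: pd.Series, groups: pd.Series) -> dict:
    """Arithmetic group means (zeros included) and the small/large ratio.

    A zero large-intestine mean yields an infinite ratio, flagged, as in
    published tables that print 'Infinity'.
    """
    means = values.groupby(groups).mean()
    small = float(means.get("small", np.nan))
    large = float(means.get("large", np.nan))
    ratio = np.inf if large == 0 else small / large
    return dict(mean_small=small, mean_large=large, ratio=float(ratio),
                infinite=bool(large == 0))


def bulk_ratio(small_ntpm: float, large_ntpm: float) -> float:
    """Small/large ratio of published bulk nTPM values."""
    return np.inf if large_ntpm == 0 else small_ntpm / large_ntpm


def nb_regression_test(
    gene: str,
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    covariate_genes: tuple = (),
) -> dict:
    """Negative-binomial GLM of one gene's counts on tissue.

    Model: count ~ tissue + log(total counts) + n_features [+ other
    APOBEC genes' relative counts]; dispersion by maximum likelihood,
    two-tailed test on the tissue coefficient.  Falls back to a Poisson
    GLM (quasi-likelihood scale) on non-convergence, flagged.
    """
    ann = annotations.set_index("cell_id").loc[matrix.columns]
    tissues = ann["tissue"]
    if tissues.nunique() < 2 or tissues.value_counts().min() < 2:
        raise ValueError("need >= 2 cells in each of two tissue groups")
    y = matrix.loc[gene].values.astype(float)
    totals = matrix.sum(axis=0).values.astype(float)
    n_features = (matrix > 0).sum(axis=0).values.astype(float)
    X = pd.DataFrame(
        dict(
            tissue=(tissues == "small").astype(float).values,
            log_total=np.log(totals),
            n_features=n_features / 1000.0,
        ),
        index=matrix.columns,
    )
    rel = relative_counts(matrix)
    for g in covariate_genes:
        if g != gene and g in matrix.index:
            X[f"cov_{g}"] = np.log1p(rel.loc[g].values)
    X = sm.add_constant(X)

    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.NegativeBinomial(y, X).fit(disp=False, maxiter=200)
            converged = getattr(fit.mle_retvals, "converged", True) if not isinstance(
                fit.mle_retvals, dict) else fit.mle_retvals.get("converged", True)
            if not converged or not np.isfinite(fit.bse["tissue"]):
                raise RuntimeError("NB fit did not converge")
        except Exception:
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
            flagged = True
    coef = float(fit.params["tissue"])
    se = float(fit.bse["tissue"])
    z = coef / se if se > 0 else np.inf * np.sign(coef)
    p = float(2 * stats.norm.sf(abs(z)))

    group_small = y[X["tissue"].values == 1.0]
    group_large = y[X["tissue"].values == 0.0]
    boundary = group_small.sum() == 0 or group_large.sum() == 0
    return dict(gene=gene, coef=coef, se=se, p_value=p,
                fallback_poisson=flagged, boundary=bool(boundary))


def compare_genes(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    genes: tuple,
    covariates_within_family: bool = True,
) -> pd.DataFrame:
    """Per-gene group means, ratios and BH-adjusted NB tissue tests."""
    rel = relative_counts(matrix)
    ann = annotations.set_index("cell_id").loc[matrix.columns]
    rows = []
    for gene in genes:
        mr = group_mean_ratio(rel.loc[gene], ann["tissue"])
        covs = tuple(g for g in genes if g != gene) if covariates_within_family else ()
        test = nb_regression_test(gene, matrix, annotations, covariate_genes=covs)
        rows.append({**dict(gene=gene), **mr,
                     **{k: v for k, v in test.items() if k != "gene"}})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
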