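"""Sensitivity-corrected mutation burdens and mixed-effects rate models.

Detection sensitivity for a crypt is the probability that a clonal variant
yields at least ``min_alt_reads`` supporting reads (4 for SBS, 5 for ID)
when depth is Poisson-distributed around the sample's mean coverage and
each read carries the variant with probability equal to the sample's
median VAF.  Burdens divided by this sensitivity estimate the true
per-crypt mutation count, which is then regressed on age with
region-specific slopes and a per-patient random effect to obtain per-year
mutation rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .containers import REGIONS, VariantCounts

MIN_ALT_READS = {"SBS": 4, "ID": 5}
DEFAULT_N_SIMS = 100_000
MIN_MODEL_COVERAGE = 15.0


@dataclass
class SensitivityEstimate:
    sample_id: str
    variant_class: str
    median_vaf: float
    mean_depth: float
    min_alt_reads: int
    n_sims: int
    sensitivity: float
    mc_se: float


def closed_form_sensitivity(median_vaf: float, mean_depth: float, min_alt_reads: int) -> float:
    """Exact P(alt >= t) with depth ~ Poisson(mean_depth) and
    alt | depth ~ Binomial(depth, vaf); the oracle the Monte-Carlo
    estimate must agree with."""
    if not 0.0 < median_vaf <= 1.0:
        raise ValueError("median_vaf must be in (0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    dmax = int(mean_depth + 12 * np.sqrt(mean_depth) + 20)
    d = np.arange(dmax + 1)
    pois = stats.poisson.pmf(d, mean_depth)
    tail = 1.0 - stats.binom.cdf(min_alt_reads - 1, d, median_vaf)
    return float(np.sum(pois * tail))


def estimate_sensitivity(
    median_vaf: float,
    mean_depth: float,
    min_alt_reads: int = 4,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | np.random.Generator = 0,
    sample_id: str = "",
    variant_class: str = "SBS",
) -> SensitivityEstimate:
    """Monte-Carlo detection sensitivity (depth-Poisson, read-Bernoulli)."""
    if not 0.0 < median_vaf <= 1.0:
        raise ValueError("median_vaf must be in (0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=n_sims)
    alt = rng.binomial(depth, median_vaf)
    hits = alt >= min_alt_reads
    sens = float(hits.mean())
    se = float(np.sqrt(max(sens * (1 - sens), 1e-12) / n_sims))
    return SensitivityEstimate(sample_id, variant_class, median_vaf, mean_depth,
                               min_alt_reads, n_sims, sens, se)


def adjust_burden(raw_count: float, sensitivity: float) -> float:
    """Sensitivity-corrected burden: raw / sensitivity."""
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    return raw_count / sensitivity


def sample_median_vaf(counts: VariantCounts) -> pd.Series:
    """Median VAF per sample over the variants carried by that sample
    (cells with alt > 0); computed on the post-filter somatic set."""
    vaf = counts.vaf()
    carried = counts.alt > 0
    return vaf[carried].median(axis=0)


def crypt_burdens(
    counts: VariantCounts,
    metadata: pd.DataFrame,
    variant_class: str = "SBS",
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-crypt raw and sensitivity-adjusted burden table.

    Raw burden counts the somatic variants of the given class carried by
    each crypt; sensitivity uses the crypt's median VAF and its metadata
    mean coverage.
    """
    rng = np.random.default_rng(seed)
    mask = counts.info.set_index("variant_id")["variant_class"] == variant_class
    sub = counts.subset(counts.info.loc[mask.values, "variant_id"])
    med_vaf = sample_median_vaf(sub)
    raw = (sub.alt > 0).sum(axis=0)
    meta = metadata.set_index("sample_id")
    rows = []
    for sample in sub.samples:
        vaf = med_vaf.get(sample, np.nan)
        vaf = 0.5 if pd.isna(vaf) else float(vaf)
        est = estimate_sensitivity(
            vaf, float(meta.loc[sample, "mean_coverage"]),
            MIN_ALT_READS[variant_class], n_sims, rng, sample, variant_class,
        )
        rows.append(dict(
            sample_id=sample, patient=meta.loc[sample, "patient"],
            age=float(meta.loc[sample, "age_years"]),
            region=meta.loc[sample, "region"], celiac=int(meta.loc[sample, "celiac"]),
            raw_count=int(raw[sample]), sensitivity=est.sensitivity,
            adjusted_count=adjust_burden(float(raw[sample]), est.sensitivity),
        ))
    return pd.DataFrame(rows)


def apply_qc_exclusions(
    metadata: pd.DataFrame,
    mode: str = "burden",
    exclude_samples: tuple = (),
    chemo_patients: tuple = (),
    child_age: float = 18.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-level QC for rate modelling.

    ``burden`` mode drops samples below 15x coverage and a configured
    exclusion list; ``dynamics`` mode additionally drops celiac patients,
    children and chemotherapy-exposed patients, whose crypts may violate
    the constant-rate, fixed-size assumptions of the stem-cell model.
    """
    if mode not in ("burden", "dynamics"):
        raise ValueError("mode must be 'burden' or 'dynamics'")
    audit = []
    keep = metadata.copy()

    low = keep["mean_coverage"] < MIN_MODEL_COVERAGE
    audit.append(("coverage_lt_15", int(low.sum())))
    keep = keep[~low]
    listed = keep["sample_id"].isin(exclude_samples)
    audit.append(("exclusion_list", int(listed.sum())))
    keep = keep[~listed]

    if mode == "dynamics":
        celiac = keep["celiac"].astype(int) == 1
        audit.append(("celiac", int(celiac.sum())))
        keep = keep[~celiac]
        child = keep["age_years"] < child_age
        audit.append(("children", int(child.sum())))
        keep = keep[~child]
        chemo = keep["patient"].isin(chemo_patients)
        audit.append(("chemotherapy", int(chemo.sum())))
        keep = keep[~chemo]

    audit_df = pd.DataFrame(audit, columns=["criterion", "n_excluded"])
    return keep.reset_index(drop=True), audit_df


@dataclass
class LmmFit:
    """Region-wise per-year rates (and optional celiac-by-age effect) from
    a linear mixed model with per-patient random effects."""

    slopes: dict          # region -> (estimate, lo95, hi95)
    celiac_effect: tuple | None
    loglik: float
    n_obs: int
    random_structure: str  # "intercept+slope", "intercept", or "ols"
    result: object = None


def fit_burden_lmm(
    burdens: pd.DataFrame,
    include_celiac: bool = False,
    reml: bool = True,
    response: str = "adjusted_count",
) -> LmmFit:
    """REML fit of burden ~ age with region-specific slopes, optional
    celiac x age term, and random intercept + age slope per patient.

    Falls back to a random intercept (then to OLS) when the richer
    random-effects structure is singular or cannot be estimated.
    """
    data = burdens.copy()
    data["response"] = data[response].astype(float)
    regions = [r for r in REGIONS if r in set(data["region"])]
    for r in regions:
        data[f"age_{r}"] = np.where(data["region"] == r, data["age"], 0.0)
    terms = [f"age_{r}" for r in regions]
    if include_celiac:
        data["age_celiac"] = data["age"] * data["celiac"].astype(float)
        terms.append("age_celiac")
    formula = "response ~ 1 + " + " + ".join(terms)

    fit, structure = None, None
    for re_formula, label in (("~age", "intercept+slope"), ("1", "intercept")):
        if data["patient"].nunique() < 2:
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups=data["patient"], re_formula=re_formula)
                cand = model.fit(reml=reml, method=["lbfgs", "powell"])
            if np.isfinite(cand.params[terms]).all() and np.isfinite(cand.bse[terms]).all():
                fit, structure = cand, label
                break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if fit is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(formula, data).fit()
        structure = "ols"

    z = stats.norm.ppf(0.975)
    slopes = {}
    for r in regions:
        est = float(fit.params[f"age_{r}"])
        se = float(fit.bse[f"age_{r}"])
        slopes[r] = (est, est - z * se, est + z * se)
    celiac_effect = None
    if include_celiac:
        est = float(fit.params["age_celiac"])
        se = float(fit.bse["age_celiac"])
        celiac_effect = (est, est - z * se, est + z * se)
    return LmmFit(slopes, celiac_effect, float(fit.llf), len(data), structure, fit)


def lrt_nested(burdens: pd.DataFrame, response: str = "adjusted_count") -> dict:
    """Likelihood-ratio comparison (ML fits) of the celiac-augmented model
    against the region-slopes-only model."""
    full = fit_burden_lmm(burdens, include_celiac=True, reml=False, response=response)
    null = fit_burden_lmm(burdens, include_celiac=False, reml=False, response=response)
    lr = 2.0 * (full.loglik - null.loglik)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return dict(lr_stat=float(lr), df=1, p_value=p)
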