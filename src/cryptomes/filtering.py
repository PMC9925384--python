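"""Post-calling variant filter chain.

Three stages, applied in order, reproduce the post-processing used for
low-input crypt whole genomes:

1. **Read metrics** — mapping-artifact predicate: median alignment score
   of supporting reads >= 140 and fewer than half of them clipped; indels
   additionally need a caller quality >= 300 at positions covered by at
   least 15 reads.
2. **Germline classification** — per patient, alt and depth are
   aggregated across all of the patient's crypts at each site and tested
   against a one-sided exact binomial null (success probability 0.5, or
   0.95 on male sex chromosomes, alternative "less"); p-values are
   Benjamini-Hochberg adjusted across all of the patient's variants and a
   variant is somatic iff q < 1e-5, otherwise germline.
3. **Beta-binomial overdispersion (rho)** — systematic artifacts show
   similar low VAFs across samples (low rho) whereas true somatic variants
   are present in some samples and absent in others (high rho).  Rho is
   estimated per variant by maximizing the beta-binomial likelihood on a
   log-spaced grid with the mean fixed at the pooled VAF; variants with
   rho < 0.1 are classified artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln
from statsmodels.stats.multitest import multipletests

from .containers import VariantCounts

#: read-metric thresholds
MIN_ALIGNMENT_SCORE = 140.0
MAX_CLIPPED_FRACTION = 0.5
MIN_INDEL_QUALITY = 300.0
MIN_INDEL_DEPTH = 15

GERMLINE_Q_CUTOFF = 1e-5
RHO_CUTOFF = 0.1
#: 64 log-spaced rho grid points, as in the Shearwater-style filter
RHO_GRID = np.logspace(np.log10(1e-6), np.log10(0.89), 64)

MALE_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def read_metric_filter(metrics: pd.DataFrame, variant_class: pd.Series) -> pd.DataFrame:
    """Per-variant pass/fail decisions for the mapping-artifact stage.

    ``variant_class`` maps variant_id -> {SBS, ID}.  Variants with missing
    required metrics are flagged unevaluable and fail with classification NA.
    """
    m = metrics.set_index("variant_id")
    is_id = variant_class.reindex(m.index).eq("ID").values
    als = m["median_alignment_score"].values.astype(float)
    clip = m["clipped_fraction"].values.astype(float)
    qual = m["pindel_quality"].values.astype(float) if "pindel_quality" in m else np.full(len(m), np.nan)
    mdep = m["min_supporting_depth"].values.astype(float) if "min_supporting_depth" in m else np.full(len(m), np.nan)

    unevaluable = np.isnan(als) | np.isnan(clip)
    unevaluable |= is_id & (np.isnan(qual) | np.isnan(mdep))
    with np.errstate(invalid="ignore"):
        ok = (als >= MIN_ALIGNMENT_SCORE) & (clip < MAX_CLIPPED_FRACTION)
        ok &= ~is_id | ((qual >= MIN_INDEL_QUALITY) & (mdep >= MIN_INDEL_DEPTH))
    ok &= ~unevaluable
    return pd.DataFrame(
        dict(
            variant_id=m.index,
            stage="read_metrics",
            statistic=als,
            verdict=np.where(ok, "pass", "fail"),
            classification="NA",
            unevaluable=unevaluable,
        )
    )


def germline_binomial_filter(
    counts: VariantCounts,
    metadata: pd.DataFrame,
    male_sex_chroms: frozenset = MALE_SEX_CHROMS,
) -> pd.DataFrame:
    """Germline/somatic classification per (patient, variant).

    Aggregates alt and depth over each patient's samples, applies the
    one-sided exact binomial test (alternative "less") and BH-adjusts
    within the patient's full variant family.  Only variants observed in
    a patient (aggregate alt > 0) are tested for that patient; sites with
    zero aggregate depth are unevaluable and skipped.
    """
    meta = metadata.set_index("sample_id")
    chroms = counts.info.set_index("variant_id")["chrom"]
    out = []
    for patient, group in meta.groupby("patient"):
        samples = [s for s in group.index if s in counts.alt.columns]
        if not samples:
            continue
        agg_alt = counts.alt[samples].sum(axis=1).values
        agg_depth = counts.depth[samples].sum(axis=1).values
        test = (agg_alt > 0) & (agg_depth > 0)
        if not test.any():
            continue
        is_male = "sex" in group and (group["sex"] == "M").any()
        on_sex = chroms.isin(male_sex_chroms).values if is_male else np.zeros(len(chroms), bool)
        p0 = np.where(on_sex, 0.95, 0.5)
        pvals = stats.binom.cdf(agg_alt[test], agg_depth[test], p0[test])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        somatic = qvals < GERMLINE_Q_CUTOFF
        out.append(
            pd.DataFrame(
                dict(
                    variant_id=counts.alt.index[test],
                    patient=patient,
                    stage="germline",
                    p=pvals,
                    statistic=qvals,
                    verdict=np.where(somatic, "pass", "fail"),
                    classification=np.where(somatic, "somatic", "germline"),
                )
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["variant_id", "patient", "stage", "p", "statistic", "verdict", "classification"]
        )
    return pd.concat(out, ignore_index=True)


def _betabinom_loglik(alt: np.ndarray, depth: np.ndarray, mu: float, rho: float) -> float:
    """Beta-binomial log-likelihood at (mu, rho) for one variant."""
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    ll = (
        gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
        + betaln(alt + a, depth - alt + b) - betaln(a, b)
    )
    return float(ll.sum())


def rho_mle(alt_vector, depth_vector, grid: np.ndarray = RHO_GRID) -> tuple[float, bool]:
    """Grid-search MLE of the beta-binomial overdispersion rho with the
    mean fixed at the pooled VAF.  Returns (rho, boundary_flag); the flag
    marks a degenerate pooled VAF of 0 or 1 where rho is undefined and the
    lower grid boundary is returned.
    """
    alt = np.asarray(alt_vector, dtype=float)
    depth = np.asarray(depth_vector, dtype=float)
    keep = depth > 0
    alt, depth = alt[keep], depth[keep]
    if len(alt) < 2:
        raise ValueError("rho estimation needs >= 2 samples with depth > 0")
    mu = alt.sum() / depth.sum()
    if mu <= 0.0 or mu >= 1.0:
        return float(grid[0]), True
    ll = np.array([_betabinom_loglik(alt, depth, mu, rho) for rho in grid])
    return float(grid[int(np.argmax(ll))]), False


def rho_filter(counts: VariantCounts, grid: np.ndarray = RHO_GRID) -> pd.DataFrame:
    """Rho estimates and artifact verdicts for all variants at once.

    Vectorized over variants: the data-dependent part of the likelihood
    is evaluated for the whole variant x sample matrix at each grid point.
    """
    alt = counts.alt.values.astype(float)
    depth = counts.depth.values.astype(float)
    live = depth > 0
    if (live.sum(axis=1) < 2).any():
        raise ValueError("rho estimation needs >= 2 samples with depth > 0 per variant")
    mu = alt.sum(axis=1) / depth.sum(axis=1)
    degenerate = (mu <= 0.0) | (mu >= 1.0)
    mu_safe = np.clip(mu, 1e-12, 1 - 1e-12)[:, None]

    ll = np.full((len(grid), alt.shape[0]), -np.inf)
    for gi, rho in enumerate(grid):
        a = mu_safe * (1 - rho) / rho
        b = (1 - mu_safe) * (1 - rho) / rho
        terms = betaln(alt + a, depth - alt + b) - betaln(a, b)
        ll[gi] = np.where(live, terms, 0.0).sum(axis=1)
    rho_hat = grid[np.argmax(ll, axis=0)]
    rho_hat = np.where(degenerate, grid[0], rho_hat)
    artifact = (rho_hat < RHO_CUTOFF) & ~degenerate
    return pd.DataFrame(
        dict(
            variant_id=counts.alt.index,
            stage="rho",
            statistic=rho_hat,
            verdict=np.where(artifact, "fail", "pass"),
            classification=np.where(artifact, "artifact", "somatic"),
            degenerate=degenerate,
        )
    ).reset_index(drop=True)


@dataclass
class FilterChainResult:
    somatic: VariantCounts
    audit: pd.DataFrame             # stage, n_in, n_out
    decisions: pd.DataFrame         # per-stage per-variant decisions
    somatic_patients: pd.DataFrame  # (variant_id, patient) pairs deemed somatic


def run_filter_chain(
    counts: VariantCounts,
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
) -> FilterChainResult:
    """Read-metric -> germline -> rho, with per-stage attrition counts."""
    audit_rows = []
    all_decisions = []

    n_in = len(counts)
    rm = read_metric_filter(
        metrics, counts.info.set_index("variant_id")["variant_class"]
    )
    all_decisions.append(rm)
    passed = set(rm.loc[rm["verdict"] == "pass", "variant_id"])
    counts1 = counts.subset([v for v in counts.variant_ids if v in passed])
    audit_rows.append(dict(stage="read_metrics", n_in=n_in, n_out=len(counts1)))

    germ = germline_binomial_filter(counts1, metadata)
    all_decisions.append(germ)
    somatic_pairs = germ.loc[germ["classification"] == "somatic", ["variant_id", "patient"]]
    somatic_set = set(somatic_pairs["variant_id"])
    counts2 = counts1.subset([v for v in counts1.variant_ids if v in somatic_set])
    audit_rows.append(dict(stage="germline", n_in=len(counts1), n_out=len(counts2)))

    if len(counts2):
        rho = rho_filter(counts2)
        all_decisions.append(rho)
        rho_pass = set(rho.loc[rho["verdict"] == "pass", "variant_id"])
    else:
        rho_pass = set()
    counts3 = counts2.subset([v for v in counts2.variant_ids if v in rho_pass])
    audit_rows.append(dict(stage="rho", n_in=len(counts2), n_out=len(counts3)))

    final_pairs = somatic_pairs[somatic_pairs["variant_id"].isin(rho_pass)]
    return FilterChainResult(
        somatic=counts3,
        audit=pd.DataFrame(audit_rows),
        decisions=pd.concat(all_decisions, ignore_index=True),
        somatic_patients=final_pairs.reset_index(drop=True),
    )
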