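import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cryptomes.containers import VariantCounts
from cryptomes.filtering import (
    RHO_GRID, germline_binomial_filter, read_metric_filter, rho_mle,
    run_filter_chain,
)


def _metrics(rows):
    return pd.DataFrame(rows)


def _vclass(d):
    return pd.Series(d)


class TestReadMetricFilter:
    @pytest.mark.parametrize(
        "als,clip,expected",
        [
            (140.0, 0.49, "pass"),   # both boundaries on the passing side
            (139.0, 0.0, "fail"),    # alignment score strictly below 140
            (200.0, 0.5, "fail"),    # half of reads clipped is too many
        ],
    )
    def test_sbs_thresholds(self, als, clip, expected):
        dec = read_metric_filter(
            _metrics([dict(variant_id="v", median_alignment_score=als,
                           clipped_fraction=clip)]),
            _vclass({"v": "SBS"}),
        )
        assert dec.loc[0, "verdict"] == expected

    @pytest.mark.parametrize(
        "qual,depth,expected",
        [(300.0, 15, "pass"), (299.0, 15, "fail"), (300.0, 14, "fail")],
    )
    def test_indel_extra_thresholds(self, qual, depth, expected):
        dec = read_metric_filter(
            _metrics([dict(variant_id="v", median_alignment_score=200.0,
                           clipped_fraction=0.1, pindel_quality=qual,
                           min_supporting_depth=depth)]),
            _vclass({"v": "ID"}),
        )
        assert dec.loc[0, "verdict"] == expected

    def test_missing_metric_is_unevaluable(self):
        dec = read_metric_filter(
            _metrics([dict(variant_id="v", median_alignment_score=np.nan,
                           clipped_fraction=0.1)]),
            _vclass({"v": "SBS"}),
        )
        assert dec.loc[0, "verdict"] == "fail"
        assert bool(dec.loc[0, "unevaluable"])


def _counts_single_patient(alt_rows, depth_rows, chrom="chr1"):
    samples = [f"c{j}" for j in range(len(alt_rows[0]))]
    ids = [f"v{i}" for i in range(len(alt_rows))]
    info = pd.DataFrame(dict(variant_id=ids, chrom=chrom,
                             pos=np.arange(1, len(ids) + 1) * 100,
                             ref="C", alt="T", variant_class="SBS"))
    idx = pd.Index(ids, name="variant_id")
    counts = VariantCounts(
        info,
        pd.DataFrame(alt_rows, index=idx, columns=samples),
        pd.DataFrame(depth_rows, index=idx, columns=samples),
    )
    meta = pd.DataFrame(dict(sample_id=samples, patient="P1", age_years=50.0,
                             region="duodenum", celiac=0, sex="F",
                             mean_coverage=25.0))
    return counts, meta


class TestGermlineFilter:
    def test_exact_binomial_pvalues_match_closed_form(self):
        # aggregates 0/100 (clearly somatic), 50/100 (clearly germline)
        counts, meta = _counts_single_patient(
            [[0, 0], [25, 25]], [[50, 50], [50, 50]]
        )
        # force the 0-alt variant to be 'observed' via one supporting read
        counts.alt.iloc[0, 0] = 0  # stays unobserved -> untested
        dec = germline_binomial_filter(counts, meta)
        row = dec.set_index("variant_id").loc["v1"]
        assert row["p"] == pytest.approx(stats.binom.cdf(50, 100, 0.5))
        assert row["classification"] == "germline"

    def test_low_vaf_aggregate_is_somatic(self):
        counts, meta = _counts_single_patient([[2, 0]], [[100, 100]])
        dec = germline_binomial_filter(counts, meta)
        assert dec.loc[0, "p"] == pytest.approx(stats.binom.cdf(2, 200, 0.5))
        assert dec.loc[0, "classification"] == "somatic"

    def test_male_sex_chromosome_null(self):
        counts, meta = _counts_single_patient([[47, 48]], [[50, 50]], chrom="chrX")
        meta["sex"] = "M"
        dec = germline_binomial_filter(counts, meta)
        assert dec.loc[0, "p"] == pytest.approx(stats.binom.cdf(95, 100, 0.95))
        assert dec.loc[0, "classification"] == "germline"

    def test_invariant_to_splitting_counts_across_samples(self):
        """Only patient-level aggregates matter."""
        a, meta = _counts_single_patient([[10, 30]], [[40, 60]])
        b, _ = _counts_single_patient([[30, 10]], [[60, 40]])
        pa = germline_binomial_filter(a, meta).loc[0, "p"]
        pb = germline_binomial_filter(b, meta).loc[0, "p"]
        assert pa == pytest.approx(pb)

    def test_bh_is_monotone_in_p(self):
        rng = np.random.default_rng(0)
        alt = rng.integers(0, 20, size=(50, 3))
        depth = alt + rng.integers(5, 30, size=(50, 3))
        counts, meta = _counts_single_patient(alt.tolist(), depth.tolist())
        dec = germline_binomial_filter(counts, meta).sort_values("p")
        q = dec["statistic"].values
        assert (np.diff(q) >= -1e-12).all()
        assert ((q >= dec["p"].values - 1e-12)).all()


class TestRhoFilter:
    def test_private_clonal_variant_passes(self):
        rho, flag = rho_mle([12] + [0] * 9, [25] * 10)
        assert rho >= 0.1 and not flag

    def test_shared_low_vaf_artifact_fails(self):
        rho, flag = rho_mle([1] * 10, [25] * 10)
        assert rho < 0.1 and not flag

    def test_identical_samples_hit_lower_boundary(self):
        rho, flag = rho_mle([5, 5], [10, 10])
        assert rho == pytest.approx(RHO_GRID[0])
        assert not flag

    def test_degenerate_pooled_vaf_flagged(self):
        rho, flag = rho_mle([0, 0], [25, 25])
        assert flag and rho == pytest.approx(RHO_GRID[0])

    def test_grid_argmax_matches_bruteforce_loglik(self):
        """The vectorized grid search equals an independent per-point
        beta-binomial likelihood evaluation."""
        from scipy.stats import betabinom
        alt = np.array([12, 0, 3, 0, 7])
        depth = np.array([25, 24, 26, 25, 25])
        mu = alt.sum() / depth.sum()
        lls = []
        for rho in RHO_GRID:
            a = mu * (1 - rho) / rho
            b = (1 - mu) * (1 - rho) / rho
            lls.append(betabinom.logpmf(alt, depth, a, b).sum())
        expected = RHO_GRID[int(np.argmax(lls))]
        assert rho_mle(alt, depth)[0] == pytest.approx(expected)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            rho_mle([5], [10])


class TestFilterChain:
    def test_empty_input(self):
        counts, meta = _counts_single_patient([[1, 1]], [[10, 10]])
        empty = counts.subset([])
        metrics = pd.DataFrame(columns=["variant_id", "median_alignment_score",
                                        "clipped_fraction"])
        res = run_filter_chain(empty, metrics, meta)
        assert len(res.somatic) == 0
        assert (res.audit["n_in"] - res.audit["n_out"] >= 0).all()

    def test_output_subset_and_attrition_consistency(self, labelled_cohort):
        _, bundle = labelled_cohort
        res = run_filter_chain(bundle.counts, bundle.metrics, bundle.metadata)
        assert set(res.somatic.variant_ids) <= set(bundle.counts.variant_ids)
        audit = res.audit.set_index("stage")
        assert audit.loc["read_metrics", "n_in"] == len(bundle.counts)
        assert audit.loc["germline", "n_in"] == audit.loc["read_metrics", "n_out"]
        assert audit.loc["rho", "n_in"] == audit.loc["germline", "n_out"]
        assert audit.loc["rho", "n_out"] == len(res.somatic)

    def test_truth_recovery_on_labelled_cohort(self, labelled_cohort):
        """Germline recall, artifact removal and somatic retention on a
        cohort with known labels (the headline filter benchmark)."""
        _, bundle = labelled_cohort
        res = run_filter_chain(bundle.counts, bundle.metrics, bundle.metadata)
        truth = bundle.truth.mutations.set_index("variant_id")
        kept = set(res.somatic.variant_ids)
        germ = set(truth.index[truth["label"] == "germline"])
        art = set(truth.index[truth["label"] == "artifact"])
        som = set(truth.index[truth["label"] == "somatic"])

        dec = res.decisions.query("stage == 'germline'").copy()
        own = dec["patient"] == dec["variant_id"].map(truth["patient"])
        germ_dec = dec[own & dec["variant_id"].isin(germ)]
        recall = (germ_dec["classification"] == "germline").mean()
        assert recall >= 0.99
        assert 1 - len(kept & art) / len(art) >= 0.90
        assert len(kept & som) / len(som) >= 0.95
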