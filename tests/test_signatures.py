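import numpy as np
import pandas as pd
import pytest

from cryptomes.signatures import (
    ExposureVector, apobec_positive, branch_proportion_test, build_spectrum,
    cosine, em_attribute, finalize_exposures, permitted_signatures,
    scale_wes, two_round_prune,
)
from cryptomes.trinuc import CHANNELS


def _spectrum(vec):
    return pd.Series(vec, index=pd.Index(CHANNELS, name="channel"))


class TestBuildSpectrum:
    def test_purine_record_folds_to_pyrimidine_channel(self):
        #            123456
        ref = {"c": "ATGCAT" + "ACGT" * 3}
        muts = pd.DataFrame([dict(chrom="c", pos=3, ref="G", alt="C")])
        spec = build_spectrum(muts, ref)
        # T G C on forward -> pyrimidine strand G[C>G]A ... revcomp(TGC)=GCA
        assert spec["G[C>G]A"] == 1
        assert spec.sum() == 1

    def test_counts_conserved_and_empty_is_zero(self):
        ref = {"c": "AACTAACTAA"}
        muts = pd.DataFrame([dict(chrom="c", pos=3, ref="C", alt="T"),
                             dict(chrom="c", pos=7, ref="C", alt="A")])
        assert build_spectrum(muts, ref).sum() == 2
        assert build_spectrum(muts.iloc[:0], ref).sum() == 0

    def test_reference_mismatch_raises(self):
        ref = {"c": "AACTAACTAA"}
        muts = pd.DataFrame([dict(chrom="c", pos=3, ref="G", alt="T")])
        with pytest.raises(ValueError, match="c:3"):
            build_spectrum(muts, ref)

    def test_sampled_signature_recovers_catalog_shape(self, catalog):
        rng = np.random.default_rng(0)
        x = rng.multinomial(1000, catalog["SBS2"].values)
        assert cosine(x, catalog["SBS2"].values) >= 0.95


class TestCosine:
    def test_self_similarity_is_one(self, catalog):
        assert cosine(catalog["SBS5"], catalog["SBS5"]) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        a, b = np.zeros(96), np.zeros(96)
        a[0], b[1] = 1, 1
        assert cosine(a, b) == 0.0

    def test_matches_bruteforce_dot_product(self, catalog):
        a = catalog["SBS2"].values
        b = catalog["SBS13"].values
        brute = sum(x * y for x, y in zip(a, b)) / (
            np.sqrt(sum(x * x for x in a)) * np.sqrt(sum(y * y for y in b))
        )
        assert cosine(a, b) == pytest.approx(brute, rel=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(96), np.ones(96))


class TestEmAttribute:
    def test_pure_component_exact_on_orthogonal_catalog(self, orthogonal_catalog):
        spec = _spectrum(500 * orthogonal_catalog["ORTHO2"].values)
        exp = em_attribute(spec, orthogonal_catalog)
        assert exp.proportions["ORTHO2"] == pytest.approx(1.0, abs=1e-6)
        assert exp.proportions.drop("ORTHO2").abs().max() < 1e-6

    def test_pure_component_on_overlapping_catalog(self, catalog):
        spec = _spectrum(500 * catalog["SBS1"].values)
        exp = em_attribute(spec, catalog[["SBS1", "SBS5", "SBS18"]])
        assert exp.proportions["SBS1"] > 0.99

    def test_mixture_recovery_within_three_percent(self, catalog):
        rng = np.random.default_rng(1)
        p = 0.6 * catalog["SBS5"].values + 0.4 * catalog["SBS18"].values
        spec = _spectrum(rng.multinomial(5000, p))
        exp = em_attribute(spec, catalog[["SBS1", "SBS5", "SBS18"]])
        assert exp.proportions["SBS5"] == pytest.approx(0.6, abs=0.03)
        assert exp.proportions["SBS18"] == pytest.approx(0.4, abs=0.03)

    def test_exposure_counts_conserve_total(self, catalog):
        rng = np.random.default_rng(2)
        spec = _spectrum(rng.multinomial(3000, catalog["SBS5"].values))
        exp = em_attribute(spec, catalog)
        assert exp.counts.sum() == pytest.approx(spec.sum())

    def test_loglik_nondecreasing_across_iterations(self, catalog):
        """EM monotonicity, tracked with an explicit re-implementation."""
        rng = np.random.default_rng(3)
        p = 0.5 * catalog["SBS2"].values + 0.5 * catalog["SBS13"].values
        x = rng.multinomial(2000, p).astype(float)
        S = catalog.values
        pi = np.full(S.shape[1], 1 / S.shape[1])
        lls = []
        for _ in range(200):
            mix = np.maximum(S @ pi, 1e-300)
            lls.append(float(x @ np.log(mix)))
            pi = pi * (S.T @ (x / mix))
            pi /= pi.sum()
        assert all(b - a >= -1e-9 for a, b in zip(lls, lls[1:]))

    def test_duplicate_catalog_entries_flagged_but_sum_preserved(self, catalog):
        dup = catalog[["SBS1"]].copy()
        dup["SBS1_copy"] = dup["SBS1"]
        spec = _spectrum(400 * catalog["SBS1"].values)
        exp = em_attribute(spec, dup)
        assert any("degenerate" in f for f in exp.flags)
        assert exp.counts.sum() == pytest.approx(400.0)

    def test_empty_spectrum_rejected(self, catalog):
        with pytest.raises(ValueError):
            em_attribute(_spectrum(np.zeros(96)), catalog)


class TestTwoRoundPrune:
    def test_minor_signature_pruned(self, catalog):
        rng = np.random.default_rng(4)
        p = (0.85 * catalog["SBS5"].values + 0.10 * catalog["SBS1"].values
             + 0.05 * catalog["SBS18"].values)
        spec = _spectrum(rng.multinomial(10_000, p))
        sub = catalog[["SBS1", "SBS5", "SBS18"]]
        round1 = em_attribute(spec, sub)
        pruned = two_round_prune(spec, sub)
        dropped = set(sub.columns) - set(pruned.proportions[pruned.proportions > 0].index)
        # whatever fell at or below 10% in round 1 must be gone
        for name, share in round1.proportions.items():
            if share <= 0.10:
                assert name not in pruned.proportions.index or \
                    name in dropped or pruned.proportions[name] == 0

    def test_burst_spectrum_reconstructs_above_cosine_08(self, catalog):
        rng = np.random.default_rng(5)
        p = 0.5 * catalog["SBS2"].values + 0.5 * catalog["SBS13"].values
        spec = _spectrum(rng.multinomial(500, p))
        exp = two_round_prune(spec, catalog)
        assert exp.reconstruction_cosine > 0.8
        assert not any("cosine" in f for f in exp.flags)

    def test_counts_conserved_after_pruning(self, catalog):
        rng = np.random.default_rng(6)
        spec = _spectrum(rng.multinomial(2000, catalog["SBS18"].values))
        exp = two_round_prune(spec, catalog)
        assert exp.counts.sum() == pytest.approx(2000.0)


class TestPermittedSignatures:
    def _exposure(self, shares, catalog):
        props = pd.Series(0.0, index=catalog.columns)
        for k, v in shares.items():
            props[k] = v
        return ExposureVector(counts=props * 100, proportions=props, total=100.0,
                              reconstruction_cosine=1.0, loglik=0.0)

    def test_five_percent_rule_on_qualifying_branch(self, catalog):
        exps = {0: self._exposure({"SBS5": 0.48, "SBS88": 0.52}, catalog),
                1: self._exposure({"SBS5": 0.951, "SBS2": 0.049}, catalog)}
        allowed, flags = permitted_signatures(exps, {0: 1200, 1: 800}, catalog)
        assert "SBS88" in allowed          # 52% on a branch of length 1200
        assert "SBS2" not in allowed       # 4.9% everywhere
        assert not flags

    def test_short_branches_cannot_permit(self, catalog):
        exps = {0: self._exposure({"SBS2": 0.30, "SBS5": 0.70}, catalog),
                1: self._exposure({"SBS5": 1.0}, catalog)}
        allowed, _ = permitted_signatures(exps, {0: 150, 1: 1000}, catalog)
        assert "SBS2" not in allowed

    def test_no_long_branch_falls_back_to_ubiquitous(self, catalog):
        exps = {0: self._exposure({"SBS2": 0.5, "SBS13": 0.5}, catalog)}
        allowed, flags = permitted_signatures(exps, {0: 150}, catalog)
        assert allowed == {"SBS1", "SBS5", "SBS18"}
        assert flags

    def test_finalize_restricted_to_allowed(self, catalog):
        rng = np.random.default_rng(7)
        spec = _spectrum(rng.multinomial(
            1000, 0.7 * catalog["SBS5"].values + 0.3 * catalog["SBS18"].values))
        final = finalize_exposures({0: spec}, catalog, {"SBS5", "SBS18"})
        assert set(final[0].proportions.index) == {"SBS5", "SBS18"}
        assert final[0].counts.sum() == pytest.approx(1000.0)


class TestPositivityAndScaling:
    @pytest.mark.parametrize("s2,s13,expected",
                             [(0.03, 0.03, True), (0.049, 0.0, False), (0.0, 0.0, False)])
    def test_apobec_positive_combined_share(self, s2, s13, expected, catalog):
        props = pd.Series(0.0, index=catalog.columns)
        props["SBS2"], props["SBS13"] = s2, s13
        props["SBS5"] = 1 - s2 - s13
        exp = ExposureVector(props * 100, props, 100.0, 1.0, 0.0)
        assert apobec_positive(exp) is expected

    @pytest.mark.parametrize("count,expected", [(12, 600), (0, 0)])
    def test_wes_scaling(self, count, expected):
        assert scale_wes(count) == expected


class TestBranchProportionTest:
    def test_reproduces_published_small_vs_large_comparison(self):
        res = branch_proportion_test([[68, 349], [6, 1069]])
        assert res["p_value"] == pytest.approx(1.6e-35, rel=0.05)
        assert res["proportions"][0] == pytest.approx(0.163, abs=5e-4)

    def test_symmetric_table_is_null(self):
        res = branch_proportion_test([[5, 5], [5, 5]])
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_low_expected_cell_flagged(self):
        res = branch_proportion_test([[1, 1], [0, 200]])
        assert res["low_expected"]
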