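import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from conftest import make_snp
from phytomr import mr
from phytomr.mr import (
    IvConfig,
    cochran_q,
    egger,
    harmonize,
    ivw,
    mode_estimators,
    mr_presso,
    run_mr,
    select_instruments,
    steiger,
    usable,
    wald_ratio,
    weighted_median,
)
from phytomr.synthdata import GwasSimSpec, simulate_gwas


def gwas_row(rsid, chrom=1, pos=1_000_000, ea="A", oa="C", eaf=0.3,
             beta=0.1, se=0.01, p=1e-8, n=18_340):
    return {
        "rsid": rsid, "chrom": chrom, "pos": pos, "effect_allele": ea,
        "other_allele": oa, "eaf": eaf, "beta": beta, "se": se, "p": p, "n": n,
    }


class TestSelectInstruments:
    def test_weak_instrument_excluded_by_f(self):
        df = pd.DataFrame([gwas_row("rs1", beta=0.1, se=0.05)])  # F = 4
        assert select_instruments(df, None).empty

    def test_greedy_clump_keeps_lowest_p(self):
        df = pd.DataFrame(
            [
                gwas_row("rs1", pos=1_000_000, p=1e-8),
                gwas_row("rs2", pos=1_010_000, p=1e-6),
            ]
        )
        ld = {frozenset(("rs1", "rs2")): 0.5}
        out = select_instruments(df, ld)
        assert list(out["rsid"]) == ["rs1"]

    def test_distant_snps_both_kept_despite_high_r2(self):
        df = pd.DataFrame(
            [
                gwas_row("rs1", pos=1_000_000, p=1e-8),
                gwas_row("rs2", pos=1_600_000, p=1e-6),
            ]
        )
        ld = {frozenset(("rs1", "rs2")): 0.9}
        assert len(select_instruments(df, ld)) == 2

    def test_unknown_ld_pairs_treated_independent(self):
        df = pd.DataFrame(
            [
                gwas_row("rs1", pos=1_000_000, p=1e-8),
                gwas_row("rs2", pos=1_010_000, p=1e-6),
            ]
        )
        assert len(select_instruments(df, None)) == 2

    def test_p_threshold_applied(self):
        df = pd.DataFrame([gwas_row("rs1", p=1e-4)])
        assert select_instruments(df, None).empty

    def test_empty_result_is_not_an_exception(self):
        df = pd.DataFrame([gwas_row("rs1", p=0.5)])
        out = select_instruments(df, None)
        assert out.empty


class TestHarmonize:
    def exposure(self):
        return pd.DataFrame([gwas_row("rs1", ea="A", oa="C", eaf=0.3, beta=0.1)])

    def test_matching_alleles_kept(self):
        out = harmonize(self.exposure(),
                        pd.DataFrame([gwas_row("rs1", ea="A", oa="C", beta=0.05)]))
        assert out[0].action_taken == "kept"
        assert out[0].beta_out == pytest.approx(0.05)

    def test_swapped_alleles_flip_beta_and_eaf(self):
        out = harmonize(
            self.exposure(),
            pd.DataFrame([gwas_row("rs1", ea="C", oa="A", beta=0.05, eaf=0.7)]),
        )
        assert out[0].action_taken == "flipped"
        assert out[0].beta_out == pytest.approx(-0.05)
        assert out[0].eaf_out == pytest.approx(0.3)

    def test_palindromic_ambiguous_frequency_dropped(self):
        exp = pd.DataFrame([gwas_row("rs1", ea="A", oa="T", eaf=0.50)])
        out = harmonize(exp, pd.DataFrame([gwas_row("rs1", ea="A", oa="T", eaf=0.50)]))
        assert out[0].action_taken == "dropped"

    def test_palindromic_informative_frequency_flipped(self):
        exp = pd.DataFrame([gwas_row("rs1", ea="A", oa="T", eaf=0.10)])
        out = harmonize(
            exp, pd.DataFrame([gwas_row("rs1", ea="A", oa="T", eaf=0.88, beta=0.05)])
        )
        assert out[0].action_taken == "flipped"
        assert out[0].beta_out == pytest.approx(-0.05)
        assert out[0].eaf_out == pytest.approx(0.12)

    def test_incompatible_allele_sets_dropped(self):
        out = harmonize(self.exposure(),
                        pd.DataFrame([gwas_row("rs1", ea="G", oa="T")]))
        assert out[0].action_taken == "dropped"


class TestWaldRatio:
    def test_ratio_and_se(self):
        r = wald_ratio(make_snp(0.1, 0.05, se_out=0.01))
        assert r.beta == pytest.approx(0.5)
        r = wald_ratio(make_snp(0.2, 0.0, se_out=0.01))
        assert r.beta == 0.0 and r.or_ == pytest.approx(1.0)
        r = wald_ratio(make_snp(0.2, 0.1, se_out=0.01))
        assert r.se == pytest.approx(0.05)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_snp(0.0, 0.1))


class TestIvw:
    def test_single_snp_reduces_to_wald(self):
        snp = make_snp(0.1, 0.05, se_out=0.02)
        assert ivw([snp]).beta == pytest.approx(wald_ratio(snp).beta)
        assert ivw([snp]).se == pytest.approx(wald_ratio(snp).se)

    def test_closed_form_weighted_least_squares(self, snp_factory):
        snps = [
            snp_factory(0.1, 0.04),
            snp_factory(0.2, 0.12),
            snp_factory(0.3, 0.15),
        ]
        assert ivw(snps, random_effects=False).beta == pytest.approx(
            0.073 / 0.14, rel=1e-9
        )

    def test_homogeneous_ratios_fixed_equals_random(self, snp_factory):
        snps = [snp_factory(b, 0.4 * b) for b in (0.1, 0.2, 0.3)]
        fixed = ivw(snps, random_effects=False)
        rand = ivw(snps, random_effects=True)
        assert fixed.beta == pytest.approx(0.4)
        assert fixed.se == pytest.approx(rand.se)
        q, _, p = cochran_q(snps)
        assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0)

    def test_random_effects_never_deflate(self, snp_factory):
        snps = [snp_factory(0.1, 0.0), snp_factory(0.1, 0.1), snp_factory(0.1, 0.05)]
        assert ivw(snps, random_effects=True).se >= ivw(
            snps, random_effects=False
        ).se


class TestEgger:
    def test_exact_line_through_origin(self, snp_factory):
        snps = [snp_factory(b, 0.5 * b) for b in (0.1, 0.2, 0.3)]
        res, intercept, _, _ = egger(snps)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert res.beta == pytest.approx(0.5)

    def test_exact_line_with_intercept(self, snp_factory):
        snps = [snp_factory(b, 0.02 + 0.5 * b) for b in (0.1, 0.2, 0.3, 0.4)]
        res, intercept, _, _ = egger(snps)
        assert intercept == pytest.approx(0.02, rel=1e-9)
        assert res.beta == pytest.approx(0.5, rel=1e-9)

    def test_refuses_below_three_snps(self, snp_factory):
        with pytest.raises(ValueError, match="3"):
            egger([snp_factory(0.1, 0.05), snp_factory(0.2, 0.1)])

    def test_directional_pleiotropy_detected(self):
        hits = 0
        for r in range(100):
            ex, out, _ = simulate_gwas(
                GwasSimSpec(
                    n_snps=30, theta=0.1, invalid_fraction=1.0,
                    pleiotropy_mean=0.02, pleiotropy_sd=0.002,
                    allele_flip_fraction=0.0, palindromic_fraction=0.0,
                    seed=1000 + r,
                )
            )
            snps = usable(harmonize(ex, out))
            _, _, _, p_int = egger(snps)
            hits += p_int < 0.05
        assert hits / 100 >= 0.8


class TestWeightedMedian:
    def test_middle_element_equal_weights(self, snp_factory):
        snps = [snp_factory(0.1, 0.1 * r) for r in (0.2, 0.5, 0.9)]
        assert weighted_median(snps, n_boot=50, seed=0).beta == pytest.approx(0.5)

    def test_dominant_weight_tracks_that_snp(self):
        # middle snp carries ~90% of the weight
        snps = [
            make_snp(0.1, 0.02, se_out=0.03, rsid="rs1"),
            make_snp(0.1, 0.05, se_out=0.01 / 3, rsid="rs2"),
            make_snp(0.1, 0.09, se_out=0.03, rsid="rs3"),
        ]
        assert weighted_median(snps, n_boot=50, seed=0).beta == pytest.approx(
            0.5, abs=0.02
        )

    def test_robust_to_single_wild_outlier(self, snp_factory):
        rng = np.random.default_rng(0)
        snps = [snp_factory(0.1, 0.1 * (0.5 + rng.normal(0, 0.01))) for _ in range(10)]
        snps.append(snp_factory(0.1, 0.1 * 25.0))  # wild ratio 25
        res = weighted_median(snps, n_boot=200, seed=1)
        assert abs(res.beta - 0.5) < 2 * res.se + 0.05

    def test_refuses_below_three(self, snp_factory):
        with pytest.raises(ValueError):
            weighted_median([snp_factory(0.1, 0.05)] * 2)


class TestModeEstimators:
    def test_zero_spread_returns_common_ratio(self, snp_factory):
        snps = [snp_factory(b, 0.7 * b) for b in (0.1, 0.2, 0.3)]
        simple, weighted = mode_estimators(snps, n_boot=10, seed=0)
        assert simple.beta == pytest.approx(0.7)
        assert weighted.beta == pytest.approx(0.7)
        assert simple.se == 0.0

    def test_majority_cluster_dominates_simple_mode(self, snp_factory):
        ratios = [0.5] * 7 + [2.0] * 3
        rng = np.random.default_rng(1)
        snps = [
            snp_factory(0.1, 0.1 * (r + rng.normal(0, 0.01))) for r in ratios
        ]
        simple, _ = mode_estimators(snps, n_boot=20, seed=0)
        assert simple.beta == pytest.approx(0.5, abs=0.1)

    def test_weighted_mode_tracks_upweighted_minority(self):
        rng = np.random.default_rng(2)
        snps = [
            make_snp(0.1, 0.1 * (0.5 + rng.normal(0, 0.01)), se_out=0.05,
                     rsid=f"a{i}") for i in range(7)
        ] + [
            make_snp(0.1, 0.1 * (2.0 + rng.normal(0, 0.01)), se_out=0.002,
                     rsid=f"b{i}") for i in range(3)
        ]
        _, weighted = mode_estimators(snps, n_boot=20, seed=0)
        assert weighted.beta == pytest.approx(2.0, abs=0.1)


class TestCochranQ:
    def test_two_point_closed_form(self):
        # ratios 0 and 1 with equal weights w -> Q = w/2
        snps = [
            make_snp(0.1, 0.0, se_out=0.01, rsid="rs1"),
            make_snp(0.1, 0.1, se_out=0.01, rsid="rs2"),
        ]
        w = (0.1 / 0.01) ** 2
        q, dof, _ = cochran_q(snps)
        assert q == pytest.approx(w / 2)
        assert dof == 1

    def test_null_distribution_chi_square(self):
        # null causal effect: the first-order weights are then exact and Q
        # follows its reference chi-square distribution
        qs = []
        n_snps = 10
        for r in range(400):
            ex, out, _ = simulate_gwas(
                GwasSimSpec(n_snps=n_snps, theta=0.0, allele_flip_fraction=0.0,
                            palindromic_fraction=0.0, seed=2000 + r)
            )
            snps = usable(harmonize(ex, out))
            qs.append(cochran_q(snps)[0])
        ks = kstest(qs, chi2(df=n_snps - 1).cdf)
        assert ks.pvalue > 0.001


class TestMrPresso:
    def test_refuses_below_four(self, snp_factory):
        with pytest.raises(ValueError, match="4"):
            mr_presso([snp_factory(0.1, 0.05)] * 3)

    def test_planted_outlier_flagged_and_distortion_reported(self):
        ex, out, _ = simulate_gwas(
            GwasSimSpec(n_snps=20, theta=0.2, allele_flip_fraction=0.0,
                        palindromic_fraction=0.0, seed=77)
        )
        out = out.copy()
        out.loc[0, "beta"] += 10 * out.loc[0, "se"]
        snps = usable(harmonize(ex, out))
        global_p, outliers, distortion_p = mr_presso(snps, n_sim=500, seed=0)
        assert global_p < 0.05
        assert snps[0].rsid in outliers
        assert distortion_p is not None

    def test_removing_outlier_moves_ivw_toward_truth(self):
        theta = 0.2
        ex, out, _ = simulate_gwas(
            GwasSimSpec(n_snps=20, theta=theta, allele_flip_fraction=0.0,
                        palindromic_fraction=0.0, seed=78)
        )
        out = out.copy()
        out.loc[0, "beta"] += 10 * out.loc[0, "se"]
        snps = usable(harmonize(ex, out))
        _, outliers, _ = mr_presso(snps, n_sim=500, seed=0)
        cleaned = [s for s in snps if s.rsid not in outliers]
        assert abs(ivw(cleaned).beta - theta) < abs(ivw(snps).beta - theta)

    def test_null_global_p_not_small(self):
        ps = []
        for r in range(40):
            ex, out, _ = simulate_gwas(
                GwasSimSpec(n_snps=15, theta=0.2, allele_flip_fraction=0.0,
                            palindromic_fraction=0.0, seed=3000 + r)
            )
            snps = usable(harmonize(ex, out))
            ps.append(mr_presso(snps, n_sim=200, seed=r)[0])
        assert np.mean(np.array(ps) < 0.05) < 0.25


class TestSteiger:
    def test_direction_from_variance_ordering(self, snp_factory):
        snps = [snp_factory(0.2, 0.01, se_out=0.01, se_exp=0.01) for _ in range(3)]
        direction, p = steiger(snps, 10_000, 10_000)
        assert direction is True

    def test_symmetric_r2_gives_p_near_one(self, snp_factory):
        snps = [snp_factory(0.2, 0.2, se_out=0.01, se_exp=0.01) for _ in range(3)]
        _, p = steiger(snps, 10_000, 10_000)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_small_sample_rejected(self, snp_factory):
        with pytest.raises(ValueError):
            steiger([snp_factory(0.1, 0.05)], 2, 100)


class TestInvariances:
    def test_allele_orientation_invariance(self, snp_factory):
        """Jointly flipping (beta_exp, beta_out) of any SNP leaves estimates
        unchanged."""
        rng = np.random.default_rng(3)
        snps = [
            snp_factory(0.1 + 0.02 * i, 0.05 + 0.01 * i + rng.normal(0, 0.005))
            for i in range(8)
        ]
        flipped = [
            make_snp(-s.beta_exp, -s.beta_out, s.se_out, s.se_exp,
                     rsid=s.rsid + "f")
            for s in snps
        ]
        assert ivw(snps).beta == pytest.approx(ivw(flipped).beta)
        assert egger(snps)[0].beta == pytest.approx(egger(flipped)[0].beta)
        assert weighted_median(snps, n_boot=10, seed=0).beta == pytest.approx(
            weighted_median(flipped, n_boot=10, seed=0).beta
        )
        assert cochran_q(snps)[0] == pytest.approx(cochran_q(flipped)[0])


class TestRunMr:
    def test_single_instrument_emits_only_wald_and_ivw(self):
        ex = pd.DataFrame([gwas_row("rs1", beta=0.15, se=0.01, p=1e-9)])
        out_df = pd.DataFrame([gwas_row("rs1", beta=0.05, se=0.005)])
        results, report, forest = run_mr(ex, out_df, None, n_boot=10,
                                         presso_n_sim=10)
        assert {r.method for r in results} == {"wald", "ivw"}
        assert report.cochran_q is None

    def test_no_valid_instruments_recorded_not_raised(self):
        ex = pd.DataFrame([gwas_row("rs1", p=0.9)])
        out_df = pd.DataFrame([gwas_row("rs1")])
        results, report, forest = run_mr(ex, out_df, None)
        assert results == [] and forest.empty

    def test_full_battery_on_synthetic_taxon(self):
        ex, out_df, ld = simulate_gwas(
            GwasSimSpec(n_snps=25, theta=math.log(1.27), seed=11)
        )
        results, report, forest = run_mr(ex, out_df, ld, seed=5, n_boot=100,
                                         presso_n_sim=200)
        methods = {r.method for r in results}
        assert methods == {"ivw", "egger", "weighted_median", "simple_mode",
                           "weighted_mode"}
        ivw_res = next(r for r in results if r.method == "ivw")
        assert ivw_res.ci95[0] < ivw_res.or_ < ivw_res.ci95[1]
        assert report.steiger_direction is True
        assert set(forest.columns) >= {"method", "n_snps", "OR", "ci_low",
                                       "ci_high", "p", "q_p"}

    def test_confounder_screen_removes_annotated_snps(self):
        df = pd.DataFrame([gwas_row("rs1"), gwas_row("rs2")])
        out = mr.confounder_screen(
            df, [("rs1", "Hepatitis C"), ("rs2", "height")],
            ["hepatitis a", "hepatitis c", "alcoholism", "autoimmune hepatitis"],
        )
        assert list(out["rsid"]) == ["rs2"]
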