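import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpair import fixtures
from mirpair.integration import (
    IntegrationConfig,
    PairResult,
    correlation_pvalue,
    critical_r,
    dedup_pairs,
    pairwise_pearson,
    run_integration,
    s_score,
    select_pairs,
)
from mirpair.io import ExpressionMatrix, SampleSheet


def _pair(mirna="mi", mrna="g", cor=-0.6, p=0.01, s=1.0, **kw):
    defaults = dict(
        mirna_id=mirna, mrna_id=mrna, cor=cor, p_value=p, adj_p=p,
        logratio_mirna=1.0, logratio_mrna=-0.5, mean_exp_mirna=3.0,
        mean_exp_mrna=4.0, s_score=s, fc_mirna=2.0, fc_mrna=-1.41,
    )
    defaults.update(kw)
    return PairResult(**defaults)


class TestPairwisePearson:
    def test_perfect_anti_and_pro_correlation(self):
        samples = ["s1", "s2", "s3", "s4"]
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        mrna = ExpressionMatrix(["g"], samples, x)
        mirna = ExpressionMatrix(["mi_neg", "mi_pos"], samples, np.vstack([-x, x]))
        r = pairwise_pearson(mrna, mirna)
        assert r[0, 0] == pytest.approx(-1.0)
        assert r[0, 1] == pytest.approx(1.0)

    def test_textbook_hand_computation(self):
        # x = (1..5), y = (2,1,4,3,6): sum of cross-deviations 10,
        # ss_x = 10, ss_y = 14.8, so r = 10 / sqrt(148) = 0.82199
        samples = [f"s{i}" for i in range(5)]
        mrna = ExpressionMatrix(["g"], samples, [[1, 2, 3, 4, 5]])
        mirna = ExpressionMatrix(["mi"], samples, [[2, 1, 4, 3, 6]])
        assert pairwise_pearson(mrna, mirna)[0, 0] == pytest.approx(
            10 / np.sqrt(148), rel=1e-12
        )

    def test_sample_mismatch_lists_difference(self):
        mrna = ExpressionMatrix(["g"], ["a", "b", "c"], [[1, 2, 3]])
        mirna = ExpressionMatrix(["mi"], ["a", "b", "d"], [[1, 2, 3]])
        with pytest.raises(ValueError, match="'c'.*'d'"):
            pairwise_pearson(mrna, mirna)

    def test_zero_variance_feature_yields_nan(self, caplog):
        samples = ["s1", "s2", "s3"]
        mrna = ExpressionMatrix(["flat", "g"], samples, [[1, 1, 1], [1, 2, 3]])
        mirna = ExpressionMatrix(["mi"], samples, [[3, 2, 1]])
        with caplog.at_level("WARNING"):
            r = pairwise_pearson(mrna, mirna)
        assert np.isnan(r[0, 0]) and np.isfinite(r[1, 0])
        assert "zero-variance" in caplog.text


class TestCorrelationPvalue:
    def test_zero_correlation_is_coin_flip(self):
        assert correlation_pvalue(0.0, 20, "less") == pytest.approx(0.5)

    def test_screen_threshold_sits_just_under_alpha(self):
        assert correlation_pvalue(-0.38, 20, "less") == pytest.approx(0.0492, abs=5e-5)

    def test_two_sided_value(self):
        assert correlation_pvalue(-0.5, 20, "two_sided") == pytest.approx(
            0.0248, abs=5e-5
        )

    def test_limits_at_perfect_correlation(self):
        assert correlation_pvalue(-1.0, 10, "less") == 0.0
        assert correlation_pvalue(1.0, 10, "two_sided") == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 2)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-0.999, 0.999), st.integers(3, 100))
    def test_one_sided_tails_sum_to_one(self, rho, n):
        p_low = correlation_pvalue(rho, n, "less")
        p_high = correlation_pvalue(-rho, n, "less")
        assert p_low + p_high == pytest.approx(1.0, abs=1e-9)


class TestCriticalR:
    def test_published_screen_gate(self):
        r = critical_r(20, 0.05, "less")
        assert r == pytest.approx(0.3783, abs=5e-5)
        assert round(r, 2) == 0.38

    def test_two_sided_differs(self):
        assert critical_r(20, 0.05, "two_sided") == pytest.approx(0.4438, abs=5e-5)

    def test_alpha_half_gives_zero(self):
        assert critical_r(20, 0.5, "less") == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(4, 60), st.floats(0.001, 0.45))
    def test_exact_inverse_of_pvalue(self, n, alpha):
        r = critical_r(n, alpha, "less")
        assert correlation_pvalue(-r, n, "less") == pytest.approx(alpha, rel=1e-9)


class TestSScore:
    @pytest.mark.parametrize(
        "lr_mi, lr_mr, expected, tol",
        [
            (0.83, -0.65, 1.07, 0.02),  # published top pair
            (1.92, -0.28, 1.06, 0.02),  # published second pair
            (0.0, 123.0, 0.0, 1e-12),
        ],
    )
    def test_examples(self, lr_mi, lr_mr, expected, tol):
        assert s_score(lr_mi, lr_mr) == pytest.approx(expected, abs=tol)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_antisymmetric_and_sign_rule(self, a, b):
        s = s_score(a, b)
        assert s_score(-a, b) == pytest.approx(-s, rel=1e-12)
        if abs(a) > 1e-6 and abs(b) > 1e-6:  # avoid product underflow to 0
            assert (s > 0) == (np.sign(a) != np.sign(b))


class TestDedupPairs:
    def test_isoforms_collapse_to_most_negative_cor(self):
        pairs = [
            _pair(mrna="probeA", cor=-0.4),
            _pair(mrna="probeB", cor=-0.6),
        ]
        annot = pd.DataFrame(
            {"feature_id": ["probeA", "probeB"], "gene_symbol": ["G", "G"]}
        )
        kept = dedup_pairs(pairs, mrna_annot=annot)
        assert len(kept) == 1
        assert kept[0].cor == -0.6

    def test_precursor_mirna_removed(self):
        pairs = [_pair(mirna="mat"), _pair(mirna="pre")]
        annot = pd.DataFrame(
            {
                "feature_id": ["mat", "pre"],
                "is_mature": [True, False],
                "organism": ["hsa", "hsa"],
            }
        )
        kept = dedup_pairs(pairs, mirna_annot=annot)
        assert [p.mirna_id for p in kept] == ["mat"]

    def test_wrong_organism_removed(self):
        pairs = [_pair(mirna="human"), _pair(mirna="mouse")]
        annot = pd.DataFrame(
            {
                "feature_id": ["human", "mouse"],
                "is_mature": [True, True],
                "organism": ["hsa", "mmu"],
            }
        )
        kept = dedup_pairs(pairs, mirna_annot=annot)
        assert [p.mirna_id for p in kept] == ["human"]

    def test_already_unique_input_unchanged(self):
        pairs = [_pair(mrna="g1"), _pair(mrna="g2")]
        assert dedup_pairs(pairs) == pairs

    def test_unannotated_feature_is_an_error(self):
        annot = pd.DataFrame({"feature_id": ["other"], "gene_symbol": ["X"]})
        with pytest.raises(ValueError, match="unannotated feature 'g'"):
            dedup_pairs([_pair()], mrna_annot=annot)


class TestSelectPairs:
    def test_published_table_replays_intact(self):
        pairs = fixtures.load_pairs()
        final = select_pairs(pairs, rho_max=-0.5, p_max=0.05, require_positive_s=True)
        assert len(final) == 97
        assert (final[0].mirna_id, final[0].mrna_id) == ("hsa-miR-574-3p", "RNF125")

    def test_zero_s_score_removed_under_strict_gate(self):
        pairs = [_pair(s=0.0), _pair(mrna="g2", s=0.5)]
        final = select_pairs(pairs, require_positive_s=True)
        assert [p.mrna_id for p in final] == ["g2"]

    def test_empty_input(self):
        assert select_pairs([]) == []

    def test_ranking_most_negative_first_then_p(self):
        pairs = [
            _pair(mrna="g1", cor=-0.55, p=0.02),
            _pair(mrna="g2", cor=-0.80, p=0.01),
            _pair(mrna="g3", cor=-0.55, p=0.001),
        ]
        final = select_pairs(pairs)
        assert [p.mrna_id for p in final] == ["g2", "g3", "g1"]


class TestRunIntegration:
    def test_forced_single_pair(self):
        samples = [f"s{i}" for i in range(20)]
        sheet = SampleSheet(samples, ["R"] * 11 + ["NR"] * 9)
        rng = np.random.default_rng(5)
        mi = np.where(np.arange(20) < 11, 2.0, 0.5) + rng.normal(0, 0.1, 20)
        mrna = ExpressionMatrix(["gene"], samples, (6.0 - mi)[None, :])
        mirna = ExpressionMatrix(["mir"], samples, mi[None, :])
        _, counts, final = run_integration(mrna, mirna, sheet)
        assert len(final) == 1
        assert (final[0].mirna_id, final[0].mrna_id) == ("mir", "gene")
        assert final[0].cor == pytest.approx(-1.0, abs=1e-9)

    def test_stage_counts_nonincreasing_and_deterministic(self):
        from mirpair.simulate import SimConfig, simulate_cohort

        cfg = SimConfig(seed=9, n_mrna=120, n_mirna=40)
        mrna, mirna, sheet, _ = simulate_cohort(cfg)
        tested, counts, final = run_integration(mrna, mirna, sheet)
        cascade = [
            counts["pairs_all"],
            counts["pairs_p"],
            counts["pairs_mature_dedup_screen"],
            counts["pairs_final_rho_p"],
            counts["pairs_s_positive"],
        ]
        assert cascade == sorted(cascade, reverse=True)
        assert counts["pairs_s_positive"] == len(final)
        # adjusted p assigned over the tested universe and >= raw p
        assert all(p.adj_p >= p.p_value - 1e-12 for p in tested)
        _, counts2, final2 = run_integration(mrna, mirna, sheet)
        assert counts == counts2 and final == final2

    def test_config_validation(self):
        with pytest.raises(ValueError, match="rho"):
            IntegrationConfig(rho_final=0.5).validate()
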