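import numpy as np
import pandas as pd
import pytest

from rbpregulon.classify import run_level
from rbpregulon.features import (
    RBP_PREDICTORS,
    TRANSCRIPT_PREDICTORS,
    biotype_effect_summary,
    fit_elastic_net,
    fit_multivariate,
    fit_stepwise,
    per_rbp_transcript_models,
    rbp_feature_table,
    transcript_feature_table,
)
from rbpregulon.formats import Peak, TranscriptRecord
from rbpregulon.network import TargetNetwork, map_targets


@pytest.fixture(scope="module")
def cohort_tables(small_cohort):
    """Classification + feature tables for the shared synthetic cohort."""
    data = small_cohort
    net = map_targets(data.peaks, data.annotation, flank=300)
    recs, _ = run_level(
        data.truth.rbp_genes, net, data.expr_rna, data.annotation,
        expr_protein=data.expr_protein, level="transcript", n_reps=5, seed=5,
    )
    rbp_tab = rbp_feature_table(
        net, data.annotation, data.expr_rna, recs,
        expr_protein=data.expr_protein, ppi_edges=data.ppi_edges,
        domain_counts=data.domain_counts, rbp_genes=data.truth.rbp_genes,
    )
    tx_tab = transcript_feature_table(net, data.annotation, recs)
    return data, net, recs, rbp_tab, tx_tab


class TestFeatureTables:
    def test_rbp_table_has_exactly_the_schema(self, cohort_tables):
        _, _, _, rbp_tab, _ = cohort_tables
        assert list(rbp_tab.columns) == ["rbp_id", "response"] + RBP_PREDICTORS + ["flags"]

    def test_transcript_table_has_exactly_the_schema(self, cohort_tables):
        _, _, _, _, tx_tab = cohort_tables
        assert list(tx_tab.columns) == ["rbp_id", "transcript_id", "response"] + TRANSCRIPT_PREDICTORS

    def test_n_targets_and_response_follow_classification(self, cohort_tables):
        data, net, recs, rbp_tab, _ = cohort_tables
        row = rbp_tab.set_index("rbp_id").loc["RBP001"]
        assert row.n_targets == len(net.targets["RBP001"])
        rec = next(r for r in recs if r.rbp_id == "RBP001")
        assert row.response == pytest.approx(rec.median_target_rho)

    def test_ppi_degree_counted_from_edges(self):
        net = TargetNetwork(targets={"R": set()})

        class FakeRec:
            rbp_id = "R"
            representative_id = "R.t1"
            median_target_rho = 0.1

        tab = rbp_feature_table(
            net, [], _empty_expr(), [FakeRec()],
            ppi_edges=[("R", "A"), ("R", "B"), ("A", "B")],
            domain_counts={"R": 3},
        )
        assert tab.iloc[0].n_ppi_partners == 2
        assert tab.iloc[0].n_rna_binding_domains == 3

    def test_median_clip_p_odd_count(self):
        net = TargetNetwork()
        tx = TranscriptRecord("T1", "G", "b", "c", "+", ((0, 100),))
        for p in (1e-5, 1e-4, 1e-3):
            net.add("R", "T1", Peak("R", "c", 10, 20, "+", p))

        class FakeRec:
            rbp_id = "R"
            representative_id = "x"
            median_target_rho = 0.0

        tab = rbp_feature_table(net, [tx], _empty_expr(), [FakeRec()])
        assert tab.iloc[0].median_clip_p == pytest.approx(1e-4)

    def test_missing_domain_and_ppi_flagged_not_silent(self, cohort_tables):
        data, net, recs, _, _ = cohort_tables
        tab = rbp_feature_table(net, data.annotation, data.expr_rna, recs[:1])
        row = tab.iloc[0]
        assert row.n_rna_binding_domains == 0 and row.n_ppi_partners == 0
        assert "no_domain_entry" in row["flags"] and "no_ppi_entry" in row["flags"]

    def test_end_distances_plus_strand(self):
        tx = TranscriptRecord("T", "G", "pc", "c", "+", ((1000, 2000),))
        net = TargetNetwork()
        net.add("R", "T", Peak("R", "c", 1200, 1230, "+", 1e-4))

        class FakeRec:
            rbp_id = "R"
            target_ids = ["T"]
            rho_targets = np.array([0.5])

        (row,) = transcript_feature_table(net, [tx], [FakeRec()]).itertuples(index=False)
        assert (row.dist_5prime, row.dist_3prime) == (200, 799)

    def test_end_distances_swap_on_minus_strand(self):
        tx = TranscriptRecord("T", "G", "pc", "c", "-", ((1000, 2000),))
        net = TargetNetwork()
        net.add("R", "T", Peak("R", "c", 1200, 1230, "-", 1e-4))

        class FakeRec:
            rbp_id = "R"
            target_ids = ["T"]
            rho_targets = np.array([0.5])

        (row,) = transcript_feature_table(net, [tx], [FakeRec()]).itertuples(index=False)
        assert (row.dist_5prime, row.dist_3prime) == (799, 200)

    def test_peak_at_transcript_start_gives_zero_distance(self):
        tx = TranscriptRecord("T", "G", "pc", "c", "+", ((1000, 2000),))
        net = TargetNetwork()
        net.add("R", "T", Peak("R", "c", 1000, 1030, "+", 1e-4))

        class FakeRec:
            rbp_id = "R"
            target_ids = ["T"]
            rho_targets = np.array([0.5])

        (row,) = transcript_feature_table(net, [tx], [FakeRec()]).itertuples(index=False)
        assert row.dist_5prime == 0

    def test_best_p_peak_represents_multi_peak_pairs(self):
        tx = TranscriptRecord("T", "G", "pc", "c", "+", ((1000, 2000),))
        net = TargetNetwork()
        net.add("R", "T", Peak("R", "c", 1500, 1530, "+", 1e-2))
        net.add("R", "T", Peak("R", "c", 1100, 1130, "+", 1e-6))

        class FakeRec:
            rbp_id = "R"
            target_ids = ["T"]
            rho_targets = np.array([0.5])

        (row,) = transcript_feature_table(net, [tx], [FakeRec()]).itertuples(index=False)
        assert row.clip_p == pytest.approx(1e-6) and row.dist_5prime == 100


def _empty_expr():
    from rbpregulon.formats import ExpressionMatrix

    return ExpressionMatrix(
        pd.DataFrame(np.ones((1, 3)), index=["x"], columns=["a", "b", "c"])
    )


class TestMultivariate:
    def test_noiseless_linear_model_recovered_exactly(self):
        x = np.arange(10.0)
        tab = pd.DataFrame({"response": 3 + 2 * x, "x": x})
        fit = fit_multivariate(tab, "response", ["x"])
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-8)

    def test_strong_vs_null_predictor_pvalues(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.standard_normal((2, 500))
        tab = pd.DataFrame(
            {"response": x1 + 0.1 * rng.standard_normal(500), "x1": x1, "x2": x2}
        )
        fit = fit_multivariate(tab, "response", ["x1", "x2"])
        assert fit.p_values["x1"] < 1e-6 and fit.p_values["x2"] > 0.05

    def test_constant_response_selects_nothing(self):
        tab = pd.DataFrame({"response": np.ones(20), "x": np.arange(20.0)})
        fit = fit_multivariate(tab, "response", ["x"])
        assert fit.selected == set()

    def test_collinear_design_rejected_naming_columns(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        tab = pd.DataFrame({"response": x, "a": x * 2, "b": x * 2})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_multivariate(tab, "response", ["a", "b"])

    def test_too_few_rows_rejected(self):
        tab = pd.DataFrame({"response": [1.0, 2], "a": [1.0, 2], "b": [3.0, 4]})
        with pytest.raises(ValueError, match="more rows"):
            fit_multivariate(tab, "response", ["a", "b"])


class TestStepwise:
    def test_keeps_strong_drops_null(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.standard_normal((2, 500))
        tab = pd.DataFrame(
            {"response": x1 + 0.1 * rng.standard_normal(500), "x1": x1, "x2": x2}
        )
        fit = fit_stepwise(tab, "response", ["x1", "x2"])
        assert fit.selected == {"x1"}

    def test_single_significant_predictor_is_fixed_point(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        tab = pd.DataFrame({"response": x + 0.1 * rng.standard_normal(100), "x": x})
        assert fit_stepwise(tab, "response", ["x"]).selected == {"x"}

    def test_all_null_usually_ends_intercept_only(self):
        empties = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tab = pd.DataFrame(
                {
                    "response": rng.standard_normal(200),
                    "a": rng.standard_normal(200),
                    "b": rng.standard_normal(200),
                }
            )
            if fit_stepwise(tab, "response", ["a", "b"]).selected == set():
                empties += 1
        assert empties >= 15  # ~(1-alpha)^2 per replicate

    def test_invariant_to_predictor_order(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((150, 4))
        y = X[:, 0] - 0.5 * X[:, 2] + 0.3 * rng.standard_normal(150)
        tab = pd.DataFrame(X, columns=list("abcd"))
        tab["response"] = y
        sel1 = fit_stepwise(tab, "response", ["a", "b", "c", "d"]).selected
        sel2 = fit_stepwise(tab, "response", ["d", "c", "b", "a"]).selected
        assert sel1 == sel2


class TestElasticNet:
    def test_sparse_truth_recovered_by_cv(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((300, 10))
        y = 2 * X[:, 0] - 1.5 * X[:, 1] + 0.2 * rng.standard_normal(300)
        tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
        tab["response"] = y
        fit = fit_elastic_net(tab, "response", [f"f{i}" for i in range(10)], seed=1)
        assert {"f0", "f1"} <= fit.selected

    def test_fold_reduction_warns_on_tiny_tables(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(
            {"response": rng.standard_normal(6), "x": rng.standard_normal(6)}
        )
        with pytest.warns(UserWarning, match="folds"):
            fit_elastic_net(tab, "response", ["x"], k_folds=10, seed=0)

    def test_seed_fixes_hyperparameter_choice(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 5))
        y = X[:, 0] + rng.standard_normal(100)
        tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        tab["response"] = y
        a = fit_elastic_net(tab, "response", [f"f{i}" for i in range(5)], seed=9)
        b = fit_elastic_net(tab, "response", [f"f{i}" for i in range(5)], seed=9)
        assert a.hyperparameters == b.hyperparameters
        assert a.coefficients == b.coefficients


class TestPerRbpModels:
    def test_small_rbps_skipped_and_reported(self):
        tab = pd.DataFrame(
            {
                "rbp_id": ["R1"] * 3,
                "response": [0.1, 0.2, 0.3],
                "clip_p": [0.01] * 3,
                "dist_5prime": [1, 2, 3],
                "dist_3prime": [4, 5, 6],
                "transcript_length": [100, 200, 300],
                "transcript_type": ["pc"] * 3,
            }
        )
        fits, sig, fracs, skipped = per_rbp_transcript_models(tab)
        assert fits == {} and skipped == ["R1"]

    def test_planted_length_effect_found_in_most_rbps(self, cohort_tables):
        data, _, _, _, tx_tab = cohort_tables
        tx_tab = tx_tab.copy()
        rng = np.random.default_rng(0)
        # overwrite response with a pure transcript_length effect
        scaled = (tx_tab.transcript_length - tx_tab.transcript_length.mean()) / tx_tab.transcript_length.std()
        tx_tab["response"] = scaled + 0.3 * rng.standard_normal(len(tx_tab))
        fits, sig, fracs, skipped = per_rbp_transcript_models(
            tx_tab, methods=("multivariate", "stepwise")
        )
        frac = fracs.set_index("feature").loc[
            "transcript_length", "frac_significant_multivariate"
        ]
        assert frac > 0.9

    def test_significance_matrix_is_minus_log10(self, cohort_tables):
        _, _, _, _, tx_tab = cohort_tables
        fits, sig, _, _ = per_rbp_transcript_models(tx_tab, methods=("multivariate",))
        rbp = next(iter(fits))
        for feat, p in fits[rbp]["multivariate"].feature_p.items():
            assert sig.loc[rbp, feat] == pytest.approx(-np.log10(p))


class TestBiotypeSummary:
    def test_grouped_medians(self):
        tab = pd.DataFrame(
            {
                "rbp_id": ["R"] * 3,
                "transcript_type": ["pc", "pc", "lnc"],
                "response": [0.5, 0.6, -0.1],
            }
        )
        out = biotype_effect_summary(tab).set_index("transcript_type")
        assert out.loc["pc", "median_rho"] == pytest.approx(0.55)
        assert out.loc["lnc", "median_rho"] == pytest.approx(-0.1)
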