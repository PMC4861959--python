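import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbpregulon.classify import (
    class_summary,
    classify,
    partition,
    run_level,
    select_representative,
    spearman_profile,
)
from rbpregulon.formats import ExpressionMatrix, TranscriptRecord
from rbpregulon.network import TargetNetwork


class TestRepresentative:
    def _expr(self, means):
        data = pd.DataFrame(
            {tid: [m] * 4 for tid, m in means.items()}
        ).T
        data.columns = [f"t{i}" for i in range(4)]
        return ExpressionMatrix(data)

    def test_highest_mean_protein_coding_wins_over_lincRNA(self):
        ann = [
            TranscriptRecord("Ta", "G", "protein_coding", "c", "+", ((0, 10),)),
            TranscriptRecord("Tb", "G", "protein_coding", "c", "+", ((0, 10),)),
            TranscriptRecord("Tc", "G", "lincRNA", "c", "+", ((0, 10),)),
        ]
        expr = self._expr({"Ta": 5.0, "Tb": 8.0, "Tc": 20.0})
        assert select_representative("G", ann, expr) == "Tb"

    def test_single_candidate_returned(self):
        ann = [TranscriptRecord("Ta", "G", "protein_coding", "c", "+", ((0, 10),))]
        assert select_representative("G", ann, self._expr({"Ta": 1.0})) == "Ta"

    def test_tie_breaks_lexicographically(self):
        ann = [
            TranscriptRecord("Tb", "G", "protein_coding", "c", "+", ((0, 10),)),
            TranscriptRecord("Ta", "G", "protein_coding", "c", "+", ((0, 10),)),
        ]
        assert select_representative("G", ann, self._expr({"Ta": 3.0, "Tb": 3.0})) == "Ta"

    def test_no_protein_coding_transcript_gives_none(self):
        ann = [TranscriptRecord("Ta", "G", "lincRNA", "c", "+", ((0, 10),))]
        assert select_representative("G", ann, self._expr({"Ta": 3.0})) is None


class TestSpearman:
    def test_perfect_monotone_profiles(self):
        x = np.arange(1.0, 17.0)
        rho, valid = spearman_profile(x, np.vstack([x, x[::-1]]))
        assert rho == pytest.approx([1.0, -1.0])
        assert valid.all()

    def test_hand_computed_rank_formula_case(self):
        # d = (1,1,1,1,0), sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman_profile(
            np.array([1.0, 2, 3, 4, 5]), np.array([[2.0, 1, 4, 3, 5]])
        )
        assert rho[0] == pytest.approx(0.8)

    def test_matches_scipy_including_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=12).astype(float)  # heavy ties
        Y = rng.integers(0, 5, size=(20, 12)).astype(float)
        rho, valid = spearman_profile(x, Y)
        for i in range(20):
            expected = stats.spearmanr(x, Y[i]).statistic
            if np.isnan(expected):
                assert not valid[i]
            else:
                assert rho[i] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_flagged_invalid(self):
        rho, valid = spearman_profile(
            np.array([1.0, 2, 3, 4]), np.array([[7.0, 7, 7, 7]])
        )
        assert not valid[0] and np.isnan(rho[0])

    def test_too_few_tissues_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            spearman_profile(np.array([1.0, 2]), np.array([[1.0, 2]]))

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=16)
        Y = rng.normal(size=(10, 16))
        rho0, _ = spearman_profile(x, Y)
        rho1, _ = spearman_profile(np.exp(x), np.exp(Y) ** 3)
        assert rho1 == pytest.approx(rho0, abs=1e-12)


class TestPartition:
    def _setup(self, n_targets=10, n_all=1000):
        net = TargetNetwork(targets={"R": {f"T{i}" for i in range(n_targets)}})
        ids = [f"T{i}" for i in range(n_all)]
        data = pd.DataFrame(
            np.ones((n_all, 4)), index=ids, columns=list("abcd")
        )
        return net, ExpressionMatrix(data)

    def test_matched_samples_respect_contract(self):
        net, expr = self._setup()
        part = partition("R", net, expr, n_reps=100, seed=1)
        assert len(part.control_matched_samples) == 100
        assert set(part.targets) & set(part.control_all) == set()
        for sample in part.control_matched_samples:
            assert len(sample) == len(part.targets)
            assert len(set(sample)) == len(sample)
            assert set(sample) <= set(part.control_all)

    def test_boundary_pool_equals_target_size(self):
        net, expr = self._setup(n_targets=10, n_all=20)
        part = partition("R", net, expr, n_reps=5, seed=0)
        for sample in part.control_matched_samples:
            assert set(sample) == set(part.control_all)

    def test_same_seed_reproduces_samples(self):
        net, expr = self._setup()
        a = partition("R", net, expr, n_reps=10, seed=42)
        b = partition("R", net, expr, n_reps=10, seed=42)
        assert a.control_matched_samples == b.control_matched_samples

    def test_control_pool_smaller_than_targets_errors(self):
        net, expr = self._setup(n_targets=900, n_all=1000)
        net.targets["R"] = {f"T{i}" for i in range(990)}
        with pytest.raises(ValueError, match="matched sampling impossible"):
            partition("R", net, expr, n_reps=5, seed=0)


class TestClassify:
    def test_identical_multisets_are_nsc(self):
        vals = np.array([0.1, -0.2, 0.3, 0.0, 0.5])
        p, label = classify(vals, vals.copy())
        assert p > 0.9 and label == "NSC"

    def test_positive_shift_is_sc(self):
        rng = np.random.default_rng(0)
        controls = rng.normal(0, 0.2, 100)
        p, label = classify(controls + 0.4, controls)
        assert p < 0.05 and label == "SC"

    def test_negative_shift_is_sic(self):
        rng = np.random.default_rng(0)
        controls = rng.normal(0, 0.2, 100)
        p, label = classify(controls - 0.4, controls)
        assert p < 0.05 and label == "SIC"

    def test_swap_maps_sc_to_sic(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.4, 0.2, 80)
        b = rng.normal(0.0, 0.2, 120)
        p_ab, lab_ab = classify(a, b)
        p_ba, lab_ba = classify(b, a)
        assert p_ab == pytest.approx(p_ba)
        assert {lab_ab, lab_ba} == {"SC", "SIC"}

    def test_insufficient_data_flagged_nsc(self):
        p, label = classify(np.array([0.1]), np.array([0.2, 0.3]))
        assert np.isnan(p) and label == "NSC"


class TestRunLevel:
    def test_recovers_planted_labels_on_small_cohort(self, small_cohort):
        from rbpregulon.network import map_targets

        data = small_cohort
        net = map_targets(data.peaks, data.annotation, flank=300)
        for level, want in (
            ("transcript", data.truth.labels_transcript),
            ("protein", data.truth.labels_protein),
        ):
            recs, _ = run_level(
                data.truth.rbp_genes, net, data.expr_rna, data.annotation,
                expr_protein=data.expr_protein, level=level, n_reps=20, seed=5,
            )
            hits = sum(r.label == want[r.rbp_id] for r in recs)
            assert hits >= len(recs) - 1  # strong planted effects

    def test_missing_protein_rows_skipped_and_reported(self, small_cohort):
        from rbpregulon.network import map_targets

        data = small_cohort
        net = map_targets(data.peaks, data.annotation, flank=300)
        recs, summary = run_level(
            data.truth.rbp_genes, net, data.expr_rna, data.annotation,
            expr_protein=data.expr_protein, level="protein", n_reps=5, seed=5,
        )
        skipped = set(summary.iloc[0]["skipped_rbps"].split(","))
        assert skipped == data.truth.missing_protein
        assert {r.rbp_id for r in recs} == set(data.truth.rbp_genes) - skipped

    def test_tiny_tissue_intersection_aborts(self, small_cohort):
        data = small_cohort
        prot = ExpressionMatrix(
            data.expr_protein.data.iloc[:, :2].copy(), level="protein"
        )
        with pytest.raises(ValueError, match="shared"):
            run_level(
                data.truth.rbp_genes, TargetNetwork(), data.expr_rna,
                data.annotation, expr_protein=prot, level="protein",
            )

    def test_matched_summary_is_median_of_matched_pvalues(self, small_cohort):
        from rbpregulon.network import map_targets

        data = small_cohort
        net = map_targets(data.peaks, data.annotation, flank=300)
        recs, _ = run_level(
            data.truth.rbp_genes, net, data.expr_rna, data.annotation,
            level="transcript", n_reps=11, seed=5,
        )
        for r in recs[:3]:
            assert r.p_matched_summary == pytest.approx(np.median(r.p_vs_matched))


class TestClassSummary:
    def test_percentages_from_label_counts(self):
        s = class_summary({"SC": 36, "SIC": 11, "NSC": 13})
        assert s["pct_significant"] == 78.33
        assert s["pct_SC"] == 60.0
        assert s["pct_SIC"] == 18.33

    def test_protein_level_count_arithmetic(self):
        s = class_summary({"SC": 11, "SIC": 44, "NSC": 3})
        assert s["pct_significant"] == 94.83
        assert s["pct_SC"] == 18.97
        assert s["pct_SIC"] == 75.86

    def test_fractions_within_significant_subset(self):
        s = class_summary({"SC": 17, "SIC": 24, "NSC": 24})
        assert s["pct_significant"] == 63.08
        assert s["pct_SC_of_significant"] == 41.46
        assert s["pct_SIC_of_significant"] == 58.54

    def test_accepts_label_iterable(self):
        s = class_summary(["SC", "SC", "SIC", "NSC"])
        assert s["n_SC"] == 2 and s["pct_significant"] == 75.0
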