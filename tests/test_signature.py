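import numpy as np
import pytest

from reopure import (
    CohortConfig,
    ExpressionMatrix,
    GenePairSet,
    SignatureModel,
    classify,
    classify_matrix,
    evaluate_accuracy,
    generate_cohort,
    reversal_degree,
    reversal_pairs,
    select_signature,
    stable_pairs,
)


def matrix(values, genes=None, prefix="s"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(genes, [f"{prefix}{k}" for k in range(values.shape[1])], values)


def split_cohort(cohort):
    normal_ids = [m.sample_id for m in cohort.metadata if m.class_label == "normal"]
    tumor_ids = [m.sample_id for m in cohort.metadata if m.class_label == "tumor"]
    return cohort.matrix.subset_samples(normal_ids), cohort.matrix.subset_samples(tumor_ids)


class TestStablePairs:
    def test_unanimous_pair_emitted(self):
        m = matrix([[3.0, 5.0, 4.0], [1.0, 2.0, 1.5]])
        result = stable_pairs(m, threshold=0.95)
        assert [tuple(p) for p in result.pairs] == [(0, 1)]
        assert result.orientation[0] == 1  # g0 > g1
        assert result.support_frequency[0] == 1.0

    def test_strict_threshold_excludes_exact_support(self):
        # 19 of 20 samples oriented: support == 0.95, NOT > 0.95
        top = np.full(20, 2.0)
        bottom = np.full(20, 1.0)
        bottom[0] = 3.0  # one reversed sample
        result = stable_pairs(matrix([top, bottom]), threshold=0.95)
        assert len(result) == 0
        relaxed = stable_pairs(matrix([top, bottom]), threshold=0.90)
        assert relaxed.support_frequency[0] == pytest.approx(0.95)

    def test_ties_count_in_denominator_only(self):
        # 3 samples: one tied, two oriented -> support 2/3, below 0.95
        m = matrix([[2.0, 2.0, 2.0], [1.0, 1.0, 2.0]])
        assert len(stable_pairs(m, threshold=0.95)) == 0
        relaxed = stable_pairs(m, threshold=0.6)
        assert relaxed.support_frequency[0] == pytest.approx(2 / 3)

    def test_singleton_cohort_rejected(self):
        with pytest.raises(ValueError):
            stable_pairs(matrix([[1.0], [2.0]]), threshold=0.95)

    def test_threshold_range_enforced(self):
        m = matrix([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            stable_pairs(m, threshold=0.5)


class TestReversalPairs:
    def _pair_set(self, orientation):
        return GenePairSet(np.array([[0, 1]]), np.array([orientation], dtype=np.int8), np.array([1.0]))

    def test_opposite_orientation_included(self):
        result = reversal_pairs(self._pair_set(+1), self._pair_set(-1))
        assert len(result) == 1

    def test_same_orientation_excluded(self):
        assert len(reversal_pairs(self._pair_set(+1), self._pair_set(+1))) == 0

    def test_pair_stable_in_one_cohort_only_excluded(self):
        empty = GenePairSet(np.empty((0, 2)), np.empty(0, np.int8), np.empty(0))
        assert len(reversal_pairs(self._pair_set(+1), empty)) == 0

    def test_orientations_required(self):
        bare = GenePairSet(np.array([[0, 1]]))
        with pytest.raises(ValueError, match="orientation"):
            reversal_pairs(bare, bare)


class TestReversalDegree:
    def test_constant_median_arithmetic(self):
        # ranks within each normal sample: g0=4, g1=1 -> Rij = 3 in all samples
        normal = matrix([[8.0] * 3, [1.0] * 3, [2.0] * 3, [3.0] * 3])
        # tumor: g0 rank 1, g1 rank 6 would need 6 genes; use shifted values for Rij = 3
        tumor = matrix([[1.0] * 3, [8.0] * 3, [2.0] * 3, [3.0] * 3])
        cand = reversal_degree(("g0", "g1"), normal, tumor)
        assert cand.median_rank_diff_normal == 3.0
        assert cand.median_rank_diff_tumor == 3.0
        assert cand.avg_rij == 3.0

    def test_single_sample_rank_difference(self):
        # 7 genes, one sample: g0 is the 7th ranked, g1 the 2nd -> Rij = 5
        values = np.array([[70.0], [20.0], [10.0], [30.0], [40.0], [50.0], [60.0]])
        cand = reversal_degree(("g0", "g1"), matrix(values), matrix(values, prefix="t"))
        assert cand.median_rank_diff_normal == 5.0

    def test_even_cohort_median_is_midpoint(self):
        # two normal samples with Rij values 1 and 3 -> median 2.0
        normal = matrix(
            [
                [3.0, 4.0],  # g0 ranks: 3, 4
                [2.0, 1.0],  # g1 ranks: 2, 1
                [1.0, 2.0],
                [4.0, 3.0],
            ]
        )
        cand = reversal_degree(("g0", "g1"), normal, normal)
        rij = [abs(3 - 2), abs(4 - 1)]
        assert cand.median_rank_diff_normal == float(np.mean(sorted(rij)[0:2]))
        assert cand.median_rank_diff_normal == 2.0

    def test_missing_gene_error(self):
        m = matrix([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(KeyError):
            reversal_degree(("g0", "gZZ"), m, m)


class TestSelectSignature:
    def test_recovers_planted_maximal_pair(self):
        cohort = generate_cohort(CohortConfig(seed=11))
        normal, tumor = split_cohort(cohort)
        model = select_signature(normal, tumor)
        gi, gj, _ = cohort.planted_pairs[0]
        assert (model.gene_i, model.gene_j) == (gi, gj)
        assert model.normal_support > 0.95 and model.tumor_support > 0.95

    def test_exhaustive_scoring_confirms_argmax(self):
        cohort = generate_cohort(CohortConfig(n_genes=40, n_tumor=12, n_normal=12, seed=5))
        normal, tumor = split_cohort(cohort)
        model = select_signature(normal, tumor)
        n_stable = stable_pairs(normal)
        t_stable = stable_pairs(tumor)
        best = None
        for (i, j), orient in zip(n_stable.pairs, n_stable.orientation):
            hit = [
                o
                for (ti, tj), o in zip(t_stable.pairs, t_stable.orientation)
                if (ti, tj) == (i, j)
            ]
            if not hit or hit[0] != -orient:
                continue
            cand = reversal_degree((normal.gene_ids[i], normal.gene_ids[j]), normal, tumor)
            key = (-cand.avg_rij, i, j)
            if best is None or key < best[0]:
                best = (key, cand.pair)
        assert best is not None
        assert (model.gene_i, model.gene_j) == best[1]
        assert model.reversal_degree == pytest.approx(-best[0][0])

    def test_equal_degree_ties_break_lexicographically(self):
        normal = matrix(np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 3)))
        tumor = matrix(np.tile([[2.0], [1.0], [4.0], [3.0]], (1, 3)), prefix="t")
        model = select_signature(normal, tumor)
        # pairs (g0,g1) and (g2,g3) both have avgRij == 1; smaller indices win
        assert (model.gene_i, model.gene_j) == ("g0", "g1")

    def test_no_reversal_pair_raises(self):
        values = np.array([[1.0, 1.0, 3.0], [2.0, 2.0, 1.0]])
        normal = matrix(values)
        tumor = matrix(values, prefix="t")
        with pytest.raises(ValueError, match="no reversal pair"):
            select_signature(normal, tumor, threshold=1.0)

    def test_discovery_invariant_under_per_sample_monotone_transforms(self):
        cohort = generate_cohort(CohortConfig(n_genes=60, n_tumor=15, n_normal=15, seed=7))
        normal, tumor = split_cohort(cohort)
        model = select_signature(normal, tumor)
        warp_n = ExpressionMatrix(
            normal.gene_ids, normal.sample_ids, np.log2(normal.values) * 3 + 1, "log2"
        )
        warp_t = ExpressionMatrix(
            tumor.gene_ids, tumor.sample_ids, np.sqrt(tumor.values), "linear"
        )
        warped = select_signature(warp_n, warp_t)
        assert (warped.gene_i, warped.gene_j) == (model.gene_i, model.gene_j)
        assert warped.reversal_degree == model.reversal_degree


class TestClassify:
    @pytest.fixture
    def model(self):
        return SignatureModel(
            gene_i="normHigh",
            gene_j="normLow",
            normal_orientation="i_gt_j",
            reversal_degree=100.0,
            normal_support=0.99,
            tumor_support=0.98,
            threshold=0.95,
        )

    def test_normal_orientation_calls_normal(self, model):
        assert classify({"normHigh": 8.1, "normLow": 3.2}, model) == "normal"

    def test_reversed_orientation_calls_tumor(self, model):
        assert classify({"normHigh": 3.2, "normLow": 8.1}, model) == "tumor"

    def test_tie_policies(self, model):
        sample = {"normHigh": 5.0, "normLow": 5.0}
        assert classify(sample, model) == "unclassifiable"
        assert classify(sample, model, tie_policy="tumor") == "tumor"

    def test_missing_gene_error(self, model):
        with pytest.raises(KeyError, match="normLow"):
            classify({"normHigh": 1.0}, model)

    def test_matrix_classification_matches_scalar(self, model, rng):
        values = rng.lognormal(3, 1, (2, 20))
        m = ExpressionMatrix(["normHigh", "normLow"], [f"s{i}" for i in range(20)], values)
        calls = classify_matrix(m, model)
        for k, sid in enumerate(m.sample_ids):
            sample = {"normHigh": values[0, k], "normLow": values[1, k]}
            assert calls[sid] == classify(sample, model)

    def test_model_json_round_trip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.to_json(path)
        assert SignatureModel.from_json(path) == model


class TestEvaluateAccuracy:
    def test_all_correct(self):
        per_class, _ = evaluate_accuracy(["tumor", "normal"], ["tumor", "normal"])
        assert (per_class["accuracy"] == 1.0).all()

    def test_partial_accuracy_per_class(self):
        per_class, _ = evaluate_accuracy(
            ["tumor", "normal", "normal"], ["tumor", "tumor", "normal"]
        )
        acc = dict(zip(per_class["label"], per_class["accuracy"]))
        assert acc["tumor"] == 0.5
        assert acc["normal"] == 1.0

    def test_empty_ptec_bin_flagged(self):
        per_class, per_bin = evaluate_accuracy(
            ["tumor", "tumor"], ["tumor", "tumor"], ptec=[35.0, 95.0]
        )
        empty = per_bin[(per_bin["ptec_low"] == 50)]
        assert empty["n"].item() == 0
        assert np.isnan(empty["accuracy"].item())
        full = per_bin[(per_bin["ptec_low"] == 30)]
        assert full["n"].item() == 1 and full["accuracy"].item() == 1.0

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            evaluate_accuracy(["tumor"], ["tumor", "normal"])
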