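"""Task admission, counterpart dataset construction, the modeling steps and
the repeated benchmark."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, matthews_corrcoef

from gesbench import taskbench
from gesbench.sigio import ActivityMatrix, CompoundRecord, SignatureRecord
from gesbench.taskbench import (
    GES,
    MORGAN_FP,
    ModelConfig,
    admit_targets,
    build_tasks,
    compare_descriptors,
    evaluate,
    run_benchmark,
    select_features,
    split_train_test,
    tune_depth,
)


class TestAdmitTargets:
    def test_fifty_active_boundary(self):
        triplets = [(f"c{i}", "T50", 1) for i in range(50)]
        triplets += [(f"c{i}", "T49", 1) for i in range(49)]
        m = ActivityMatrix(triplets)
        assert admit_targets(m) == ["T50"]

    def test_empty_matrix(self):
        assert admit_targets(ActivityMatrix([])) == []

    def test_mixed_scenario_recovers_truth(self, mixed_run):
        world = mixed_run["world"]
        admitted = set(admit_targets(world.activity))
        expected = {
            t.target_id
            for t in world.config.targets
            if world.activity.n_actives(t.target_id) >= 50
        }
        assert admitted == expected
        assert admitted == {t.target_id for t in world.config.targets}


def tiny_inputs():
    """4 compounds; c3 has no signature in MCF7; c0..c2 labeled for T."""
    rng = np.random.default_rng(0)
    compounds = [
        CompoundRecord(f"c{i}", "x", (rng.random(16) < 0.4).astype(np.uint8))
        for i in range(4)
    ]
    signatures = [
        SignatureRecord(f"c{i}:{cell}", f"c{i}", cell, 10.0, 24.0, rng.normal(size=8))
        for cell in ("A549", "MCF7")
        for i in range(4)
        if not (cell == "MCF7" and i == 3)
    ]
    activity = ActivityMatrix(
        [("c0", "T", 1), ("c1", "T", 1), ("c2", "T", 0), ("c3", "T", 1)]
    )
    return signatures, compounds, activity


class TestBuildTasks:
    def test_rows_restricted_to_labeled_with_signature(self):
        signatures, compounds, activity = tiny_inputs()
        pairs = build_tasks(signatures, compounds, activity, ["T"], min_actives_per_dataset=2)
        by_cell = {p.key[1]: p for p in pairs}
        assert set(by_cell) == {"A549", "MCF7"}
        assert by_cell["A549"].ges.compound_ids == ["c0", "c1", "c2", "c3"]
        assert by_cell["MCF7"].ges.compound_ids == ["c0", "c1", "c2"]  # c3 lacks signature

    def test_counterpart_rows_identical(self, small_world):
        pairs = build_tasks(
            small_world.signatures,
            small_world.compounds,
            small_world.activity,
            admit_targets(small_world.activity),
        )
        assert pairs
        for p in pairs:
            assert p.ges.compound_ids == p.fp.compound_ids
            np.testing.assert_array_equal(p.ges.y, p.fp.y)
            assert p.ges.X.shape[1] == small_world.config.n_genes
            assert p.fp.X.shape[1] == small_world.config.bit_length

    def test_min_actives_per_dataset_boundary(self):
        signatures, compounds, activity = tiny_inputs()
        pairs = build_tasks(signatures, compounds, activity, ["T"], min_actives_per_dataset=3)
        # A549 has 3 actives (c0, c1, c3), MCF7 only 2 -> dropped
        assert [p.key[1] for p in pairs] == ["A549"]

    def test_unaveraged_replicates_rejected(self):
        signatures, compounds, activity = tiny_inputs()
        signatures.append(signatures[0])
        with pytest.raises(ValueError, match="average replicates"):
            build_tasks(signatures, compounds, activity, ["T"])


class TestSplit:
    def test_stratification_arithmetic(self):
        y = np.array([1] * 20 + [0] * 80)
        train, test = split_train_test(100, y, 0.67, seed=0)
        assert train.size == 67 and test.size == 33
        assert y[train].sum() in (13, 14)
        assert np.array_equal(np.sort(np.concatenate([train, test])), np.arange(100))

    def test_deterministic(self):
        y = np.array([0, 1] * 20)
        assert all(
            np.array_equal(a, b)
            for a, b in zip(
                split_train_test(40, y, 0.67, 9), split_train_test(40, y, 0.67, 9)
            )
        )

    def test_tiny_class_raises(self):
        with pytest.raises(ValueError, match="class too small"):
            split_train_test(5, np.array([1, 0, 0, 0, 0]), 0.67, 0)


class TestSelectFeatures:
    def test_no_more_columns_than_k_passes_through(self):
        X = np.random.default_rng(0).normal(size=(40, 20))
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        np.testing.assert_array_equal(
            select_features(X, y, ModelConfig(), seed=0), np.arange(20)
        )

    def test_recovers_injected_signal_columns(self):
        # 5 informative columns out of 30; selection keeps all 5 in ≥95% of runs
        cfg = ModelConfig(n_selected_features=8)
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(120, 30))
            y = (X[:, :5].sum(axis=1) > 0).astype(int)
            cols = set(select_features(X, y, cfg, seed=s).tolist())
            hits += {0, 1, 2, 3, 4} <= cols
        assert hits >= 38

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(60, 15)), rng.integers(0, 2, 60)
        f = RandomForestClassifier(50, random_state=0).fit(X, y)
        assert f.feature_importances_.sum() == pytest.approx(1.0, abs=1e-9)


class TestTuneDepth:
    def test_single_entry_grid_short_circuits(self):
        cfg = ModelConfig(depth_grid=(7,))
        assert tune_depth(np.zeros((4, 2)), np.array([0, 1, 0, 1]), cfg, 0) == 7

    def test_separable_data_ties_break_to_smallest(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(-5, 0.1, (30, 3)), rng.normal(5, 0.1, (30, 3))]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        cfg = ModelConfig(depth_grid=(3, None))
        assert tune_depth(X, y, cfg, seed=1) == 3

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(50, 5)), rng.integers(0, 2, 50)
        cfg = ModelConfig(depth_grid=(2, 5, None))
        assert tune_depth(X, y, cfg, 3) == tune_depth(X, y, cfg, 3)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1, 0, 1, 0], [1, 0, 1, 0])
        assert (m.sensitivity, m.specificity, m.balanced_accuracy, m.mcc) == (1, 1, 1, 1)

    def test_hand_computed_confusion(self):
        y_true = [1] * 4 + [0] * 6
        y_pred = [1, 1, 1, 0] + [0] * 5 + [1]  # tp=3 fn=1 tn=5 fp=1
        m = evaluate(y_true, y_pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 5, 1)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.balanced_accuracy == pytest.approx(19 / 24)
        assert m.mcc == pytest.approx(14 / 24)
        # independent implementation cross-check
        assert m.balanced_accuracy == pytest.approx(balanced_accuracy_score(y_true, y_pred))
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_majority_predictor_is_exactly_half(self):
        m = evaluate([1, 1, 0, 0, 0, 0, 0, 0], [0] * 8)
        assert m.balanced_accuracy == 0.5
        assert m.mcc == 0.0  # zero-denominator convention

    def test_inverted_perfect_prediction(self):
        m = evaluate([1, 1, 0, 0], [0, 0, 1, 1])
        assert m.mcc == -1.0

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate([], [])


@pytest.fixture(scope="module")
def small_bench(small_world):
    pairs = build_tasks(
        small_world.signatures,
        small_world.compounds,
        small_world.activity,
        admit_targets(small_world.activity),
    )
    cfg = ModelConfig(n_pipeline_repeats=4, seed=11)
    return pairs, run_benchmark(pairs, cfg), cfg


class TestRunBenchmark:
    def test_shapes_and_counterpart_symmetry(self, small_bench):
        pairs, results, cfg = small_bench
        assert len(results) == 2 * len(pairs)
        by_key = {}
        for r in results:
            assert len(r.per_repeat) == cfg.n_pipeline_repeats
            by_key.setdefault(r.key, {})[r.descriptor_kind] = r
        for kinds in by_key.values():
            for rep in range(cfg.n_pipeline_repeats):
                g, f = kinds[GES].per_repeat[rep], kinds[MORGAN_FP].per_repeat[rep]
                # identical train/test partition => identical test composition
                assert g.tp + g.fn == f.tp + f.fn
                assert g.tn + g.fp == f.tn + f.fp

    def test_deterministic_given_master_seed(self, small_world, small_bench):
        pairs, results, cfg = small_bench
        again = run_benchmark(pairs, cfg)
        assert [r.per_repeat for r in again] == [r.per_repeat for r in results]
        assert [r.depths for r in again] == [r.depths for r in results]

    def test_responsive_cell_line_beats_nonresponsive(self, small_bench, small_world):
        _, results, _ = small_bench
        ges = {r.cell_line: r.mean_ba for r in results if r.descriptor_kind == GES}
        assert ges["A549"] > ges["MCF7"]  # A549 is the responsive line

    def test_doubling_repeats_is_stable(self, small_world, small_bench):
        pairs, results, cfg = small_bench
        doubled = run_benchmark(
            pairs, ModelConfig(n_pipeline_repeats=2 * cfg.n_pipeline_repeats, seed=cfg.seed)
        )
        for r8 in doubled:
            r4 = next(
                r for r in results
                if r.key == r8.key and r.descriptor_kind == r8.descriptor_kind
            )
            se = np.std([m.balanced_accuracy for m in r8.per_repeat]) / np.sqrt(
                len(r8.per_repeat)
            )
            assert abs(r8.mean_ba - r4.mean_ba) <= max(3 * se, 0.05)


class TestMonotoneDataQuality:
    def test_tighter_active_signatures_never_hurt_ges(self):
        """Lowering the active cosine-distance target (tighter signatures)
        must not reduce mean GES BA by more than one standard error."""
        from gesbench.synthgen import ScenarioConfig, TargetSpec, make_world

        levels = [0.95, 0.80, 0.65]
        means, ses = [], []
        for level in levels:
            bas = []
            for s in range(5):
                cfg = ScenarioConfig(
                    n_compounds=400,
                    n_genes=150,
                    bit_length=128,
                    cell_lines=("A549",),
                    n_scaffolds=10,
                    observed_fraction=0.3,
                    targets=(
                        TargetSpec(
                            target_id="T1",
                            active_fraction=0.15,
                            responsive_cell_lines=("A549",),
                            active_cosine_target=level,
                        ),
                    ),
                    seed=200 + s,
                )
                world = make_world(cfg)
                pairs = build_tasks(
                    world.signatures, world.compounds, world.activity,
                    admit_targets(world.activity),
                )
                results = run_benchmark(
                    pairs, ModelConfig(n_pipeline_repeats=3, seed=300 + s)
                )
                bas.extend(
                    r.mean_ba for r in results if r.descriptor_kind == GES
                )
            means.append(np.mean(bas))
            ses.append(np.std(bas) / np.sqrt(len(bas)))
        for i in range(1, len(levels)):
            assert means[i] >= means[i - 1] - max(ses[i], ses[i - 1])


class TestCompareDescriptors:
    def test_identical_results_give_fraction_one(self, small_bench):
        _, results, _ = small_bench
        ges_only = [r for r in results if r.descriptor_kind == GES]
        mirrored = ges_only + [
            taskbench.BenchmarkResult(
                r.target_id, r.cell_line, MORGAN_FP, r.per_repeat, r.depths,
                r.selected_features,
            )
            for r in ges_only
        ]
        report = compare_descriptors(mirrored)
        assert report.fraction_ges_wins == 1.0

    def test_threshold_counts_match_brute_force(self, mixed_run):
        report = mixed_run["comparison"]
        raw = taskbench.results_table(mixed_run["results"])
        mean_ba = raw.groupby(["target_id", "cell_line", "descriptor_kind"])[
            "balanced_accuracy"
        ].mean()
        assert report.n_models_ba_gt_07 == int((mean_ba > 0.7).sum())
        assert report.n_models_ba_gt_08 == int((mean_ba > 0.8).sum())

    def test_ges_win_fraction_tracks_responsive_fraction(self, mixed_run):
        assert mixed_run["comparison"].fraction_ges_wins == pytest.approx(
            mixed_run["responsive_fraction"], abs=0.1
        )

    def test_unpaired_task_excluded(self, small_bench, caplog):
        _, results, _ = small_bench
        partial = [r for r in results if not (r.descriptor_kind == MORGAN_FP and r.cell_line == "MCF7")]
        with caplog.at_level("WARNING"):
            report = compare_descriptors(partial)
        assert len(report.table) == len([r for r in results if r.descriptor_kind == GES]) - 1
        assert "unpaired" in caplog.text
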