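"""Weighted-forest training, OOB probabilities, tuning and routing."""

import numpy as np
import pandas as pd
import pytest

from ahrqsar.curation import ActivityCategory
from ahrqsar.features import DescriptorMatrix
from ahrqsar.model import (
    Hyperparameters,
    load_model,
    make_class_weights,
    oob_binary_metrics,
    oob_importance,
    predict,
    route_and_predict,
    save_model,
    train,
    tune,
)
from ahrqsar.synthetic import GeneratorConfig, generate_compounds

I = ActivityCategory.INACTIVE
A = ActivityCategory.ACTIVE


def _binary_matrix(n: int, seed: int, separation: float) -> tuple[DescriptorMatrix, list]:
    """Balanced two-class fixture with a controllable mean shift."""
    rng = np.random.default_rng(seed)
    y = [I] * (n // 2) + [A] * (n - n // 2)
    shift = np.array([separation if lab is A else 0.0 for lab in y])
    cols = {f"d{j}": rng.normal(shift, 1.0) for j in range(10)}
    frame = pd.DataFrame(cols, index=[f"c{i}" for i in range(n)])
    kinds = pd.Series({c: "descriptor" for c in cols})
    return DescriptorMatrix(frame, kinds), y


@pytest.fixture(scope="module")
def separable():
    cfg = GeneratorConfig(n_compounds=400, seed=101)
    comp = generate_compounds(cfg)
    labels = list(comp.labels)
    return comp.matrix, labels


class TestTrain:
    def test_determinism(self, separable):
        matrix, labels = separable
        hp = Hyperparameters(n_trees=40)
        m1 = train(matrix, labels, hp, seed=5)
        m2 = train(matrix, labels, hp, seed=5)
        pd.testing.assert_frame_equal(m1.oob_probabilities, m2.oob_probabilities)
        p1 = predict(m1, matrix.values.iloc[:5])
        p2 = predict(m2, matrix.values.iloc[:5])
        assert [r.probabilities for r in p1] == [r.probabilities for r in p2]

    def test_single_category_errors(self, separable):
        matrix, _ = separable
        with pytest.raises(ValueError, match="single category"):
            train(matrix, [I] * matrix.values.shape[0], Hyperparameters(n_trees=5))

    def test_oob_probabilities_normalized(self, separable):
        matrix, labels = separable
        model = train(matrix, labels, Hyperparameters(n_trees=60), seed=3)
        probs = model.oob_probabilities.dropna().to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_tiny_forest_flags_never_oob(self):
        matrix, y = _binary_matrix(30, 7, 3.0)
        model = train(matrix, y, Hyperparameters(n_trees=2), seed=1)
        # with 2 trees some compounds are almost surely in both bootstraps
        assert set(model.oob_missing) == set(
            model.oob_probabilities.index[model.oob_probabilities.isna().any(axis=1)]
        )

    def test_separable_oob_woa_high(self):
        matrix, y = _binary_matrix(300, 19, 3.0)
        model = train(matrix, y, Hyperparameters(n_trees=150), seed=2)
        assert oob_binary_metrics(model, y).woa > 0.9

    def test_pure_noise_oob_woa_near_half(self):
        matrix, y = _binary_matrix(400, 31, 0.0)
        model = train(matrix, y, Hyperparameters(n_trees=200), seed=4)
        assert oob_binary_metrics(model, y).woa == pytest.approx(0.5, abs=0.07)

    def test_weight_monotonicity_on_imbalanced_fixture(self):
        """Raising the active-class weight must not hurt OOB sensitivity.
        Asserted in bootstrap mode, where the weights act on the sampling
        draw itself; split-level weights are close to inert for fully
        grown trees (leaves are pure regardless of weighting)."""
        cfg = GeneratorConfig(n_compounds=330, seed=41, class_separation=1.0)
        comp = generate_compounds(cfg)
        labels = list(comp.labels)
        sens = {}
        for w in (1.0, 10.0):
            hp = Hyperparameters(
                n_trees=150, class_weights=make_class_weights(set(labels), w)
            )
            model = train(comp.matrix, labels, hp, seed=8, weight_mode="bootstrap")
            sens[w] = oob_binary_metrics(model, labels).sensitivity
        assert sens[10.0] >= sens[1.0]

    def test_split_mode_agrees_with_sklearn_reference(self):
        """Dual-route check: on a well-separated fixture, an independent
        sklearn forest with class weights reaches the same OOB regime."""
        from sklearn.ensemble import RandomForestClassifier

        matrix, y = _binary_matrix(300, 53, 3.0)
        hp = Hyperparameters(n_trees=150, class_weights={I: 1.0, A: 2.0})
        ours = train(matrix, y, hp, seed=9, weight_mode="split")
        woa_ours = oob_binary_metrics(ours, y).woa

        ref = RandomForestClassifier(
            n_estimators=150, class_weight={0: 1.0, 1: 2.0},
            oob_score=True, random_state=9,
        )
        y_int = np.array([0 if lab is I else 1 for lab in y])
        ref.fit(matrix.values.to_numpy(), y_int)
        ref_pred = ref.oob_decision_function_.argmax(axis=1)
        sens = np.mean(ref_pred[y_int == 1] == 1)
        spec = np.mean(ref_pred[y_int == 0] == 0)
        woa_ref = (sens + spec) / 2
        assert woa_ours == pytest.approx(woa_ref, abs=0.05)


class TestPredict:
    def test_probabilities_sum_to_one_and_quantized(self, separable):
        matrix, labels = separable
        model = train(matrix, labels, Hyperparameters(n_trees=25), seed=6)
        for res in predict(model, matrix.values.iloc[:10]):
            total = sum(res.probabilities.values())
            assert total == pytest.approx(1.0, abs=1e-12)
            for p in res.probabilities.values():
                assert (p * 25) == pytest.approx(round(p * 25))  # vote fractions

    def test_full_forest_vs_oob_reported_distinctly(self, separable):
        matrix, labels = separable
        model = train(matrix, labels, Hyperparameters(n_trees=60), seed=3)
        cid = model.training_ids[0]
        full = predict(model, matrix.values.iloc[[0]])[0]
        oob = model.oob_probabilities.loc[cid]
        assert set(full.probabilities) == set(model.categories)
        assert not oob.isna().any()  # both views exist independently

    def test_missing_predictor_column_named(self, separable):
        matrix, labels = separable
        model = train(matrix, labels, Hyperparameters(n_trees=10), seed=3)
        dropped = matrix.predictor_names[0]
        with pytest.raises(KeyError, match=dropped):
            predict(model, matrix.values.drop(columns=[dropped]))

    def test_argmax_is_predicted_category(self, separable):
        matrix, labels = separable
        model = train(matrix, labels, Hyperparameters(n_trees=30), seed=3)
        for res in predict(model, matrix.values.iloc[:20]):
            best = max(res.probabilities.values())
            assert res.probabilities[res.predicted_category] == best


class TestTune:
    def test_single_point_space_returned(self):
        matrix, y = _binary_matrix(80, 61, 3.0)
        space = {
            "n_trees": [20], "predictors_per_split": [3],
            "min_node_size": [1], "active_weight": [1.0],
        }
        best, trace = tune(matrix, y, space, seed=1)
        assert best.n_trees == 20 and best.predictors_per_split == 3
        assert len(trace) == 1

    def test_dominant_config_wins(self):
        matrix, y = _binary_matrix(150, 67, 2.0)
        space = {
            "n_trees": [5, 100], "predictors_per_split": [3],
            "min_node_size": [1], "active_weight": [1.0],
        }
        best, trace = tune(matrix, y, space, seed=2)
        by_trees = trace.set_index("n_trees")["woa"]
        assert best.n_trees == int(by_trees.idxmax())

    def test_tie_breaks_to_smaller_forest(self):
        matrix, y = _binary_matrix(60, 71, 5.0)  # trivially separable: ties at 1.0
        space = {
            "n_trees": [50, 100], "predictors_per_split": [3],
            "min_node_size": [1], "active_weight": [1.0],
        }
        best, trace = tune(matrix, y, space, seed=3)
        if trace["woa"].nunique() == 1:
            assert best.n_trees == 50

    def test_bad_budget_errors(self):
        matrix, y = _binary_matrix(40, 73, 3.0)
        with pytest.raises(ValueError, match="budget"):
            tune(matrix, y, seed=1, budget=0)

    def test_bayesian_refinement_extends_trace(self):
        matrix, y = _binary_matrix(80, 79, 2.0)
        space = {
            "n_trees": [20, 40], "predictors_per_split": [2, 4],
            "min_node_size": [1], "active_weight": [1.0, 5.0],
        }
        best, trace = tune(matrix, y, space, seed=4, budget=11, n_refine=3)
        assert (trace["stage"] == "bayesian").sum() == 3
        assert len(trace) == 11


class TestRouting:
    def test_routing_by_ring_class(self):
        cfg = GeneratorConfig(n_compounds=300, seed=83)
        comp = generate_compounds(cfg)
        labels3 = comp.labels.map(
            lambda c: ActivityCategory.MEDIUM_HIGH
            if c in (ActivityCategory.MEDIUM, ActivityCategory.HIGH)
            else c
        )
        arom = comp.ring_classes == "aromatic_ring"
        m_all3 = train(
            comp.matrix, list(labels3), Hyperparameters(n_trees=40),
            seed=1, model_tag="M_ALL_3",
        )
        m_arom4 = train(
            comp.matrix.subset_rows(list(comp.labels.index[arom])),
            list(comp.labels[arom]), Hyperparameters(n_trees=40),
            seed=1, model_tag="M_arom_4",
        )
        routed = route_and_predict(
            comp.matrix.values.iloc[:40], comp.ring_classes, m_all3, m_arom4
        )
        for cid, results in routed.items():
            if comp.ring_classes[cid] == "aromatic_ring":
                assert set(results) == {"M_ALL_3", "M_arom_4"}
            else:
                assert set(results) == {"M_ALL_3"}


def test_oob_importance_ranks_informative_predictors():
    rng = np.random.default_rng(97)
    n = 200
    y = [I] * 100 + [A] * 100
    signal = np.array([0.0] * 100 + [3.0] * 100)
    frame = pd.DataFrame(
        {
            "signal": rng.normal(signal, 1.0),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        },
        index=[f"c{i}" for i in range(n)],
    )
    matrix = DescriptorMatrix(frame, pd.Series({c: "descriptor" for c in frame}))
    model = train(matrix, y, Hyperparameters(n_trees=60), seed=5)
    iv = oob_importance(model, matrix, y, seed=5)
    rel = dict(zip(iv.predictor_names, iv.relative))
    assert rel["signal"] == 1.0
    assert rel["noise1"] < 0.5 and rel["noise2"] < 0.5


def test_model_round_trip(tmp_path, separable):
    matrix, labels = separable
    model = train(matrix, labels, Hyperparameters(n_trees=15), seed=2, model_tag="M_ALL_3")
    path = tmp_path / "model.joblib"
    save_model(model, str(path))
    loaded = load_model(str(path))
    assert loaded.model_tag == "M_ALL_3"
    p1 = predict(model, matrix.values.iloc[:3])
    p2 = predict(loaded, matrix.values.iloc[:3])
    assert [r.probabilities for r in p1] == [r.probabilities for r in p2]
    assert (tmp_path / "model.joblib.json").exists()
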