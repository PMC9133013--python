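"""Bagged-tree ensemble: partition arithmetic, metric formulas, the
depth-first trace oracle, bounds, determinism, and an external
cross-check against an independent random-forest implementation."""

import numpy as np
import pandas as pd
import pytest

from nrloss import BaggedTreeRegressor, evaluate, random_partition, repeated_runs
from nrloss.dataset import assemble_pathway_dataset
from nrloss.forest import predict_ef, train_pathway_model
from nrloss.rda import PathwaySpec, preset_spec


@pytest.mark.parametrize("n, n_train, n_test", [(100, 70, 30), (20, 14, 6),
                                                (103, 73, 30), (10, 7, 3)])
def test_partition_follows_seven_three_part_rule(n, n_train, n_test):
    train, test = random_partition(n, seed=0)
    assert len(train) == n_train and len(test) == n_test
    both = np.concatenate([train, test])
    assert sorted(both) == list(range(n))  # disjoint cover


def test_partition_remainder_rule_enumerated():
    """n=103: parts (11,11,11,10,...,10); recomputed by brute force from
    the shuffled order."""
    n = 103
    perm = np.random.default_rng(4).permutation(n)
    sizes = [11, 11, 11] + [10] * 7
    bounds = np.cumsum([0] + sizes)
    expect_train = np.concatenate([perm[bounds[p]:bounds[p + 1]] for p in range(7)])
    train, _ = random_partition(n, seed=4)
    np.testing.assert_array_equal(train, expect_train)


def test_partition_needs_ten_records():
    with pytest.raises(ValueError):
        random_partition(9, seed=0)


class TestEvaluate:
    def test_perfect_and_mean_predictions(self):
        y = np.array([0.1, 0.5, 0.9])
        assert evaluate(y, y) == (pytest.approx(1.0), pytest.approx(0.0))
        r2, _ = evaluate(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_fixed_example(self):
        r2, rmse = evaluate([0.1, 0.2, 0.3], [0.1, 0.2, 0.2])
        assert rmse == pytest.approx(np.sqrt(0.01 / 3))
        assert r2 == pytest.approx(0.5)

    def test_zero_variance_truth_warns_nan(self):
        with pytest.warns(UserWarning, match="zero test variance"):
            r2, rmse = evaluate([1.0, 1.0], [1.0, 2.0])
        assert np.isnan(r2) and rmse > 0


def _toy_table(rng, n=60):
    X = pd.DataFrame({
        "rainfall": rng.uniform(100, 500, n),
        "pH": rng.uniform(5, 9, n),
        "clay": rng.uniform(10, 40, n),
    })
    y = 0.01 + 0.0004 * X["rainfall"] + rng.normal(0, 0.005, n)
    return X, y.to_numpy()


def test_constant_response_predicts_constant(rng):
    X, _ = _toy_table(rng)
    with pytest.warns(UserWarning, match="constant response"):
        model = BaggedTreeRegressor(n_trees=5, random_state=0).fit(X, np.full(len(X), 0.3))
    assert np.allclose(model.predict(X), 0.3)


def test_single_stump_predicts_bootstrap_mean_everywhere(rng):
    X, y = _toy_table(rng, n=20)
    model = BaggedTreeRegressor(n_trees=1, min_leaf=len(X), random_state=7).fit(X, y)
    preds = model.predict(X)
    assert np.ptp(preds) == 0.0
    boot = np.random.default_rng(7).integers(0, len(X), len(X))
    assert preds[0] == pytest.approx(y[boot].mean(), abs=1e-12)


def test_predictions_bounded_by_training_extremes(rng):
    X, y = _toy_table(rng, n=80)
    model = BaggedTreeRegressor(n_trees=40, min_leaf=2, random_state=1).fit(X, y)
    Xq = pd.DataFrame({
        "rainfall": rng.uniform(-500, 1500, 200),
        "pH": rng.uniform(0, 14, 200),
        "clay": rng.uniform(-50, 150, 200),
    })
    preds = model.predict(Xq)
    assert preds.min() >= y.min() - 1e-12 and preds.max() <= y.max() + 1e-12


def test_fit_is_deterministic_under_seed(rng):
    X, y = _toy_table(rng)
    p1 = BaggedTreeRegressor(n_trees=10, random_state=42).fit(X, y).predict(X)
    p2 = BaggedTreeRegressor(n_trees=10, random_state=42).fit(X, y).predict(X)
    np.testing.assert_array_equal(p1, p2)
    p3 = BaggedTreeRegressor(n_trees=10, random_state=43).fit(X, y).predict(X)
    assert not np.array_equal(p1, p3)


def test_k_must_be_below_m(rng):
    X, y = _toy_table(rng)
    with pytest.raises(ValueError, match="k_features"):
        BaggedTreeRegressor(n_trees=2, k_features=3).fit(X, y)


def test_missing_factor_named_in_error(rng):
    X, y = _toy_table(rng)
    model = BaggedTreeRegressor(n_trees=2, random_state=0).fit(X, y)
    with pytest.raises(KeyError, match="clay"):
        model.predict(X[["rainfall", "pH"]])


def test_json_round_trip_preserves_predictions(rng):
    X, y = _toy_table(rng)
    model = BaggedTreeRegressor(n_trees=8, random_state=3).fit(X, y)
    clone = BaggedTreeRegressor.from_json(model.to_json())
    np.testing.assert_array_equal(model.predict(X), clone.predict(X))


# --- depth-first trace oracle -------------------------------------------

def _oracle_tree(X, y, idx, k, min_leaf, rng):
    """Independent exhaustive re-execution of the documented procedure:
    leaf below 2*min_leaf or constant target; otherwise draw k features
    and scan every midpoint threshold by brute force."""
    yn = y[idx]
    if len(idx) < 2 * min_leaf or np.ptp(yn) == 0.0:
        return ("leaf", yn.mean())
    feats = rng.choice(X.shape[1], size=k, replace=False)
    best = None
    for f in feats:
        xv = X[idx, f]
        vs = np.unique(xv)
        for lo, hi in zip(vs[:-1], vs[1:]):
            thr = 0.5 * (lo + hi)
            left, right = idx[xv <= thr], idx[xv > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            sse = (np.sum((y[left] - y[left].mean()) ** 2)
                   + np.sum((y[right] - y[right].mean()) ** 2))
            if best is None or sse < best[0] - 1e-12:
                best = (sse, f, thr)
    if best is None:
        return ("leaf", yn.mean())
    _, f, thr = best
    return ("split", f, thr,
            _oracle_tree(X, y, idx[X[idx, f] <= thr], k, min_leaf, rng),
            _oracle_tree(X, y, idx[X[idx, f] > thr], k, min_leaf, rng))


def _oracle_predict(node, x):
    while node[0] == "split":
        node = node[3] if x[node[1]] <= node[2] else node[4]
    return node[1]


def test_ensemble_matches_brute_force_trace_on_12_rows():
    rng0 = np.random.default_rng(99)
    X = rng0.uniform(0, 1, size=(12, 3))
    y = rng0.uniform(0, 1, size=12)
    n_trees, k, min_leaf, seed = 2, 2, 2, 5

    oracle_rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        boot = oracle_rng.integers(0, 12, 12)
        trees.append(_oracle_tree(X, y, boot, k, min_leaf, oracle_rng))
    Xq = rng0.uniform(0, 1, size=(20, 3))
    expected = np.array([
        np.mean([_oracle_predict(t, x) for t in trees]) for x in Xq])

    model = BaggedTreeRegressor(n_trees=n_trees, k_features=k, min_leaf=min_leaf,
                                random_state=seed).fit(X, y)
    np.testing.assert_allclose(model.predict(Xq), expected, atol=1e-12)


def test_agrees_with_reference_forest_implementation(ef_records):
    """Held-out R^2 within 0.1 of scikit-learn's RandomForestRegressor
    on the same split (cross-check only; not used at runtime)."""
    from sklearn.ensemble import RandomForestRegressor

    table = assemble_pathway_dataset(ef_records, "N2O", preset_spec("N2O").factors)
    X = table[list(table.attrs["factors"])]
    y = table["ef"].to_numpy()
    tr, te = random_partition(len(table), seed=0)
    ours = BaggedTreeRegressor(n_trees=150, random_state=0).fit(X.iloc[tr], y[tr])
    r2_ours, _ = evaluate(y[te], ours.predict(X.iloc[te]))
    ref = RandomForestRegressor(n_estimators=150, max_features=1 / 3,
                                min_samples_leaf=5, random_state=0)
    ref.fit(X.iloc[tr], y[tr])
    r2_ref, _ = evaluate(y[te], ref.predict(X.iloc[te]))
    assert abs(r2_ours - r2_ref) < 0.1


def test_monotone_truth_yields_nearly_monotone_predictions(rng):
    n = 150
    X = pd.DataFrame({
        "rainfall": rng.uniform(100, 500, n),
        "pH": rng.uniform(5, 9, n),
    })
    y = 1.0 / (1.0 + np.exp(-(X["rainfall"] - 300) / 80)) + rng.normal(0, 0.02, n)
    model = BaggedTreeRegressor(n_trees=80, min_leaf=5, random_state=0).fit(X, y)
    sweep = pd.DataFrame({"rainfall": np.linspace(120, 480, 40), "pH": 7.0})
    preds = model.predict(sweep)
    worst_drop = np.max(np.maximum(0.0, -np.diff(preds)))
    assert worst_drop <= 0.1 * np.ptp(preds)


class TestRepeatedRuns:
    def test_single_run_average_equals_that_run(self, ef_records):
        table = assemble_pathway_dataset(ef_records, "runoff",
                                         preset_spec("runoff").factors)
        res = repeated_runs(table, table.attrs["factors"], n_runs=1,
                            base_seed=3, n_trees=10)
        assert res.summary["r2_test_mean"] == res.runs["r2_test"].iloc[0]
        assert np.all(res.prediction_sd == 0.0)

    def test_identical_base_seed_reproduces_run_table(self, ef_records):
        table = assemble_pathway_dataset(ef_records, "runoff",
                                         preset_spec("runoff").factors)
        a = repeated_runs(table, table.attrs["factors"], n_runs=3, base_seed=1,
                          n_trees=5)
        b = repeated_runs(table, table.attrs["factors"], n_runs=3, base_seed=1,
                          n_trees=5)
        pd.testing.assert_frame_equal(a.runs, b.runs)

    def test_predict_ef_on_training_rows_and_spec(self, ef_records):
        table = assemble_pathway_dataset(ef_records, "NO",
                                         preset_spec("NO").factors)
        spec = PathwaySpec("NO", preset_spec("NO").factors, 97.8)
        model = train_pathway_model(table, spec, seed=0, n_trees=60, min_leaf=2)
        row = table.iloc[0]
        pred = predict_ef(model, row)
        assert model.y_min_ <= pred[0] <= model.y_max_
        # deep ensemble interpolates near the training value
        assert pred[0] == pytest.approx(row["ef"], abs=0.3 * np.ptp(table["ef"]))
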