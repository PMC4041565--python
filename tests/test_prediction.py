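import numpy as np
import pandas as pd
import pytest

import irclust as ir
from irclust.errors import ConsistencyError, DegenerateLabelsError, DomainError, ParameterError
from irclust.prediction import base_terms


def snp_frame(rng, n, cols):
    return pd.DataFrame(
        rng.integers(0, 3, (n, len(cols))).astype(float),
        index=pd.Index([f"i{k}" for k in range(n)], name="id"),
        columns=cols,
    )


def test_cart_depth_one_on_single_snp_rule():
    rng = np.random.default_rng(0)
    X = snp_frame(rng, 300, ["A", "B", "C"])
    y = np.where(X["A"] >= 1, 1, 2)
    model = ir.grow_cart(X, y, seed=0)
    assert model.depth == 1
    words = ir.extract_words(model)
    assert words.mains == {"A"}
    assert words.pairs == set()


def test_cart_prunes_noise_to_root():
    rng = np.random.default_rng(1)
    roots = 0
    for rep in range(20):
        X = snp_frame(rng, 200, list("ABCDE"))
        y = rng.choice([1, 2], 200)
        model = ir.grow_cart(X, y, seed=rep)
        roots += model.depth == 0
    # the 3-SE signal guard collapses noise fits to the root ~85-90% of the time
    assert roots >= 14


def test_cart_rejects_single_class():
    rng = np.random.default_rng(2)
    X = snp_frame(rng, 50, ["A"])
    with pytest.raises(DegenerateLabelsError):
        ir.grow_cart(X, np.ones(50, dtype=int), seed=0)


def test_extract_words_xor_interaction():
    """An XOR-style label forces a depth-2 tree whose adjacent splits mine
    the two-factor word; sub-word closure holds by construction."""
    rng = np.random.default_rng(3)
    X = snp_frame(rng, 600, ["A", "B", "C"])
    y = np.where((X["A"] >= 1) ^ (X["B"] >= 1), 1, 2)
    model = ir.grow_cart(X, y, seed=0)
    words = ir.extract_words(model)
    assert {"A", "B"} <= words.mains
    assert frozenset(("A", "B")) in words.pairs
    for pair in words.pairs:
        assert pair <= words.mains


def test_extract_words_excludes_self_pairs():
    """A three-interval rule in one variable splits twice on it; a repeated
    variable on a path is a main effect only, never a pair."""
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 10, 500)
    X = pd.DataFrame({"A": x}, index=[f"i{k}" for k in range(500)])
    y = np.where((x > 3) & (x < 7), 1, 2)
    model = ir.grow_cart(X, y, seed=0)
    assert model.depth >= 2
    words = ir.extract_words(model)
    assert words.mains == {"A"}
    assert words.pairs == set()


def test_word_set_enforces_subword_closure():
    with pytest.raises(ConsistencyError):
        ir.InteractionWordSet(mains={"A"}, pairs={frozenset(("A", "B"))})


def test_assemble_feature_sets_bookkeeping(default_cohort_truth):
    cohort, _ = default_cohort_truth
    rng = np.random.default_rng(5)
    snps = pd.DataFrame(
        rng.integers(0, 3, (cohort.n, 4)).astype(float),
        index=pd.Index(cohort.ids, name="id"),
        columns=["S1", "S2", "S3", "S4"],
    )
    words = ir.InteractionWordSet(
        mains={"S1", "AGE", "BMI"}, pairs={frozenset(("S1", "AGE"))}
    )
    sets = ir.assemble_feature_sets(cohort, snps, words)
    assert sets["FS1"].matrix().shape[1] == 5
    assert sets["FS2"].matrix().shape[1] == 5 + 4
    assert sets["FS3"].matrix().shape[1] == 5 + 4 + 1
    # FS nesting: FS1 columns appear unchanged in FS2 and FS3
    for name in ("FS2", "FS3"):
        m = sets[name].matrix()
        assert np.allclose(m[list(sets["FS1"].matrix().columns)],
                           sets["FS1"].matrix())
    # empty word set leaves FS3 identical to FS2
    sets0 = ir.assemble_feature_sets(cohort, snps, ir.InteractionWordSet())
    assert sets0["FS3"].matrix().equals(sets0["FS2"].matrix())


def test_feature_set_rejects_unknown_word(default_cohort_truth):
    cohort, _ = default_cohort_truth
    snps = pd.DataFrame(index=pd.Index(cohort.ids, name="id"))
    words = ir.InteractionWordSet(mains={"AGE", "NOPE"},
                                  pairs={frozenset(("AGE", "NOPE"))})
    with pytest.raises(ConsistencyError):
        ir.assemble_feature_sets(cohort, snps, words)


def _labels_for(ids, y):
    return ir.Assignment(pd.Series(y, index=ids))


def test_cv_perfect_on_separable_data():
    rng = np.random.default_rng(6)
    n = 200
    y = np.array([1] * 60 + [2] * 140)
    base = pd.DataFrame(
        {
            "AGE": np.where(y == 1, 10.0, -10.0) + rng.normal(0, 0.5, n),
            "BMI": rng.normal(size=n),
            "AGE2": rng.normal(size=n),
            "BMI2": rng.normal(size=n),
            "AGE_BMI": rng.normal(size=n),
        },
        index=pd.Index([f"i{k}" for k in range(n)], name="id"),
    )
    fs = ir.FeatureSet("FS1", base, base.iloc[:, :0])
    report = ir.cost_sensitive_cv(fs, _labels_for(base.index, y), n_folds=5, seed=0)
    assert (report.summary["sensitivity"] == 1.0).all()
    assert (report.summary["specificity"] == 1.0).all()
    assert (report.summary["miscost"] == 0.0).all()


def test_cv_null_features_near_cost_weighted_base_rate():
    rng = np.random.default_rng(7)
    n = 400
    y = rng.choice([1, 2], n)
    base = pd.DataFrame(
        rng.normal(size=(n, 5)),
        columns=["AGE", "BMI", "AGE2", "BMI2", "AGE_BMI"],
        index=pd.Index([f"i{k}" for k in range(n)], name="id"),
    )
    fs = ir.FeatureSet("FS1", base, base.iloc[:, :0])
    report = ir.cost_sensitive_cv(
        fs, _labels_for(base.index, y), cost_ratios=(1.0,), n_folds=5, seed=0
    )
    acc = float(report.summary["overall"].iloc[0])
    assert abs(acc - 0.5) < 4 * np.sqrt(0.25 / n)


def test_cost_ratio_monotone_sensitivity_threshold_oracle():
    """On 1-d data, the cost-weighted optimal threshold moves monotonically
    with the FN:FP ratio, so training sensitivity never decreases."""
    rng = np.random.default_rng(8)
    x = np.concatenate([rng.normal(1, 1, 80), rng.normal(-1, 1, 120)])
    y = np.array([1] * 80 + [2] * 120)
    order = np.argsort(x)
    xs, ys = x[order], y[order]

    def best_threshold_sensitivity(ratio):
        cuts = np.concatenate([[-np.inf], (xs[1:] + xs[:-1]) / 2, [np.inf]])
        best_cost, best_sens = np.inf, None
        for c in cuts:
            pred = np.where(xs > c, 1, 2)
            fn = np.sum((ys == 1) & (pred == 2))
            fp = np.sum((ys == 2) & (pred == 1))
            cost = ratio * fn + fp
            sens = np.sum((ys == 1) & (pred == 1)) / np.sum(ys == 1)
            if cost < best_cost - 1e-12:
                best_cost, best_sens = cost, sens
        return best_sens

    sens = [best_threshold_sensitivity(r) for r in (1.0, 1.5, 2.0, 3.0, 5.0)]
    assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))


def test_cv_stratification_error_on_single_class_fold():
    rng = np.random.default_rng(9)
    n = 30
    y = np.array([1] * 2 + [2] * 28)  # fewer positives than folds
    base = pd.DataFrame(
        rng.normal(size=(n, 2)),
        columns=["AGE", "BMI"],
        index=pd.Index([f"i{k}" for k in range(n)], name="id"),
    )
    fs = ir.FeatureSet("X", base, base.iloc[:, :0])
    with pytest.raises(Exception):
        ir.cost_sensitive_cv(fs, _labels_for(base.index, y), n_folds=10, seed=0)


def test_cv_is_leakage_free_canary():
    """A feature equal to the held-out labels, injected after the split,
    cannot raise held-out accuracy above the no-cheat baseline."""
    rng = np.random.default_rng(10)
    n = 200
    y = rng.choice([1, 2], n)
    ids = [f"i{k}" for k in range(n)]
    noise = rng.normal(size=(n, 3))
    y_series = pd.Series(y, index=ids)

    def builder_cheat(train_ids, test_ids):
        tr = [ids.index(i) for i in train_ids]
        te = [ids.index(i) for i in test_ids]
        cheat_tr = rng.normal(size=len(tr))  # built post-split: train part is noise
        cheat_te = y_series.loc[test_ids].to_numpy().astype(float)
        return (
            np.column_stack([noise[tr], cheat_tr]),
            np.column_stack([noise[te], cheat_te]),
        )

    base = pd.DataFrame(
        noise, columns=["a", "b", "c"], index=pd.Index(ids, name="id")
    )
    fs = ir.FeatureSet("X", base, base.iloc[:, :0])
    labels = _labels_for(ids, y)
    plain = ir.cost_sensitive_cv(fs, labels, cost_ratios=(1.0,), n_folds=5, seed=1)
    cheat = ir.cost_sensitive_cv(
        fs, labels, cost_ratios=(1.0,), n_folds=5, seed=1, builder=builder_cheat
    )
    acc_plain = float(plain.summary["overall"].iloc[0])
    acc_cheat = float(cheat.summary["overall"].iloc[0])
    assert acc_cheat < acc_plain + 4 * np.sqrt(0.25 / n)


def test_permutation_auc_power_and_boundaries():
    rng = np.random.default_rng(11)
    n = 150
    y = rng.choice([1, 2], n)
    ids = pd.Index([f"i{k}" for k in range(n)], name="id")
    base = pd.DataFrame(rng.normal(size=(n, 2)), columns=["AGE", "BMI"], index=ids)
    strong = (y == 1).astype(float) * 2 + rng.normal(0, 0.3, n)
    snps = pd.DataFrame({"S1": strong}, index=ids)
    # continuous stand-in column is fine: FeatureSet does not re-validate coding
    full = ir.FeatureSet("FS2", base, snps)
    fs1 = ir.FeatureSet("FS1", base, base.iloc[:, :0])
    labels = _labels_for(ids, y)
    p, obs, null = ir.permutation_auc_test(fs1, full, labels, n_perm=19, seed=0,
                                           n_folds=3)
    assert obs > 0.9
    assert p == pytest.approx(1 / 20)
    with pytest.raises(ParameterError):
        ir.permutation_auc_test(fs1, full, labels, n_perm=0, seed=0)
    with pytest.raises(ParameterError):
        ir.permutation_auc_test(fs1, fs1, labels, n_perm=5, seed=0)


def test_classification_chisq_closed_forms():
    a = np.array([1] * 10 + [2] * 10)
    assert ir.classification_chisq(a, a) == pytest.approx(20.0)
    pred = np.array([1, 1, 2, 2])
    act = np.array([1, 1, 1, 1])
    with pytest.raises(DomainError):
        ir.classification_chisq(pred, act)  # degenerate margin
    with pytest.raises(ParameterError):
        ir.classification_chisq(a[:5], a)


def test_classification_chisq_null_distribution():
    rng = np.random.default_rng(12)
    stats_ = []
    for _ in range(300):
        p = rng.choice([1, 2], 80)
        q = rng.choice([1, 2], 80)
        try:
            stats_.append(ir.classification_chisq(p, q))
        except DomainError:
            continue
    assert np.mean(stats_) == pytest.approx(1.0, abs=0.35)
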