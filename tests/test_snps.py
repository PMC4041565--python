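import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import irclust as ir
from irclust.errors import ConsistencyError, DegenerateLabelsError, DomainError, ParameterError
from irclust.snps import entropy


TABLE_HIGH = [[266, 0, 0], [1, 175, 0], [0, 0, 37]]  # near-duplicate SNP pair
TABLE_LOW = [[94, 35, 0], [59, 32, 0], [4, 1, 0]]  # nearly independent pair


def test_mutual_information_worked_examples():
    assert ir.mutual_information(TABLE_HIGH, base=2) == pytest.approx(1.2675, abs=5e-5)
    assert ir.mutual_information(TABLE_LOW, base=10) == pytest.approx(0.0018, abs=5e-5)


def test_mi_zero_on_product_table():
    margins_r = np.array([3.0, 5.0, 2.0])
    margins_c = np.array([1.0, 4.0])
    assert ir.mutual_information(np.outer(margins_r, margins_c)) == 0.0


def test_mi_domain_errors():
    with pytest.raises(DomainError):
        ir.mutual_information(np.zeros((3, 3)))
    with pytest.raises(DomainError):
        ir.mutual_information([[1, -1], [0, 2]])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=3),
        min_size=3,
        max_size=3,
    ).filter(lambda t: sum(map(sum, t)) > 0)
)
def test_mi_invariants_on_random_tables(table):
    t = np.array(table, dtype=float)
    i_bits = ir.mutual_information(t, base=2)
    assert i_bits >= 0
    hx = entropy(t.sum(axis=1))
    hy = entropy(t.sum(axis=0))
    assert i_bits <= min(hx, hy) + 1e-10
    # base conversion identities
    i_nats = ir.mutual_information(t, base=np.e)
    i_ten = ir.mutual_information(t, base=10)
    assert i_ten == pytest.approx(i_nats / np.log(10), abs=1e-12)
    assert i_bits == pytest.approx(i_nats / np.log(2), abs=1e-12)


def make_gm(data, ids=None):
    arr = np.array(data, dtype=float)
    ids = ids or [f"i{k}" for k in range(arr.shape[0])]
    cols = [f"S{j}" for j in range(arr.shape[1])]
    return ir.GenotypeMatrix(pd.DataFrame(arr, index=ids, columns=cols))


def test_filter_snps_constant_and_undergenotyped():
    nan = np.nan
    gm = make_gm(
        [
            [2, 0, 1, nan],
            [2, 1, 1, 1],
            [2, 2, 0, nan],
            [2, 0, 2, 0],
            [2, 1, 0, nan],
        ]
    )
    retained, report = ir.filter_snps(gm, min_genotyped=4)
    assert report.dropped_constant == ["S0"]
    assert report.dropped_undergenotyped == ["S3"]
    assert retained.snps == ["S1", "S2"]
    assert report.n_input == report.n_constant + report.n_undergenotyped + report.n_retained


def test_filter_snps_identity_when_clean():
    gm = make_gm([[0, 1], [1, 2], [2, 0], [0, 1]])
    retained, report = ir.filter_snps(gm, min_genotyped=4)
    assert retained == gm
    assert report.n_constant == report.n_undergenotyped == 0


def test_filter_individuals_boundary():
    nan = np.nan
    rows = np.ones((3, 5))
    data = pd.DataFrame(rows, index=["a", "b", "c"], columns=list("PQRST"))
    data.loc["a", ["P", "Q", "R"]] = nan  # 3 missing
    data.loc["b", ["P", "Q"]] = nan  # 2 missing
    gm = ir.GenotypeMatrix(data)
    retained, dropped = ir.filter_individuals(gm, max_missing=2)
    assert list(dropped) == ["a"]  # strictly more than the threshold
    assert "b" in retained.ids


def test_impute_identity_when_complete():
    gm = make_gm([[0, 1], [1, 2], [2, 0]])
    assert ir.impute_genotypes(gm, 0) == gm


def test_impute_uses_perfect_duplicate_predictor():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 3, 60).astype(float)
    dup = x.copy()
    noise = rng.integers(0, 3, 60).astype(float)
    df = pd.DataFrame(
        {"A": x, "B": dup, "C": noise},
        index=[f"i{k}" for k in range(60)],
    )
    df.loc["i5", "A"] = np.nan
    imputed = ir.impute_genotypes(ir.GenotypeMatrix(df), 1)
    assert imputed.frame.loc["i5", "A"] == dup[5]
    # observed entries preserved exactly
    mask = df.notna().to_numpy()
    assert (imputed.frame.to_numpy()[mask] == df.to_numpy()[mask]).all()


def test_impute_beats_modal_baseline_on_masked_data():
    """Tree imputation exploits inter-SNP dependence a modal fill ignores."""
    rng = np.random.default_rng(2)
    wins = 0
    for rep in range(5):
        n = 300
        base = rng.integers(0, 3, (n, 6)).astype(float)
        # correlated companions: copy with sparse flips
        comp = base.copy()
        flips = rng.random(comp.shape) < 0.05
        comp[flips] = rng.integers(0, 3, flips.sum())
        full = np.column_stack([base, comp])
        mask = rng.random(full.shape) < 0.05
        masked = full.copy()
        masked[mask] = np.nan
        gm = ir.GenotypeMatrix(
            pd.DataFrame(masked, index=[f"i{k}" for k in range(n)],
                         columns=[f"S{j}" for j in range(12)])
        )
        imputed = ir.impute_genotypes(gm, rep).frame.to_numpy()
        acc_tree = np.mean(imputed[mask] == full[mask])
        modes = pd.DataFrame(masked).mode().iloc[0].to_numpy()
        modal = np.where(np.isnan(masked), modes[None, :], masked)
        acc_modal = np.mean(modal[mask] == full[mask])
        wins += acc_tree > acc_modal
    assert wins >= 4


def test_distance_matrix_properties():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 3, 200).astype(float)
    y = rng.integers(0, 3, 200).astype(float)
    gm = make_gm(np.column_stack([x, x, y]))
    d = ir.mi_distance_matrix(gm)
    assert d.loc["S0", "S1"] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(d.to_numpy(), d.to_numpy().T)
    assert np.allclose(np.diag(d.to_numpy()), 0.0)
    assert d.loc["S0", "S2"] > 0.8  # independent SNPs are far


def test_distance_matrix_rejects_constant_snp():
    gm = make_gm([[2, 0], [2, 1], [2, 2], [2, 0]])
    with pytest.raises(ConsistencyError, match="S0"):
        ir.mi_distance_matrix(gm)


def test_cluster_snps_duplicates_merge_first():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 3, 300).astype(float)
    y = rng.integers(0, 3, 300).astype(float)
    gm = make_gm(np.column_stack([x, y, x]))
    dendro = ir.cluster_snps(ir.mi_distance_matrix(gm))
    z = dendro.linkage_matrix
    # first merge joins the duplicated pair (leaves 0 and 2) at height ~0
    assert sorted(z[0, :2].astype(int)) == [0, 2]
    assert np.all(np.diff(dendro.merge_heights) >= -1e-12)


def test_cluster_snps_matches_brute_force_average_linkage():
    rng = np.random.default_rng(5)
    G = rng.integers(0, 3, (150, 6)).astype(float)
    gm = make_gm(G)
    d = ir.mi_distance_matrix(gm)
    dendro = ir.cluster_snps(d)

    # brute-force average linkage on the same distances
    clusters = {i: [i] for i in range(6)}
    dist = {frozenset((i, j)): d.iloc[i, j] for i in range(6) for j in range(i + 1, 6)}
    heights = []
    while len(clusters) > 1:
        pair = min(dist, key=dist.get)
        heights.append(dist[pair])
        i, j = sorted(pair)
        merged = clusters[i] + clusters[j]
        for key in [k for k in dist if k & pair]:
            del dist[key]
        del clusters[i], clusters[j]
        for k, members in clusters.items():
            dist[frozenset((i, k))] = float(
                np.mean([d.iloc[a, b] for a in merged for b in members])
            )
        clusters[i] = merged
    assert np.allclose(sorted(dendro.merge_heights), sorted(heights), atol=1e-10)


def test_cluster_snps_needs_two(snp_pipeline):
    with pytest.raises(ParameterError):
        ir.cluster_snps(pd.DataFrame([[0.0]], index=["S"], columns=["S"]))


def test_select_representatives_root_cut_single_rep(snp_pipeline):
    sel = ir.select_representatives(
        snp_pipeline["dendrogram"],
        snp_pipeline["imputed"],
        snp_pipeline["assignment"],
        seed=0,
        cut_heights=(1.5,),
    )
    assert len(sel.representatives) == 1
    # the single representative is the most label-informative SNP overall
    assert sel.representatives[0] == sel.mi_with_label.idxmax()


def test_select_representatives_degenerate_labels(snp_pipeline):
    imputed = snp_pipeline["imputed"]
    ones = ir.Assignment(pd.Series(np.ones(len(imputed.ids), dtype=int), index=imputed.ids))
    with pytest.raises(DegenerateLabelsError):
        ir.select_representatives(
            snp_pipeline["dendrogram"], imputed, ones, seed=0
        )
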