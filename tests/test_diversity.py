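import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutrhythm.datamodel import BETA_METRICS, FeatureTable, RootedTree, TaxonomyMap
from gutrhythm.diversity import (
    DistanceMatrix,
    alpha_kernels,
    beta_kernels,
    bootstrapped_alpha,
    bootstrapped_beta,
    collapse_to_genus,
    filter_table,
    pcoa,
    rarefy,
)
from gutrhythm.errors import GutRhythmError


# ---------------------------------------------------------------------------
# alpha kernels (closed forms)


def test_shannon_uniform_16():
    vals = alpha_kernels(np.ones(16))
    assert vals["observed_features"] == 16
    assert vals["shannon"] == pytest.approx(4.0, abs=1e-12)
    assert vals["pielou"] == pytest.approx(1.0, abs=1e-12)


def test_shannon_half_quarter_quarter():
    vals = alpha_kernels(np.array([2, 1, 1]))
    assert vals["shannon"] == pytest.approx(1.5, abs=1e-12)


def test_alpha_all_zero_missing():
    vals = alpha_kernels(np.zeros(5))
    assert all(v is None for v in vals.values())


def test_pielou_single_feature_missing():
    vals = alpha_kernels(np.array([7, 0, 0]))
    assert vals["pielou"] is None
    assert vals["observed_features"] == 1


def test_faith_pd_worked_tree(worked_tree):
    fids = ["A", "B", "C", "D"]
    cases = {(1, 0, 0, 0): 2.0, (1, 1, 0, 0): 3.0, (1, 0, 1, 0): 4.0}
    for counts, expected in cases.items():
        vals = alpha_kernels(np.array(counts), worked_tree, fids)
        assert vals["faith_pd"] == pytest.approx(expected, abs=1e-12)


def test_faith_pd_monotone(worked_tree):
    fids = ["A", "B", "C", "D"]
    rng = np.random.default_rng(1)
    for _ in range(20):
        present = rng.integers(0, 2, 4)
        if present.sum() == 0:
            continue
        base = alpha_kernels(present, worked_tree, fids)["faith_pd"]
        absent = np.flatnonzero(present == 0)
        for j in absent:
            more = present.copy()
            more[j] = 1
            assert alpha_kernels(more, worked_tree, fids)["faith_pd"] >= base


@given(
    st.lists(st.integers(min_value=0, max_value=100), min_size=2, max_size=20).filter(
        lambda c: sum(1 for x in c if x > 0) >= 1
    )
)
def test_shannon_bounded_by_log_observed(counts):
    vals = alpha_kernels(np.array(counts))
    obs = vals["observed_features"]
    assert vals["shannon"] <= np.log2(max(obs, 1)) + 1e-9


# ---------------------------------------------------------------------------
# beta kernels


def test_identical_samples_zero(worked_tree):
    u = np.array([3, 1, 4, 1])
    vals = beta_kernels(u, u.copy(), worked_tree, ["A", "B", "C", "D"])
    for m in BETA_METRICS:
        assert vals[m] == pytest.approx(0.0, abs=1e-12)


def test_bray_curtis_closed_form():
    vals = beta_kernels(np.array([6, 2]), np.array([2, 2]))
    assert vals["bray_curtis"] == pytest.approx(1 / 3, abs=1e-12)


def test_disjoint_star_tree(star_tree):
    u = np.array([5, 5, 0, 0])
    v = np.array([0, 0, 5, 5])
    vals = beta_kernels(u, v, star_tree, ["A", "B", "C", "D"])
    assert vals["unweighted_unifrac"] == pytest.approx(1.0, abs=1e-12)
    assert vals["jaccard"] == pytest.approx(1.0, abs=1e-12)


def test_weighted_unifrac_star_manual(star_tree):
    # star tree unit branches: sum_b |p_u - p_v| over tips
    u = np.array([4, 0, 0, 0])
    v = np.array([0, 4, 0, 0])
    vals = beta_kernels(u, v, star_tree, ["A", "B", "C", "D"])
    assert vals["weighted_unifrac"] == pytest.approx(2.0, abs=1e-12)


def test_both_empty_missing():
    vals = beta_kernels(np.zeros(3), np.zeros(3))
    assert all(vals[m] is None for m in BETA_METRICS)


@given(
    st.lists(st.integers(0, 30), min_size=4, max_size=4),
    st.lists(st.integers(0, 30), min_size=4, max_size=4),
)
@settings(max_examples=50)
def test_beta_symmetry_and_bounds(cu, cv):
    u, v = np.array(cu), np.array(cv)
    if u.sum() == 0 and v.sum() == 0:
        return
    tree = RootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    ab = beta_kernels(u, v, tree, ["A", "B", "C", "D"])
    ba = beta_kernels(v, u, tree, ["A", "B", "C", "D"])
    for m in BETA_METRICS:
        if ab[m] is None:
            assert ba[m] is None
            continue
        assert ab[m] == pytest.approx(ba[m], abs=1e-12)
        if m != "weighted_unifrac":
            assert -1e-12 <= ab[m] <= 1 + 1e-12


# ---------------------------------------------------------------------------
# filtering


def _mk_table(count_rows, sample_ids=None, feature_ids=None):
    counts = np.array(count_rows)
    s = sample_ids or [f"s{i}" for i in range(counts.shape[0])]
    f = feature_ids or [f"f{j}" for j in range(counts.shape[1])]
    return FeatureTable(s, f, counts)


def _full_taxonomy(fids):
    return TaxonomyMap(
        {f: ["Bacteria", "Firmicutes", "", "", "", "G"] for f in fids}
    )


def test_filter_feature_total_boundary():
    table = _mk_table([[9, 10, 250]]).subset()  # one sample, three features
    tax = _full_taxonomy(table.feature_ids)
    filtered, report = filter_table(table, tax, min_feature_total=10, min_depth=1)
    assert filtered.feature_ids == ["f1", "f2"]
    dropped = [r for r in report if r.entity == "feature"]
    assert [r.entity_id for r in dropped] == ["f0"]


def test_filter_sample_depth_boundary():
    table = _mk_table([[3034, 0], [3035, 0], [4000, 100]])
    tax = _full_taxonomy(table.feature_ids)
    filtered, report = filter_table(table, tax, min_feature_total=1, min_depth=3035)
    assert filtered.sample_ids == ["s1", "s2"]
    assert any(r.entity_id == "s0" and "3034" in r.reason for r in report)


def test_filter_phylum_first():
    table = _mk_table([[100, 100]])
    tax = TaxonomyMap(
        {
            "f0": ["Bacteria", "", "", "", "", ""],
            "f1": ["Bacteria", "Firmicutes", "", "", "", ""],
        }
    )
    filtered, report = filter_table(table, tax, min_feature_total=1, min_depth=1)
    assert filtered.feature_ids == ["f1"]
    assert report[0].reason == "phylum unassigned"


def test_filter_all_samples_dropped_errors():
    table = _mk_table([[5, 5]])
    tax = _full_taxonomy(table.feature_ids)
    with pytest.raises(GutRhythmError, match="no samples retained"):
        filter_table(table, tax, min_feature_total=1, min_depth=10**6)


def test_filter_planted_rare_features(small_bundle):
    filtered, report = filter_table(
        small_bundle.table, small_bundle.taxonomy, min_feature_total=10, min_depth=3035
    )
    reported = {r.entity_id for r in report if "total count" in r.reason}
    planted = set(small_bundle.ground_truth["rare_features"])
    # planted features still phylum-assigned must all be caught by the
    # frequency filter
    unassigned = set(small_bundle.ground_truth["phylum_unassigned_features"])
    assert (planted - unassigned) <= reported


# ---------------------------------------------------------------------------
# rarefaction & bootstrap


def test_rarefy_preserves_depth():
    rng = np.random.default_rng(0)
    counts = np.array([100, 50, 3, 0, 7])
    for depth in (10, 50, 160):
        assert rarefy(counts, depth, rng).sum() == depth


def test_rarefy_at_full_depth_identity():
    rng = np.random.default_rng(0)
    counts = np.array([5, 7, 2])
    assert np.array_equal(rarefy(counts, 14, rng), counts)


def test_bootstrapped_alpha_exact_at_depth(worked_tree):
    table = FeatureTable(["s0"], ["A", "B", "C", "D"], np.array([[10, 10, 10, 10]]))
    res = bootstrapped_alpha(table, worked_tree, depth=40, n_boot=5, seed=0)
    by_metric = {r.metric: r.value for r in res}
    single = alpha_kernels(table.counts[0], worked_tree, table.feature_ids)
    for m, v in by_metric.items():
        assert v == pytest.approx(single[m], abs=1e-12)


def test_bootstrapped_alpha_seed_reproducible(worked_tree):
    table = FeatureTable(
        ["s0", "s1"],
        ["A", "B", "C", "D"],
        np.array([[40, 30, 20, 10], [5, 5, 80, 10]]),
    )
    r1 = bootstrapped_alpha(table, worked_tree, depth=50, n_boot=20, seed=3)
    r2 = bootstrapped_alpha(table, worked_tree, depth=50, n_boot=20, seed=3)
    assert [(a.sample_id, a.metric, a.value) for a in r1] == [
        (a.sample_id, a.metric, a.value) for a in r2
    ]


def test_bootstrapped_alpha_nboot_convergence(worked_tree):
    rng = np.random.default_rng(5)
    counts = rng.integers(50, 500, size=(1, 4))
    table = FeatureTable(["s0"], ["A", "B", "C", "D"], counts)
    # distribution of single-replicate values
    singles = []
    for seed in range(200):
        r = bootstrapped_alpha(table, worked_tree, depth=100, n_boot=1, seed=seed)
        singles.append([x.value for x in r if x.metric == "shannon"][0])
    mean100 = [
        x.value
        for x in bootstrapped_alpha(table, worked_tree, depth=100, n_boot=100, seed=0)
        if x.metric == "shannon"
    ][0]
    se = np.std(singles, ddof=1)
    assert abs(mean100 - np.mean(singles)) < 3 * se


def test_bootstrapped_alpha_shallow_sample_errors(worked_tree):
    table = FeatureTable(["s0"], ["A", "B", "C", "D"], np.array([[1, 1, 1, 1]]))
    with pytest.raises(GutRhythmError, match="below rarefaction depth"):
        bootstrapped_alpha(table, worked_tree, depth=100)


def test_bootstrapped_beta_symmetric_reproducible(worked_tree):
    rng = np.random.default_rng(2)
    counts = rng.integers(20, 200, size=(5, 4))
    table = FeatureTable(
        [f"s{i}" for i in range(5)], ["A", "B", "C", "D"], counts
    )
    dms1 = bootstrapped_beta(table, worked_tree, depth=60, n_boot=10, seed=1)
    dms2 = bootstrapped_beta(table, worked_tree, depth=60, n_boot=10, seed=1)
    for m in BETA_METRICS:
        assert np.allclose(dms1[m].data, dms1[m].data.T, atol=1e-12)
        assert np.array_equal(dms1[m].data, dms2[m].data)
        assert np.all(np.diag(dms1[m].data) == 0)


def test_bootstrapped_beta_duplicate_sample_noise_bound(worked_tree):
    # duplicated counts: averaged distance between duplicates stays within
    # the same-sample rarefaction noise scale
    counts = np.array([[400, 300, 200, 100], [400, 300, 200, 100]])
    table = FeatureTable(["a", "b"], ["A", "B", "C", "D"], counts)
    dms = bootstrapped_beta(table, worked_tree, depth=200, n_boot=50, seed=0)
    # null distribution: distance between two independent rarefactions
    rng = np.random.default_rng(99)
    null = []
    for _ in range(200):
        u = rarefy(counts[0], 200, rng)
        v = rarefy(counts[0], 200, rng)
        null.append(beta_kernels(u, v)["bray_curtis"])
    q99 = np.quantile(null, 0.99)
    assert dms["bray_curtis"]["a", "b"] <= q99


# ---------------------------------------------------------------------------
# genus collapse


def test_collapse_relative_abundance(flat_taxonomy):
    # two ASVs of Genus0 (f0, f3) with counts 3 and 7 in a 20-count sample
    counts = np.zeros((1, 8), dtype=int)
    counts[0, 0] = 3
    counts[0, 3] = 7
    counts[0, 1] = 10  # Genus1
    table = FeatureTable(["s0"], [f"f{j}" for j in range(8)], counts)
    rel, top = collapse_to_genus(table, flat_taxonomy)
    assert rel.loc["s0", "Genus0"] == pytest.approx(0.5, abs=1e-12)


def test_collapse_rowsums_one(tiny_table, flat_taxonomy):
    rel, _ = collapse_to_genus(tiny_table, flat_taxonomy)
    assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)


def test_collapse_top5_matches_plant(small_bundle):
    filtered, _ = filter_table(
        small_bundle.table, small_bundle.taxonomy, min_feature_total=10, min_depth=3035
    )
    _, top = collapse_to_genus(filtered, small_bundle.taxonomy, top_k=5)
    assert set(top) == set(small_bundle.ground_truth["top_genera_by_baseline"])


def test_collapse_empty_taxonomy_errors(tiny_table):
    with pytest.raises(GutRhythmError):
        collapse_to_genus(tiny_table, TaxonomyMap({}))


# ---------------------------------------------------------------------------
# PCoA


def pcoa_oracle(D, n_axes):
    """Independent dense eigendecomposition oracle."""
    import scipy.linalg

    n = D.shape[0]
    A = np.empty_like(D)
    for i in range(n):
        for j in range(n):
            A[i, j] = -0.5 * D[i, j] ** 2
    row = A.mean(axis=1)
    col = A.mean(axis=0)
    grand = A.mean()
    B = A - row[:, None] - col[None, :] + grand
    w, v = scipy.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_axes]
    return v[:, idx] * np.sqrt(np.maximum(w[idx], 0))


def test_pcoa_two_points():
    d = 3.7
    dm = DistanceMatrix(["a", "b"], np.array([[0, d], [d, 0]]), "test")
    emb = pcoa(dm, n_axes=1)
    coords = np.sort(emb.coordinates[:, 0])
    assert coords == pytest.approx([-d / 2, d / 2], abs=1e-10)


def test_pcoa_recovers_euclidean_geometry():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(12, 3))
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(pts))
    dm = DistanceMatrix([f"s{i}" for i in range(12)], D, "euclid")
    emb = pcoa(dm, n_axes=3)
    D2 = squareform(pdist(emb.coordinates))
    assert np.allclose(D, D2, atol=1e-9)


def test_pcoa_permutation_invariance():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(10, 3))
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(pts))
    ids = [f"s{i}" for i in range(10)]
    emb1 = pcoa(DistanceMatrix(ids, D, "e"), 3)
    perm = rng.permutation(10)
    emb2 = pcoa(DistanceMatrix([ids[i] for i in perm], D[np.ix_(perm, perm)], "e"), 3)
    d1 = squareform(pdist(emb1.coords_of(ids)))
    d2 = squareform(pdist(emb2.coords_of(ids)))
    assert np.allclose(d1, d2, atol=1e-9)


def test_pcoa_matches_oracle_random():
    rng = np.random.default_rng(11)
    for n in (10, 30, 50):
        pts = rng.normal(size=(n, 5))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        dm = DistanceMatrix([f"s{i}" for i in range(n)], D, "e")
        emb = pcoa(dm, 3)
        oracle = pcoa_oracle(D, 3)
        d_emb = squareform(pdist(emb.coordinates))
        d_orc = squareform(pdist(oracle))
        assert np.allclose(d_emb, d_orc, atol=1e-8)


def test_pcoa_too_few_positive_eigenvalues():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]), "t")
    with pytest.raises(GutRhythmError):
        pcoa(dm, n_axes=3)
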