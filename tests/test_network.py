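import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from scentnet.network import (
    EdgeSet,
    ProfileMatrix,
    build_network,
    condition_means,
    correlation_matrix,
    export_network,
    mutual_rank,
    mutual_rank_matrix,
    pearson,
    read_network_graphml,
)


def mr_brute_force(c: pd.DataFrame, a: str, b: str) -> float:
    """Mutual rank by direct enumeration with average ranks for ties."""

    def rank(x, y):
        target = abs(c.at[x, y])
        others = [abs(c.at[x, z]) for z in c.columns if z != x]
        greater = sum(1 for v in others if v > target)
        tied = sum(1 for v in others if v == target)
        return greater + (tied + 1) / 2

    return float(np.sqrt(rank(a, b) * rank(b, a)))


def random_pcc_matrix(rng, n_nodes, tie_prob=0.0):
    x = rng.standard_normal((n_nodes, 6))
    c = np.corrcoef(x)
    if tie_prob and rng.random() < tie_prob:
        c = np.round(c, 1)  # force tied |PCC| values
        np.fill_diagonal(c, 1.0)
    ids = [f"n{i}" for i in range(n_nodes)]
    return pd.DataFrame(c, index=ids, columns=ids)


class TestPearson:
    def test_exact_positive_linearity(self):
        x = np.arange(5.0)
        r, p = pearson(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_exact_negative_linearity(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_r_07_n_9_pvalue(self):
        # numeric value checked against the t-CDF with 7 df
        rng = np.random.default_rng(0)
        # construct a pair with sample r exactly 0.7 via orthogonalization
        x = rng.standard_normal(9)
        e = rng.standard_normal(9)
        xs = (x - x.mean()) / x.std()
        es = e - e.mean() - np.dot(e - e.mean(), xs) / np.dot(xs, xs) * xs
        es /= es.std()
        y = 0.7 * xs + np.sqrt(1 - 0.49) * es
        r, p = pearson(x, y)
        assert r == pytest.approx(0.7, abs=1e-12)
        assert p == pytest.approx(0.0356, abs=2e-4)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(1)
        for n in (4, 7, 15, 30):
            x, y = rng.standard_normal((2, n))
            r, p = pearson(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_definitional_two_pass_covariance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.standard_normal((2, 12))
            r, _ = pearson(x, y)
            mx, my = x.mean(), y.mean()
            cov = ((x - mx) * (y - my)).sum() / (len(x) - 1)
            ref = cov / (x.std(ddof=1) * y.std(ddof=1))
            assert r == pytest.approx(ref, rel=1e-12)

    def test_constant_vector_is_undefined_marker(self):
        r, p = pearson([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [3.0, 4.0])

    def test_pvalue_decreases_with_abs_r_at_fixed_n(self):
        n = 9
        rs = np.linspace(0.05, 0.99, 20)
        from scentnet.network import _pvalue_from_r

        ps = _pvalue_from_r(rs, n)
        assert (np.diff(ps) < 0).all()


class TestMutualRank:
    def test_reciprocal_top_partners_mr_one(self):
        ids = list("abc")
        c = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]], index=ids, columns=ids
        )
        assert mutual_rank(c, "a", "b") == 1.0

    def test_rank_product_sqrt(self):
        # construct ranks rank_a(b)=2, rank_b(a)=8 in a 9-node matrix
        rng = np.random.default_rng(3)
        c = random_pcc_matrix(rng, 9)
        ids = list(c.index)
        # overwrite row a so b is its 2nd partner; row b so a is its 8th
        a, b = ids[0], ids[1]
        others_a = [z for z in ids if z not in (a, b)]
        c.loc[a, :] = 0.0
        c.loc[:, a] = 0.0
        c.loc[b, :] = 0.0
        c.loc[:, b] = 0.0
        c.at[a, others_a[0]] = c.at[others_a[0], a] = 0.95
        c.at[a, b] = c.at[b, a] = 0.90
        for k, z in enumerate(others_a):  # 7 partners of b above 0.90
            c.at[b, z] = c.at[z, b] = 0.99 - 0.001 * k
        np.fill_diagonal(c.values, 1.0)
        assert mutual_rank(c, a, b) == pytest.approx(4.0)  # sqrt(2*8)

    def test_matches_brute_force_on_random_8_node_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            c = random_pcc_matrix(rng, 8, tie_prob=0.5)
            mr = mutual_rank_matrix(c)
            for a, b in itertools.combinations(c.index, 2):
                assert mr.at[a, b] == pytest.approx(mr_brute_force(c, a, b), rel=1e-12)

    def test_symmetry_and_lower_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            c = random_pcc_matrix(rng, rng.integers(4, 12))
            mr = mutual_rank_matrix(c).to_numpy()
            off = ~np.eye(len(mr), dtype=bool)
            assert np.array_equal(mr[off], mr.T[off])
            assert (mr[off] >= 1.0).all()

    def test_undefined_pcc_gives_nan_mr(self):
        ids = list("abc")
        c = pd.DataFrame(
            [[1.0, np.nan, 0.5], [np.nan, 1.0, 0.2], [0.5, 0.2, 1.0]],
            index=ids,
            columns=ids,
        )
        mr = mutual_rank_matrix(c)
        assert np.isnan(mr.at["a", "b"])
        assert np.isfinite(mr.at["a", "c"])


def planted_profiles(n_genes=30, seed=0, rho=0.98):
    """Nine-condition volatile and gene profiles with one planted pair."""
    rng = np.random.default_rng(seed)
    conds = [f"{g}_{s}" for g in ("SF", "WF", "Mr") for s in ("EB", "ES", "LS")]
    vol = pd.DataFrame(
        np.exp(rng.normal(2, 1, size=(4, 9))),
        index=["v01", "v06", "v10", "v26"],
        columns=conds,
    )
    genes = pd.DataFrame(
        np.exp(rng.normal(3, 1, size=(n_genes, 9))),
        index=[f"HF{i:05d}" for i in range(n_genes)],
        columns=conds,
    )
    v = vol.loc["v01"].to_numpy()
    z = (v - v.mean()) / v.std()
    e = rng.standard_normal(9)
    e = e - e.mean() - np.dot(e - e.mean(), z) / np.dot(z, z) * z
    e /= e.std()
    genes.loc["HF00000"] = 50 + 20 * (rho * z + np.sqrt(1 - rho**2) * e)
    return ProfileMatrix(vol, "volatile"), ProfileMatrix(genes, "gene")


class TestBuildNetwork:
    def test_planted_pair_passes_full_filter(self):
        vol, genes = planted_profiles()
        edges = build_network(vol, genes, guides=["v01"])
        passing = edges.passing()
        assert (
            (passing["node_a"] == "HF00000") & (passing["node_b"] == "v01")
        ).any()

    def test_no_guides_no_full_gives_empty_set(self):
        vol, genes = planted_profiles()
        assert build_network(vol, genes).edges.empty

    def test_missing_guide_named_in_error(self):
        vol, genes = planted_profiles()
        with pytest.raises(KeyError, match="v99"):
            build_network(vol, genes, guides=["v99"])

    def test_permuted_conditions_break_planted_edge(self):
        vol, genes = planted_profiles()
        rng = np.random.default_rng(12)
        perm = rng.permutation(genes.values.columns)
        shuffled = ProfileMatrix(
            pd.DataFrame(
                genes.values.to_numpy(), index=genes.values.index,
                columns=list(perm),
            )[list(genes.values.columns)],
            "gene",
        )
        edges = build_network(vol, shuffled, full=True)
        vg = edges.passing()
        vg = vg[vg["class_a"] != vg["class_b"]]
        # the planted edge itself must not survive the shuffle
        assert not (
            (vg["node_a"] == "HF00000") & (vg["node_b"] == "v01")
        ).any()
        # null survivors bounded by the binomial expectation of |r| >= 0.7
        # at n = 9 (p ~ 0.0357) plus 3 sigma; MR filters little in a
        # 34-node universe
        m = 4 * len(genes.values)
        expected = m * 0.0357
        assert len(vg) <= expected + 3 * np.sqrt(expected)

    def test_bipartite_excludes_volatile_volatile_edges(self):
        vol, genes = planted_profiles()
        edges = build_network(vol, genes, full=True, bipartite=True)
        assert (edges.edges["class_a"] != edges.edges["class_b"]).all()

    def test_too_few_shared_conditions_rejected(self):
        vol, genes = planted_profiles()
        vol2 = ProfileMatrix(vol.values.iloc[:, :2], "volatile")
        with pytest.raises(ValueError, match="shared conditions"):
            build_network(vol2, genes)

    def test_condition_means_averages_replicates(self):
        df = pd.DataFrame(
            {"SF_ES_1": [2.0], "SF_ES_2": [4.0], "WF_ES_1": [6.0]}, index=["g"]
        )
        out = condition_means(df)
        assert out.at["g", "SF_ES"] == 3.0 and out.at["g", "WF_ES"] == 6.0


class TestExport:
    @pytest.fixture
    def small_edges(self):
        vol, genes = planted_profiles()
        return build_network(vol, genes, full=True)

    def test_sif_lines_sorted(self, small_edges, tmp_path):
        path = tmp_path / "net.sif"
        export_network(small_edges, path, "sif")
        lines = path.read_text().splitlines()
        assert lines == sorted(lines)
        assert all(len(line.split("\t")) == 3 for line in lines)
        assert all(line.split("\t")[1] == "pcc_edge" for line in lines)

    def test_graphml_round_trip_preserves_attributes(self, small_edges, tmp_path):
        path = tmp_path / "net.graphml"
        export_network(small_edges, path, "graphml")
        back = read_network_graphml(path)
        orig = small_edges.edges[
            ["node_a", "node_b", "pcc", "pvalue", "mutual_rank", "sign"]
        ].sort_values(["node_a", "node_b"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            back[["node_a", "node_b", "pcc", "pvalue", "mutual_rank", "sign"]], orig
        )

    def test_empty_graphml_is_valid(self, tmp_path):
        empty = EdgeSet(
            edges=pd.DataFrame(
                columns=["node_a", "node_b", "class_a", "class_b", "pcc",
                         "pvalue", "mutual_rank", "sign", "passes"]
            ),
            n_conditions=9,
        )
        path = tmp_path / "empty.graphml"
        export_network(empty, path, "graphml")
        assert read_network_graphml(path).empty

    def test_unknown_format_rejected(self, small_edges, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(small_edges, tmp_path / "x", "xlsx")
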