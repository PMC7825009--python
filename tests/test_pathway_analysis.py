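import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metpath as mp
from metpath.pathway_analysis import RegressionRecord, information_gain


def pds_from(arr, pathways):
    arr = np.asarray(arr, dtype=float)
    return mp.PDSMatrix(pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=pathways
    ))


class TestSelectTopPathways:
    def test_perfect_separator_has_one_bit_gain_and_rank_one(self):
        rng = np.random.default_rng(0)
        n = 200
        labels = np.array([0] * 100 + [1] * 100)
        sep = np.concatenate([rng.uniform(0, 0.4, 100), rng.uniform(0.6, 1.0, 100)])
        noise = rng.uniform(0, 1, n)
        pds = pds_from(np.column_stack([noise, sep]), ["noisy", "separating"])
        assert information_gain(sep, labels) == pytest.approx(1.0)
        ranked = mp.select_top_pathways(pds, labels, k=2)
        assert ranked[0] == "separating"

    def test_gain_bounded_by_label_entropy_and_nonnegative(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 300)
        for _ in range(10):
            g = information_gain(rng.uniform(size=300), labels)
            assert -1e-12 <= g <= 1.0

    def test_gain_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=120)
        labels = (x + rng.normal(0, 0.3, 120) > 0.5).astype(int)
        g1 = information_gain(x, labels)
        g2 = information_gain(np.exp(3 * x), labels)
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_k_exceeding_pathways_returns_all(self, caplog):
        pds = pds_from(np.random.default_rng(3).uniform(size=(20, 3)), list("abc"))
        labels = np.array([0, 1] * 10)
        with caplog.at_level("WARNING"):
            out = mp.select_top_pathways(pds, labels, k=10)
        assert sorted(out) == ["a", "b", "c"]


class TestRegression:
    def _setup(self, y_fn, n=50, seed=4):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        met = pd.DataFrame({"m1": x, "m2": rng.normal(size=n), "m3": rng.normal(size=n)},
                           index=[f"s{i}" for i in range(n)])
        matrix = mp.MetaboliteMatrix(met)
        pds = pds_from(y_fn(x, rng)[:, None], ["P"])
        mapping = mp.FeatureMapping(
            mapped={"m1": "M1", "m2": "M2", "m3": "M3"}, unmapped=[],
            pathway_cover={"P": ["m1", "m2", "m3"]},
        )
        return pds, matrix, mapping

    def test_deterministic_linear_relation(self):
        pds, matrix, mapping = self._setup(lambda x, rng: 2 * x)
        recs = mp.pathway_metabolite_regression(pds, matrix, mapping)
        r1 = next(r for r in recs if r.metabolite_id == "M1")
        assert r1.coefficient == pytest.approx(1.0)  # z-scored slope = Pearson r
        assert r1.p_value < 1e-10 and r1.significant

    def test_slope_and_p_match_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        pds, matrix, mapping = self._setup(lambda *_: y, n=10, seed=5)
        matrix.values["m1"] = x
        recs = mp.pathway_metabolite_regression(pds, matrix, mapping)
        r1 = next(r for r in recs if r.metabolite_id == "M1")
        # closed-form simple regression on z-scored variables
        xz = (x - x.mean()) / x.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        slope = (xz * yz).sum() / (xz * xz).sum()
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt(8 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df=8)
        assert r1.coefficient == pytest.approx(slope, abs=1e-10)
        assert r1.p_value == pytest.approx(p, abs=1e-10)

    def test_null_significance_rate_near_alpha(self):
        rng = np.random.default_rng(6)
        n = 100
        n_feats = 40
        met = pd.DataFrame(rng.normal(size=(n, n_feats)),
                           index=[f"s{i}" for i in range(n)],
                           columns=[f"m{j}" for j in range(n_feats)])
        matrix = mp.MetaboliteMatrix(met)
        sig = 0
        total = 0
        for rep in range(25):
            pds = pds_from(rng.uniform(size=(n, 1)), ["P"])
            mapping = mp.FeatureMapping(
                mapped={c: c for c in met.columns}, unmapped=[],
                pathway_cover={"P": list(met.columns)},
            )
            recs = mp.pathway_metabolite_regression(pds, matrix, mapping)
            sig += sum(r.significant for r in recs)
            total += len(recs)
        assert 0.02 <= sig / total <= 0.08  # 1000 null records, alpha 0.05

    def test_coefficient_within_unit_interval(self):
        pds, matrix, mapping = self._setup(lambda x, rng: x + rng.normal(size=len(x)))
        recs = mp.pathway_metabolite_regression(pds, matrix, mapping)
        for r in recs:
            assert -1 - 1e-9 <= r.coefficient <= 1 + 1e-9

    def test_zero_variance_metabolite_skipped(self, caplog):
        pds, matrix, mapping = self._setup(lambda x, rng: 2 * x)
        matrix.values["m2"] = 1.0
        with caplog.at_level("WARNING"):
            recs = mp.pathway_metabolite_regression(pds, matrix, mapping)
        assert {r.metabolite_id for r in recs} == {"M1", "M3"}


class TestExportBipartite:
    def _records(self):
        return [
            RegressionRecord("P1", "M1", 0.9, 0.001, True),
            RegressionRecord("P1", "M2", -0.5, 0.01, True),
            RegressionRecord("P2", "M1", 0.1, 0.5, False),
        ]

    def test_only_significant_records_become_edges(self, tmp_path):
        g = mp.export_bipartite(self._records(), tmp_path / "g.graphml")
        assert g.number_of_edges() == 2

    def test_node_classes_disjoint(self, tmp_path):
        g = mp.export_bipartite(self._records(), tmp_path / "g.graphml")
        kinds = nx.get_node_attributes(g, "kind")
        for u, v in g.edges:
            assert {kinds[u], kinds[v]} == {"pathway", "metabolite"}

    def test_graphml_roundtrip_preserves_weights(self, tmp_path):
        p = tmp_path / "g.graphml"
        g = mp.export_bipartite(self._records(), p)
        back = nx.read_graphml(p)
        for u, v, data in g.edges(data=True):
            assert back.edges[u, v]["weight"] == pytest.approx(data["weight"])
            assert back.edges[u, v]["sign"] == data["sign"]

    def test_empty_graph_with_warning(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            g = mp.export_bipartite(
                [RegressionRecord("P", "M", 0.1, 0.9, False)], tmp_path / "g.graphml"
            )
        assert g.number_of_edges() == 0
        assert (tmp_path / "g.graphml").exists()


class TestFoldChange:
    def _fixture(self):
        values = pd.DataFrame(
            {"a": [2.0, 2.0, 4.0, 4.0], "b": [3.0, 3.0, 3.0, 3.0],
             "c": [1.0, 1.0, 2.0, 2.0]},
            index=["s1", "s2", "s3", "s4"],
        )
        matrix = mp.MetaboliteMatrix(values)
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=values.index)
        mapping = mp.FeatureMapping(
            mapped={"a": "K1", "b": "K2", "c": "K3"}, unmapped=[],
            pathway_cover={"P": ["a", "b", "c"]},
        )
        return matrix, mapping, labels

    def test_ratios(self):
        matrix, mapping, labels = self._fixture()
        tab = mp.pathway_foldchange_table(matrix, mapping, labels, "P",
                                          group1="g2", group2="g1")
        by = tab.set_index("metabolite").log2_ratio
        assert by["a"] == pytest.approx(1.0)   # 4 vs 2
        assert by["b"] == pytest.approx(0.0)   # equal means
        assert by["c"] == pytest.approx(1.0)

    def test_row_count_equals_mapped_members(self):
        matrix, mapping, labels = self._fixture()
        tab = mp.pathway_foldchange_table(matrix, mapping, labels, "P",
                                          group1="g1", group2="g2")
        assert len(tab) == len(mapping.pathway_cover["P"])
        assert list(tab.compound_id) == ["K1", "K2", "K3"]

    def test_nonpositive_mean_flagged_undefined(self):
        matrix, mapping, labels = self._fixture()
        matrix.values.loc[["s1", "s2"], "a"] = -1.0
        tab = mp.pathway_foldchange_table(matrix, mapping, labels, "P",
                                          group1="g2", group2="g1")
        row = tab[tab.metabolite == "a"].iloc[0]
        assert row.undefined and np.isnan(row.log2_ratio)
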