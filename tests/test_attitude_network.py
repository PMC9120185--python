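import numpy as np
import networkx as nx
import pytest

from attiso import (
    UndefinedResultError,
    attitude_isolation,
    bootstrap_test,
    build_network,
    dummy_code,
    export_graph,
    network_statistic,
    phi_edge,
)
from attiso.attitude_network import permute_items, trust_band

from conftest import make_survey


class TestPhiEdge:
    def test_identical_columns(self):
        x = np.array([0, 1, 0, 1, 1])
        assert phi_edge(x, x) == pytest.approx(1.0)

    def test_complement_columns(self):
        x = np.array([0, 1, 0, 1, 1])
        assert phi_edge(x, 1 - x) == pytest.approx(-1.0)

    def test_contingency_worked_example(self):
        # n11=4, n10=1, n01=1, n00=4 -> (4*4 - 1*1)/sqrt(5^4) = 0.6
        x = np.array([1] * 5 + [0] * 5)
        y = np.array([1] * 4 + [0] + [1] + [0] * 4)
        assert phi_edge(x, y) == pytest.approx(0.6, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(phi_edge(np.ones(5), np.array([0, 1, 0, 1, 1])))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            phi_edge(np.ones(3), np.ones(4))

    def test_pairwise_complete_rows(self):
        x = np.array([1, 0, 1, np.nan, 0])
        y = np.array([1, 0, 1, 1, np.nan])
        assert phi_edge(x, y) == pytest.approx(1.0)

    def test_matches_generic_correlation_routine(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            x = rng.integers(0, 2, 40).astype(float)
            y = rng.integers(0, 2, 40).astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            assert phi_edge(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


class TestBuildNetwork:
    def test_three_item_node_edge_and_exclusion_counts(self):
        rng = np.random.default_rng(0)
        data = make_survey(rng.integers(1, 6, size=(500, 3)))
        net = build_network(dummy_code(data))
        assert net.n_nodes == 15
        assert net.n_edges == 75  # 3 item pairs x 5 x 5
        assert len(net.excluded_pairs) == 30  # 3 items x C(5,2)

    def test_no_edge_joins_same_item(self):
        rng = np.random.default_rng(1)
        data = make_survey(rng.integers(1, 6, size=(200, 3)))
        net = build_network(dummy_code(data))
        for u, v in net.graph.edges():
            assert net.graph.nodes[u]["item"] != net.graph.nodes[v]["item"]

    def test_duplicated_items_give_unit_same_level_edges(self):
        codes = np.tile(np.array([[1], [2], [3], [4], [5]] * 4), (1, 3))
        net = build_network(dummy_code(make_survey(codes)))
        for lv in range(1, 6):
            assert net.graph[f"vax_important:{lv}"][f"vax_safe:{lv}"][
                "weight"
            ] == pytest.approx(1.0)

    def test_never_chosen_level_edges_omitted(self):
        codes = np.array([[1, 1, 1], [2, 2, 2], [4, 4, 4], [5, 5, 5]] * 5)
        net = build_network(dummy_code(make_survey(codes)))
        assert all("vax_important:3" not in e for e in net.graph.edges())
        assert any("vax_important:3" in pair for pair in net.dropped_edges)

    def test_single_item_is_hard_error(self):
        data = make_survey([[5, 5, 5]] * 3)
        with pytest.raises(ValueError):
            build_network(dummy_code(data, ["vax_important"]))

    def test_weights_bounded(self):
        rng = np.random.default_rng(2)
        data = make_survey(rng.integers(1, 6, size=(100, 3)))
        for w in build_network(dummy_code(data)).weights().values():
            assert -1.0 <= w <= 1.0


class TestNetworkStatistic:
    def test_absolute_value_sum(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("a", "c", weight=-0.5)
        from attiso.attitude_network import AttitudeNetwork

        assert network_statistic(AttitudeNetwork(g)) == pytest.approx(1.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        data = make_survey(rng.integers(1, 6, size=(300, 3)))
        net = build_network(dummy_code(data))
        brute = sum(abs(w) for w in net.weights().values())
        assert network_statistic(net) == pytest.approx(brute, abs=1e-12)


class TestBootstrap:
    def test_permutation_preserves_level_counts_and_one_hot(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(1, 6, size=(200, 3)).astype(float)
        codes[rng.random(codes.shape) < 0.1] = np.nan
        shuffled = permute_items(codes, rng)
        for j in range(3):
            for lv in range(1, 6):
                assert (shuffled[:, j] == lv).sum() == (codes[:, j] == lv).sum()
            assert np.isnan(shuffled[:, j]).sum() == np.isnan(codes[:, j]).sum()

    def test_p_value_formula_holds(self, structured_data):
        res = bootstrap_test(structured_data, n_iter=20, seed=5)
        expected = (1 + int((res.null_stats >= res.observed_stat).sum())) / 21
        assert res.p_value == pytest.approx(expected)
        assert 0 < res.p_value <= 1

    def test_minimum_p_with_one_iteration(self, structured_data):
        res = bootstrap_test(structured_data, n_iter=1, seed=5)
        assert res.p_value in (0.5, 1.0)

    def test_structured_data_rejected(self, structured_data):
        res = bootstrap_test(structured_data, n_iter=100, seed=6)
        assert res.p_value <= 0.01
        assert res.observed_stat > res.null_stats.max()


class TestAttitudeIsolation:
    def test_sign_convention_isolated_strong_trust(self):
        # strong trust holders answer (5,5,5); everyone else stays below 5,
        # so every (strong-trust, other) phi is negative
        rng = np.random.default_rng(7)
        others = rng.integers(1, 5, size=(300, 3))
        codes = np.vstack([others, np.full((100, 3), 5)])
        res = attitude_isolation(make_survey(codes))
        assert res.isolation > 0
        assert res.n_pairs_used == 24

    def test_coupled_strong_trust_gives_negative_isolation(self):
        # strong-trust answers co-occur with non-strong answers: one bloc
        # pairs item-1 strong trust with weak trust / neutral elsewhere,
        # the other blocs pair items 2-3 strong trust with low item-1 codes
        codes = np.array(
            [[5, 4, 3]] * 25 + [[1, 5, 5]] * 25 + [[2, 5, 5]] * 25 + [[3, 5, 5]] * 25
        )
        res = attitude_isolation(make_survey(codes))
        assert res.isolation == pytest.approx(-0.2, abs=1e-12)

    def test_matches_direct_phi_average(self):
        rng = np.random.default_rng(8)
        data = make_survey(rng.integers(1, 6, size=(400, 3)))
        dm = dummy_code(data)
        vals = []
        for p, (ip, lp) in enumerate(dm.attitude_index):
            if lp != 5:
                continue
            for q, (iq, lq) in enumerate(dm.attitude_index):
                if lq == 5 or iq == ip:
                    continue
                vals.append(
                    phi_edge(dm.matrix[:, p].astype(float), dm.matrix[:, q].astype(float))
                )
        expected = -np.nanmean(vals)
        assert attitude_isolation(data).isolation == pytest.approx(expected, abs=1e-12)

    def test_within_item_mode_uses_more_pairs(self):
        rng = np.random.default_rng(9)
        data = make_survey(rng.integers(1, 6, size=(400, 3)))
        res = attitude_isolation(data, include_within_item=True)
        assert res.n_pairs_used == 36

    def test_invariant_to_respondent_order(self):
        rng = np.random.default_rng(10)
        arr = rng.integers(1, 6, size=(300, 3))
        a = attitude_isolation(make_survey(arr)).isolation
        b = attitude_isolation(make_survey(arr[::-1])).isolation
        assert a == pytest.approx(b, abs=1e-12)

    def test_country_restriction(self):
        rng = np.random.default_rng(11)
        arr = rng.integers(1, 6, size=(300, 3))
        import pandas as pd

        from attiso import SurveyDataset
        from attiso.synthetic_data import default_items

        items = default_items(0)
        table = pd.DataFrame(
            {
                "country": ["AA"] * 150 + ["BB"] * 150,
                **{it.item_id: arr[:, j] for j, it in enumerate(items)},
            }
        )
        data = SurveyDataset(table, items)
        only_aa = make_survey(arr[:150])
        assert attitude_isolation(data, "AA").isolation == pytest.approx(
            attitude_isolation(only_aa).isolation, abs=1e-12
        )

    def test_undefined_when_no_pairs(self):
        data = make_survey([[5, 5, 5]] * 10)  # every column constant
        with pytest.raises(UndefinedResultError):
            attitude_isolation(data)


class TestTrustBands:
    @pytest.mark.parametrize(
        "level,n,band",
        [
            (5, 5, "strong-trust"),
            (3, 5, "neutral"),
            (1, 5, "strong-distrust"),
            (4, 4, "strong-trust"),
            (3, 4, "weak-trust"),
        ],
    )
    def test_band_mapping(self, level, n, band):
        assert trust_band(level, n) == band


class TestExportGraph:
    @pytest.fixture()
    def net(self):
        rng = np.random.default_rng(13)
        return build_network(dummy_code(make_survey(rng.integers(1, 6, size=(200, 3)))))

    def test_gexf_round_trip(self, net, tmp_path):
        p = tmp_path / "net.gexf"
        export_graph(net, p, dialect="gexf")
        g = nx.read_gexf(p)
        assert g.number_of_nodes() == net.n_nodes
        assert g.number_of_edges() == net.n_edges

    def test_graphml_round_trip(self, net, tmp_path):
        p = tmp_path / "net.graphml"
        export_graph(net, p, dialect="graphml")
        g = nx.read_graphml(p)
        assert g.number_of_edges() == net.n_edges

    def test_drop_negative_mode(self, net, tmp_path):
        p = tmp_path / "pos.gexf"
        export_graph(net, p, dialect="gexf", drop_negative=True)
        n_pos = sum(1 for w in net.weights().values() if w >= 0)
        assert nx.read_gexf(p).number_of_edges() == n_pos

    def test_empty_edge_network_is_valid(self, tmp_path):
        from attiso.attitude_network import AttitudeNetwork

        g = nx.Graph()
        g.add_node("a:1", item="a", level=1, trust_band="neutral", color="#000")
        empty = AttitudeNetwork(g)
        p = tmp_path / "empty.gexf"
        export_graph(empty, p)
        assert nx.read_gexf(p).number_of_nodes() == 1
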