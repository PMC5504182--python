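"""Tests of SUS-plot classification, Venn partitioning, correlation networks
and STOCSY."""

import numpy as np
import pandas as pd
import pytest

from nmrmetab.chemometrics import OPLSDA
from nmrmetab.comparative import (
    correlation_network,
    filter_network_by_sus,
    network_edge_table,
    stocsy,
    sus_plot,
    venn_categorize,
)
from nmrmetab.containers import SpectraSet
from nmrmetab.synthetic import default_axis, make_default_library, simulate_spectrum

from conftest import make_fm, make_spectra


def _fit(rng, labels, effect_cols, p=10, flip=False):
    n = len(labels)
    X = rng.normal(size=(n, p))
    y = np.array([1.0 if l == labels[-1] else -1.0 for l in labels])
    for j, size in effect_cols.items():
        X[:, j] += y * size * (-1 if flip else 1)
    return OPLSDA(X, labels, n_orthogonal=0, positive_class=labels[-1]).fit()


def _sus_pair(rng, shared=(0, 1), only_a=(2,), only_b=(3,)):
    labels_a = ["ref"] * 12 + ["A"] * 12
    labels_b = ["ref"] * 12 + ["B"] * 12
    eff_a = {j: 3.0 for j in (*shared, *only_a)}
    eff_b = {j: 3.0 for j in (*shared, *only_b)}
    return (
        _fit(rng, labels_a, eff_a),
        _fit(rng, labels_b, eff_b),
    )


class TestSusPlot:
    def test_self_comparison_lies_on_the_diagonal(self, rng):
        labels = ["ref"] * 10 + ["A"] * 10
        res = _fit(rng, labels, {0: 2.0, 3: 1.0})
        sus = sus_plot(res, res, threshold=0.5)
        assert np.array_equal(sus["corr_A"], sus["corr_B"])
        assert (sus["diagonal_distance"] == 0).all()

    def test_threshold_rule_categories(self, rng):
        # constructed correlation pairs exercised through hand-built results
        res_a, res_b = _sus_pair(rng)
        sus = sus_plot(res_a, res_b, threshold=0.5)
        assert sus.loc["0", "category"].startswith("shared")
        assert sus.loc["2", "category"] == "unique-A"
        assert sus.loc["3", "category"] == "unique-B"

    def test_sign_agreement_controls_the_diagonal(self, rng):
        labels = ["ref"] * 15 + ["A"] * 15
        res_a = _fit(rng, labels, {0: 3.0})
        res_b = _fit(rng, labels, {0: 3.0}, flip=True)  # opposite direction
        sus = sus_plot(res_a, res_b, threshold=0.5)
        assert sus.loc["0", "category"] == "shared-negative"
        same = sus_plot(res_a, res_a, threshold=0.5)
        assert same.loc["0", "category"] == "shared-positive"

    def test_category_invariant_to_simultaneous_score_flip(self, rng):
        res_a, res_b = _sus_pair(rng)
        sus = sus_plot(res_a, res_b, threshold=0.5)
        for r in (res_a, res_b):
            r.corr = -r.corr  # simultaneous sign flip of both models
        flipped = sus_plot(res_a, res_b, threshold=0.5)
        assert list(sus["category"]) == list(flipped["category"])

    def test_mismatched_reference_rejected(self, rng):
        labels_a = ["ref"] * 8 + ["A"] * 8
        labels_b = ["other"] * 8 + ["B"] * 8
        res_a = _fit(rng, labels_a, {0: 2.0})
        res_b = _fit(rng, labels_b, {0: 2.0})
        with pytest.raises(ValueError, match="reference"):
            sus_plot(res_a, res_b)

    def test_mismatched_features_rejected(self, rng):
        labels = ["ref"] * 8 + ["A"] * 8
        res_a = _fit(rng, labels, {0: 2.0}, p=5)
        res_b = _fit(rng, labels, {0: 2.0}, p=6)
        with pytest.raises(ValueError, match="feature"):
            sus_plot(res_a, res_b)


class TestVenn:
    def test_no_significant_features_gives_empty_sets(self, rng):
        labels = ["ref"] * 10 + ["A"] * 10
        res = _fit(rng, labels, {})  # pure noise
        sus = sus_plot(res, res, threshold=0.999)
        venn = venn_categorize(sus)
        assert venn["A_only"] == set() and venn["B_only"] == set()
        assert venn["shared"] == {}

    def test_partition_is_disjoint_and_complete(self, rng):
        res_a, res_b = _sus_pair(rng)
        sus = sus_plot(res_a, res_b, threshold=0.5)
        venn = venn_categorize(sus)
        shared = set(venn["shared"])
        assert venn["A_only"] & venn["B_only"] == set()
        assert venn["A_only"] & shared == set()
        assert venn["B_only"] & shared == set()
        significant = set(sus.index[sus["category"] != "not-significant"])
        assert venn["A_only"] | venn["B_only"] | shared == significant

    def test_shared_features_carry_sign_pairs(self, rng):
        res_a, res_b = _sus_pair(rng)
        venn = venn_categorize(sus_plot(res_a, res_b, threshold=0.5))
        for signs in venn["shared"].values():
            assert signs in {(1, 1), (-1, -1), (1, -1), (-1, 1)}


class TestCorrelationNetwork:
    def test_duplicated_feature_gives_unit_edge(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([x, x, rng.normal(size=10)])
        fm = make_fm(X, ["g"] * 10, feature_names=["a", "b", "c"])
        net = correlation_network(fm, threshold=0.6)
        assert net.has_edge("a", "b")
        assert net.edges["a", "b"]["r"] == pytest.approx(1.0)

    def test_negated_feature_gives_minus_one_edge(self, rng):
        x = rng.normal(size=12)
        fm = make_fm(np.column_stack([x, -x]), ["g"] * 12, feature_names=["a", "b"])
        net = correlation_network(fm, threshold=0.6)
        assert net.edges["a", "b"]["r"] == pytest.approx(-1.0)

    def test_edge_matrix_matches_brute_force_loop(self, rng):
        X = rng.normal(size=(10, 8))
        fm = make_fm(X, ["g"] * 10)
        net = correlation_network(fm, threshold=0.0001)
        for i in range(8):
            for j in range(i + 1, 8):
                xi, xj = X[:, i], X[:, j]
                r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                    np.sqrt(np.sum((xi - xi.mean()) ** 2))
                    * np.sqrt(np.sum((xj - xj.mean()) ** 2))
                )
                if abs(r) > 0.0001:
                    assert net.edges[f"f{i}", f"f{j}"]["r"] == pytest.approx(r, abs=1e-12)

    def test_null_features_produce_no_edges(self):
        clean = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            fm = make_fm(r.normal(size=(100, 30)), ["g"] * 100)
            net = correlation_network(fm, threshold=0.6)
            clean += net.number_of_edges() == 0
        assert clean >= 48  # >= 95% of seeds edge-free

    def test_zero_variance_feature_is_isolated_node(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.2
        fm = make_fm(X, ["g"] * 10, feature_names=["a", "b", "c"])
        net = correlation_network(fm, threshold=0.1)
        assert "b" in net.nodes
        assert net.degree["b"] == 0

    def test_too_few_samples_rejected(self, rng):
        fm = make_fm(rng.normal(size=(3, 4)), ["g"] * 3)
        with pytest.raises(ValueError, match="4 samples"):
            correlation_network(fm)


class TestSusFiltering:
    def test_empty_significant_set_gives_empty_graph(self, rng):
        fm = make_fm(rng.normal(size=(10, 4)), ["g"] * 10, feature_names=list("abcd"))
        net = correlation_network(fm, threshold=0.2)
        sus = pd.DataFrame(
            {
                "corr_A": [0.1] * 4,
                "corr_B": [0.1] * 4,
                "category": ["not-significant"] * 4,
                "diagonal_distance": [0.0] * 4,
            },
            index=list("abcd"),
        )
        out = filter_network_by_sus(net, sus)
        assert out.number_of_nodes() == 0

    def test_filtering_never_adds_edges(self, rng):
        fm = make_fm(rng.normal(size=(20, 6)), ["g"] * 20)
        net = correlation_network(fm, threshold=0.1)
        sus = pd.DataFrame(
            {
                "corr_A": [0.9, 0.9, 0.1, 0.9, 0.1, 0.1],
                "corr_B": [0.9, 0.1, 0.1, 0.8, 0.1, 0.1],
                "category": ["shared-positive", "unique-A", "not-significant",
                             "shared-positive", "not-significant", "not-significant"],
                "diagonal_distance": 0.0,
            },
            index=[f"f{j}" for j in range(6)],
        )
        out = filter_network_by_sus(net, sus)
        assert set(out.edges) <= set(net.edges)
        assert all(out.nodes[n]["direction"] == "increased" for n in out.nodes)

    def test_planted_correlated_block_survives(self, rng):
        base = rng.normal(size=30)
        X = np.column_stack(
            [base + rng.normal(0, 0.1, 30) for _ in range(3)]
            + [rng.normal(size=30) for _ in range(3)]
        )
        fm = make_fm(X, ["g"] * 30)
        net = correlation_network(fm, threshold=0.6)
        sus = pd.DataFrame(
            {
                "corr_A": [0.9] * 3 + [0.1] * 3,
                "corr_B": [0.9] * 3 + [0.1] * 3,
                "category": ["shared-positive"] * 3 + ["not-significant"] * 3,
                "diagonal_distance": 0.0,
            },
            index=[f"f{j}" for j in range(6)],
        )
        out = filter_network_by_sus(net, sus)
        assert out.has_edge("f0", "f1")
        assert out.has_edge("f0", "f2")
        assert out.has_edge("f1", "f2")

    def test_edge_table_lists_every_edge(self, rng):
        x = rng.normal(size=10)
        fm = make_fm(np.column_stack([x, x]), ["g"] * 10, feature_names=["a", "b"])
        net = correlation_network(fm, threshold=0.5)
        table = network_edge_table(net)
        assert len(table) == 1
        assert table.loc[0, "r"] == pytest.approx(1.0)


class TestStocsy:
    def test_driver_against_itself_is_one(self, rng):
        fm = make_fm(rng.normal(size=(10, 5)), ["g"] * 10)
        out = stocsy(fm, "f2")
        assert out.set_index("feature").loc["f2", "r"] == pytest.approx(1.0)

    def test_multiplets_of_one_metabolite_correlate(self, default_library):
        # lactate doublet (1.33) and quartet (4.12) share the concentration
        axis = default_axis(n_points=4096)
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(50):
            conc = {"Lactate": rng.lognormal(0, 0.3), "Formate": rng.lognormal(0, 0.3)}
            rows.append(
                simulate_spectrum(conc, default_library, axis, noise_sd=0.01 * 120,
                                  seed=rng)
            )
        ss = make_spectra(np.vstack(rows), axis)
        out = stocsy(ss, 1.33).set_index("feature")
        j_other = f"{axis[np.argmin(np.abs(axis - 4.12))]:.4f}"
        assert out.loc[j_other, "r"] >= 0.95

    def test_independent_metabolites_uncorrelated(self, default_library):
        axis = default_axis(n_points=2048)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = [
                simulate_spectrum(
                    {"Formate": rng.lognormal(0, 0.3), "Succinate": rng.lognormal(0, 0.3)},
                    default_library, axis, seed=rng,
                )
                for _ in range(50)
            ]
            ss = make_spectra(np.vstack(rows), axis)
            out = stocsy(ss, 8.46).set_index("feature")
            j_other = f"{axis[np.argmin(np.abs(axis - 2.41))]:.4f}"
            hits += abs(out.loc[j_other, "r"]) < 0.5
        assert hits >= 19  # >= 95% of seeds

    def test_zero_variance_driver_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        X[:, 0] = 1.0
        fm = make_fm(X, ["g"] * 8)
        with pytest.raises(ValueError, match="zero-variance driver"):
            stocsy(fm, "f0")
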