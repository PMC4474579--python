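"""Weight construction: log1p transform, sum-to-m normalisation, sensitivity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netwfdr import (
    FunctionalNetwork,
    QuerySet,
    assign_weights,
    log1p_transform,
    normalize_to_m,
    sensitivity_weights,
)
from netwfdr.weighting import WeightVector


class TestLog1p:
    def test_closed_form_values(self):
        trc = {"a": 0.0, "b": math.e - 1, "c": math.e**2 - 1}
        out = log1p_transform(trc)
        assert out["a"] == 0.0
        assert out["b"] == pytest.approx(1.0)
        assert out["c"] == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log1p_transform({"a": -0.1})

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=30, unique=True))
    @settings(derandomize=True)
    def test_rank_preserving(self, values):
        trc = {f"g{i}": v for i, v in enumerate(values)}
        out = log1p_transform(trc)
        by_input = sorted(trc, key=trc.get)
        transformed = [out[g] for g in by_input]
        assert transformed == sorted(transformed)


class TestNormalizeToM:
    def test_constant_vector_becomes_ones(self):
        w = normalize_to_m({"a": 7.0, "b": 7.0, "c": 7.0}, ["a", "b", "c"])
        assert dict(w.weights) == {"a": 1.0, "b": 1.0, "c": 1.0}

    def test_mean_one_fixed_point(self):
        w = normalize_to_m({"a": 0.0, "b": 1.0, "c": 2.0}, ["a", "b", "c"])
        assert dict(w.weights) == pytest.approx({"a": 0.0, "b": 1.0, "c": 2.0})
        assert sum(w.weights.values()) == pytest.approx(3.0)

    def test_missing_genes_contribute_zero(self):
        w = normalize_to_m({"a": 2.0}, ["a", "b"])
        assert w["b"] == 0.0
        assert w["a"] == pytest.approx(2.0)

    def test_all_zero_falls_back_to_uniform(self, caplog):
        with caplog.at_level("WARNING"):
            w = normalize_to_m({"a": 0.0, "b": 0.0}, ["a", "b"])
        assert dict(w.weights) == {"a": 1.0, "b": 1.0}
        assert any("uniform" in r.message for r in caplog.records)

    @given(
        st.lists(st.floats(0, 1e3), min_size=1, max_size=100).filter(
            lambda v: sum(v) > 0
        )
    )
    @settings(derandomize=True)
    def test_sum_equals_m(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        w = normalize_to_m(dict(zip(genes, values)), genes)
        assert sum(w.weights.values()) == pytest.approx(len(values), rel=1e-9)

    def test_ratio_preserving(self):
        w = normalize_to_m({"a": 1.0, "b": 4.0}, ["a", "b"])
        assert w["b"] / w["a"] == pytest.approx(4.0)


class TestSensitivity:
    def test_residual_mass_redistributed(self):
        w = WeightVector({"q": 2.0, "a": 0.5, "b": 0.5}, 3)
        s = sensitivity_weights(w, QuerySet.from_iterable(["q"]))
        assert dict(s.weights) == pytest.approx({"q": 1.0, "a": 1.0, "b": 1.0})

    def test_worked_five_gene_example(self):
        w = WeightVector({"q": 4.0, "a": 0.2, "b": 0.3, "c": 0.1, "d": 0.4}, 5)
        s = sensitivity_weights(w, QuerySet.from_iterable(["q"]))
        assert dict(s.weights) == pytest.approx(
            {"q": 1.0, "a": 0.8, "b": 1.2, "c": 0.4, "d": 1.6}
        )
        assert sum(s.weights.values()) == pytest.approx(5.0)

    def test_all_queries_gives_all_ones(self):
        w = WeightVector({"a": 0.5, "b": 1.5}, 2)
        s = sensitivity_weights(w, QuerySet.from_iterable(["a", "b"]))
        assert dict(s.weights) == {"a": 1.0, "b": 1.0}

    def test_zero_nonquery_mass_goes_uniform(self, caplog):
        w = WeightVector({"q": 3.0, "a": 0.0, "b": 0.0}, 3)
        with caplog.at_level("WARNING"):
            s = sensitivity_weights(w, QuerySet.from_iterable(["q"]))
        assert dict(s.weights) == {"q": 1.0, "a": 1.0, "b": 1.0}

    def test_nonquery_zero_weights_stay_zero(self):
        w = WeightVector({"q": 2.0, "a": 1.0, "b": 0.0}, 3)
        s = sensitivity_weights(w, QuerySet.from_iterable(["q"]))
        assert s["b"] == 0.0
        assert sum(s.weights.values()) == pytest.approx(3.0)

    def test_missing_query_rejected(self):
        w = WeightVector({"a": 1.0, "b": 1.0}, 2)
        with pytest.raises(ValueError, match="ghost"):
            sensitivity_weights(w, QuerySet.from_iterable(["ghost"]))

    @given(
        st.lists(st.floats(0.0, 10.0), min_size=3, max_size=40).filter(
            lambda v: sum(v[1:]) > 0
        )
    )
    @settings(derandomize=True)
    def test_idempotent_and_pins_queries(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        w = normalize_to_m(dict(zip(genes, values)), genes)
        qs = QuerySet.from_iterable(genes[:1])
        s1 = sensitivity_weights(w, qs)
        s2 = sensitivity_weights(s1, qs)
        assert s1["g0"] == 1.0
        assert dict(s2.weights) == pytest.approx(dict(s1.weights), rel=1e-12)
        assert sum(s1.weights.values()) == pytest.approx(len(genes), rel=1e-9)


class TestAssignWeights:
    def test_raw_scheme_proportional_to_trc(self, star_net, queries_q):
        genes = ["q", "a", "b", "c"]
        w = assign_weights(star_net, queries_q, genes, scheme="raw", expansion=2)
        # 2-hop subnetwork is the full graph; TRC q=.7, a=.9, b=.2, c=.4, mean .55
        assert dict(w.weights) == pytest.approx(
            {g: t / 0.55 for g, t in {"q": 0.7, "a": 0.9, "b": 0.2, "c": 0.4}.items()}
        )
        assert sum(w.weights.values()) == pytest.approx(4.0)

    def test_outside_universe_fallback_uniform(self, star_net, queries_q, caplog):
        with caplog.at_level("WARNING"):
            w = assign_weights(star_net, queries_q, ["x", "y"], scheme="raw")
        assert dict(w.weights) == {"x": 1.0, "y": 1.0}

    def test_log1p_and_raw_rank_identically(self, rng):
        from conftest import random_network

        net, genes = random_network(rng, n_nodes=12, n_edges=20)
        seed = next(iter(net.graph.nodes))
        qs = QuerySet.from_iterable([seed])
        w_raw = assign_weights(net, qs, genes, scheme="raw", expansion=3)
        w_log = assign_weights(net, qs, genes, scheme="log1p", expansion=3)
        rank = lambda w: sorted(genes, key=lambda g: (w[g], g))
        assert rank(w_raw) == rank(w_log)

    def test_min_weight_floor_keeps_sum(self, star_net, queries_q):
        genes = ["q", "a", "b", "c", "z"]
        w = assign_weights(star_net, queries_q, genes, min_weight=0.05)
        assert w["z"] > 0.0
        assert sum(w.weights.values()) == pytest.approx(5.0, rel=1e-9)

    def test_sensitivity_flag_pins_queries(self, star_net, queries_q):
        w = assign_weights(
            star_net, queries_q, ["q", "a", "b", "c"], sensitivity=True
        )
        assert w["q"] == 1.0
        assert sum(w.weights.values()) == pytest.approx(4.0)
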