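"""Ranked-node network construction and truncated-Normal NPT generation."""

import itertools

import numpy as np
import pytest

from conftest import TOY_WEIGHTS, tnormal_cell_quadrature, toy_spec
from pancbn.errors import (
    ConfigurationError,
    DegenerateNodeError,
    ParameterError,
    StructureError,
)
from pancbn.network import (
    CompiledNetwork,
    NetworkSpec,
    RankedVariable,
    TNormalParams,
    build_child_npt,
    build_network,
    build_output_npt,
    default_spec,
    discretize_truncated_normal,
    interval_edges,
    map_states_to_scale,
    weighted_mean,
)


class TestScaleMapping:
    @pytest.mark.parametrize(
        "states, expected",
        [
            (["No", "Yes"], [0.25, 0.75]),
            (["a", "b", "c"], [1 / 6, 1 / 2, 5 / 6]),
            (["0", "1", "2", "3", "4"], [0.1, 0.3, 0.5, 0.7, 0.9]),
        ],
    )
    def test_midpoints(self, states, expected):
        assert map_states_to_scale(states) == pytest.approx(expected)

    def test_degenerate(self):
        with pytest.raises(DegenerateNodeError):
            map_states_to_scale(["only"])


class TestWeightedMean:
    @pytest.mark.parametrize(
        "values, weights, expected",
        [
            ([0.75, 0.75], [1, 3], 0.75),
            ([0.25, 0.75], [1, 1], 0.5),
            ([0.25, 0.75], [1, 3], 0.625),
        ],
    )
    def test_values(self, values, weights, expected):
        assert weighted_mean(values, weights) == pytest.approx(expected)

    def test_zero_weights(self):
        with pytest.raises(ConfigurationError):
            weighted_mean([0.5], [0.0])


class TestDiscretization:
    def test_symmetry_about_mean(self):
        probs = discretize_truncated_normal(TNormalParams(0.5, 0.04), interval_edges(5))
        assert probs[0] == pytest.approx(probs[4], abs=1e-12)
        assert probs[1] == pytest.approx(probs[3], abs=1e-12)

    @pytest.mark.parametrize("mean,var,k", [(0.1, 0.3, 4), (0.9, 0.001, 5), (0.5, 2.0, 7)])
    def test_normalization(self, mean, var, k):
        probs = discretize_truncated_normal(TNormalParams(mean, var), interval_edges(k))
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(probs >= 0)

    def test_matches_quadrature(self):
        edges = interval_edges(5)
        probs = discretize_truncated_normal(TNormalParams(0.9, 0.001), edges)
        expected = tnormal_cell_quadrature(0.9, 0.001, edges[-2], edges[-1])
        assert probs[-1] == pytest.approx(expected, abs=1e-6)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            TNormalParams(0.5, 0.0)
        with pytest.raises(ParameterError):
            TNormalParams(1.5, 0.1)
        with pytest.raises(ParameterError):
            discretize_truncated_normal(TNormalParams(0.5, 0.1), [0.0, 0.5, 0.4, 1.0])


class TestChildNPT:
    def _parents(self):
        return [
            RankedVariable("p1", ("lo", "hi"), "pre_operative", "g", weight=0.6),
            RankedVariable("p2", ("lo", "hi"), "pre_operative", "g", weight=0.3),
        ]

    def test_columns_sum_to_one(self):
        factor = build_child_npt("child", 5, self._parents(), variance=0.1)
        sums = factor.table.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_stochastic_dominance_of_high_risk_column(self):
        factor = build_child_npt("child", 5, self._parents(), variance=0.1)
        low = factor.table[0, 0]
        high = factor.table[1, 1]
        # higher TNormal mean => cumulative mass grows strictly slower
        assert np.all(np.cumsum(high)[:-1] < np.cumsum(low)[:-1])

    def test_full_table_matches_quadrature(self):
        parents = self._parents()
        variance = 0.05 / 0.9
        factor = build_child_npt("child", 4, parents, variance=variance)
        edges = interval_edges(4)
        scales = [p.scale_values for p in parents]
        for i, j in itertools.product(range(2), range(2)):
            mean = (0.6 * scales[0][i] + 0.3 * scales[1][j]) / 0.9
            for b in range(4):
                expected = tnormal_cell_quadrature(mean, variance, edges[b], edges[b + 1])
                assert factor.table[i, j, b] == pytest.approx(expected, abs=1e-6)

    def test_missing_weight_rejected(self):
        parents = [RankedVariable("p", ("a", "b"), "pre_operative", "g")]
        with pytest.raises(ConfigurationError):
            build_child_npt("child", 3, parents, variance=0.1)


class TestOutputNPT:
    GROUPS = [("g1", ("a", "b", "c")), ("g2", ("a", "b", "c")), ("g3", ("a", "b", "c"))]

    def test_rows_sum_to_one(self):
        factor = build_output_npt("out", self.GROUPS, [1.0, 2.0, 0.5], variance=0.05)
        assert np.allclose(factor.table.sum(axis=-1), 1.0, atol=1e-12)

    def test_symmetric_midpoint_is_half(self):
        factor = build_output_npt("out", self.GROUPS, [1.0, 1.0, 1.0], variance=0.05)
        # all groups at mid state: mean 0.5, symmetric about the 0.5 threshold
        assert factor.table[1, 1, 1, 1] == pytest.approx(0.5, abs=1e-9)

    def test_matches_upper_tail_quadrature(self):
        weights = [1.0, 2.0, 0.5]
        variance = 0.08
        factor = build_output_npt("out", self.GROUPS, weights, variance=variance)
        scales = map_states_to_scale(("a", "b", "c"))
        config = (2, 0, 1)
        mean = float(np.dot(weights, [scales[i] for i in config]) / sum(weights))
        expected = tnormal_cell_quadrature(mean, variance, 0.5, 1.0)
        assert factor.table[config + (1,)] == pytest.approx(expected, abs=1e-6)


class TestBuildNetwork:
    def test_pre_operative_excludes_pathology(self, default_networks_cached):
        pre, post = default_networks_cached
        assert "R0 Resection" not in pre.nodes
        assert "Lymph Node Positive" not in pre.nodes
        assert "Pathology" not in pre.nodes
        assert "R0 Resection" in post.nodes
        assert pre.phase == "pre_operative"

    def test_factor_count_equals_node_count(self, toy_networks):
        for net in toy_networks:
            assert len(net.factors) == len(net.nodes)

    def test_toy_joint_sums_to_one(self, toy_networks):
        from pancbn.inference import enumerate_joint

        for net in toy_networks:
            joint = enumerate_joint(net)
            assert joint.table.sum() == pytest.approx(1.0, abs=1e-9)

    def test_default_network_npt_columns_normalized(self, default_networks_cached):
        for net in default_networks_cached:
            for node, factor in net.factors.items():
                assert np.allclose(factor.table.sum(axis=-1), 1.0, atol=1e-9), node

    def test_unknown_variable_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            build_network(toy_spec(), {"inflammation": 0.5}, "post_operative")

    def test_duplicate_names_rejected(self):
        v = RankedVariable("x", ("a", "b"), "pre_operative", "g")
        with pytest.raises(StructureError):
            NetworkSpec(variables=(v, v))

    def test_group_name_clash_rejected(self):
        with pytest.raises(StructureError):
            NetworkSpec(
                variables=(
                    RankedVariable("g", ("a", "b"), "pre_operative", "g"),
                )
            )

    def test_refinement_changes_output_little(self):
        """Doubling category-node granularity moves P(poor) by < 0.01."""
        from pancbn.evidence import synthesize, weight_map
        from pancbn.inference import posterior_marginal
        from pancbn.synthetic import reference_study_table
        from dataclasses import replace

        weights = weight_map(synthesize(reference_study_table()))
        spec5 = default_spec()
        spec10 = replace(spec5, n_group_states=10)
        net5 = build_network(spec5, weights, "pre_operative")
        net10 = build_network(spec10, weights, "pre_operative")
        evidence = {"Albumin": "Low", "T Stage": "T3", "Age": "<70"}
        for ev in ({}, evidence):
            p5 = posterior_marginal(net5, net5.output_name, ev)[1]
            p10 = posterior_marginal(net10, net10.output_name, ev)[1]
            assert abs(p5 - p10) < 0.01


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, toy_networks):
        pre, post = toy_networks
        path = tmp_path / "net.json"
        post.save(path)
        loaded = CompiledNetwork.load(path)
        assert loaded.nodes == dict(post.nodes)
        assert loaded.parents == dict(post.parents)
        for node in post.nodes:
            assert np.array_equal(loaded.factors[node].table, post.factors[node].table)
        assert loaded.output_name == post.output_name
        assert loaded.spec is not None

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = default_spec()
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert NetworkSpec.from_yaml(path) == spec

    def test_default_spec_has_25_variables(self):
        spec = default_spec()
        assert len(spec.variables) == 25
        assert len(spec.phase_variables("pre_operative")) == 16
        assert len(spec.group_names) == 7
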