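"""Preprocessing chain: probe aggregation, normalization, rescaling, node values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathsig.errors import DegenerateMatrixError, DegenerateScaleWarning, EmptyMappingError
from pathsig.preprocessing import (
    ExpressionPreprocessor,
    aggregate_probes,
    compute_node_values,
    log_truncate_quantile_normalize,
    rescale_unit_interval,
)

from conftest import build_graph


def frame(values, index=None, columns=None):
    values = np.asarray(values, dtype=float)
    index = index or [f"g{i}" for i in range(values.shape[0])]
    columns = columns or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=index, columns=columns)


class TestAggregateProbes:
    def test_percentile90_of_probe_block(self):
        probes = frame([[1.0], [2.0], [10.0]], index=["p1", "p2", "p3"])
        mapping = {"p1": ["gA"], "p2": ["gA"], "p3": ["gA"]}
        out = aggregate_probes(probes, mapping)
        # independent order-statistic computation, linear interpolation
        expected = np.percentile([1.0, 2.0, 10.0], 90, method="linear")
        assert out.loc["gA", "s0"] == pytest.approx(expected)

    def test_single_probe_passthrough(self):
        probes = frame([[3.5, 4.5]], index=["p1"])
        out = aggregate_probes(probes, {"p1": ["gA"]})
        assert out.loc["gA"].tolist() == [3.5, 4.5]

    def test_multigene_probe_dropped_when_gene_has_unique_probes(self):
        probes = frame([[100.0], [1.0], [2.0]], index=["pshared", "pa", "pb"])
        mapping = {"pshared": ["gA", "gB"], "pa": ["gA"], "pb": ["gB"]}
        out = aggregate_probes(probes, mapping)
        assert out.loc["gA", "s0"] == 1.0
        assert out.loc["gB", "s0"] == 2.0

    def test_multigene_probes_used_as_median_when_sole_probes(self):
        probes = frame([[1.0], [5.0], [9.0]], index=["p1", "p2", "p3"])
        mapping = {"p1": ["gA", "gB"], "p2": ["gA", "gB"], "p3": ["gA", "gB"]}
        out = aggregate_probes(probes, mapping)
        assert out.loc["gA", "s0"] == 5.0  # median of the shared probes

    def test_empty_mapping_rejected(self):
        probes = frame([[1.0]], index=["p1"])
        with pytest.raises(EmptyMappingError):
            aggregate_probes(probes, {"px": ["gA"]})


class TestQuantileNormalize:
    def test_rank_wise_means_hand_example(self):
        # post-log stand-in: identity log disabled via expm1 inverse trick
        raw = frame(np.expm1([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = log_truncate_quantile_normalize(raw, q_high=1.0, q_low=0.0)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)

    def test_columns_share_order_statistics(self, rng):
        # tie-free input (no truncation): sorted columns must agree exactly
        raw = frame(rng.lognormal(3, 1, size=(50, 6)))
        out = log_truncate_quantile_normalize(raw, q_high=1.0, q_low=0.0)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 6):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)

    def test_truncation_ties_get_mean_of_rank_positions(self):
        # two values clipped to the bottom bound share ranks {1,2} → mean ref
        raw = frame(np.expm1([[0.0, 1.0], [0.1, 2.0], [3.0, 3.0], [4.0, 4.0]]))
        out = log_truncate_quantile_normalize(raw, q_high=1.0, q_low=0.25)
        arr = np.log1p(raw.to_numpy())
        lo = np.quantile(arr, 0.25)
        clipped = np.clip(arr, lo, None)
        ref = np.sort(clipped, axis=0).mean(axis=1)
        assert out.iloc[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_truncation_clamps_at_global_quantiles(self, rng):
        raw = frame(rng.lognormal(3, 1, size=(200, 4)))
        arr = np.log1p(raw.to_numpy())
        lo, hi = np.quantile(arr, [0.01, 0.99])
        clipped = np.clip(arr, lo, hi)
        # feed the already-normalized clip through with q at the extremes
        out = log_truncate_quantile_normalize(raw)
        assert out.to_numpy().max() <= np.sort(clipped, axis=0).mean(axis=1).max() + 1e-12
        assert out.to_numpy().min() >= np.sort(clipped, axis=0).mean(axis=1).min() - 1e-12

    def test_all_zero_matrix_is_identity_with_warning(self):
        raw = frame(np.zeros((4, 3)))
        with pytest.warns(DegenerateScaleWarning):
            out = log_truncate_quantile_normalize(raw)
        assert (out.to_numpy() == 0).all()

    def test_single_constant_column_rejected(self):
        raw = frame([[1.0, 5.0], [1.0, 6.0], [1.0, 7.0]])
        with pytest.raises(DegenerateMatrixError):
            log_truncate_quantile_normalize(raw, q_high=1.0, q_low=0.0)


class TestRescale:
    def test_affine_map(self):
        out = rescale_unit_interval(frame([[0.0], [5.0], [10.0]]))
        assert out.to_numpy().ravel().tolist() == [0.0, 0.5, 1.0]

    def test_interior_point(self):
        out = rescale_unit_interval(frame([[2.0], [3.0], [6.0]]))
        assert out.iloc[1, 0] == pytest.approx(0.25)

    def test_constant_maps_to_half_with_warning(self):
        with pytest.warns(DegenerateScaleWarning):
            out = rescale_unit_interval(frame([[2.0, 2.0]]))
        assert (out.to_numpy() == 0.5).all()

    def test_per_gene_mode(self):
        out = rescale_unit_interval(frame([[0.0, 10.0], [5.0, 15.0]]), mode="per_gene")
        np.testing.assert_allclose(out.to_numpy(), [[0, 1], [0, 1]])

    def test_idempotent_in_scale(self, rng):
        once = rescale_unit_interval(frame(rng.random((10, 4))))
        twice = rescale_unit_interval(once)
        pd.testing.assert_frame_equal(once, twice)


class TestNodeValues:
    def test_single_gene_node_unchanged(self):
        g = build_graph([("A", "B")])
        X = frame([[0.2, 0.4], [0.6, 0.8]], index=["g_A", "g_B"])
        nv = compute_node_values(X, g)
        assert nv.loc["A"].tolist() == [0.2, 0.4]

    def test_mean_aggregator(self):
        g = build_graph([("A", "B")], genes={"A": ["x", "y"]})
        X = frame([[0.2], [0.8], [0.5]], index=["x", "y", "g_B"])
        nv = compute_node_values(X, g, aggregator="mean")
        assert nv.loc["A", "s0"] == pytest.approx(0.5)

    def test_missing_gene_node_defaults(self):
        g = build_graph([("A", "B")])
        X = frame([[0.2]], index=["g_A"])
        nv = compute_node_values(X, g, missing_default=0.5)
        assert nv.loc["B", "s0"] == 0.5


class TestExpressionPreprocessor:
    def test_full_chain_lands_in_unit_interval(self, rng):
        X = frame(rng.lognormal(4, 1, size=(60, 8)))
        out = ExpressionPreprocessor().fit_transform(X)
        assert out.to_numpy().min() >= 0 and out.to_numpy().max() <= 1
        assert out.to_numpy().min() == 0 and out.to_numpy().max() == 1

    def test_transform_on_fitted_matrix_matches_fit_transform(self, rng):
        X = frame(rng.lognormal(4, 1, size=(30, 5)))
        pp = ExpressionPreprocessor().fit(X)
        pd.testing.assert_frame_equal(pp.transform(X), pp.fit_transform(X))

    def test_frozen_reference_keeps_untouched_rows_identical(self, rng):
        X = frame(rng.lognormal(4, 1, size=(30, 5)))
        pp = ExpressionPreprocessor().fit(X)
        Y = X.copy()
        Y.iloc[0] *= 0.01
        a, b = pp.transform(X), pp.transform(Y)
        pd.testing.assert_frame_equal(a.iloc[1:], b.iloc[1:])
        assert (b.iloc[0] <= a.iloc[0]).all()

    def test_column_permutation_equivariance(self, rng):
        X = frame(rng.lognormal(4, 1, size=(30, 6)))
        pp = ExpressionPreprocessor().fit(X)
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        pd.testing.assert_frame_equal(pp.transform(X[perm]), pp.transform(X)[perm])

    def test_rejects_negative_and_mismatched_index(self, rng):
        X = frame(rng.lognormal(4, 1, size=(10, 3)))
        with pytest.raises(ValueError):
            ExpressionPreprocessor().fit(-X)
        pp = ExpressionPreprocessor().fit(X)
        with pytest.raises(ValueError):
            pp.transform(X.iloc[:5])

    def test_sklearn_params_roundtrip(self):
        pp = ExpressionPreprocessor(q_low=0.02, rescale_mode="per_gene")
        assert ExpressionPreprocessor(**pp.get_params()).get_params() == pp.get_params()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_chain_output_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        X = frame(rng.lognormal(3, 1.5, size=(20, 4)))
        out = ExpressionPreprocessor().fit_transform(X)
        arr = out.to_numpy()
        assert np.isfinite(arr).all() and arr.min() >= 0 and arr.max() <= 1
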