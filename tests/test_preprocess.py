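"""Normalisation, DE filter, imputation and probe collapsing."""

import numpy as np
import pandas as pd
import pytest

from loopmed import (
    ExpressionMatrix,
    collapse_probes,
    differential_expression,
    generate_dataset,
    impute_timepoints,
    normalize,
)
from loopmed.preprocess import bh_adjust, signed_fold_change


def _matrix(values: np.ndarray, conditions=None, time_points=None):
    n = values.shape[1]
    conditions = conditions or ["injured"] * (n // 2) + ["sham"] * (n - n // 2)
    time_points = time_points or ["24h"] * n
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"time_point": time_points, "condition": conditions,
         "replicate": list(range(n))},
        index=pd.Index(ids, name="sample_id"),
    )
    df = pd.DataFrame(values, index=[f"e{i}" for i in range(values.shape[0])],
                      columns=ids)
    return ExpressionMatrix(df, meta)


class TestNormalize:
    def test_constant_column_scales_to_one(self):
        # a column constant at 4 becomes all-1 after per-chip scaling; with
        # every column constant the row medians are 1 so output is all 1
        m = _matrix(np.full((3, 6), 4.0))
        out = normalize(m)
        assert np.allclose(out.values.to_numpy(), 1.0)

    def test_row_medians_are_one(self, rng):
        for _ in range(100):
            m = _matrix(rng.uniform(0.5, 50.0, size=(7, 9)))
            out = normalize(m)
            med = out.values.median(axis=1)
            assert np.allclose(med, 1.0, atol=1e-12)

    def test_renormalization_preserves_row_medians(self, rng):
        # the per-gene step guarantees unit row medians, and that property
        # is stable under re-normalization (the column step rescales within
        # rows but the subsequent median centring restores medians exactly)
        m = _matrix(rng.uniform(0.5, 50.0, size=(6, 8)))
        twice = normalize(normalize(m))
        assert np.allclose(twice.values.median(axis=1), 1.0, atol=1e-12)

    def test_error_names_bad_column(self):
        vals = np.ones((3, 4))
        vals[:, 2] = 0.0
        with pytest.raises(ValueError, match="s2"):
            normalize(_matrix(vals))


class TestDifferentialExpression:
    def test_identical_groups_fc_one_not_passing(self):
        base = np.tile([[5.0, 6.0, 7.0, 8.0]], (2, 1))
        m = _matrix(np.hstack([base, base]))
        records = differential_expression(m, "24h")
        for r in records:
            assert r.fc == pytest.approx(1.0)
            assert not r.passes

    def test_bh_step_up_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_bh_monotone_and_bounded(self, rng):
        raw = np.sort(rng.uniform(size=30))
        adj = bh_adjust(raw)
        assert np.all(np.diff(adj) >= -1e-15)
        assert np.all(adj >= raw) and np.all(adj <= 1.0)

    def test_signed_fold_change_symmetric(self):
        assert signed_fold_change(4.0) == 4.0
        assert signed_fold_change(0.25) == -4.0
        with pytest.raises(ValueError):
            signed_fold_change(0.0)

    def test_planted_fourfold_change_detected(self, rng):
        """fc = 4 at noise sd 0.2, n = 10/group passes in >= 95% of sims."""
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            inj = 8.0 * 4 + rng.normal(0, 0.2, size=(1, 10))
            sham = 8.0 + rng.normal(0, 0.2, size=(1, 10))
            m = _matrix(np.hstack([inj, sham]))
            hits += differential_expression(m, "24h")[0].passes
        assert hits / n_sim >= 0.95

    def test_null_entities_rarely_pass(self):
        """Entities with no true group difference pass the filter at well
        below the nominal 5%: the |fc| >= 2 gate compounds the p filter."""
        rng = np.random.default_rng(1)
        vals = 10.0 + rng.normal(0, 1.0, size=(400, 20))
        records = differential_expression(_matrix(vals), "24h")
        assert sum(r.passes for r in records) / len(records) < 0.05

    def test_planted_members_survive_de(self):
        """Generator fold changes pass the default filter with prob > 0.95."""
        ds = generate_dataset({"M_TM": 40}, n_samples=20, noise_sd=0.5, seed=17)
        records = differential_expression(ds.gene_expr, "24h")
        planted = {t.gene_id for t in ds.truth}
        passed = {r.entity_id for r in records if r.passes}
        assert len(planted & passed) / len(planted) > 0.95

    def test_too_few_replicates_raise(self):
        m = _matrix(np.ones((2, 3)), conditions=["injured", "injured", "sham"])
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(m, "24h")


class TestImpute:
    def test_line_through_two_points(self):
        m = _matrix(np.array([[1.0, 3.0]]), conditions=["injured"] * 2,
                    time_points=["0h", "24h"])
        out = impute_timepoints(m, {"0h": 0, "24h": 24}, {"12h": 12},
                                condition="injured")
        col = [c for c in out.values.columns if "12h" in c][0]
        assert out.values.loc["e0", col] == pytest.approx(2.0)

    def test_constant_series_stays_constant(self):
        m = _matrix(np.full((2, 3), 5.0), conditions=["injured"] * 3,
                    time_points=["0h", "24h", "7d"])
        out = impute_timepoints(m, {"0h": 0, "24h": 24, "7d": 168}, {"48h": 48},
                                condition="injured")
        col = [c for c in out.values.columns if "48h" in c][0]
        assert np.allclose(out.values[col], 5.0)

    def test_collinear_points_zero_residual(self):
        t = np.array([0.0, 10.0, 20.0])
        m = _matrix((2.0 + 0.3 * t)[None, :], conditions=["injured"] * 3,
                    time_points=["a", "b", "c"])
        out = impute_timepoints(m, {"a": 0, "b": 10, "c": 20}, {"d": 15},
                                condition="injured")
        col = [c for c in out.values.columns if "d" in c][0]
        assert out.values.loc["e0", col] == pytest.approx(2.0 + 0.3 * 15, abs=1e-10)

    def test_observed_columns_unchanged(self):
        vals = np.array([[1.0, 3.0]])
        m = _matrix(vals, conditions=["injured"] * 2, time_points=["0h", "24h"])
        out = impute_timepoints(m, {"0h": 0, "24h": 24}, {"12h": 12},
                                condition="injured")
        assert np.allclose(out.values[["s0", "s1"]].to_numpy(), vals)

    def test_single_time_point_raises(self):
        m = _matrix(np.ones((1, 2)), conditions=["injured"] * 2,
                    time_points=["0h", "0h"])
        with pytest.raises(ValueError):
            impute_timepoints(m, {"0h": 0}, {"12h": 12})


class TestCollapseProbes:
    def test_first_listed_probe_used(self, rng):
        vals = rng.uniform(1, 10, size=(100, 6))
        m = _matrix(vals)
        m.values.index = [f"p{i}" for i in range(100)]
        probe_order = {f"g{i}": [f"p{2*i}", f"p{2*i+1}"] for i in range(50)}
        out = collapse_probes(m, probe_order)
        for i in range(50):
            assert (out.values.loc[f"g{i}"] == m.values.loc[f"p{2*i}"]).all()

    def test_single_probe_genes_unchanged(self, small_matrix):
        out = collapse_probes(small_matrix, {})
        assert out.values.sort_index().equals(small_matrix.values.sort_index())

    def test_missing_probe_named_in_error(self, small_matrix):
        with pytest.raises(ValueError, match="p_missing"):
            collapse_probes(small_matrix, {"g1": ["p_missing"]})
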