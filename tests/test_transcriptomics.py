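import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pbsikit.synthetic import ExpressionSpec, generate_expression
from pbsikit.transcriptomics import (
    aggregate_region_expression,
    assign_samples_to_regions,
    associate_delta_expression,
    bh_fdr,
    srs_normalize,
)

from oracles import bh_stepup_oracle


class TestSrsNormalize:
    def test_formula_oracle(self):
        x = np.array([0.0, 1, 2, 3, 4])
        med, iqr = 2.0, 2.0
        s = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
        want = (s - s.min()) / (s.max() - s.min())
        assert np.allclose(srs_normalize(x), want)

    def test_median_maps_to_half_before_rescale(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, -4.0])
        med, iqr = np.median(x), stats.iqr(x)
        s = 1 / (1 + np.exp(-(x[np.argsort(np.abs(x - med))[0]] - med) / (iqr / 1.35)))
        assert s == pytest.approx(0.5)

    def test_monotone(self, rng):
        x = np.sort(rng.normal(size=20))
        out = srs_normalize(x)
        assert np.all(np.diff(out) > 0)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError, match="IQR"):
            srs_normalize([1.0, 1.0, 1.0, 1.0])


class TestAssignSamples:
    VOXELS = {
        "A": np.array([[0.0, 0, 0], [1.0, 0, 0]]),
        "B": np.array([[10.0, 0, 0]]),
        "C": np.array([[0.0, 10, 0]]),
    }

    def test_exact_hit(self):
        out = assign_samples_to_regions(np.array([[1.0, 0, 0]]), self.VOXELS)
        assert out == ["A"]

    def test_far_sample_unassigned(self):
        out = assign_samples_to_regions(np.array([[5.0, 5, 5]]), self.VOXELS)
        assert out == [None]

    def test_nearest_region_wins(self):
        # 2 mm from A's nearest voxel, 2.5 mm vs exhaustive check on toy set
        sample = np.array([[3.0, 0, 0]])
        out = assign_samples_to_regions(sample, self.VOXELS)
        dists = {lab: np.sqrt(((vox - sample[0]) ** 2).sum(1)).min()
                 for lab, vox in self.VOXELS.items()}
        assert out == [min(dists, key=dists.get)]
        assert out == ["A"]

    def test_boundary_inclusive(self):
        out = assign_samples_to_regions(np.array([[4.0, 0, 0]]), self.VOXELS,
                                        max_distance=3.0)
        assert out == ["A"]  # exactly 3 mm from (1,0,0)

    def test_tie_goes_to_earlier_label(self):
        voxels = {"A": np.array([[0.0, 0, 0]]), "B": np.array([[2.0, 0, 0]])}
        out = assign_samples_to_regions(np.array([[1.0, 0, 0]]), voxels)
        assert out == ["A"]

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_samples_to_regions(np.zeros((1, 3)), {"A": np.empty((0, 3))})

    def test_assigned_distance_within_limit(self, rng):
        voxels = {f"R{i}": rng.uniform(-20, 20, (5, 3)) for i in range(6)}
        samples = rng.uniform(-20, 20, (40, 3))
        out = assign_samples_to_regions(samples, voxels)
        for s, lab in zip(samples, out):
            if lab is not None:
                d = np.sqrt(((voxels[lab] - s) ** 2).sum(1)).min()
                assert d <= 3.0


class TestAggregate:
    def test_single_sample_per_region(self, rng):
        expr = rng.normal(size=(3, 4))
        df, dropped = aggregate_region_expression(expr, ["A", "B", "C"])
        assert np.allclose(df["A"], expr[0])
        assert dropped == []

    def test_mean_of_two(self):
        expr = np.array([[1.0], [3.0]])
        df, _ = aggregate_region_expression(expr, ["A", "A"])
        assert df["A"].iloc[0] == 2.0

    def test_groupby_oracle(self, rng):
        expr = rng.normal(size=(30, 5))
        labels = rng.choice(["A", "B", "C", None], size=30).tolist()
        df, dropped = aggregate_region_expression(expr, labels)
        for lab in df.columns:
            idx = [i for i, l in enumerate(labels) if l == lab]
            assert np.allclose(df[lab], expr[idx].mean(axis=0))
        assert len(dropped) == sum(1 for l in labels if l is None)


class TestBhFdr:
    def test_worked_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.03, 0.5])
        q, reject = bh_fdr(p)
        assert list(reject) == [True, True, True, True, False]

    def test_all_ones(self):
        q, reject = bh_fdr(np.ones(10))
        assert np.all(q == 1.0)
        assert not reject.any()

    def test_matches_stepup_oracle(self, rng):
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.uniform(0, 1, m)
            q, reject = bh_fdr(p)
            q_o, rej_o = bh_stepup_oracle(p)
            assert np.allclose(q, q_o, atol=1e-12)
            assert np.array_equal(reject, rej_o)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 500)
        q, reject = bh_fdr(p)
        rej_sm, q_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(q, q_sm)
        assert np.array_equal(reject, rej_sm)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_q_at_least_p_over_max_rank(self, p):
        q, _ = bh_fdr(np.array(p))
        assert np.all(q >= np.array(p) - 1e-12)  # q_i >= p_i always for BH
        assert np.all(q <= 1.0)


class TestAssociate:
    def _setup(self, rng, n_regions=60):
        delta = pd.Series(rng.normal(size=n_regions),
                          index=[f"r{i}" for i in range(n_regions)])
        return delta

    def test_monotone_transform_gene_significant(self, rng):
        delta = self._setup(rng)
        expr = pd.DataFrame(
            {c: [np.exp(delta[c])] for c in delta.index}, index=["g0"])
        expr = pd.concat([expr] + [
            pd.DataFrame({c: [rng.normal()] for c in delta.index},
                         index=[f"g{i}"]) for i in range(1, 30)])
        res = associate_delta_expression(delta, expr)
        row = res.table.set_index("gene_id").loc["g0"]
        assert row.rho == pytest.approx(1.0)
        assert row.significant

    def test_constant_delta_rejected(self, rng):
        delta = pd.Series(np.ones(30), index=[f"r{i}" for i in range(30)])
        expr = pd.DataFrame(rng.normal(size=(5, 30)), columns=delta.index)
        with pytest.raises(ValueError, match="constant"):
            associate_delta_expression(delta, expr)

    def test_label_mismatch_rejected(self, rng):
        delta = self._setup(rng, 30)
        expr = pd.DataFrame(rng.normal(size=(5, 30)),
                            columns=[f"zzz{i}" for i in range(30)])
        with pytest.raises(ValueError, match="common regions"):
            associate_delta_expression(delta, expr)

    def test_rank_invariance(self, rng):
        delta = self._setup(rng)
        expr = pd.DataFrame(rng.normal(size=(20, 60)), columns=delta.index)
        r1 = associate_delta_expression(delta, expr)
        r2 = associate_delta_expression(delta ** 3, np.exp(expr * 0.5))
        assert np.allclose(r1.table["rho"], r2.table["rho"], atol=1e-12)

    def test_planted_recovery(self, rng):
        delta = self._setup(rng, 180)
        expr, planted = generate_expression(
            ExpressionSpec(n_genes=500, n_planted=25, rho_target=0.6, seed=8),
            delta)
        res = associate_delta_expression(delta, expr)
        hits = set(res.significant_genes)
        sensitivity = len(hits & set(planted)) / len(planted)
        fdp = len(hits - set(planted)) / max(1, len(hits))
        assert sensitivity >= 0.9
        assert fdp <= 0.1

    def test_p_values_match_scipy(self, rng):
        delta = self._setup(rng, 40)
        expr = pd.DataFrame(rng.normal(size=(10, 40)), columns=delta.index)
        res = associate_delta_expression(delta, expr)
        for i in range(10):
            ref = stats.spearmanr(expr.iloc[i], delta)
            assert res.table["rho"].iloc[i] == pytest.approx(ref.statistic)
            assert res.table["p"].iloc[i] == pytest.approx(ref.pvalue, rel=1e-6)
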