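import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meanet.drugstats import (
    PCA5_PARAMETERS,
    anova_dunnett,
    build_param_table,
    manova_pairwise,
    paired_t,
    pca5,
)
from meanet.errors import InsufficientDataError, ValidationError
from meanet.netburst import METRIC_NAMES
from meanet.synth import gen_param_samples


def _table(seed=0, n=8, conditions=None, effects=None):
    conditions = conditions or {"DMSO": [0.2], "drug": [1.0, 10.0]}
    entries, _ = gen_param_samples(conditions, n_per_group=n, seed=seed,
                                   effects=effects)
    return build_param_table(entries, control="DMSO")


class TestBuildTable:
    def test_shape(self):
        t = _table()
        assert len(t) == 24
        assert all(p in t.columns for p in METRIC_NAMES)

    def test_duplicate_rows_rejected(self):
        entries = [("s1", "DMSO", 0.2, dict.fromkeys(METRIC_NAMES, 1.0))] * 2
        with pytest.raises(ValidationError):
            build_param_table(entries, control="DMSO")

    def test_missing_control_rejected(self):
        entries = [("s1", "drug", 1.0, dict.fromkeys(METRIC_NAMES, 1.0)),
                   ("s2", "drug", 1.0, dict.fromkeys(METRIC_NAMES, 1.0))]
        with pytest.raises(ValidationError):
            build_param_table(entries, control="DMSO")

    def test_nan_metrics_propagate(self):
        m = dict.fromkeys(METRIC_NAMES, 1.0)
        m["cv_imfi"] = float("nan")
        entries = [("s1", "DMSO", 0.2, m), ("s2", "drug", 1.0, m)]
        t = build_param_table(entries, control="DMSO")
        assert t["cv_imfi"].isna().all()


class TestAnovaDunnett:
    def test_identical_groups_degenerate(self):
        m = dict.fromkeys(METRIC_NAMES, 2.0)
        entries = [(f"c{i}", "DMSO", 0.2, m) for i in range(4)] + \
                  [(f"d{i}", "drug", 1.0, m) for i in range(4)]
        t = build_param_table(entries, control="DMSO")
        row = anova_dunnett(t, "n_nb", "DMSO")
        assert row["F"].iloc[0] == 0.0
        assert (row["p_adj"] == 1.0).all()

    def test_shifted_group_detected_in_power_simulation(self):
        """Control N(0,1) vs one group shifted by 3 SD: adjusted p < 0.01 in
        >= 95% of seeded replicates."""
        hits = 0
        reps = 200
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            groups = [rng.normal(3.0, 1.0, 8), rng.normal(0.0, 1.0, 8),
                      rng.normal(0.0, 1.0, 8)]
            ctrl = rng.normal(0.0, 1.0, 8)
            res = sps.dunnett(*groups, control=ctrl, rng=r)
            if res.pvalue[0] < 0.01:
                hits += 1
        assert hits / reps >= 0.95

    def test_adjusted_p_not_below_unadjusted(self):
        """The many-to-one adjustment can only raise each comparison's p
        relative to the unadjusted t-test on the same pooled error term."""
        t = _table(seed=3, effects={"drug": {"n_nb": 1.6}})
        row = anova_dunnett(t, "n_nb", "DMSO")
        ctrl = t.loc[t.condition == "DMSO", "n_nb"].to_numpy()
        groups = [t.loc[(t.condition == r.condition)
                        & (t.concentration == r.concentration), "n_nb"].to_numpy()
                  for _, r in row.iterrows()]
        all_groups = [ctrl] + groups
        dof = sum(g.size for g in all_groups) - len(all_groups)
        s2 = sum(np.sum((g - g.mean()) ** 2) for g in all_groups) / dof
        for g, (_, r) in zip(groups, row.iterrows()):
            t_stat = (g.mean() - ctrl.mean()) / np.sqrt(
                s2 * (1 / g.size + 1 / ctrl.size))
            p_raw = 2 * sps.t.sf(abs(t_stat), dof)
            assert r.p_adj >= p_raw - 1e-12

    def test_small_group_rejected(self):
        m = dict.fromkeys(METRIC_NAMES, 1.0)
        entries = [("c1", "DMSO", 0.2, m), ("c2", "DMSO", 0.2, m),
                   ("d1", "drug", 1.0, m)]
        t = build_param_table(entries, control="DMSO")
        with pytest.raises(InsufficientDataError):
            anova_dunnett(t, "n_nb", "DMSO")


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=30)
        m = {p: None for p in PCA5_PARAMETERS}
        entries = []
        for i, ui in enumerate(u):
            vals = dict.fromkeys(METRIC_NAMES, 0.0)
            for j, p in enumerate(PCA5_PARAMETERS):
                vals[p] = (j + 1.0) * ui  # all columns collinear
            entries.append((f"s{i}", "DMSO" if i < 15 else "drug", 1.0, vals))
        t = build_param_table(entries, control="DMSO")
        res = pca5(t)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        res = pca5(_table(seed=5))
        g = res.loadings @ res.loadings.T
        np.testing.assert_allclose(g, np.eye(g.shape[0]), atol=1e-10)

    def test_scores_match_svd_oracle(self):
        t = _table(seed=7)
        res = pca5(t)
        x = t[list(PCA5_PARAMETERS)].to_numpy(float)
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        oracle = u[:, :2] * s[:2]
        for i in range(2):
            j = int(np.argmax(np.abs(vt[i])))
            if vt[i, j] < 0:
                oracle[:, i] = -oracle[:, i]
        np.testing.assert_allclose(res.scores, oracle, atol=1e-10)

    def test_invariant_to_column_rescaling(self):
        t = _table(seed=9)
        res1 = pca5(t)
        t2 = t.copy()
        t2["total_spikes"] = t2["total_spikes"] * 1e-4 + 7.0
        res2 = pca5(t2)
        np.testing.assert_allclose(res1.scores, res2.scores, atol=1e-8)


class TestManova:
    def test_symmetry_and_separation(self):
        rng = np.random.default_rng(2)
        scores = np.vstack([rng.normal(0, 1, (30, 2)),
                            rng.normal(5, 1, (30, 2))])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        p = manova_pairwise(scores, labels)
        assert p.loc["a", "b"] == p.loc["b", "a"]
        assert p.loc["a", "b"] < 0.01

    def test_null_rarely_significant(self):
        hits = 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(5000 + r)
            scores = rng.normal(size=(100, 2))
            labels = np.array(["a"] * 50 + ["b"] * 50)
            if manova_pairwise(scores, labels).loc["a", "b"] > 0.05:
                hits += 1
        assert hits >= 90

    def test_small_group_rejected(self):
        scores = np.zeros((4, 2))
        labels = np.array(["a", "a", "b", "b"])
        with pytest.raises(InsufficientDataError):
            manova_pairwise(scores, labels)


class TestPairedT:
    def test_identical_pairs(self):
        t, p, md = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, md) == (0.0, 1.0, 0.0)

    def test_hand_computed_value(self):
        pre = np.array([10.0, 12.0, 9.0, 11.0, 10.5])
        post = np.array([12.0, 13.5, 9.5, 12.0, 12.5])
        d = post - pre
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=4)
        t, p, md = paired_t(pre, post)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)
        assert md == pytest.approx(d.mean())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_t([1.0, 2.0], [1.0])
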