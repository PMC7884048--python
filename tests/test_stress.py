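"""Transcription-stress detection: DEG calling, length bias, lesion-rate
recovery, PCA — checked against hand arithmetic and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import txstress as tx
from txstress.stress import LengthBiasResult

from conftest import null_expression


def _hand_welch_bh(expr, design, prior_df=0.0):
    """Spreadsheet-style oracle: per-gene Welch t + explicit BH, loops only."""
    a_cols = design.loc[design.group == "A", "sample_id"].tolist()
    b_cols = design.loc[design.group == "B", "sample_id"].tolist()
    rows = []
    vs, ds = [], []
    for g in expr.index:
        la = np.log2(expr.loc[g, a_cols].to_numpy(dtype=float))
        lb = np.log2(expr.loc[g, b_cols].to_numpy(dtype=float))
        va = la.var(ddof=1) / la.size
        vb = lb.var(ddof=1) / lb.size
        v = va + vb
        d = v**2 / (va**2 / (la.size - 1) + vb**2 / (lb.size - 1))
        vs.append(v)
        ds.append(d)
        rows.append(lb.mean() - la.mean())
    v0 = float(np.mean(vs))
    ps = []
    for fc, v, d in zip(rows, vs, ds):
        v_mod = (prior_df * v0 + d * v) / (prior_df + d)
        t = fc / np.sqrt(v_mod)
        ps.append(2 * stats.t.sf(abs(t), d + prior_df))
    # explicit BH
    order = np.argsort(ps)
    n = len(ps)
    q = np.empty(n)
    prev = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = n - rank_from_last
        prev = min(prev, ps[idx] * n / rank)
        q[idx] = prev
    return np.array(rows), np.array(ps), q


class TestCallDegs:
    def test_identical_columns_give_zero_degs(self):
        rng = np.random.default_rng(0)
        half = pd.DataFrame(
            rng.lognormal(5, 1, size=(50, 3)),
            index=[f"g{i}" for i in range(50)],
            columns=["s1", "s2", "s3"],
        )
        expr = pd.concat([half, half.set_axis(["s4", "s5", "s6"], axis=1)], axis=1)
        expr.index.name = "gene_id"
        design = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(1, 7)],
             "group": ["A"] * 3 + ["B"] * 3, "sex": "F"}
        )
        out = tx.call_degs(expr, design, "A", "B")
        assert np.allclose(out["log2fc"], 0.0)
        assert not out["is_deg"].any()

    def test_matches_hand_welch_and_bh_at_zero_prior(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.lognormal(5, 0.5, size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=["a1", "a2", "b1", "b2"],
        )
        design = pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "b2"],
             "group": ["A", "A", "B", "B"], "sex": "F"}
        )
        out = tx.call_degs(expr, design, "A", "B", moderation_prior_df=0.0)
        fc, p, q = _hand_welch_bh(expr, design, prior_df=0.0)
        np.testing.assert_allclose(out["log2fc"], fc, rtol=1e-10)
        np.testing.assert_allclose(out["p_value"], p, rtol=1e-10)
        np.testing.assert_allclose(out["q_value"], q, rtol=1e-10)

    def test_matches_hand_moderated_t_at_default_prior(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.lognormal(6, 0.4, size=(8, 6)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(6)],
        )
        design = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(6)],
             "group": ["A"] * 3 + ["B"] * 3, "sex": "F"}
        )
        out = tx.call_degs(expr, design, "A", "B", moderation_prior_df=4.0)
        _, p, q = _hand_welch_bh(expr, design, prior_df=4.0)
        np.testing.assert_allclose(out["p_value"], p, rtol=1e-10)
        np.testing.assert_allclose(out["q_value"], q, rtol=1e-10)

    def test_bh_monotonicity_invariant(self):
        _, expr, design = null_expression(400, 3, seed=13)
        out = tx.call_degs(expr, design, "g1", "g2").sort_values("p_value")
        q = out["q_value"].to_numpy()
        p = out["p_value"].to_numpy()
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0 + 1e-12)

    def test_fdr_controlled_under_null(self):
        """Mean fraction of false DEG calls under the null stays below nominal."""
        fps = []
        for rep in range(30):
            _, expr, design = null_expression(1000, 5, seed=100 + rep)
            out = tx.call_degs(expr, design, "g1", "g2")
            fps.append(out["is_deg"].mean())
        assert np.mean(fps) <= 0.05

    def test_errors(self):
        _, expr, design = null_expression(30, 2, seed=3)
        with pytest.raises(ValueError, match="group"):
            tx.call_degs(expr, design, "g1", "nope")
        with pytest.raises(ValueError, match="positive"):
            tx.call_degs(expr - expr.to_numpy().max(), design, "g1", "g2")


class TestFilterAmbiguous:
    def test_single_mapped_pass_through(self):
        ann = {"a": {"X"}, "b": {"Y"}}
        assert tx.filter_ambiguous(["a", "b"], ann) == ["a", "b"]

    def test_multi_mapped_removed_order_preserved(self):
        ann = {"a": {"X"}, "b": {"X", "Y"}, "c": {"Z"}}
        assert tx.filter_ambiguous(["a", "b", "c"], ann) == ["a", "c"]

    def test_missing_id_named_in_error(self):
        with pytest.raises(KeyError, match="zz"):
            tx.filter_ambiguous(["zz"], {"a": {"X"}})


def _degs_frame(up_ids, down_ids):
    ids = list(up_ids) + list(down_ids)
    return pd.DataFrame(
        {"direction": ["up"] * len(up_ids) + ["down"] * len(down_ids)},
        index=pd.Index(ids, name="gene_id"),
    )


class TestLengthBias:
    def test_exact_wmw_small_sample(self):
        """3-vs-3 fully separated classes: U = 0, exact two-sided p = 0.1.

        Oracle: of the C(6,3)=20 equally likely rank arrangements exactly one
        puts all 'up' ranks below all 'down' ranks, so P(U<=0)=1/20 per side.
        """
        cat = tx.GeneCatalog(
            np.array([f"u{i}" for i in range(3)] + [f"d{i}" for i in range(3)], dtype=object),
            np.array([1000, 2000, 3000, 10_000, 20_000, 30_000]),
        )
        res = tx.length_bias(_degs_frame(["u0", "u1", "u2"], ["d0", "d1", "d2"]), cat)
        assert res.method == "exact"
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.median_up_bp == 2000 and res.median_down_bp == 20_000

    def test_identical_multisets_give_p_one(self):
        cat = tx.GeneCatalog(
            np.array(["u0", "u1", "u2", "d0", "d1", "d2"], dtype=object),
            np.array([1000, 2000, 3000, 1000, 2000, 3000]),
        )
        res = tx.length_bias(_degs_frame(["u0", "u1", "u2"], ["d0", "d1", "d2"]), cat)
        assert res.p_value == pytest.approx(1.0)
        assert res.median_up_bp == res.median_down_bp

    def test_kde_mass_conservation(self, small_catalog):
        ids = small_catalog.gene_ids
        res = tx.length_bias(_degs_frame(ids[:200], ids[200:500]), small_catalog)
        up_mass = np.trapezoid(res.density_up, res.grid_log10)
        down_mass = np.trapezoid(res.density_down, res.grid_log10)
        assert up_mass == pytest.approx(1.0, abs=1e-6)
        assert down_mass == pytest.approx(1.0, abs=1e-6)

    def test_asymptotic_close_to_exact_at_moderate_n(self):
        """Normal approximation within 0.02 of the exact p for 5<=n<=25."""
        rng = np.random.default_rng(42)
        for n in (5, 12, 26):
            up = rng.lognormal(9, 1, size=n)
            down = rng.lognormal(9.5, 1, size=n)
            exact = stats.mannwhitneyu(up, down, alternative="two-sided", method="exact")
            approx = stats.mannwhitneyu(
                up, down, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert abs(exact.pvalue - approx.pvalue) < 0.02

    def test_empty_direction_class_raises(self, small_catalog):
        with pytest.raises(ValueError, match="no downregulated"):
            tx.length_bias(_degs_frame(small_catalog.gene_ids[:3], []), small_catalog)

    def test_increasing_lesion_rate_widens_length_gap(self):
        """Median(down) - median(up) grows with the lesion-rate difference."""
        gaps = []
        for dlam in (0.001, 0.004, 0.008):
            reps = []
            for rep in range(15):
                cat = tx.simulate_gene_catalog(1500, seed=500 + rep)
                groups = [
                    ("wt", tx.LesionModelParams(0.0, prog_de_fraction=0.05,
                                                n_samples_per_group=4, seed=rep)),
                    ("mut", tx.LesionModelParams(dlam, prog_de_fraction=0.05,
                                                 n_samples_per_group=4, seed=rep)),
                ]
                expr, design, _ = tx.simulate_expression(cat, groups)
                table = tx.call_degs(expr, design, "wt", "mut")
                res = tx.length_bias(table, cat)
                reps.append(res.median_down_bp - res.median_up_bp)
            gaps.append(np.mean(reps))
        assert gaps[0] < gaps[1] < gaps[2]


class TestEstimateLesionRate:
    def test_null_within_two_se(self):
        cat, expr, design = null_expression(2000, 5, seed=21)
        est = tx.estimate_lesion_rate(expr, design, "g1", "g2", cat)
        assert abs(est.delta_lambda_per_kb) < 2 * est.se

    def test_noiseless_limit_is_exact(self):
        """With near-zero noise the regression recovers delta-lambda exactly."""
        cat = tx.simulate_gene_catalog(200, seed=22)
        groups = [
            ("a", tx.LesionModelParams(0.0, noise_sd_log2=1e-9, n_samples_per_group=2, seed=1)),
            ("b", tx.LesionModelParams(0.003, noise_sd_log2=1e-9, n_samples_per_group=2, seed=1)),
        ]
        expr, design, _ = tx.simulate_expression(cat, groups)
        est = tx.estimate_lesion_rate(expr, design, "a", "b", cat)
        assert est.delta_lambda_per_kb == pytest.approx(0.003, rel=1e-5)

    def test_refuses_tiny_catalogs(self):
        cat, expr, design = null_expression(30, 3, seed=23)
        small = tx.GeneCatalog(cat.gene_ids[:5], cat.length_bp[:5])
        with pytest.raises(ValueError, match="10 genes"):
            tx.estimate_lesion_rate(expr.iloc[:5], design, "g1", "g2", small)


class TestPCAVariance:
    def test_rank_one_matrix(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0])
        expr = pd.DataFrame(2.0 ** np.outer(a, b), columns=["s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="rank"):
            res = tx.pca_variance(expr, k=2)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.lognormal(4, 0.8, size=(50, 10)),
            columns=[f"s{i}" for i in range(10)],
        )
        res = tx.pca_variance(expr, k=5)
        x = np.log2(expr.to_numpy()).T
        x = x - x.mean(axis=0)
        evals = np.linalg.eigvalsh(x @ x.T)[::-1]
        frac = evals / evals.sum()
        np.testing.assert_allclose(res.variance_fraction, frac[:5], atol=1e-8)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_identical_samples_rejected(self):
        col = np.random.default_rng(4).lognormal(5, 1, size=20)
        expr = pd.DataFrame({"s1": col, "s2": col})
        with pytest.raises(ValueError, match="zero"):
            tx.pca_variance(expr)
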