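"""eQTL tissue-sharing decomposition, enrichment, and dilution power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from genepip import eqtl_share as eqs
from genepip import simulate as sim


def records(spec):
    """spec: list of (category, n_total, n_shared)."""
    rows = []
    for cat, n, k in spec:
        for i in range(n):
            rows.append({"variant_id": f"{cat}{i}", "gene_id": "g", "pip": 0.9,
                         "category": cat, "n_tissues_active": 10,
                         "shared_second": i < k})
    return pd.DataFrame(rows)


class TestDecomposition:
    def test_two_category_hand_example(self):
        # w = (0.7, 0.3), p_c = (0.9, 0.2) -> p = 0.69
        df = records([("a", 70, 63), ("b", 30, 6)])
        d = eqs.decompose_sharing(df)
        assert d.w == {"a": pytest.approx(0.7), "b": pytest.approx(0.3)}
        assert d.p_c["a"] == pytest.approx(0.9)
        assert d.p_c["b"] == pytest.approx(0.2)
        assert d.p == pytest.approx(0.69)

    def test_single_category_collapses(self):
        d = eqs.decompose_sharing(records([("only", 20, 11)]))
        assert d.p == d.p_c["only"]

    def test_matches_brute_force_counts(self, rng):
        rows = []
        for i in range(20):
            rows.append({"variant_id": f"v{i}", "gene_id": "g", "pip": 0.95,
                         "category": str(rng.choice(["x", "y", "z"])),
                         "n_tissues_active": 5,
                         "shared_second": bool(rng.random() < 0.5)})
        df = pd.DataFrame(rows)
        d = eqs.decompose_sharing(df)
        assert d.p == pytest.approx(df.shared_second.mean(), abs=1e-15)
        for c in d.w:
            sub = df[df.category == c]
            assert d.w[c] == pytest.approx(len(sub) / 20)
            assert d.p_c[c] == pytest.approx(sub.shared_second.mean())

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from("abcd"), st.integers(1, 15), st.integers(0, 15)),
        min_size=1, max_size=6,
    ))
    def test_identity_holds_on_arbitrary_tables(self, spec):
        spec = [(c, n, min(k, n)) for c, n, k in spec]
        d = eqs.decompose_sharing(records(spec))
        assert d.p == pytest.approx(sum(d.p_c[c] * d.w[c] for c in d.w), abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            eqs.decompose_sharing(pd.DataFrame(columns=["category", "shared_second"]))

    def test_pip_filter(self):
        df = pd.DataFrame({"pip": [0.79, 0.8, 0.95], "category": "a", "shared_second": True})
        assert len(eqs.filter_eqtls(df)) == 2


class TestSummary:
    def test_median_of_three(self):
        df = records([("a", 3, 0)])
        df["n_tissues_active"] = [5, 31, 43]
        out = eqs.sharing_summary(df)
        assert out.iloc[0]["median"] == 31

    def test_bimodal_matches_direct_computation(self, rng):
        df = records([("lo", 30, 0), ("hi", 30, 0)])
        df.loc[df.category == "lo", "n_tissues_active"] = rng.poisson(4, 30) + 1
        df.loc[df.category == "hi", "n_tissues_active"] = rng.poisson(40, 30) + 1
        out = eqs.sharing_summary(df).set_index("category")
        for c in ("lo", "hi"):
            v = df[df.category == c].n_tissues_active
            assert out.loc[c, "median"] == v.median()
            assert out.loc[c, "q25"] == v.quantile(0.25)


class TestEnrichment:
    def test_fold_hand_example(self):
        eqtls = records([("cm", 26, 0), ("other", 74, 0)])
        controls = pd.DataFrame({"category": ["cm"] * 1 + ["other"] * 99})
        out = eqs.category_enrichment(eqtls, controls).set_index("category")
        assert out.loc["cm", "fold"] == pytest.approx(26.0)

    def test_identical_distributions_fold_one(self):
        eqtls = records([("a", 30, 0), ("b", 70, 0)])
        controls = pd.DataFrame({"category": ["a"] * 30 + ["b"] * 70})
        out = eqs.category_enrichment(eqtls, controls)
        np.testing.assert_allclose(out.fold, 1.0)

    def test_invariant_to_duplicating_controls(self):
        eqtls = records([("a", 10, 0), ("b", 30, 0)])
        controls = pd.DataFrame({"category": ["a"] * 25 + ["b"] * 75})
        once = eqs.category_enrichment(eqtls, controls)
        twice = eqs.category_enrichment(eqtls, pd.concat([controls, controls]))
        np.testing.assert_allclose(once.fold, twice.fold)

    def test_zero_control_category_flagged_inf(self):
        eqtls = records([("rare", 5, 0), ("common", 5, 0)])
        controls = pd.DataFrame({"category": ["common"] * 50})
        out = eqs.category_enrichment(eqtls, controls).set_index("category")
        assert np.isinf(out.loc["rare", "fold"]) and out.loc["rare", "control_zero"]

    def test_recovers_simulated_folds(self):
        rng = np.random.default_rng(5)
        w = {"a": 0.26, "b": 0.18, "c": 0.06, "other": 0.50}
        folds = {"a": 26.0, "b": 9.0, "c": 2.0}
        ctrl_prop = {c: w[c] / folds.get(c, 1.0) for c in w}
        ctrl_prop["other"] = 1.0 - sum(v for c, v in ctrl_prop.items() if c != "other")
        eqtls = sim.simulate_eqtl_records(4000, w, {c: 0.5 for c in w}, rng)
        controls = sim.simulate_matched_controls(8000, ctrl_prop, rng)
        out = eqs.category_enrichment(eqtls, controls).set_index("category")
        for c, f in folds.items():
            assert out.loc[c, "fold"] == pytest.approx(f, rel=0.35)  # Poisson error


class TestPower:
    def test_full_fraction_ratio_is_exactly_one(self):
        out = eqs.power_ratio_simulation(1.0, effect_grid=(0.1, 0.2), n=100, reps=50, seed=1)
        assert (out.ratio == 1.0).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            eqs.power_ratio_simulation(0.0)
        with pytest.raises(ValueError):
            eqs.power_ratio_simulation(1.2)

    def test_ratio_below_one_for_partial_fraction(self):
        out = eqs.power_ratio_simulation(0.3, effect_grid=(0.2,), n=400, alpha=1e-3,
                                         reps=800, seed=2)
        assert (out.ratio <= 1.0 + 3 * 0.02).all()

    def test_analytic_power_matches_scipy(self):
        # two-sided z-test power cross-check
        for ncp, alpha in [(2.0, 0.05), (4.0, 1e-3)]:
            z = stats.norm.isf(alpha / 2)
            expected = 1 - (stats.norm.cdf(z - ncp) - stats.norm.cdf(-z - ncp))
            assert eqs.analytic_power(ncp, alpha) == pytest.approx(expected, abs=1e-12)

    def test_ratio_monotone_in_fraction(self):
        outs = [
            eqs.power_ratio_simulation(f, effect_grid=(0.2,), n=400, alpha=1e-3,
                                       reps=1200, seed=3).ratio.iloc[0]
            for f in (0.2, 0.5, 1.0)
        ]
        assert outs[0] <= outs[1] + 0.03 <= outs[2] + 0.06


class TestMixtureGenerator:
    def test_bulk_slope_diluted_by_cell_fraction(self):
        cfg = sim.SimConfig(seed=21, n_individuals=4000)
        X, Y, truth = sim.simulate_eqtl_mixture(cfg, beta=0.5, n_eqtls=60, specific_prob=1.0)
        slopes = [stats.linregress(X[i], Y[i]).slope for i in range(60)]
        resid = np.array(slopes) - truth.true_slope.to_numpy()
        assert abs(resid.mean()) < 3 * 1 / np.sqrt(4000 * 60 / 2)
        # each specific slope equals f_k * beta for its cell type
        fr = np.array(cfg.cell_fractions)
        assert set(np.round(truth.true_slope.unique(), 6)) <= set(np.round(fr * 0.5, 6))
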