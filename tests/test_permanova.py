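import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coralnet import (
    Permanova,
    ValidationError,
    bray_curtis,
    gower_center,
    holm_adjust,
    pairwise_permanova,
)
from coralnet.community import euclidean

from conftest import survey_design


class TestGowerCentering:
    def test_trace_equals_total_ss_univariate(self):
        y = np.array([0.3, 1.7, 2.0, -1.0, 0.5])
        d = np.abs(y[:, None] - y[None, :])
        G = gower_center(d)
        assert np.trace(G) == pytest.approx(np.sum((y - y.mean()) ** 2), abs=1e-10)

    def test_degenerate_and_centering(self):
        G = gower_center(np.zeros((4, 4)))
        np.testing.assert_allclose(G, 0.0, atol=1e-12)
        rng = np.random.default_rng(0)
        y = rng.random((6, 3))
        G = gower_center(euclidean(pd.DataFrame(y)))
        np.testing.assert_allclose(G.sum(axis=0), 0.0, atol=1e-9)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            gower_center(d)


class TestPermanovaOracles:
    def test_univariate_equals_classical_anova_f(self):
        y = np.array([0.0, 1.0, 1.0, 2.0])
        meta = pd.DataFrame({"genus": ["A", "A", "B", "B"],
                             "species": ["A", "A", "B", "B"],
                             "site": ["x"] * 4, "time": ["x"] * 4},
                            index=[f"s{i}" for i in range(4)])
        d = np.abs(y[:, None] - y[None, :])
        res = Permanova(d, meta, ["Genus"]).fit(permutations=0)
        row = res.table["Genus"]
        assert row["statistic"] == pytest.approx(2.0, abs=1e-9)
        assert row["df"] == 1

    def test_sequential_ss_matches_statsmodels_anova(self):
        """Euclidean-distance PERMANOVA on univariate data reproduces the
        classical sequential (Type-I) ANOVA decomposition."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(42)
        meta = survey_design(reps=1)
        y = (
            rng.normal(size=len(meta))
            + meta["genus"].map({"Porites": 0.0, "Acropora": 1.0, "Diploria": -0.5}).to_numpy()
            + meta["site"].map({"PC": 0.3, "CB": 0.0, "C14": -0.3, "C4": 0.1}).to_numpy()
        )
        d = np.abs(y[:, None] - y[None, :])
        # full-rank crossed design (treatment coding cannot express nesting)
        res = Permanova(d, meta, ["Genus", "Site", "Time", "Genus:Site"]).fit(permutations=0)
        df = meta.assign(y=y)
        fit = ols("y ~ C(genus) + C(site) + C(time) + C(genus):C(site)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        ss_mine = res.r_squared[["Genus", "Site", "Time", "Genus:Site"]].to_numpy() * res.total_ss
        np.testing.assert_allclose(ss_mine, table["sum_sq"].to_numpy()[:4], atol=1e-9)
        F_mine = res.table.frame["statistic"].to_numpy()[:4]
        np.testing.assert_allclose(F_mine, table["F"].to_numpy()[:4], atol=1e-9)
        np.testing.assert_allclose(
            res.table.frame["df"].to_numpy()[:4].astype(float), table["df"].to_numpy()[:4]
        )

    def test_one_way_f_matches_skbio(self):
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.random((12, 6)) + 0.05,
                              index=[f"s{i}" for i in range(12)])
        values.iloc[:6] += 0.7
        dm = bray_curtis(values)
        meta = pd.DataFrame(
            {"genus": ["A"] * 6 + ["B"] * 6, "species": ["A"] * 6 + ["B"] * 6,
             "site": ["x"] * 12, "time": ["x"] * 12},
            index=values.index,
        )
        mine = Permanova(dm, meta, ["Genus"]).fit(permutations=0).table["Genus"]
        ref = skbio_permanova(dm, grouping=meta["genus"], permutations=0)
        assert mine["statistic"] == pytest.approx(ref["test statistic"], rel=1e-9)


class TestPermanovaDesign:
    def test_nested_survey_degrees_of_freedom(self):
        meta = survey_design(reps=2)
        rng = np.random.default_rng(0)
        d = euclidean(pd.DataFrame(rng.random((len(meta), 5)), index=meta.index))
        terms = ["Genus", "Site", "Time", "Species(Genus)", "Genus:Site",
                 "Genus:Time", "Site:Time"]
        res = Permanova(d, meta, terms).fit(permutations=0)
        dfs = dict(zip(res.table.frame["term"], res.table.frame["df"]))
        assert dfs["Genus"] == 2
        assert dfs["Site"] == 3
        assert dfs["Time"] == 2
        assert dfs["Species(Genus)"] == 3
        assert dfs["Genus:Site"] == 6
        assert dfs["Genus:Time"] == 4
        assert dfs["Site:Time"] == 6

    def test_r_squared_sums_to_one(self, sim_survey):
        counts, md, _, _ = sim_survey
        from coralnet import normalize_median_of_ratios

        dm = bray_curtis(normalize_median_of_ratios(counts, "pseudo-geomean"))
        res = Permanova(dm, md, ["Genus", "Site", "Time"]).fit(permutations=0)
        assert res.table.frame["effect_size"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_aliased_term_rejected(self):
        meta = survey_design(reps=1)
        rng = np.random.default_rng(0)
        d = euclidean(pd.DataFrame(rng.random((len(meta), 3)), index=meta.index))
        with pytest.raises(ValidationError, match="aliased"):
            Permanova(d, meta, ["Species(Genus)", "Genus"]).fit(permutations=0)

    def test_seed_reproducibility_and_order_invariance(self):
        rng = np.random.default_rng(9)
        values = pd.DataFrame(rng.random((16, 8)) + 0.05, index=[f"s{i}" for i in range(16)])
        meta = pd.DataFrame(
            {"genus": ["A", "B"] * 8, "species": ["A", "B"] * 8,
             "site": (["x"] * 8 + ["y"] * 8), "time": ["t"] * 16},
            index=values.index,
        )
        dm = bray_curtis(values)
        r1 = Permanova(dm, meta, ["Genus", "Site"]).fit(99, seed=5)
        r2 = Permanova(dm, meta, ["Genus", "Site"]).fit(99, seed=5)
        assert r1.table == r2.table
        # reordering the samples leaves the observed statistics unchanged
        perm = np.random.default_rng(1).permutation(16)
        ids = [f"s{i}" for i in perm]
        dm2 = bray_curtis(values.loc[ids])
        r3 = Permanova(dm2, meta.loc[ids], ["Genus", "Site"]).fit(permutations=0)
        np.testing.assert_allclose(
            r1.table.frame["statistic"].to_numpy()[:2],
            r3.table.frame["statistic"].to_numpy()[:2],
            rtol=1e-9,
        )


class TestHolm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.5], [0.5]),
            ([0.001, 0.001, 0.001], [0.003, 0.003, 0.003]),
            ([0.001] * 6, [0.006] * 6),
            ([0.01, 0.02, 0.03], [0.03, 0.04, 0.04]),
            ([0.04, 0.04], [0.08, 0.08]),
        ],
    )
    def test_hand_examples(self, raw, expected):
        np.testing.assert_allclose(holm_adjust(raw), expected, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1.0, size=11)
        np.testing.assert_allclose(
            holm_adjust(p), multipletests(p, method="holm")[1], atol=1e-12
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_monotone_and_bounded(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.0, 0.5])


class TestPairwise:
    def test_three_strong_groups_adjusted_p(self):
        """Three clearly separated levels: every pairwise permutation p is the
        minimum attainable 1/(1+999) = 0.001, Holm-adjusted to 0.003."""
        rng = np.random.default_rng(4)
        base = rng.random((30, 10)) * 0.05 + 0.01
        values = pd.DataFrame(base, index=[f"s{i}" for i in range(30)])
        for k in range(3):
            values.iloc[10 * k : 10 * k + 10, 3 * k : 3 * k + 3] += 5.0
        meta = pd.DataFrame(
            {"genus": ["P"] * 10 + ["A"] * 10 + ["D"] * 10,
             "species": ["P"] * 10 + ["A"] * 10 + ["D"] * 10,
             "site": ["x"] * 30, "time": ["t"] * 30},
            index=values.index,
        )
        tt = pairwise_permanova(bray_curtis(values), meta, "genus", permutations=999, seed=0)
        assert len(tt.frame) == 3
        np.testing.assert_allclose(tt.frame["p_value"], 0.001, atol=1e-12)
        np.testing.assert_allclose(tt.frame["p_adjusted"], 0.003, atol=1e-12)

    def test_small_level_rejected(self):
        values = pd.DataFrame(np.random.default_rng(0).random((4, 3)) + 0.1,
                              index=list("abcd"))
        meta = pd.DataFrame(
            {"genus": ["A", "A", "A", "B"], "species": ["A"] * 3 + ["B"],
             "site": ["x"] * 4, "time": ["t"] * 4},
            index=values.index,
        )
        with pytest.raises(ValidationError, match="< 2 samples"):
            pairwise_permanova(bray_curtis(values), meta, "genus", permutations=9)
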