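"""Ordination, VIP scores, repeated-measures ANOVA and SI contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lipidstress.io import PeakTable, SampleMeta
from lipidstress.stats import (
    contrast_si,
    pca,
    per_species_rm_anova,
    plsda_vip,
    significance_stars,
)

from conftest import build_table


def random_matrix(rng, p, n):
    names = [f"PC {30 + i}:0" for i in range(p)]
    return pd.DataFrame(
        rng.normal(size=(p, n)), index=names, columns=[f"S{k}" for k in range(n)]
    )


class TestPca:
    def test_two_samples_single_component(self, rng):
        m = random_matrix(rng, 5, 2)
        res = pca(m, n_components=1)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition(self, rng):
        m = random_matrix(rng, 20, 6)
        res = pca(m, n_components=3)
        X = m.T.to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        # compare explained fractions and |scores| (signs are conventional)
        assert np.allclose(
            res.explained_variance_fraction, (evals / evals.sum())[:3], atol=1e-8
        )
        scores_oracle = Xc @ evecs[:, :3]
        assert np.allclose(np.abs(res.scores.to_numpy()), np.abs(scores_oracle), atol=1e-8)

    def test_explained_fractions_valid_and_order_invariant(self, rng):
        m = random_matrix(rng, 15, 8)
        res = pca(m, n_components=4)
        ev = res.explained_variance_fraction
        assert (ev >= 0).all() and (ev <= 1).all()
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1 + 1e-12
        perm = list(np.random.default_rng(0).permutation(m.index))
        res2 = pca(m.loc[perm], n_components=4)
        assert np.allclose(res2.explained_variance_fraction, ev)

    def test_duplicated_samples_zero_variance_beyond_first(self, rng):
        col = rng.normal(size=5)
        m = pd.DataFrame(
            {"S1": col, "S2": col, "S3": 2 * col},
            index=[f"PC {30 + i}:0" for i in range(5)],
        )
        res = pca(m, n_components=2)
        assert res.explained_variance_fraction[1] == pytest.approx(0.0, abs=1e-12)

    def test_too_many_components_errors(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            pca(random_matrix(rng, 5, 3), n_components=4)

    def test_sign_convention_deterministic(self, rng):
        m = random_matrix(rng, 10, 5)
        r1, r2 = pca(m, 2), pca(m, 2)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        for j in ("PC1", "PC2"):
            i = r1.loadings[j].abs().idxmax()
            assert r1.loadings.loc[i, j] > 0


class TestVip:
    def test_mean_square_identity(self, rng):
        for trial in range(3):
            m = random_matrix(rng, 12, 10)
            labels = np.array(["a"] * 5 + ["b"] * 5)
            res = plsda_vip(m, labels, n_components=2)
            assert (res.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_single_component_closed_form(self, rng):
        """One-component VIP reduces to sqrt(p) * |w_j| / ||w||."""
        m = random_matrix(rng, 8, 12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = plsda_vip(m, labels, n_components=1)
        # oracle: first PLS2 weight is the dominant left singular vector of
        # Xs^T Yc, which for a 2-class one-hot Y is proportional to Xs^T yc
        X = m.T.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = (labels == "a").astype(float)
        yc -= yc.mean()
        w = Xs.T @ yc
        w /= np.linalg.norm(w)
        expected = np.sqrt(len(w)) * np.abs(w)
        assert np.allclose(res.vip.to_numpy(), expected, atol=1e-8)

    def test_signal_species_rank_top(self, rng):
        """Species carrying the class signal get the top VIP ranks."""
        p, n = 30, 40
        X = rng.normal(size=(p, n))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        signal = [0, 1, 2]
        for j in signal:
            X[j, labels == "b"] += 4.0
        m = pd.DataFrame(X, index=[f"PC {30 + i}:0" for i in range(p)],
                         columns=[f"S{k}" for k in range(n)])
        res = plsda_vip(m, labels, n_components=2)
        top3 = set(res.vip.sort_values(ascending=False).index[:3])
        assert top3 == {f"PC {30 + j}:0" for j in signal}
        assert set(res.selected["species"]) >= top3

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            plsda_vip(random_matrix(rng, 5, 4), ["a"] * 4)

    def test_rank_bound_errors(self, rng):
        with pytest.raises(ValueError, match="rank"):
            plsda_vip(random_matrix(rng, 5, 4), ["a", "a", "b", "b"], n_components=4)


def paired_table(values: np.ndarray, conditions, n_reps, cell_line="A549"):
    """PeakTable with species x (rep x condition) log2 values."""
    samples = [
        SampleMeta(f"{cell_line}_{c}_R{r}", cell_line, c, r)
        for r in range(1, n_reps + 1)
        for c in conditions
    ]
    names = [f"PC {30 + i}:0" for i in range(values.shape[0])]
    mat = pd.DataFrame(values, index=names, columns=[s.sample_id for s in samples])
    species = [__import__("lipidstress").parse_lipid_name(n) for n in names]
    return PeakTable(species, mat, samples, log_scale=True)


class TestRmAnova:
    def test_f_equals_squared_paired_t(self, rng):
        vals = rng.normal(size=(25, 8))  # 4 replicates x 2 conditions
        t = paired_table(vals, ["Nor", "Hyp"], 4)
        res = per_species_rm_anova(t)
        for i, name in enumerate(t.species_names):
            a = vals[i, 0::2]  # Nor columns (rep-major layout)
            b = vals[i, 1::2]
            tt = sps.ttest_rel(a, b)
            row = res[res.species == name].iloc[0]
            assert row["statistic"] == pytest.approx(tt.statistic**2, abs=1e-8)
            assert row["p_value"] == pytest.approx(tt.pvalue, abs=1e-10)

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        vals = rng.normal(size=(4, 9))  # 3 replicates x 3 conditions
        t = paired_table(vals, ["Nor", "LS", "Hyp"], 3)
        res = per_species_rm_anova(t)
        meta = t.sample_meta_frame()
        for i, name in enumerate(t.species_names):
            df = meta.assign(y=vals[i])
            sm = AnovaRM(df, "y", "replicate", within=["condition"]).fit()
            F = sm.anova_table["F Value"].iloc[0]
            p = sm.anova_table["Pr > F"].iloc[0]
            row = res[res.species == name].iloc[0]
            assert row["statistic"] == pytest.approx(F, rel=1e-8)
            assert row["p_value"] == pytest.approx(p, rel=1e-6)

    def test_constant_species_boundary(self):
        vals = np.full((1, 6), 3.5)
        t = paired_table(vals, ["Nor", "Hyp"], 3)
        row = per_species_rm_anova(t).iloc[0]
        assert row["statistic"] == 0.0
        assert row["p_value"] == 1.0

    def test_unbalanced_falls_back_with_warning(self, rng):
        vals = rng.normal(size=(3, 5))
        samples = [
            SampleMeta(f"A549_Nor_R{r}", "A549", "Nor", r) for r in (1, 2, 3)
        ] + [SampleMeta(f"A549_Hyp_R{r}", "A549", "Hyp", r) for r in (1, 2)]
        names = [f"PC {30 + i}:0" for i in range(3)]
        mat = pd.DataFrame(vals, index=names, columns=[s.sample_id for s in samples])
        species = [__import__("lipidstress").parse_lipid_name(n) for n in names]
        t = PeakTable(species, mat, samples, log_scale=True)
        with pytest.warns(UserWarning, match="unbalanced"):
            res = per_species_rm_anova(t)
        assert (res["test_name"] == "oneway_anova_unpaired_fallback").all()
        i = 0
        f, p = sps.f_oneway(vals[i, :3], vals[i, 3:])
        assert res.iloc[i]["statistic"] == pytest.approx(f)


class TestContrastSi:
    def _si(self, rows):
        return pd.DataFrame(
            rows, columns=["cell_line", "condition", "replicate", "lipid_class", "si"]
        )

    def test_identical_groups_p_one(self):
        df = self._si(
            [("KG1", "Nor", r, "TG", v) for r, v in [(1, 0.5), (2, 0.7), (3, 0.6)]]
            + [("KG1", "LS", r, "TG", v) for r, v in [(1, 0.5), (2, 0.7), (3, 0.6)]]
        )
        r = contrast_si(df, "KG1", "TG", ("LS", "Nor"))
        assert r.p_value == pytest.approx(1.0)
        assert r.stars == ""

    def test_degenerate_distinct_constants(self):
        df = self._si(
            [("KG1", "Nor", r, "TG", 1.0) for r in (1, 2, 3)]
            + [("KG1", "LS", r, "TG", 2.0) for r in (1, 2, 3)]
        )
        r = contrast_si(df, "KG1", "TG", ("LS", "Nor"))
        assert r.p_value == 0.0
        assert r.degenerate
        assert r.significant

    def test_degenerate_equal_constants(self):
        df = self._si(
            [("KG1", "Nor", r, "TG", 1.0) for r in (1, 2)]
            + [("KG1", "LS", r, "TG", 1.0) for r in (1, 2)]
        )
        r = contrast_si(df, "KG1", "TG", ("LS", "Nor"))
        assert r.p_value == 1.0 and not r.degenerate

    def test_too_few_replicates_errors(self):
        df = self._si([("KG1", "Nor", 1, "TG", 1.0), ("KG1", "LS", 1, "TG", 2.0)])
        with pytest.raises(ValueError, match=">=2"):
            contrast_si(df, "KG1", "TG", ("LS", "Nor"))

    def test_paired_uses_replicate_pairing(self, rng):
        nor = [0.5, 0.6, 0.7]
        ls = [0.7, 0.8, 0.9]
        df = self._si(
            [("KG1", "Nor", r + 1, "TG", v) for r, v in enumerate(nor)]
            + [("KG1", "LS", r + 1, "TG", v) for r, v in enumerate(ls)]
        )
        r = contrast_si(df, "KG1", "TG", ("LS", "Nor"), paired=True)
        tt = sps.ttest_rel(ls, nor)
        assert r.p_value == pytest.approx(tt.pvalue)
        assert r.test_name == "paired_t"


@pytest.mark.parametrize(
    "p, stars", [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, ""), (np.nan, "")]
)
def test_significance_stars(p, stars):
    assert significance_stars(p) == stars
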