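"""Repeated-measures ANOVA machinery against explicit oracles."""

import numpy as np
import pandas as pd
import pytest

from brainstates.atlas import ValidationError
from brainstates.stats import (
    nodewise_fdr,
    partial_omega_squared,
    per_threshold_anovas,
    rm_anova,
    rm_anova_oneway,
    rm_ancova_distance,
    sidak_adjust,
    sidak_pairwise,
    sphericity_epsilons,
    _orthonormal_contrasts,
)


def long_table(cube, conditions=None, thresholds=None):
    n, a, b = cube.shape
    conditions = conditions or [f"c{i}" for i in range(a)]
    thresholds = thresholds or list(range(b))
    rows = []
    for si in range(n):
        for ai in range(a):
            for bi in range(b):
                rows.append((f"s{si}", conditions[ai], thresholds[bi],
                             cube[si, ai, bi]))
    return pd.DataFrame(rows, columns=["subject", "condition", "threshold",
                                       "value"])


def anova_two_way_oracle(cube):
    """Explicit sums-of-squares decomposition from marginal means."""
    n, a, b = cube.shape
    grand = cube.mean()
    ss = {}
    ss["A"] = n * b * ((cube.mean((0, 2)) - grand) ** 2).sum()
    ss["B"] = n * a * ((cube.mean((0, 1)) - grand) ** 2).sum()
    m_ab = cube.mean(0)
    ss["AB"] = n * ((m_ab - cube.mean((0, 2))[:, None]
                     - cube.mean((0, 1))[None, :] + grand) ** 2).sum()
    m_sa, m_sb, m_s = cube.mean(2), cube.mean(1), cube.mean((1, 2))
    ss["AS"] = b * ((m_sa - m_s[:, None] - cube.mean((0, 2))[None, :] + grand) ** 2).sum()
    ss["BS"] = a * ((m_sb - m_s[:, None] - cube.mean((0, 1))[None, :] + grand) ** 2).sum()
    ss["ABS"] = ((cube - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None]
                  + m_s[:, None, None] + cube.mean((0, 2))[None, :, None]
                  + cube.mean((0, 1))[None, None, :] - grand) ** 2).sum()
    f_a = (ss["A"] / (a - 1)) / (ss["AS"] / ((n - 1) * (a - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["BS"] / ((n - 1) * (b - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (ss["ABS"] / ((n - 1) * (a - 1) * (b - 1)))
    return f_a, f_b, f_ab


class TestRmAnova:
    def test_all_identical_values_give_zero_f(self):
        cube = np.full((5, 4, 5), 3.14)
        res = rm_anova(long_table(cube))
        for eff in res.effects.values():
            assert eff.F == pytest.approx(0.0)

    def test_random_tables_match_ss_oracle(self, rng):
        for _ in range(10):
            cube = rng.standard_normal((6, 4, 5))
            res = rm_anova(long_table(cube))
            f_a, f_b, f_ab = anova_two_way_oracle(cube)
            assert res.effects["condition"].F == pytest.approx(f_a, rel=1e-8)
            assert res.effects["threshold"].F == pytest.approx(f_b, rel=1e-8)
            assert res.effects["condition x threshold"].F == pytest.approx(
                f_ab, rel=1e-8)

    def test_matches_pingouin_oneway(self, rng):
        import pingouin as pg

        cells = rng.standard_normal((8, 4)) + np.array([0, 0.3, 0.6, 0.1])
        tab = long_table(cells[:, :, None])
        res = rm_anova_oneway(tab)
        df = tab.rename(columns={"condition": "within"})
        pg_res = pg.rm_anova(data=df, dv="value", within="within",
                             subject="subject", correction=False)
        assert res.effects["condition"].F == pytest.approx(
            float(pg_res["F"].iloc[0]), rel=1e-6)
        assert res.effects["condition"].p_uncorrected == pytest.approx(
            float(pg_res["p_unc"].iloc[0]), rel=1e-6)

    def test_missing_cell_rejected(self, rng):
        tab = long_table(rng.standard_normal((4, 3, 2)))
        with pytest.raises(ValidationError):
            rm_anova(tab.iloc[:-1])


class TestSphericity:
    def test_two_levels_trivial(self):
        w, p, gg, hf = sphericity_epsilons(np.array([[2.0]]), n=10)
        assert (w, gg, hf) == (1.0, 1.0, 1.0)

    def test_spherical_identity_covariance(self):
        w, p, gg, hf = sphericity_epsilons(np.eye(3), n=12)
        assert gg == pytest.approx(1.0)
        assert w == pytest.approx(1.0)

    def test_epsilon_inequalities_on_random_covariances(self, rng):
        for k in (3, 4, 5):
            for _ in range(20):
                b = rng.standard_normal((k - 1, k - 1))
                cov = b @ b.T
                _, _, gg, hf = sphericity_epsilons(cov, n=12)
                assert gg >= 1.0 / (k - 1) - 1e-12
                assert hf >= gg - 1e-12
                assert gg <= 1.0 + 1e-12

    def test_gg_matches_eigenvalue_formula(self, rng):
        b = rng.standard_normal((3, 3))
        cov = b @ b.T
        lam = np.linalg.eigvalsh(cov)
        expect = lam.sum() ** 2 / (3 * (lam ** 2).sum())
        _, _, gg, _ = sphericity_epsilons(cov, n=10)
        assert gg == pytest.approx(expect, rel=1e-12)

    def test_matches_pingouin_epsilons(self, rng):
        import pingouin as pg

        data = pd.DataFrame(rng.standard_normal((12, 4)),
                            columns=list("abcd"))
        gg_pg = pg.epsilon(data, correction="gg")
        hf_pg = pg.epsilon(data, correction="hf")
        contrasts = _orthonormal_contrasts(4)
        cov = np.cov(data.to_numpy() @ contrasts.T, rowvar=False)
        _, _, gg, hf = sphericity_epsilons(cov, n=12)
        assert gg == pytest.approx(float(gg_pg), rel=1e-6)
        assert hf == pytest.approx(float(hf_pg), rel=1e-4)


class TestEffectSizeAndSidak:
    def test_partial_omega_squared_values(self):
        assert partial_omega_squared(1.0, 3, 48) == 0.0
        assert partial_omega_squared(10.0, 3, 48) == pytest.approx(27 / 75)
        assert partial_omega_squared(1e9, 3, 48) == pytest.approx(1.0, abs=1e-6)
        assert partial_omega_squared(0.2, 3, 48) == 0.0  # clipped

    def test_sidak_closed_form(self):
        assert sidak_adjust(0.01, 1) == pytest.approx(0.01)
        assert sidak_adjust(0.01, 6) == pytest.approx(1 - 0.99**6)
        # monotone in m
        ps = [sidak_adjust(0.02, m) for m in range(1, 10)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_pairwise_table_shape(self, rng):
        data = rng.standard_normal((10, 4))
        tab = sidak_pairwise(data, ["W", "S", "LOC", "R"])
        assert len(tab) == 6
        assert (tab["p_sidak"] >= tab["p_raw"] - 1e-12).all()
        assert (tab["p_sidak"] <= 1.0).all()


class TestPerThresholdAndFdr:
    def test_one_anova_per_threshold(self, rng):
        tab = long_table(rng.standard_normal((6, 4, 5)))
        out = per_threshold_anovas(tab)
        assert len(out) == 5

    def test_type_one_error_calibrated(self):
        hits = 0
        total = 0
        for rep in range(200):
            rng = np.random.default_rng(4000 + rep)
            tab = long_table(rng.standard_normal((8, 4, 1)))
            res = per_threshold_anovas(tab)[0]
            hits += res.effects["condition"].p < 0.05
            total += 1
        # binomial 99.9% envelope around 5% over 200 draws
        assert 1 <= hits <= 22

    def test_by_fdr_matches_stepwise_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(0, 1, 20)
            reject, p_adj = nodewise_fdr(p, q=0.05)
            # step-by-step Benjamini-Yekutieli
            m = len(p)
            cm = np.sum(1.0 / np.arange(1, m + 1))
            order = np.argsort(p)
            thresh = 0.05 * np.arange(1, m + 1) / (m * cm)
            below = np.flatnonzero(p[order] <= thresh)
            expect = np.zeros(m, bool)
            if below.size:
                expect[order[: below.max() + 1]] = True
            np.testing.assert_array_equal(reject, expect)

    def test_all_zero_p_all_rejected(self):
        reject, _ = nodewise_fdr(np.zeros(7))
        assert reject.all()

    def test_single_p_reduces_to_threshold(self):
        assert nodewise_fdr(np.array([0.04]), q=0.05)[0][0]
        assert not nodewise_fdr(np.array([0.06]), q=0.05)[0][0]


class TestDistanceAncova:
    @staticmethod
    def binned_table(rng, n_subj=8, slope=0.0, cond_offsets=(0, 0, 0, 0),
                     cond_slopes=(0, 0, 0, 0), noise=0.02):
        rows = []
        centers = (np.arange(15) + 0.5) * 9.0
        for s in range(n_subj):
            for ci, cond in enumerate(["W", "S", "LOC", "R"]):
                base = 0.3 + cond_offsets[ci] + rng.normal(0, 0.02)
                sl = slope + cond_slopes[ci]
                for b, d in enumerate(centers):
                    rows.append((f"s{s}", cond, b, d,
                                 base + sl * d + rng.normal(0, noise)))
        return pd.DataFrame(rows, columns=["subject", "condition", "bin",
                                           "center_mm", "mean_r"])

    def test_no_distance_decay_null(self, rng):
        ps = []
        for rep in range(20):
            tab = self.binned_table(np.random.default_rng(rep), slope=0.0)
            res = rm_ancova_distance(tab)
            ps.append(res.distance.p)
        assert np.mean([p < 0.05 for p in ps]) < 0.3

    def test_planted_condition_gain_detected(self, rng):
        tab = self.binned_table(rng, slope=-0.001,
                                cond_offsets=(0.1, 0.05, -0.1, 0.0))
        res = rm_ancova_distance(tab)
        assert res.condition.p < 0.01
        assert res.distance.p < 0.01
        assert res.interaction.p > 0.001  # no planted interaction

    def test_per_bin_followups_cover_bins(self, rng):
        tab = self.binned_table(rng)
        res = rm_ancova_distance(tab)
        assert len(res.per_bin) == 15
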