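"""Statistical engine: t-tests, Holm, JZS BF, RM-ANOVA, LMM, mediation, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melanosub.stats import (
    DegenerateDataError,
    IncompleteDesignError,
    PowerSpec,
    achieved_power_rm_anova,
    apriori_n_rm_anova,
    bf10_ttest,
    fit_lmm_random_intercept,
    holm_adjust,
    mediate,
    paired_t,
    rm_anova_2x2,
    rm_anova_oneway,
)


class TestPairedT:
    def test_zero_mean_difference(self):
        r = paired_t([1.0, 0.0, 0.5], [0.0, 1.0, 0.5])
        assert r.estimate == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # d = (1, 2, 3): mean 2, sd 1 → t = 2/(1/√3) = 3.4641, df = 2, dz = 2
        r = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.estimate == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert r.df == 2
        assert r.effect_size == pytest.approx(2.0)

    def test_dz_times_sqrt_n_is_t(self, rng):
        x, y = rng.random(20), rng.random(20)
        r = paired_t(x, y)
        assert r.effect_size * np.sqrt(20) == pytest.approx(r.estimate, rel=1e-12)

    def test_degenerate_differences_raise(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_stepped_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(9)
        _, adj, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), adj, rtol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_dominance_and_monotonicity(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestBayesFactor:
    @pytest.mark.parametrize(
        "t,expected",
        [(2.728, 4.2), (0.702, 0.259), (1.914, 1.003)],
    )
    def test_reference_values_n26(self, t, expected):
        assert bf10_ttest(t, 26) == pytest.approx(expected, rel=0.02)

    def test_large_t_overwhelming_evidence(self):
        assert bf10_ttest(4.943, 26) > 100.0

    def test_null_t_favors_h0(self):
        for n in (2, 5, 26, 100):
            assert bf10_ttest(0.0, n) < 1.0

    def test_strictly_increasing_in_abs_t(self):
        bfs = [bf10_ttest(t, 26) for t in np.linspace(0.0, 5.0, 11)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_against_pingouin(self, rng):
        import pingouin as pg

        for _ in range(5):
            t = float(rng.uniform(-3, 3))
            n = int(rng.integers(5, 60))
            assert bf10_ttest(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-3
            )


def _random_2x2(rng, n=8, a_eff=0.0, b_eff=0.0, ab_eff=0.0):
    rows = []
    for s in range(n):
        base = rng.normal(0, 1)
        for ai, a in enumerate(("low", "high")):
            for bi, b in enumerate(("1-back", "2-back")):
                rows.append(
                    {
                        "subject": s,
                        "light": a,
                        "task": b,
                        "value": base
                        + rng.normal(0, 1)
                        + a_eff * ai
                        + b_eff * bi
                        + ab_eff * ai * bi,
                    }
                )
    return pd.DataFrame(rows)


def _ss_oracle(y):
    """From-scratch sums-of-squares decomposition for a 2×2 within design.

    y has shape (n, 2, 2) indexed (subject, A, B).
    """
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    ss_a = 2 * n * np.sum((a_m - grand) ** 2)
    ss_b = 2 * n * np.sum((b_m - grand) ** 2)
    cell = y.mean(axis=0)
    ss_ab = n * np.sum((cell - a_m[:, None] - b_m[None, :] + grand) ** 2)
    sa = y.mean(axis=2)
    ss_as = 2 * np.sum((sa - a_m[None, :] - subj[:, None] + grand) ** 2)
    sb = y.mean(axis=1)
    ss_bs = 2 * np.sum((sb - b_m[None, :] - subj[:, None] + grand) ** 2)
    resid = (
        y
        - cell[None]
        - sa[:, :, None]
        - sb[:, None, :]
        + a_m[None, :, None]
        + b_m[None, None, :]
        + subj[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)
    return {
        "A": (ss_a, ss_as),
        "B": (ss_b, ss_bs),
        "AB": (ss_ab, ss_abs),
    }


class TestRmAnova2x2:
    def test_matches_sums_of_squares_oracle(self, rng):
        df = _random_2x2(rng, n=8, a_eff=0.5, ab_eff=0.3)
        res = rm_anova_2x2(df)
        wide = df.pivot_table(index="subject", columns=["light", "task"], values="value")
        y = wide.to_numpy().reshape(8, 2, 2)  # columns sorted: (high, low) × tasks
        # pivot sorts 'high' before 'low'; map accordingly
        oracle = _ss_oracle(y)
        n = 8
        for key, eff in (("light", "A"), ("task", "B"), ("interaction", "AB")):
            ss_e, ss_err = oracle[eff]
            f_oracle = (ss_e / 1) / (ss_err / (n - 1))
            assert res[key].estimate == pytest.approx(f_oracle, abs=1e-8)
            assert res[key].extra["ss_effect"] == pytest.approx(ss_e, abs=1e-8)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        df = _random_2x2(rng, n=10, a_eff=0.4, b_eff=0.2, ab_eff=0.1)
        res = rm_anova_2x2(df)
        ref = pg.rm_anova(
            data=df, dv="value", within=["light", "task"], subject="subject", detailed=True
        ).set_index("Source")
        assert res["light"].estimate == pytest.approx(ref.loc["light", "F"], rel=1e-9)
        assert res["task"].estimate == pytest.approx(ref.loc["task", "F"], rel=1e-9)
        assert res["interaction"].estimate == pytest.approx(
            ref.loc["light * task", "F"], rel=1e-9
        )
        assert res["light"].p == pytest.approx(ref.loc["light", "p_unc"], rel=1e-9)

    def test_f_equals_t_squared_for_two_level_margins(self, rng):
        df = _random_2x2(rng, n=12, a_eff=0.6)
        res = rm_anova_2x2(df)
        wide = df.pivot_table(index="subject", columns=["light", "task"], values="value")
        t = paired_t(wide["high"].mean(axis=1), wide["low"].mean(axis=1))
        assert res["light"].estimate == pytest.approx(t.estimate**2, abs=1e-8)

    def test_all_identical_cells_have_zero_effect_ss(self):
        df = _random_2x2(np.random.default_rng(0), n=5)
        df["value"] = 3.0
        res = rm_anova_2x2(df)
        for key in ("light", "task", "interaction"):
            assert res[key].extra["ss_effect"] == pytest.approx(0.0, abs=1e-20)

    def test_incomplete_design_rejected(self, rng):
        df = _random_2x2(rng, n=5).iloc[:-1]
        with pytest.raises(IncompleteDesignError):
            rm_anova_2x2(df)


class TestRmAnovaOneway:
    def test_matches_pingouin_with_gg(self, rng):
        import pingouin as pg

        rows = []
        for s in range(12):
            base = rng.normal(0, 1)
            scale = [1.0, 1.0, 3.0, 6.0]  # heterogeneous → sphericity violated
            for k in range(4):
                rows.append(
                    {"subject": s, "condition": f"c{k}",
                     "value": base + 0.4 * k + scale[k] * rng.normal()}
                )
        df = pd.DataFrame(rows)
        res = rm_anova_oneway(df)
        ref = pg.rm_anova(data=df, dv="value", within="condition", subject="subject",
                          correction=True)
        assert res.estimate == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.extra["epsilon"] == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        if res.correction == "GG":
            assert res.p == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_two_levels_never_corrected(self, rng):
        rows = [
            {"subject": s, "condition": c, "value": rng.normal()}
            for s in range(6)
            for c in ("a", "b")
        ]
        res = rm_anova_oneway(pd.DataFrame(rows))
        assert res.correction == "none" and res.extra["epsilon"] == 1.0


class TestLmm:
    def test_equals_ols_without_subject_variance(self, rng):
        rows = []
        for s in range(10):
            for light in (0.0, 1.0):
                for _ in range(20):
                    rows.append({"subject": s, "light": light,
                                 "rt": 500 - 15 * light + rng.normal(0, 30)})
        df = pd.DataFrame(rows)
        res = fit_lmm_random_intercept(df, "rt", ["light"], n_boot=200, seed=0)
        ols = np.polyfit(df.light, df.rt, 1)[0]
        assert res["light"].estimate == pytest.approx(ols, abs=1e-4)

    def test_bootstrap_ci_deterministic(self, rng):
        rows = [
            {"subject": s, "light": l, "rt": 500 + 10 * s - 20 * l + rng.normal(0, 50)}
            for s in range(12)
            for l in (0.0, 1.0)
            for _ in range(30)
        ]
        df = pd.DataFrame(rows)
        a = fit_lmm_random_intercept(df, "rt", ["light"], n_boot=500, seed=7)
        b = fit_lmm_random_intercept(df, "rt", ["light"], n_boot=500, seed=7)
        assert a["light"].ci == b["light"].ci

    def test_recovers_injected_effect_with_ci(self):
        rng = np.random.default_rng(11)
        hits = 0
        for rep in range(10):
            rows = []
            for s in range(26):
                icept = rng.normal(0, 30)
                for l in (0.0, 1.0):
                    for _ in range(100):
                        rows.append({"subject": s, "light": l,
                                     "rt": 550 + icept - 20 * l + rng.normal(0, 80)})
            df = pd.DataFrame(rows)
            res = fit_lmm_random_intercept(df, "rt", ["light"], n_boot=1000, seed=rep)
            lo, hi = res["light"].ci
            if lo <= -20.0 <= hi:
                hits += 1
            assert hi < 0.0  # CI excludes zero every time at this n
        assert hits >= 9


class TestMediation:
    def test_standardisation_invariance(self, rng):
        x = np.repeat([0.0, 1.0], 20)
        m = 0.5 * x + rng.normal(0, 1, 40)
        y = 0.4 * m + rng.normal(0, 1, 40)
        a = mediate(x, m, y, n_boot=50, seed=1)
        b = mediate(x, m * 1000.0, y, n_boot=50, seed=1)
        for key in ("a", "b", "c_prime", "indirect"):
            assert a[key].estimate == pytest.approx(b[key].estimate, abs=1e-9)

    def test_full_mediation_recovery(self):
        rng = np.random.default_rng(5)
        n = 400
        x = np.repeat([0.0, 1.0], n // 2)
        m = 1.0 * x + rng.normal(0, 1, n)
        y = 0.8 * m + rng.normal(0, 0.5, n)
        res = mediate(x, m, y, n_boot=2000, seed=2)
        assert abs(res["c_prime"].estimate) < 0.15
        lo, hi = res["indirect"].ci
        assert lo <= res["a"].estimate * res["b"].estimate <= hi
        assert lo > 0.0  # indirect path clearly positive

    def test_collinear_mediator_rejected(self):
        x = np.repeat([0.0, 1.0], 10)
        with pytest.raises(np.linalg.LinAlgError):
            mediate(x, x.copy(), np.random.default_rng(0).normal(size=20))

    def test_zero_variance_rejected(self):
        x = np.repeat([0.0, 1.0], 10)
        with pytest.raises(ValueError):
            mediate(x, np.ones(20), np.arange(20.0))


class TestPower:
    def test_monotone_in_n(self):
        spec = PowerSpec()
        powers = [achieved_power_rm_anova(n, spec) for n in range(4, 60, 4)]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))

    def test_returned_n_is_minimal(self):
        spec = PowerSpec(f=0.25, power=0.9)
        n = apriori_n_rm_anova(spec)
        assert achieved_power_rm_anova(n, spec) >= spec.power
        assert achieved_power_rm_anova(n - 1, spec) < spec.power

    def test_independent_noncentral_f_evaluation(self):
        from scipy import stats as sps

        spec = PowerSpec()
        n = 24
        lam = n * spec.f**2 * (2 / (1 - spec.corr))
        fcrit = sps.f.isf(0.05, 1, n - 1)
        assert achieved_power_rm_anova(n, spec) == pytest.approx(
            sps.ncf.sf(fcrit, 1, n - 1, lam), rel=1e-12
        )

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(f=0.0)
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5)
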