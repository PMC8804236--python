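import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rvcpipe import (
    count_nhae,
    fit_linear_predictor,
    ks_normality,
    mauchly_test,
    posthoc_matrix,
    rm_anova,
    screen_correlation,
    sex_effect_check,
)
from rvcpipe.stats import TestResult as StatResult
from rvcpipe.stats import (
    RANOVA_SESSIONS,
    bonferroni,
    complete_cases,
    paired_t,
    pearson_r,
    unpaired_t,
)


def long_rtvc(values_by_session, tissue="GM", group="CSA", sex=None):
    """values_by_session: {session: array over athletes A0..A(n-1)}."""
    rows = []
    for s, vals in values_by_session.items():
        for j, v in enumerate(vals):
            rows.append(
                {
                    "athlete_id": f"A{j}",
                    "group": group,
                    "sex": sex[j] if sex else ("M" if j % 2 else "F"),
                    "sport": "football",
                    "session": s,
                    "tissue": tissue,
                    "rtvc": float(v),
                }
            )
    return pd.DataFrame(rows)


class TestBonferroni:
    def test_correction_arithmetic(self):
        res = bonferroni(StatResult("t", 1.0, (5,), 0.01), 6)
        assert res.p_corrected == pytest.approx(0.06)
        assert not res.significant

    def test_capped_at_one_and_monotone(self):
        res = bonferroni(StatResult("t", 1.0, (5,), 0.4), 6)
        assert res.p_corrected == 1.0
        assert res.p_corrected >= res.p_raw


class TestTTests:
    def test_identical_groups_give_t0_p1(self):
        res = unpaired_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_groups_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            unpaired_t(np.array([0.0, 0, 0]), np.array([1.0, 1, 1]))

    def test_pooled_t_matches_textbook_formula(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, size=int(rng.integers(4, 12)))
            y = rng.normal(0.3, 1.4, size=int(rng.integers(4, 12)))
            res = unpaired_t(x, y)
            nx, ny = len(x), len(y)
            sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
            t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
            assert res.statistic == pytest.approx(t_hand, rel=1e-10)
            assert res.p_raw == pytest.approx(
                2 * sps.t.sf(abs(t_hand), nx + ny - 2), rel=1e-10
            )

    def test_paired_t_matches_textbook_formula(self, rng):
        x = rng.normal(0, 1, 4)
        y = x + rng.normal(0.5, 0.3, 4)
        res = paired_t(x, y)
        d = y - x
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_hand, rel=1e-10)

    def test_sex_effect_runs_per_tissue(self, rng):
        df = long_rtvc(
            {"Retest": rng.normal(0, 0.01, 10)},
            tissue="GM",
            group="NCA",
            sex=["M"] * 5 + ["F"] * 5,
        )
        res = sex_effect_check(df)
        assert set(res) == {"GM"}
        assert res["GM"].df[0] == 8


class TestMauchly:
    def test_two_sessions_vacuous(self, rng):
        df = long_rtvc({"In1": rng.normal(size=6), "In2": rng.normal(size=6)})
        res = mauchly_test(df, sessions=("In1", "In2"))
        assert res.statistic == 1.0 and res.p_raw == 1.0

    def test_w_in_unit_interval(self, rng):
        df = long_rtvc({s: rng.normal(size=12) for s in RANOVA_SESSIONS})
        res = mauchly_test(df)
        assert 0.0 < res.statistic <= 1.0

    def test_too_few_subjects_rejected(self, rng):
        df = long_rtvc({s: rng.normal(size=3) for s in RANOVA_SESSIONS})
        with pytest.raises(ValueError, match="subjects"):
            mauchly_test(df)

    def test_near_one_under_compound_symmetry(self, rng):
        """Compound-symmetric covariance satisfies sphericity, so W -> 1
        at large n."""
        n, k = 4000, 4
        shared = rng.normal(0, 1.0, size=(n, 1))
        x = shared + rng.normal(0, 1.0, size=(n, k))
        df = long_rtvc({s: x[:, i] for i, s in enumerate(RANOVA_SESSIONS)})
        res = mauchly_test(df)
        assert res.statistic > 0.995

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(20):
            n = int(rng.integers(8, 20))
            x = rng.normal(size=(n, 4)) @ rng.normal(size=(4, 4))
            df = long_rtvc({s: x[:, i] for i, s in enumerate(RANOVA_SESSIONS)})
            res = mauchly_test(df)
            long = df.rename(columns={"rtvc": "y"})
            ref = pingouin.sphericity(
                long, dv="y", within="session", subject="athlete_id"
            )
            assert res.statistic == pytest.approx(ref.W, rel=1e-8)
            assert res.p_raw == pytest.approx(ref.pval, rel=1e-6, abs=1e-12)


class TestKsNormality:
    def test_d_matches_brute_force_ecdf_gap(self):
        """D equals the max gap between the ECDF and the fitted normal CDF,
        computed by hand at the jump points."""
        x = np.array([-1.0, 0.2, 0.5, 1.1, 2.0])
        res = ks_normality(x)
        mu, sd = x.mean(), x.std(ddof=1)
        xs = np.sort(x)
        n = len(x)
        cdf = sps.norm.cdf(xs, mu, sd)
        d_hand = max(
            max(abs((i + 1) / n - c) for i, c in enumerate(cdf)),
            max(abs(i / n - c) for i, c in enumerate(cdf)),
        )
        assert res.statistic == pytest.approx(d_hand, rel=1e-10)

    def test_bimodal_input_rejected_strongly(self, rng):
        x = np.concatenate([rng.normal(-4, 0.3, 500), rng.normal(4, 0.3, 500)])
        assert ks_normality(x).p_raw < 1e-3

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(10))


class TestRmAnova:
    def test_full_cohort_degrees_of_freedom(self, rng):
        df = long_rtvc({s: rng.normal(size=57) for s in RANOVA_SESSIONS})
        res = rm_anova(df)
        assert res.df == (3, 168)

    def test_constant_subjects_give_f0(self):
        df = long_rtvc({s: np.array([0.1, 0.4, -0.2]) for s in RANOVA_SESSIONS})
        res = rm_anova(df)
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_hand_partition_3x3(self):
        """3 subjects x 3 sessions against a hand sums-of-squares partition."""
        x = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 3.0], [0.0, 2.0, 5.0]])
        sessions = ("In1", "In2", "Post1")
        df = long_rtvc({s: x[:, i] for i, s in enumerate(sessions)})
        res = rm_anova(df, sessions=sessions)
        grand = x.mean()
        ss_sub = 3 * ((x.mean(axis=1) - grand) ** 2).sum()
        ss_ses = 3 * ((x.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((x - grand) ** 2).sum() - ss_sub - ss_ses
        f_hand = (ss_ses / 2) / (ss_err / 4)
        assert res.statistic == pytest.approx(f_hand, rel=1e-10)

    def test_missing_session_lists_athlete(self, rng):
        df = long_rtvc({s: rng.normal(size=5) for s in RANOVA_SESSIONS})
        df = df[~((df.athlete_id == "A2") & (df.session == "Post1"))]
        with pytest.raises(ValueError, match="A2"):
            rm_anova(df)
        comp = complete_cases(df, RANOVA_SESSIONS)
        assert comp.athlete_id.nunique() == 4
        rm_anova(comp)  # complete cases pass

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(20):
            n = int(rng.integers(5, 15))
            x = rng.normal(size=(n, 4)) + rng.normal(size=(1, 4))
            df = long_rtvc({s: x[:, i] for i, s in enumerate(RANOVA_SESSIONS)})
            res = rm_anova(df)
            ref = pingouin.rm_anova(
                df, dv="rtvc", within="session", subject="athlete_id"
            )
            pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
            assert res.statistic == pytest.approx(ref["F"].item(), rel=1e-8)
            assert res.p_raw == pytest.approx(ref[pcol].item(), rel=1e-6)


class TestPosthoc:
    def _cohorts(self, rng, n_csa=10, n_nca=6):
        csa = long_rtvc(
            {s: rng.normal(0.01 * i, 0.02, n_csa) for i, s in enumerate(RANOVA_SESSIONS)}
        )
        nca = long_rtvc({"Retest": rng.normal(0, 0.02, n_nca)}, group="NCA")
        return csa, nca

    def test_family_sizes_and_structure(self, rng):
        csa, nca = self._cohorts(rng)
        matrix = posthoc_matrix(csa, nca, "GM")
        frame = matrix.to_frame()
        within = frame[frame.kind == "within"]
        across = frame[frame.kind == "across"]
        assert len(within) == 6 and (within.m == 6).all()
        assert len(across) == 4 and (across.m == 4).all()

    def test_sign_convention_later_minus_earlier(self):
        csa = long_rtvc({"In1": [0.0, 0.001, -0.001], "In2": [0.011, 0.01, 0.009],
                         "Post1": [0.0, 0.001, -0.001], "Post2": [0.0, 0.002, -0.002]})
        nca = long_rtvc({"Retest": [0.0, 0.001, -0.001, 0.0005]}, group="NCA")
        frame = posthoc_matrix(csa, nca, "GM").to_frame()
        row = frame[frame.comparison == "In2 vs In1"]
        assert row.mean_diff_pct.item() == pytest.approx(1.0)

    def test_identical_sessions_null(self, rng):
        vals = rng.normal(0, 0.01, 8)
        csa = long_rtvc({s: vals for s in RANOVA_SESSIONS})
        nca = long_rtvc({"Retest": rng.normal(0, 0.01, 6)}, group="NCA")
        frame = posthoc_matrix(csa, nca, "GM").to_frame()
        within = frame[frame.kind == "within"]
        assert (within.mean_diff_pct.abs() < 1e-12).all()
        assert (within.p_bonf == 1.0).all()

    def test_insufficient_pairs_marked_unavailable(self, rng):
        csa = long_rtvc({"In1": rng.normal(size=1), "In2": rng.normal(size=1),
                         "Post1": rng.normal(size=1), "Post2": rng.normal(size=1)})
        nca = long_rtvc({"Retest": rng.normal(size=6)}, group="NCA")
        frame = posthoc_matrix(csa, nca, "GM").to_frame()
        assert frame[frame.kind == "within"].note.str.contains("unavailable").all()


def exposure_from_counts(counts_by_athlete, thresholds=(20, 50, 95)):
    """Build an exposure matrix where every event precedes In1."""
    rows = []
    for athlete, ptas in counts_by_athlete.items():
        for i, p in enumerate(ptas):
            rows.append(
                {
                    "athlete_id": athlete,
                    "timestamp": pd.Timestamp("2023-08-05") + pd.Timedelta(minutes=i),
                    "pta_g": p,
                    "window_id": "W0",
                    "sensor": "HITS",
                }
            )
    ev = pd.DataFrame(rows)
    return count_nhae(
        ev,
        {"In1": "2023-08-31", "In2": "2023-09-30", "Post1": "2023-10-30"},
        thresholds=thresholds,
        athletes=list(counts_by_athlete),
    )


class TestScreen:
    def test_perfectly_linear_rtvc_gives_r_one(self):
        counts = {f"A{j}": [30.0] * (j + 1) for j in range(6)}
        matrix = exposure_from_counts(counts, thresholds=(20, 25))
        rtvc = long_rtvc({"In1": [0.001 * (j + 1) for j in range(6)]}, tissue="dCSF")
        cells = screen_correlation(rtvc, matrix, sessions=("In1",))
        for c in cells:
            assert not c.degenerate
            assert c.r == pytest.approx(1.0)

    def test_zero_variance_cell_degenerate_and_out_of_family(self):
        counts = {f"A{j}": [30.0] * (j + 1) for j in range(6)}
        matrix = exposure_from_counts(counts, thresholds=(20, 95))
        rtvc = long_rtvc({"In1": [0.001 * j for j in range(6)]}, tissue="dCSF")
        cells = screen_correlation(rtvc, matrix, sessions=("In1",))
        degen = {c.threshold_g: c.degenerate for c in cells}
        assert degen == {20.0: False, 95.0: True}
        assert all(c.m == 1 for c in cells)  # family excludes the degenerate cell

    def test_r_matches_product_moment_formula(self):
        x = np.array([1.0, 2, 3, 5, 8])
        y = np.array([0.2, 0.1, 0.45, 0.8, 0.65])
        res = pearson_r(x, y)
        r_hand = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert res.statistic == pytest.approx(r_hand, rel=1e-12)


class TestLinearPredictor:
    def test_exact_line_zero_width_band(self):
        x = np.arange(5, dtype=float)
        fit = fit_linear_predictor(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        lo, hi = fit.confidence_band(x)
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-10)

    def test_band_halfwidth_at_xbar_closed_form(self, rng):
        x = rng.uniform(0, 10, 30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        fit = fit_linear_predictor(x, y)
        lo, hi = fit.confidence_band(np.array([x.mean()]))
        t = sps.t.ppf(0.975, len(x) - 2)
        assert (hi - lo).item() / 2 == pytest.approx(t * fit.sigma / np.sqrt(len(x)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_linear_predictor(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
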