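"""Delineation statistics: t tests, Fisher combination, table assembly, classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from etpheno import reference
from etpheno.delineation_stats import (
    classification_benchmark,
    classify_sample,
    combined_from_published,
    delineation_table,
    fisher_combined,
    fold_change,
    paired_t_test,
    pairwise_r_squared,
    pairwise_regression,
    significance_label,
    welch_t_test,
)
from etpheno.errors import DegenerateFitError, InputError, InvalidParametersError


class TestPairedT:
    def test_identical_samples(self):
        t, df, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 2 and p == 1.0

    def test_constant_nonzero_difference(self):
        t, _, p = paired_t_test([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isinf(t) and p == 0.0

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            paired_t_test([1.0, 2.0], [1.0])

    def test_against_sign_flip_enumeration_oracle(self, rng):
        """The t reference closely tracks the exact 2^8 sign-flip null at n=8."""
        signs = np.array(list(itertools.product([1, -1], repeat=8)))
        deviations = []
        for _ in range(200):
            d = rng.normal(0.4, 1.0, 8)
            t_obs, _, p_t = paired_t_test(d, np.zeros(8))
            flipped = signs * d
            t_perm = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / math.sqrt(8))
            p_perm = float(np.mean(np.abs(t_perm) >= abs(t_obs) - 1e-12))
            deviations.append((p_t, p_perm))
        p_ts, p_perms = map(np.array, zip(*deviations))
        assert np.mean(np.abs(p_ts - p_perms)) < 0.05
        assert stats.spearmanr(p_ts, p_perms).statistic > 0.95


class TestWelchT:
    def test_identical_groups(self):
        t, _, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_equal_variance_equal_n_df(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10) * x.std(ddof=1) / rng.normal(0, 1, 10).std(ddof=1)
        # construct exactly equal sample variances
        y = (y - y.mean()) / y.std(ddof=1) * x.std(ddof=1) + 1.0
        _, df, _ = welch_t_test(x, y)
        assert df == pytest.approx(18.0, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_p_matches_quadrature_oracle(self, rng):
        """Two-tailed p equals the numerically integrated t tail at the Welch df."""
        def t_pdf(x, df):
            c = math.exp(math.lgamma((df + 1) / 2) - math.lgamma(df / 2)) / math.sqrt(df * math.pi)
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        for _ in range(20):
            x = rng.normal(0.0, 1.0, 8)
            y = rng.normal(0.5, 2.5, 13)
            t, df, p = welch_t_test(x, y)
            tail, _ = integrate.quad(t_pdf, abs(t), np.inf, args=(df,))
            assert p == pytest.approx(2 * tail, rel=1e-6, abs=1e-12)


class TestFoldChange:
    @pytest.mark.parametrize(
        "hi, lo, expected",
        [
            (991.4, 224.125, 4.42),    # formalin tumor rho_B
            (195.70, 56.39, 3.47),     # formalin normal rho_B
            (1980.87, 411.25, 4.82),   # deparaffinized tumor rho_B
            (3131.88, 753.05, 4.16),   # deparaffinized tumor rho_S
        ],
    )
    def test_published_group_fold_changes(self, hi, lo, expected):
        assert fold_change(hi, lo) == pytest.approx(expected, abs=5e-3)

    def test_identity_and_errors(self):
        assert fold_change(3.0, 3.0) == 1.0
        with pytest.raises(InvalidParametersError):
            fold_change(1.0, 0.0)


class TestFisherCombined:
    def test_identity_for_single_p(self):
        for p in (1e-6, 0.04, 0.5, 1.0):
            assert fisher_combined([p]) == pytest.approx(p, rel=1e-12)

    def test_all_ones(self):
        assert fisher_combined([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_published_combination_cells(self):
        # all-three-parameter columns of the published table
        assert fisher_combined([8.7e-3, 2.89e-4, 3.21e-4]) == pytest.approx(1.95e-7, rel=0.02)
        assert fisher_combined([1.15e-3, 8e-3, 5.15e-3]) == pytest.approx(7.6e-6, rel=0.02)
        assert fisher_combined([1.4e-2, 7.44e-3, 6e-3]) == pytest.approx(7.3e-5, rel=0.02)
        assert fisher_combined([1.15e-3, 8e-3]) == pytest.approx(1.16e-4, rel=0.02)
        assert fisher_combined([1.3e-3, 2.15e-2, 1.49e-3]) == pytest.approx(6.74e-6, rel=0.02)

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=2, max_size=6))
    @settings(derandomize=True, deadline=None)
    def test_exchangeable_and_monotone(self, ps):
        base = fisher_combined(ps)
        assert fisher_combined(list(reversed(ps))) == pytest.approx(base, rel=1e-9)
        shrunk = [ps[0] * 0.5] + ps[1:]
        assert fisher_combined(shrunk) <= base + 1e-15

    def test_invalid_probability_rejected(self):
        with pytest.raises(InvalidParametersError):
            fisher_combined([0.0, 0.5])
        with pytest.raises(InvalidParametersError):
            fisher_combined([1.5])

    def test_null_uniformity(self):
        """Combining m uniform p-values gives a uniform combined p (KS)."""
        rng = np.random.default_rng(2718)
        for m in (2, 3):
            u = rng.uniform(size=(100_000, m))
            chi2 = -2.0 * np.log(u).sum(axis=1)
            combined = stats.chi2.sf(chi2, df=2 * m)
            ks = stats.kstest(combined, "uniform")
            assert ks.pvalue > 0.01


class TestRegressionAndLabels:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = pairwise_regression(x, 3.0 * x - 2.0)
        assert (slope, intercept, r2) == pytest.approx((3.0, -2.0, 1.0))

    def test_independent_variables_r2_near_zero(self, rng):
        x = rng.normal(size=4000)
        y = rng.normal(size=4000)
        *_, r2 = pairwise_regression(x, y)
        assert r2 < 0.01

    def test_against_normal_equations_oracle(self, rng):
        x = rng.normal(2.0, 3.0, 50)
        y = 1.5 * x + rng.normal(0.0, 1.0, 50)
        slope, intercept, r2 = pairwise_regression(x, y)
        n = x.size
        a = np.array([[n, x.sum()], [x.sum(), (x**2).sum()]])
        b = np.array([y.sum(), (x * y).sum()])
        c0, c1 = np.linalg.solve(a, b)
        sse = ((y - c0 - c1 * x) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(c1, rel=1e-10)
        assert intercept == pytest.approx(c0, rel=1e-10)
        assert r2 == pytest.approx(1 - sse / sst, rel=1e-10)

    def test_degenerate_x(self):
        with pytest.raises(DegenerateFitError):
            pairwise_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize(
        "p, label",
        [
            (1.95e-7, "***"), (5e-4, "***"), (1e-3, "**"), (5e-3, "**"),
            (1e-2, "*"), (0.04, "*"), (0.05, "ns"), (0.5, "ns"), (1.0, "ns"),
        ],
    )
    def test_significance_bands(self, p, label):
        assert significance_label(p) == label

    def test_label_rejects_out_of_range(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(InvalidParametersError):
                significance_label(bad)


def _profile_frame(rng, n=12, tumor_shift=0.0, temp_shift=0.0, preparation="formalin_fixed"):
    """Synthetic endpoint profile frame with controllable group/temperature effects."""
    rows = []
    for group in ("tumor", "normal"):
        for i in range(n):
            base = {
                "rho_b_ohm_cm": rng.lognormal(5.0, 0.3),
                "rho_s_ohm_sq": rng.lognormal(6.0, 0.3),
                "k_w_m_k": rng.lognormal(-1.0, 0.2),
            }
            for temp in (25.0, 37.0):
                mult = 1.0
                if group == "tumor":
                    mult *= 1.0 + tumor_shift
                if temp == 37.0:
                    mult *= 1.0 + temp_shift
                rows.append(
                    {
                        "sample_id": f"{group}{i}",
                        "patient_id": f"p{i}",
                        "group": group,
                        "preparation": preparation,
                        "temperature_c": temp,
                        **{c: v * mult * (1 + 0.05 * rng.standard_normal()) for c, v in base.items()},
                        "delta_t_k": 5.0,
                        "q_w": 0.01,
                        "missing": False,
                    }
                )
    return pd.DataFrame(rows)


class TestDelineationTable:
    def test_published_combined_cells_reproduced(self):
        table = combined_from_published()
        expectations = {
            ("formalin_fixed", "rho_b+rho_s+k", "T37_vs_N37"): 1.95e-7,
            ("deparaffinized", "rho_b+rho_s+k", "T37_vs_T25"): 7.6e-6,
            ("formalin_fixed", "rho_b+rho_s+k", "T37_vs_T25"): 7.3e-5,
            ("deparaffinized", "rho_b+rho_s", "T37_vs_T25"): 1.16e-4,
            ("deparaffinized", "rho_b+rho_s+k", "T37_vs_N37"): 6.74e-6,
        }
        for (prep, pset, contrast), expected in expectations.items():
            row = table[
                (table.preparation == prep)
                & (table.parameter_set == pset)
                & (table.contrast == contrast)
            ]
            assert row.p_value.iloc[0] == pytest.approx(expected, rel=0.02)
            assert row.label.iloc[0] == "***"

    def test_all_published_combination_cells_within_input_rounding(self):
        table = combined_from_published()
        printed = {
            ("deparaffinized", "rho_b+rho_s"): [1.40e-1, 1.16e-4, 1.64e-1, 3.21e-4],
            ("deparaffinized", "rho_b+k"): [1.36e-1, 7.72e-5, 1.4e-3, 2.74e-5],
            ("deparaffinized", "rho_s+k"): [3.06e-1, 4.57e-4, 1e-3, 3.64e-4],
            ("deparaffinized", "rho_b+rho_s+k"): [1.54e-1, 7.6e-6, 1.6e-3, 6.74e-6],
            ("formalin_fixed", "rho_b+rho_s"): [7.24e-2, 1.1e-3, 4.94e-2, 3.51e-5],
            ("formalin_fixed", "rho_b+k"): [1.47e-2, 8.72e-4, 7.6e-4, 3.85e-5],
            ("formalin_fixed", "rho_s+k"): [2.08e-2, 4.92e-4, 1.2e-3, 1.6e-6],
            ("formalin_fixed", "rho_b+rho_s+k"): [1.24e-2, 7.3e-5, 7.12e-4, 1.95e-7],
        }
        for (prep, pset), vals in printed.items():
            for contrast, expected in zip(reference.CONTRASTS, vals):
                got = table[
                    (table.preparation == prep)
                    & (table.parameter_set == pset)
                    & (table.contrast == contrast)
                ].p_value.iloc[0]
                # inputs are printed at 2-3 significant figures; half-ulp at
                # 2 s.f. allows up to ~5% relative deviation
                assert got == pytest.approx(expected, rel=0.05)

    def test_structure_28_cells_per_preparation(self, rng):
        table = delineation_table(_profile_frame(rng))
        assert len(table) == 28
        assert set(table.contrast) == set(reference.CONTRASTS)
        assert table.parameter_set.nunique() == 7

    def test_combined_cells_consistent_with_own_singles(self, rng):
        """Audit: every combination cell equals Fisher over the table's own singles."""
        table = delineation_table(_profile_frame(rng, tumor_shift=1.0, temp_shift=2.0))
        for contrast in reference.CONTRASTS:
            col = table[table.contrast == contrast].set_index("parameter_set").p_value
            for pset in ("rho_b+rho_s", "rho_b+k", "rho_s+k", "rho_b+rho_s+k"):
                singles = [col[p] for p in pset.split("+")]
                assert col[pset] == pytest.approx(fisher_combined(singles), rel=1e-12)

    def test_single_group_flags_between_group_cells(self, rng):
        frame = _profile_frame(rng)
        frame = frame[frame.group == "tumor"]
        table = delineation_table(frame)
        between = table[table.contrast.isin(["T25_vs_N25", "T37_vs_N37"])]
        assert (between.label == "na").all()
        within = table[(table.contrast == "T37_vs_T25") & (table.parameter_set == "rho_b")]
        assert np.isfinite(within.p_value.iloc[0])

    def test_null_cohort_false_positive_rate_near_alpha(self):
        """No group or temperature effect: single-parameter cells reject at ~5%."""
        rng = np.random.default_rng(31)
        n_sig = n_tot = 0
        for _ in range(20):
            table = delineation_table(_profile_frame(rng))
            singles = table[table.parameter_set.isin(["rho_b", "rho_s", "k"])]
            n_sig += (singles.p_value < 0.05).sum()
            n_tot += len(singles)
        rate = n_sig / n_tot
        assert 0.005 < rate < 0.12

    def test_sign_pattern_of_published_table_reproduced_in_majority_of_seeds(self):
        """Tumor resistivity temperature contrasts significant, normal ones weaker."""
        from etpheno.io_cli import RunConfig, infer_profiles
        from etpheno.synthetic_study import generate_study

        tumor_all_sig, order_ok, normal_ns = [], [], []
        for seed in range(12):
            cfg = RunConfig(seed=seed)
            truth, meas = generate_study(cfg.study_config())
            table = delineation_table(infer_profiles(meas, truth, cfg))
            sig, order, ns = [], [], 0
            for prep in reference.PREPARATIONS:
                for param in ("rho_b", "rho_s"):
                    sub = table[(table.preparation == prep) & (table.parameter_set == param)]
                    p_t = sub[sub.contrast == "T37_vs_T25"].p_value.iloc[0]
                    p_n = sub[sub.contrast == "N37_vs_N25"].p_value.iloc[0]
                    sig.append(p_t < 0.05)
                    order.append(p_n > p_t)
                    ns += p_n >= 0.05
            tumor_all_sig.append(all(sig))
            order_ok.append(sum(order) >= 3)
            normal_ns.append(ns >= 2)
        assert sum(tumor_all_sig) >= 7
        assert sum(order_ok) >= 7
        assert sum(normal_ns) >= 7


class TestClassification:
    def _noiseless_profiles(self, group, preparation="formalin_fixed", repeats=3):
        from etpheno.inference import build_profile
        from etpheno.synthetic_study import (
            SampleGeometry,
            StudyConfig,
            TissueTruth,
            forward_measurements,
            group_parameters,
        )

        gp = group_parameters(preparation, group)
        cfg = StudyConfig(noise_cv=0.0, temperature_setpoints=(25.0, 37.0))
        profiles = []
        for r in range(repeats):
            truth = TissueTruth(
                sample_id=f"s-r{r}", patient_id="p", group=group, preparation=preparation,
                geometry=SampleGeometry(),
                rho_b_25=gp.rho_b_25_mean, rho_s_25=gp.rho_s_25_mean, k_25=gp.k_25_mean,
                fold_rho_b=gp.fold_rho_b, fold_rho_s=gp.fold_rho_s, fold_k=gp.fold_k,
            )
            recs = forward_measurements(truth, cfg)
            profiles.append(build_profile(recs, cfg.chip, cfg.calib, truth.geometry))
        return profiles

    def test_noiseless_group_mean_samples(self):
        call_t, ev_t = classify_sample(self._noiseless_profiles("tumor"))
        call_n, ev_n = classify_sample(self._noiseless_profiles("normal"))
        assert call_t == "tumor" and ev_t["fold_rho_b"] == pytest.approx(4.42, abs=5e-3)
        assert call_n == "normal" and ev_n["fold_rho_b"] == pytest.approx(3.47, abs=5e-3)

    def test_requires_two_repeats(self):
        with pytest.raises(InputError):
            classify_sample(self._noiseless_profiles("tumor", repeats=1))

    def test_noisy_benchmark_sensitivity_specificity(self):
        res = classification_benchmark(n_per_class=100, seed=17)
        assert res["sensitivity"] > 0.9
        assert res["specificity"] > 0.9


class TestTypeIError:
    def test_both_tests_hold_alpha_under_gaussian_null(self):
        """Type-I error at alpha = 0.05 within [0.04, 0.06] over 1e4 replicates."""
        rng = np.random.default_rng(99)
        n_rep = 10_000
        # paired t, n = 10 pairs (vectorised)
        d = rng.normal(size=(n_rep, 10))
        t = d.mean(1) / (d.std(1, ddof=1) / math.sqrt(10))
        p_paired = 2 * stats.t.sf(np.abs(t), 9)
        rate = np.mean(p_paired < 0.05)
        assert 0.04 < rate < 0.06
        # Welch, unequal variance and n
        x = rng.normal(0.0, 1.0, size=(n_rep, 10))
        y = rng.normal(0.0, 3.0, size=(n_rep, 14))
        v1, v2 = x.var(1, ddof=1) / 10, y.var(1, ddof=1) / 14
        tw = (x.mean(1) - y.mean(1)) / np.sqrt(v1 + v2)
        dfw = (v1 + v2) ** 2 / (v1**2 / 9 + v2**2 / 13)
        p_welch = 2 * stats.t.sf(np.abs(tw), dfw)
        rate_w = np.mean(p_welch < 0.05)
        assert 0.04 < rate_w < 0.06
        # the vectorised nulls match the scalar implementations
        ti, dfi, pi = paired_t_test(d[0], np.zeros(10))
        assert pi == pytest.approx(p_paired[0], rel=1e-9)
        tw0, dfw0, pw0 = welch_t_test(x[0], y[0])
        assert pw0 == pytest.approx(p_welch[0], rel=1e-9)


class TestPairwiseRSquared:
    def test_scopes_and_groups_present(self, rng):
        frame = _profile_frame(rng, tumor_shift=1.0)
        r2 = pairwise_r_squared(frame)
        assert set(r2.scope) == {"pooled", "formalin_fixed"}
        assert set(r2.group) == {"tumor", "normal"}
        assert len(r2[r2.scope == "pooled"]) == 6  # 3 pairs x 2 groups
        assert ((r2.r_squared >= 0) & (r2.r_squared <= 1)).all()
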