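"""Binned regression training: bin partitioning, per-bin fits, coefficient
functions, grouped ABSOLV fits and selector profiling."""

import numpy as np
import pandas as pd
import pytest

import flexsol as fx
from flexsol.train import fit_bin_gse, fit_c_functions, profile_bins


def make_gse_frame(rng, n, c0, c1, c2, noise=0.0, phi=5.0):
    clogp = rng.uniform(-2, 6, n)
    mp = rng.uniform(26, 300, n)
    logs0 = c0 + c1 * clogp + c2 * (mp - 25) / 100 + noise * rng.normal(size=n)
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n)],
            "clogp": clogp,
            "mp_c": mp,
            "phi": phi,
            "abraham_b": 1.0,
            "logs0_obs": logs0,
        }
    )


class TestBinByKey:
    def test_equal_count_exact_division(self, rng):
        df = make_gse_frame(rng, 40, 0.5, -1.0, -1.0)
        df["phi"] = rng.uniform(0.5, 40, 40)
        bins = fx.bin_by_key(df, key="phi", n_bins=20)
        assert [len(b) for b in bins] == [2] * 20

    def test_key_means_strictly_increasing(self, rng):
        df = make_gse_frame(rng, 200, 0.5, -1.0, -1.0)
        df["phi"] = rng.uniform(1, 100, 200)
        bins = fx.bin_by_key(df, key="phi", n_bins=20)
        means = [b["phi"].mean() for b in bins]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_partition_is_exhaustive_with_duplicate_keys(self, rng):
        df = make_gse_frame(rng, 60, 0.5, -1.0, -1.0)
        df["phi"] = np.repeat([1.0, 2.0, 3.0], 20)  # heavy ties at bin edges
        bins = fx.bin_by_key(df, key="phi", n_bins=4)
        ids = sorted(pd.concat(bins)["id"])
        assert ids == sorted(df["id"])

    def test_insufficient_records_raise(self, rng):
        df = make_gse_frame(rng, 10, 0.5, -1.0, -1.0)
        with pytest.raises(fx.TrainingError):
            fx.bin_by_key(df, n_bins=20)


class TestFitBinGse:
    def test_noiseless_recovery(self, rng):
        df = make_gse_frame(rng, 50, 0.5, -1.0, -1.0)
        c = fit_bin_gse(df)
        assert c == pytest.approx((0.5, -1.0, -1.0), abs=1e-8)

    def test_permutation_invariance(self, rng):
        df = make_gse_frame(rng, 50, 0.2, -0.8, -0.5, noise=0.3)
        shuffled = df.sample(frac=1.0, random_state=1)
        assert fit_bin_gse(df) == pytest.approx(fit_bin_gse(shuffled))

    def test_rank_deficient_design_raises(self):
        df = pd.DataFrame(
            {"clogp": [1.0] * 5, "mp_c": [100.0] * 5, "logs0_obs": [0.1] * 5}
        )
        with pytest.raises(fx.TrainingError, match="rank-deficient"):
            fit_bin_gse(df, label="bin 3")

    def test_noisy_recovery_is_unbiased(self, rng):
        """Monte-Carlo: mean recovered clogP slope near truth at sigma = 0.5."""
        c1s = [
            fit_bin_gse(make_gse_frame(rng, 1000, 0.5, -1.0, -1.0, noise=0.5))[1]
            for _ in range(40)
        ]
        assert np.mean(c1s) == pytest.approx(-1.0, abs=0.05)


class TestFitCFunctions:
    def test_noiseless_inversion_of_builtin_parameters(self, bundle):
        x = np.arange(1.0, 21.0)
        c0, c1, c2 = fx.c_coefficients(x, bundle.flex_params)
        points = list(zip(x, c0, c1, c2))
        params, diag = fit_c_functions(points)
        truth = np.array(bundle.flex_params.as_tuple())
        rel = np.abs(np.array(params.as_tuple()) - truth) / np.abs(truth)
        assert rel.max() < 1e-4
        assert diag["c0"]["rmse"] < 1e-8

    def test_linear_subproblem_equals_ols(self, bundle, rng):
        x = np.arange(1.0, 16.0)
        c0, c1, _ = fx.c_coefficients(x, bundle.flex_params)
        c2 = 0.3 * x - 1.2 + rng.normal(scale=0.05, size=len(x))
        params, _ = fit_c_functions(list(zip(x, c0, c1, c2)))
        slope, intercept = np.polyfit(x, c2, 1)
        assert params.b7 == pytest.approx(slope)
        assert params.b6 == pytest.approx(intercept)

    def test_invariant_to_bin_ordering(self, bundle, rng):
        x = np.arange(1.0, 21.0)
        c0, c1, c2 = fx.c_coefficients(x, bundle.flex_params)
        points = list(zip(x, c0, c1, c2))
        shuffled = [points[i] for i in rng.permutation(len(points))]
        a, _ = fit_c_functions(points)
        b, _ = fit_c_functions(shuffled)
        assert a.as_tuple() == pytest.approx(b.as_tuple())

    def test_noisy_recovery_median_error(self, bundle, rng):
        """20 noisy bins, 25 replicates: median relative error <= 10%."""
        x = np.arange(1.0, 21.0)
        c0, c1, c2 = fx.c_coefficients(x, bundle.flex_params)
        truth = np.array(bundle.flex_params.as_tuple())
        errs = []
        for _ in range(25):
            pts = list(
                zip(
                    x,
                    c0 + rng.normal(scale=0.1, size=20),
                    c1 + rng.normal(scale=0.02, size=20),
                    c2 + rng.normal(scale=0.05, size=20),
                )
            )
            p, _ = fit_c_functions(pts)
            errs.append(np.abs(np.array(p.as_tuple()) - truth) / np.abs(truth))
        assert np.median(np.vstack(errs)) <= 0.10

    def test_too_few_bins_raise(self, bundle):
        x = np.arange(1.0, 7.0)
        c0, c1, c2 = fx.c_coefficients(x, bundle.flex_params)
        with pytest.raises(fx.TrainingError):
            fit_c_functions(list(zip(x, c0, c1, c2)))


class TestGroupedAbsolv:
    def make_absolv_frame(self, rng, n, group, coef, noise=0.0):
        A = rng.uniform(0, 2, n)
        B = rng.uniform(0.4, 6, n)
        S = rng.uniform(0.5, 4, n)
        E = rng.uniform(0, 4, n)
        V = rng.uniform(0.5, 6, n)
        y = (
            coef.a0 + coef.a1 * A + coef.a2 * B + coef.a3 * S
            + coef.a4 * E + coef.a5 * V + coef.a6 * A * B
            + noise * rng.normal(size=n)
        )
        return pd.DataFrame(
            {
                "id": [f"g{i}" for i in range(n)],
                "abraham_a": A, "abraham_b": B, "abraham_s": S,
                "abraham_e": E, "abraham_v": V,
                "charge_class": group.value,
                "logs0_obs": y,
            }
        )

    def test_noiseless_neutral_row_recovery(self, bundle, rng):
        coef = bundle.absolv_table[fx.ChargeGroup.NEUTRAL]
        df = self.make_absolv_frame(rng, 100, fx.ChargeGroup.NEUTRAL, coef)
        res = fx.GroupedAbsolv(df).fit()
        got = res.coefficients[fx.ChargeGroup.NEUTRAL].as_array()
        assert got == pytest.approx(coef.as_array(), abs=1e-8)
        assert set(res.unfit_groups) == set(fx.ChargeGroup) - {fx.ChargeGroup.NEUTRAL}

    def test_shuffle_invariance(self, bundle, rng):
        coef = bundle.absolv_table[fx.ChargeGroup.ACID]
        df = self.make_absolv_frame(rng, 60, fx.ChargeGroup.ACID, coef, noise=0.4)
        a = fx.GroupedAbsolv(df).fit().coefficients[fx.ChargeGroup.ACID]
        b = fx.GroupedAbsolv(df.sample(frac=1.0, random_state=7)).fit().coefficients[
            fx.ChargeGroup.ACID
        ]
        assert a.as_array() == pytest.approx(b.as_array())

    def test_noisy_b_coefficient_recovery(self, bundle, rng):
        """Monte-Carlo: mean recovered B coefficient near truth at sigma = 0.5."""
        coef = bundle.absolv_table[fx.ChargeGroup.NEUTRAL]
        a2s = [
            fx.GroupedAbsolv(
                self.make_absolv_frame(rng, 500, fx.ChargeGroup.NEUTRAL, coef, 0.5)
            )
            .fit()
            .coefficients[fx.ChargeGroup.NEUTRAL]
            .a2
            for _ in range(20)
        ]
        assert np.mean(a2s) == pytest.approx(coef.a2, abs=0.1)

    def test_all_groups_below_floor_raise(self, bundle, rng):
        coef = bundle.absolv_table[fx.ChargeGroup.NEUTRAL]
        df = self.make_absolv_frame(rng, 5, fx.ChargeGroup.NEUTRAL, coef)
        with pytest.raises(fx.TrainingError):
            fx.GroupedAbsolv(df).fit()

    def test_summary_and_table(self, bundle, rng):
        frames = [
            self.make_absolv_frame(rng, 30, g, bundle.absolv_table[g])
            for g in fx.ChargeGroup
        ]
        res = fx.GroupedAbsolv(pd.concat(frames, ignore_index=True)).fit()
        assert not res.unfit_groups
        table = res.table
        for g in fx.ChargeGroup:
            assert table[g].as_array() == pytest.approx(
                bundle.absolv_table[g].as_array(), abs=1e-8
            )
        assert "neutral" in res.summary()


class TestEndToEnd:
    def test_exact_recovery_at_zero_noise(self, bundle):
        """Discrete Phi+B levels, sigma = 0: the two-step pipeline inverts
        the generating b-parameters to machine precision."""
        cfg = fx.SimulationConfig(
            n_records=4000, seed=7, noise_sd=0.0,
            key_levels=np.linspace(1, 20, 20),
        )
        df = fx.simulate_frame(cfg)
        res = fx.FlexibleAcceptorGSE(df, n_bins=20, binning="width").fit()
        truth = np.array(bundle.flex_params.as_tuple())
        rel = np.abs(np.array(res.params.as_tuple()) - truth) / np.abs(truth)
        assert rel.max() < 1e-4

    def test_noisy_recovery(self, bundle, flexacceptor_frame):
        """sigma = 0.5, 20 quantile bins: median relative error <= 10%."""
        res = fx.FlexibleAcceptorGSE(flexacceptor_frame, n_bins=20).fit()
        truth = np.array(bundle.flex_params.as_tuple())
        rel = np.abs(np.array(res.params.as_tuple()) - truth) / np.abs(truth)
        assert np.median(rel) <= 0.10

    def test_results_predict_and_summary(self, flexacceptor_frame):
        res = fx.FlexibleAcceptorGSE(flexacceptor_frame, n_bins=20).fit()
        preds = res.predict(flexacceptor_frame.head(100))
        assert np.isfinite(preds).all()
        assert "c0(x)" in res.summary()
        # bin populations are near-equal under quantile binning
        sizes = res.bin_fits["n_entries"]
        assert sizes.max() - sizes.min() <= 1
        assert res.bin_fits["key_mean"].is_monotonic_increasing


class TestProfileBins:
    def test_generating_model_wins_every_bin(self, flexacceptor_frame):
        """Data generated from GSE(Phi,B) + noise: it is best in all bins."""
        prof = profile_bins(flexacceptor_frame, n_bins=10)
        assert (prof["best_model"] == "gse_phib").all()

    def test_rmse_matches_brute_force(self, bundle, flexacceptor_frame):
        df = flexacceptor_frame.head(2000)
        prof = profile_bins(df, n_bins=5)
        preds = fx.predict_frame(df, bundle)
        merged = df.reset_index(drop=True).join(
            preds[["logs0_gse", "logs0_absolv_grp", "logs0_gse_phib"]]
        )
        bins = fx.bin_by_key(merged, key="phi", n_bins=5)
        for i, b in enumerate(bins):
            r = b["logs0_obs"] - b["logs0_gse_phib"]
            assert prof.loc[i, "rmse_gse_phib"] == pytest.approx(
                np.sqrt(np.mean(r**2))
            )

    def test_bin_counts_sum_to_usable_records(self, flexacceptor_frame):
        df = flexacceptor_frame.head(1000).copy()
        df.loc[:49, "clogp"] = np.nan  # classic GSE unavailable for these
        prof = profile_bins(df, n_bins=8)
        assert prof["n_entries"].sum() == 950

    def test_decision_rule_from_profile(self, flexacceptor_frame):
        prof = profile_bins(flexacceptor_frame, n_bins=10)
        rule = fx.decision_rule_from_profile(prof)
        assert rule.lookup(0.5) == fx.ModelName.GSE_CLASSIC
        assert rule.lookup(50.0) == fx.ModelName.GSE_PHIB
        assert rule.lookup(5.0) in (fx.ModelName.ABSOLV_GRP, fx.ModelName.GSE_PHIB)
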