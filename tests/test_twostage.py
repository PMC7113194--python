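"""Two-stage model: transforms, inclusion rules, period weights, trajectories."""

import numpy as np
import pandas as pd
import pytest

from longreml.exceptions import DegenerateDataError
from longreml.simulate import SimulationConfig, simulate_genotypes, simulate_longitudinal_phenotypes
from longreml.twostage import (
    TraitConfig,
    apply_trait_transforms,
    estimate_period_weights,
    exclude_sparse_trait_periods,
    filter_min_measurements,
    fit_subject_trajectories,
    health_trait_panel,
)


def long_table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "period", "age", "sex", "trait", "value"])


class TestTransforms:
    def test_log_and_identity(self):
        t = long_table(
            [
                ("a", 1, 50.0, 1, "HDL", np.e**2),
                ("a", 1, 50.0, 1, "Height", 170.0),
            ]
        )
        out = apply_trait_transforms(
            t, [TraitConfig("HDL", "log"), TraitConfig("Height", "identity")]
        )
        assert out["value"].iloc[0] == pytest.approx(2.0)
        assert out["value"].iloc[1] == 170.0

    def test_non_positive_under_log_becomes_missing_with_warning(self):
        t = long_table([("a", 1, 50.0, 1, "TG", 0.0), ("b", 1, 51.0, 2, "TG", 1.0)])
        with pytest.warns(UserWarning, match="non-positive"):
            out = apply_trait_transforms(t, [TraitConfig("TG", "log")])
        assert np.isnan(out["value"].iloc[0])
        assert out["value"].iloc[1] == pytest.approx(0.0)


class TestInclusionRules:
    def _sparse_table(self, missing_at_p2):
        rows = []
        for i in range(10):
            for per in (1, 2, 3):
                val = np.nan if (per == 2 and i < missing_at_p2) else float(i)
                rows.append((f"s{i}", per, 48.0 + 2 * per, 1, "X", val))
        return long_table(rows)

    def test_sparse_period_removed_only_for_that_trait_period(self):
        pheno, report = exclude_sparse_trait_periods(self._sparse_table(6))  # 60% missing
        assert set(pheno["period"]) == {1, 3}
        row = report.set_index("period").loc[2]
        assert bool(row["excluded"]) and row["missing_rate"] == pytest.approx(0.6)

    def test_exactly_half_missing_retained(self):
        pheno, report = exclude_sparse_trait_periods(self._sparse_table(5))
        assert set(pheno["period"]) == {1, 2, 3}
        assert not report["excluded"].any()

    def test_fully_observed_untouched(self):
        t = self._sparse_table(0)
        pheno, report = exclude_sparse_trait_periods(t)
        assert pheno.equals(t)
        assert not report["excluded"].any()

    def test_min_measurement_rule(self):
        rows = []
        for per in (1, 3, 5):
            rows.append(("keep", per, 40.0 + 2 * per, 1, "X", 1.0))
        for per in (1, 2):
            rows.append(("drop", per, 40.0 + 2 * per, 1, "X", 1.0))
        t = long_table(rows)
        out = filter_min_measurements(t, min_obs=3)
        assert set(out["subject_id"]) == {"keep"}
        assert len(filter_min_measurements(t, min_obs=1)) == len(t)


class TestPeriodWeights:
    def test_recovers_known_noise_variance(self):
        rng = np.random.default_rng(31)
        rows = []
        for per in (1, 2):
            age = rng.uniform(40, 70, 500)
            sex = rng.integers(1, 3, 500)
            val = 3.0 * age + rng.normal(0, 2.0, 500)  # variance 4
            rows += [
                (f"s{i}", per, age[i], sex[i], "X", val[i]) for i in range(500)
            ]
        w = estimate_period_weights(long_table(rows), "X")
        np.testing.assert_allclose(w["w"], 4.0, rtol=0.15)

    def test_exact_linear_trait_raises(self):
        rows = [(f"s{i}", 1, 40.0 + i, 1, "X", 2.0 * (40.0 + i)) for i in range(30)]
        with pytest.raises(DegenerateDataError, match="period 1"):
            estimate_period_weights(long_table(rows), "X")

    def test_scaling_values_scales_weights_quadratically(self):
        rng = np.random.default_rng(32)
        rows = [
            (f"s{i}", 1, rng.uniform(40, 70), 1, "X", rng.normal()) for i in range(200)
        ]
        t = long_table(rows)
        w1 = estimate_period_weights(t, "X")["w"].iloc[0]
        t2 = t.assign(value=2 * t["value"])
        w2 = estimate_period_weights(t2, "X")["w"].iloc[0]
        assert w2 == pytest.approx(4 * w1)

    def test_underdetermined_period_excluded_with_warning(self):
        rows = [(f"s{i}", 1, 40.0 + i, 1 + i % 2, "X", float(i % 7)) for i in range(30)]
        rows += [("s0", 2, 50.0, 1, "X", 1.0), ("s1", 2, 52.0, 2, "X", 2.0)]
        with pytest.warns(UserWarning, match="period 2"):
            w = estimate_period_weights(long_table(rows), "X")
        assert bool(w.set_index("period").loc[2, "excluded"])


def weights_for(trait, periods, w=1.0):
    return pd.DataFrame(
        {"trait": trait, "period": periods, "w": w, "n": 10, "excluded": False}
    )


class TestTrajectories:
    def test_exact_line_through_centred_mean(self):
        t = long_table(
            [
                ("a", 1, 40.0, 1, "X", 10.0),
                ("a", 2, 42.0, 1, "X", 12.0),
                ("a", 3, 44.0, 1, "X", 14.0),
            ]
        )
        tr = fit_subject_trajectories(t, weights_for("X", [1, 2, 3]), "X")
        assert tr["B0"].iloc[0] == pytest.approx(12.0)
        assert tr["B1"].iloc[0] == pytest.approx(1.0)
        assert tr["mean_age"].iloc[0] == pytest.approx(42.0)
        assert tr["sigma2"].iloc[0] == pytest.approx(0.0)

    def test_affine_equivariance_in_values(self):
        rng = np.random.default_rng(33)
        rows = [("a", p, 40.0 + 2 * p, 1, "X", float(rng.normal())) for p in range(1, 7)]
        t = long_table(rows)
        w = weights_for("X", list(range(1, 7)), w=[1.0, 2.0, 0.5, 1.5, 3.0, 1.0])
        tr1 = fit_subject_trajectories(t, w, "X")
        tr2 = fit_subject_trajectories(t.assign(value=t["value"] + 7.5), w, "X")
        assert tr2["B0"].iloc[0] == pytest.approx(tr1["B0"].iloc[0] + 7.5)
        assert tr2["B1"].iloc[0] == pytest.approx(tr1["B1"].iloc[0])

    def test_time_translation_invariance_of_slope(self):
        rng = np.random.default_rng(34)
        vals = rng.normal(size=6)
        rows1 = [("a", p + 1, 40.0 + 2 * p, 1, "X", vals[p]) for p in range(6)]
        rows2 = [("a", p + 1, 55.0 + 2 * p, 1, "X", vals[p]) for p in range(6)]
        w = weights_for("X", list(range(1, 7)), w=[1, 3, 2, 1, 2, 3])
        b1_a = fit_subject_trajectories(long_table(rows1), w, "X")["B1"].iloc[0]
        b1_b = fit_subject_trajectories(long_table(rows2), w, "X")["B1"].iloc[0]
        assert b1_a == pytest.approx(b1_b, abs=1e-12)

    def test_matches_weighted_normal_equations_oracle(self):
        # ages (40, 42, 46), values (1, 5, 3), weights (1, 4, 1)
        t = long_table(
            [
                ("a", 1, 40.0, 1, "X", 1.0),
                ("a", 2, 42.0, 1, "X", 5.0),
                ("a", 3, 46.0, 1, "X", 3.0),
            ]
        )
        w = weights_for("X", [1, 2, 3], w=[1.0, 0.25, 1.0])  # 1/w = (1, 4, 1)
        tr = fit_subject_trajectories(t, w, "X")
        ages = np.array([40.0, 42.0, 46.0])
        x = ages - ages.mean()
        W = np.diag([1.0, 4.0, 1.0])
        Xd = np.column_stack([np.ones(3), x])
        y = np.array([1.0, 5.0, 3.0])
        beta = np.linalg.solve(Xd.T @ W @ Xd, Xd.T @ W @ y)
        assert tr["B0"].iloc[0] == pytest.approx(beta[0], abs=1e-12)
        assert tr["B1"].iloc[0] == pytest.approx(beta[1], abs=1e-12)

    def test_equal_weights_match_ols(self):
        rng = np.random.default_rng(35)
        rows = []
        for i in range(20):
            ages = 40.0 + np.sort(rng.choice(12, size=4, replace=False)) * 2.0
            for p, a in enumerate(ages, start=1):
                rows.append((f"s{i}", p, a, 1, "X", float(rng.normal())))
        t = long_table(rows)
        tr = fit_subject_trajectories(t, weights_for("X", [1, 2, 3, 4]), "X")
        for sid, grp in t.groupby("subject_id"):
            x = grp["age"] - grp["age"].mean()
            slope, intercept = np.polyfit(x, grp["value"], 1)
            row = tr.set_index("subject_id").loc[sid]
            assert row["B1"] == pytest.approx(slope, abs=1e-10)
            assert row["B0"] == pytest.approx(intercept, abs=1e-10)

    def test_recovers_truth_without_period_noise(self):
        cfg = SimulationConfig(
            n_subjects=50,
            n_snps=40,
            period_noise_variances=(1e-20,) * 6,
            sex_effect=0.0,
            seed=36,
        )
        g = simulate_genotypes(cfg)
        table, truth = simulate_longitudinal_phenotypes(g, cfg)
        w = weights_for("trait1", list(range(1, 7)))
        tr = fit_subject_trajectories(table, w, "trait1").set_index("subject_id")
        iid = g.sample_meta["iid"]
        np.testing.assert_allclose(tr.loc[iid, "B0"], truth.b0, atol=1e-8)
        np.testing.assert_allclose(tr.loc[iid, "B1"], truth.b1, atol=1e-8)

    def test_mean_slope_near_zero_under_zero_mean_slopes(self):
        cfg = SimulationConfig(n_subjects=400, n_snps=50, age_effect=0.0, seed=37)
        g = simulate_genotypes(cfg)
        table, _ = simulate_longitudinal_phenotypes(g, cfg)
        w = estimate_period_weights(table, "trait1")
        tr = fit_subject_trajectories(table, w, "trait1")
        assert abs(tr["B1"].mean()) < 3 * tr["B1"].std() / np.sqrt(len(tr))

    def test_single_age_subject_dropped_with_warning(self):
        t = long_table(
            [
                ("solo", 1, 50.0, 1, "X", 1.0),
                ("solo", 2, 50.0, 1, "X", 2.0),
                ("ok", 1, 50.0, 1, "X", 1.0),
                ("ok", 2, 52.0, 1, "X", 2.0),
            ]
        )
        with pytest.warns(UserWarning, match="distinct ages"):
            tr = fit_subject_trajectories(t, weights_for("X", [1, 2]), "X")
        assert set(tr["subject_id"]) == {"ok"}

    def test_missing_weight_excludes_period(self):
        t = long_table(
            [
                ("a", 1, 40.0, 1, "X", 0.0),
                ("a", 2, 42.0, 1, "X", 2.0),
                ("a", 3, 44.0, 1, "X", 100.0),  # excluded period
            ]
        )
        w = pd.DataFrame(
            {
                "trait": "X",
                "period": [1, 2, 3],
                "w": [1.0, 1.0, np.nan],
                "n": 10,
                "excluded": [False, False, True],
            }
        )
        tr = fit_subject_trajectories(t, w, "X")
        assert tr["n_obs"].iloc[0] == 2
        assert tr["B1"].iloc[0] == pytest.approx(1.0)


def test_health_panel_flags_skewed_traits_for_log():
    panel = health_trait_panel()
    assert len(panel) == 16
    logged = {t.name for t in panel if t.transform == "log"}
    assert logged == {"HbA1c", "GLU0", "HDL", "TG", "SBP"}
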