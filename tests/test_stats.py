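"""Mixed-model assembly, fitting, contrasts, bootstrap, subgroups."""

import numpy as np
import pandas as pd
import pytest

from gaitprop.stats import (
    LimbLevelDataset,
    assemble,
    cluster_bootstrap,
    design_matrix,
    fit_lmm,
    fit_robust_lmm,
    slope_contrasts,
    subgroup_split,
)
from gaitprop.synth import generate_cohort
from tests.conftest import AGRF_EFFECTS, AGRF_SD_INTERCEPT, AGRF_SD_RESID, AGRF_TRUTH


def metrics_table(n_participants=4, speeds=(0.5, 1.0, 1.5)) -> pd.DataFrame:
    rows = []
    for i in range(n_participants):
        for v in speeds:
            rows.append(
                {
                    "participant_id": f"P{i}",
                    "speed": v,
                    "mean_step_length_paretic": 0.40 + 0.2 * v,
                    "mean_step_length_nonparetic": 0.45 + 0.2 * v,
                    "mean_agrf_paretic": 40 + 50 * v,
                    "mean_agrf_nonparetic": 60 + 60 * v,
                    "predicted_step_length": 0.30 + 0.29 * v,
                    "predicted_agrf": 30 + 126.6 * v,
                }
            )
    return pd.DataFrame(rows)


def dataset_from(df: pd.DataFrame) -> LimbLevelDataset:
    df = df.copy()
    df["centered_speed"] = df["speed"] - df["speed"].mean()
    return LimbLevelDataset(df, float(df["speed"].mean()))


class TestAssemble:
    def test_three_rows_per_trial_and_centering(self):
        ds = assemble(metrics_table(), "step_length")
        assert len(ds.data) == 4 * 3 * 3
        assert ds.data["centered_speed"].mean() == pytest.approx(0.0, abs=1e-12)
        assert set(np.round(ds.data["centered_speed"].unique(), 9)) == {-0.5, 0.0, 0.5}
        assert ds.grand_mean_speed == pytest.approx(1.0)

    def test_missing_prediction_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assemble(metrics_table().drop(columns=["predicted_agrf"]), "agrf")

    def test_single_speed_participant_warns_but_is_retained(self):
        df = metrics_table()
        df = df[(df["participant_id"] != "P0") | (df["speed"] == 1.0)]
        with pytest.warns(UserWarning, match="single"):
            ds = assemble(df, "step_length")
        assert "P0" in set(ds.data["participant_id"])


class TestFitLmm:
    def test_noiseless_cohort_identified_to_machine_precision(self):
        df = generate_cohort(5, AGRF_EFFECTS, sd_intercept=0.0, sd_resid=0.0, seed=0)
        fit = fit_lmm(dataset_from(df))
        np.testing.assert_allclose(fit.params.to_numpy(), AGRF_TRUTH, atol=1e-6)
        assert fit.sigma_e2 == pytest.approx(0.0, abs=1e-9)

    def test_agreement_with_statsmodels_reml(self, agrf_cohort):
        """Independent oracle: statsmodels MixedLM on the same data."""
        import statsmodels.formula.api as smf

        fit = fit_lmm(LimbLevelDataset(agrf_cohort, agrf_cohort["speed"].mean()))
        sm_fit = smf.mixedlm(
            "outcome ~ centered_speed * C(limb, Treatment('predicted'))",
            agrf_cohort,
            groups=agrf_cohort["participant_id"],
        ).fit(reml=True)
        ours = {
            "intercept": "Intercept",
            "centered_speed": "centered_speed",
            "limb[paretic]": "C(limb, Treatment('predicted'))[T.paretic]",
            "limb[nonparetic]": "C(limb, Treatment('predicted'))[T.nonparetic]",
            "centered_speed:limb[paretic]": "centered_speed:C(limb, Treatment('predicted'))[T.paretic]",
            "centered_speed:limb[nonparetic]": "centered_speed:C(limb, Treatment('predicted'))[T.nonparetic]",
        }
        for our_name, sm_name in ours.items():
            assert fit.params[our_name] == pytest.approx(sm_fit.params[sm_name], abs=1e-3)
            assert fit.se[our_name] == pytest.approx(sm_fit.bse[sm_name], rel=1e-2)
        assert fit.sigma_e2 == pytest.approx(sm_fit.scale, rel=1e-3)
        assert fit.sigma_b2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2)

    def test_zero_between_participant_variance_boundary(self):
        df = generate_cohort(20, AGRF_EFFECTS, sd_intercept=0.0, sd_resid=10.0, seed=3)
        fit = fit_lmm(dataset_from(df))
        assert fit.sigma_b2 < 0.5 * fit.sigma_e2  # boundary-ish estimate

    def test_minimal_design_two_participants_two_speeds(self):
        df = generate_cohort(
            2, AGRF_EFFECTS, 1.0, 1.0, seed=0,
            speeds={"P001": [0.5, 1.0], "P002": [0.6, 1.1]},
        )
        fit = fit_lmm(dataset_from(df))
        assert len(fit.params) == 6

    def test_reparameterization_invariance(self, agrf_cohort):
        """Changing the reference level changes coefficients, not the fit."""
        ds = LimbLevelDataset(agrf_cohort, agrf_cohort["speed"].mean())
        f1 = fit_lmm(ds, reference="predicted")
        f2 = fit_lmm(ds, reference="paretic")
        X1, _ = design_matrix(ds.data, "predicted")
        X2, _ = design_matrix(ds.data, "paretic")
        np.testing.assert_allclose(X1 @ f1.params, X2 @ f2.params, atol=1e-6)
        s1 = slope_contrasts(f1).set_index("contrast")["estimate"]
        s2 = slope_contrasts(f2).set_index("contrast")["estimate"]
        for lv in ("predicted", "paretic", "nonparetic"):
            assert s1[f"slope[{lv}]"] == pytest.approx(s2[f"slope[{lv}]"], abs=1e-6)

    def test_centering_invariance_of_slopes(self, agrf_cohort):
        """Centering changes intercept-type terms only."""
        ds = LimbLevelDataset(agrf_cohort, agrf_cohort["speed"].mean())
        df2 = agrf_cohort.copy()
        df2["centered_speed"] = df2["speed"]  # no centering
        ds2 = LimbLevelDataset(df2, 0.0)
        f1, f2 = fit_lmm(ds), fit_lmm(ds2)
        for term in ("centered_speed", "centered_speed:limb[paretic]", "centered_speed:limb[nonparetic]"):
            assert f1.params[term] == pytest.approx(f2.params[term], abs=1e-4)
        assert f1.params["intercept"] != pytest.approx(f2.params["intercept"], abs=1.0)


class TestSlopeContrasts:
    def test_slope_is_speed_plus_interaction(self, agrf_cohort):
        fit = fit_lmm(LimbLevelDataset(agrf_cohort, agrf_cohort["speed"].mean()))
        s = slope_contrasts(fit).set_index("contrast")
        b = fit.params
        assert s.loc["slope[predicted]", "estimate"] == pytest.approx(b["centered_speed"])
        assert s.loc["slope[paretic]", "estimate"] == pytest.approx(
            b["centered_speed"] + b["centered_speed:limb[paretic]"]
        )
        assert s.loc["slope[paretic]-slope[predicted]", "estimate"] == pytest.approx(
            b["centered_speed:limb[paretic]"]
        )
        assert s.loc["slope[paretic]-slope[predicted]", "se"] == pytest.approx(
            fit.se["centered_speed:limb[paretic]"]
        )

    def test_zero_interactions_give_equal_slopes(self):
        import dataclasses

        eff = dataclasses.replace(
            AGRF_EFFECTS, slope_offset_paretic=0.0, slope_offset_nonparetic=0.0
        )
        df = generate_cohort(5, eff, 0.0, 0.0, seed=0)
        s = slope_contrasts(fit_lmm(dataset_from(df))).set_index("contrast")["estimate"]
        assert s["slope[predicted]"] == pytest.approx(s["slope[paretic]"], abs=1e-6)
        assert s["slope[predicted]"] == pytest.approx(s["slope[nonparetic]"], abs=1e-6)


class TestRobust:
    def test_agreement_with_reml_in_low_noise_limit(self):
        df = generate_cohort(32, AGRF_EFFECTS, sd_intercept=1.0, sd_resid=0.3, seed=3)
        ds = dataset_from(df)
        f1, f2 = fit_lmm(ds), fit_robust_lmm(ds)
        rel = (f2.params - f1.params).abs() / f1.params.abs()
        assert float(rel.max()) < 0.01
        assert f2.converged

    def test_huber_weights_near_one_without_outliers(self):
        df = generate_cohort(20, AGRF_EFFECTS, 25.0, 15.0, seed=5)
        fit = fit_robust_lmm(dataset_from(df))
        assert np.median(fit.weights) == pytest.approx(1.0, abs=1e-6)
        assert np.mean(fit.weights > 0.9) > 0.7

    def test_gross_contamination_hurts_robust_less(self):
        """5% of observations x10 residuals: robust stays closer to truth."""
        d_plain, d_robust = 0.0, 0.0
        for seed in range(6):
            df = generate_cohort(30, AGRF_EFFECTS, AGRF_SD_INTERCEPT, AGRF_SD_RESID, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            idx = rng.choice(len(df), size=int(0.05 * len(df)), replace=False)
            df.loc[idx, "outcome"] += rng.choice([-1.0, 1.0], size=len(idx)) * 10 * AGRF_SD_RESID
            ds = dataset_from(df)
            d_plain += np.linalg.norm(fit_lmm(ds).params.to_numpy() - AGRF_TRUTH)
            d_robust += np.linalg.norm(fit_robust_lmm(ds).params.to_numpy() - AGRF_TRUTH)
        assert d_robust < d_plain


class TestClusterBootstrap:
    def test_same_seed_identical_cis(self, agrf_cohort):
        ds = LimbLevelDataset(agrf_cohort, agrf_cohort["speed"].mean())
        c1 = cluster_bootstrap(ds, fit_lmm, B=50, seed=9)
        c2 = cluster_bootstrap(ds, fit_lmm, B=50, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_single_replicate_degenerate_interval(self, agrf_cohort):
        ds = LimbLevelDataset(agrf_cohort, agrf_cohort["speed"].mean())
        ci = cluster_bootstrap(ds, fit_lmm, B=1, seed=2)
        np.testing.assert_allclose(ci["ci_low"], ci["ci_high"])

    def test_affine_equivariance(self, agrf_cohort):
        """Rescaling the outcome rescales the percentile CIs."""
        ds = LimbLevelDataset(agrf_cohort, agrf_cohort["speed"].mean())
        df2 = agrf_cohort.copy()
        df2["outcome"] = 2.0 * df2["outcome"] + 5.0
        ds2 = LimbLevelDataset(df2, agrf_cohort["speed"].mean())
        c1 = cluster_bootstrap(ds, fit_lmm, B=40, seed=4).set_index("term")
        c2 = cluster_bootstrap(ds2, fit_lmm, B=40, seed=4).set_index("term")
        for term in c1.index:
            shift = 5.0 if term == "intercept" else 0.0
            assert c2.loc[term, "ci_low"] == pytest.approx(
                2.0 * c1.loc[term, "ci_low"] + shift, abs=1e-6
            )
            assert c2.loc[term, "ci_high"] == pytest.approx(
                2.0 * c1.loc[term, "ci_high"] + shift, abs=1e-6
            )

    def test_too_few_participants_rejected(self):
        df = generate_cohort(3, AGRF_EFFECTS, 1.0, 1.0, seed=0)
        with pytest.raises(ValueError, match="participants"):
            cluster_bootstrap(dataset_from(df), fit_lmm, B=10, seed=0)


class TestSubgroupSplit:
    def test_direction_labels_and_boundary(self):
        df = generate_cohort(4, AGRF_EFFECTS, 0.0, 0.0, seed=0)
        ds = dataset_from(df)
        ss_sla = {"P001": 0.09, "P002": -0.04, "P003": 0.02, "P004": -0.021}
        labels, subs = subgroup_split(ds, ss_sla)
        by_id = {l.participant_id: l.direction for l in labels}
        assert by_id == {
            "P001": "longer_paretic",
            "P002": "longer_nonparetic",
            "P003": "excluded_symmetric",  # |SLA| <= 0.02 excluded
            "P004": "longer_nonparetic",
        }
        assert set(subs["longer_paretic"].data["participant_id"]) == {"P001"}
        assert set(subs["longer_nonparetic"].data["participant_id"]) == {"P002", "P004"}

    def test_subgroups_recentered_on_own_mean(self):
        df = generate_cohort(4, AGRF_EFFECTS, 0.0, 0.0, seed=0)
        ds = dataset_from(df)
        _, subs = subgroup_split(ds, {"P001": 0.1, "P002": 0.1, "P003": -0.1, "P004": -0.1})
        for sub in subs.values():
            assert sub.data["centered_speed"].mean() == pytest.approx(0.0, abs=1e-12)
            assert sub.grand_mean_speed == pytest.approx(sub.data["speed"].mean())

    def test_missing_ss_sla_rejected(self):
        df = generate_cohort(2, AGRF_EFFECTS, 0.0, 0.0, seed=0)
        with pytest.raises(ValueError, match="missing"):
            subgroup_split(dataset_from(df), {"P001": 0.1})
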