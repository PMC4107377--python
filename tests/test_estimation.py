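import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from adgrs.estimation import (
    ModelSpec,
    NotEstimableError,
    build_analysis_frame,
    cluster_robust_vcov_brute,
    fit_linear_clustered,
    fit_pooled_logistic,
    interaction_test,
    run_model_battery,
)


def small_frame(n_persons=12, waves=2, seed=0, binary=True):
    """Tiny hand-sized panel-like analysis frame for sandwich checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_persons):
        grs = rng.normal(0.1, 0.03)
        male = "male" if rng.random() < 0.5 else "female"
        race = "NHW" if rng.random() < 0.8 else "NHB"
        age0 = rng.uniform(65, 80)
        for t in range(waves):
            y = float(rng.random() < 0.3) if binary else rng.normal()
            rows.append(
                {
                    "person_id": f"p{i}",
                    "wave_year": 2006 + 2 * t,
                    "race": race,
                    "sex": male,
                    "age": age0 + 2 * t,
                    "dementia_prob": y,
                    "memory_score": rng.normal(),
                    "grs": grs,
                }
            )
    return pd.DataFrame(rows)


class TestSandwich:
    @pytest.mark.parametrize("outcome", ["dementia", "memory"])
    def test_matches_brute_force_formula(self, outcome):
        frame = small_frame(n_persons=14, waves=2, seed=4)
        spec = ModelSpec(outcome=outcome)
        fit = (
            fit_pooled_logistic(frame, spec)
            if outcome == "dementia"
            else fit_linear_clustered(frame, spec)
        )
        # rebuild the design exactly as the fit saw it
        X = pd.DataFrame(
            {
                "const": 1.0,
                "grs": frame["grs"],
                "age_c": frame["age"] - 70.0,
                "male": (frame["sex"] == "male").astype(float),
                "year_c": frame["wave_year"] - 2008,
                "black": (frame["race"] == "NHB").astype(float),
            }
        )
        y = frame["dementia_prob" if outcome == "dementia" else "memory_score"]
        groups = pd.Categorical(frame["person_id"]).codes
        V = cluster_robust_vcov_brute(
            X.to_numpy(),
            y.to_numpy(),
            fit.params.to_numpy(),
            groups,
            "binomial" if outcome == "dementia" else "gaussian",
        )
        np.testing.assert_allclose(fit.vcov_cluster.to_numpy(), V, atol=1e-10)

    def test_single_observation_clusters_equal_hc0(self):
        frame = small_frame(n_persons=25, waves=1, seed=8)
        fit = fit_pooled_logistic(frame, ModelSpec(outcome="dementia"))
        X = np.column_stack(
            [
                np.ones(len(frame)),
                frame["grs"],
                frame["age"] - 70.0,
                (frame["sex"] == "male").astype(float),
                frame["wave_year"] - 2008,
                (frame["race"] == "NHB").astype(float),
            ]
        )
        # year is constant with one wave -> drop it as the fit's rank check would
        keep = [0, 1, 2, 3, 5]
        res = sm.GLM(
            frame["dementia_prob"].to_numpy(), X[:, keep], family=sm.families.Binomial()
        ).fit(cov_type="HC0", tol=1e-10)
        got = fit.vcov_cluster
        want = pd.DataFrame(
            res.cov_params(),
            index=[fit.params.index[i] for i in range(len(keep))],
        )
        np.testing.assert_allclose(
            np.sort(np.diag(got)), np.sort(np.diag(want)), rtol=1e-8
        )

    def test_within_cluster_duplication_leaves_cr0_unchanged(self):
        frame = small_frame(n_persons=15, waves=2, seed=3)
        doubled = pd.concat([frame, frame], ignore_index=True)
        # keep person-wave uniqueness out of it: estimation works on frames
        a = fit_pooled_logistic(frame, ModelSpec(outcome="dementia"))
        b = fit_pooled_logistic(doubled, ModelSpec(outcome="dementia"))
        pd.testing.assert_series_equal(a.params, b.params, atol=1e-8, rtol=0)
        np.testing.assert_allclose(
            a.vcov_cluster.to_numpy(), b.vcov_cluster.to_numpy(), atol=1e-8
        )


class TestPooledLogistic:
    def test_collapsed_two_by_two_equals_cross_product_ratio(self):
        # 2x2 table: exposed 30/70 events, unexposed 15/85
        rows = []
        counts = {(1, 1): 30, (1, 0): 70, (0, 1): 15, (0, 0): 85}
        i = 0
        for (x, y), n in counts.items():
            for _ in range(n):
                rows.append(
                    {
                        "person_id": f"p{i}",
                        "wave_year": 2006,
                        "race": "NHW",
                        "sex": "male",
                        "age": 70.0,
                        "dementia_prob": float(y),
                        "grs": float(x),
                    }
                )
                i += 1
        frame = pd.DataFrame(rows)
        fit = fit_pooled_logistic(
            frame, ModelSpec(outcome="dementia", exposure="grs", exposure_scale=1.0)
        )
        expected = (30 * 85) / (70 * 15)
        assert fit.effect_per_scale["estimate"] == pytest.approx(expected, abs=1e-8)

    def test_zero_outcome_variation_errors(self):
        frame = small_frame(seed=1)
        frame["dementia_prob"] = 0.0
        with pytest.raises(NotEstimableError, match="no variation"):
            fit_pooled_logistic(frame, ModelSpec(outcome="dementia"))

    def test_year_relabel_invariance(self):
        frame = small_frame(n_persons=40, waves=3, seed=6)
        a = fit_pooled_logistic(frame, ModelSpec(outcome="dementia"))
        shifted = frame.copy()
        shifted["wave_year"] = 3 * (shifted["wave_year"] - 2006) + 11
        b = fit_pooled_logistic(shifted, ModelSpec(outcome="dementia"))
        ea, eb = a.effect_per_scale, b.effect_per_scale
        assert ea["estimate"] == pytest.approx(eb["estimate"], rel=1e-8)
        assert ea["ci_low"] == pytest.approx(eb["ci_low"], rel=1e-8)


class TestLinear:
    def test_noiseless_outcome_recovered_exactly(self):
        frame = small_frame(n_persons=30, waves=2, seed=5)
        frame["memory_score"] = (
            2.0
            - 3.0 * frame["grs"]
            - 0.02 * (frame["age"] - 70.0)
            + 0.1 * (frame["sex"] == "male")
            + 0.05 * (frame["wave_year"] - 2008)
            - 0.4 * (frame["race"] == "NHB")
        )
        fit = fit_linear_clustered(frame, ModelSpec(outcome="memory"))
        assert fit.params["grs"] == pytest.approx(-3.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["black"] == pytest.approx(-0.4, abs=1e-10)

    def test_rank_deficiency_names_collinear_columns(self):
        frame = small_frame(n_persons=20, waves=2, seed=2)
        frame["dup"] = frame["grs"]  # exact copy of the exposure
        spec = ModelSpec(outcome="memory", exposure="grs", interactions=())
        frame["memory_score"] = frame["grs"] * 2.0
        # inject the duplicate through the exposure column path
        frame2 = frame.copy()
        frame2["age"] = 70.0 + frame2["grs"]  # age_c == grs -> collinear
        with pytest.raises(NotEstimableError, match="collinear"):
            fit_linear_clustered(frame2, spec)


class TestInteraction:
    def test_fully_interacted_model_reproduces_stratified_fits(self):
        frame = small_frame(n_persons=120, waves=2, seed=9)
        nhw = fit_pooled_logistic(
            frame, ModelSpec(outcome="dementia", stratum={"race": "NHW"})
        )
        nhb = fit_pooled_logistic(
            frame, ModelSpec(outcome="dementia", stratum={"race": "NHB"})
        )
        # independent fully-interacted fit: every column crossed with race
        X = pd.DataFrame(
            {
                "const": 1.0,
                "grs": frame["grs"],
                "age_c": frame["age"] - 70.0,
                "male": (frame["sex"] == "male").astype(float),
                "year_c": frame["wave_year"] - 2008,
            }
        )
        black = (frame["race"] == "NHB").astype(float)
        full = pd.concat([X, X.mul(black, axis=0).add_suffix(":black")], axis=1)
        res = sm.GLM(
            frame["dementia_prob"].to_numpy(), full.to_numpy(), family=sm.families.Binomial()
        ).fit(tol=1e-12, maxiter=200)
        b = pd.Series(res.params, index=full.columns)
        # stratum effect = main-effect OR x interaction OR
        assert math.exp(b["grs"]) == pytest.approx(
            math.exp(nhw.params["grs"]), rel=1e-6
        )
        assert math.exp(b["grs"] + b["grs:black"]) == pytest.approx(
            math.exp(nhb.params["grs"]), rel=1e-6
        )

    def test_interaction_term_requires_presence(self):
        frame = small_frame(seed=12)
        fit = fit_pooled_logistic(frame, ModelSpec(outcome="dementia"))
        with pytest.raises(KeyError):
            interaction_test(fit, "race")


class TestBattery:
    def test_layout_contract(self, small_study, weights):
        frame = build_analysis_frame(small_study.panel, small_study.genotypes, weights)
        battery = run_model_battery(frame)
        dem = battery[battery["outcome"] == "dementia"]
        for exposure in ("grs", "grs_no_apoe"):
            cells = dem[dem["exposure"] == exposure]["model"].tolist()
            assert cells == ["pooled", "NHW", "NHB", "race_interaction"]
        assert set(battery["outcome"]) == {"dementia", "memory"}
        # APOE-carrier rows are appended when the genotype matrix has rs429358
        assert battery["exposure"].eq("apoe_carrier").any()

    def test_empty_stratum_marked_not_estimable(self, weights):
        from adgrs.simulate import SimulationParams, simulate_study

        study = simulate_study(
            SimulationParams(n_persons=120, seed=4, prop_nhb=0.0), weights
        )
        frame = build_analysis_frame(study.panel, study.genotypes, weights)
        battery = run_model_battery(frame, outcomes=("dementia",), exposures=("grs",))
        nhb = battery[battery["model"] == "NHB"].iloc[0]
        assert not nhb["estimable"] and np.isnan(nhb["effect"])

    def test_single_snp_null_recovery(self, weights):
        from adgrs.simulate import SimulationParams, simulate_study

        # rs7412 carries no generative effect: across replicates its mean
        # estimated log-OR should sit at zero within Monte-Carlo error
        log_ors = []
        for seed in range(8):
            study = simulate_study(
                SimulationParams(n_persons=2500, seed=100 + seed), weights
            )
            frame = build_analysis_frame(
                study.panel,
                study.genotypes,
                weights,
                snp_exposures=("rs7412",),
            )
            fit = fit_pooled_logistic(
                frame,
                ModelSpec(outcome="dementia", exposure="rs7412", exposure_scale=1.0),
            )
            log_ors.append(math.log(fit.effect_per_scale["estimate"]))
        log_ors = np.asarray(log_ors)
        mc_err = log_ors.std(ddof=1) / math.sqrt(len(log_ors))
        assert abs(log_ors.mean()) < 4 * mc_err + 0.02
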