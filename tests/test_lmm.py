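"""Mixed-model engine and model-comparison logic.

Two independent oracles guard the estimator: the closed-form OLS fit
(the zero-variance limit of the mixed model) and statsmodels MixedLM on
a single-grouping fixture.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from morphgaze.lmm import (
    RegressionSpec, baseline_spec, compare_to_baseline, correlations,
    fit_lmm, joint_with_word_unigram, run_model_ranking, summary,
)
from morphgaze.surprisal import SurprisalVector


def _crossed_data(rng, ns=12, ni=30, subj_sd=0.0, item_sd=0.0, beta=2.0,
                  resid=1.0, extra_cols=()):
    subj = np.repeat(np.arange(ns), ni)
    item = np.tile(np.arange(ni), ns)
    x = rng.normal(size=ns * ni)
    u_s = rng.normal(0, subj_sd, ns)
    u_i = rng.normal(0, item_sd, ni)
    y = 1.0 + beta * x + u_s[subj] + u_i[item] + rng.normal(0, resid, ns * ni)
    df = pd.DataFrame(dict(y=y, x=x, subject=subj, item=item))
    for c in extra_cols:
        df[c] = rng.normal(size=len(df))
    return df


SPEC = RegressionSpec("y", ["x"], ["subject", "item"])


class TestFit:
    def test_aic_identity(self, rng):
        res = fit_lmm(SPEC, _crossed_data(rng, subj_sd=1.0, item_sd=0.5))
        assert res.aic == res.deviance + 2 * res.n_params

    def test_ols_limit(self, rng):
        """With zero true variance components the ML mixed fit collapses
        to ordinary least squares."""
        df = _crossed_data(rng)
        res = fit_lmm(SPEC, df)
        x = df["x"].to_numpy()
        X = sm.add_constant((x - x.mean()) / x.std(ddof=0))
        ols = sm.OLS(df["y"], X).fit()
        assert res.log_likelihood == pytest.approx(ols.llf, rel=1e-3)
        assert res.coefficients["x"][0] == pytest.approx(
            ols.params.iloc[1], rel=1e-3
        )

    def test_matches_statsmodels_single_group(self, rng):
        df = _crossed_data(rng, subj_sd=1.5)
        df["x"] = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)
        mine = fit_lmm(RegressionSpec("y", ["x"], ["subject"]), df)
        ref = sm.MixedLM.from_formula(
            "y ~ x", groups="subject", data=df
        ).fit(reml=False)
        assert mine.log_likelihood == pytest.approx(ref.llf, abs=1e-4)
        assert mine.coefficients["x"][0] == pytest.approx(
            ref.params["x"], abs=1e-5
        )
        assert mine.coefficients["x"][1] == pytest.approx(
            ref.bse["x"], rel=1e-3
        )

    def test_variance_components_recovered(self, rng):
        """Balanced two-level fixture with known components (40 x 60)."""
        df = _crossed_data(rng, ns=40, ni=60, subj_sd=2.0, item_sd=1.5,
                           resid=1.0)
        res = fit_lmm(SPEC, df)
        assert res.variance_components["subject (Intercept)"] == pytest.approx(
            4.0, rel=0.25
        )
        assert res.variance_components["item (Intercept)"] == pytest.approx(
            2.25, rel=0.25
        )

    def test_missing_rows_dropped(self, rng):
        df = _crossed_data(rng)
        df.loc[3, "y"] = np.nan
        res = fit_lmm(SPEC, df)
        assert res.n_obs == len(df) - 1

    def test_few_group_levels_rejected(self, rng):
        df = _crossed_data(rng)
        df["one"] = "all"
        with pytest.raises(ValueError, match="levels"):
            fit_lmm(RegressionSpec("y", ["x"], ["one"]), df)

    def test_summary_renders(self, rng):
        res = fit_lmm(SPEC, _crossed_data(rng, subj_sd=1.0))
        text = summary(res)
        assert "AIC" in text and "x" in text and "residual" in text


class TestComparison:
    def test_zero_delta_p_one(self, rng):
        res = fit_lmm(SPEC, _crossed_data(rng))
        row = compare_to_baseline(res, res)
        assert row.delta_deviance == 0.0 and row.p_value == 1.0

    def test_chi_square_reference_value(self):
        base = type("R", (), dict(n_obs=10, deviance=103.84, aic=0.0,
                                  coefficients={}))()
        aug = type("R", (), dict(n_obs=10, deviance=100.0, aic=0.0,
                                 coefficients={"m": (0, 0)}))()
        row = compare_to_baseline(base, aug, df=1)
        assert row.p_value == pytest.approx(
            stats.chi2.sf(3.84, 1), rel=1e-12
        )
        assert row.p_value == pytest.approx(0.050, abs=5e-4)

    def test_redundant_covariate_zero_delta(self, rng):
        df = _crossed_data(rng, subj_sd=1.0)
        df["x_copy"] = df["x"]
        base = fit_lmm(SPEC, df)
        aug = fit_lmm(
            RegressionSpec("y", ["x", "x_copy"], ["subject", "item"]), df
        )
        row = compare_to_baseline(base, aug)
        assert row.delta_deviance <= 1e-6

    def test_differing_rows_rejected(self, rng):
        df = _crossed_data(rng)
        a = fit_lmm(SPEC, df)
        b = fit_lmm(SPEC, df.iloc[:-5])
        with pytest.raises(ValueError, match="rows"):
            compare_to_baseline(a, b)

    def test_worse_augmented_model_rejected(self):
        base = type("R", (), dict(n_obs=10, deviance=100.0, aic=0.0,
                                  coefficients={}))()
        aug = type("R", (), dict(n_obs=10, deviance=100.5, aic=0.0,
                                 coefficients={}))()
        with pytest.raises(ValueError, match="non-nested"):
            compare_to_baseline(base, aug)


def _measure_frame(rng, ns=8, ni=40, beta=0.0, predictor=None):
    items = [f"w{i}" for i in range(ni)]
    x = predictor if predictor is not None else rng.normal(size=ni)
    rows = []
    for s in range(ns):
        order = rng.permutation(ni)
        for i in range(ni):
            y = 300 + beta * x[i] + rng.normal(0, 30)
            rows.append({
                "subject": f"s{s}", "item": items[i], "FFD": y,
                "GD": y * 2, "GmF": y, "presentation_order": order[i],
                "launch_site": np.nan, "row_position": None,
                "rt_ms": np.nan, "response_correct": True, "list_id": None,
                "excluded": False, "exclude_reason": "",
            })
    return pd.DataFrame(rows), x


class TestRanking:
    def test_true_predictor_ranks_first(self, rng):
        x = rng.normal(size=40)
        meas, _ = _measure_frame(rng, beta=25.0, predictor=x)
        sur = {
            # shifted copy of the generating signal vs pure noise
            "true": SurprisalVector(
                "true",
                {f"w{i}": float(x[i] - x.min() + 0.1) for i in range(40)},
            ),
            "noise": SurprisalVector("noise", {
                f"w{i}": float(v) for i, v in
                enumerate(np.abs(rng.normal(size=40)))
            }),
        }
        ranks = run_model_ranking(meas, sur, "exp1", dependents=("FFD",))
        assert ranks["FFD"].iloc[0]["model"] == "true"
        assert ranks["FFD"].iloc[0]["p_value"] < 1e-6

    def test_identical_vectors_identical_rows(self, rng):
        meas, x = _measure_frame(rng, beta=10.0)
        v = {f"w{i}": float(x[i] - x.min() + 0.1) for i in range(40)}
        sur = {
            "a": SurprisalVector("a", dict(v)),
            "b": SurprisalVector("b", dict(v)),
        }
        ranks = run_model_ranking(meas, sur, "exp1", dependents=("GmF",))
        df = ranks["GmF"]
        ra = df[df["model"] == "a"].iloc[0]
        rb = df[df["model"] == "b"].iloc[0]
        assert ra["delta_deviance"] == pytest.approx(
            rb["delta_deviance"], abs=1e-6
        )
        assert ra["AIC"] == pytest.approx(rb["AIC"], abs=1e-6)

    def test_missing_surprisal_is_error(self, rng):
        meas, _ = _measure_frame(rng)
        sur = {"m": SurprisalVector("m", {"w0": 1.0})}
        with pytest.raises(ValueError, match="no surprisal"):
            run_model_ranking(meas, sur, "exp1")

    def test_joint_baseline_absorbs_word_unigram(self, rng):
        """A model identical to the word unigram adds nothing beyond it."""
        meas, x = _measure_frame(rng, beta=20.0)
        v = {f"w{i}": float(x[i] - x.min() + 0.1) for i in range(40)}
        sur = {
            "word_unigram": SurprisalVector("word_unigram", dict(v)),
            "clone": SurprisalVector("clone", dict(v)),
        }
        joint = joint_with_word_unigram(meas, sur, "exp1",
                                        dependents=("FFD",))
        clone = joint["FFD"].set_index("model").loc["clone"]
        assert clone["delta_deviance"] <= 0.1

    def test_gmf_missing_mask_not_applied_to_ffd(self, rng):
        meas, x = _measure_frame(rng)
        meas.loc[meas.index[:30], "GmF"] = np.nan
        sur = {"m": SurprisalVector(
            "m", {f"w{i}": float(i + 1) for i in range(40)}
        )}
        ranks = run_model_ranking(meas, sur, "exp1",
                                  dependents=("FFD", "GmF"))
        assert ranks["FFD"] is not None and ranks["GmF"] is not None


class TestCorrelations:
    def test_perfect_and_flipped(self, rng):
        meas, x = _measure_frame(rng, beta=0.0)
        item_ffd = meas.groupby("item")["FFD"].mean()
        preds = pd.DataFrame({
            "same": item_ffd, "flipped": -item_ffd,
        })
        out = correlations(meas, preds, dependents=("FFD",))
        r_same = out[(out.predictor == "same")]["r"].item()
        r_flip = out[(out.predictor == "flipped")]["r"].item()
        assert r_same == pytest.approx(1.0)
        assert r_flip == pytest.approx(-r_same)

    def test_constant_column_missing(self, rng):
        meas, _ = _measure_frame(rng)
        preds = pd.DataFrame(
            {"const": 1.0},
            index=sorted(meas["item"].unique()),
        )
        out = correlations(meas, preds, dependents=("FFD",))
        assert np.isnan(out["r"]).all()


def test_baseline_specs_match_designs():
    s1 = baseline_spec("exp1", "GD")
    assert s1.fixed_effects == ["presentation_order"]
    assert s1.random_intercepts == ["subject", "item"]
    s2 = baseline_spec("exp2", "GmF")
    assert "launch_site" in s2.fixed_effects
    assert "list_id" in s2.random_intercepts
    assert ("subject", "position_coded") in s2.random_slopes
    with pytest.raises(ValueError):
        baseline_spec("exp3", "GD")
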