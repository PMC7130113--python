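"""Probit pipeline: proportions, transform, line fit, PSS/JND estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tactoj.design import Block, TrialSchedule
from tactoj.observer import Observer, response_probability, simulate_subject
from tactoj.psychometric import (
    LineFit,
    aggregate_proportions,
    compute_jnd,
    compute_pss,
    fit_probit_line,
    fit_subject,
    percent_correct_at,
    probit_transform,
    table_from_probabilities,
)

US = np.array([-200.0, -90.0, -55.0, -30.0, -10.0, 10.0, 30.0, 55.0, 90.0, 200.0])


def _trials(soa, response, posture="uncrossed", subject="S01"):
    n = len(soa)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "block": 1,
            "trial_index": range(1, n + 1),
            "posture": posture,
            "soa_ms": soa,
            "response": response,
        }
    )


class TestAggregateProportions:
    def test_affected_frame_mapping_left(self):
        # affected = left: a left-first trial at soa=-200 counts as an
        # affected-first report at u = -200
        t = _trials([-200], ["left_first"])
        out = aggregate_proportions(t, "left")
        assert out.loc[0, "u_ms"] == -200
        assert out.loc[0, "k"] == 1
        assert out.loc[0, "p"] == 1.0

    def test_affected_frame_mapping_right(self):
        # affected = right: soa=-200 (left first) means the unaffected hand
        # led by 200 ms and the response is not affected-first
        t = _trials([-200], ["left_first"])
        out = aggregate_proportions(t, "right")
        assert out.loc[0, "u_ms"] == 200
        assert out.loc[0, "k"] == 0

    def test_proportion_of_half(self):
        t = _trials([30] * 12, ["left_first"] * 6 + ["right_first"] * 6)
        out = aggregate_proportions(t, "left")
        assert out.loc[0, "n"] == 12
        assert out.loc[0, "p"] == 0.5

    def test_full_schedule_yields_ten_rows_of_twelve_per_posture(
        self, simulated_subject
    ):
        obs, trials = simulated_subject
        out = aggregate_proportions(trials, obs.affected_side)
        for _, sub in out.groupby("posture"):
            assert len(sub) == 10
            assert (sub["n"] == 12).all()

    def test_multiple_subjects_rejected(self):
        t = pd.concat([_trials([10], ["left_first"], subject=s) for s in ("A", "B")])
        with pytest.raises(ValueError):
            aggregate_proportions(t, "left")


class TestProbitTransform:
    def test_half_proportion_maps_to_zero(self):
        tab = table_from_probabilities([0.0001], [0.5])
        assert probit_transform(tab, clip=None)["z"].iloc[0] == pytest.approx(0.0)

    def test_extreme_proportion_clipped(self):
        tab = pd.DataFrame({"posture": "uncrossed", "u_ms": [-200], "n": [12], "k": [12], "p": [1.0]})
        z = probit_transform(tab)["z"].iloc[0]
        assert z == pytest.approx(1.7317, abs=1e-3)  # Phi^-1(23/24), inverse-normal table

    def test_table_value(self):
        tab = table_from_probabilities([0.0], [0.1587])
        z = probit_transform(tab, clip=None)["z"].iloc[0]
        assert z == pytest.approx(-1.0, abs=1e-3)

    def test_unknown_clip_rule(self):
        with pytest.raises(ValueError):
            probit_transform(table_from_probabilities([0.0], [0.5]), clip="winsor")


class TestLineFitAndDerived:
    def test_perfect_line(self):
        pts = pd.DataFrame({"u_ms": US, "z": -0.01 * US})
        fit = fit_probit_line(pts)
        assert fit.slope == pytest.approx(-0.01, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_perfect_line_with_offset(self):
        pts = pd.DataFrame({"u_ms": US, "z": (50 - US) / 100})
        fit = fit_probit_line(pts)
        assert fit.slope == pytest.approx(-0.01, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        u = rng.uniform(-200, 200, size=10)
        z = -0.008 * u + 0.3 + rng.normal(0, 0.2, size=10)
        fit = fit_probit_line(pd.DataFrame({"u_ms": u, "z": z}))
        # independent closed-form least squares via the normal equations
        X = np.column_stack([np.ones_like(u), u])
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_input_rejected(self):
        pts = pd.DataFrame({"u_ms": [10.0, 10.0], "z": [0.1, 0.2]})
        with pytest.raises(ValueError):
            fit_probit_line(pts)

    def test_pss_arithmetic(self):
        assert compute_pss(LineFit(-0.01, 0.5, 10, 1.0)) == pytest.approx(50.0)
        assert compute_pss(LineFit(0.02, 0.0, 10, 1.0)) == pytest.approx(0.0)
        with pytest.raises(ZeroDivisionError):
            compute_pss(LineFit(0.0, 0.5, 10, 1.0))

    def test_jnd_arithmetic(self):
        signed, mag = compute_jnd(LineFit(-0.00675, 0.0, 10, 1.0))
        assert signed == pytest.approx(-100.0)
        assert mag == pytest.approx(100.0)

    @given(
        slope=st.floats(-0.05, -0.001),
        intercept=st.floats(-2.0, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_jnd_dual_formula_agreement(self, slope, intercept):
        # 0.675/slope vs half the distance between the 25% and 75% crossings
        # (the sign conventions of the two formulas differ; magnitudes agree)
        fit = LineFit(slope, intercept, 10, 1.0)
        _, mag = compute_jnd(fit)
        z75 = 0.6744897501960817  # Phi^-1(0.75)
        u25 = (-z75 - intercept) / slope
        u75 = (z75 - intercept) / slope
        alt = abs(u25 - u75) / 2
        assert abs(mag - alt) / alt < 1e-3


class TestRoundTrip:
    @pytest.mark.parametrize("pss,sigma", [(30.0, 100.0), (-75.0, 40.0), (0.0, 250.0)])
    def test_exact_probabilities_recover_parameters(self, pss, sigma):
        # probit of a cumulative normal is exactly linear: the pipeline is an
        # identity for the generating parameters, to machine precision
        obs = Observer(pss_true=pss, sigma=sigma)
        probs = response_probability(obs, US, "uncrossed")
        tab = table_from_probabilities(US, probs)
        fit = fit_probit_line(probit_transform(tab, clip=None))
        assert compute_pss(fit) == pytest.approx(pss, abs=max(1, abs(pss)) * 1e-9)
        _, mag = compute_jnd(fit)
        assert mag == pytest.approx(0.675 * sigma, rel=1e-9)

    def test_two_points_suffice(self):
        obs = Observer(pss_true=20.0, sigma=80.0)
        us = np.array([-50.0, 50.0])
        tab = table_from_probabilities(us, response_probability(obs, us, "uncrossed"))
        fit = fit_probit_line(probit_transform(tab, clip=None))
        assert compute_pss(fit) == pytest.approx(20.0, rel=1e-9)


class TestPercentCorrect:
    def test_all_correct(self):
        t = _trials([-200, 200], ["left_first", "right_first"])
        assert percent_correct_at(t, 200) == 1.0

    def test_noiseless_observer_perfect_at_largest_soa(self, schedule):
        obs = Observer(pss_true=150.0, sigma=1e-9)
        trials = simulate_subject(obs, schedule, rng_seed=1)
        assert percent_correct_at(trials, 200) == 1.0

    def test_matches_binomial_oracle(self):
        n = 3000
        sched = TrialSchedule(
            blocks=(Block(posture="uncrossed", soa_ms=(200, -200) * (n // 2)),), seed=0
        )
        obs = Observer(pss_true=0.0, sigma=100.0)
        trials = simulate_subject(obs, sched, rng_seed=2)
        p_expected = 0.9772498680518208  # Phi(2)
        tol = 3 * np.sqrt(p_expected * (1 - p_expected) / n)
        assert percent_correct_at(trials, 200) == pytest.approx(p_expected, abs=tol)

    def test_missing_soa_rejected(self):
        with pytest.raises(ValueError):
            percent_correct_at(_trials([10], ["left_first"]), 200)


class TestFitSubject:
    def test_relabeling_leaves_estimates_unchanged(self, simulated_subject):
        obs, trials = simulated_subject
        mirrored = trials.copy()
        mirrored["soa_ms"] = -mirrored["soa_ms"]
        mirrored["response"] = np.where(
            mirrored["response"] == "left_first", "right_first", "left_first"
        )
        a = fit_subject(trials, "left")
        b = fit_subject(mirrored, "right")
        for posture in a.postures:
            assert a.postures[posture].pss_ms == pytest.approx(
                b.postures[posture].pss_ms
            )
            assert a.postures[posture].jnd_mag_ms == pytest.approx(
                b.postures[posture].jnd_mag_ms
            )

    def test_recovers_generative_parameters_roughly(self, simulated_subject):
        obs, trials = simulated_subject
        summary = fit_subject(trials, obs.affected_side)
        unc = summary.postures["uncrossed"]
        # single-subject estimates: RMSE ~ 13-17 ms for PSS at sigma=100
        assert unc.pss_ms == pytest.approx(obs.pss_true, abs=60.0)
        assert summary.postures["crossed"].jnd_mag_ms > 0

    def test_ml_probit_oracle_agreement(self, simulated_subject):
        # a maximum-likelihood probit GLM on the raw binary responses is an
        # independent estimator of the same curve; for a well-behaved subject
        # both routes land on nearby PSS values
        sm = pytest.importorskip("statsmodels.api")
        obs, trials = simulated_subject
        unc = trials[trials["posture"] == "uncrossed"]
        u = unc["soa_ms"].to_numpy(float)  # affected = left: u = soa
        y = (unc["response"] == "left_first").to_numpy(int)
        glm = sm.GLM(y, np.column_stack([np.ones_like(u), u]),
                     family=sm.families.Binomial(sm.families.links.Probit()))
        res = glm.fit()
        # fitted probit line z = b0 + b1*u crosses 0.5 probability at -b0/b1
        pss_ml = -res.params[0] / res.params[1]
        summary = fit_subject(trials, obs.affected_side)
        assert summary.postures["uncrossed"].pss_ms == pytest.approx(pss_ml, abs=15.0)
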