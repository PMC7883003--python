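"""Variable coding, mixed-model fitting, simple slopes, Welch test."""

import numpy as np
import pandas as pd
import pytest

from counterbart import models
from counterbart.models import (
    CoefStats,
    FitResult,
    fit_emotion_model,
    fixed_effects_at_zero_variance,
    prepare_variables,
    replication_interaction_model,
    simple_slopes,
    welch_test,
)


def _toy_trials(rows):
    """Build a minimal tidy trial table from (pid, idx, pv, n, limit,
    sought, emotion) tuples; outcome and points follow the task rule."""
    recs = []
    for pid, idx, pv, n, limit, sought, emo in rows:
        bank = n <= limit
        recs.append(
            dict(
                participant_id=pid,
                experiment_id="toy",
                trial_index=idx,
                is_practice=False,
                pump_value=pv,
                n_pumps=n,
                limit=limit,
                outcome="bank" if bank else "bust",
                points=n * pv if bank else 0,
                info_sought=sought,
                info_received=sought,
                try_harder=False,
                outcome_rating=0.0,
                emotion_change=emo,
                cost_type="none",
                cost_amount=0.0,
                time_penalty_s=0.0,
            )
        )
    return pd.DataFrame(recs)


def test_prepare_variables_centering_and_coding():
    trials = _toy_trials(
        [
            ("p1", 1, 50, 4, 9, True, 10.0),  # MO 5
            ("p1", 2, 60, 5, 5, False, -20.0),  # MO 0
            ("p1", 3, 40, 6, 7, True, 5.0),  # MO 1
            ("p2", 1, 30, 3, 8, False, 0.0),
            ("p2", 2, 70, 2, 4, True, 15.0),
        ]
    )
    frame = prepare_variables(trials, "bank")
    p1 = frame[frame.participant_id == "p1"].sort_values("trial_index")
    # MO values (5, 0, 1) center to (3, -2, -1)
    np.testing.assert_allclose(p1.MO_c.to_numpy(), [3.0, -2.0, -1.0])
    # IS mapping: sought -> +1, not sought -> -1
    np.testing.assert_allclose(p1.IS.to_numpy(), [1.0, -1.0, 1.0])
    # outcome standardized over included rows
    assert frame.outcome_z.mean() == pytest.approx(0.0, abs=1e-12)
    assert frame.outcome_z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    # within-participant means of the centered covariates vanish
    assert frame.groupby("participant_id").PV_c.mean().abs().max() < 1e-12
    assert frame.groupby("participant_id").MO_c.mean().abs().max() < 1e-12


def test_prepare_variables_filters(default_study):
    _, tables, _ = default_study
    tab = tables["exp3"]  # effort condition: has try-harder rows
    frame = prepare_variables(tab, "bank")
    merged = frame.merge(
        tab[["participant_id", "trial_index", "outcome", "is_practice", "try_harder"]],
        on=["participant_id", "trial_index"],
    )
    assert (merged.outcome == "bank").all()
    assert not merged.is_practice.any()
    assert not merged.try_harder.any()
    bust = prepare_variables(tab, "bust")
    assert (bust.MO < 0).all()  # bust rows encode overshoot
    with pytest.raises(ValueError):
        prepare_variables(tab, "all")


def test_mixed_model_equals_ols_at_zero_variance():
    """GLS fixed effects at vanishing random variance match the
    closed-form least-squares solution on the same design (1e-6)."""
    rng = np.random.default_rng(8)
    rows = []
    for pid in ("a", "b", "c"):
        for idx in range(1, 13):
            n = int(rng.integers(1, 13))
            limit = int(rng.integers(n, 13))  # force bank
            rows.append(
                (pid, idx, int(rng.integers(1, 101)), n, limit,
                 bool(rng.random() < 0.5), float(rng.normal() * 30))
            )
    frame = prepare_variables(_toy_trials(rows), "bank")
    for step in (1, 2):
        fe = fixed_effects_at_zero_variance(frame, step)
        cols = ["IS", "PV_c", "MO_c"] + (["ISxPV", "ISxMO"] if step == 2 else [])
        X = np.column_stack(
            [np.ones(len(frame)), frame.IS, frame.PV_c, frame.MO_c]
            + ([frame.IS * frame.PV_c, frame.IS * frame.MO_c] if step == 2 else [])
        )
        beta = np.linalg.lstsq(X, frame.outcome_z.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fe.to_numpy(), beta, atol=1e-6)


def test_effect_code_flip_flips_is_terms():
    """Swapping the IS codes flips IS and its interactions, nothing else."""
    rng = np.random.default_rng(9)
    rows = [
        (f"p{i%4}", i, int(rng.integers(1, 101)), 3, int(rng.integers(3, 13)),
         bool(rng.random() < 0.5), float(rng.normal() * 25))
        for i in range(48)
    ]
    frame = prepare_variables(_toy_trials(rows), "bank")
    flipped = frame.copy()
    flipped["IS"] = -flipped["IS"]
    fe = fixed_effects_at_zero_variance(frame, 2)
    fe_f = fixed_effects_at_zero_variance(flipped, 2)
    for name in ("IS", "IS:PV_c", "IS:MO_c"):
        assert fe_f[name] == pytest.approx(-fe[name], abs=1e-10)
    for name in ("Intercept", "PV_c", "MO_c"):
        assert fe_f[name] == pytest.approx(fe[name], abs=1e-10)


def test_centering_absorbs_participant_constants():
    """A common pump-value shift and per-participant missed-opportunity
    shifts wash out of the centered covariates."""
    rng = np.random.default_rng(10)
    rows = [
        ("p1", i, 40 + i, 4, 4 + (i % 6), i % 2 == 0, float(rng.normal())) for i in range(1, 7)
    ] + [
        ("p2", i, 60 - i, 3, 3 + (i % 7), i % 2 == 1, float(rng.normal())) for i in range(1, 8)
    ]
    trials = _toy_trials(rows)
    frame = prepare_variables(trials, "bank")
    shifted = trials.copy()
    shifted["pump_value"] += 7  # common shift: sample SD unchanged
    frame2 = prepare_variables(shifted, "bank")
    np.testing.assert_allclose(frame.PV_c, frame2.PV_c, atol=1e-12)
    # per-participant limit shifts change MO by a participant constant only
    shifted = trials.copy()
    shifted.loc[shifted.participant_id == "p1", "limit"] += 2
    shifted["outcome"] = np.where(shifted.n_pumps <= shifted.limit, "bank", "bust")
    frame3 = prepare_variables(shifted, "bank")
    np.testing.assert_allclose(frame.MO_c, frame3.MO_c, atol=1e-12)


def test_fit_recovers_planted_step_values(default_study):
    """Default generator plants the Step-2 coefficient pattern; each fit
    recovers every planted fixed effect within 3 SE."""
    spec, tables, _ = default_study
    planted = {
        "IS": spec.beta_is,
        "PV_c": spec.beta_pv,
        "MO_c": spec.beta_mo,
        "IS:PV_c": spec.beta_is_pv,
        "IS:MO_c": spec.beta_is_mo,
    }
    frame = prepare_variables(tables["exp1"], "bank")
    fit = fit_emotion_model(frame, step=2)
    assert set(planted) <= set(fit.coefficients)
    for name, value in planted.items():
        stats = fit.coef(name)
        assert stats.b == pytest.approx(value, abs=3 * stats.se)
        assert stats.z == pytest.approx(stats.b / stats.se)
    assert fit.n_participants == spec.n_participants


def test_singular_refit_drops_slopes_in_order():
    """With zero planted random-effect variance the maximal model is
    singular; the fallback chain drops slopes (interactions first)."""
    from counterbart import cohort
    from counterbart.task import CostType, ExperimentConfig

    spec = cohort.GeneratorSpec(re_sd=0.0, n_participants=20, n_trials=30)
    cfg = ExperimentConfig("exp1", CostType.NONE, n_participants=20, n_trials=30)
    tab = cohort.generate_experiment(spec, cfg, np.random.default_rng(41))
    frame = prepare_variables(tab, "bank")
    fit = fit_emotion_model(frame, step=2, refit_on_singular=True)
    assert fit.singular_fit
    if fit.dropped_slopes:
        order = [models.SLOPE_DROP_ORDER.index(s) for s in fit.dropped_slopes]
        assert order == sorted(order)


def test_simple_slopes_arithmetic_and_zero_interaction():
    cov = pd.DataFrame(
        [[0.0004, 0.0001], [0.0001, 0.0009]],
        index=["MO_c", "IS:MO_c"],
        columns=["MO_c", "IS:MO_c"],
    )
    fit = FitResult(
        coefficients={
            "MO_c": CoefStats(-0.163, 0.02, -8.15, 0.0),
            "IS:MO_c": CoefStats(-0.144, 0.03, -4.8, 0.0),
        },
        cov_fixed=cov,
        re_var={},
        singular_fit=False,
        dropped_slopes=[],
        n_obs=100,
        n_participants=10,
        method="manual",
    )
    sought = simple_slopes(fit, +1)
    assert sought.b == pytest.approx(-0.307)
    assert sought.se == pytest.approx(np.sqrt(0.0004 + 0.0009 + 2 * 0.0001))
    not_sought = simple_slopes(fit, -1)
    assert not_sought.b == pytest.approx(-0.163 + 0.144)
    assert not_sought.se == pytest.approx(np.sqrt(0.0004 + 0.0009 - 2 * 0.0001))
    # zero interaction: both conditional slopes equal the main effect
    fit.coefficients["IS:MO_c"] = CoefStats(0.0, 0.03, 0.0, 1.0)
    assert simple_slopes(fit, +1).b == simple_slopes(fit, -1).b == -0.163
    with pytest.raises(ValueError):
        simple_slopes(fit, 0)
    del fit.coefficients["IS:MO_c"]
    with pytest.raises(KeyError):
        simple_slopes(fit, +1)


def test_welch_hand_computed_fixture():
    """5+5 fixture checked against the Welch-Satterthwaite formulas."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    w = welch_test(x, y)
    assert w.t == pytest.approx(-3.0 / np.sqrt(2.5))
    assert w.df == pytest.approx(6.25 / 1.0625)
    assert w.cohens_d == pytest.approx(-1.2)
    # identical groups: no effect
    same = welch_test(x, x.copy())
    assert same.t == 0.0 and same.cohens_d == 0.0
    with pytest.raises(ValueError):
        welch_test(x, np.array([1.0]))


def test_welch_recovers_planted_standardized_gap():
    """A -0.8 SD group gap at the replication's 153/63 split comes back
    as d ~ -0.8."""
    rng = np.random.default_rng(12)
    sought = rng.normal(-0.8, 1.0, size=153)
    not_sought = rng.normal(0.0, 1.0, size=63)
    w = welch_test(sought, not_sought)
    # sampling SE of d at these group sizes is ~0.15
    assert w.cohens_d == pytest.approx(-0.8, abs=0.45)
    assert w.p < 0.001


def test_replication_model_requires_unique_critical_rows():
    trials = _toy_trials(
        [("p1", 1, 20, 4, 9, True, 10.0), ("p1", 2, 20, 4, 9, True, 10.0)]
    )
    with pytest.raises(ValueError):
        replication_interaction_model(trials)
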