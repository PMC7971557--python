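import dataclasses

import numpy as np
import pandas as pd
import pytest

from purinomics import control_zscore, fit_dose_response
from purinomics.synthetic import (CalorimetryGroupSpec, CalorimetrySpec,
                                  MetabolomeSpec, simple_metabolome_spec,
                                  simulate_breath, simulate_calorimetry,
                                  simulate_dose_response, simulate_metabolome,
                                  study_breath_spec, study_calorimetry_spec,
                                  study_metabolome_spec)


def test_metabolome_seed_determinism():
    spec = simple_metabolome_spec(10, seed=1)
    t1 = simulate_metabolome(spec).auc.to_csv()
    t2 = simulate_metabolome(simple_metabolome_spec(10, seed=1)).auc.to_csv()
    assert t1 == t2
    t3 = simulate_metabolome(simple_metabolome_spec(10, seed=2)).auc.to_csv()
    assert t1 != t3


def test_metabolome_positive_and_complete():
    m = simulate_metabolome(study_metabolome_spec(seed=0))
    assert (m.auc.to_numpy() > 0).all()
    assert not m.auc.isna().any().any()
    assert m.auc.shape == (16, 401)
    assert m.pathways.nunique() == 37


def test_null_spec_gives_near_zero_treated_z():
    spec = simple_metabolome_spec(10, effect_z=0.0, seed=4)
    zm = control_zscore(simulate_metabolome(spec), "saline")
    assert np.all(np.abs(zm.mean_treated_z()) < 0.5 * 3)  # |mean| small at n=8
    assert np.abs(zm.mean_treated_z().mean()) < 0.5


def test_planted_effect_recovered_without_bias():
    """Monte-Carlo oracle: effect_z = -5 on 19 of 100 metabolites is
    recovered by preprocess with |bias| < 0.5 averaged over 100 seeds."""
    recovered = []
    for seed in range(100):
        eff = np.zeros(100)
        eff[:19] = -5.0
        spec = simple_metabolome_spec(100, effect_z=eff, seed=seed)
        zm = control_zscore(simulate_metabolome(spec), "saline")
        recovered.append(zm.mean_treated_z().iloc[:19].mean())
    assert abs(np.mean(recovered) - (-5.0)) < 0.5


def test_supercluster_members_correlate():
    met = simple_metabolome_spec(40, seed=0).metabolites.copy()
    met["supercluster"] = [0] * 20 + [-1] * 20
    spec = MetabolomeSpec(n_control=8, n_treated=60, metabolites=met,
                          supercluster_loading=0.8, seed=0)
    zm = control_zscore(simulate_metabolome(spec), "saline")
    zt = zm.z.loc[zm.treated_mask()]
    within = zt.iloc[:, :20].corr().to_numpy()[np.triu_indices(20, 1)].mean()
    across = np.corrcoef(zt.iloc[:, 0], zt.iloc[:, 30])[0, 1]
    assert within > 0.2
    assert within > abs(across)


def test_metabolome_spec_validation_names_the_field():
    with pytest.raises(ValueError, match="n_control"):
        simple_metabolome_spec(5, n_control=2)
    spec = simple_metabolome_spec(5)
    bad = spec.metabolites.assign(log2_sd=[0.5, 0.0, 0.5, 0.5, 0.5])
    with pytest.raises(ValueError, match="log2_sd"):
        MetabolomeSpec(8, 8, bad)
    bad = spec.metabolites.assign(effect_z=[0, np.inf, 0, 0, 0])
    with pytest.raises(ValueError, match="effect_z"):
        MetabolomeSpec(8, 8, bad)


def test_calorimetry_recovers_group_mean_within_three_se():
    spec = study_calorimetry_spec(seed=11)
    traces = simulate_calorimetry(spec)
    saline = [t for t in traces if t.group == "saline"]
    mean_vo2 = np.mean([t.intervals["vo2"].mean() for t in saline])
    se = 710 / np.sqrt(6)
    assert abs(mean_vo2 - 5302) < 3 * se


def test_calorimetry_zero_noise_intervals_equal_spec_mean():
    spec = CalorimetrySpec(
        groups={
            "saline": CalorimetryGroupSpec(n=2, vo2_mean=5302, vo2_sd=0,
                                           vco2_mean=4324, vco2_sd=0,
                                           activity_mean=100, activity_sd=0),
        },
        within_sd_frac=0.0,
        seed=0,
    )
    traces = simulate_calorimetry(spec)
    for t in traces:
        assert (t.intervals["vo2"] == 5302).all()
        assert (t.intervals["vco2"] == 4324).all()
        assert (t.intervals["beam_breaks"] == 100).all()
        assert len(t.intervals) == 14  # 13-minute cycles over 3 hours
        assert np.allclose(np.diff(t.intervals["start_min"]), 13.0)


def test_calorimetry_treated_traces_drop_after_injection():
    spec = study_calorimetry_spec(seed=0, injection_min=26.0)
    spec.within_sd_frac = 0.0
    for g in spec.groups.values():
        g.vo2_sd = g.vco2_sd = g.activity_sd = 0.0
    traces = simulate_calorimetry(spec)
    atp = next(t for t in traces if t.group == "ATP")
    pre = atp.intervals[atp.intervals["start_min"] < 26]["vo2"]
    post = atp.intervals[atp.intervals["start_min"] >= 26]["vo2"]
    assert (pre == 5302).all() and (post == 1382).all()


def test_calorimetry_seed_determinism_and_validation():
    s1 = simulate_calorimetry(study_calorimetry_spec(seed=5))
    s2 = simulate_calorimetry(study_calorimetry_spec(seed=5))
    for a, b in zip(s1, s2):
        pd.testing.assert_frame_equal(a.intervals, b.intervals)
    with pytest.raises(ValueError, match="vo2_mean"):
        CalorimetrySpec(groups={"g": CalorimetryGroupSpec(
            n=2, vo2_mean=-1, vo2_sd=0, vco2_mean=1, vco2_sd=0)},
            control_group="g")


def test_dose_response_noiseless_identity_and_determinism():
    t = simulate_dose_response(-27.8, 38.4, [0, 0.1, 0.2], 3, 0.0, seed=0)
    fit = fit_dose_response(t)
    assert fit.slopes["female"] == pytest.approx(-27.8)
    a = simulate_dose_response(-5, 38, [0, 0.1, 0.2], 4, 0.3, seed=2).to_csv()
    b = simulate_dose_response(-5, 38, [0, 0.1, 0.2], 4, 0.3, seed=2).to_csv()
    assert a == b
    with pytest.raises(ValueError, match="empty"):
        simulate_dose_response(-5, 38, [], 3, 0.1, seed=0)


def test_zero_slope_confidence_interval_covers_zero():
    """95% CI on a null slope covers 0 in >= 90/100 seeds."""
    from scipy import stats as ss

    covered = 0
    for seed in range(100):
        t = simulate_dose_response(0.0, 38.0, [0, 0.05, 0.1, 0.2], 6, 0.5,
                                   seed=seed)
        fit = fit_dose_response(t)
        half = ss.t.ppf(0.975, len(t) - 2) * fit.slope_se["female"]
        covered += int(abs(fit.slopes["female"]) <= half)
    assert covered >= 90


def test_breath_seed_determinism_and_structure():
    d1 = simulate_breath(study_breath_spec(seed=8)).to_csv()
    d2 = simulate_breath(study_breath_spec(seed=8)).to_csv()
    assert d1 == d2
    df = simulate_breath(study_breath_spec(seed=8))
    animals = df.loc[~df["is_background"], "animal"].unique()
    assert len(animals) == 6  # 3 per group x 2 groups
    per_animal = df.loc[~df["is_background"]].groupby("animal").size()
    assert (per_animal == 3).all()  # canisters at 1, 5 and 10 minutes
    assert df["is_background"].sum() == 2
    with pytest.raises(ValueError, match="non-negative"):
        spec = study_breath_spec()
        spec.background["CO"] = -1.0
        spec.validate()
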