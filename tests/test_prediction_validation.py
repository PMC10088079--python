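"""VPC bands, prediction intervals, coverage and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest

from sglt2mbma.errors import InputError
from sglt2mbma.parameters import DoseRegimen, PKParameters
from sglt2mbma.prediction_validation import (
    PredictionBand,
    coverage_check,
    gof_diagnostics,
    predict_new_drug,
    vpc,
)
from sglt2mbma.synthetic_data import (
    StudyDesign,
    default_endpoint_designs,
    endpoint_delta_uge_map,
    generate_endpoint_dataset,
)
from sglt2mbma.endpoint_model import hba1c_total


def test_band_ordering_enforced():
    with pytest.raises(InputError):
        PredictionBand(times=(0.0, 1.0), median=(1.0, 1.0),
                       lower=(2.0, 0.0), upper=(3.0, 3.0), n_sim=200)


def test_vpc_requires_enough_replicates(truth):
    designs = default_endpoint_designs(n_studies=4)
    obs = generate_endpoint_dataset(truth, designs, seed=0)
    with pytest.raises(InputError):
        vpc(obs, truth, designs, n_sim=50, seed=0)


def test_vpc_zero_variability_band_collapses(noiseless_truth):
    designs = default_endpoint_designs(n_studies=4)
    obs = generate_endpoint_dataset(noiseless_truth, designs, seed=0)
    res = vpc(obs, noiseless_truth, designs, n_sim=200, seed=1)
    assert res  # all four strata present at four studies
    for r in res.values():
        # every replicate is identical to the observations: the simulated
        # median collapses onto the observed one and the Monte-Carlo
        # envelope of the median has zero width
        assert np.allclose(r.band.median, r.observed["p50"], atol=1e-9)
        assert np.allclose(r.median_envelope["lo"], r.median_envelope["hi"],
                           atol=1e-9)
        assert np.allclose(r.median_envelope["lo"], r.observed["p50"],
                           atol=1e-9)


def test_vpc_stratifies_by_treatment_type(truth):
    designs = default_endpoint_designs(n_studies=8)
    obs = generate_endpoint_dataset(truth, designs, seed=2)
    res = vpc(obs, truth, designs, n_sim=200, seed=3)
    strata = {k[0] for k in res}
    assert strata == {"naive", "non_naive", "add_on", "mixed"}
    # empty stratum is skipped, not an error
    sub = obs[obs["treatment_type"] == "naive"]
    res2 = vpc(sub, truth, designs, n_sim=200, seed=3)
    assert {k[0] for k in res2} == {"naive"}


def test_vpc_self_coverage_near_ninety_percent(truth):
    """Data simulated from the same model: ~90% of points in the 5–95 band."""
    designs = default_endpoint_designs(n_studies=40)
    obs = generate_endpoint_dataset(truth, designs, seed=101)
    res = vpc(obs, truth, designs, n_sim=200, seed=7)
    hits, total = 0.0, 0
    for (stratum, endpoint), r in res.items():
        col = "fpg_mg_dl" if endpoint == "fpg" else "hba1c_pct"
        sub = obs[(obs["treatment_type"] == stratum) & obs[col].notna()]
        frac = coverage_check(
            pd.DataFrame({"time": sub["time_week"], "value": sub[col]}),
            r.band)
        hits += frac * len(sub)
        total += len(sub)
    assert hits / total == pytest.approx(0.90, abs=0.05)


def test_vpc_observed_median_calibrated_against_envelope(truth):
    """Averaged over replicate observed datasets, the observed median falls
    inside the 95% envelope of the simulated median in ≳90% of time bins."""
    designs = default_endpoint_designs(n_studies=16)
    res = vpc(generate_endpoint_dataset(truth, designs, seed=900),
              truth, designs, n_sim=200, seed=17)
    inside, total = 0, 0
    for rep in range(8):
        obs = generate_endpoint_dataset(truth, designs, seed=1000 + rep)
        for (stratum, endpoint), r in res.items():
            col = "fpg_mg_dl" if endpoint == "fpg" else "hba1c_pct"
            sub = obs[(obs["treatment_type"] == stratum) & obs[col].notna()]
            med = sub.groupby("time_week")[col].median()
            lo = r.median_envelope["lo"].reindex(med.index)
            hi = r.median_envelope["hi"].reindex(med.index)
            ok = (med >= lo) & (med <= hi)
            inside += int(ok.sum())
            total += int(ok.notna().sum())
    assert inside / total >= 0.90


def test_coverage_check_degenerate_cases():
    band = PredictionBand(times=(0.0, 10.0), median=(1.0, 1.0),
                          lower=(0.0, 0.0), upper=(2.0, 2.0), n_sim=200)
    on_median = pd.DataFrame({"time": [0.0, 5.0, 10.0], "value": [1.0] * 3})
    assert coverage_check(on_median, band) == 1.0
    outside = pd.DataFrame({"time": [0.0, 5.0, 10.0],
                            "value": [5.0, -5.0, 5.0]})
    assert coverage_check(outside, band) == 0.0
    with pytest.raises(InputError):
        coverage_check(pd.DataFrame(columns=["time", "value"]), band)


def test_predict_new_drug_center_matches_deterministic_curve(truth):
    """Without variability the band collapses onto the model trajectory of a
    reference-drug clone."""
    dapa = truth.pk["dapagliflozin"]
    weeks = (0.0, 4.0, 8.0, 12.0, 24.0)
    arm = StudyDesign(study_id="p", drug="clone", dose=10.0, n=200,
                      treatment_type="naive", endpoint_times=weeks,
                      baseline_fpg=160.0, baseline_hba1c=7.92)
    bands = predict_new_drug(dapa, 56.6, DoseRegimen(dose=10.0), arm, truth,
                             uncertainty=None, n_sim=200, seed=5,
                             include_iiv=False, include_residual=False)
    from sglt2mbma.biomarker_model import predict_delta_uge_c
    from sglt2mbma.pk_model import auc_ss_24
    duge = predict_delta_uge_c(auc_ss_24(dapa, DoseRegimen(dose=10.0)),
                               truth.biomarker, "dapagliflozin")
    expected = hba1c_total(np.asarray(weeks), truth.endpoints, "naive",
                           160.0, 7.92, duge)
    assert np.allclose(bands["hba1c"].median, expected, atol=1e-9)
    assert np.allclose(bands["hba1c"].lower, bands["hba1c"].upper, atol=1e-9)


def test_predict_new_drug_coverage_of_held_out_arms(truth):
    """≥ ~90% of held-out synthetic observations fall inside the 90% band."""
    pk = truth.pk["empagliflozin"]
    weeks = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    arm = StudyDesign(study_id="held-out", drug="empagliflozin", dose=25.0,
                      n=150, treatment_type="mixed", hba1c_times=weeks,
                      fpg_times=weeks)
    band = predict_new_drug(pk, 841.0, DoseRegimen(dose=25.0), arm, truth,
                            n_sim=500, seed=11)["hba1c"]
    obs_designs = [StudyDesign(study_id=f"ho-{i}", drug="empagliflozin",
                               dose=25.0, n=150, treatment_type="mixed",
                               hba1c_times=weeks, fpg_times=weeks)
                   for i in range(30)]
    obs = generate_endpoint_dataset(truth, obs_designs, seed=12)
    obs = obs[obs["hba1c_pct"].notna()]
    frac = coverage_check(pd.DataFrame({"time": obs["time_week"],
                                        "value": obs["hba1c_pct"]}), band)
    assert frac >= 0.85


def test_predict_band_stable_under_more_replicates(truth):
    pk = truth.pk["dapagliflozin"]
    arm = StudyDesign(study_id="p", drug="dapagliflozin", dose=10.0, n=150,
                      treatment_type="naive",
                      endpoint_times=(0.0, 12.0, 24.0))
    b1 = predict_new_drug(pk, 56.6, DoseRegimen(dose=10.0), arm, truth,
                          n_sim=1000, seed=3)["hba1c"]
    b2 = predict_new_drug(pk, 56.6, DoseRegimen(dose=10.0), arm, truth,
                          n_sim=2000, seed=4)["hba1c"]
    assert np.allclose(b1.median, b2.median, atol=0.05)
    assert np.allclose(b1.lower, b2.lower, atol=0.12)
    assert np.allclose(b1.upper, b2.upper, atol=0.12)


def test_gof_zero_noise_residuals_vanish(noiseless_truth):
    designs = default_endpoint_designs(n_studies=4)
    df = generate_endpoint_dataset(noiseless_truth, designs, seed=0)
    duge = endpoint_delta_uge_map(noiseless_truth, designs)
    g = gof_diagnostics(df, noiseless_truth, duge)
    assert np.max(np.abs(g["residual"])) < 1e-9


def test_gof_detects_misspecified_clearance(truth, noiseless_truth):
    """Doubling CL (halving exposure) leaves a one-sided residual trend."""
    from dataclasses import replace

    designs = [d for d in default_endpoint_designs(n_studies=8)
               if d.drug != "placebo"]
    df = generate_endpoint_dataset(noiseless_truth, designs, seed=1)
    bad_pk = {k: replace(v, CL=2 * v.CL) for k, v in truth.pk.items()}
    bad = replace(noiseless_truth, pk=bad_pk)
    g = gof_diagnostics(df[df["time_week"] > 0], bad)
    fpg = g[g["endpoint"] == "fpg"]["residual"]
    # halved exposure -> under-predicted drug effect -> negative residuals
    assert (fpg < 0).mean() > 0.95
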