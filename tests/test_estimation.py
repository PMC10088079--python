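"""Weighted estimation: weights, self-consistency, nesting, identifiability."""

from dataclasses import replace

import numpy as np
import pytest

from sglt2mbma.errors import InputError
from sglt2mbma.estimation import (
    FitSettings,
    compare_ofv,
    fit_endpoints,
    fit_pk,
    fit_pkpd,
    weight_of,
)
from sglt2mbma.parameters import DoseRegimen
from sglt2mbma.pk_model import auc_ss_24
from sglt2mbma.synthetic_data import (
    default_endpoint_designs,
    default_pk_designs,
    default_uge_designs,
    endpoint_delta_uge_map,
    generate_endpoint_dataset,
    generate_pk_dataset,
    generate_uge_dataset,
)

FAST = FitSettings(seed=0, n_starts=2)


def _auc_map(truth, designs):
    return {d.study_id: auc_ss_24(truth.pk[d.drug], DoseRegimen(dose=d.dose))
            for d in designs}


def test_weight_of_is_sqrt_n():
    assert weight_of(100) == 10.0
    assert weight_of(1) == 1.0
    assert weight_of(16) == 4.0
    with pytest.raises(InputError):
        weight_of(0)


def test_pk_zero_noise_exact_recovery(truth, noiseless_truth):
    """Noise-free profiles return every generating PK parameter < 0.1%."""
    designs = default_pk_designs("dapagliflozin", n_studies=6)
    df = generate_pk_dataset(noiseless_truth, designs, seed=5)
    fit = fit_pk(df, "dapagliflozin", truth.pk["dapagliflozin"], FAST)
    assert fit.converged
    p = truth.pk["dapagliflozin"]
    for name in ("CL", "Vc", "CLD", "VT", "Kt"):
        assert fit.estimates[name] == pytest.approx(getattr(p, name),
                                                    rel=1e-3)
    assert fit.estimates["fed_effect"] == pytest.approx(0.254, rel=1e-3)
    assert fit.estimates["CL"] == pytest.approx(19.5, rel=1e-3)


def test_pk_stochastic_recovery_cl(truth):
    """12 noisy studies recover clearance within 10% of the truth."""
    df = generate_pk_dataset(truth, default_pk_designs("dapagliflozin", 12),
                             seed=11)
    fit = fit_pk(df, "dapagliflozin", truth.pk["dapagliflozin"],
                 FitSettings(seed=1, n_starts=3))
    assert fit.converged
    assert fit.estimates["CL"] == pytest.approx(19.5, rel=0.10)
    assert all(v >= 0 for v in fit.rse_pct.values())


def test_pk_sparse_single_dose_design_flagged(noiseless_truth, truth):
    """One dose level and 3 sampling times: identifiability is flagged."""
    designs = [replace(d, pk_sampling=(1.0, 4.0, 24.0), dose=10.0)
               for d in default_pk_designs("dapagliflozin", 3)]
    df = generate_pk_dataset(noiseless_truth, designs, seed=2)
    fit = fit_pk(df, "dapagliflozin", truth.pk["dapagliflozin"], FAST)
    assert (not fit.converged) or any(not np.isfinite(v)
                                      for v in fit.rse_pct.values()) \
        or fit.messages


def test_pkpd_zero_noise_exact(truth, noiseless_truth):
    designs = default_uge_designs()
    uge = generate_uge_dataset(noiseless_truth, designs, seed=3)
    fit = fit_pkpd(uge, _auc_map(truth, designs), truth.biomarker, FAST)
    assert fit.estimates["Emax"] == pytest.approx(0.606, rel=1e-6)
    assert fit.estimates["EC50_dapagliflozin"] == pytest.approx(56.6, rel=1e-6)
    assert fit.estimates["EC50_canagliflozin"] == pytest.approx(2310, rel=1e-6)
    assert fit.estimates["EC50_empagliflozin"] == pytest.approx(841, rel=1e-6)


def test_pkpd_stochastic_recovery(truth):
    """27 noisy arms: Emax within 10%, EC50s within their published RSEs."""
    designs = default_uge_designs()
    uge = generate_uge_dataset(truth, designs, seed=0)
    fit = fit_pkpd(uge, _auc_map(truth, designs), truth.biomarker,
                   FitSettings(seed=0, n_starts=3))
    assert fit.estimates["Emax"] == pytest.approx(0.606, rel=0.10)
    assert fit.estimates["EC50_dapagliflozin"] == pytest.approx(56.6, rel=0.25)
    assert fit.estimates["EC50_canagliflozin"] == pytest.approx(2310, rel=0.25)
    assert fit.estimates["EC50_empagliflozin"] == pytest.approx(841, rel=0.30)


def test_pkpd_single_drug_warns(truth, noiseless_truth):
    designs = [d for d in default_uge_designs() if d.drug == "dapagliflozin"]
    uge = generate_uge_dataset(noiseless_truth, designs, seed=1)
    fit = fit_pkpd(uge, _auc_map(truth, designs), truth.biomarker, FAST)
    assert any("one drug" in m for m in fit.messages)


def test_shared_vs_per_drug_emax_nesting(truth):
    """Freeing Emax per drug adds 2 parameters and cannot worsen the OFV."""
    designs = default_uge_designs()
    uge = generate_uge_dataset(truth, designs, seed=4)
    auc = _auc_map(truth, designs)
    shared = fit_pkpd(uge, auc, truth.biomarker, FAST, shared_emax=True)
    free = fit_pkpd(uge, auc, truth.biomarker, FAST, shared_emax=False)
    cmp = compare_ofv(shared, free)
    assert cmp.delta_k == 2
    assert cmp.delta_ofv <= 1e-6


def test_compare_ofv_contracts(truth):
    designs = default_uge_designs()
    uge = generate_uge_dataset(truth, designs, seed=4)
    fit = fit_pkpd(uge, _auc_map(truth, designs), truth.biomarker, FAST)
    assert compare_ofv(fit, fit).delta_ofv == 0.0
    other = generate_uge_dataset(truth, designs, seed=5)
    fit2 = fit_pkpd(other, _auc_map(truth, designs), truth.biomarker, FAST)
    with pytest.raises(InputError):
        compare_ofv(fit, fit2)


def test_endpoint_zero_noise_placebo_recovery(truth, noiseless_truth):
    designs = default_endpoint_designs(n_studies=12)
    df = generate_endpoint_dataset(noiseless_truth, designs, seed=6)
    duge = endpoint_delta_uge_map(truth, designs)
    fit = fit_endpoints(df, duge, truth.endpoints, FAST, stage="placebo")
    ep = truth.endpoints
    for g, v in ep.p_fmax.items():
        assert fit.estimates[f"p_fmax_{g}"] == pytest.approx(v, rel=1e-3)
    assert fit.estimates["k_fp"] == pytest.approx(ep.k_fp, rel=1e-3)
    assert fit.estimates["dis_fp"] == pytest.approx(ep.dis_fp, rel=1e-3)
    assert fit.estimates["k_hp"] == pytest.approx(ep.k_hp, rel=1e-3)


def test_endpoint_zero_noise_drug_recovery(truth, noiseless_truth):
    designs = default_endpoint_designs(n_studies=12)
    df = generate_endpoint_dataset(noiseless_truth, designs, seed=6)
    duge = endpoint_delta_uge_map(truth, designs)
    fit = fit_endpoints(df, duge, truth.endpoints, FAST, stage="drug")
    assert fit.estimates["slope_fd"] == pytest.approx(-43.3, rel=1e-4)
    assert fit.estimates["k_out"] == pytest.approx(0.200, rel=1e-3)
    assert fit.estimates["k_in2"] == pytest.approx(0.500, rel=1e-3)


def test_endpoint_stage_input_contracts(truth, noiseless_truth):
    designs = default_endpoint_designs(n_studies=4)
    df = generate_endpoint_dataset(noiseless_truth, designs, seed=1)
    drug_only = df[df["drug"] != "placebo"]
    with pytest.raises(InputError):
        fit_endpoints(drug_only, {}, truth.endpoints, FAST, stage="placebo")
    pbo_only = df[df["drug"] == "placebo"]
    with pytest.raises(InputError):
        fit_endpoints(pbo_only, {}, truth.endpoints, FAST, stage="drug")
    with pytest.raises(InputError):
        fit_endpoints(df, {}, truth.endpoints, FAST, stage="bogus")


def test_objective_invariant_under_uniform_n_rescale(truth, noiseless_truth):
    """Multiplying every arm size by a constant leaves the argmin unchanged."""
    designs = default_uge_designs()
    uge = generate_uge_dataset(truth, designs, seed=9)
    auc = _auc_map(truth, designs)
    fit1 = fit_pkpd(uge, auc, truth.biomarker, FAST)
    big = uge.copy()
    big["n"] = big["n"] * 9
    fit2 = fit_pkpd(big, auc, truth.biomarker, FAST)
    for k, v in fit1.estimates.items():
        assert fit2.estimates[k] == pytest.approx(v, rel=1e-5)
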