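"""Seeded generators for summary-level (arm-mean) meta-analysis datasets.

The generators emulate the statistical structure the estimation stages
assume: arm means whose residual noise shrinks as 1/√n, inter-study random
effects (additive on the placebo-maximum parameters, exponential/log-normal
elsewhere), four treatment-type strata, and drugs that differ only in PK
parameters and EC50.  Every generator is a pure function of
(truth, designs, seed): per-study random substreams are derived from the
root seed and the study index, so adding a study never perturbs the draws
of existing ones.

The default design catalogs mirror the published data volumes: 12 pooled PK
studies per drug, 27 biomarker (ΔUGEc) arms across the three drugs, and 40
endpoint studies across the four treatment types whose time grids emit
exactly 195 placebo + 653 drug FPG and 290 placebo + 929 drug HbA1c points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarker_model import predict_delta_uge_c
from .errors import InputError
from .parameters import (
    DRUGS,
    DoseRegimen,
    PKParameters,
    SimulationTruth,
    TreatmentType,
)
from .pk_model import auc_ss_24, simulate_pk

__all__ = [
    "StudyDesign",
    "generate_pk_dataset",
    "generate_uge_dataset",
    "generate_endpoint_dataset",
    "generate_new_drug_scenario",
    "draw_study_effects",
    "endpoint_delta_uge_map",
    "default_pk_designs",
    "default_uge_designs",
    "default_endpoint_designs",
    "minimal_designs",
]

_GROUPS = tuple(t.value for t in TreatmentType)


@dataclass(frozen=True)
class StudyDesign:
    """One study arm of a synthetic meta-dataset."""

    study_id: str
    drug: str  # drug name or "placebo"
    dose: float  # mg (0 for placebo)
    n: int  # arm size
    fed: bool = False
    treatment_type: str = "mixed"
    population: str = "T2DM"  # "healthy" | "T2DM"
    pk_sampling: tuple[float, ...] | None = None  # h
    uge_measured: bool = False
    endpoint_times: tuple[float, ...] = ()  # weeks (fallback grid)
    fpg_times: tuple[float, ...] | None = None
    hba1c_times: tuple[float, ...] | None = None
    baseline_fpg: float | None = None  # mg/dL; None -> population value
    baseline_hba1c: float | None = None  # %

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError("arm size n must be >= 1")
        for grid in (self.endpoint_times, self.fpg_times, self.hba1c_times):
            if grid is not None and len(grid) and (
                np.any(np.asarray(grid) < 0)
                or np.any(np.diff(np.asarray(grid)) <= 0)
            ):
                raise InputError("time grids must be non-negative increasing")

    @property
    def arm_id(self) -> str:
        return f"{self.study_id}:{self.drug}:{self.dose:g}"


def _rng(seed: int, stream: int, idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, idx]))


def _exp_eta(rng, magnitude: float) -> float:
    return float(np.exp(rng.normal(0.0, magnitude))) if magnitude > 0 else 1.0


def _residual(rng, pred, n, sig2p, sig2a):
    """Arm-mean residual model: pred·(1 + εp/√n) + εa/√n."""
    pred = np.asarray(pred, dtype=float)
    sqn = np.sqrt(n)
    eps_p = rng.normal(0.0, np.sqrt(sig2p), pred.shape) if sig2p > 0 else 0.0
    eps_a = rng.normal(0.0, np.sqrt(sig2a), pred.shape) if sig2a > 0 else 0.0
    return pred * (1.0 + eps_p / sqn) + eps_a / sqn


def _perturb_pk(rng, p: PKParameters) -> PKParameters:
    from dataclasses import replace

    kw = {}
    for name in ("CL", "Vc", "CLD", "VT", "Kt"):
        kw[name] = getattr(p, name) * _exp_eta(rng, p.iiv.get(name, 0.0))
    return replace(p, **kw)


def draw_study_effects(rng: np.random.Generator, ep) -> dict:
    """Draw one study's inter-study random effects on the endpoint model.

    Additive normal deviates on the placebo maxima, exponential (log-normal)
    multipliers elsewhere; zero magnitudes give the population values.
    """
    iiv = ep.iiv
    pf_sd = iiv.get("p_fmax", {})
    ph_sd = iiv.get("p_hmax", {})
    return {
        "fpg_b_eta": _exp_eta(rng, iiv.get("fpg_baseline", 0.0)),
        "hba_b_eta": _exp_eta(rng, iiv.get("hba1c_baseline", 0.0)),
        "p_fmax": {g: ep.p_fmax[g] + (rng.normal(0.0, pf_sd.get(g, 0.0))
                                      if pf_sd.get(g, 0.0) > 0 else 0.0)
                   for g in _GROUPS},
        "p_hmax": {g: ep.p_hmax[g] + (rng.normal(0.0, ph_sd.get(g, 0.0))
                                      if ph_sd.get(g, 0.0) > 0 else 0.0)
                   for g in _GROUPS},
        "k_fp": ep.k_fp * _exp_eta(rng, iiv.get("k_fp", 0.0)),
        "dis_fp": ep.dis_fp * _exp_eta(rng, iiv.get("dis_fp", 0.0)),
        "slope_fd": ep.slope_fd * _exp_eta(rng, iiv.get("slope_fd", 0.0)),
        "k_hp": ep.k_hp * _exp_eta(rng, iiv.get("k_hp", 0.0)),
        "dis_hp": ep.dis_hp * _exp_eta(rng, iiv.get("dis_hp", 0.0)),
        "k_out": ep.k_out * _exp_eta(rng, iiv.get("k_out", 0.0)),
        "k_in2": ep.k_in2 * _exp_eta(rng, iiv.get("k_in2", 0.0)),
    }


# ---------------------------------------------------------------------------
# generators

def generate_pk_dataset(truth: SimulationTruth, designs, seed: int) -> pd.DataFrame:
    """Arm-mean concentration records (concentrations CSV schema)."""
    rows = []
    for idx, d in enumerate(designs):
        if d.pk_sampling is None:
            continue
        rng = _rng(seed, 1, idx)
        p = _perturb_pk(rng, truth.pk[d.drug])
        times = np.asarray(d.pk_sampling, dtype=float)
        prof = simulate_pk(p, DoseRegimen(dose=d.dose, fed=d.fed), times)
        obs = _residual(rng, prof.concentrations, d.n,
                        p.sigma2_prop, p.sigma2_add)
        for t, c in zip(times, obs):
            rows.append({"study_id": d.study_id, "drug": d.drug,
                         "dose_mg": d.dose, "fed": int(d.fed),
                         "time_h": t, "conc_ng_ml": c, "n": d.n})
    return pd.DataFrame(rows)


def generate_uge_dataset(truth: SimulationTruth, designs, seed: int) -> pd.DataFrame:
    """24-h UGE records with baselines (uge CSV schema).

    The sampled ΔUGEc value is emitted as a raw (uge24, baseline, FPG
    baseline) triplet whose recomputed ΔUGEc reproduces it exactly.
    """
    bm = truth.biomarker
    rows = []
    for idx, d in enumerate(designs):
        if not d.uge_measured:
            continue
        rng = _rng(seed, 2, idx)
        healthy = d.population == "healthy"
        fpg_b = d.baseline_fpg if d.baseline_fpg is not None else (
            95.0 if healthy else truth.endpoints.fpg_baseline_pop)
        uge_b = 0.06 if healthy else 3.0
        if d.drug == "placebo":
            duge_true = 0.0
        else:
            auc = auc_ss_24(truth.pk[d.drug], DoseRegimen(dose=d.dose))
            duge_true = predict_delta_uge_c(auc, bm, d.drug)
        duge_obs = float(_residual(rng, duge_true, d.n,
                                   bm.sigma2_prop, bm.sigma2_add))
        rows.append({
            "study_id": d.study_id, "drug": d.drug, "dose_mg": d.dose,
            "n": d.n, "uge24_g": uge_b + duge_obs * fpg_b,
            "uge24_baseline_g": uge_b, "fpg_baseline_mg_dl": fpg_b,
            "population": d.population,
        })
    return pd.DataFrame(rows)


def endpoint_delta_uge_map(truth: SimulationTruth, designs) -> dict[str, float]:
    """Model-predicted ΔUGEc per endpoint arm (0 for placebo arms).

    This is the quantity the sequential workflow feeds into the endpoint
    fit: the biomarker predicted from each arm's steady-state exposure.
    """
    out = {}
    for d in designs:
        if not (d.fpg_times or d.hba1c_times or d.endpoint_times):
            continue
        if d.drug == "placebo":
            out[d.arm_id] = 0.0
        else:
            auc = auc_ss_24(truth.pk[d.drug], DoseRegimen(dose=d.dose))
            out[d.arm_id] = predict_delta_uge_c(auc, truth.biomarker, d.drug)
    return out


def generate_endpoint_dataset(truth: SimulationTruth, designs,
                              seed: int) -> pd.DataFrame:
    """FPG/HbA1c time-course records (endpoints CSV schema).

    Study-level random effects are drawn once per study (keyed by study
    index) and shared by all arms of the study; residual noise is additive
    with SD shrinking as 1/√n.
    """
    ep = truth.endpoints
    designs = [d for d in designs
               if d.fpg_times or d.hba1c_times or d.endpoint_times]
    study_ids = []
    for d in designs:
        if d.study_id not in study_ids:
            study_ids.append(d.study_id)

    study_fx = {sid: draw_study_effects(_rng(seed, 3, s_idx), ep)
                for s_idx, sid in enumerate(study_ids)}

    rows = []
    for a_idx, d in enumerate(designs):
        rng = _rng(seed, 4, a_idx)
        fx = study_fx[d.study_id]
        g = TreatmentType.parse(d.treatment_type).value
        fpg_b = (d.baseline_fpg or ep.fpg_baseline_pop) * fx["fpg_b_eta"]
        hba_b = (d.baseline_hba1c or ep.hba1c_baseline_pop) * fx["hba_b_eta"]
        if d.drug == "placebo":
            duge, slope = 0.0, 0.0
        else:
            auc = auc_ss_24(truth.pk[d.drug], DoseRegimen(dose=d.dose))
            duge = predict_delta_uge_c(auc, truth.biomarker, d.drug)
            slope = fx["slope_fd"]
        fpg_times = np.asarray(d.fpg_times if d.fpg_times is not None
                               else d.endpoint_times, dtype=float)
        hba_times = np.asarray(d.hba1c_times if d.hba1c_times is not None
                               else d.endpoint_times, dtype=float)

        fpg_pred = (fpg_b + fx["p_fmax"][g] * (1.0 - np.exp(-fx["k_fp"] * fpg_times))
                    + fx["dis_fp"] / 100.0 * fpg_times + slope * duge)
        fpg_obs = fpg_pred + (rng.normal(0.0, np.sqrt(ep.sigma2_fpg),
                                         fpg_times.shape) / np.sqrt(d.n)
                              if ep.sigma2_fpg > 0 else 0.0)

        k_in = max(fx["k_out"] * hba_b - fx["k_in2"], 1e-3)
        hba_pred = (hba_b + fx["p_hmax"][g] * (1.0 - np.exp(-fx["k_hp"] * hba_times))
                    + fx["dis_hp"] / 100.0 * hba_times
                    + (slope * duge / fpg_b) * (k_in / fx["k_out"])
                    * (1.0 - np.exp(-fx["k_out"] * hba_times)))
        hba_obs = hba_pred + (rng.normal(0.0, np.sqrt(ep.sigma2_hba1c),
                                         hba_times.shape) / np.sqrt(d.n)
                              if ep.sigma2_hba1c > 0 else 0.0)

        all_times = sorted(set(fpg_times) | set(hba_times))
        fpg_map = dict(zip(fpg_times, np.atleast_1d(fpg_obs)))
        hba_map = dict(zip(hba_times, np.atleast_1d(hba_obs)))
        for t in all_times:
            rows.append({
                "study_id": d.study_id, "arm_id": d.arm_id, "drug": d.drug,
                "treatment_type": g, "dose_mg": d.dose, "n": d.n,
                "time_week": t,
                "fpg_mg_dl": fpg_map.get(t, np.nan),
                "hba1c_pct": hba_map.get(t, np.nan),
                "fpg_baseline_mg_dl": fpg_b,
                "hba1c_baseline_pct": hba_b,
            })
    return pd.DataFrame(rows)


def generate_new_drug_scenario(truth_extended: SimulationTruth, designs=None,
                               seed: int = 0) -> dict[str, pd.DataFrame]:
    """Full synthetic dataset for a hypothetical fourth same-in-class drug.

    ``truth_extended`` must already carry the new drug's PK parameters and
    EC50 (see :meth:`SimulationTruth.with_new_drug`); Emax and all endpoint
    parameters are inherited as system-specific.  Rehearses the
    translational workflow: healthy-subject PK and ΔUGEc arms plus patient
    endpoint arms.
    """
    new_drugs = [d for d in truth_extended.pk if d not in DRUGS]
    if not new_drugs:
        raise InputError("truth carries no drug beyond the reference three")
    missing = [d for d in new_drugs
               if d not in truth_extended.biomarker.EC50_by_drug]
    if missing:
        raise InputError(f"new drug(s) missing an EC50 entry: {missing}")
    drug = new_drugs[0]
    if designs is None:
        designs = _new_drug_designs(drug)
    return {
        "concentrations": generate_pk_dataset(truth_extended, designs, seed),
        "uge": generate_uge_dataset(truth_extended, designs, seed),
        "endpoints": generate_endpoint_dataset(truth_extended, designs, seed),
    }


# ---------------------------------------------------------------------------
# default design catalogs

_PK_TIMES = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0)


def default_pk_designs(drug: str = "dapagliflozin",
                       n_studies: int = 12) -> list[StudyDesign]:
    """Single-dose PK studies: 2 dose levels, 10 sampling times over 48 h."""
    doses = {"dapagliflozin": (5.0, 10.0), "canagliflozin": (100.0, 300.0),
             "empagliflozin": (10.0, 25.0)}.get(drug, (5.0, 10.0))
    sizes = (12, 18, 24, 36)
    out = []
    for i in range(n_studies):
        out.append(StudyDesign(
            study_id=f"pk-{drug[:4]}-{i:02d}", drug=drug,
            dose=doses[i % 2], n=sizes[i % 4],
            fed=(drug == "dapagliflozin" and i % 4 >= 2),
            population="healthy", pk_sampling=_PK_TIMES,
        ))
    return out


_UGE_DOSES = {
    "dapagliflozin": (0.3, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0),
    "canagliflozin": (2.5, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 300.0, 600.0),
    "empagliflozin": (0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0),
}


def default_uge_designs(n_per_arm: int = 24) -> list[StudyDesign]:
    """27 ΔUGEc arms (9 doses × 3 drugs) spanning each drug's EC50."""
    out = []
    for drug in DRUGS:
        for j, dose in enumerate(_UGE_DOSES[drug]):
            out.append(StudyDesign(
                study_id=f"uge-{drug[:4]}-{j:02d}", drug=drug, dose=dose,
                n=n_per_arm, population="healthy" if j % 2 == 0 else "T2DM",
                uge_measured=True,
            ))
    return out


# endpoint time-grid templates (weeks); assignment rules below reproduce the
# published data volume: 195/653 FPG and 290/929 HbA1c placebo/drug points
_PBO_FPG_5 = (0.0, 2.0, 4.0, 24.0, 52.0)
_PBO_FPG_4 = (0.0, 4.0, 24.0, 52.0)
_DRUG_FPG_8 = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0, 24.0)
_DRUG_FPG_9 = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0, 24.0, 52.0)
_PBO_HBA_7 = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
_PBO_HBA_8 = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 52.0)
_DRUG_HBA_11 = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 40.0, 52.0)
_DRUG_HBA_12 = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 40.0, 46.0, 52.0)

_EP_DOSES = {"dapagliflozin": (5.0, 10.0), "canagliflozin": (100.0, 300.0),
             "empagliflozin": (10.0, 25.0)}
_EP_SIZES = (50, 80, 120, 200, 300, 500, 64, 150, 250, 400)


def default_endpoint_designs(n_studies: int = 40) -> list[StudyDesign]:
    """Endpoint catalog: per study one placebo + two drug arms, 0–52 weeks."""
    out = []
    drug_arm_idx = 0
    for s in range(n_studies):
        sid = f"ep-{s:02d}"
        group = _GROUPS[s % 4]
        drug = DRUGS[s % 3]
        n_pbo = _EP_SIZES[s % len(_EP_SIZES)]
        out.append(StudyDesign(
            study_id=sid, drug="placebo", dose=0.0, n=n_pbo,
            treatment_type=group,
            fpg_times=_PBO_FPG_5 if s < 35 else _PBO_FPG_4,
            hba1c_times=_PBO_HBA_8 if s < 10 else _PBO_HBA_7,
        ))
        for j, dose in enumerate(_EP_DOSES[drug]):
            out.append(StudyDesign(
                study_id=sid, drug=drug, dose=dose,
                n=_EP_SIZES[(s + 3 * j + 1) % len(_EP_SIZES)],
                treatment_type=group,
                fpg_times=_DRUG_FPG_9 if drug_arm_idx < 13 else _DRUG_FPG_8,
                hba1c_times=_DRUG_HBA_12 if drug_arm_idx < 49 else _DRUG_HBA_11,
            ))
            drug_arm_idx += 1
    return out


def _new_drug_designs(drug: str) -> list[StudyDesign]:
    designs = []
    for i in range(4):
        designs.append(StudyDesign(
            study_id=f"nd-pk-{i}", drug=drug, dose=(5.0, 15.0)[i % 2],
            n=(12, 24)[i % 2], population="healthy", pk_sampling=_PK_TIMES,
        ))
    for j, dose in enumerate((1.0, 2.5, 5.0, 10.0, 15.0, 25.0)):
        designs.append(StudyDesign(
            study_id=f"nd-uge-{j}", drug=drug, dose=dose, n=24,
            population="healthy", uge_measured=True,
        ))
    for s in range(6):
        sid = f"nd-ep-{s}"
        group = _GROUPS[s % 4]
        designs.append(StudyDesign(
            study_id=sid, drug="placebo", dose=0.0, n=150,
            treatment_type=group, fpg_times=_PBO_FPG_5,
            hba1c_times=_PBO_HBA_7,
        ))
        designs.append(StudyDesign(
            study_id=sid, drug=drug, dose=15.0, n=150,
            treatment_type=group, fpg_times=_DRUG_FPG_8,
            hba1c_times=_DRUG_HBA_11,
        ))
    return designs


def minimal_designs() -> dict[str, list[StudyDesign]]:
    """A small catalog exercising every pipeline stage quickly."""
    pk = default_pk_designs("dapagliflozin", n_studies=4)
    uge = [d for i, d in enumerate(default_uge_designs()) if i % 3 == 0]
    ep = default_endpoint_designs(n_studies=8)
    return {"pk": pk, "uge": uge, "endpoints": ep}
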