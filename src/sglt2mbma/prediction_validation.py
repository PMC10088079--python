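"""Visual predictive checks, new-drug prediction intervals and diagnostics.

The VPC re-simulates the endpoint meta-dataset under the fitted (or true)
parameters with full inter-study and residual variability and compares
observed percentiles per time bin and treatment-type stratum with
simulation percentile bands.  New-drug prediction propagates parameter
uncertainty (normal on the estimation scale: log for positive parameters,
relative-normal for signed ones), inter-study variability, and residual
noise through the PK → ΔUGEc → FPG → HbA1c chain to a 90% prediction
interval.

"Weighted residuals" here are √n-standardized residuals of the weighted
fit — an intentional desk-scale stand-in for the conditional weighted
residuals of full conditional-estimation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarker_model import predict_delta_uge_c
from .errors import InputError
from .parameters import (
    DoseRegimen,
    PKParameters,
    SimulationTruth,
    TreatmentType,
)
from .pk_model import auc_ss_24
from .synthetic_data import (
    StudyDesign,
    draw_study_effects,
    generate_endpoint_dataset,
)

__all__ = ["PredictionBand", "VPCResult", "vpc", "predict_new_drug",
           "coverage_check", "gof_diagnostics"]

_MIN_SIM = 200


@dataclass(frozen=True)
class PredictionBand:
    """Time-indexed simulation percentiles: median and 5%/95% bounds."""

    times: tuple[float, ...]
    median: tuple[float, ...]
    lower: tuple[float, ...]  # 5th percentile
    upper: tuple[float, ...]  # 95th percentile
    n_sim: int
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        lo, md, up = map(np.asarray, (self.lower, self.median, self.upper))
        if not (t.size == lo.size == md.size == up.size):
            raise InputError("band arrays must have equal length")
        if np.any(lo > md + 1e-12) or np.any(md > up + 1e-12):
            raise InputError("band percentiles must be ordered lower<=median<=upper")


@dataclass(frozen=True)
class VPCResult:
    """Observed vs simulated percentiles for one stratum and endpoint."""

    stratum: str
    endpoint: str
    times: tuple[float, ...]
    observed: pd.DataFrame  # columns p5, p50, p95 indexed by time
    band: PredictionBand  # pooled simulated 5/50/95
    median_envelope: pd.DataFrame  # 95% envelope of the simulated median


def _percentiles_by_time(df: pd.DataFrame, col: str):
    sub = df[df[col].notna()]
    grouped = sub.groupby("time_week")[col]
    times = np.array(sorted(grouped.groups))
    p = {q: grouped.quantile(q / 100.0).reindex(times).to_numpy()
         for q in (5, 50, 95)}
    return times, p


def vpc(dataset: pd.DataFrame, truth: SimulationTruth, designs,
        n_sim: int = 200, seed: int = 0,
        stratify: bool = True) -> dict[tuple[str, str], VPCResult]:
    """Visual predictive check of the endpoint models.

    Simulates ``n_sim`` replicate meta-datasets from ``designs`` under
    ``truth`` and returns, per (treatment-type stratum, endpoint), the
    observed 5/50/95 percentiles, the pooled simulated percentile band, and
    the 95% Monte-Carlo envelope of the simulated median.  Empty strata are
    skipped.
    """
    if n_sim < _MIN_SIM:
        raise InputError(f"n_sim must be >= {_MIN_SIM}")
    ss = np.random.SeedSequence([int(seed), 7])
    rep_seeds = [int(s) for s in
                 ss.generate_state(n_sim, dtype=np.uint32)]
    reps = [generate_endpoint_dataset(truth, designs, s) for s in rep_seeds]

    strata = (sorted(dataset["treatment_type"].unique()) if stratify
              else ["all"])
    out: dict[tuple[str, str], VPCResult] = {}
    for stratum in strata:
        if stratify:
            obs_sub = dataset[dataset["treatment_type"] == stratum]
            rep_subs = [r[r["treatment_type"] == stratum] for r in reps]
        else:
            obs_sub, rep_subs = dataset, reps
        if obs_sub.empty:
            continue
        for col, short in (("fpg_mg_dl", "fpg"), ("hba1c_pct", "hba1c")):
            if obs_sub[col].notna().sum() == 0:
                continue
            times, obs_p = _percentiles_by_time(obs_sub, col)
            sim_p = {5: [], 50: [], 95: []}
            pooled = {t: [] for t in times}
            for r in rep_subs:
                rt, rp = _percentiles_by_time(r, col)
                aligned = {q: np.interp(times, rt, rp[q]) for q in rp}
                for q in sim_p:
                    sim_p[q].append(aligned[q])
                vals = r[r[col].notna()]
                for t, g in vals.groupby("time_week")[col]:
                    if t in pooled:
                        pooled[t].append(g.to_numpy())
            med_stack = np.vstack(sim_p[50])
            pooled_arr = [np.concatenate(pooled[t]) for t in times]
            band = PredictionBand(
                times=tuple(times),
                median=tuple(np.median(v) for v in pooled_arr),
                lower=tuple(np.percentile(v, 5) for v in pooled_arr),
                upper=tuple(np.percentile(v, 95) for v in pooled_arr),
                n_sim=n_sim, seed=seed,
            )
            env = pd.DataFrame({
                "time_week": times,
                "lo": np.percentile(med_stack, 2.5, axis=0),
                "hi": np.percentile(med_stack, 97.5, axis=0),
            }).set_index("time_week")
            observed = pd.DataFrame(
                {"p5": obs_p[5], "p50": obs_p[50], "p95": obs_p[95]},
                index=pd.Index(times, name="time_week"))
            out[(stratum, short)] = VPCResult(
                stratum=stratum, endpoint=short, times=tuple(times),
                observed=observed, band=band, median_envelope=env)
    return out


def predict_new_drug(
    pk: PKParameters,
    ec50: float,
    regimen: DoseRegimen,
    arm: StudyDesign,
    truth: SimulationTruth,
    uncertainty: dict[str, float] | None = None,
    n_sim: int = 500,
    seed: int = 0,
    include_iiv: bool = True,
    include_residual: bool = True,
) -> dict[str, PredictionBand]:
    """90% prediction interval for a new same-in-class drug's endpoints.

    ``uncertainty`` maps parameter names (``CL``, ``Emax``, ``EC50``,
    ``slope_fd``, ``k_out``, ``k_in2``) to fractional standard errors; when
    omitted the band reflects variability only.  Emax and all endpoint
    parameters come from the fitted system model in ``truth``; only PK and
    EC50 are drug-specific.
    """
    if n_sim < _MIN_SIM:
        raise InputError(f"n_sim must be >= {_MIN_SIM}")
    ep = truth.endpoints
    group = TreatmentType.parse(arm.treatment_type).value
    t_fpg = np.asarray(arm.fpg_times if arm.fpg_times is not None
                       else arm.endpoint_times, dtype=float)
    t_hba = np.asarray(arm.hba1c_times if arm.hba1c_times is not None
                       else arm.endpoint_times, dtype=float)
    unc = dict(uncertainty or {})
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 8]))

    fpg_sims = np.empty((n_sim, t_fpg.size))
    hba_sims = np.empty((n_sim, t_hba.size))
    for s in range(n_sim):
        # parameter uncertainty (estimation-scale normal approximation)
        cl = pk.CL * np.exp(rng.normal(0, unc.get("CL", 0.0)))
        emax = truth.biomarker.Emax * np.exp(rng.normal(0, unc.get("Emax", 0.0)))
        ec = ec50 * np.exp(rng.normal(0, unc.get("EC50", 0.0)))
        slope_pop = ep.slope_fd * (1.0 + rng.normal(0, unc.get("slope_fd", 0.0)))
        k_out_pop = ep.k_out * np.exp(rng.normal(0, unc.get("k_out", 0.0)))
        k_in2_pop = ep.k_in2 * np.exp(rng.normal(0, unc.get("k_in2", 0.0)))
        from dataclasses import replace
        ep_s = replace(ep, slope_fd=slope_pop, k_out=k_out_pop,
                       k_in2=k_in2_pop)
        fx = (draw_study_effects(rng, ep_s) if include_iiv
              else draw_study_effects(np.random.default_rng(0),
                                      replace(ep_s, iiv={})))
        fpg_b = (arm.baseline_fpg or ep.fpg_baseline_pop) * fx["fpg_b_eta"]
        hba_b = (arm.baseline_hba1c or ep.hba1c_baseline_pop) * fx["hba_b_eta"]
        auc = regimen.dose / cl * (24.0 / regimen.interval) * 1000.0
        duge = emax * auc / (ec + auc)
        dfpg = fx["slope_fd"] * duge
        fpg = (fpg_b + fx["p_fmax"][group] * (1 - np.exp(-fx["k_fp"] * t_fpg))
               + fx["dis_fp"] / 100.0 * t_fpg + dfpg)
        k_in = max(fx["k_out"] * hba_b - fx["k_in2"], 1e-3)
        hba = (hba_b + fx["p_hmax"][group] * (1 - np.exp(-fx["k_hp"] * t_hba))
               + fx["dis_hp"] / 100.0 * t_hba
               + (dfpg / fpg_b) * (k_in / fx["k_out"])
               * (1 - np.exp(-fx["k_out"] * t_hba)))
        if include_residual:
            fpg = fpg + rng.normal(0, np.sqrt(ep.sigma2_fpg / arm.n),
                                   t_fpg.shape)
            hba = hba + rng.normal(0, np.sqrt(ep.sigma2_hba1c / arm.n),
                                   t_hba.shape)
        fpg_sims[s] = fpg
        hba_sims[s] = hba

    def band(times, sims):
        return PredictionBand(
            times=tuple(times),
            median=tuple(np.percentile(sims, 50, axis=0)),
            lower=tuple(np.percentile(sims, 5, axis=0)),
            upper=tuple(np.percentile(sims, 95, axis=0)),
            n_sim=n_sim, seed=seed)

    return {"fpg": band(t_fpg, fpg_sims), "hba1c": band(t_hba, hba_sims)}


def coverage_check(observations: pd.DataFrame, band: PredictionBand) -> float:
    """Fraction of observed (time, value) points inside the band.

    ``observations`` needs columns ``time`` and ``value``; band bounds are
    linearly interpolated at the observation times.
    """
    if observations.empty:
        raise InputError("no observations supplied")
    t = observations["time"].to_numpy(dtype=float)
    v = observations["value"].to_numpy(dtype=float)
    lo = np.interp(t, band.times, band.lower)
    up = np.interp(t, band.times, band.upper)
    return float(np.mean((v >= lo) & (v <= up)))


def gof_diagnostics(dataset: pd.DataFrame, truth: SimulationTruth,
                    delta_uge_c_by_arm: dict[str, float] | None = None
                    ) -> pd.DataFrame:
    """Goodness-of-fit residual table for an endpoint dataset.

    Population predictions (no inter-study effects) per record, residuals,
    and √n-standardized weighted residuals; tidy long format with one row
    per observation, suitable for plotting prediction-vs-observation and
    residual-vs-time/prediction diagnostics with any plotting tool.
    """
    ep = truth.endpoints
    duge_map = delta_uge_c_by_arm or {}
    rows = []
    for _, rec in dataset.iterrows():
        group = TreatmentType.parse(rec["treatment_type"]).value
        if rec["arm_id"] in duge_map:
            duge = duge_map[rec["arm_id"]]
        elif rec["drug"] == "placebo":
            duge = 0.0
        else:
            auc = auc_ss_24(truth.pk[rec["drug"]],
                            DoseRegimen(dose=rec["dose_mg"]))
            duge = predict_delta_uge_c(auc, truth.biomarker, rec["drug"])
        t = float(rec["time_week"])
        n = float(rec["n"])
        fpg_b = float(rec["fpg_baseline_mg_dl"])
        hba_b = float(rec["hba1c_baseline_pct"])
        dfpg = ep.slope_fd * duge
        for col, short, sig2 in (("fpg_mg_dl", "fpg", ep.sigma2_fpg),
                                 ("hba1c_pct", "hba1c", ep.sigma2_hba1c)):
            if pd.isna(rec[col]):
                continue
            if short == "fpg":
                pred = (fpg_b + ep.p_fmax[group] * (1 - np.exp(-ep.k_fp * t))
                        + ep.dis_fp / 100.0 * t + dfpg)
            else:
                k_in = ep.k_out * hba_b - ep.k_in2
                pred = (hba_b + ep.p_hmax[group] * (1 - np.exp(-ep.k_hp * t))
                        + ep.dis_hp / 100.0 * t
                        + (dfpg / fpg_b) * (k_in / ep.k_out)
                        * (1 - np.exp(-ep.k_out * t)))
            resid = float(rec[col]) - pred
            sd = np.sqrt(sig2 / n) if sig2 > 0 else np.nan
            rows.append({
                "arm_id": rec["arm_id"], "endpoint": short,
                "time_week": t, "n": n, "observation": float(rec[col]),
                "prediction": pred, "residual": resid,
                "weighted_residual": resid / sd if sd and np.isfinite(sd)
                else np.nan,
            })
    return pd.DataFrame(rows)
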