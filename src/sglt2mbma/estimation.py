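"""Sqrt(sample-size)-weighted nonlinear estimation for summary-level data.

Each stage (PK → PK/PD → endpoint placebo → endpoint drug) is fitted to
arm-level means under the residual model

    Var(y_i) = V_i = (σ²_prop · f_i² + σ²_add) / n_i,

in which the residual SD of an arm mean shrinks as 1/√n — the
standard-error-of-a-mean reading of "weighting the data by the square root
of sample size".  The default estimator is iteratively reweighted least
squares: weights are frozen at the current predictions, the weighted sum of
squares Σ (y−f)²/V is minimized, and the weights are refreshed from the new
predictions until stable (generalized least squares).  This avoids both the
downward-shrinkage bias of the prediction-referenced extended-least-squares
objective (its ln V term rewards small predictions) and the data-weighting
bias of observation-referenced weights under large proportional error, and
it recovers the generating parameters exactly on noise-free data.  The
reported OFV is Σ [(y−f)²/V + ln V] at the optimum, prediction-referenced,
for NONMEM-style nested-model bookkeeping.  Residual variances are fixed at
their configured values; only structural parameters are estimated.

Optimization: multi-start (jittered, seeded) Nelder–Mead with
gradient-based refinement of the best start; positive parameters on the log
scale, signed parameters untransformed.  Standard errors come from the
inverse Hessian of the frozen-weight objective at the optimum, reported as
RSE% . ``variance_reference`` in :class:`FitSettings` switches to pure
observation-referenced weighting ("observation") or the full ELS objective
("prediction") when those variants are wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .biomarker_model import delta_uge_c as _obs_duge
from .errors import InputError
from .parameters import (
    BiomarkerParameters,
    EndpointParameters,
    PKParameters,
    TreatmentType,
)
from .pk_model import DoseRegimen, unit_dose_concentrations

__all__ = ["FitSettings", "FitResult", "OFVComparison", "weight_of",
           "fit_pk", "fit_pkpd", "fit_endpoints", "compare_ofv"]

_GROUPS = tuple(t.value for t in TreatmentType)
_PENALTY = 1e12
_V_FLOOR = 1e-12


def weight_of(n) -> float:
    """Meta-analytic data weight of an arm: sqrt(sample size)."""
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 1):
        raise InputError("arm size n must be >= 1")
    out = np.sqrt(arr)
    return float(out) if out.ndim == 0 else out


@dataclass
class FitSettings:
    """Estimation settings shared by all stages."""

    n_starts: int = 5
    jitter_sd: float = 0.10  # SD of the log-scale start jitter
    seed: int | None = None
    maxiter: int = 4000
    gls_iterations: int = 3
    variance_reference: str = "gls"  # "gls" | "observation" | "prediction"
    use_population_baseline: bool = False
    marginal_iiv: bool = False  # reserved hook, off by default


@dataclass
class FitResult:
    """Outcome of one estimation stage."""

    stage: str
    estimates: dict[str, float]
    rse_pct: dict[str, float]
    ofv: float
    converged: bool
    n_obs: int
    seed: int | None = None
    dataset_id: str | None = None
    messages: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.estimates)

    def summary(self) -> pd.DataFrame:
        """Human-readable parameter table."""
        rows = [
            {"parameter": k, "estimate": v,
             "rse_pct": self.rse_pct.get(k, float("nan"))}
            for k, v in self.estimates.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OFVComparison:
    """ΔOFV and parameter-count delta between two fits (B minus A)."""

    delta_ofv: float
    delta_k: int


def compare_ofv(fit_a: FitResult, fit_b: FitResult) -> OFVComparison:
    """Nested-model bookkeeping: OFV and parameter-count differences.

    Both fits must come from the same dataset; no automatic decision is
    made.
    """
    if fit_a.dataset_id != fit_b.dataset_id or fit_a.n_obs != fit_b.n_obs:
        raise InputError("OFV comparison requires fits of the same dataset")
    return OFVComparison(delta_ofv=fit_b.ofv - fit_a.ofv,
                         delta_k=fit_b.n_params - fit_a.n_params)


# ---------------------------------------------------------------------------
# generic weighted-fit machinery

def _variance(ref: np.ndarray, n: np.ndarray, s2p: float, s2a: float):
    if s2p == 0.0 and s2a == 0.0:
        return 1.0 / n  # pure sqrt(n) data weighting
    return np.maximum((s2p * ref ** 2 + s2a) / n, _V_FLOOR)


def _multistart(fun, x0, settings: FitSettings):
    rng = np.random.default_rng(settings.seed)
    best = None
    for s in range(max(1, settings.n_starts)):
        start = np.asarray(x0, dtype=float)
        if s > 0:
            start = start + rng.normal(0.0, settings.jitter_sd, start.size)
        res = minimize(fun, start, method="Nelder-Mead",
                       options={"maxiter": settings.maxiter,
                                "xatol": 1e-9, "fatol": 1e-11})
        if best is None or res.fun < best.fun:
            best = res
    refined = minimize(fun, best.x, method="L-BFGS-B",
                       options={"maxiter": 500})
    if np.isfinite(refined.fun) and refined.fun <= best.fun:
        best = refined
    return best


def _polish(fun, x):
    res = minimize(fun, x, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12})
    refined = minimize(fun, res.x, method="L-BFGS-B",
                       options={"maxiter": 500})
    return refined if refined.fun <= res.fun else res


def _fit_weighted(predict: Callable[[np.ndarray], np.ndarray | None],
                  y: np.ndarray, n: np.ndarray, s2p: float, s2a: float,
                  x0: np.ndarray, settings: FitSettings):
    """Minimize the weighted objective; returns (x, ofv, frozen_obj).

    ``predict`` maps the encoded parameter vector to the prediction vector
    (or None for an infeasible point).  The returned ``frozen_obj`` is the
    final fixed-weight objective used for Hessian-based standard errors.
    """

    def make_frozen(V):
        def obj(x):
            f = predict(x)
            if f is None or not np.all(np.isfinite(f)):
                return _PENALTY
            return float(np.sum((y - f) ** 2 / V))
        return obj

    mode = settings.variance_reference
    if mode == "prediction":  # full extended least squares
        def obj(x):
            f = predict(x)
            if f is None or not np.all(np.isfinite(f)):
                return _PENALTY
            V = _variance(f, n, s2p, s2a)
            return float(np.sum((y - f) ** 2 / V + np.log(V)))

        best = _multistart(obj, x0, settings)
        frozen = make_frozen(_variance(predict(best.x), n, s2p, s2a))
        return best.x, float(best.fun), frozen

    V = _variance(y, n, s2p, s2a)
    frozen = make_frozen(V)
    best = _multistart(frozen, x0, settings)
    if mode == "gls":
        for _ in range(max(0, settings.gls_iterations - 1)):
            f = predict(best.x)
            if f is None:
                break
            V = _variance(f, n, s2p, s2a)
            frozen = make_frozen(V)
            best = _polish(frozen, best.x)
    f = predict(best.x)
    V = _variance(f if f is not None else y, n, s2p, s2a)
    ofv = float(np.sum((y - f) ** 2 / V + np.log(V))) if f is not None \
        else _PENALTY
    return best.x, ofv, make_frozen(V)


def _numeric_hessian(fun, x, rel_step=1e-4):
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _rse_from_hessian(fun, x, names, transforms, estimates):
    """RSE% from the inverse Hessian of the -2LL-scale objective.

    cov ≈ 2·H⁻¹; a non-positive-definite Hessian yields infinite RSEs and
    ok=False (identifiability flag).
    """
    H = _numeric_hessian(fun, x)
    rse = {}
    ok = True
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.min(eigvals) <= 0:
            raise np.linalg.LinAlgError("Hessian not positive definite")
        cov = 2.0 * np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for i, name in enumerate(names):
            if transforms[i] == "log":
                rse[name] = 100.0 * se[i]  # log-scale SE ≈ CV
            else:
                denom = abs(estimates[name])
                rse[name] = 100.0 * se[i] / denom if denom > 0 else math.inf
    except np.linalg.LinAlgError:
        ok = False
        for name in names:
            rse[name] = math.inf
    return rse, ok


def _encode(values, transforms):
    return np.array([math.log(v) if tr == "log" else v
                     for v, tr in zip(values, transforms)])


def _decode(x, transforms):
    return [math.exp(v) if tr == "log" else v for v, tr in zip(x, transforms)]


def _dataset_id(tag: str, y: np.ndarray) -> str:
    return f"{tag}:{y.size}:{float(np.sum(y)):.9g}"


# ---------------------------------------------------------------------------
# PK stage

def fit_pk(dataset: pd.DataFrame, drug: str, init: PKParameters,
           settings: FitSettings | None = None) -> FitResult:
    """Fit the two-compartment transit PK model to pooled arm-mean profiles.

    ``dataset`` follows the concentrations schema (study_id, drug, dose_mg,
    fed, time_h, conc_ng_ml, n); records are single-dose profiles.  Free
    parameters: CL, Vc, CLD, VT, Kt (log scale) and the food covariate on
    Kt when the drug carries one and fed arms are present.  Residual
    variances are fixed at ``init.sigma2_prop`` / ``init.sigma2_add``.

    Non-convergence or an ill-conditioned Hessian is flagged on the result
    (messages / infinite RSE), never raised.
    """
    settings = settings or FitSettings()
    df = dataset[dataset["drug"] == drug]
    if df.empty:
        raise InputError(f"no records for drug {drug!r}")

    arms = []
    for (study, dose, fed), g in df.groupby(["study_id", "dose_mg", "fed"],
                                            sort=True):
        g = g.sort_values("time_h")
        arms.append({
            "dose": float(dose), "fed": bool(fed),
            "times": g["time_h"].to_numpy(dtype=float),
            "y": g["conc_ng_ml"].to_numpy(dtype=float),
            "n": g["n"].to_numpy(dtype=float),
        })
    messages = []
    if df["dose_mg"].nunique() < 2:
        messages.append("single dose level: absorption/disposition "
                        "parameters may be poorly identified")
    if df["time_h"].nunique() < 8:
        messages.append("fewer than 8 distinct sampling times: sparse design")

    names = ["CL", "Vc", "CLD", "VT", "Kt"]
    transforms = ["log"] * 5
    fit_fed = init.fed_effect is not None and bool(df["fed"].any())
    if fit_fed:
        names.append("fed_effect")
        transforms.append("log")

    # arms sharing (fed, time-grid) share one unit-dose simulation per eval
    groups: dict[tuple, list[int]] = {}
    for i, arm in enumerate(arms):
        key = (arm["fed"], tuple(np.round(arm["times"], 10)))
        groups.setdefault(key, []).append(i)

    y = np.concatenate([a["y"] for a in arms])
    n = np.concatenate([a["n"] for a in arms])
    offsets = np.cumsum([0] + [a["y"].size for a in arms])

    def predict(x):
        vals = _decode(x, transforms)
        kw = dict(zip(names, vals))
        fed_eff = kw.pop("fed_effect", init.fed_effect)
        try:
            p = replace(init, fed_effect=fed_eff, **kw)
        except Exception:
            return None
        f = np.empty_like(y)
        for (fed, tkey), idxs in groups.items():
            try:
                unit = unit_dose_concentrations(
                    p, DoseRegimen(dose=1.0, fed=fed), np.asarray(tkey))
            except Exception:
                return None
            for i in idxs:
                f[offsets[i]:offsets[i + 1]] = arms[i]["dose"] * unit
        return f

    x0 = _encode([getattr(init, nm) for nm in names], transforms)
    xhat, ofv, frozen = _fit_weighted(predict, y, n, init.sigma2_prop,
                                      init.sigma2_add, x0, settings)
    estimates = dict(zip(names, _decode(xhat, transforms)))
    rse, hess_ok = _rse_from_hessian(frozen, xhat, names, transforms,
                                     estimates)
    if not hess_ok:
        messages.append("Hessian not positive definite at the optimum "
                        "(identifiability problem)")
    return FitResult(
        stage="pk", estimates=estimates, rse_pct=rse, ofv=ofv,
        converged=bool(np.isfinite(ofv) and ofv < _PENALTY) and hess_ok,
        n_obs=int(y.size), seed=settings.seed,
        dataset_id=_dataset_id(f"pk:{drug}", y), messages=messages,
    )


# ---------------------------------------------------------------------------
# PK/PD stage

def fit_pkpd(uge_dataset: pd.DataFrame,
             auc_by_arm: Mapping[str, float] | None,
             init: BiomarkerParameters,
             settings: FitSettings | None = None,
             shared_emax: bool = True) -> FitResult:
    """Fit the shared-Emax / per-drug-EC50 exposure–biomarker model.

    ``uge_dataset`` follows the uge schema; observed ΔUGEc is computed from
    the raw UGE triplets.  Steady-state exposures come from ``auc_by_arm``
    (study_id → AUC) or an ``auc24`` column.  With ``shared_emax=False`` a
    per-drug Emax is estimated instead (nested comparison via
    :func:`compare_ofv`).
    """
    settings = settings or FitSettings()
    df = uge_dataset.copy()
    if auc_by_arm is not None:
        df["auc24"] = df["study_id"].map(auc_by_arm)
    if "auc24" not in df or df["auc24"].isna().any():
        raise InputError("steady-state AUC missing for some arms")
    df["duge_obs"] = _obs_duge(df["uge24_g"], df["uge24_baseline_g"],
                               df["fpg_baseline_mg_dl"])
    active = df[df["drug"] != "placebo"]
    drugs = sorted(active["drug"].unique())
    messages = []
    if len(drugs) < 2 and shared_emax:
        messages.append("all arms from one drug: the shared-Emax constraint "
                        "is not exercised by pooling")

    if shared_emax:
        names = ["Emax"] + [f"EC50_{d}" for d in drugs]
        x0_vals = [init.Emax] + [
            init.EC50_by_drug.get(d, float(np.median(active["auc24"])))
            for d in drugs]
    else:
        names = [f"Emax_{d}" for d in drugs] + [f"EC50_{d}" for d in drugs]
        x0_vals = [init.Emax] * len(drugs) + [
            init.EC50_by_drug.get(d, float(np.median(active["auc24"])))
            for d in drugs]
    transforms = ["log"] * len(names)

    y = df["duge_obs"].to_numpy(dtype=float)
    n = df["n"].to_numpy(dtype=float)
    auc = df["auc24"].to_numpy(dtype=float)
    drug_col = df["drug"].to_numpy()

    def predict(x):
        vals = dict(zip(names, _decode(x, transforms)))
        f = np.zeros_like(y)
        for d in drugs:
            emax = vals["Emax"] if shared_emax else vals[f"Emax_{d}"]
            ec50 = vals[f"EC50_{d}"]
            mask = drug_col == d
            f[mask] = emax * auc[mask] / (ec50 + auc[mask])
        return f

    xhat, ofv, frozen = _fit_weighted(
        predict, y, n, init.sigma2_prop, init.sigma2_add,
        _encode(x0_vals, transforms), settings)
    estimates = dict(zip(names, _decode(xhat, transforms)))
    rse, hess_ok = _rse_from_hessian(frozen, xhat, names, transforms,
                                     estimates)
    if not hess_ok:
        messages.append("Hessian not positive definite at the optimum")
    return FitResult(
        stage="pkpd", estimates=estimates, rse_pct=rse, ofv=ofv,
        converged=bool(np.isfinite(ofv) and ofv < _PENALTY) and hess_ok,
        n_obs=int(y.size), seed=settings.seed,
        dataset_id=_dataset_id("pkpd", y), messages=messages,
    )


# ---------------------------------------------------------------------------
# endpoint stage

def fit_endpoints(endpoint_dataset: pd.DataFrame,
                  delta_uge_c_by_arm: Mapping[str, float] | None,
                  init: EndpointParameters,
                  settings: FitSettings | None = None,
                  stage: str = "placebo") -> FitResult:
    """Fit the FPG/HbA1c endpoint models, sequentially by default.

    ``stage="placebo"`` estimates the placebo/progression parameters
    (p_fmax and p_hmax per treatment type, k_fp, dis_fp, k_hp, dis_hp) from
    placebo arms.  ``stage="drug"`` estimates slope_fd then k_out and k_in2
    from drug arms, conditional on the placebo parameters carried by
    ``init`` (build it with ``dataclasses.replace`` from the placebo-stage
    estimates, mirroring the sequential model build).  ``stage="joint"``
    runs both blocks in one call.

    Arm-specific baselines from the dataset drive the predictions unless
    ``settings.use_population_baseline`` is set.
    """
    settings = settings or FitSettings()
    if stage not in ("placebo", "drug", "joint"):
        raise InputError(f"unknown stage {stage!r}")
    if "treatment_type" not in endpoint_dataset.columns or \
            endpoint_dataset["treatment_type"].isna().any():
        raise InputError("treatment-type labels are required for endpoint fits")
    df = endpoint_dataset.copy()
    df["treatment_type"] = [TreatmentType.parse(v).value
                            for v in df["treatment_type"]]
    is_placebo = df["drug"] == "placebo"
    if stage in ("placebo", "joint") and not is_placebo.any():
        raise InputError("placebo stage requires placebo arms")
    if stage in ("drug", "joint") and bool(is_placebo.all()):
        raise InputError("drug stage requires active-treatment arms")
    duge = dict(delta_uge_c_by_arm or {})

    def rows_of(sub, value_col):
        sub = sub[sub[value_col].notna()]
        base_col = ("fpg_baseline_mg_dl" if value_col == "fpg_mg_dl"
                    else "hba1c_baseline_pct")
        pop = (init.fpg_baseline_pop if value_col == "fpg_mg_dl"
               else init.hba1c_baseline_pop)
        baseline = (np.full(len(sub), pop) if settings.use_population_baseline
                    else sub[base_col].to_numpy(dtype=float))
        return {
            "t": sub["time_week"].to_numpy(dtype=float),
            "y": sub[value_col].to_numpy(dtype=float),
            "n": sub["n"].to_numpy(dtype=float),
            "group": sub["treatment_type"].to_numpy(),
            "baseline": baseline,
            "fpg_baseline": sub["fpg_baseline_mg_dl"].to_numpy(dtype=float),
            "duge": np.array([duge.get(a, 0.0) for a in sub["arm_id"]]),
        }

    estimates: dict[str, float] = {}
    rse: dict[str, float] = {}
    messages: list[str] = []
    total_ofv = 0.0
    all_ok = True

    def run(names, transforms, x0_vals, predict, rows, sig2):
        nonlocal total_ofv, all_ok
        xhat, ofv, frozen = _fit_weighted(
            predict, rows["y"], rows["n"], 0.0, sig2,
            _encode(x0_vals, transforms), settings)
        vals = dict(zip(names, _decode(xhat, transforms)))
        sub_rse, ok = _rse_from_hessian(frozen, xhat, names, transforms, vals)
        if not ok:
            messages.append(f"Hessian not positive definite for {names}")
        all_ok = all_ok and ok and np.isfinite(ofv) and ofv < _PENALTY
        total_ofv += ofv
        estimates.update(vals)
        rse.update(sub_rse)
        return vals

    def placebo_curve(vals, prefix, k_name, dis_name, rows):
        pmax = np.array([vals[f"{prefix}_{g}"] for g in rows["group"]])
        return (rows["baseline"]
                + pmax * (1.0 - np.exp(-vals[k_name] * rows["t"]))
                + vals[dis_name] / 100.0 * rows["t"])

    def placebo_block(fpg_rows, hba_rows):
        names_f = [f"p_fmax_{g}" for g in _GROUPS] + ["k_fp", "dis_fp"]
        tr_f = ["id"] * 4 + ["log", "id"]
        x0_f = [init.p_fmax[g] for g in _GROUPS] + [init.k_fp, init.dis_fp]

        def pred_f(x):
            vals = dict(zip(names_f, _decode(x, tr_f)))
            return placebo_curve(vals, "p_fmax", "k_fp", "dis_fp", fpg_rows)

        run(names_f, tr_f, x0_f, pred_f, fpg_rows, init.sigma2_fpg)

        names_h = [f"p_hmax_{g}" for g in _GROUPS] + ["k_hp", "dis_hp"]
        tr_h = ["id"] * 4 + ["log", "id"]
        x0_h = [init.p_hmax[g] for g in _GROUPS] + [init.k_hp, init.dis_hp]

        def pred_h(x):
            vals = dict(zip(names_h, _decode(x, tr_h)))
            return placebo_curve(vals, "p_hmax", "k_hp", "dis_hp", hba_rows)

        run(names_h, tr_h, x0_h, pred_h, hba_rows, init.sigma2_hba1c)

    def drug_block(fpg_rows, hba_rows, pv):
        fpg_pbo = placebo_curve(pv, "p_fmax", "k_fp", "dis_fp", fpg_rows)

        def pred_slope(x):
            return fpg_pbo + x[0] * fpg_rows["duge"]

        slope = run(["slope_fd"], ["id"], [init.slope_fd], pred_slope,
                    fpg_rows, init.sigma2_fpg)["slope_fd"]

        hb_b = hba_rows["baseline"]
        hba_pbo = placebo_curve(pv, "p_hmax", "k_hp", "dis_hp", hba_rows)
        delta_fpg = slope * hba_rows["duge"]

        def pred_turnover(x):
            k_out, k_in2 = math.exp(x[0]), math.exp(x[1])
            k_in = k_out * hb_b - k_in2
            if np.any(k_in <= 0):
                return None
            return hba_pbo + (delta_fpg / hba_rows["fpg_baseline"]) \
                * (k_in / k_out) * (1.0 - np.exp(-k_out * hba_rows["t"]))

        run(["k_out", "k_in2"], ["log", "log"], [init.k_out, init.k_in2],
            pred_turnover, hba_rows, init.sigma2_hba1c)

    pbo, act = df[is_placebo], df[~is_placebo]
    y_parts = []
    if stage in ("placebo", "joint"):
        fpg_rows, hba_rows = rows_of(pbo, "fpg_mg_dl"), rows_of(pbo, "hba1c_pct")
        placebo_block(fpg_rows, hba_rows)
        y_parts += [fpg_rows["y"], hba_rows["y"]]
    if stage in ("drug", "joint"):
        fpg_rows, hba_rows = rows_of(act, "fpg_mg_dl"), rows_of(act, "hba1c_pct")
        if stage == "drug":
            pv = {f"p_fmax_{g}": init.p_fmax[g] for g in _GROUPS}
            pv |= {f"p_hmax_{g}": init.p_hmax[g] for g in _GROUPS}
            pv |= {"k_fp": init.k_fp, "dis_fp": init.dis_fp,
                   "k_hp": init.k_hp, "dis_hp": init.dis_hp}
        else:
            pv = dict(estimates)
        drug_block(fpg_rows, hba_rows, pv)
        y_parts += [fpg_rows["y"], hba_rows["y"]]

    y_all = np.concatenate([p for p in y_parts if p.size])
    return FitResult(
        stage=f"endpoint-{stage}", estimates=estimates, rse_pct=rse,
        ofv=total_ofv, converged=bool(all_ok), n_obs=int(y_all.size),
        seed=settings.seed, dataset_id=_dataset_id("endpoint", y_all),
        messages=messages,
    )
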