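"""Two-compartment transit-absorption PK model for SGLT2 inhibitors.

Structure: an oral depot feeds a chain of ``n_transit`` identical transit
compartments which absorb into the central compartment; disposition is
two-compartmental with first-order elimination from the central compartment.
Every transfer along the absorption chain — depot exit, transit-to-transit,
and final absorption — shares the single rate constant Kt, the most
parsimonious reading of one estimated "absorption rate constant between
transit compartments" per drug.

The system is linear and stiffness-free, so the default solver is the exact
matrix-exponential propagator; :func:`simulate_pk_ode` provides an
independent general-purpose ODE integration of the same system (with an
explicit cumulative-elimination state) used as a cross-check oracle.

Units: time h, dose mg, volumes L, clearances L/h, concentration ng/mL
(amount mg / volume L = µg/mL → ×1000).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import DomainError, InputError
from .parameters import ConcentrationProfile, DoseRegimen, PKParameters

__all__ = ["simulate_pk", "simulate_pk_ode", "effective_kt", "auc_ss_24",
           "unit_dose_concentrations"]

_MG_PER_L_TO_NG_PER_ML = 1000.0


def effective_kt(params: PKParameters, fed: bool) -> float:
    """Absorption rate constant under the fed/fasted covariate.

    Fasted state (or a drug without a food covariate) returns Kt unchanged;
    fed state multiplies Kt by ``fed_effect``.  A ``fed_effect`` below 1
    slows absorption, reproducing the prolonged time-to-peak seen when
    dapagliflozin is taken with food.
    """
    if fed and params.fed_effect is not None:
        return params.Kt * params.fed_effect
    return params.Kt


def _system_matrix(params: PKParameters, kt: float) -> np.ndarray:
    """Rate matrix over states [depot, transit_1..n, central, peripheral]."""
    n = params.n_transit
    m = n + 3
    central = n + 1
    periph = n + 2
    A = np.zeros((m, m))
    for i in range(n + 1):  # depot -> chain -> central, shared rate kt
        A[i, i] -= kt
        A[i + 1, i] += kt
    ke = params.CL / params.Vc
    k12 = params.CLD / params.Vc
    k21 = params.CLD / params.VT
    A[central, central] -= ke + k12
    A[periph, central] += k12
    A[central, periph] += k21
    A[periph, periph] -= k21
    return A


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputError("time grid must be a non-empty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise InputError("time grid must be strictly increasing")
    if t[0] < 0:
        raise InputError("times must be >= 0")
    return t


def unit_dose_concentrations(
    params: PKParameters, regimen: DoseRegimen, times: np.ndarray
) -> np.ndarray:
    """Central-compartment concentrations (ng/mL) for a 1-mg dose regimen.

    Exact propagation of the linear system with the matrix exponential;
    dose events are impulses into the depot.  By linearity, scale by
    ``regimen.dose`` for any actual dose.
    """
    t = _check_times(times)
    kt = effective_kt(params, regimen.fed)
    A = _system_matrix(params, kt)
    m = A.shape[0]
    central = params.n_transit + 1

    dose_times = np.arange(regimen.n_doses) * regimen.interval
    # merge dose events and observation times into one forward sweep
    events = sorted(
        set(np.round(dose_times, 12)) | set(np.round(t, 12))
    )
    cache: dict[float, np.ndarray] = {}
    state = np.zeros(m)
    out = {}
    prev = 0.0
    dose_set = set(np.round(dose_times, 12))
    obs_set = set(np.round(t, 12))
    if events and events[0] > 0:
        events.insert(0, 0.0)
    for ev in events:
        dt = ev - prev
        if dt > 0:
            key = round(dt, 12)
            P = cache.get(key)
            if P is None:
                P = expm(A * dt)
                cache[key] = P
            state = P @ state
        prev = ev
        if ev in dose_set:
            state = state.copy()
            state[0] += 1.0  # unit dose, mg
        if ev in obs_set:
            out[ev] = state[central] / params.Vc * _MG_PER_L_TO_NG_PER_ML
    return np.array([out[k] for k in np.round(t, 12)])


def simulate_pk(
    params: PKParameters, regimen: DoseRegimen, times: np.ndarray
) -> ConcentrationProfile:
    """Simulate the concentration–time profile of a dosing regimen.

    Deterministic and linear in dose (superposition of identical unit-dose
    responses shifted by the dosing interval).
    """
    t = _check_times(times)
    conc = regimen.dose * unit_dose_concentrations(params, regimen, t)
    return ConcentrationProfile(times=tuple(t), concentrations=tuple(conc))


def simulate_pk_ode(
    params: PKParameters,
    regimen: DoseRegimen,
    times: np.ndarray,
    return_states: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Cross-check oracle: integrate the same system with ``solve_ivp``.

    The state vector is augmented with a cumulative-elimination compartment
    so that mass balance (depot + chain + central + peripheral + eliminated
    = administered dose) can be asserted at any time.

    Returns a :class:`ConcentrationProfile`, or ``(profile, states)`` with
    ``states`` of shape (n_times, n_compartments+1) in mg if
    ``return_states``.
    """
    t = _check_times(times)
    kt = effective_kt(params, regimen.fed)
    A = _system_matrix(params, kt)
    m = A.shape[0]
    central = params.n_transit + 1
    ke = params.CL / params.Vc

    def rhs(_t, y):
        dy = np.empty(m + 1)
        dy[:m] = A @ y[:m]
        dy[m] = ke * y[central]  # cumulative elimination
        return dy

    dose_times = [k * regimen.interval for k in range(regimen.n_doses)]
    state = np.zeros(m + 1)
    out = np.zeros((t.size, m + 1))
    events = sorted(set(dose_times))
    prev = 0.0
    horizon = max(float(t[-1]), events[-1])
    for ev in events + [None]:
        seg_end = horizon if ev is None else ev
        if seg_end > prev:
            mask = (t > prev) & (t <= seg_end)
            idx = np.where(mask)[0]
            t_eval = list(t[idx])
            if not t_eval or t_eval[-1] < seg_end:
                t_eval.append(seg_end)
            sol = solve_ivp(rhs, (prev, seg_end), state, t_eval=t_eval,
                            method="LSODA", rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            out[idx] = sol.y[:, : idx.size].T
            state = sol.y[:, -1]
            prev = seg_end
        if ev is None:
            break
        state = state.copy()
        state[0] += regimen.dose  # impulse dose into the depot
    # post-dose convention at t coinciding with a dose time handled by the
    # forward sweep; t == 0 is pre-dose (empty system)
    conc = out[:, central] / params.Vc * _MG_PER_L_TO_NG_PER_ML
    profile = ConcentrationProfile(times=tuple(t), concentrations=tuple(conc))
    if return_states:
        return profile, out
    return profile


def auc_ss_24(params: PKParameters, regimen: DoseRegimen) -> float:
    """Steady-state AUC over 24 h, ng/mL·h.

    For a linear model at steady state the AUC over one dosing interval
    equals dose/CL (apparent oral clearance), so the 24-h exposure is
    dose/CL scaled by 24/interval.  Agrees with numeric quadrature of the
    simulated steady-state profile to < 1e-3 relative.
    """
    if not regimen.interval > 0:
        raise InputError("dosing interval must be > 0")
    if params.CL <= 0:
        raise DomainError("CL must be > 0")
    auc_tau_mg_h_per_l = regimen.dose / params.CL
    return auc_tau_mg_h_per_l * (24.0 / regimen.interval) * _MG_PER_L_TO_NG_PER_ML
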