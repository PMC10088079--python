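"""The ΔUGEc translational biomarker and its exposure–response model.

ΔUGEc is the change of 24-h urinary glucose excretion (UGE) from baseline
divided by the baseline fasting plasma glucose,

    ΔUGEc = (UGE − UGE_baseline) / FPG_baseline     [g/(mg/dL)],

interpretable as a 24-h renal glucose clearance gained on treatment.  The
normalization makes healthy subjects and T2DM patients (whose filtered
glucose loads differ via FPG) comparable on one exposure–response curve: a
hyperbolic Emax model on steady-state 24-h exposure with one Emax shared by
all SGLT2 inhibitors and a drug-specific EC50.

:func:`mechanistic_uge_rate` is the stand-alone mechanistic rate of urinary
glucose excretion (filtration minus inhibitable reabsorption) that motivates
the FPG correction; it is not integrated over time anywhere in the pipeline.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .parameters import BiomarkerParameters, MechanisticUGEParams

__all__ = ["delta_uge_c", "predict_delta_uge_c", "mechanistic_uge_rate"]


def delta_uge_c(uge24, uge24_baseline, fpg_baseline):
    """Observed biomarker from raw arm summaries.

    Parameters are 24-h UGE on treatment (g), at baseline (g), and baseline
    FPG (mg/dL).  Vectorized; may be negative if on-treatment UGE falls
    below baseline.
    """
    fpg = np.asarray(fpg_baseline, dtype=float)
    if np.any(fpg <= 0):
        raise DomainError("fpg_baseline must be > 0")
    out = (np.asarray(uge24, dtype=float) - np.asarray(uge24_baseline, dtype=float)) / fpg
    return float(out) if out.ndim == 0 else out


def predict_delta_uge_c(auc24, params: BiomarkerParameters, drug: str):
    """Model-predicted ΔUGEc at steady-state 24-h exposure ``auc24``.

    Emax·AUC/(EC50 + AUC): bounded in [0, Emax), strictly increasing and
    concave in exposure.  Vectorized over ``auc24``.
    """
    try:
        ec50 = params.EC50_by_drug[drug]
    except KeyError:
        raise KeyError(f"no EC50 entry for drug {drug!r}") from None
    auc = np.asarray(auc24, dtype=float)
    if np.any(auc < 0):
        raise DomainError("auc24 must be >= 0")
    out = params.Emax * auc / (ec50 + auc)
    return float(out) if out.ndim == 0 else out


def mechanistic_uge_rate(p: MechanisticUGEParams) -> float:
    """Mechanistic urinary glucose excretion rate, g/h.

    Rate = filtration − reabsorption with the reabsorption capacity
    inhibited by drug through an Imax function:

        dUGE/dt = GFR·PG − f_reabs·GFR·PG·(1 − Imax·C/(IC50 + C))

    GFR (mL/min) and PG (mg/dL) are harmonized internally to g/h:
    mL/min × mg/dL = mg/min × (1 dL / 100 mL); ×60 min/h ÷1000 mg/g gives
    the 6e-4 factor.  At C=0 the rate is GFR·PG·(1 − f_reabs); with a
    normal GFR of 125 mL/min and PG 100 mg/dL the filtered load is
    ~7.5 g/h (≈180 g/day), matching renal physiology.
    """
    filtered_mg_per_min = p.GFR * p.PG / 100.0  # mL/min * mg/dL -> mg/min
    inhibition = 1.0 - p.Imax * p.C / (p.IC50 + p.C)
    rate_mg_per_min = filtered_mg_per_min * (1.0 - p.f_reabs * inhibition)
    return rate_mg_per_min * 60.0 / 1000.0  # -> g/h
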