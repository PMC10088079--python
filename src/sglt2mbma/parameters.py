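"""Parameter containers for the PK / biomarker / endpoint model chain.

The defaults returned by :func:`default_truth` are the published fixed-effect
estimates for the three globally marketed SGLT2 inhibitors (dapagliflozin,
canagliflozin, empagliflozin): a two-compartment transit-absorption PK model
per drug, a shared-Emax / per-drug-EC50 exposure–biomarker model, and a
treatment-type-stratified placebo + indirect-response endpoint model for FPG
and HbA1c.

Conventions
-----------
* PK time unit: hours.  Endpoint time unit: weeks.
* Doses in mg, concentrations in ng/mL, exposures (AUC) in ng/mL·h.
* FPG in mg/dL, HbA1c in %, 24-h urinary glucose excretion in g.
* Inter-study variability (``iiv``) magnitudes are fractional (log-normal /
  exponential form) for all parameters except the placebo-maximum parameters
  ``p_fmax`` / ``p_hmax``, whose study effects are additive with the stated
  absolute SDs.
"""

from __future__ import annotations

import enum
import math
import unicodedata
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError, DomainError

__all__ = [
    "TreatmentType",
    "PKParameters",
    "DoseRegimen",
    "ConcentrationProfile",
    "BiomarkerParameters",
    "MechanisticUGEParams",
    "EndpointParameters",
    "SimulationTruth",
    "default_truth",
    "DRUGS",
]

DRUGS = ("dapagliflozin", "canagliflozin", "empagliflozin")


class TreatmentType(str, enum.Enum):
    """Treatment-history stratum of a study arm.

    ``naive``     — patients naive to oral hypoglycemic agents;
    ``non_naive`` — previously treated, washed out > 2 weeks;
    ``add_on``    — background hypoglycemic therapy continued;
    ``mixed``     — mixed or unknown treatment history.
    """

    NAIVE = "naive"
    NON_NAIVE = "non_naive"
    ADD_ON = "add_on"
    MIXED = "mixed"

    @classmethod
    def parse(cls, label: str) -> "TreatmentType":
        """Normalize free-text labels ('naïve', 'add-on', 'Add On', …)."""
        text = unicodedata.normalize("NFKD", str(label))
        text = "".join(ch for ch in text if not unicodedata.combining(ch))
        text = text.strip().lower().replace("-", "_").replace(" ", "_")
        aliases = {
            "naive": cls.NAIVE,
            "non_naive": cls.NON_NAIVE,
            "nonnaive": cls.NON_NAIVE,
            "add_on": cls.ADD_ON,
            "addon": cls.ADD_ON,
            "mixed": cls.MIXED,
        }
        try:
            return aliases[text]
        except KeyError:
            raise DomainError(f"unknown treatment type label: {label!r}") from None


@dataclass(frozen=True)
class PKParameters:
    """Structural + variability parameters of the two-compartment transit model.

    Apparent (oral) parameters throughout: bioavailability is absorbed into
    CL, Vc, CLD and VT, as the estimates derive from oral data only.
    """

    drug_name: str
    CL: float  # apparent clearance, L/h
    Vc: float  # central volume, L
    CLD: float  # inter-compartmental clearance, L/h
    VT: float  # peripheral volume, L
    Kt: float  # transit/absorption rate constant, 1/h
    n_transit: int  # number of transit compartments (>= 0)
    fed_effect: float | None = None  # multiplicative food covariate on Kt
    iiv: dict[str, float] = field(default_factory=dict)  # fractional magnitudes
    sigma2_prop: float = 0.0  # proportional residual variance
    sigma2_add: float = 0.0  # additive residual variance, (ng/mL)^2

    def __post_init__(self) -> None:
        for name in ("CL", "Vc", "CLD", "VT", "Kt"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{self.drug_name}: {name} must be > 0")
        if self.n_transit < 0 or int(self.n_transit) != self.n_transit:
            raise DomainError("n_transit must be a non-negative integer")
        if self.fed_effect is not None and not self.fed_effect > 0:
            raise DomainError("fed_effect must be > 0")
        if self.sigma2_prop < 0 or self.sigma2_add < 0:
            raise DomainError("residual variances must be >= 0")


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing: `n_doses` doses of `dose` mg every `interval` h."""

    dose: float  # mg
    interval: float = 24.0  # h
    n_doses: int = 1
    fed: bool = False

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise DomainError("dose must be >= 0")
        if not self.interval > 0:
            raise DomainError("interval must be > 0")
        if self.n_doses < 1:
            raise DomainError("n_doses must be >= 1")


@dataclass(frozen=True)
class ConcentrationProfile:
    """A concentration–time profile (times in h, concentrations in ng/mL)."""

    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise DomainError("times and concentrations must have equal length")


@dataclass(frozen=True)
class BiomarkerParameters:
    """Shared-Emax exposure–response parameters for the ΔUGEc biomarker."""

    Emax: float  # g/(mg/dL), shared across drugs
    EC50_by_drug: dict[str, float]  # ng/mL·h
    sigma2_prop: float = 0.0
    sigma2_add: float = 0.0
    iiv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.Emax > 0:
            raise DomainError("Emax must be > 0")
        for drug, ec50 in self.EC50_by_drug.items():
            if not ec50 > 0:
                raise DomainError(f"EC50 for {drug} must be > 0")
        if self.sigma2_prop < 0 or self.sigma2_add < 0:
            raise DomainError("residual variances must be >= 0")


@dataclass(frozen=True)
class MechanisticUGEParams:
    """Inputs to the mechanistic urinary-glucose-excretion rate.

    GFR in mL/min, PG in mg/dL, C and IC50 in any common concentration unit,
    Imax and f_reabs dimensionless fractions.
    """

    GFR: float
    PG: float
    C: float
    Imax: float
    IC50: float
    f_reabs: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.Imax <= 1.0):
            raise DomainError("Imax must lie in [0, 1]")
        if not (0.0 <= self.f_reabs <= 1.0):
            raise DomainError("f_reabs must lie in [0, 1]")
        if not self.GFR > 0 or not self.IC50 > 0:
            raise DomainError("GFR and IC50 must be > 0")
        if self.PG < 0 or self.C < 0:
            raise DomainError("PG and C must be >= 0")


_GROUPS = tuple(t.value for t in TreatmentType)


@dataclass(frozen=True)
class EndpointParameters:
    """Placebo, disease-progression, drug-effect and turnover parameters.

    ``p_fmax``/``p_hmax`` hold one signed placebo-maximum per treatment type.
    Progression rates ``dis_fp``/``dis_hp`` are stored per 100 weeks as
    published and divided by 100 at evaluation.  ``iiv`` keys mirror parameter
    names; ``p_fmax``/``p_hmax`` entries are per-group dicts of absolute SDs,
    everything else fractional magnitudes.
    """

    fpg_baseline_pop: float  # mg/dL
    p_fmax: dict[str, float]  # mg/dL per treatment type, signed
    k_fp: float  # 1/week
    dis_fp: float  # mg/dL per 100 weeks
    slope_fd: float  # mg/dL FPG change per unit ΔUGEc, signed
    hba1c_baseline_pop: float  # %
    p_hmax: dict[str, float]  # % per treatment type, signed
    k_hp: float  # 1/week
    dis_hp: float  # % per 100 weeks
    k_out: float  # 1/week
    k_in2: float  # %/week
    iiv: dict[str, object] = field(default_factory=dict)
    sigma2_fpg: float = 0.0  # additive residual variance, (mg/dL)^2
    sigma2_hba1c: float = 0.0  # additive residual variance, (%)^2

    def __post_init__(self) -> None:
        for name in ("k_fp", "k_hp", "k_out"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if not self.fpg_baseline_pop > 0 or not self.hba1c_baseline_pop > 0:
            raise DomainError("population baselines must be > 0")
        if self.k_in2 < 0:
            raise DomainError("k_in2 must be >= 0")
        for d in (self.p_fmax, self.p_hmax):
            missing = set(_GROUPS) - set(d)
            if missing:
                raise ConfigurationError(
                    f"placebo-maximum parameters missing groups: {sorted(missing)}"
                )
        if self.k_out * self.hba1c_baseline_pop - self.k_in2 <= 0:
            raise ConfigurationError(
                "k_in = k_out*hba1c_baseline - k_in2 must be > 0 "
                f"(got {self.k_out * self.hba1c_baseline_pop - self.k_in2:g})"
            )
        if self.sigma2_fpg < 0 or self.sigma2_hba1c < 0:
            raise DomainError("residual variances must be >= 0")


@dataclass(frozen=True)
class SimulationTruth:
    """A complete parameterization of the PK → ΔUGEc → FPG → HbA1c chain."""

    pk: dict[str, PKParameters]
    biomarker: BiomarkerParameters
    endpoints: EndpointParameters
    seed: int | None = None

    def with_new_drug(
        self, pk: PKParameters, ec50: float
    ) -> "SimulationTruth":
        """Extend the truth with a fourth same-in-class drug.

        Only PK parameters and EC50 are drug-specific; Emax and all endpoint
        parameters are system-specific and inherited unchanged.
        """
        pk_map = dict(self.pk)
        pk_map[pk.drug_name] = pk
        ec50_map = dict(self.biomarker.EC50_by_drug)
        ec50_map[pk.drug_name] = ec50
        return replace(
            self, pk=pk_map, biomarker=replace(self.biomarker, EC50_by_drug=ec50_map)
        )


def default_truth(seed: int | None = None) -> SimulationTruth:
    """Published fixed-effect estimates for the three marketed drugs."""
    pk = {
        "dapagliflozin": PKParameters(
            drug_name="dapagliflozin",
            CL=19.5, Vc=82.0, CLD=10.3, VT=122.0, Kt=6.50,
            n_transit=2, fed_effect=0.254,
            iiv={"CL": 0.0250, "Vc": 0.0944, "VT": 0.0583, "Kt": 0.230},
            sigma2_prop=0.457, sigma2_add=0.462,
        ),
        "canagliflozin": PKParameters(
            drug_name="canagliflozin",
            CL=12.0, Vc=85.5, CLD=9.77, VT=108.0, Kt=6.38,
            n_transit=4, fed_effect=None,
            iiv={"CL": 0.0590, "Vc": 0.0243, "CLD": 0.128, "VT": 0.0314,
                 "Kt": 0.0317},
            sigma2_prop=0.126, sigma2_add=0.0,
        ),
        "empagliflozin": PKParameters(
            drug_name="empagliflozin",
            CL=4.25, Vc=30.6, CLD=1.37, VT=28.3, Kt=4.13,
            n_transit=2, fed_effect=None,
            iiv={"CL": 0.0569, "Vc": 0.0563, "VT": 0.220, "Kt": 0.0567},
            sigma2_prop=0.521, sigma2_add=0.0,
        ),
    }
    biomarker = BiomarkerParameters(
        Emax=0.606,
        EC50_by_drug={
            "dapagliflozin": 56.6,
            "canagliflozin": 2310.0,
            "empagliflozin": 841.0,
        },
        sigma2_prop=0.222,
        sigma2_add=0.0646,
        iiv={},  # not reported for Emax/EC50; defaults to zero
    )
    endpoints = EndpointParameters(
        fpg_baseline_pop=160.0,
        p_fmax={"naive": 1.45, "non_naive": 1.90, "add_on": -1.37,
                "mixed": 4.30},
        k_fp=0.340,
        dis_fp=3.13,
        slope_fd=-43.3,
        hba1c_baseline_pop=7.92,
        p_hmax={"naive": -0.200, "non_naive": 0.0510, "add_on": -0.230,
                "mixed": -0.06},
        k_hp=0.240,
        dis_hp=0.310,
        k_out=0.200,
        k_in2=0.500,
        iiv={
            "fpg_baseline": 0.0540,
            "p_fmax": {"naive": 5.74, "non_naive": 0.0, "add_on": 6.83,
                       "mixed": 0.87},
            "k_fp": 0.427,
            "dis_fp": 0.0,
            "slope_fd": 0.292,
            "hba1c_baseline": 0.0390,
            "p_hmax": {"naive": 0.08, "non_naive": 0.0, "add_on": 0.13,
                       "mixed": 0.20},
            "k_hp": 0.294,
            "dis_hp": 1.367,
            "k_out": 0.164,
            "k_in2": 0.0,
        },
        sigma2_fpg=0.0330,
        sigma2_hba1c=0.006,
    )
    return SimulationTruth(pk=pk, biomarker=biomarker, endpoints=endpoints,
                           seed=seed)


def terminal_half_life(p: PKParameters) -> float:
    """Terminal (beta-phase) half-life in hours of the disposition model."""
    ke = p.CL / p.Vc
    k12 = p.CLD / p.Vc
    k21 = p.CLD / p.VT
    s = ke + k12 + k21
    beta = 0.5 * (s - math.sqrt(s * s - 4.0 * ke * k21))
    return math.log(2.0) / beta
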