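"""Dosing regimens and drug-exposure forcing functions.

Two exposures drive host lymphodepletion:

* alemtuzumab serum concentration, described by a linear two-compartment
  model with first-order systemic elimination (parameters CL, V1, V2, Q);
* a fludarabine/cyclophosphamide (FC) "virtual compartment" (KPD model):
  no F/C concentrations are measured, so a dimensionless dose — the
  individual totals normalised to the study medians — is placed in a
  virtual compartment seven days before CAR-T infusion and decays
  first-order at ``kDE``.

Time is expressed in days relative to the CAR-T (UCART19) infusion, which
defines day 0; lymphodepletion days are negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Drug",
    "DoseEvent",
    "RegimenSpec",
    "AlemtuzumabPKParams",
    "FCKPDParams",
    "normalize_fc_dose",
    "alem_concentration",
    "alem_biexponential",
    "alem_macro_constants",
    "fc_exposure",
    "FC_VIRTUAL_DOSE_DAY",
]

#: Day on which the combined FC virtual dose is administered.
FC_VIRTUAL_DOSE_DAY = -7.0


class Drug(str, enum.Enum):
    UCART19 = "UCART19"
    ALEMTUZUMAB = "ALEM"
    FLUDARABINE = "FLU"
    CYCLOPHOSPHAMIDE = "CYC"


@dataclass(frozen=True)
class DoseEvent:
    """A single dosing event.

    ``amount`` is in mg for drugs and cells for UCART19; ``time`` in days
    relative to the UCART19 infusion; ``duration`` 0 means bolus.
    """

    drug: Drug
    time: float
    amount: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.duration < 0:
            raise ValueError(f"dose duration must be >= 0, got {self.duration}")


@dataclass
class RegimenSpec:
    """Ordered dose events for one PK/PD set, plus body weight.

    Exactly one UCART19 infusion is allowed per set (redosed patients are
    represented as independent sets).
    """

    events: list[DoseEvent] = field(default_factory=list)
    body_weight: float = 75.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)
        n_ucart = sum(1 for e in self.events if e.drug is Drug.UCART19)
        if n_ucart > 1:
            raise ValueError(f"exactly one UCART19 infusion allowed, got {n_ucart}")

    def doses_of(self, drug: Drug) -> list[DoseEvent]:
        return [e for e in self.events if e.drug is drug]

    def total_dose(self, drug: Drug) -> float:
        return float(sum(e.amount for e in self.doses_of(drug)))


@dataclass(frozen=True)
class AlemtuzumabPKParams:
    """Two-compartment PK parameters (CL, Q in L/day; V1, V2 in L)."""

    CL: float = 0.96
    V1: float = 3.74
    V2: float = 6.01
    Q: float = 3.51

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "V2", "Q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FCKPDParams:
    """KPD virtual-compartment parameters for the F/C protocol.

    Reference doses are the study median totals: 165 mg fludarabine and
    2,670 mg cyclophosphamide.
    """

    kDE: float = 0.2
    fluda_ref_dose: float = 165.0
    cyclo_ref_dose: float = 2670.0

    def __post_init__(self) -> None:
        if self.kDE <= 0:
            raise ValueError("kDE must be > 0")
        if self.fluda_ref_dose <= 0 or self.cyclo_ref_dose <= 0:
            raise ValueError("reference doses must be > 0")


def normalize_fc_dose(regimen: RegimenSpec, params: FCKPDParams) -> float:
    """Dimensionless FC dose: mean of the two per-drug total/median ratios.

    Equals 1 when both totals match the study medians, is linear in each
    drug, and 0 for a regimen without F or C events.
    """
    total_f = regimen.total_dose(Drug.FLUDARABINE)
    total_c = regimen.total_dose(Drug.CYCLOPHOSPHAMIDE)
    if total_f == 0.0 and total_c == 0.0:
        return 0.0
    return 0.5 * (total_f / params.fluda_ref_dose + total_c / params.cyclo_ref_dose)


def fc_exposure(fc_dose: float, params: FCKPDParams, t, t_dose: float = FC_VIRTUAL_DOSE_DAY):
    """FC virtual-compartment exposure FC(t) = dose * exp(-kDE (t - t_dose)).

    Vectorised over ``t``; zero before the virtual dose time.
    """
    if fc_dose < 0:
        raise ValueError("fc_dose must be >= 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= t_dose, fc_dose * np.exp(-params.kDE * (t - t_dose)), 0.0)
    return out if out.ndim else float(out)


def alem_macro_constants(p: AlemtuzumabPKParams) -> tuple[float, float, float, float]:
    """Bi-exponential macro constants for a unit bolus in the central cpt.

    Returns (c_alpha, c_beta, alpha, beta) such that the central-compartment
    concentration after a bolus dose D at t=0 is
    ``(D / V1) * (c_alpha * exp(-alpha t) + c_beta * exp(-beta t))``
    with mg/L == ug/mL units.
    """
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    c_alpha = (alpha - k21) / (alpha - beta)
    c_beta = (k21 - beta) / (alpha - beta)
    return c_alpha, c_beta, alpha, beta


def alem_biexponential(
    p: AlemtuzumabPKParams, regimen: RegimenSpec, times
) -> np.ndarray:
    """Closed-form central concentration (ug/mL) by superposition of boluses."""
    times = np.asarray(times, dtype=float)
    c_a, c_b, alpha, beta = alem_macro_constants(p)
    conc = np.zeros_like(times)
    for e in regimen.doses_of(Drug.ALEMTUZUMAB):
        dt = times - e.time
        mask = dt >= 0
        conc[mask] += (e.amount / p.V1) * (
            c_a * np.exp(-alpha * dt[mask]) + c_b * np.exp(-beta * dt[mask])
        )
    return conc


def alem_concentration(
    p: AlemtuzumabPKParams,
    regimen: RegimenSpec,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Central-compartment alemtuzumab concentration (ug/mL) on ``times``.

    Integrates the two-compartment ODE system dose interval by dose
    interval (boluses are state jumps in the central amount).  ``times``
    must be sorted ascending.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be a sorted 1-D array")
    doses = regimen.doses_of(Drug.ALEMTUZUMAB)
    conc = np.zeros_like(times)
    if not doses:
        return conc

    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2

    def rhs(t, y):
        a1, a2 = y
        return [-(k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    breakpoints = sorted({e.time for e in doses})
    t_end = max(times[-1], breakpoints[-1])
    y = np.zeros(2)
    t_cur = breakpoints[0]
    conc[times < t_cur] = 0.0
    segments = breakpoints[1:] + [t_end]
    for e in doses:
        if e.time == t_cur:
            y[0] += e.amount
    for t_next in segments:
        mask = (times >= t_cur) & (times <= t_next)
        # the segment endpoint is always evaluated so the next segment
        # starts from the state at exactly t_next
        t_eval = np.unique(np.append(times[mask], t_next))
        if t_next > t_cur:
            sol = solve_ivp(
                rhs,
                (t_cur, t_next),
                y,
                method="LSODA",
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:  # pragma: no cover - linear system, never fails
                raise RuntimeError(f"alemtuzumab PK integration failed: {sol.message}")
            if mask.any():
                seg = dict(zip(sol.t, sol.y[0]))
                conc[mask] = np.array([seg[t] for t in times[mask]]) / p.V1
            y = sol.y[:, -1].copy()
        else:
            conc[mask] = y[0] / p.V1
        t_cur = t_next
        # doses at the first breakpoint were already applied before the loop
        if t_cur != breakpoints[0]:
            for e in doses:
                if e.time == t_cur:
                    y[0] += e.amount
                    conc[times == t_cur] = y[0] / p.V1
    return conc


def alem_flat_regimen(total_mg: float, n_doses: int = 5, first_day: float = -7.0) -> list[DoseEvent]:
    """Split a total alemtuzumab dose into daily boluses from ``first_day``."""
    return [
        DoseEvent(Drug.ALEMTUZUMAB, first_day + i, total_mg / n_doses)
        for i in range(n_doses)
    ]
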