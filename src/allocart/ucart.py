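"""UCART19 memory-subpopulation kinetics.

The infused product is split into three memory subpopulations — stem-cell
memory (T_SCM), central memory (T_CM) and effector memory (T_EM) — each
existing in blood and tissue.  The model follows a progressive
differentiation scheme (SCM -> CM -> EM) with:

* homing (blood -> tissue) and egress (tissue -> blood) per subpopulation;
* physiologic elimination in tissue (k_elimEM > k_elimCM, so T_CM
  ultimately controls the persistence phase);
* a time-limited first-order expansion in tissue, strongest for T_SCM and
  potentiated by IL-7 through a Hill term, with a capacity safeguard;
* a time-varying CM -> EM differentiation rate, high during/after the
  expansion (contraction phase) and basal afterwards (persistence);
* optional allogeneic elimination by host T lymphocytes (second-order,
  blood and tissue), switched off for the persistent sets;
* optional transient blood-only elimination reproducing "truncated"
  profiles.

The dose is fixed at a nominal 6e6 cells regardless of the administered
dose level: the observed absence of dose-proportionality is deliberately
not modelled mechanistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "UCARTParams",
    "UCARTState",
    "initial_dose_split",
    "scm_expansion_rate",
    "derived_expansion_rates",
    "safeguard_factor",
    "cmem_rate",
    "ucart_rhs",
    "NOMINAL_DOSE_CELLS",
]

#: Nominal infused dose (cells); the lowest study dose level.
NOMINAL_DOSE_CELLS = 6e6

#: Width (days) of the smoothed contraction->persistence switch.
CMEM_SWITCH_WIDTH = 1.0


@dataclass
class UCARTParams:
    # blood <-> tissue exchange and tissue elimination, per subpopulation
    k_homingSCM: float = 2.0
    k_homingCM: float = 2.0
    k_homingEM: float = 2.0
    k_egressSCM: float = 0.35
    k_egressCM: float = 0.35
    k_egressEM: float = 0.35
    k_elimSCM: float = 0.01
    k_elimCM: float = 0.02
    k_elimEM: float = 0.2
    # progressive differentiation
    k_SCMCM: float = 0.2
    k_CMEM_high: float = 0.3
    k_CMEM_basal: float = 0.01
    t_persist: float = 25.0
    # expansion
    T_exp_start: float = 4.0
    T_exp: float = 7.0
    xfoldUCART19preIL7: float = 30.0
    IL7effMax: float = 28000.0
    IL7_50: float = 19.0
    hill_h: float = 8.0
    expansionCMfromSCM: float = 0.65
    expansionEMfromSCM: float = 0.35
    K_safeguard: float = 100.0
    # eliminations beyond physiology
    k_allo: float = 8.0
    allo_active: bool = True
    k_trunc: float = 6.0
    trunc_window: tuple[float, float] = (4.0, 14.0)
    trunc_active: bool = False
    # infusion
    dose_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    nominal_dose: float = NOMINAL_DOSE_CELLS
    V_blood: float = 5.0

    def __post_init__(self) -> None:
        rate_names = [
            "k_homingSCM", "k_homingCM", "k_homingEM",
            "k_egressSCM", "k_egressCM", "k_egressEM",
            "k_elimSCM", "k_elimCM", "k_elimEM",
            "k_SCMCM", "k_CMEM_high", "k_CMEM_basal",
            "k_allo", "k_trunc",
        ]
        for name in rate_names:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # EM elimination must not be slower than CM elimination (equality is
        # tolerated so that fully switched-off configurations stay valid)
        if self.k_elimEM < self.k_elimCM:
            raise ValueError("k_elimEM must be >= k_elimCM")
        if not (0 < self.expansionCMfromSCM < 1 and 0 < self.expansionEMfromSCM < 1):
            raise ValueError("expansion shares from SCM must lie in (0, 1)")
        if abs(sum(self.dose_fractions) - 1.0) > 1e-9:
            raise ValueError("dose fractions must sum to 1")
        if self.T_exp <= 0:
            raise ValueError("T_exp must be > 0")


@dataclass
class UCARTState:
    scm_blood: float = 0.0
    scm_tissue: float = 0.0
    cm_blood: float = 0.0
    cm_tissue: float = 0.0
    em_blood: float = 0.0
    em_tissue: float = 0.0

    @property
    def blood_total(self) -> float:
        return self.scm_blood + self.cm_blood + self.em_blood

    @property
    def total(self) -> float:
        return (
            self.scm_blood + self.cm_blood + self.em_blood
            + self.scm_tissue + self.cm_tissue + self.em_tissue
        )


def initial_dose_split(p: UCARTParams) -> tuple[float, float, float]:
    """Blood initial conditions (G/L) for SCM, CM, EM at infusion.

    The nominal dose (cells) is converted to a concentration over the
    blood volume; 1 G/L = 1e9 cells/L.
    """
    if abs(sum(p.dose_fractions) - 1.0) > 1e-9:
        raise ValueError("dose fractions must sum to 1")
    total = p.nominal_dose / (p.V_blood * 1e9)
    return tuple(f * total for f in p.dose_fractions)


@njit(cache=True)
def _hill(il7, emax, c50, h):
    if il7 <= 0.0:
        return 0.0
    x = (il7 / c50) ** h
    return emax * x / (1.0 + x)


@njit(cache=True)
def _scm_expansion_rate(il7, t, t_start, t_dur, xfold_pre, emax, c50, h):
    if t < t_start or t > t_start + t_dur:
        return 0.0
    return np.log(xfold_pre * (1.0 + _hill(il7, emax, c50, h))) / t_dur


def scm_expansion_rate(il7: float, t: float, p: UCARTParams) -> float:
    """First-order T_SCM tissue expansion rate (1/day) inside the window."""
    if il7 < 0:
        raise ValueError("il7 must be >= 0")
    return float(
        _scm_expansion_rate(
            il7, t, p.T_exp_start, p.T_exp,
            p.xfoldUCART19preIL7, p.IL7effMax, p.IL7_50, p.hill_h,
        )
    )


def derived_expansion_rates(scm_rate: float, p: UCARTParams) -> tuple[float, float]:
    """(CMexp, EMexp) as fixed shares of the T_SCM expansion rate."""
    if scm_rate < 0:
        raise ValueError("scm_rate must be >= 0")
    return p.expansionCMfromSCM * scm_rate, p.expansionEMfromSCM * scm_rate


@njit(cache=True)
def _safeguard(total, cap):
    s = 1.0 - total / cap
    if s < 0.0:
        return 0.0
    if s > 1.0:
        return 1.0
    return s


def safeguard_factor(total_ucart: float, p: UCARTParams) -> float:
    """Linear logistic brake on expansion: (1 - total/K_safeguard), in [0, 1]."""
    if total_ucart < 0:
        raise ValueError("total_ucart must be >= 0")
    return float(_safeguard(total_ucart, p.K_safeguard))


@njit(cache=True)
def _cmem_rate(t, k_high, k_basal, t_persist, width):
    z = (t - t_persist) / (width / 4.0)
    if z > 50.0:
        w = 1.0
    elif z < -50.0:
        w = 0.0
    else:
        w = 1.0 / (1.0 + np.exp(-z))
    return k_high + (k_basal - k_high) * w


def cmem_rate(t: float, p: UCARTParams) -> float:
    """Time-varying CM -> EM differentiation rate (smoothed step at t_persist)."""
    return float(
        _cmem_rate(t, p.k_CMEM_high, p.k_CMEM_basal, p.t_persist, CMEM_SWITCH_WIDTH)
    )


@njit(cache=True)
def _ucart_rates(
    scm_b, scm_t, cm_b, cm_t, em_b, em_t,
    t, il7, hostT_blood, hostT_tissue,
    kh_scm, kh_cm, kh_em, ke_scm, ke_cm, ke_em,
    kel_scm, kel_cm, kel_em,
    k_scmcm, k_cmem_high, k_cmem_basal, t_persist,
    t_exp_start, t_exp, xfold_pre, il7_emax, il7_50, hill_h,
    share_cm, share_em, k_safeguard,
    k_allo, allo_on, k_trunc, trunc_lo, trunc_hi, trunc_on,
):
    total = scm_b + scm_t + cm_b + cm_t + em_b + em_t
    guard = _safeguard(total, k_safeguard)
    scm_exp = _scm_expansion_rate(
        il7, t, t_exp_start, t_exp, xfold_pre, il7_emax, il7_50, hill_h
    ) * guard
    cm_exp = share_cm * scm_exp
    em_exp = share_em * scm_exp
    k_cmem = _cmem_rate(t, k_cmem_high, k_cmem_basal, t_persist, CMEM_SWITCH_WIDTH)

    allo_b = k_allo * hostT_blood if allo_on else 0.0
    allo_t = k_allo * hostT_tissue if allo_on else 0.0
    trunc = k_trunc if (trunc_on and trunc_lo <= t <= trunc_hi) else 0.0

    d_scm_b = ke_scm * scm_t - kh_scm * scm_b - allo_b * scm_b - trunc * scm_b
    d_scm_t = (
        kh_scm * scm_b - ke_scm * scm_t - kel_scm * scm_t
        + scm_exp * scm_t - allo_t * scm_t - k_scmcm * scm_t
    )
    d_cm_b = ke_cm * cm_t - kh_cm * cm_b - allo_b * cm_b - trunc * cm_b
    d_cm_t = (
        kh_cm * cm_b - ke_cm * cm_t - kel_cm * cm_t
        + cm_exp * cm_t - allo_t * cm_t + k_scmcm * scm_t - k_cmem * cm_t
    )
    d_em_b = ke_em * em_t - kh_em * em_b - allo_b * em_b - trunc * em_b
    d_em_t = (
        kh_em * em_b - ke_em * em_t - kel_em * em_t
        + em_exp * em_t - allo_t * em_t + k_cmem * cm_t
    )
    return d_scm_b, d_scm_t, d_cm_b, d_cm_t, d_em_b, d_em_t


def ucart_rhs(
    state: UCARTState,
    t: float,
    p: UCARTParams,
    il7: float,
    hostT_blood: float,
    hostT_tissue: float,
) -> tuple[float, float, float, float, float, float]:
    """Derivatives (scm_b, scm_t, cm_b, cm_t, em_b, em_t).

    Differentiation occurs in tissue; allogeneic elimination pairs each
    compartment with the matching host-T compartment; the truncation term
    acts in blood only, inside its window.  Host T cells are not consumed
    by killing (one-way interaction).
    """
    return _ucart_rates(
        state.scm_blood, state.scm_tissue,
        state.cm_blood, state.cm_tissue,
        state.em_blood, state.em_tissue,
        t, il7, hostT_blood, hostT_tissue,
        p.k_homingSCM, p.k_homingCM, p.k_homingEM,
        p.k_egressSCM, p.k_egressCM, p.k_egressEM,
        p.k_elimSCM, p.k_elimCM, p.k_elimEM,
        p.k_SCMCM, p.k_CMEM_high, p.k_CMEM_basal, p.t_persist,
        p.T_exp_start, p.T_exp,
        p.xfoldUCART19preIL7, p.IL7effMax, p.IL7_50, p.hill_h,
        p.expansionCMfromSCM, p.expansionEMfromSCM, p.K_safeguard,
        p.k_allo, p.allo_active,
        p.k_trunc, p.trunc_window[0], p.trunc_window[1], p.trunc_active,
    )
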