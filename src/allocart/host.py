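"""Host NK and T lymphocyte kinetics under lymphodepletion.

Each host cell type is described by a two-compartment maturation chain
with a feedback loop on production — the structure used in chemotherapy
haematotoxicity ("HemTox-like") models:

    d(tissue)/dt = k_tr * tissue * (ref(t)/blood)^gamma - k_tr * tissue
                   - k_effFC * FC(t) * tissue - k_effAl * Alem(t) * tissue
    d(blood)/dt  = k_tr * tissue - k_tr * blood - k_effAl * Alem(t) * blood

FC acts only in tissue; alemtuzumab acts in both tissue and blood.  The
feedback reference ref(t) transitions from the pre-treatment baseline
(``refHostX``, taken from the first observation) to a distinct
post-recovery level (``refHostXlast``), because recovered counts differ
substantially from pre-lymphodepletion counts.

A transient "expanding" pool (hostX2) is superimposed on the blood
compartment to capture the lymphocyte peak observed around the CAR-T
expansion; it grows exponentially over a fixed window to ``xfold`` times
its seed and then decays first-order.  Because this pool depends only on
time, it is evaluated in closed form rather than integrated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "HostCellType",
    "HostCellParams",
    "HostState",
    "feedback_reference",
    "host_rhs",
    "expanding_pool",
    "expanding_pool_rhs",
    "observed_host",
    "FEEDBACK_EPS",
    "EXPANSION_SEED",
]

#: Floor on blood counts inside the feedback power term (G/L).
FEEDBACK_EPS = 1e-6
#: Seed value of the expanding pool at the start of its window (G/L).
EXPANSION_SEED = 1e-4


class HostCellType(str, enum.Enum):
    NK = "NK"
    T = "T"


@dataclass
class HostCellParams:
    cell_type: HostCellType
    k_trX: float              # 1/day production/transfer/elimination rate
    gamma_X: float            # feedback exponent
    k_effAlhostX: float       # mL ug^-1 day^-1 alemtuzumab kill (tissue+blood)
    k_effFChostX: float       # day^-1 FC^-1 kill (tissue only)
    refHostX: float           # G/L pre-treatment baseline (data input)
    refHostXlast: float       # G/L post-recovery reference (estimated)
    t_ref_switch: float = 28.0
    tau_ref: float = 5.0
    xfold_X: float = 1.0      # magnitude of the transient expansion
    t_exp_start_X: float = 5.0
    t_exp_end_X: float = 15.0
    k_elimHostX: float = 0.3  # 1/day post-expansion elimination

    def __post_init__(self) -> None:
        for name in ("k_trX", "gamma_X", "k_effAlhostX", "k_effFChostX", "k_elimHostX"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.refHostX <= 0 or self.refHostXlast <= 0:
            raise ValueError("reference levels must be > 0")
        if self.t_exp_end_X <= self.t_exp_start_X:
            raise ValueError("t_exp_end_X must exceed t_exp_start_X")
        if self.xfold_X < 1:
            raise ValueError("xfold_X must be >= 1")


@dataclass
class HostState:
    hostX1_tissue: float
    hostX1_blood: float
    hostX2: float = 0.0


@njit(cache=True)
def _feedback_reference(t, ref0, ref_last, t_switch, tau):
    # logistic interpolation between the two reference levels
    z = (t - t_switch) / tau
    if z > 50.0:
        w = 1.0
    elif z < -50.0:
        w = 0.0
    else:
        w = 1.0 / (1.0 + np.exp(-z))
    return ref0 + (ref_last - ref0) * w


def feedback_reference(t: float, p: HostCellParams) -> float:
    """Time-dependent feedback reference, ref0 -> ref_last (G/L)."""
    return float(
        _feedback_reference(t, p.refHostX, p.refHostXlast, p.t_ref_switch, p.tau_ref)
    )


@njit(cache=True)
def _host_rates(tissue, blood, t, k_tr, gamma, k_al, k_fc,
                ref0, ref_last, t_switch, tau, alem_t, fc_t):
    ref = _feedback_reference(t, ref0, ref_last, t_switch, tau)
    b = blood if blood > FEEDBACK_EPS else FEEDBACK_EPS
    fb = (ref / b) ** gamma
    # the production term is floored so that integration noise around zero
    # cannot seed a spurious negative recovery branch (fb > 1 amplifies it)
    tis = tissue if tissue > 1e-12 else 1e-12
    d_tissue = (
        k_tr * tis * fb
        - k_tr * tissue
        - k_fc * fc_t * tissue
        - k_al * alem_t * tissue
    )
    d_blood = k_tr * tissue - k_tr * blood - k_al * alem_t * blood
    return d_tissue, d_blood


def host_rhs(
    state: HostState, t: float, p: HostCellParams, alem_t: float, fc_t: float
) -> tuple[float, float]:
    """Derivatives (d tissue/dt, d blood/dt) for the maturation chain."""
    return _host_rates(
        state.hostX1_tissue,
        state.hostX1_blood,
        t,
        p.k_trX,
        p.gamma_X,
        p.k_effAlhostX,
        p.k_effFChostX,
        p.refHostX,
        p.refHostXlast,
        p.t_ref_switch,
        p.tau_ref,
        alem_t,
        fc_t,
    )


@njit(cache=True)
def _expanding_pool(t, xfold, t_start, t_end, k_elim, seed):
    if xfold <= 1.0 or t < t_start:
        return 0.0
    g = np.log(xfold) / (t_end - t_start)
    if t <= t_end:
        return seed * np.exp(g * (t - t_start))
    return seed * xfold * np.exp(-k_elim * (t - t_end))


def expanding_pool(t: float, p: HostCellParams, seed: float = EXPANSION_SEED) -> float:
    """Closed-form value of the transient blood pool hostX2(t) in G/L.

    Zero before the expansion window; exponential growth from ``seed`` to
    ``seed * xfold`` over the window; first-order decay afterwards.  A
    unit xfold means no expansion and the pool stays at zero.
    """
    return float(
        _expanding_pool(
            t, p.xfold_X, p.t_exp_start_X, p.t_exp_end_X, p.k_elimHostX, seed
        )
    )


def expanding_pool_rhs(hostX2: float, t: float, p: HostCellParams) -> float:
    """Derivative of the expanding pool (equivalent ODE form)."""
    if hostX2 < 0:
        raise ValueError("hostX2 must be >= 0")
    if t < p.t_exp_start_X:
        return 0.0
    if t <= p.t_exp_end_X:
        g = np.log(p.xfold_X) / (p.t_exp_end_X - p.t_exp_start_X)
        return g * hostX2
    return -p.k_elimHostX * hostX2


def observed_host(state: HostState) -> float:
    """Observed blood count: slowly recovering chain plus expanding pool."""
    return state.hostX1_blood + state.hostX2
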