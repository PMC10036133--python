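"""IL-7 plasma concentration: indirect response to host-T lymphodepletion.

IL-7 is produced at a zero-order rate ``k_inIL7`` and cleared first-order
at ``k_outIL7``; lymphodepletion of host T cells stimulates production:

    dIL7/dt = k_inIL7 * (1 + IL7IncrMax * (LDP - 1) / (hostTLDP50 + (LDP - 1)))
              - k_outIL7 * IL7

where LDP (the lymphodepletion ratio) is the pre-treatment host-T
baseline over the current blood host-T count, clamped at 1 so the
stimulus vanishes at (or above) baseline.  The baseline steady state is
k_in/k_out; at full depletion production saturates at (1 + IL7IncrMax)
times baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

from numba import njit

__all__ = ["IL7Params", "lymphodepletion_ratio", "il7_rhs", "LDP_EPS"]

#: Floor on blood host-T counts in the depletion ratio (G/L).
LDP_EPS = 1e-6


@dataclass
class IL7Params:
    k_inIL7: float = 1.5      # pg/mL/day zero-order production
    k_outIL7: float = 0.5     # 1/day first-order loss
    IL7IncrMax: float = 9.7   # max fold-increase of production
    hostTLDP50: float = 10.0  # (LDP - 1) level giving half of IL7IncrMax

    def __post_init__(self) -> None:
        for name in ("k_inIL7", "k_outIL7", "IL7IncrMax", "hostTLDP50"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def baseline(self) -> float:
        return self.k_inIL7 / self.k_outIL7


@njit(cache=True)
def _ldp(hostT_blood, refHostT):
    b = hostT_blood if hostT_blood > LDP_EPS else LDP_EPS
    r = refHostT / b
    return r if r > 1.0 else 1.0


def lymphodepletion_ratio(hostT_blood: float, refHostT: float) -> float:
    """Host-T lymphodepletion ratio: baseline over current blood count, >= 1."""
    if refHostT <= 0:
        raise ValueError("refHostT must be > 0")
    return float(_ldp(hostT_blood, refHostT))


@njit(cache=True)
def _il7_production(ldp, k_in, incr_max, ldp50):
    s = ldp - 1.0
    return k_in * (1.0 + incr_max * s / (ldp50 + s))


def il7_rhs(il7: float, hostTLDP: float, p: IL7Params) -> float:
    """Turnover derivative with depletion-stimulated production."""
    return float(
        _il7_production(hostTLDP, p.k_inIL7, p.IL7IncrMax, p.hostTLDP50)
        - p.k_outIL7 * il7
    )
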