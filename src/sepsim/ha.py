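"""Hemoadsorption (HA) treatment configuration and elimination kinetics.

The hypothetical HA device removes exactly three circulating components —
activated neutrophils (N_a), pro-inflammatory activity (PI) and
anti-inflammatory activity (AI) — during a finite treatment window
(default 18-22 h after CLP).  Each elimination rate is a Hill function of
its target's current level times a maximal rate; outside the window all
rates are exactly zero.  The three terms are subtracted from the N_a, PI
and AI balance equations respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HAConfig:
    """Treatment window and per-target elimination kinetics.

    Rates are maximal elimination rates (cells/ml/hr for N_a, 1/hr-scale
    unit-interval flux for PI and AI); ``K_*`` are half-maximal levels.
    Zero rates define a sham treatment.
    """

    t_on: float = 18.0
    t_off: float = 22.0
    rate_na: float = 3.0e6
    K_na: float = 2.0e5
    rate_pi: float = 1.5
    K_pi: float = 0.2
    rate_ai: float = 0.1
    K_ai: float = 0.35
    hill_n: float = 3.0

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValueError("require t_on < t_off")
        if min(self.rate_na, self.rate_pi, self.rate_ai) < 0:
            raise ValueError("elimination rates must be nonnegative")
        if min(self.K_na, self.K_pi, self.K_ai) <= 0 or self.hill_n < 1:
            raise ValueError("half-max constants must be positive and hill_n >= 1")

    @property
    def is_sham(self) -> bool:
        return self.rate_na == 0 and self.rate_pi == 0 and self.rate_ai == 0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rate_na, self.K_na, self.rate_pi, self.K_pi,
             self.rate_ai, self.K_ai, self.hill_n],
            dtype=float,
        )


SHAM = HAConfig(rate_na=0.0, rate_pi=0.0, rate_ai=0.0)


def ha_removal_rates(state, ha: HAConfig | None, t: float) -> np.ndarray:
    """Instantaneous HA elimination rates for (N_a, PI, AI) at time ``t``.

    Outside ``[t_on, t_off)`` — or with no device configured — all three
    rates are exactly zero.
    """
    if ha is None or not (ha.t_on <= t < ha.t_off):
        return np.zeros(3)
    na, pi, ai = float(state.N_a), float(state.PI), float(state.AI)
    n = ha.hill_n
    return np.array(
        [
            ha.rate_na * na**n / (na**n + ha.K_na**n),
            ha.rate_pi * pi**n / (pi**n + ha.K_pi**n),
            ha.rate_ai * ai**n / (ai**n + ha.K_ai**n),
        ]
    )
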