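"""Compartmental ODE model of the acute inflammatory response to CLP sepsis.

The model tracks 19 states across three well-mixed compartments
(peritoneum, blood, lung):

* ``B`` — bacteria at the infection site (CFU/ml).  CLP seeds bacteria at a
  constant rate proportional to the surgical severity grade ``g``; bacteria
  grow logistically toward the carrying capacity, are killed by migrated
  tissue neutrophils (with killing capacity that saturates at high burden)
  and are removed by peritoneum-resident macrophages up to a fixed level.
* seven neutrophil pools — a bone-marrow reserve ``N_bm`` releasing mature
  cells into the circulation; resting ``N_r``, primed ``N_p`` and
  systemically activated ``N_a`` blood neutrophils; peritoneal ``N_t``,
  lung-capillary sequestered ``N_s`` and migrated lung ``N_l`` neutrophils.
  Resting cells are primed by the local infection and primed cells migrate
  to the infected tissue; systemic activation (driven by PI) diverts cells
  into a non-chemotactic activated pool that sequesters in lung capillaries
  and transmigrates into lung tissue, and it also directly impairs the
  migration of primed cells.
* three unit-interval effectors — systemic pro-inflammation ``PI``,
  anti-inflammation ``AI`` and integrated tissue damage ``D`` — written as
  normalized Hill-gate (HillCube) relaxation equations, so they remain
  closed in [0, 1].  AI inhibition of PI is partial: it is moderated away
  as PI itself approaches saturation.
* eight observable states mapping the coarse effectors sigmoidally onto the
  normalized measurement scale (TNFa, IL-1b, IL-6 from PI; IL-10 from AI;
  HMGB1, creatinine, ALT from D; L-selectin from the neutrophil activation
  flux).

All Hill exponents are 3.  Simulated outcomes are classified at the end of
the 200 h horizon: a virtual animal survives iff the bacterial burden is
below ``B_crit`` and systemic inflammation is below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ha import HAConfig
from .registry import HILL_N, ModelParameters

try:  # optional JIT of the right-hand side
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


STATE_NAMES = (
    "B", "N_bm", "N_r", "N_p", "N_a", "N_t", "N_s", "N_l",
    "PI", "AI", "D",
    "O_TNF", "O_IL1b", "O_IL6", "O_IL10", "O_Lsel", "O_HMGB1", "O_CRT", "O_ALT",
)
N_STATES = 19
COUNT_IDX = np.arange(8)          # concentration-valued states
UNIT_IDX = np.arange(8, 19)       # unit-interval states
OBSERVABLES = ("TNF", "IL1b", "IL6", "IL10", "Lsel", "HMGB1", "CRT", "ALT")
OBS_STATE_IDX = {name: 11 + i for i, name in enumerate(OBSERVABLES)}
CYTOKINES = frozenset({"TNF", "IL1b", "IL6", "IL10"})


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the offending parameter values."""

    def __init__(self, message: str, params: ModelParameters | None = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class CLPSeverity:
    """Severity grade of the CLP operation, a unit-interval scalar."""

    g: float = 0.08

    def __post_init__(self) -> None:
        if not 0.0 <= self.g <= 1.0:
            raise ValueError(f"severity grade must lie in [0,1], got {self.g}")


@dataclass(frozen=True)
class SurvivalCriteria:
    """End-of-horizon survival rule: B below ``B_crit`` and PI below ``PI_crit``."""

    horizon: float = 200.0
    B_crit: float = 3.0e7
    PI_crit: float = 0.5

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.B_crit <= 0:
            raise ValueError("horizon and B_crit must be positive")
        if not 0.0 < self.PI_crit < 1.0:
            raise ValueError("PI_crit must lie in (0,1)")


@dataclass(frozen=True)
class SolverConfig:
    """Stiff-integration settings.

    Absolute tolerances are split by state scale: 1 CFU- or cell-per-ml for
    the concentration states (which span nine orders of magnitude) and 1e-9
    for the unit-interval states.
    """

    rtol: float = 1e-6
    atol_counts: float = 1.0
    atol_unit: float = 1e-9
    method: str = "LSODA"
    max_step: float = np.inf

    def atol_vector(self) -> np.ndarray:
        atol = np.full(N_STATES, self.atol_unit)
        atol[COUNT_IDX] = self.atol_counts
        return atol


@dataclass(frozen=True)
class InitialState:
    """Homeostatic initial condition.

    The pre-CLP animal is at the infection-free fixed point: no bacteria,
    no inflammation or damage, empty primed/activated/tissue/lung pools,
    and resting blood neutrophils ``N_r0`` balanced by basal marrow release
    (which pins the reserve size at ``N_r0 / (tau_nr_death * k_release_basal)``).
    Marrow granulopoiesis replenishes the reserve at the basal release rate,
    making the fixed point exact.
    """

    N_r0: float = 8.0e6
    f_sat: float = 1.0e8     # saturation level of the neutrophil-killing capacity (CFU/ml)
    phi_ref: float = 1.0e6   # activation-flux normalization for the L-selectin mapping


@dataclass
class StateVector:
    """Named view of one 19-component model state."""

    B: float = 0.0
    N_bm: float = 0.0
    N_r: float = 0.0
    N_p: float = 0.0
    N_a: float = 0.0
    N_t: float = 0.0
    N_s: float = 0.0
    N_l: float = 0.0
    PI: float = 0.0
    AI: float = 0.0
    D: float = 0.0
    O_TNF: float = 0.0
    O_IL1b: float = 0.0
    O_IL6: float = 0.0
    O_IL10: float = 0.0
    O_Lsel: float = 0.0
    O_HMGB1: float = 0.0
    O_CRT: float = 0.0
    O_ALT: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} states, got {y.shape}")
        return cls(**dict(zip(STATE_NAMES, map(float, y))))

    def validate(self) -> None:
        y = self.to_array()
        if np.any(y[COUNT_IDX] < 0):
            raise ValueError("count-valued states must be nonnegative")
        if np.any(y[UNIT_IDX] < 0) or np.any(y[UNIT_IDX] > 1):
            raise ValueError("PI, AI, D and observables must lie in [0,1]")


def hill(x: float, K: float, n: float = HILL_N):
    """Plain Hill activation x^n / (x^n + K^n) for concentration regulators."""
    if K <= 0:
        raise ValueError("half-max constant K must be positive")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill regulator must be nonnegative")
    out = x**n / (x**n + K**n)
    return float(out) if out.ndim == 0 else out


def hillcube(x: float, K: float, n: float = HILL_N):
    """Normalized Hill gate for unit-interval regulators.

    Rescales the plain Hill function so a fully-on regulator (x = 1) gives
    exactly 1; this keeps unit-interval states closed under the relaxation
    dynamics dx/dt = (gate - x)/tau.
    """
    h = hill(x, K, n)
    return h * (1.0 + K**n)


@_njit(cache=False)
def _rhs(y, k, g, ha_arr, ha_on, f_sat, phi_ref, prod):  # pragma: no cover - exercised via simulate
    # unpack with overshoot guards (roundoff-scale negatives clamped; larger
    # violations are caught post hoc by trajectory validation)
    B = max(y[0], 0.0)
    Nbm = max(y[1], 0.0)
    Nr = max(y[2], 0.0)
    Np_ = max(y[3], 0.0)
    Na = max(y[4], 0.0)
    Nt = max(y[5], 0.0)
    Ns = max(y[6], 0.0)
    Nl = max(y[7], 0.0)
    PI = min(max(y[8], 0.0), 1.0)
    AI = min(max(y[9], 0.0), 1.0)
    D = min(max(y[10], 0.0), 1.0)

    r_growth = k[50]
    r_mac = k[51]
    B_inf = k[52]
    B_mac = k[53]
    Nt_max = k[54]
    V_bt = k[55]
    V_bl = k[56]

    Bn = B / B_inf
    Bn3 = Bn * Bn * Bn
    PI3 = PI * PI * PI
    D3 = D * D * D

    # --- bacteria ------------------------------------------------------
    fB = B if B < f_sat else f_sat
    mac = B if B < B_mac else B_mac
    # CLP source and logistic growth both saturate at the carrying capacity
    dB = (k[32] * g + r_growth * B) * (1.0 - Bn) - k[33] * Nt * fB - r_mac * mac

    # --- bone marrow release ------------------------------------------
    kap9 = k[8]
    rel = (k[7] + k[9] * Bn3 / (Bn3 + kap9 * kap9 * kap9)) * Nbm
    dNbm = prod - rel

    # --- blood neutrophil transitions ---------------------------------
    k12_3 = k[11] * k[11] * k[11]
    B3 = B * B * B
    prime = Nr * (B3 / (B3 + k12_3)) / k[12]

    def _hc(x3, kap):
        kap3 = kap * kap * kap
        return x3 * (1.0 + kap3) / (x3 + kap3) if x3 > 0.0 else 0.0

    act_r = Nr * _hc(PI3, k[13]) / k[14]
    act_p = Np_ * _hc(PI3, k[16]) / k[17]
    dNr = rel - Nr / k[10] - prime - act_r

    k25_3 = k[24] * k[24] * k[24]
    impair = 1.0 - _hc(PI3, k[25])
    headroom = 1.0 - Nt / Nt_max
    if headroom < 0.0:
        headroom = 0.0
    mig = Np_ * (1.0 / k[23] + (B3 / (B3 + k25_3)) / k[18]) * impair * headroom
    dNp = prime - Np_ / k[15] - act_p - mig

    seq = Na * _hc(PI3, k[20]) / k[21]
    # --- hemoadsorption elimination (active only inside the window) ----
    rem_na = 0.0
    rem_pi = 0.0
    rem_ai = 0.0
    if ha_on:
        n_ha = ha_arr[6]
        if Na > 0.0:
            rem_na = ha_arr[0] * Na**n_ha / (Na**n_ha + ha_arr[1] ** n_ha)
        if PI > 0.0:
            rem_pi = ha_arr[2] * PI**n_ha / (PI**n_ha + ha_arr[3] ** n_ha)
        if AI > 0.0:
            rem_ai = ha_arr[4] * AI**n_ha / (AI**n_ha + ha_arr[5] ** n_ha)
    dNa = act_r + act_p - Na / k[19] - seq - rem_na

    lung = Ns * _hc(PI3, k[27]) / k[21]
    dNt = V_bt * mig - Nt / k[26]
    dNs = V_bl * seq - Ns / k[22] - lung
    dNl = lung - Nl / k[28]

    # --- effectors (normalized Hill-gate relaxation, OR-combined) ------
    act_B = Bn3 / (Bn3 + k[0] * k[0] * k[0])
    act_D = _hc(D3, k[1])
    inh_AI = _hc(AI * AI * AI, k[2]) * (1.0 - PI)  # partial: moderated at high PI
    f_pi = (1.0 - (1.0 - act_B) * (1.0 - act_D)) * (1.0 - inh_AI)
    dPI = (f_pi - PI) / k[3] - rem_pi

    f_ai = 1.0 - (1.0 - _hc(PI3, k[4])) * (1.0 - _hc(D3, k[5]))
    dAI = (f_ai - AI) / k[6] - rem_ai

    ns_n = Ns / Nt_max
    nl_n = Nl / Nt_max
    ns3 = ns_n * ns_n * ns_n
    nl3 = nl_n * nl_n * nl_n
    k30_3 = k[29] * k[29] * k[29]
    k31_3 = k[30] * k[30] * k[30]
    f_d = 1.0 - (1.0 - ns3 / (ns3 + k30_3)) * (1.0 - nl3 / (nl3 + k31_3))
    dD = (f_d - D) / k[31]

    # --- observable mappings ------------------------------------------
    flux = act_r + act_p + seq  # neutrophil activation flux (drives L-selectin)
    fn = flux / phi_ref
    fn3 = fn * fn * fn
    k43_3 = k[42] * k[42] * k[42]

    dy = np.empty(19)
    dy[0] = dB
    dy[1] = dNbm
    dy[2] = dNr
    dy[3] = dNp
    dy[4] = dNa
    dy[5] = dNt
    dy[6] = dNs
    dy[7] = dNl
    dy[8] = dPI
    dy[9] = dAI
    dy[10] = dD
    dy[11] = (_hc(PI3, k[34]) - y[11]) / k[35]   # TNFa <- PI
    dy[12] = (_hc(PI3, k[36]) - y[12]) / k[37]   # IL-1b <- PI
    dy[13] = (_hc(PI3, k[38]) - y[13]) / k[39]   # IL-6 <- PI
    dy[14] = (_hc(AI * AI * AI, k[40]) - y[14]) / k[41]  # IL-10 <- AI
    dy[15] = (fn3 / (fn3 + k43_3) - y[15]) / k[43]       # L-selectin <- activation flux
    dy[16] = (_hc(D3, k[44]) - y[16]) / k[45]    # HMGB1 <- D
    dy[17] = (_hc(D3, k[46]) - y[17]) / k[47]    # creatinine <- D
    dy[18] = (_hc(D3, k[48]) - y[18]) / k[49]    # ALT <- D
    return dy


def homeostatic_state(params: ModelParameters, init: InitialState | None = None) -> StateVector:
    """Construct the infection-free fixed point used as the initial condition."""
    init = init or InitialState()
    k8 = params[8]
    tau11 = params[11]
    return StateVector(N_r=init.N_r0, N_bm=init.N_r0 / (tau11 * k8))


def derivatives(
    t: float,
    state: StateVector,
    params: ModelParameters,
    severity: CLPSeverity,
    ha: HAConfig | None = None,
    init: InitialState | None = None,
) -> np.ndarray:
    """Time derivative of the full 19-state vector (user-facing wrapper)."""
    state.validate()
    init = init or InitialState()
    y = state.to_array()
    ha_on = ha is not None and ha.t_on <= t < ha.t_off
    ha_arr = ha.as_array() if ha is not None else np.zeros(7)
    prod = params[8] * (init.N_r0 / (params[11] * params[8]))
    return np.asarray(
        _rhs(y, params.values, severity.g, ha_arr, ha_on, init.f_sat, init.phi_ref, prod)
    )


@dataclass
class Trajectory:
    """Solved model trajectory on a fixed output grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 19)
    params: ModelParameters = field(repr=False, default=None)
    severity: CLPSeverity = None
    ha: HAConfig | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def at(self, t: float) -> StateVector:
        """State at time ``t`` (linear interpolation on the output grid)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside trajectory range")
        y = np.array([np.interp(t, self.times, self.states[:, i]) for i in range(N_STATES)])
        return StateVector.from_array(y)

    def observables_at(self, times: np.ndarray) -> np.ndarray:
        """Observable states (8 x len(times)) interpolated at measurement times."""
        out = np.empty((len(OBSERVABLES), len(times)))
        for i, name in enumerate(OBSERVABLES):
            out[i] = np.interp(times, self.times, self.states[:, OBS_STATE_IDX[name]])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, state, value) representation."""
        frames = [
            pd.DataFrame({"time": self.times, "state": name, "value": self.states[:, i]})
            for i, name in enumerate(STATE_NAMES)
        ]
        return pd.concat(frames, ignore_index=True)

    def to_hdf5(self, path) -> None:
        """Dense matrix plus metadata (severity, HA window, parameters)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("states", data=self.states)
            f.attrs["state_names"] = list(STATE_NAMES)
            if self.severity is not None:
                f.attrs["severity"] = self.severity.g
            if self.ha is not None:
                f.attrs["ha_window"] = (self.ha.t_on, self.ha.t_off)
            if self.params is not None:
                f.create_dataset("params", data=self.params.values)


def simulate(
    params: ModelParameters,
    severity: CLPSeverity,
    t_grid: np.ndarray | None = None,
    ha: HAConfig | None = None,
    y0: StateVector | None = None,
    init: InitialState | None = None,
    solver: SolverConfig | None = None,
) -> Trajectory:
    """Integrate the model from the homeostatic state over ``t_grid``.

    With an HA device configured, the integration is restarted exactly at
    the treatment window edges so the discontinuous elimination terms never
    straddle a solver step.
    """
    init = init or InitialState()
    solver = solver or SolverConfig()
    if t_grid is None:
        t_grid = np.linspace(0.0, 200.0, 201)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    if y0 is None:
        y0 = homeostatic_state(params, init)
    y = y0.to_array()

    prod = params[8] * (init.N_r0 / (params[11] * params[8]))
    ha_arr = ha.as_array() if ha is not None else np.zeros(7)
    k = params.values
    g = severity.g
    atol = solver.atol_vector()

    # segment boundaries: split at the HA window edges when a device is present
    edges = [t_grid[0], t_grid[-1]]
    if ha is not None:
        edges += [t for t in (ha.t_on, ha.t_off) if t_grid[0] < t < t_grid[-1]]
    edges = sorted(set(edges))

    times_out = [t_grid[:1]]
    states_out = [y.reshape(1, -1)]
    for a, b in zip(edges[:-1], edges[1:]):
        ha_on = ha is not None and ha.t_on <= a < ha.t_off

        def fun(t, yv, _on=ha_on):
            return _rhs(yv, k, g, ha_arr, _on, init.f_sat, init.phi_ref, prod)

        inner = t_grid[(t_grid > a) & (t_grid < b)]
        t_eval = np.concatenate([inner, [b]])
        sol = solve_ivp(
            fun, (a, b), y, method=solver.method, t_eval=t_eval,
            rtol=solver.rtol, atol=atol, max_step=solver.max_step,
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{a},{b}]: {sol.message}", params)
        y = sol.y[:, -1].copy()
        times_out.append(sol.t)
        states_out.append(sol.y.T)

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    # keep only requested grid points (window edges may not be on the grid)
    keep = np.isin(times, t_grid)
    times, states = times[keep], states[keep]

    # roundoff guard: clamp solver undershoot at tolerance scale, flag worse
    tol_counts, tol_unit = 10 * solver.atol_counts, 1e-6
    counts = states[:, COUNT_IDX]
    if counts.min() < -tol_counts:
        raise IntegrationError(f"negative count state beyond tolerance ({counts.min():.3g})", params)
    unit = states[:, UNIT_IDX]
    if unit.min() < -tol_unit or unit.max() > 1 + tol_unit:
        raise IntegrationError("unit-interval state escaped [0,1] beyond tolerance", params)
    states[:, COUNT_IDX] = np.clip(counts, 0.0, None)
    states[:, UNIT_IDX] = np.clip(unit, 0.0, 1.0)

    return Trajectory(times=times, states=states, params=params, severity=severity, ha=ha)


def activation_flux(state: StateVector, params: ModelParameters) -> float:
    """Total neutrophil activation flux (cells/ml/hr).

    Sum of the three PI-gated transitions: resting->activated,
    primed->activated and activated->sequestered.  Drives the L-selectin
    observable.
    """
    state.validate()
    pi = state.PI
    a = state.N_r * hillcube(pi, params[14]) / params[15]
    b = state.N_p * hillcube(pi, params[17]) / params[18]
    c = state.N_a * hillcube(pi, params[21]) / params[22]
    return float(a + b + c)


def classify_survival(traj: Trajectory, criteria: SurvivalCriteria | None = None) -> str:
    """Label a trajectory ``"survivor"`` or ``"non-survivor"`` at the horizon."""
    criteria = criteria or SurvivalCriteria()
    if traj.times[-1] < criteria.horizon:
        raise ValueError(
            f"trajectory ends at {traj.times[-1]} h, before the {criteria.horizon} h horizon"
        )
    end = traj.at(criteria.horizon)
    ok = end.B < criteria.B_crit and end.PI < criteria.PI_crit
    return "survivor" if ok else "non-survivor"
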