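"""Metropolis MCMC ensemble calibration against cohort time-course data.

The posterior over the 34 dynamic parameters is proportional to
``exp(-C(theta)/T)`` — a Boltzmann form whose energy is the weighted sum of
squared residuals

    C(theta) = sum_s sum_t ((m_st - yhat_st) / sigma_st)^2

between the cohort's normalized measurement means ``m`` and the simulated
observables ``yhat`` at the measurement times, weighted by the measurement
SDs.  The prior is uniform on the log10 scale between wide per-parameter
bounds; proposals are componentwise normal in log10 space; proposals
falling outside the prior box are rejected.  The temperature ``T`` and the
proposal scale are tuned during burn-in toward a target acceptance ratio of
about 0.25 and then frozen, so post-burn-in samples form a time-homogeneous
Markov chain.

Convergence across independent chains is assessed with the Gelman-Rubin
potential scale reduction factor (PSRF), the square root of the ratio of
the pooled-variance estimate to the within-chain variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import CLPSeverity, InitialState, IntegrationError, SolverConfig, simulate
from .registry import ModelParameters, N_MAPPING, N_SAMPLED, prior_bounds
from .synthetic import CohortData


@dataclass(frozen=True)
class PriorBounds:
    """Uniform prior box over the sampled parameters, on the log10 scale."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if lo.shape != hi.shape or np.any(lo <= 0) or np.any(lo >= hi):
            raise ValueError("prior bounds must be positive with lo < hi elementwise")

    @classmethod
    def default(cls, mask: np.ndarray | None = None) -> "PriorBounds":
        lo, hi = prior_bounds()
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            lo, hi = lo[mask], hi[mask]
        return cls(lo=lo, hi=hi)

    @property
    def log_lo(self) -> np.ndarray:
        return np.log10(self.lo)

    @property
    def log_hi(self) -> np.ndarray:
        return np.log10(self.hi)

    def contains(self, log_theta: np.ndarray) -> bool:
        return bool(np.all(log_theta >= self.log_lo) and np.all(log_theta <= self.log_hi))

    @property
    def n_dim(self) -> int:
        return self.lo.size


@dataclass
class ChainConfig:
    """One Metropolis chain: temperature, proposal scale, budget, seed.

    ``mask`` selects which of the 34 dynamic parameters are sampled (all by
    default); the rest stay at their values in ``start``.  ``sigma_prop``
    is the componentwise normal proposal SD in log10 space.

    The default sampling temperature (T = 20) is sized to the desk-scale
    calibration problem: typical proposal cost increments are then of
    order T, so the acceptance ratio is governed by the proposal scale
    rather than by the local ruggedness of the cost landscape, and the
    burn-in adaptation converges to a stable ~0.25 acceptance.  Analytic
    toy targets (and any run wanting the untempered posterior) should set
    T explicitly.
    """

    n_steps: int = 20_000
    burn_in: int = 6_000
    thinning: int = 10
    T: float = 20.0
    sigma_prop: float = 0.02
    seed: int = 0
    start: ModelParameters | None = None
    mask: np.ndarray | None = None
    tune: bool = True
    target_acceptance: float = 0.25
    tune_window: int = 100

    def __post_init__(self) -> None:
        if self.T <= 0 or self.sigma_prop <= 0:
            raise ValueError("temperature and proposal scale must be positive")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("require n_steps > burn_in >= 0")
        if not 0 < self.target_acceptance < 1:
            raise ValueError("target acceptance must lie in (0,1)")


@dataclass
class Chain:
    """Post-burn-in, thinned Metropolis samples with their costs."""

    samples: np.ndarray        # (n_kept, n_dim) log10-scale
    costs: np.ndarray
    accepted: np.ndarray       # per-step acceptance flags (post burn-in)
    config: ChainConfig
    acceptance_ratio: float
    T_final: float
    sigma_final: float
    final_state: np.ndarray = None  # last log10 position (independent of thinning)

    @property
    def n_kept(self) -> int:
        return self.samples.shape[0]


@dataclass
class PSRFReport:
    """Gelman-Rubin diagnostics over parallel chains."""

    psrf: np.ndarray
    n_chains: int
    n_samples: int

    @property
    def max(self) -> float:
        return float(np.max(self.psrf))

    def converged(self, threshold: float = 1.1) -> bool:
        return bool(np.all(self.psrf < threshold))


def cost(
    theta: ModelParameters,
    data: CohortData,
    severity: CLPSeverity,
    init: InitialState | None = None,
    solver: SolverConfig | None = None,
) -> float:
    """Weighted sum of squared residuals of the simulated observables.

    The simulated observables are max-normalized over the measurement grid
    per channel — the same scale the cohort means live on.  Integration
    failure maps to +inf (the proposal is rejected by the sampler).
    """
    times = np.asarray(data.timepoints, dtype=float)
    t_grid = np.unique(np.concatenate([[0.0], times]))
    try:
        traj = simulate(theta, severity, t_grid=t_grid, init=init, solver=solver)
    except IntegrationError:
        return np.inf
    yhat = traj.observables_at(times)
    ymax = yhat.max(axis=1, keepdims=True)
    yhat = np.divide(yhat, ymax, out=np.zeros_like(yhat), where=ymax > 0)
    resid = (data.means - yhat) / data.sds
    return float(np.sum(resid**2))


def log_target(cost_value: float, T: float) -> float:
    """Boltzmann log-density -C/T (up to an additive constant)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -cost_value / T


def sample_prior(bounds: PriorBounds, seed: int, size: int | None = None) -> np.ndarray:
    """Draw parameter vectors uniform in log10 space inside the prior box.

    Returns natural-scale values, shape (n_dim,) or (size, n_dim).
    """
    rng = np.random.default_rng(seed)
    n = 1 if size is None else size
    u = rng.uniform(bounds.log_lo, bounds.log_hi, size=(n, bounds.n_dim))
    out = 10**u
    return out[0] if size is None else out


def _make_cost_fn(
    data: CohortData,
    severity: CLPSeverity,
    base: ModelParameters,
    mask: np.ndarray,
    init: InitialState | None,
) -> Callable[[np.ndarray], float]:
    def fn(log_theta: np.ndarray) -> float:
        theta = base.with_sampled(10**log_theta, mask=mask)
        return cost(theta, data, severity, init=init)

    return fn


def run_chain(
    config: ChainConfig,
    data: CohortData,
    bounds: PriorBounds | None = None,
    severity: CLPSeverity | None = None,
    init: InitialState | None = None,
    cost_fn: Callable[[np.ndarray], float] | None = None,
) -> Chain:
    """Run one Metropolis chain against a cohort.

    ``cost_fn`` may replace the ODE-based cost (a callable on the log10
    parameter vector) — used by tests with analytic targets.  Proposal:
    componentwise normal in log10 space; out-of-bounds proposals are
    rejected, preserving the truncated-uniform prior.  Fixed seed gives a
    bit-identical chain.
    """
    severity = severity or CLPSeverity()
    base = config.start if config.start is not None else ModelParameters.baseline()
    mask = (
        np.asarray(config.mask, dtype=bool)
        if config.mask is not None
        else np.ones(N_SAMPLED, dtype=bool)
    )
    if bounds is None:
        bounds = PriorBounds.default(mask)
    if bounds.n_dim != int(mask.sum()):
        raise ValueError("prior bounds dimension does not match the sampling mask")
    if cost_fn is None:
        cost_fn = _make_cost_fn(data, severity, base, mask, init)

    rng = np.random.default_rng(config.seed)
    x = np.log10(base.sampled[mask])
    if not bounds.contains(x):
        raise ValueError("chain start lies outside the prior bounds")
    c = cost_fn(x)

    T = config.T
    sigma = config.sigma_prop
    log_sigma = np.log(sigma)
    n_dim = bounds.n_dim

    kept_x, kept_c, acc_flags = [], [], []
    window_acc = 0
    n_windows = 0
    for step in range(config.n_steps):
        prop = x + rng.normal(0.0, sigma, n_dim)
        accept = False
        if bounds.contains(prop):
            c_prop = cost_fn(prop)
            dC = c_prop - c
            if dC <= 0 or rng.random() < np.exp(-dC / T):
                accept = True
                x, c = prop, c_prop
        in_burn = step < config.burn_in
        if in_burn and config.tune:
            window_acc += accept
            if (step + 1) % config.tune_window == 0:
                n_windows += 1
                rate = window_acc / config.tune_window
                window_acc = 0
                # Robbins-Monro on the log proposal scale, decaying gain
                gain = 2.0 / (1 + n_windows) ** 0.6
                log_sigma += gain * (rate - config.target_acceptance)
                sigma = float(np.exp(log_sigma))
        if not in_burn:
            acc_flags.append(accept)
            if (step - config.burn_in) % config.thinning == 0:
                kept_x.append(x.copy())
                kept_c.append(c)

    acc_flags = np.asarray(acc_flags, dtype=bool)
    return Chain(
        samples=np.asarray(kept_x),
        costs=np.asarray(kept_c, dtype=float),
        accepted=acc_flags,
        config=config,
        acceptance_ratio=float(acc_flags.mean()) if acc_flags.size else 0.0,
        T_final=T,
        sigma_final=sigma,
        final_state=x.copy(),
    )


def tune_chain(
    config: ChainConfig,
    data: CohortData | None,
    bounds: PriorBounds | None = None,
    target_acceptance: float | None = None,
    severity: CLPSeverity | None = None,
    init: InitialState | None = None,
    cost_fn: Callable[[np.ndarray], float] | None = None,
) -> ChainConfig:
    """Adapt the proposal scale during a burn-in phase and freeze it.

    Runs a tuning-only chain (burn-in length from ``config``) and returns a
    configuration with ``sigma_prop`` frozen at the adapted value and
    tuning disabled.  If tuning is already disabled the config is returned
    unchanged.  Failure to move at all is reported via the returned config
    (sigma at its last value) rather than raised.
    """
    if not config.tune:
        return config
    target = config.target_acceptance if target_acceptance is None else target_acceptance
    probe = replace(
        config,
        n_steps=config.burn_in + 1,
        burn_in=config.burn_in,
        target_acceptance=target,
    )
    chain = run_chain(probe, data, bounds, severity=severity, init=init, cost_fn=cost_fn)
    base = config.start if config.start is not None else ModelParameters.baseline()
    mask = (
        np.asarray(config.mask, dtype=bool)
        if config.mask is not None
        else np.ones(N_SAMPLED, dtype=bool)
    )
    start = base.with_sampled(10**chain.final_state, mask=mask)
    return replace(
        config,
        sigma_prop=chain.sigma_final,
        T=chain.T_final,
        tune=False,
        start=start,
        burn_in=config.burn_in,
    )


def gelman_rubin(chains: Sequence[Chain | np.ndarray]) -> PSRFReport:
    """Potential scale reduction factor across parallel chains.

    Uses the classic multi-chain estimator: with within-chain variance W
    and between-chain variance B/n, the pooled estimate is
    V = (n-1)/n * W + B/n and PSRF = sqrt(V/W), per parameter.
    """
    arrs = [c.samples if isinstance(c, Chain) else np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    arrs = [a.reshape(a.shape[0], -1) for a in arrs]
    n = min(a.shape[0] for a in arrs)
    if n < 10:
        raise ValueError("chains too short for a variance-ratio diagnostic")
    X = np.stack([a[-n:] for a in arrs])  # (m, n, d)
    m = X.shape[0]
    chain_means = X.mean(axis=1)
    chain_vars = X.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    if np.any(W <= 0):
        raise ValueError("zero within-chain variance; PSRF undefined")
    B_over_n = chain_means.var(axis=0, ddof=1)
    V = (n - 1) / n * W + B_over_n
    return PSRFReport(psrf=np.sqrt(V / W), n_chains=m, n_samples=n)


def fit_mapping_parameters(
    theta: ModelParameters,
    data_surv: CohortData,
    data_nonsurv: CohortData,
    severity: CLPSeverity | None = None,
    init: InitialState | None = None,
    maxiter: int = 60,
) -> ModelParameters:
    """Estimate the 16 observation-mapping parameters, shared by cohorts.

    Minimizes the sum of both cohorts' costs over the mapping block with a
    bounded local optimizer (L-BFGS-B in log10 space), dynamic parameters
    held fixed; the result is frozen for the subsequent MCMC.
    """
    severity = severity or CLPSeverity()
    tab = theta.table
    mp = tab[tab["group"] == "mapping"].sort_values("id")
    lo = np.log10(mp["prior_lo"].to_numpy(dtype=float))
    hi = np.log10(mp["prior_hi"].to_numpy(dtype=float))
    x0 = np.log10(theta.mapping)

    def objective(logm: np.ndarray) -> float:
        cand = theta.copy()
        cand.values[N_SAMPLED : N_SAMPLED + N_MAPPING] = 10**logm
        return cost(cand, data_surv, severity, init=init) + cost(
            cand, data_nonsurv, severity, init=init
        )

    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"maxiter": maxiter},
    )
    out = theta.copy()
    out.values[N_SAMPLED : N_SAMPLED + N_MAPPING] = 10**res.x
    return out
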