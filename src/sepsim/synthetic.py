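"""Synthetic two-cohort measurement data with the structure of a CLP study.

Emulates a longitudinal septic-rat experiment: 23 virtual animals (7
survivors, 16 non-survivors), eight plasma observables sampled at 18, 22,
48, 72, 120, 144 and 168 h after CLP.  Each cohort is generated from its
own ground-truth parameter vector with lognormal inter-animal variation;
raw measurements carry multiplicative lognormal assay noise; cytokine
channels are natural-log transformed and every channel is normalized by
its per-cohort maximum, mirroring the experimental processing pipeline.
The generator reproduces the *statistical shape* of such data (transform,
noise character, cohort imbalance), not any particular animal experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CLPSeverity,
    CYTOKINES,
    InitialState,
    IntegrationError,
    OBSERVABLES,
    simulate,
)
from .registry import ModelParameters, prior_bounds

DEFAULT_TIMEPOINTS = (18.0, 22.0, 48.0, 72.0, 120.0, 144.0, 168.0)

# raw-scale synthesis: cytokines span ~3 decades above a unit baseline so
# the ln-transform returns the model observable exactly; other markers get
# a small positive offset so the log/ratio pipeline stays defined
_CYTO_DECADES = np.log(1000.0)
_MARKER_OFFSET = 1e-4


def nonsurvivor_shift(theta: ModelParameters) -> ModelParameters:
    """Derive the non-survivor ground truth from a survivor parameterization.

    The shifted phenotype encodes the dysregulation signature: easier
    systemic activation of blood neutrophils (lower PI thresholds), slower
    priming and tissue migration, stronger migration impairment, delayed
    anti-inflammatory activation and slower damage resolution.
    """
    return theta.with_values(
        kappa_nr_act_pi=0.35,
        kappa_np_act_pi=0.35,
        tau_prime=3.5,
        tau_migration=5.0,
        kappa_mig_inh_pi=0.4,
        kappa_ai_pi=0.6,
        tau_dam=120.0,
    )


@dataclass
class GroundTruth:
    """Cohort-generating configuration: true parameters, severity and noise."""

    theta_surv: ModelParameters = field(default_factory=ModelParameters.baseline)
    theta_nonsurv: ModelParameters = None
    severity: CLPSeverity = field(default_factory=CLPSeverity)
    init: InitialState = field(default_factory=InitialState)
    noise_sd: float = 0.2        # multiplicative lognormal measurement noise (log scale)
    animal_sd: float = 0.1       # inter-animal parameter jitter, sd in log10 space
    n_animals: int = 23
    n_survivors: int = 7
    timepoints: tuple = DEFAULT_TIMEPOINTS
    sd_floor: float = 0.05       # floor on normalized-scale SDs (keeps cost weights finite)

    def __post_init__(self) -> None:
        if self.theta_nonsurv is None:
            self.theta_nonsurv = nonsurvivor_shift(self.theta_surv)
        if not 0 < self.n_survivors <= self.n_animals:
            raise ValueError("require 0 < n_survivors <= n_animals")
        if self.noise_sd < 0 or self.animal_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive (degenerate noise configuration)")


@dataclass
class CohortData:
    """Per-cohort normalized measurement summary — the calibration target.

    ``table`` has columns (cohort, observable, time_h, mean, sd, n).  The
    ``means``/``sds`` arrays are ordered observables x timepoints.
    """

    cohort: str
    table: pd.DataFrame
    timepoints: np.ndarray

    @property
    def means(self) -> np.ndarray:
        return self._pivot("mean")

    @property
    def sds(self) -> np.ndarray:
        return self._pivot("sd")

    def _pivot(self, col: str) -> np.ndarray:
        piv = self.table.pivot(index="observable", columns="time_h", values=col)
        piv = piv.loc[list(OBSERVABLES), list(self.timepoints)]
        return piv.to_numpy(dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortData":
        tab = pd.read_csv(path)
        cohorts = tab["cohort"].unique()
        if len(cohorts) != 1:
            raise ValueError("CohortData CSV must contain exactly one cohort")
        times = np.sort(tab["time_h"].unique())
        return cls(cohort=str(cohorts[0]), table=tab, timepoints=times)


def log_max_normalize(values: np.ndarray, cytokine: bool = True) -> np.ndarray:
    """Normalize one observable's raw values onto the unit measurement scale.

    Cytokines: natural-log transform, then divide by the maximum over all
    values (all animals and time points pooled).  Other markers: divide by
    the maximum directly.  The maximal element maps to exactly 1.
    """
    v = np.asarray(values, dtype=float)
    if cytokine:
        if np.any(v <= 0):
            raise ValueError("cytokine measurements must be strictly positive to log-transform")
        v = np.log(v)
    else:
        if np.any(v < 0):
            raise ValueError("marker measurements must be nonnegative")
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("maximum of transformed values must be positive")
    return v / vmax


def _synthesize_raw(obs_value: float, observable: str) -> float:
    """Map a model observable (unit scale) to a plausible raw assay value."""
    if observable in CYTOKINES:
        return float(np.exp(_CYTO_DECADES * obs_value))
    return float(obs_value + _MARKER_OFFSET)


def generate_cohort(
    truth: GroundTruth, seed: int
) -> tuple[CohortData, CohortData, pd.DataFrame]:
    """Simulate, measure, corrupt and summarize a two-cohort virtual study.

    Returns (survivor CohortData, non-survivor CohortData, raw measurements).
    Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(seed)
    lo, hi = prior_bounds(truth.theta_surv.table)
    times = np.asarray(truth.timepoints, dtype=float)
    t_grid = np.unique(np.concatenate([np.linspace(0.0, max(200.0, times[-1]), 201), times]))

    rows = []
    for animal in range(truth.n_animals):
        is_surv = animal < truth.n_survivors
        theta = truth.theta_surv if is_surv else truth.theta_nonsurv
        jitter = 10 ** rng.normal(0.0, truth.animal_sd, theta.sampled.size)
        p = theta.with_sampled(np.clip(theta.sampled * jitter, lo, hi))
        try:
            traj = simulate(p, truth.severity, t_grid=t_grid, init=truth.init)
        except IntegrationError as err:
            raise IntegrationError(
                f"ground-truth simulation failed for virtual animal {animal}", p
            ) from err
        obs = traj.observables_at(times)  # 8 x n_times
        for i, name in enumerate(OBSERVABLES):
            for j, t in enumerate(times):
                raw = _synthesize_raw(obs[i, j], name)
                raw *= np.exp(rng.normal(0.0, truth.noise_sd))
                rows.append(
                    {
                        "animal_id": animal,
                        "cohort": "survivor" if is_surv else "non-survivor",
                        "observable": name,
                        "time_h": t,
                        "value": raw,
                    }
                )
    raw_df = pd.DataFrame(rows)

    cohorts = []
    for label in ("survivor", "non-survivor"):
        sub = raw_df[raw_df["cohort"] == label]
        recs = []
        for name in OBSERVABLES:
            vals = sub.loc[sub["observable"] == name]
            norm = log_max_normalize(vals["value"].to_numpy(), cytokine=name in CYTOKINES)
            # assay noise can push ln-values below the pre-CLP baseline;
            # clamp onto the unit measurement scale
            norm_df = vals.assign(norm=np.clip(norm, 0.0, 1.0))
            for t, grp in norm_df.groupby("time_h"):
                recs.append(
                    {
                        "cohort": label,
                        "observable": name,
                        "time_h": float(t),
                        "mean": float(grp["norm"].mean()),
                        "sd": max(float(grp["norm"].std(ddof=1)) if len(grp) > 1 else 0.0,
                                  truth.sd_floor),
                        "n": int(len(grp)),
                    }
                )
        cohorts.append(CohortData(cohort=label, table=pd.DataFrame(recs), timepoints=times))
    return cohorts[0], cohorts[1], raw_df
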