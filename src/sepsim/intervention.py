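"""In-silico hemoadsorption trials on virtual cohorts.

Members of a (typically non-survivor) parameter ensemble are simulated
twice — once untreated (sham) and once with the HA device active during
its treatment window — and both trajectories are classified against the
end-of-horizon survival criteria.  The treated cohort splits into a
rescued sub-population and a refractory one; the per-member outcomes and
the two sub-ensembles are returned for downstream multivariate contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ha import HAConfig
from .model import (
    CLPSeverity,
    InitialState,
    IntegrationError,
    SurvivalCriteria,
    Trajectory,
    classify_survival,
    simulate,
)
from .registry import ModelParameters


@dataclass
class TreatmentReport:
    """Per-member outcomes of a virtual HA trial.

    ``table`` columns: member_id, sham_outcome, treated_outcome, B_end,
    PI_end (treated end-state).  ``treated_survivor_idx`` /
    ``treated_nonsurvivor_idx`` index rows of the *drawn* member matrix.
    """

    table: pd.DataFrame
    members: np.ndarray                  # (n_draw, n_dim) log10-scale draws
    n_failures: int
    ha: HAConfig
    criteria: SurvivalCriteria
    trajectories: list = field(default=None, repr=False)

    @property
    def n_members(self) -> int:
        return len(self.table)

    @property
    def counts(self) -> dict:
        t = self.table
        return {
            "sham_survivor": int((t["sham_outcome"] == "survivor").sum()),
            "sham_non_survivor": int((t["sham_outcome"] == "non-survivor").sum()),
            "treated_survivor": int((t["treated_outcome"] == "survivor").sum()),
            "treated_non_survivor": int((t["treated_outcome"] == "non-survivor").sum()),
        }

    @property
    def treated_survivor_idx(self) -> np.ndarray:
        """Row indices into ``members`` of the rescued sub-population."""
        t = self.table
        return t.loc[t["treated_outcome"] == "survivor", "member_id"].to_numpy()

    @property
    def treated_nonsurvivor_idx(self) -> np.ndarray:
        """Row indices into ``members`` of the refractory sub-population."""
        t = self.table
        return t.loc[t["treated_outcome"] == "non-survivor", "member_id"].to_numpy()


def treat_member(
    params: ModelParameters,
    ha: HAConfig,
    severity: CLPSeverity,
    criteria: SurvivalCriteria,
    init: InitialState | None = None,
    t_grid: np.ndarray | None = None,
) -> tuple[str, str, Trajectory, Trajectory]:
    """Simulate one member with and without HA; return both labels and trajectories."""
    if t_grid is None:
        t_grid = np.linspace(0.0, criteria.horizon, int(criteria.horizon) + 1)
    sham_traj = simulate(params, severity, t_grid=t_grid, ha=None, init=init)
    ha_traj = simulate(params, severity, t_grid=t_grid, ha=None if ha.is_sham else ha, init=init)
    return (
        classify_survival(sham_traj, criteria),
        classify_survival(ha_traj, criteria),
        sham_traj,
        ha_traj,
    )


def treat_ensemble(
    members: np.ndarray,
    base: ModelParameters,
    ha: HAConfig,
    n_draw: int,
    seed: int,
    severity: CLPSeverity | None = None,
    criteria: SurvivalCriteria | None = None,
    init: InitialState | None = None,
    mask: np.ndarray | None = None,
    replace: bool = True,
    keep_trajectories: bool = False,
) -> TreatmentReport:
    """Run a virtual HA trial over ``n_draw`` members drawn from an ensemble.

    ``members`` is an (n, n_dim) matrix of log10-scale sampled-parameter
    vectors (a calibration ensemble); ``base`` supplies the non-sampled
    parameters and ``mask`` maps columns onto the 34-entry dynamic block.
    Integration failures are counted and excluded from the outcome table.
    """
    severity = severity or CLPSeverity()
    criteria = criteria or SurvivalCriteria()
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if members.size == 0:
        raise ValueError("ensemble must be non-empty")
    if not replace and n_draw > members.shape[0]:
        raise ValueError("n_draw exceeds ensemble size without replacement")
    rng = np.random.default_rng(seed)
    idx = rng.choice(members.shape[0], size=n_draw, replace=replace)
    drawn = members[idx]

    t_grid = np.linspace(0.0, criteria.horizon, int(criteria.horizon) + 1)
    rows, trajs = [], []
    n_failures = 0
    for mid, logv in enumerate(drawn):
        p = base.with_sampled(10**logv, mask=mask)
        try:
            sham_lab, ha_lab, sham_traj, ha_traj = treat_member(
                p, ha, severity, criteria, init=init, t_grid=t_grid
            )
        except IntegrationError:
            n_failures += 1
            continue
        end = ha_traj.at(criteria.horizon)
        rows.append(
            {
                "member_id": mid,
                "sham_outcome": sham_lab,
                "treated_outcome": ha_lab,
                "B_end": end.B,
                "PI_end": end.PI,
            }
        )
        if keep_trajectories:
            trajs.append((sham_traj, ha_traj))
    return TreatmentReport(
        table=pd.DataFrame(rows),
        members=drawn,
        n_failures=n_failures,
        ha=ha,
        criteria=criteria,
        trajectories=trajs if keep_trajectories else None,
    )
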