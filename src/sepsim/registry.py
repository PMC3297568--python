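"""Parameter registry for the CLP sepsis model.

The model carries 57 parameters in three groups:

* ``dynamic`` (ids 1-34): kinetic parameters of the 11 mechanistic states —
  half-maximal activation/inhibition constants (``kappa``), first-order time
  constants (``tau``, hours) and a few mass-action rates.  These are the
  parameters sampled by the MCMC calibration.
* ``mapping`` (ids 35-50): the 16 observation-mapping parameters, one
  (kappa, tau) pair per measured observable.  They are fitted once, jointly
  over both cohorts, and frozen during MCMC.
* ``constant`` (ids 51-57): physical constants — bacterial growth and
  resident-macrophage removal rates (0.1 /hr each), the carrying capacity
  (1e9 CFU/ml), the macrophage-controlled level (1e5 CFU/ml), the tissue
  neutrophil maximum (2e7 cells/ml) and the blood:tissue / blood:lung volume
  ratios (34.4/25 and 34.4/48).

All Hill exponents are globally fixed at 3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_PARAMS = 57
N_SAMPLED = 34
N_MAPPING = 16
N_CONSTANT = 7
HILL_N = 3.0

# id, name, baseline value, unit, group, sampled, prior_lo, prior_hi
# kappa_* with unit "" act on unit-interval (or max-normalized) regulators;
# kappa_* with a concentration unit act on raw concentrations.
_REGISTRY_CSV = """\
id,name,value,unit,group,sampled,prior_lo,prior_hi
1,kappa_pi_bac,0.02,,dynamic,1,1e-3,1
2,kappa_pi_dam,0.5,,dynamic,1,1e-3,1
3,kappa_pi_ai,0.3,,dynamic,1,1e-3,1
4,tau_pi,10.0,hr,dynamic,1,0.5,500
5,kappa_ai_pi,0.4,,dynamic,1,1e-3,1
6,kappa_ai_dam,0.5,,dynamic,1,1e-3,1
7,tau_ai,15.0,hr,dynamic,1,0.5,500
8,k_release_basal,3.22e-06,1/hr,dynamic,1,1e-7,1e-4
9,kappa_release_bac,0.01,,dynamic,1,1e-3,1
10,k_release_infect,3.15e-07,1/hr,dynamic,1,1e-8,1e-5
11,tau_nr_death,10.0,hr,dynamic,1,0.5,500
12,kappa_prime_bac,1e6,CFU/ml,dynamic,1,1e4,1e9
13,tau_prime,2.0,hr,dynamic,1,0.5,500
14,kappa_nr_act_pi,0.5,,dynamic,1,1e-3,1
15,tau_nr_act,5.0,hr,dynamic,1,0.5,500
16,tau_np_death,10.0,hr,dynamic,1,0.5,500
17,kappa_np_act_pi,0.5,,dynamic,1,1e-3,1
18,tau_np_act,5.0,hr,dynamic,1,0.5,500
19,tau_migration,2.0,hr,dynamic,1,0.5,500
20,tau_na_death,10.0,hr,dynamic,1,0.5,500
21,kappa_seq_pi,0.4,,dynamic,1,1e-3,1
22,tau_seq,5.0,hr,dynamic,1,0.5,500
23,tau_ns_death,20.0,hr,dynamic,1,0.5,500
24,tau_mig_basal,50.0,hr,dynamic,1,0.5,500
25,kappa_mig_bac,1e6,CFU/ml,dynamic,1,1e4,1e9
26,kappa_mig_inh_pi,0.6,,dynamic,1,1e-3,1
27,tau_nt_death,24.0,hr,dynamic,1,0.5,500
28,kappa_lung_pi,0.6,,dynamic,1,1e-3,1
29,tau_nl_death,48.0,hr,dynamic,1,0.5,500
30,kappa_dam_ns,0.02,,dynamic,1,1e-3,1
31,kappa_dam_nl,0.02,,dynamic,1,1e-3,1
32,tau_dam,48.0,hr,dynamic,1,0.5,500
33,k_clp_source,9.40e+07,CFU/ml/hr,dynamic,1,3e6,3e9
34,k_kill,6.61e-08,ml/neu/hr,dynamic,1,2e-9,2e-6
35,kappa_tnf_pi,0.3,,mapping,0,1e-3,1
36,tau_tnf,4.0,hr,mapping,0,0.5,500
37,kappa_il1b_pi,0.35,,mapping,0,1e-3,1
38,tau_il1b,6.0,hr,mapping,0,0.5,500
39,kappa_il6_pi,0.3,,mapping,0,1e-3,1
40,tau_il6,8.0,hr,mapping,0,0.5,500
41,kappa_il10_ai,0.12,,mapping,0,1e-3,1
42,tau_il10,10.0,hr,mapping,0,0.5,500
43,kappa_lsel_flux,0.15,,mapping,0,1e-3,1
44,tau_lsel,6.0,hr,mapping,0,0.5,500
45,kappa_hmgb1_dam,0.04,,mapping,0,1e-3,1
46,tau_hmgb1,24.0,hr,mapping,0,0.5,500
47,kappa_crt_dam,0.05,,mapping,0,1e-3,1
48,tau_crt,30.0,hr,mapping,0,0.5,500
49,kappa_alt_dam,0.06,,mapping,0,1e-3,1
50,tau_alt,36.0,hr,mapping,0,0.5,500
51,r_growth,0.1,1/hr,constant,0,,
52,r_mac,0.1,1/hr,constant,0,,
53,B_inf,1.0e9,CFU/ml,constant,0,,
54,B_mac,1.0e5,CFU/ml,constant,0,,
55,Nt_max,2.0e7,cells/ml,constant,0,,
56,V_bt,1.376,,constant,0,,
57,V_bl,0.7166666666666667,,constant,0,,
"""


def registry_table() -> pd.DataFrame:
    """Baseline registry as a DataFrame (one row per parameter, id-indexed)."""
    df = pd.read_csv(io.StringIO(_REGISTRY_CSV))
    df["unit"] = df["unit"].fillna("")
    return df


@dataclass
class ModelParameters:
    """The 57-parameter vector plus group metadata.

    ``values[i]`` holds parameter id ``i+1``; indexing helpers below use the
    1-based table ids throughout.
    """

    values: np.ndarray
    table: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters, got {self.values.shape}")
        if self.table is None:
            self.table = registry_table()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all parameter values must be finite")
        head = self.values[: N_SAMPLED + N_MAPPING]
        # mass-action rates (ids 8, 10, 33, 34) may be zero (e.g. killing
        # disabled); thresholds and time constants must be strictly positive
        zero_ok = np.zeros(N_SAMPLED + N_MAPPING, dtype=bool)
        zero_ok[[7, 9, 32, 33]] = True
        if np.any(head[~zero_ok] <= 0) or np.any(head[zero_ok] < 0):
            raise ValueError("thresholds and time constants must be strictly positive")

    @classmethod
    def baseline(cls) -> "ModelParameters":
        table = registry_table()
        return cls(values=table["value"].to_numpy(dtype=float), table=table)

    def copy(self) -> "ModelParameters":
        return ModelParameters(values=self.values.copy(), table=self.table)

    def __getitem__(self, pid: int) -> float:
        return float(self.values[pid - 1])

    def with_values(self, **overrides: float) -> "ModelParameters":
        """Return a copy with named parameters replaced (e.g. ``tau_pi=12``)."""
        new = self.copy()
        names = self.table.set_index("name")["id"]
        for name, val in overrides.items():
            if name not in names.index:
                raise KeyError(f"unknown parameter {name!r}")
            new.values[int(names[name]) - 1] = float(val)
        return new

    def with_sampled(self, sampled: np.ndarray, mask: np.ndarray | None = None) -> "ModelParameters":
        """Return a copy with the MCMC-sampled block (ids 1-34) replaced.

        ``sampled`` is on the natural scale.  With ``mask`` (boolean, length
        34) only the masked subset is replaced, in mask order.
        """
        new = self.copy()
        if mask is None:
            new.values[:N_SAMPLED] = np.asarray(sampled, dtype=float)
        else:
            idx = np.flatnonzero(np.asarray(mask, dtype=bool))
            new.values[idx] = np.asarray(sampled, dtype=float)
        return new

    @property
    def sampled(self) -> np.ndarray:
        """The 34 dynamic (MCMC-sampled) parameter values."""
        return self.values[:N_SAMPLED].copy()

    @property
    def mapping(self) -> np.ndarray:
        """The 16 observation-mapping parameter values."""
        return self.values[N_SAMPLED : N_SAMPLED + N_MAPPING].copy()

    @property
    def constants(self) -> np.ndarray:
        """The 7 physical constants (ids 51-57)."""
        return self.values[N_SAMPLED + N_MAPPING :].copy()

    def name_of(self, pid: int) -> str:
        return str(self.table.loc[self.table["id"] == pid, "name"].iloc[0])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["value"] = self.values
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ModelParameters":
        df = pd.read_csv(path)
        df["unit"] = df["unit"].fillna("")
        df = df.sort_values("id").reset_index(drop=True)
        if len(df) != N_PARAMS:
            raise ValueError(f"registry CSV must have {N_PARAMS} rows, got {len(df)}")
        return cls(values=df["value"].to_numpy(dtype=float), table=df)


def prior_bounds(table: pd.DataFrame | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper prior bounds for the 34 sampled parameters (natural scale).

    The prior is uniform on the log10 scale between these bounds; they are
    deliberately wide (threshold parameters span three decades, time constants
    span 0.5-500 h) and cover every baseline value.
    """
    if table is None:
        table = registry_table()
    dyn = table[table["sampled"] == 1].sort_values("id")
    lo = dyn["prior_lo"].to_numpy(dtype=float)
    hi = dyn["prior_hi"].to_numpy(dtype=float)
    if np.any(lo <= 0) or np.any(lo >= hi):
        raise ValueError("prior bounds must be positive with lo < hi")
    return lo, hi
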