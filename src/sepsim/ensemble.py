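"""Multivariate contrast of parameter ensembles via the inverse correlation matrix.

For an ensemble of sampled parameter vectors (log10 scale), the inverse of
the sample correlation matrix K = C^-1 approximates the Hessian of the cost
function around its minima.  Three views are extracted:

* the eigenstructure of K — large eigenvalues mark *stiff* parameter
  combinations that the data constrain tightly, small eigenvalues mark
  *sloppy* ones;
* the multiple correlation of each parameter with all others,
  R_i = sqrt(1 - 1/K_ii);
* the partial correlation between two parameters controlling for all
  others, P_ij = -K_ij / sqrt(K_ii K_jj).

Two ensembles (e.g. survivor vs non-survivor cohorts) are contrasted by
testing each pair's partial-correlation difference (Fisher z, BH-corrected)
and classifying significant changes as *lose*, *gain* or *flip*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ParameterEnsemble:
    """n_samples x n_params matrix of log10-scale parameter draws."""

    samples: np.ndarray
    label: str = ""
    param_ids: np.ndarray | None = None  # 1-based registry ids per column

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("ensemble must be a 2-D matrix")
        n, p = self.samples.shape
        if n <= p:
            raise ValueError(f"need more samples than parameters (got {n} x {p})")
        if self.param_ids is None:
            self.param_ids = np.arange(1, p + 1)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_params(self) -> int:
        return self.samples.shape[1]

    def subsample(self, n: int, seed: int) -> "ParameterEnsemble":
        rng = np.random.default_rng(seed)
        idx = rng.choice(self.n_samples, size=min(n, self.n_samples), replace=False)
        return ParameterEnsemble(self.samples[idx], label=self.label, param_ids=self.param_ids)


class SingularEnsembleError(ValueError):
    """Correlation matrix is (numerically) singular — e.g. a constant or
    duplicated parameter column; remove it before analysis."""


@dataclass
class CorrelationSummary:
    """Correlation matrix, its inverse, and the derived multivariate statistics."""

    C: np.ndarray
    K: np.ndarray
    eigenvalues: np.ndarray = field(default=None)
    eigenvectors: np.ndarray = field(default=None)
    label: str = ""
    n_samples: int = 0
    param_ids: np.ndarray = field(default=None)

    @property
    def n_params(self) -> int:
        return self.C.shape[0]


def inverse_correlation(ensemble: ParameterEnsemble, cond_max: float = 1e12) -> CorrelationSummary:
    """Sample correlation matrix and its inverse (the approximate Hessian)."""
    X = ensemble.samples
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise SingularEnsembleError(f"constant parameter column(s) at index {bad.tolist()}")
    C = np.corrcoef(X, rowvar=False)
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > cond_max:
        raise SingularEnsembleError(
            f"correlation matrix condition number {cond:.3g} exceeds {cond_max:.0e}; "
            "remove duplicate or linearly dependent parameters"
        )
    K = np.linalg.inv(C)
    K = (K + K.T) / 2.0
    return CorrelationSummary(
        C=C, K=K, label=ensemble.label,
        n_samples=ensemble.n_samples, param_ids=ensemble.param_ids,
    )


def stiffness_spectrum(summary: CorrelationSummary) -> CorrelationSummary:
    """Eigendecomposition of K, eigenvalues descending (stiffest first).

    Eigenvector sign convention: the largest-magnitude component of each
    vector is made positive.
    """
    K = summary.K
    if np.max(np.abs(K - K.T)) > 1e-8:
        raise ValueError("inverse correlation matrix is not symmetric")
    w, V = np.linalg.eigh(K)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    summary.eigenvalues = w
    summary.eigenvectors = V
    return summary


def multiple_correlation(summary: CorrelationSummary) -> np.ndarray:
    """Per-parameter multiple correlation R_i = sqrt(1 - 1/K_ii)."""
    Kd = np.diag(summary.K)
    if np.any(Kd < 1.0 - 1e-8):
        raise ValueError("diagonal of the inverse correlation matrix must be >= 1")
    return np.sqrt(1.0 - 1.0 / np.maximum(Kd, 1.0))


def partial_correlation(summary: CorrelationSummary) -> np.ndarray:
    """Partial correlation matrix P_ij = -K_ij / sqrt(K_ii K_jj), unit diagonal."""
    K = summary.K
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


@dataclass
class PairChange:
    """A parameter pair whose partial correlation changed between ensembles."""

    i: int
    j: int
    r_a: float
    r_b: float
    difference: float
    p_value: float
    p_adjusted: float
    kind: str  # lose | gain | flip


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def classify_pair_changes(
    summary_a: CorrelationSummary,
    summary_b: CorrelationSummary,
    n_a: int | None = None,
    n_b: int | None = None,
    alpha: float = 0.05,
    min_delta: float = 0.1,
) -> pd.DataFrame:
    """Contrast partial correlations of two ensembles pair by pair.

    A two-sample Fisher z test (with the partial-correlation degrees-of-
    freedom correction n - 3 - k, k = number of controlled variables) is
    applied to every pair, Benjamini-Hochberg corrected at ``alpha``;
    significant pairs with |difference| >= ``min_delta`` are classified:

    * ``flip`` — the sign reverses, both magnitudes individually significant;
    * ``lose`` — |r| drops in ensemble B;
    * ``gain`` — |r| rises in ensemble B.

    Returns a tidy DataFrame (one row per significant pair) with 1-based
    parameter ids, mirroring published pair-change tables.
    """
    if summary_a.n_params != summary_b.n_params:
        raise ValueError("ensembles have mismatched parameter dimensions")
    p = summary_a.n_params
    n_a = n_a or summary_a.n_samples
    n_b = n_b or summary_b.n_samples
    k_ctrl = p - 2
    df_a, df_b = n_a - 3 - k_ctrl, n_b - 3 - k_ctrl
    if min(df_a, df_b) <= 0:
        raise ValueError("too few samples for the partial-correlation z test")

    P_a = partial_correlation(summary_a)
    P_b = partial_correlation(summary_b)
    iu = np.triu_indices(p, k=1)
    ra, rb = P_a[iu], P_b[iu]
    z_diff = (_fisher_z(ra) - _fisher_z(rb)) / np.sqrt(1 / df_a + 1 / df_b)
    pvals = 2 * stats.norm.sf(np.abs(z_diff))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    # per-ensemble significance of each coefficient (for the flip rule)
    za = np.abs(_fisher_z(ra)) * np.sqrt(df_a)
    zb = np.abs(_fisher_z(rb)) * np.sqrt(df_b)
    zcrit = stats.norm.isf(alpha / 2)

    rows = []
    for idx in range(len(ra)):
        if not reject[idx] or abs(ra[idx] - rb[idx]) < min_delta:
            continue
        i, j = int(iu[0][idx]), int(iu[1][idx])
        if np.sign(ra[idx]) != np.sign(rb[idx]) and za[idx] > zcrit and zb[idx] > zcrit:
            kind = "flip"
        elif abs(rb[idx]) < abs(ra[idx]):
            kind = "lose"
        else:
            kind = "gain"
        ids = summary_a.param_ids
        rows.append(
            PairChange(
                i=int(ids[i]) if ids is not None else i + 1,
                j=int(ids[j]) if ids is not None else j + 1,
                r_a=float(ra[idx]),
                r_b=float(rb[idx]),
                difference=float(ra[idx] - rb[idx]),
                p_value=float(pvals[idx]),
                p_adjusted=float(p_adj[idx]),
                kind=kind,
            )
        )
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["i", "j", "r_a", "r_b", "difference", "p_value", "p_adjusted", "kind"],
    )


def effective_sample_size(x: np.ndarray, max_lag: int | None = None) -> float:
    """ESS via the integrated autocorrelation time (initial-positive-sum).

    MCMC autocorrelation shrinks the information content of an ensemble;
    significance tests on chain-derived ensembles should use this in place
    of the raw sample count.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        return float(n)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    max_lag = max_lag or min(n // 3, 1000)
    tau = 1.0
    for lag in range(1, max_lag):
        rho = np.dot(x[:-lag], x[lag:]) / ((n - lag) * var)
        if rho <= 0:
            break
        tau += 2.0 * rho
    return float(n / tau)
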