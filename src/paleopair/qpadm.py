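"""Admixture-proportion modelling of a target from k sources via f4 systems.

The target's ancestry is modelled as a weighted mixture of source
populations relative to m "right" reference populations. With pivot right
population R1, the estimating equations are

    y_j = f4(T,  R1; R_{j+1}, R1)      j = 1 .. m-1
    X_{j,i} = f4(S_i, R1; R_{j+1}, R1)

and weights solve min (y - Xw)' Omega^{-1} (y - Xw) subject to sum(w) = 1,
where Omega is the weighted block-jackknife covariance of the residual
evaluated at the equality-constrained OLS solution, followed by one GLS
refinement. The fit statistic is chi-square with m - k degrees of freedom
(m - 1 equations, k - 1 free parameters). A model is infeasible when any
point-estimate weight is negative, regardless of its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .fstats import FreqTable
from .jackknife import BlockPartition, jackknife_covariance

__all__ = ["AdmixtureModel", "f4_system", "fit_qpadm", "nested_model_search"]

_RIDGE = 1e-9


@dataclass(frozen=True)
class AdmixtureModel:
    """One fitted model — the shape of a qpAdm results-table row."""

    target: str
    sources: tuple[str, ...]
    rights: tuple[str, ...]
    weights: np.ndarray
    se: np.ndarray
    p_value: float
    feasible: bool
    chi2: float
    dof: int
    n_sites: int

    def summary(self) -> str:
        tag = " (infeasible)" if not self.feasible else ""
        parts = [
            f"{src}={w:+.3f} ± {s:.3f}"
            for src, w, s in zip(self.sources, self.weights, self.se)
        ]
        return (
            f"{self.target}{tag}: p={self.p_value:.4g}  " + "  ".join(parts)
            + f"  [chi2={self.chi2:.2f}, dof={self.dof}, n={self.n_sites}]"
        )


@dataclass(frozen=True)
class F4System:
    """Block partial sums for the estimating equations.

    ``y_sums`` is (B, m-1), ``x_sums`` is (B, m-1, k) and ``n_sums`` (B,)
    holds per-block usable-site counts; ratios of their totals give the f4
    estimates.
    """

    target: str
    sources: tuple[str, ...]
    rights: tuple[str, ...]
    y_sums: np.ndarray
    x_sums: np.ndarray
    n_sums: np.ndarray
    weights: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.n_sums.sum())

    def y(self) -> np.ndarray:
        return self.y_sums.sum(axis=0) / self.n_sums.sum()

    def x(self) -> np.ndarray:
        return self.x_sums.sum(axis=0) / self.n_sums.sum()


def f4_system(
    target: str,
    sources: list[str],
    rights: list[str],
    freqs: FreqTable,
    partition: BlockPartition,
) -> F4System:
    """Build y, X and their per-block partial sums over complete-case sites."""
    k = len(sources)
    m = len(rights)
    if m < k + 1:
        raise ValueError(
            f"need at least k+1={k + 1} right populations for {k} sources, got {m}"
        )
    pops = [target, *sources, *rights]
    mask = freqs.complete_cases(pops)
    if not mask.any():
        raise ValueError(f"no sites with data in all of {pops}")

    p_t = freqs.freq(target)
    p_s = [freqs.freq(s) for s in sources]
    p_r = [freqs.freq(r) for r in rights]
    pivot = p_r[0]

    B = partition.n_blocks
    y_sums = np.zeros((B, m - 1))
    x_sums = np.zeros((B, m - 1, k))
    n_sums = np.zeros(B)
    d_t = np.where(mask, p_t - pivot, 0.0)
    d_s = [np.where(mask, ps - pivot, 0.0) for ps in p_s]
    for j in range(1, m):
        d_r = np.where(mask, p_r[j] - pivot, 0.0)
        y_site = d_t * d_r
        for b, idx in enumerate(partition.blocks):
            y_sums[b, j - 1] = y_site[idx].sum()
        for i in range(k):
            x_site = d_s[i] * d_r
            for b, idx in enumerate(partition.blocks):
                x_sums[b, j - 1, i] = x_site[idx].sum()
    for b, idx in enumerate(partition.blocks):
        n_sums[b] = mask[idx].sum()
    return F4System(
        target=target,
        sources=tuple(sources),
        rights=tuple(rights),
        y_sums=y_sums,
        x_sums=x_sums,
        n_sums=n_sums,
        weights=partition.weights,
    )


def _constrained_gls(y: np.ndarray, X: np.ndarray, omega_inv: np.ndarray) -> np.ndarray:
    """argmin (y - Xw)' Oi (y - Xw) s.t. 1'w = 1, via the Lagrange system."""
    k = X.shape[1]
    A = X.T @ omega_inv @ X
    b = X.T @ omega_inv @ y
    ones = np.ones(k)
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular design matrix X in admixture fit")
    w_free = A_inv @ b
    lam = (1.0 - ones @ w_free) / (ones @ A_inv @ ones)
    return w_free + lam * (A_inv @ ones)


def _residual_covariance(
    system: F4System, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted block-jackknife covariance of e(w) = y - X w at fixed w."""
    B = system.y_sums.shape[0]
    q = system.y_sums.shape[1]
    per_block = np.concatenate(
        [
            system.y_sums,
            system.x_sums.reshape(B, -1),
            system.n_sums[:, None],
        ],
        axis=1,
    )

    def resid(t: np.ndarray) -> np.ndarray:
        y = t[:q]
        X = t[q:-1].reshape(q, -1)
        n = t[-1]
        return (y - X @ w) / n

    return jackknife_covariance(per_block, resid, system.weights)


def _fit_weights(system: F4System) -> tuple[np.ndarray, np.ndarray, float]:
    """Weights, Omega^{-1}, and the minimized quadratic form."""
    q = system.y_sums.shape[1]
    y = system.y()
    X = system.x()
    # pass 1: equality-constrained OLS
    w0 = _constrained_gls(y, X, np.eye(q))
    # Omega from block jackknife of the residual at w0
    _, omega = _residual_covariance(system, w0)
    try:
        omega_inv = np.linalg.inv(omega)
    except np.linalg.LinAlgError:
        omega_inv = np.linalg.inv(omega + _RIDGE * np.eye(q))
    # pass 2: one GLS refinement
    w = _constrained_gls(y, X, omega_inv)
    e = y - X @ w
    chi2 = float(e @ omega_inv @ e)
    return w, omega_inv, chi2


def fit_qpadm(
    target: str,
    sources: list[str],
    rights: list[str],
    freqs: FreqTable,
    partition: BlockPartition,
) -> AdmixtureModel:
    """Fit one admixture model; SEs from a block jackknife of the whole fit."""
    system = f4_system(target, sources, rights, freqs, partition)
    w, omega_inv, chi2 = _fit_weights(system)
    dof = len(rights) - len(sources)
    p_value = float(stats.chi2.sf(chi2, dof)) if chi2 > 0 else 1.0

    # delete-one-block refits of the full functional, Omega included:
    # holding Omega fixed understates the SEs by ~10% in calibration runs
    B = system.y_sums.shape[0]
    keep_all = np.arange(B)
    loo = []
    for b in range(B):
        keep = keep_all != b
        sub = F4System(
            target=system.target,
            sources=system.sources,
            rights=system.rights,
            y_sums=system.y_sums[keep],
            x_sums=system.x_sums[keep],
            n_sums=system.n_sums[keep],
            weights=system.weights[keep],
        )
        loo.append(_fit_weights(sub)[0])
    loo = np.stack(loo)
    weights = system.weights
    M = weights.sum()
    h = M / weights
    theta_j = B * w - ((1.0 - weights / M)[:, None] * loo).sum(axis=0)
    tau = h[:, None] * w[None, :] - (h - 1.0)[:, None] * loo
    var = (((tau - theta_j[None, :]) ** 2) / (h - 1.0)[:, None]).sum(axis=0) / B
    se = np.sqrt(np.maximum(var, 0.0))

    return AdmixtureModel(
        target=target,
        sources=tuple(sources),
        rights=tuple(rights),
        weights=w,
        se=se,
        p_value=p_value,
        feasible=bool(np.all(w >= 0)),
        chi2=chi2,
        dof=dof,
        n_sites=system.n_sites,
    )


def nested_model_search(
    target: str,
    sources: list[str],
    rights: list[str],
    freqs: FreqTable,
    partition: BlockPartition,
) -> list[AdmixtureModel]:
    """Fit the full model and every proper non-empty source subset.

    Results ordered by ascending source count, then descending p-value.
    """
    if len(sources) < 2:
        raise ValueError("nested search needs at least 2 sources")
    models = []
    for r in range(1, len(sources) + 1):
        for subset in combinations(sources, r):
            models.append(fit_qpadm(target, list(subset), rights, freqs, partition))
    models.sort(key=lambda m: (len(m.sources), -m.p_value))
    return models
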