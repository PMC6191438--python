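"""Supervised ancestry against fixed reference-panel frequencies, plus the
yield ~ ancestry + inbreeding fitness regression.

Ancestry proportions q (on the K-simplex) maximize the binomial genotype
likelihood sum_j [g_j log(sum_k q_k f_kj) + (2 - g_j) log(sum_k q_k (1 - f_kj))]
by the standard admixture EM update with panel frequencies held fixed
(supervised mode). Yield is modelled as a Gaussian GLM
y = beta0 + beta1*q_focal + beta2*F + eps; ancestry enters as a proportion in
[0, 1], so beta1 is the yield change over the full 0 -> 1 ancestry range (divide
by 100 for a per-percent slope).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, ParameterError
from .diversity import GLMFit, fit_gaussian_glm

logger = logging.getLogger("cacao_popgen")

__all__ = [
    "PanelFrequencies",
    "QEstimate",
    "supervised_ancestry",
    "cohort_ancestry",
    "yield_ancestry_fit",
]

_EPS = 1e-6


@dataclass
class PanelFrequencies:
    """K populations x M sites of alt-allele frequencies, clamped to
    [eps, 1-eps] before likelihood use."""

    freqs: np.ndarray  # (K, M)
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2:
            raise ParameterError("panel frequencies must be (K, M)")
        if (f < 0).any() or (f > 1).any():
            raise ParameterError("panel frequencies must lie in [0,1]")
        self.freqs = np.clip(f, _EPS, 1.0 - _EPS)
        if not self.labels:
            self.labels = tuple(f"pop{k}" for k in range(f.shape[0]))

    @property
    def K(self) -> int:
        return self.freqs.shape[0]


@dataclass(frozen=True)
class QEstimate:
    q: np.ndarray  # (K,) on the simplex
    loglik: float
    iterations: int
    converged: bool


def _loglik(q: np.ndarray, f: np.ndarray, g: np.ndarray) -> float:
    pj = q @ f
    return float(np.sum(g * np.log(pj) + (2.0 - g) * np.log1p(-pj)))


def supervised_ancestry(
    g: np.ndarray,
    panel: PanelFrequencies,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> QEstimate:
    """EM estimate of one individual's ancestry vector against a fixed panel.

    ``g`` holds genotype codes in {0,1,2,MISSING}; missing sites are dropped.
    The E-step assigns each of the individual's 2M allele copies to source
    populations by responsibility; the M-step renormalizes. The log-likelihood
    is non-decreasing across iterations and convergence is declared when its
    gain drops below ``tol``.
    """
    g = np.asarray(g, dtype=float)
    keep = g != MISSING
    if not keep.any():
        raise ParameterError("all sites missing for this individual")
    g = g[keep]
    f = panel.freqs[:, keep]  # (K, M)
    K, M = f.shape
    q = np.full(K, 1.0 / K)
    ll = _loglik(q, f, g)
    if not np.isfinite(ll):
        j = int(np.argmax(~np.isfinite(g * np.log(q @ f))))
        raise ParameterError(f"non-finite likelihood at site index {j}")
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        pj = q @ f  # (M,)
        # responsibilities for alt and ref allele copies
        r_alt = (q[:, None] * f) / pj[None, :]
        r_ref = (q[:, None] * (1.0 - f)) / (1.0 - pj)[None, :]
        q_new = (r_alt @ g + r_ref @ (2.0 - g)) / (2.0 * M)
        q_new = np.clip(q_new, 0.0, None)
        q_new /= q_new.sum()
        ll_new = _loglik(q_new, f, g)
        gain = ll_new - ll
        q, ll = q_new, ll_new
        if gain < tol:
            converged = True
            break
    return QEstimate(q=q, loglik=ll, iterations=it, converged=converged)


def cohort_ancestry(
    calls: np.ndarray, panel: PanelFrequencies, tol: float = 1e-6,
    max_iter: int = 2000,
) -> np.ndarray:
    """Per-individual supervised ancestry for a cohort; returns (n_ind, K)."""
    return np.stack([
        supervised_ancestry(row, panel, tol=tol, max_iter=max_iter).q
        for row in calls
    ])


def yield_ancestry_fit(
    yields: np.ndarray,
    q_focal: np.ndarray,
    F: np.ndarray,
    q_alternative: np.ndarray | None = None,
    condition_threshold: float = 1e8,
) -> dict:
    """Gaussian GLM of yield on focal ancestry and inbreeding.

    Returns {"fit": GLMFit, "slope_per_proportion", "slope_per_percent", and
    optionally "alternative_fit"} where the alternative swaps in another
    population's ancestry (the non-domesticate contrast). Complete cases only;
    a collinearity warning is attached when the design is ill-conditioned.
    """
    yields = np.asarray(yields, dtype=float)
    q_focal = np.asarray(q_focal, dtype=float)
    F = np.asarray(F, dtype=float)
    ok = np.isfinite(yields) & np.isfinite(q_focal) & np.isfinite(F)
    if (q_focal[ok] < 0).any() or (q_focal[ok] > 1).any():
        raise ParameterError("ancestry proportions must lie in [0,1]")
    X = np.column_stack([np.ones(ok.sum()), q_focal[ok], F[ok]])
    warn = None
    if np.linalg.cond(X) > condition_threshold:
        warn = "design matrix ill-conditioned: ancestry and inbreeding collinear"
        logger.warning(warn)
    fit = fit_gaussian_glm(yields[ok], X, names=("intercept", "q_focal", "F"))
    out = {
        "fit": fit,
        "slope_per_proportion": float(fit.params[1]),
        "slope_per_percent": float(fit.params[1]) / 100.0,
        "collinearity_warning": warn,
        "n": int(ok.sum()),
    }
    if q_alternative is not None:
        q_alt = np.asarray(q_alternative, dtype=float)
        Xa = np.column_stack([np.ones(ok.sum()), q_alt[ok], F[ok]])
        out["alternative_fit"] = fit_gaussian_glm(
            yields[ok], Xa, names=("intercept", "q_alt", "F")
        )
    return out
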