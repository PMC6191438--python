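"""Folded joint SFS construction and isolation-with-migration model fitting.

The observed 2D site frequency spectrum is compared with model expectations via
a Poisson composite likelihood in which the mutation-scaled parameter theta =
4*N_ref*mu*L is profiled out in closed form. Expected spectra are estimated by
Monte-Carlo branch tallying under the structured coalescent (common random
numbers across parameter evaluations keep the surface smooth for Nelder-Mead).
Bootstrap confidence intervals resample contiguous physical blocks of sites.

Model set:

* ``SI``   — split with no migration; free (nu1, nu2, T); k = 3
* ``IM``   — split + asymmetric migration, population 1 stays at the ancestral
  size (nu1 = 1); free (nu2, T, m12, m21); k = 4
* ``IM_B`` — IM plus an instantaneous founder bottleneck on population 1 at the
  split (free nu_B); free (nu_B, nu2, T, m12, m21); k = 5
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import hypergeom

from ._coalescent import tally_branch_lengths
from .core_io import GenotypeMatrix, ParameterError

logger = logging.getLogger("cacao_popgen")

__all__ = [
    "JointSFS",
    "DemographicParams",
    "ScalingConfig",
    "FitResult",
    "BootstrapCI",
    "folded_joint_sfs",
    "fold_matrix",
    "expected_sfs_im",
    "composite_loglik",
    "fit_im_model",
    "bootstrap_ci",
    "scale_to_physical_units",
    "model_selection_aic",
]

MODEL_FREE_PARAMS = {
    "SI": ("nu_B", "nu_2", "T"),
    "IM": ("nu_2", "T", "m12", "m21"),
    "IM_B": ("nu_B", "nu_2", "T", "m12", "m21"),
}

#: optimization bounds in natural parameter space
BOUNDS = {"nu": (1e-4, 100.0), "T": (1e-4, 10.0), "m": (1e-6, 20.0)}


def _bound_of(name: str) -> tuple[float, float]:
    if name.startswith("nu"):
        return BOUNDS["nu"]
    if name == "T":
        return BOUNDS["T"]
    return BOUNDS["m"]


@dataclass
class JointSFS:
    """Folded 2D SFS: counts over (i alt copies of n1, j of n2), minor-allele
    orientation, with the monomorphic corner and fold-redundant cells masked."""

    data: np.ndarray  # (n1+1, n2+1)
    mask: np.ndarray  # True = excluded from likelihood sums
    n1: int
    n2: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != (self.n1 + 1, self.n2 + 1):
            raise ParameterError("SFS shape does not match (n1+1, n2+1)")
        if self.data.shape != self.mask.shape:
            raise ParameterError("mask shape mismatch")
        if (self.data[~self.mask] < 0).any():
            raise ParameterError("SFS entries must be nonnegative")

    @property
    def S_total(self) -> float:
        return float(self.data[~self.mask].sum())


@dataclass(frozen=True)
class DemographicParams:
    """IM-family parameters in coalescent units (theta profiled separately)."""

    model_id: str
    nu_B: float = 1.0
    nu_2: float = 1.0
    T: float = 1.0
    m12: float = 0.0
    m21: float = 0.0
    theta_hat: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_FREE_PARAMS:
            raise ParameterError(f"unknown model {self.model_id!r}")

    @property
    def k_free(self) -> int:
        return len(MODEL_FREE_PARAMS[self.model_id])

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MODEL_FREE_PARAMS[self.model_id]])

    @classmethod
    def from_free(cls, model_id: str, values: np.ndarray,
                  theta_hat: float | None = None) -> "DemographicParams":
        kw = dict(zip(MODEL_FREE_PARAMS[model_id], (float(v) for v in values)))
        if model_id == "SI":
            kw.update(m12=0.0, m21=0.0)
        if model_id == "IM":
            kw.update(nu_B=1.0)
        return cls(model_id=model_id, theta_hat=theta_hat, **kw)

    def sim_args(self) -> tuple[float, float, float, float, float]:
        """(nu1, nu2, T, m12, m21) for the coalescent engine."""
        return (self.nu_B, self.nu_2, self.T, self.m12, self.m21)


@dataclass(frozen=True)
class ScalingConfig:
    """Constants mapping coalescent units to physical units."""

    mu: float = 7.1e-9  # per-bp per-generation mutation rate
    g: float = 5.0  # generation time in years
    L: float = 1e7  # callable sequence length (bp)

    def __post_init__(self) -> None:
        if min(self.mu, self.g, self.L) <= 0:
            raise ParameterError("mu, g, L must all be positive")


@dataclass
class FitResult:
    params: DemographicParams
    loglik: float
    aic: float
    expected_sfs: np.ndarray  # theta_hat-scaled model matrix
    anscombe: np.ndarray
    obs: JointSFS
    n_evals: int = 0

    @property
    def mean_abs_anscombe(self) -> float:
        return float(np.abs(self.anscombe[~self.obs.mask]).mean())


@dataclass
class BootstrapCI:
    lower: dict[str, float]
    upper: dict[str, float]
    B: int
    estimates: np.ndarray  # (B, k_free)
    names: tuple[str, ...]


# ---------------------------------------------------------------------------
# observed SFS
# ---------------------------------------------------------------------------

def fold_matrix(unfolded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold an unfolded joint spectrum to minor-allele orientation.

    Cell (i, j) is canonical when 2*(i+j) < n1+n2, or at the fold line when
    (i, j) <= (n1-i, n2-j) lexicographically. Returns (folded, mask) where the
    mask covers the redundant half and the (0, 0) corner.
    """
    n1 = unfolded.shape[0] - 1
    n2 = unfolded.shape[1] - 1
    folded = np.zeros_like(unfolded, dtype=float)
    mask = np.ones_like(folded, dtype=bool)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            d = 2 * (i + j) - (n1 + n2)
            if d < 0 or (d == 0 and (i, j) <= (n1 - i, n2 - j)):
                folded[i, j] = unfolded[i, j] + (
                    unfolded[n1 - i, n2 - j] if (i, j) != (n1 - i, n2 - j) else 0.0
                )
                mask[i, j] = False
    mask[0, 0] = True  # monomorphic corner
    folded[mask] = 0.0
    return folded, mask


def folded_joint_sfs(
    G: GenotypeMatrix,
    pop1: str,
    pop2: str,
    project_to: tuple[int, int] | None = None,
) -> JointSFS:
    """Build the folded joint SFS for two populations.

    With ``project_to`` = (n1, n2) haploid sizes, sites with missing calls are
    hypergeometrically projected down to the target sizes; sites with fewer
    observed haploids than the target are skipped.
    """
    i1 = G.sample_indices(pop1)
    i2 = G.sample_indices(pop2)
    a1, h1 = G.allele_counts(i1)
    a2, h2 = G.allele_counts(i2)
    if project_to is None:
        n1 = int(h1.max(initial=0))
        n2 = int(h2.max(initial=0))
        if ((h1 != n1) & (h1 > 0)).any() or ((h2 != n2) & (h2 > 0)).any():
            raise ParameterError(
                "missing calls present: supply project_to=(n1, n2) for projection"
            )
    else:
        n1, n2 = project_to
        if n1 > int(h1.max(initial=0)) or n2 > int(h2.max(initial=0)):
            raise ParameterError("projection target exceeds observed haploid counts")
    unfolded = np.zeros((n1 + 1, n2 + 1))
    exact = (h1 == n1) & (h2 == n2)
    np.add.at(unfolded, (a1[exact], a2[exact]), 1.0)
    for s in np.flatnonzero(~exact):
        if h1[s] < n1 or h2[s] < n2:
            continue
        w1 = hypergeom.pmf(np.arange(n1 + 1), h1[s], a1[s], n1)
        w2 = hypergeom.pmf(np.arange(n2 + 1), h2[s], a2[s], n2)
        unfolded += np.outer(w1, w2)
    folded, mask = fold_matrix(unfolded)
    return JointSFS(data=folded, mask=mask, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# model expectation & likelihood
# ---------------------------------------------------------------------------

def expected_sfs_im(
    params: DemographicParams,
    n1: int,
    n2: int,
    mc_reps: int = 20000,
    seed: int = 0,
) -> np.ndarray:
    """Unscaled folded model SFS by Monte-Carlo branch-length tallying.

    Entry (i, j) is half the mean genealogical branch length subtending exactly
    i sampled lineages in population 1 and j in population 2 (time in 2*N_ref
    generations), folded to minor orientation. Multiplying by theta = 4*N_ref*
    mu*L gives expected site counts, so the profiled theta_hat of
    :func:`composite_loglik` is directly on the 4*N_ref*mu*L scale. Reusing the
    same ``seed`` across calls implements common random numbers.
    """
    if mc_reps < 1000:
        logger.warning("mc_reps=%d is small; expected SFS will be noisy", mc_reps)
    nu1, nu2, T, m12, m21 = params.sim_args()
    L = tally_branch_lengths(n1, n2, nu1, nu2, T, m12, m21, mc_reps, seed)
    folded, _ = fold_matrix(L)
    return folded / 2.0


def composite_loglik(
    obs: JointSFS, model_unscaled: np.ndarray, eps: float = 1e-12
) -> tuple[float, float, np.ndarray]:
    """Poisson composite log-likelihood with theta profiled in closed form.

    theta_hat = sum(obs)/sum(model) over unmasked cells; returns (loglik,
    theta_hat, anscombe residual matrix). Model cells that are zero where the
    observation is positive are floored at ``eps`` with a warning.
    """
    model = np.asarray(model_unscaled, dtype=float)
    if model.shape != obs.data.shape:
        raise ParameterError("model and observed SFS shapes differ")
    if (model[~obs.mask] < 0).any():
        raise ParameterError("model entries must be nonnegative")
    live = ~obs.mask
    o = obs.data[live]
    m = model[live].copy()
    bad = (m <= 0) & (o > 0)
    if bad.any():
        logger.debug("flooring %d zero model cells with positive counts", bad.sum())
    m = np.maximum(m, eps)
    theta_hat = float(o.sum() / m.sum())
    mu = theta_hat * m
    loglik = float(np.sum(o * np.log(mu) - mu - gammaln(o + 1.0)))
    anscombe = np.zeros_like(obs.data)
    anscombe[live] = 1.5 * (o ** (2.0 / 3.0) - mu ** (2.0 / 3.0)) / mu ** (1.0 / 6.0)
    return loglik, theta_hat, anscombe


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _neg_loglik_factory(obs: JointSFS, model_id: str, mc_reps: int, seed: int):
    names = MODEL_FREE_PARAMS[model_id]
    lo = np.log([_bound_of(n)[0] for n in names])
    hi = np.log([_bound_of(n)[1] for n in names])
    state = {"evals": 0}
    # floor empty Monte-Carlo cells at the tallier's resolution so that rare
    # cells penalize the likelihood smoothly instead of catastrophically
    eps = 0.05 / mc_reps

    def neg_loglik(x: np.ndarray) -> float:
        state["evals"] += 1
        if (x < lo).any() or (x > hi).any():
            return 1e12 + float(np.sum((np.maximum(x - hi, 0) + np.maximum(lo - x, 0)) ** 2))
        p = DemographicParams.from_free(model_id, np.exp(x))
        model = expected_sfs_im(p, obs.n1, obs.n2, mc_reps=mc_reps, seed=seed)
        ll, _, _ = composite_loglik(obs, model, eps=eps)
        return -ll

    return neg_loglik, names, lo, hi, state


#: neutral-ish default optimizer start in natural units
DEFAULT_START = {"nu_B": 1.0, "nu_2": 1.0, "T": 0.5, "m12": 1.0, "m21": 1.0}


def _simplex_around(x0: np.ndarray, spread: float) -> np.ndarray:
    """Initial simplex: x0 plus one vertex displaced by +spread per coordinate."""
    n = x0.size
    simp = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simp[i + 1, i] += spread
    return simp


def _profile_T_continuation(
    obs: JointSFS,
    model_id: str,
    mc_reps: int,
    mc_seed: int,
    t_grid: np.ndarray,
    state: dict,
) -> np.ndarray:
    """Warm-started profile search over the split time T.

    For each T on a descending log grid, the remaining free parameters are
    optimized by Nelder-Mead starting from the previous grid point's solution
    (continuation). Returns the best full free-parameter vector in log space.
    The profile tames the strong T-versus-migration ridge of the folded joint
    SFS that traps a direct joint search.
    """
    neg5, names, lo, hi, st = _neg_loglik_factory(obs, model_id, mc_reps, mc_seed)
    t_pos = names.index("T")
    rest = [i for i in range(len(names)) if i != t_pos]
    x_rest = np.array([np.log(DEFAULT_START[names[i]]) for i in rest])
    candidates: list[tuple[float, np.ndarray]] = []
    for Tfix in t_grid:
        logT = np.log(Tfix)

        def conditional(xr: np.ndarray) -> float:
            x = np.empty(len(names))
            x[t_pos] = logT
            x[rest] = xr
            return neg5(x)

        res = None
        for spread in (0.5, 0.25):
            res = minimize(
                conditional, x_rest, method="Nelder-Mead",
                options={"maxiter": 200, "fatol": 5.0, "xatol": 1e-3,
                         "initial_simplex": _simplex_around(x_rest, spread)},
            )
            x_rest = res.x
        x_full = np.empty(len(names))
        x_full[t_pos] = logT
        x_full[rest] = x_rest
        candidates.append((float(res.fun), x_full))
    state["evals"] += st["evals"]
    candidates.sort(key=lambda c: c[0])
    return [x for _, x in candidates]


def fit_im_model(
    obs: JointSFS,
    model_id: str = "IM_B",
    starts: int = 1,
    seed: int = 0,
    mc_reps: int = 2000,
    refine_reps: int = 32000,
    maxiter: int = 400,
    refine_maxiter: int = 200,
    coarse_spread: float = 1.0,
    refine_spread: float = 0.2,
    t_grid: np.ndarray | None = None,
    extra_starts: list[DemographicParams] | None = None,
) -> FitResult:
    """Maximize the Poisson composite likelihood over the free IM parameters.

    The Monte-Carlo expected SFS makes the surface deterministic (common random
    numbers: one seed across evaluations) but locally rugged, and the folded
    joint SFS carries a strong ridge coupling split time and migration. The
    default search therefore proceeds in three phases at increasing Monte-Carlo
    resolution: (1) a warm-started profile over T on a log grid at ``mc_reps``
    genealogies per evaluation, plus coarse wide-simplex Nelder-Mead from a
    neutral default start and ``starts`` log-uniform random restarts; (2) a
    joint Nelder-Mead from the phase-1 best; (3) a refinement ladder that
    quadruples the resolution per rung up to ``refine_reps`` with a tight
    simplex. When ``extra_starts`` are supplied (e.g. warm bootstrap restarts)
    the profile phase is skipped. Optimization is in log-parameter space with
    bounds nu in [1e-4, 100], T in [1e-4, 10], m in [1e-6, 20].
    """
    if mc_reps < 1000:
        logger.warning("mc_reps=%d is small for fitting", mc_reps)
    rng = np.random.default_rng(seed)
    mc_seed = int(rng.integers(2**31))
    neg_coarse, names, lo, hi, state = _neg_loglik_factory(obs, model_id, mc_reps, mc_seed)
    profile_candidates: list[np.ndarray] = []
    x0s = []
    if extra_starts is None:
        if t_grid is None:
            t_grid = np.exp(np.linspace(np.log(5.0), np.log(0.02), 12))
        profile_candidates = _profile_T_continuation(
            obs, model_id, mc_reps, mc_seed, t_grid, state)[:3]
        x0s.append(np.log([DEFAULT_START[n] for n in names]))
    x0s += [rng.uniform(lo, hi) for _ in range(starts)]
    for p in extra_starts or []:
        x0s.append(np.log(np.clip(p.free_values(),
                                  np.exp(lo), np.exp(hi))))
    finalists: list[np.ndarray] = list(profile_candidates)
    for x0 in x0s:
        res = minimize(
            neg_coarse, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": 5.0, "xatol": 1e-3,
                     "initial_simplex": _simplex_around(np.asarray(x0), coarse_spread)},
        )
        if np.isfinite(res.fun):
            finalists.append(res.x)
    if not finalists:
        raise ParameterError(
            f"no start converged for model {model_id} "
            f"(starts={len(x0s)}, evals={state['evals']})"
        )
    # mid-resolution tournament among finalists, then a refinement ladder that
    # quadruples the Monte-Carlo resolution per rung so the simplex stops
    # chasing tally noise and starts following the model signal
    mid_reps = min(4 * mc_reps, refine_reps)
    neg_mid, _, _, _, state_m = _neg_loglik_factory(obs, model_id, mid_reps, mc_seed)
    best_val, x_best = np.inf, finalists[0]
    for x in finalists:
        res = minimize(
            neg_mid, x, method="Nelder-Mead",
            options={"maxiter": refine_maxiter, "fatol": 2.0, "xatol": 1e-3,
                     "initial_simplex": _simplex_around(x, refine_spread)},
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, x_best = res.fun, res.x
    state["evals"] += state_m["evals"]
    rung_reps = mid_reps
    while rung_reps < refine_reps:
        rung_reps = min(4 * rung_reps, refine_reps)
        neg_fine, _, _, _, state_f = _neg_loglik_factory(obs, model_id, rung_reps, mc_seed)
        res = minimize(
            neg_fine, x_best, method="Nelder-Mead",
            options={"maxiter": refine_maxiter, "fatol": 2.0, "xatol": 1e-3,
                     "initial_simplex": _simplex_around(x_best, refine_spread)},
        )
        state["evals"] += state_f["evals"]
        if np.isfinite(res.fun):
            x_best = res.x
    best_x = x_best
    mc_reps = refine_reps  # final evaluation at refinement resolution
    params = DemographicParams.from_free(model_id, np.exp(best_x))
    model = expected_sfs_im(params, obs.n1, obs.n2, mc_reps=mc_reps, seed=mc_seed)
    loglik, theta_hat, anscombe = composite_loglik(obs, model, eps=0.05 / mc_reps)
    params = DemographicParams.from_free(model_id, np.exp(best_x), theta_hat=theta_hat)
    k = params.k_free + 1  # + profiled theta
    return FitResult(
        params=params,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        expected_sfs=theta_hat * model,
        anscombe=anscombe,
        obs=obs,
        n_evals=state["evals"],
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _block_of_sites(G: GenotypeMatrix, block_bp: int) -> np.ndarray:
    """Assign each site to a contiguous physical block index."""
    chroms = G.chroms
    pos0 = G.positions - 1
    block = np.empty(G.n_sites, dtype=np.int64)
    next_id = 0
    for chrom in dict.fromkeys(chroms):
        on = chroms == chrom
        ids = pos0[on] // block_bp
        _, dense = np.unique(ids, return_inverse=True)
        block[on] = dense + next_id
        next_id = int(block[on].max()) + 1 if on.any() else next_id
    return block


def bootstrap_ci(
    G: GenotypeMatrix,
    pop1: str,
    pop2: str,
    model_id: str = "IM_B",
    B: int = 1000,
    block_bp: int = 1_000_000,
    project_to: tuple[int, int] | None = None,
    point_fit: FitResult | None = None,
    seed: int = 0,
    mc_reps: int = 1000,
    maxiter: int = 100,
) -> BootstrapCI:
    """Percentile block-bootstrap CIs for the free demographic parameters.

    Sites are partitioned into contiguous physical blocks (default 1 Mb) that
    are resampled with replacement; each replicate rebuilds the folded SFS and
    refits starting from the point estimate. The default B matches a
    1000-replicate bootstrap; reduce it for desk-scale runs.
    """
    block = _block_of_sites(G, block_bp)
    uniq = np.unique(block)
    if uniq.size < 20:
        raise ParameterError(f"only {uniq.size} blocks; need >= 20 for a CI")
    if point_fit is None:
        obs = folded_joint_sfs(G, pop1, pop2, project_to=project_to)
        point_fit = fit_im_model(obs, model_id, seed=seed, mc_reps=mc_reps)
    names = MODEL_FREE_PARAMS[model_id]
    n1, n2 = point_fit.obs.n1, point_fit.obs.n2

    # per-block unfolded tallies so replicates are cheap to assemble
    i1 = G.sample_indices(pop1)
    i2 = G.sample_indices(pop2)
    a1, h1 = G.allele_counts(i1)
    a2, h2 = G.allele_counts(i2)
    per_block = np.zeros((uniq.size, n1 + 1, n2 + 1))
    exact = (h1 == n1) & (h2 == n2)
    for s in range(G.n_sites):
        b = int(np.searchsorted(uniq, block[s]))
        if exact[s]:
            per_block[b, a1[s], a2[s]] += 1.0
        elif h1[s] >= n1 and h2[s] >= n2:
            w1 = hypergeom.pmf(np.arange(n1 + 1), h1[s], a1[s], n1)
            w2 = hypergeom.pmf(np.arange(n2 + 1), h2[s], a2[s], n2)
            per_block[b] += np.outer(w1, w2)

    rng = np.random.default_rng(seed)
    estimates = np.empty((B, len(names)))
    start = point_fit.params
    # ridge-aware warm starts: the split time trades off against migration on
    # a flat likelihood ridge, so each refit may start from the point estimate
    # and from the same estimate with T nudged down/up the ridge
    starts_b = [start]
    if "T" in names:
        from dataclasses import replace as _replace
        starts_b += [_replace(start, T=start.T * f) for f in (0.6, 1.67)]
    lo = np.log([_bound_of(n)[0] for n in names])
    hi = np.log([_bound_of(n)[1] for n in names])
    x0s = [np.log(np.clip(p.free_values(), np.exp(lo), np.exp(hi)))
           for p in starts_b]
    for r in range(B):
        pick = rng.integers(uniq.size, size=uniq.size)
        unfolded = per_block[pick].sum(axis=0)
        folded, mask = fold_matrix(unfolded)
        obs_b = JointSFS(data=folded, mask=mask, n1=n1, n2=n2)
        # lightweight warm refit: one Nelder-Mead per start, best kept
        neg, _, _, _, _ = _neg_loglik_factory(
            obs_b, model_id, mc_reps, int(rng.integers(2**31)))
        best = None
        for x0 in x0s:
            res = minimize(
                neg, x0, method="Nelder-Mead",
                options={"maxiter": maxiter, "fatol": 2.0, "xatol": 1e-3,
                         "initial_simplex": _simplex_around(x0, 0.3)},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        estimates[r] = np.exp(best.x)
    lower = {n: float(np.percentile(estimates[:, i], 2.5)) for i, n in enumerate(names)}
    upper = {n: float(np.percentile(estimates[:, i], 97.5)) for i, n in enumerate(names)}
    return BootstrapCI(lower=lower, upper=upper, B=B,
                       estimates=estimates, names=names)


# ---------------------------------------------------------------------------
# scaling & model selection
# ---------------------------------------------------------------------------

def scale_to_physical_units(fit: FitResult, scaling: ScalingConfig) -> dict:
    """Convert a fit to physical units via N_ref = theta_hat / (4*mu*L).

    Returns N_ref, per-population diploid sizes, split time in years
    (T_years = 2*N_ref*T*g) and per-generation migration fractions.
    """
    p = fit.params
    if p.theta_hat is None or p.theta_hat <= 0:
        raise ParameterError("fit carries no positive theta_hat")
    N_ref = p.theta_hat / (4.0 * scaling.mu * scaling.L)
    out = {
        "model_id": p.model_id,
        "N_ref": N_ref,
        "N_pop1": p.nu_B * N_ref,
        "N_pop2": p.nu_2 * N_ref,
        "T_years": 2.0 * N_ref * p.T * scaling.g,
        "T_generations": 2.0 * N_ref * p.T,
        "m12_per_gen": p.m12 / (2.0 * N_ref),
        "m21_per_gen": p.m21 / (2.0 * N_ref),
        "mu": scaling.mu,
        "generation_years": scaling.g,
        "L": scaling.L,
    }
    return out


def model_selection_aic(fits: list[FitResult]) -> "pd.DataFrame":
    """Rank fits of the same observed SFS by AIC; report residual magnitudes."""
    import pandas as pd

    if not fits:
        raise ParameterError("no fits supplied")
    ref = fits[0].obs
    for f in fits[1:]:
        if f.obs.data.shape != ref.data.shape or not np.allclose(f.obs.data, ref.data):
            raise ParameterError("fits compare different observed spectra")
    rows = [
        {
            "model_id": f.params.model_id,
            "k": f.params.k_free + 1,
            "loglik": f.loglik,
            "aic": f.aic,
            "mean_abs_anscombe": f.mean_abs_anscombe,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["best"] = df["delta_aic"] == 0.0
    return df
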