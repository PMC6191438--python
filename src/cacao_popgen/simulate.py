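"""Synthetic-data generators with known truth.

Four generators cover the inputs the analysis modules consume:

* a structured-coalescent simulator for two-population split histories
  (isolation with migration, optional founder bottleneck) emitting diploid
  genotypes under infinite sites;
* a forward per-site Wright-Fisher engine with selection, dominance and
  partial selfing, tracking genotype frequencies so that selfing dynamics
  (e.g. heterozygosity halving under full selfing) are exact;
* a Balding-Nichols reference-panel / admixed-cohort generator with yield
  phenotypes linear in focal ancestry and inbreeding;
* a sweep-model allele-frequency sampler matching the mixture density used by
  the sweep scan.

All generators are deterministic given a seed; independent substreams are
split per locus/replicate via ``numpy.random.SeedSequence.spawn``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._coalescent import simulate_locus_branches
from .core_io import MISSING, GenotypeMatrix, ParameterError, VariantSite

__all__ = [
    "IMModel",
    "WFSimConfig",
    "AdmixturePanelConfig",
    "PhenotypeConfig",
    "simulate_im_genotypes",
    "simulate_wf_site_frequencies",
    "simulate_admixed_cohort",
    "sample_sweep_frequencies",
]


@dataclass(frozen=True)
class IMModel:
    """Two-population isolation-with-migration history.

    Population 1 (the domesticate side) is founded at the split with relative
    size ``nu_B``; population 2 keeps relative size ``nu_2``. Times are in units
    of 2*N_ref generations and migration rates are scaled as 2*N_ref*m in the
    receiving-population convention.
    """

    n1: int = 16
    n2: int = 16
    nu_B: float = 0.05
    nu_2: float = 1.0
    T: float = 0.36
    m12: float = 0.0
    m21: float = 0.0
    N_ref: float = 10000.0
    L: float = 1e7
    mu: float = 7.1e-9
    loci: int = 500

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ParameterError("need at least 2 haploid samples per population")
        if min(self.nu_B, self.nu_2, self.N_ref, self.L, self.mu) <= 0:
            raise ParameterError("sizes, length and mutation rate must be positive")
        if self.T < 0 or self.m12 < 0 or self.m21 < 0:
            raise ParameterError("T and migration rates must be nonnegative")
        if self.loci < 1:
            raise ParameterError("need at least one locus")

    @property
    def theta_per_locus(self) -> float:
        """4*N_ref*mu*(L/loci): Watterson theta of one locus."""
        return 4.0 * self.N_ref * self.mu * (self.L / self.loci)


@dataclass(frozen=True)
class WFSimConfig:
    """Forward Wright-Fisher per-site engine configuration.

    ``s`` is the selection coefficient against the (deleterious) alt allele with
    dominance ``h`` (genotype fitnesses 1, 1-h*s, 1-s); ``sigma`` is the selfing
    rate.
    """

    N: int = 500
    s: float = 0.0
    h: float = 0.5
    sigma: float = 0.0
    generations: int = 100
    p0: float = 0.05
    replicates: int = 1000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError("N must be >= 2")
        if not (0.0 <= self.p0 <= 1.0):
            raise ParameterError("p0 must be in [0,1]")
        if not (0.0 <= self.sigma <= 1.0):
            raise ParameterError("sigma must be in [0,1]")
        if self.generations < 1 or self.replicates < 1:
            raise ParameterError("generations and replicates must be positive")


@dataclass(frozen=True)
class AdmixturePanelConfig:
    """Balding-Nichols structured panel with admixed individuals."""

    K: int
    fst_k: tuple[float, ...]
    M: int
    q_true: np.ndarray  # (n_ind, K) rows on the simplex
    n_ind: int

    def __post_init__(self) -> None:
        q = np.asarray(self.q_true, dtype=float)
        if q.shape != (self.n_ind, self.K):
            raise ParameterError("q_true must be (n_ind, K)")
        if len(self.fst_k) != self.K:
            raise ParameterError("fst_k length must equal K")
        if any(not (0.0 <= f < 1.0) for f in self.fst_k):
            raise ParameterError("each fst_k must be in [0,1)")
        if (q < 0).any() or not np.allclose(q.sum(axis=1), 1.0):
            raise ParameterError("each q_true row must lie on the K-simplex")
        object.__setattr__(self, "q_true", q)


@dataclass(frozen=True)
class PhenotypeConfig:
    """Yield model: y = beta0 + beta1*q_focal + beta2*F + Normal(0, sigma_e)."""

    beta0: float = 2000.0
    beta1: float = -319.9
    beta2: float = -500.0
    sigma_e: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma_e < 0:
            raise ParameterError("sigma_e must be >= 0")


def simulate_im_genotypes(
    model: IMModel, seed: int
) -> tuple[GenotypeMatrix, dict]:
    """Simulate diploid genotypes under the two-deme IM history.

    Loci are independent and non-recombining; infinite-sites mutations fall on
    branches as Poisson(theta/2 per unit branch length). Haploid genomes are
    paired at random within each deme to form diploids (Hardy-Weinberg within
    deme). Returns the genotype matrix (populations "pop1"/"pop2") and a truth
    sidecar with the model and per-site deme of origin of the mutation carrier
    population at sampling time.
    """
    if model.n1 % 2 or model.n2 % 2:
        raise ParameterError("haploid sample sizes must be even to form diploids")
    ss = np.random.SeedSequence(seed)
    locus_seeds = ss.spawn(model.loci)
    theta = model.theta_per_locus
    locus_len = int(model.L / model.loci)
    n1, n2 = model.n1, model.n2
    n_hap = n1 + n2

    site_list: list[VariantSite] = []
    hap_cols: list[np.ndarray] = []
    site_locus: list[int] = []
    for locus in range(model.loci):
        rng = np.random.default_rng(locus_seeds[locus])
        branches = simulate_locus_branches(
            rng, n1, n2, model.nu_B, model.nu_2, model.T, model.m12, model.m21
        )
        muts: list[int] = []  # masks carrying a mutation
        for bmask, blen in branches:
            k = rng.poisson(blen * theta / 2.0)
            muts.extend([bmask] * k)
        if not muts:
            continue
        n_mut = len(muts)
        if n_mut > locus_len:
            raise ParameterError("locus too short for infinite-sites mutation count")
        offsets = np.sort(rng.choice(locus_len, size=n_mut, replace=False))
        order = rng.permutation(n_mut)
        for off, mi in zip(offsets, order):
            bmask = muts[mi]
            col = np.fromiter(
                ((bmask >> k) & 1 for k in range(n_hap)), dtype=np.int8, count=n_hap
            )
            pos = locus * locus_len + int(off) + 1
            site_list.append(VariantSite("chr1", pos))
            hap_cols.append(col)
            site_locus.append(locus)

    if hap_cols:
        H = np.stack(hap_cols, axis=1)  # (n_hap, n_sites)
    else:
        H = np.zeros((n_hap, 0), dtype=np.int8)
    calls = H[0::2] + H[1::2]  # consecutive haplotypes pair into diploids
    n_d1 = n1 // 2
    samples = [f"pop1_{i}" for i in range(n_d1)] + [
        f"pop2_{i}" for i in range(n2 // 2)
    ]
    pop_of = {s: ("pop1" if s.startswith("pop1") else "pop2") for s in samples}
    G = GenotypeMatrix(samples=samples, sites=site_list, calls=calls, pop_of=pop_of)
    truth = {
        "model": model,
        "site_locus": np.array(site_locus, dtype=np.int64),
        "theta_per_locus": theta,
    }
    return G, truth


def _selfing_offspring(geno: np.ndarray, sigma: float, p: np.ndarray) -> np.ndarray:
    """One round of reproduction: mixture of selfing and random mating.

    ``geno`` has shape (reps, 3) with frequencies of (aa, Aa, AA) where A is the
    alt allele; ``p`` is the alt-allele frequency per replicate.
    """
    f0, f1, f2 = geno[:, 0], geno[:, 1], geno[:, 2]
    self0 = f0 + 0.25 * f1
    self1 = 0.5 * f1
    self2 = f2 + 0.25 * f1
    q = 1.0 - p
    out = np.empty_like(geno)
    out[:, 0] = sigma * self0 + (1 - sigma) * q * q
    out[:, 1] = sigma * self1 + (1 - sigma) * 2 * p * q
    out[:, 2] = sigma * self2 + (1 - sigma) * p * p
    return out


def simulate_wf_site_frequencies(cfg: WFSimConfig, seed: int) -> dict:
    """Forward-simulate independent sites under selection, selfing and drift.

    Per generation: reproduction mixes selfing (rate sigma) with random mating,
    then viability selection with fitnesses (1, 1-h*s, 1-s) against the alt
    allele, then multinomial sampling of N diploid individuals. Returns allele
    frequency trajectories (replicates x generations+1), final genotype
    frequencies, and final observed heterozygosity per replicate.
    """
    rng = np.random.default_rng(seed)
    R = cfg.replicates
    p = np.full(R, cfg.p0)
    # start at Hardy-Weinberg; partial selfing then drives heterozygosity toward
    # the inbreeding equilibrium F_is = sigma/(2-sigma) over the first generations
    geno = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
    w = np.array([1.0, 1.0 - cfg.h * cfg.s, 1.0 - cfg.s])
    traj = np.empty((R, cfg.generations + 1))
    het = np.empty((R, cfg.generations + 1))
    traj[:, 0] = p
    het[:, 0] = geno[:, 1]
    for t in range(1, cfg.generations + 1):
        geno = _selfing_offspring(geno, cfg.sigma, p)
        gw = geno * w  # viability selection
        tot = gw.sum(axis=1, keepdims=True)
        gsel = np.divide(gw, tot, out=np.zeros_like(gw), where=tot > 0)
        counts = rng.multinomial(cfg.N, gsel)
        geno = counts / cfg.N
        p = geno[:, 2] + 0.5 * geno[:, 1]
        traj[:, t] = p
        het[:, t] = geno[:, 1]
    return {
        "freq": traj,
        "het": het,
        "final_geno": geno,
        "config": cfg,
    }


def simulate_admixed_cohort(
    cfg: AdmixturePanelConfig, pheno: PhenotypeConfig, seed: int
) -> dict:
    """Balding-Nichols panel + admixed cohort + yield phenotypes.

    Ancestral frequencies are Uniform(0.05, 0.95); population k frequencies are
    Beta-distributed around the ancestral draw with variance fst_k*p*(1-p).
    Each individual carries a true inbreeding coefficient F_i ~ Uniform(0, 0.3)
    (cacao germplasm mixes outbred hybrids with partially selfed accessions):
    at each site the two allele copies are identical by descent with
    probability F_i (one Bernoulli draw copied) and independent otherwise, so
    genotypes reduce to Binomial(2, sum_k q_k f_kj) in the F_i = 0 limit.
    Yield is linear in focal (first-population) ancestry and in F_i.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=cfg.M)
    panel = np.empty((cfg.K, cfg.M))
    for k in range(cfg.K):
        f = cfg.fst_k[k]
        if f == 0.0:
            panel[k] = p_anc
        else:
            shape = (1.0 - f) / f
            panel[k] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    mix = cfg.q_true @ panel  # (n_ind, M) expected dosage/2
    F_true = rng.uniform(0.0, 0.3, size=cfg.n_ind)
    a = rng.random(mix.shape) < mix  # first allele copy
    b_indep = rng.random(mix.shape) < mix
    ibd = rng.random(mix.shape) < F_true[:, None]
    b = np.where(ibd, a, b_indep)  # second copy IBD with prob F_i
    geno = a.astype(np.int8) + b.astype(np.int8)
    q_focal = cfg.q_true[:, 0]
    yields = (
        pheno.beta0
        + pheno.beta1 * q_focal
        + pheno.beta2 * F_true
        + rng.normal(0.0, pheno.sigma_e, size=cfg.n_ind)
    )
    samples = [f"ind_{i}" for i in range(cfg.n_ind)]
    sites = [VariantSite("chr1", j + 1) for j in range(cfg.M)]
    G = GenotypeMatrix(samples=samples, sites=sites, calls=geno, pop_of={})
    return {
        "panel": panel,
        "genotypes": G,
        "yield": yields,
        "q_true": cfg.q_true,
        "F_true": F_true,
        "p_anc": p_anc,
    }


def sample_sweep_frequencies(
    p_A: np.ndarray,
    omega: float,
    c: float,
    n_B: int,
    seed: int,
) -> np.ndarray:
    """Draw test-population alt-allele counts under the sweep mixture model.

    With probability ``c`` (the escape probability) a site behaves neutrally:
    x ~ Normal(p_A, omega*p_A*(1-p_A)) with tail mass below 0 / above 1 assigned
    to loss / fixation, then count ~ Binomial(n_B, x). With probability 1-c the
    site was dragged by the sweep: the count is n_B with probability p_A and 0
    otherwise.
    """
    p_A = np.asarray(p_A, dtype=float)
    if ((p_A <= 0) | (p_A >= 1)).any():
        raise ParameterError("reference frequencies must lie strictly in (0,1)")
    if omega < 0:
        raise ParameterError("omega must be >= 0")
    if not (0.0 <= c <= 1.0):
        raise ParameterError("escape probability c must be in [0,1]")
    rng = np.random.default_rng(seed)
    m = p_A.size
    escaped = rng.random(m) < c
    counts = np.empty(m, dtype=np.int64)
    # neutral (escaped) sites: truncated-normal drift then binomial sampling
    sd = np.sqrt(omega * p_A * (1.0 - p_A))
    x = rng.normal(p_A, sd)
    x = np.clip(x, 0.0, 1.0)  # tail mass collapses onto loss/fixation
    counts_esc = rng.binomial(n_B, x)
    # swept sites: fixed (count n_B) with prob p_A, lost otherwise
    fixed = rng.random(m) < p_A
    counts_swept = np.where(fixed, n_B, 0)
    counts = np.where(escaped, counts_esc, counts_swept)
    return counts
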