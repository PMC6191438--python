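"""Cross-population composite-likelihood sweep scan (XP-CLR style).

A test population's allele frequencies are modelled conditional on a reference
population's. Under neutrality, the test frequency x at a site with reference
frequency p drifts as Normal(p, omega*p*(1-p)) truncated to (0,1) with tail
mass collapsing onto loss/fixation, and the observed alt count is
Binomial(n_B, x). Near a sweep, a site escapes the sweeping haplotype with
probability c = 1 - exp(-d / s) (d = distance to the grid point in Morgans,
s = composite selection scale); non-escaping sites are dragged to fixation
(count n_B with probability p) or loss. The scan statistic per grid point is
CLR = 2 * (max_s loglik - neutral loglik); the neutral model is the in-grid
boundary s -> 0 (c -> 1), so CLR >= 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .core_io import GenotypeMatrix, ParameterError, WindowTrack
from .differentiation import top_fraction_outliers

__all__ = [
    "DriftOmega",
    "SweepWindow",
    "estimate_omega",
    "clr_window",
    "xpclr_scan",
    "default_s_grid",
]


@dataclass(frozen=True)
class DriftOmega:
    omega: float
    n_snps_used: int


@dataclass(frozen=True)
class SweepWindow:
    chrom: str
    grid_pos: int  # bp
    clr: float
    s_hat: float
    n_snps: int


def default_s_grid(n: int = 12) -> np.ndarray:
    """Log-spaced selection-scale grid on [1e-5, 1]; the smallest entry is the
    effective neutral limit (escape probability ~1 at any mapped distance)."""
    return np.logspace(-5, 0, n)


def estimate_omega(
    pA: np.ndarray, kB: np.ndarray, nB: np.ndarray | int
) -> DriftOmega:
    """Method-of-moments genome-wide drift scale for p_B | p_A.

    omega = mean over sites of [(kB/nB - pA)^2 - pA(1-pA)/nB] / [pA(1-pA)],
    floored at 0; the second numerator term removes binomial sampling variance.
    Only sites with 0 < pA < 1 are eligible.
    """
    pA = np.asarray(pA, dtype=float)
    kB = np.asarray(kB, dtype=float)
    nB = np.broadcast_to(np.asarray(nB, dtype=float), pA.shape)
    ok = (pA > 0.0) & (pA < 1.0) & (nB > 0)
    if not ok.any():
        raise ParameterError("no eligible sites with 0 < pA < 1")
    p = pA[ok]
    f = kB[ok] / nB[ok]
    num = (f - p) ** 2 - p * (1.0 - p) / nB[ok]
    omega = float(np.mean(num / (p * (1.0 - p))))
    return DriftOmega(omega=max(omega, 0.0), n_snps_used=int(ok.sum()))


def _site_probs(
    pA: np.ndarray,
    kB: np.ndarray,
    nB: np.ndarray,
    omega: float,
    n_quad: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (neutral, swept) probabilities of the observed counts.

    Neutral: Binomial(nB, x) integrated over x ~ Normal(pA, omega*pA*(1-pA))
    by fixed midpoint quadrature on (0,1), with truncated-normal tail mass
    below 0 / above 1 reassigned to k=0 / k=nB. Swept: the site was dragged to
    fixation (k=nB with probability pA) or loss. These do not depend on the
    selection scale, so the CLR grid search reuses them.
    """
    x = (np.arange(n_quad) + 0.5) / n_quad  # midpoint grid
    var = omega * pA * (1.0 - pA)
    sd = np.sqrt(np.maximum(var, 1e-300))
    # phi: (sites, quad) density of the drift distribution on the open interval
    phi = norm.pdf(x[None, :], loc=pA[:, None], scale=sd[:, None]) / n_quad
    like_x = binom.pmf(kB[:, None], nB[:, None], x[None, :])
    p_neut = (phi * like_x).sum(axis=1)
    lo_mass = norm.cdf(0.0, loc=pA, scale=sd)
    hi_mass = norm.sf(1.0, loc=pA, scale=sd)
    p_neut = p_neut + lo_mass * (kB == 0) + hi_mass * (kB == nB)
    p_sweep = pA * (kB == nB) + (1.0 - pA) * (kB == 0)
    return p_neut, p_sweep


def clr_window(
    pA: np.ndarray,
    kB: np.ndarray,
    nB: np.ndarray | int,
    dist_cM: np.ndarray,
    omega: float,
    s_grid: np.ndarray | None = None,
    chrom: str = "chr1",
    grid_pos: int = 0,
    n_quad: int = 1000,
) -> SweepWindow | None:
    """Composite likelihood ratio at one grid point.

    ``dist_cM`` is each SNP's map distance to the grid point. The neutral
    log-likelihood is the c=1 case; CLR = 2*(max over the s grid - neutral) and
    is always >= 0 because the near-zero s entry reproduces neutrality.
    """
    pA = np.asarray(pA, dtype=float)
    kB = np.asarray(kB, dtype=float)
    if pA.size == 0:
        return None
    nB = np.broadcast_to(np.asarray(nB, dtype=float), pA.shape).astype(float)
    dist_cM = np.asarray(dist_cM, dtype=float)
    if s_grid is None:
        s_grid = default_s_grid()
    d_morgan = np.abs(dist_cM) / 100.0
    p_neut, p_sweep = _site_probs(pA, kB, nB, omega, n_quad)
    ll_neutral = float(np.log(np.maximum(p_neut, 1e-300)).sum())
    best_ll, best_s = ll_neutral, 0.0
    for s in s_grid:
        c = 1.0 - np.exp(-d_morgan / s)
        p = c * p_neut + (1.0 - c) * p_sweep
        ll = float(np.log(np.maximum(p, 1e-300)).sum())
        if ll > best_ll:
            best_ll, best_s = ll, float(s)
    clr = 2.0 * (best_ll - ll_neutral)
    return SweepWindow(chrom=chrom, grid_pos=int(grid_pos), clr=max(clr, 0.0),
                       s_hat=best_s, n_snps=int(pA.size))


def xpclr_scan(
    G: GenotypeMatrix,
    ref_pop: str,
    test_pop: str,
    window_cM: float = 0.05,
    snp_cap: int = 200,
    grid_bp: int = 2000,
    top_fraction: float = 0.01,
    s_grid: np.ndarray | None = None,
    n_quad: int = 1000,
) -> tuple[list[SweepWindow], WindowTrack, "pd.DataFrame"]:
    """Genome scan: grid points every ``grid_bp``, SNPs within +/- window_cM/2.

    Windows exceeding ``snp_cap`` SNPs are thinned deterministically (uniform by
    index). Sites must carry genetic-map positions (see core_io.interpolate_cm;
    sites without a map fall back to 1 cM/Mb). Returns the per-grid-point
    records, a WindowTrack of CLR values, and the flagged top-fraction windows.
    """
    ref_idx = G.sample_indices(ref_pop)
    test_idx = G.sample_indices(test_pop)
    pA_all = G.alt_freq(ref_idx)
    kB_all, nB_all = G.allele_counts(test_idx)
    cm = G.cm_positions
    chroms = G.chroms
    positions = G.positions
    eligible = (pA_all > 0.0) & (pA_all < 1.0) & (nB_all > 0)
    omega = estimate_omega(pA_all[eligible], kB_all[eligible], nB_all[eligible]).omega

    records: list[SweepWindow] = []
    half = window_cM / 2.0
    for chrom in dict.fromkeys(chroms):
        on = (chroms == chrom) & eligible
        if not on.any():
            continue
        pos_c = positions[on]
        cm_c = cm[on]
        pA_c, kB_c, nB_c = pA_all[on], kB_all[on], nB_all[on]
        lo, hi = int(pos_c.min()), int(pos_c.max())
        for gp in range(lo - lo % grid_bp, hi + grid_bp, grid_bp):
            gp_cm = float(np.interp(gp, pos_c, cm_c))
            sel = np.flatnonzero(np.abs(cm_c - gp_cm) <= half)
            if sel.size == 0:
                continue
            if sel.size > snp_cap:
                keep = np.linspace(0, sel.size - 1, snp_cap).round().astype(int)
                sel = sel[np.unique(keep)]
            win = clr_window(
                pA_c[sel], kB_c[sel], nB_c[sel],
                cm_c[sel] - gp_cm, omega, s_grid,
                chrom=str(chrom), grid_pos=gp, n_quad=n_quad,
            )
            if win is not None:
                records.append(win)
    track = WindowTrack(pd.DataFrame(
        [(w.chrom, w.grid_pos, w.grid_pos + grid_bp, "clr", w.clr) for w in records],
        columns=list(WindowTrack.COLUMNS)))
    # the CLR is a boundary statistic with a point mass at exactly 0 (the
    # neutral fit), so ranking is confined to strictly positive scores; the
    # flagged count stays capped at the top fraction of all evaluated windows
    positive = track.records[track.values > 0.0]
    if len(positive) == 0:
        flagged = positive
    else:
        k_cap = int(np.ceil(top_fraction * len(track)))
        if len(positive) <= k_cap:
            flagged = positive.reset_index(drop=True)
        else:
            sub = WindowTrack(positive.reset_index(drop=True))
            flagged = top_fraction_outliers(
                sub, k_cap / len(positive)).flagged
    return records, track, flagged
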