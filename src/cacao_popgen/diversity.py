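"""Windowed diversity estimators, LD pruning, MDS, inbreeding, and small models.

Diversity is summarized per population in fixed physical windows (default 1 kb)
tiling each chromosome from coordinate 0: per-bp pairwise diversity (pi) using
the unbiased per-site estimator n/(n-1)*2p(1-p), and Watterson's theta from the
segregating-site count with the window's median non-missing haploid sample size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .core_io import (
    MISSING,
    GenotypeMatrix,
    ParameterError,
    WindowTrack,
)

__all__ = [
    "DiversityWindow",
    "InbreedingRecord",
    "MDSResult",
    "GLMFit",
    "KWResult",
    "windowed_diversity",
    "individual_inbreeding",
    "ld_prune",
    "mds_coordinates",
    "fit_gaussian_glm",
    "kruskal_nemenyi",
    "harmonic_mean_ne",
]


@dataclass(frozen=True)
class DiversityWindow:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    S: int
    pi: float
    thetaW: float
    n_eff: float  # median non-missing haploid n over sites in the window


@dataclass(frozen=True)
class InbreedingRecord:
    sample: str
    o_het: int
    e_het: float
    F: float  # 1 - o_het/e_het; nan when e_het == 0


@dataclass(frozen=True)
class MDSResult:
    coordinates: np.ndarray  # samples x components
    eigenvalues: np.ndarray  # descending, squared singular values / n_sites


@dataclass(frozen=True)
class GLMFit:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r2: float
    residuals: np.ndarray
    names: tuple[str, ...] = ()


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    pvalue: float
    groups: tuple[str, ...]
    nemenyi: pd.DataFrame  # pairwise p-value matrix


def _harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1))) if n >= 1 else 0.0


def per_site_pi(alt: np.ndarray, n_hap: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity n/(n-1) * 2p(1-p); 0 where n < 2."""
    n = n_hap.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        pi = np.where(n >= 2, n / (n - 1) * 2.0 * p * (1.0 - p), 0.0)
    return pi


def windowed_diversity(
    G: GenotypeMatrix, pop: str, window_bp: int = 1000
) -> tuple[list[DiversityWindow], WindowTrack, WindowTrack]:
    """Per-window pi and Watterson's theta (both per bp) for one population.

    Windows tile each chromosome from position 0 in steps of ``window_bp``;
    windows with no genotyped site are omitted. Returns the window records plus
    pi and thetaW tracks.
    """
    idx = G.sample_indices(pop)
    if idx.size < 2:
        raise ParameterError(f"population {pop!r} needs >= 2 diploid samples")
    alt, n_hap = G.allele_counts(idx)
    pi_site = per_site_pi(alt, n_hap)
    seg = (alt > 0) & (alt < n_hap) & (n_hap >= 2)
    chroms = G.chroms
    positions = G.positions
    windows: list[DiversityWindow] = []
    for chrom in dict.fromkeys(chroms):
        on = chroms == chrom
        pos0 = positions[on] - 1  # to 0-based
        widx = pos0 // window_bp
        for w in np.unique(widx):
            in_w = on.copy()
            in_w[on] = widx == w
            usable = in_w & (n_hap >= 2)
            if not usable.any():
                continue
            S = int(seg[in_w].sum())
            n_med = float(np.median(n_hap[usable]))
            a_n1 = _harmonic(int(round(n_med)) - 1)
            thetaW = S / a_n1 / window_bp if a_n1 > 0 else 0.0
            windows.append(
                DiversityWindow(
                    chrom=str(chrom),
                    start=int(w) * window_bp,
                    end=(int(w) + 1) * window_bp,
                    S=S,
                    pi=float(pi_site[in_w].sum()) / window_bp,
                    thetaW=thetaW,
                    n_eff=n_med,
                )
            )
    pi_track = WindowTrack(pd.DataFrame(
        [(w.chrom, w.start, w.end, "pi", w.pi) for w in windows],
        columns=list(WindowTrack.COLUMNS)))
    tw_track = WindowTrack(pd.DataFrame(
        [(w.chrom, w.start, w.end, "thetaW", w.thetaW) for w in windows],
        columns=list(WindowTrack.COLUMNS)))
    return windows, pi_track, tw_track


def individual_inbreeding(G: GenotypeMatrix) -> list[InbreedingRecord]:
    """Moment estimator F = 1 - observed het / expected het per sample.

    Expected heterozygosity per sample sums 2p(1-p)*n/(n-1) over its non-missing
    sites, with allele frequencies taken from the analyzed cohort.
    """
    if G.n_samples < 2:
        raise ParameterError("need >= 2 samples to estimate cohort frequencies")
    alt, n_hap = G.allele_counts()
    e_site = per_site_pi(alt, n_hap)  # 2p(1-p) * n/(n-1)
    records = []
    for i, s in enumerate(G.samples):
        row = G.calls[i]
        obs = row != MISSING
        o_het = int((row == 1).sum())
        e_het = float(e_site[obs].sum())
        F = 1.0 - o_het / e_het if e_het > 0 else float("nan")
        records.append(InbreedingRecord(sample=s, o_het=o_het, e_het=e_het, F=F))
    return records


def _dosage_r2(calls: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of dosage over jointly non-missing samples."""
    a, b = calls[:, i], calls[:, j]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def ld_prune(
    G: GenotypeMatrix,
    r2_max: float = 0.45,
    window_snps: int = 2000,
    step_overlap: int = 500,
    maf_min: float = 0.05,
) -> np.ndarray:
    """Greedy LD pruning: drop the later SNP of any pair with r^2 > ``r2_max``.

    SNPs are first filtered to MAF >= ``maf_min``; windows of ``window_snps``
    SNPs advance with ``step_overlap`` SNPs of overlap. Returns retained site
    indices into the original matrix. A pair at exactly r^2 = r2_max is kept
    (strict inequality).
    """
    if window_snps <= step_overlap:
        raise ParameterError("window_snps must exceed step_overlap")
    maf = G.maf()
    cand = np.flatnonzero(maf >= maf_min)
    removed: set[int] = set()
    step = window_snps - step_overlap
    calls = G.calls
    start = 0
    while start < cand.size:
        win = [int(w) for w in cand[start:start + window_snps] if w not in removed]
        if len(win) > 1:
            block = calls[:, win].astype(float)
            missing = block == MISSING
            has_missing = missing.any(axis=0)
            if has_missing.any():
                col_mean = np.where(
                    missing, 0.0, block
                ).sum(axis=0) / np.maximum((~missing).sum(axis=0), 1)
                block = np.where(missing, col_mean, block)
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(block, rowvar=False)
            r2 = np.nan_to_num(r * r, nan=0.0)
            for jj in range(1, len(win)):
                j = win[jj]
                if j in removed:
                    continue
                for ii in range(jj):
                    i = win[ii]
                    if i in removed:
                        continue
                    val = r2[ii, jj]
                    if has_missing[ii] or has_missing[jj]:
                        # exact r2 on jointly non-missing samples
                        val = _dosage_r2(calls, i, j)
                    if val > r2_max:
                        removed.add(j)
                        break
        if start + window_snps >= cand.size:
            break
        start += step
    return np.array([int(i) for i in cand if int(i) not in removed], dtype=np.int64)


def mds_coordinates(G: GenotypeMatrix, k: int) -> MDSResult:
    """MDS via SVD of the centered/standardized genotype matrix.

    Each site is centered by 2*p and scaled by sqrt(2*p*(1-p)); missing dosages
    are mean-imputed (i.e. contribute 0 after centering). Coordinates are the
    top-k left singular vectors scaled by their singular values.
    """
    if k > min(G.n_samples, G.n_sites):
        raise ParameterError(f"k={k} exceeds min(samples, sites)")
    calls = G.calls.astype(float)
    obs = calls != MISSING
    alt, n_hap = G.allele_counts()
    p = np.where(n_hap > 0, alt / np.maximum(n_hap, 1), 0.0)
    denom = np.sqrt(2.0 * p * (1.0 - p))
    denom[denom == 0.0] = 1.0
    Z = np.where(obs, (calls - 2.0 * p) / denom, 0.0)
    # remove residual column means (mean imputation leaves exact centering intact
    # only without missingness)
    Z -= Z.mean(axis=0, keepdims=True)
    U, svals, _ = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :k] * svals[:k]
    eigenvalues = (svals[:k] ** 2) / G.n_sites
    return MDSResult(coordinates=coords, eigenvalues=eigenvalues)


def fit_gaussian_glm(
    y: np.ndarray, X: np.ndarray, names: tuple[str, ...] | None = None
) -> GLMFit:
    """Ordinary least squares with t-based inference (Gaussian GLM).

    ``X`` must include the intercept column. Raises on collinear predictors,
    naming the offending column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ParameterError("X must be 2-D with one row per observation")
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a column whose removal restores full rank
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ParameterError(f"collinear predictor column {names[j]!r}")
        raise ParameterError("collinear predictors")
    res = sm.OLS(y, X).fit()
    return GLMFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        residuals=res.resid,
        names=names,
    )


def kruskal_nemenyi(values: np.ndarray, groups: np.ndarray) -> KWResult:
    """Kruskal-Wallis H (tie-corrected) plus Nemenyi pairwise post-hoc tests.

    The Nemenyi p-values use the studentized-range distribution on mean ranks
    with infinite degrees of freedom (the large-sample approximation).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [str(g) for g in dict.fromkeys(groups)]
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2:
        raise ParameterError("need >= 2 groups")
    for lab, s in zip(labels, samples):
        if s.size < 2:
            raise ParameterError(f"group {lab!r} has < 2 observations")
    H, p = st.kruskal(*samples)
    k = len(labels)
    n = values.size
    ranks = st.rankdata(values)
    mean_rank = np.array([ranks[groups == g].mean() for g in labels])
    sizes = np.array([s.size for s in samples], dtype=float)
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(n * (n + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_rank[i] - mean_rank[j]) / se * np.sqrt(2.0)
            pv = float(st.studentized_range.sf(q, k, np.inf))
            pmat[i, j] = pmat[j, i] = pv
    nem = pd.DataFrame(pmat, index=labels, columns=labels)
    return KWResult(H=float(H), df=k - 1, pvalue=float(p),
                    groups=tuple(labels), nemenyi=nem)


def harmonic_mean_ne(traj: pd.DataFrame, t_max: float) -> float:
    """Generation-weighted harmonic mean of Ne over (0, t_max].

    ``traj`` has columns (t_start, t_end, ne) in generations before present;
    epochs must cover (0, t_max] without gaps.
    """
    df = traj.sort_values("t_start")
    if df["t_start"].iloc[0] > 0:
        raise ParameterError("trajectory must start at generation 0")
    if df["t_end"].iloc[-1] < t_max:
        raise ParameterError(f"trajectory does not cover t_max={t_max}")
    total = 0.0
    for r in df.itertuples():
        lo = max(0.0, r.t_start)
        hi = min(t_max, r.t_end)
        if hi > lo:
            total += (hi - lo) / r.ne
    return t_max / total
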