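"""Weir-Cockerham F_ST in physical windows, plus top-fraction outlier selection.

Per biallelic site, the two-population variance components a (among
populations), b (between individuals within populations) and c (within
individuals) follow Weir & Cockerham (1984), computed from sample sizes, allele
frequencies and observed heterozygosity. Windows report the ratio of sums
sum(a) / sum(a+b+c); negative single-site components are retained in the sums.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, ParameterError, WindowTrack

__all__ = [
    "FstWindow",
    "OutlierSet",
    "site_variance_components",
    "fst_windows",
    "genomewide_fst",
    "top_fraction_outliers",
]


@dataclass(frozen=True)
class FstWindow:
    chrom: str
    start: int
    end: int
    sum_a: float
    sum_bc: float
    fst: float
    n_sites: int


@dataclass(frozen=True)
class OutlierSet:
    flagged: pd.DataFrame  # subset of track records
    threshold: float
    fraction: float


def site_variance_components(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site WC84 components (a, b, c) for two populations of diploids.

    ``calls_a`` / ``calls_b`` are (samples x sites) dosage arrays with MISSING
    allowed. Sites where either population has < 2 genotyped individuals get
    NaN components.
    """
    r = 2.0
    comps = []
    for calls in (calls_a, calls_b):
        obs = calls != MISSING
        n_i = obs.sum(axis=0).astype(float)  # diploid individuals
        alt = np.where(obs, calls, 0).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(n_i > 0, alt / (2.0 * n_i), np.nan)
        h_i = np.where(n_i > 0, (calls == 1).sum(axis=0) / np.maximum(n_i, 1), np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1.0)
            * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return a, b, c


def fst_windows(
    G: GenotypeMatrix,
    popA: str,
    popB: str,
    window_bp: int = 5000,
    maf_min: float = 0.05,
    floor_at_zero: bool = False,
) -> tuple[list[FstWindow], WindowTrack]:
    """Windowed Weir-Cockerham F_ST (ratio of sums) between two populations.

    Sites are filtered to combined-sample MAF >= ``maf_min`` before summation;
    windows with no passing site are omitted. With ``floor_at_zero`` the
    reported window values (not the components) are floored at 0.
    """
    ia = G.sample_indices(popA)
    ib = G.sample_indices(popB)
    if ia.size < 2 or ib.size < 2:
        raise ParameterError("both populations need >= 2 diploid samples")
    both = np.concatenate([ia, ib])
    maf = G.maf(both)
    a, b, c = site_variance_components(G.calls[ia], G.calls[ib])
    usable = np.isfinite(a) & (maf >= maf_min)
    chroms = G.chroms
    pos0 = G.positions - 1
    windows: list[FstWindow] = []
    for chrom in dict.fromkeys(chroms):
        on = (chroms == chrom) & usable
        if not on.any():
            continue
        widx = pos0[on] // window_bp
        for w in np.unique(widx):
            sel = np.flatnonzero(on)[widx == w]
            sum_a = float(a[sel].sum())
            sum_abc = float((a[sel] + b[sel] + c[sel]).sum())
            fst = sum_a / sum_abc if sum_abc != 0.0 else float("nan")
            if floor_at_zero and np.isfinite(fst):
                fst = max(fst, 0.0)
            windows.append(
                FstWindow(
                    chrom=str(chrom),
                    start=int(w) * window_bp,
                    end=(int(w) + 1) * window_bp,
                    sum_a=sum_a,
                    sum_bc=sum_abc - sum_a,
                    fst=fst,
                    n_sites=int(sel.size),
                )
            )
    track = WindowTrack(pd.DataFrame(
        [(w.chrom, w.start, w.end, "fst", w.fst) for w in windows],
        columns=list(WindowTrack.COLUMNS)))
    return windows, track


def genomewide_fst(
    G: GenotypeMatrix, popA: str, popB: str, maf_min: float = 0.0
) -> tuple[float, float]:
    """Genome-wide F_ST two ways: ratio of sums, and mean of window-free site ratios.

    Returns (ratio_of_sums, mean_of_site_ratios); the latter averages a/(a+b+c)
    over sites where the denominator is positive.
    """
    ia = G.sample_indices(popA)
    ib = G.sample_indices(popB)
    both = np.concatenate([ia, ib])
    maf = G.maf(both)
    a, b, c = site_variance_components(G.calls[ia], G.calls[ib])
    ok = np.isfinite(a) & (maf >= maf_min)
    denom = a[ok] + b[ok] + c[ok]
    ratio_of_sums = float(a[ok].sum() / denom.sum())
    pos = denom > 0
    mean_of_ratios = float((a[ok][pos] / denom[pos]).mean())
    return ratio_of_sums, mean_of_ratios


def top_fraction_outliers(track: WindowTrack, fraction: float = 0.01) -> OutlierSet:
    """Flag windows at or above the (1 - fraction) empirical quantile.

    The threshold is the value of the ceil(fraction * n)-th largest window; ties
    at the threshold are all included.
    """
    if not (0.0 < fraction < 1.0):
        raise ParameterError("fraction must lie in (0,1)")
    if len(track) == 0:
        raise ParameterError("track is empty")
    vals = track.values
    finite = np.isfinite(vals)
    n = int(finite.sum())
    k = int(np.ceil(fraction * n))
    order = np.sort(vals[finite])[::-1]
    threshold = float(order[k - 1])
    flagged = track.records[finite & (vals >= threshold)]
    return OutlierSet(flagged=flagged.reset_index(drop=True),
                      threshold=threshold, fraction=fraction)
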