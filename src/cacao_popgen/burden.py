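"""Cost-of-domestication statistics: MAF-binned burden tables and stratified tests.

Annotated non-synonymous sites are tallied per population into effect classes
(deleterious vs tolerated, from the SIFT-score rule) and minor-allele-frequency
bins: rare (0, 0.25], intermediate (0.25, 0.375], frequent (0.375, 0.5] — bins
are right-closed and MAF is computed within each population. The population x
effect contrast is tested with a Poisson log-linear three-way interaction LRT
and with the Cochran-Mantel-Haenszel test stratified by MAF bin.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .core_io import EffectAnnotation, GenotypeMatrix, ParameterError

logger = logging.getLogger("cacao_popgen")

__all__ = [
    "BurdenTable",
    "CMHResult",
    "LLMResult",
    "MAF_BIN_EDGES",
    "maf_bin",
    "burden_table",
    "cmh_test",
    "loglinear_interaction_test",
]

MAF_BINS = ("rare", "intermediate", "frequent")
#: right-closed bin edges on minor allele frequency
MAF_BIN_EDGES = (0.0, 0.25, 0.375, 0.5)

EFFECTS = ("deleterious", "tolerated")


@dataclass
class BurdenTable:
    """Counts indexed by (population, effect class, MAF bin)."""

    counts: pd.DataFrame  # MultiIndex (population, effect, maf_bin) -> count

    def population_total(self, pop: str) -> int:
        return int(self.counts.loc[pop].sum())

    def cell(self, pop: str, effect: str, maf_bin: str) -> int:
        return int(self.counts.loc[(pop, effect, maf_bin)])

    def strata_tables(self, popA: str, popB: str) -> list[np.ndarray]:
        """2x2 tables (rows = populations, cols = effect) per MAF-bin stratum."""
        tabs = []
        for b in MAF_BINS:
            tabs.append(np.array([
                [self.cell(popA, "deleterious", b), self.cell(popA, "tolerated", b)],
                [self.cell(popB, "deleterious", b), self.cell(popB, "tolerated", b)],
            ], dtype=float))
        return tabs


@dataclass(frozen=True)
class CMHResult:
    statistic: float
    df: int
    pvalue: float
    common_odds_ratio: float
    n_strata: int


@dataclass(frozen=True)
class LLMResult:
    deviance_null: float
    deviance_full: float
    lrt: float
    df: int
    pvalue: float


def maf_bin(maf: float) -> str | None:
    """Right-closed bin for a within-population minor allele frequency.

    Returns None for monomorphic sites (MAF 0) or values above 0.5.
    """
    if maf <= MAF_BIN_EDGES[0] or maf > MAF_BIN_EDGES[3]:
        return None
    if maf <= MAF_BIN_EDGES[1]:
        return "rare"
    if maf <= MAF_BIN_EDGES[2]:
        return "intermediate"
    return "frequent"


def burden_table(
    G: GenotypeMatrix,
    annotations: list[EffectAnnotation],
    pops: list[str],
) -> BurdenTable:
    """Tally annotated segregating sites per population into (effect, MAF bin).

    MAF is computed within each population; sites monomorphic in a population do
    not count for it. Annotations that reference unknown sites are skipped with
    a warning.
    """
    site_index = {s.key: j for j, s in enumerate(G.sites)}
    ann_idx: list[tuple[int, str]] = []
    n_unknown = 0
    for ann in annotations:
        j = site_index.get(ann.key)
        if j is None:
            n_unknown += 1
            continue
        ann_idx.append((j, ann.effect))
    if n_unknown:
        logger.warning("%d annotations reference unknown sites; skipped", n_unknown)

    index = pd.MultiIndex.from_product(
        [pops, EFFECTS, MAF_BINS], names=["population", "effect", "maf_bin"]
    )
    counts = pd.Series(0, index=index, name="count")
    for pop in pops:
        idx = G.sample_indices(pop)
        maf = G.maf(idx)
        for j, effect in ann_idx:
            b = maf_bin(float(maf[j]))
            if b is None:
                continue
            counts.loc[(pop, effect, b)] += 1
    return BurdenTable(counts=counts)


def cmh_test(strata: list[np.ndarray], correction: bool = False) -> CMHResult:
    """Cochran-Mantel-Haenszel chi-square over 2x2 strata.

    Strata with an empty margin are dropped with a warning; continuity
    correction is off by default. Also returns the Mantel-Haenszel common odds
    ratio.
    """
    kept = []
    for t in strata:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2):
            raise ParameterError("each stratum must be a 2x2 table")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            logger.warning("dropping stratum with an empty margin")
            continue
        kept.append(t)
    if not kept:
        raise ParameterError("no usable strata")
    num = 0.0
    var = 0.0
    or_num = 0.0
    or_den = 0.0
    for t in kept:
        n = t.sum()
        row1, col1 = t[0].sum(), t[:, 0].sum()
        row2, col2 = t[1].sum(), t[:, 1].sum()
        expected = row1 * col1 / n
        num += t[0, 0] - expected
        var += row1 * row2 * col1 * col2 / (n**2 * (n - 1.0))
        or_num += t[0, 0] * t[1, 1] / n
        or_den += t[0, 1] * t[1, 0] / n
    adj = abs(num) - 0.5 if correction else abs(num)
    stat = max(adj, 0.0) ** 2 / var if var > 0 else 0.0
    pvalue = float(st.chi2.sf(stat, 1))
    cor = float(or_num / or_den) if or_den > 0 else float("inf")
    return CMHResult(statistic=float(stat), df=1, pvalue=pvalue,
                     common_odds_ratio=cor, n_strata=len(kept))


def loglinear_interaction_test(
    table: BurdenTable, popA: str, popB: str, zero_cell_constant: float = 0.5
) -> LLMResult:
    """Poisson log-linear LRT for the population x effect x MAF-bin interaction.

    The null model contains all main effects and two-way interactions; the full
    model adds the three-way term. Zero cells are lifted by a continuity
    constant (with a warning) so both deviances are finite.
    """
    rows = []
    for pop in (popA, popB):
        for effect in EFFECTS:
            for b in MAF_BINS:
                rows.append({
                    "count": table.cell(pop, effect, b),
                    "pop": pop, "effect": effect, "bin": b,
                })
    df = pd.DataFrame(rows)
    if (df["count"] == 0).any():
        logger.warning("zero cells lifted by %.2f for the log-linear fit",
                       zero_cell_constant)
        df["count"] = df["count"] + zero_cell_constant

    y = df["count"].to_numpy(dtype=float)
    pop_d = (df["pop"] == popB).to_numpy(dtype=float)
    eff_d = (df["effect"] == "tolerated").to_numpy(dtype=float)
    bin_d = pd.get_dummies(df["bin"], drop_first=True).to_numpy(dtype=float)

    def design(three_way: bool) -> np.ndarray:
        cols = [np.ones_like(y), pop_d, eff_d]
        cols += [bin_d[:, i] for i in range(bin_d.shape[1])]
        cols.append(pop_d * eff_d)
        cols += [pop_d * bin_d[:, i] for i in range(bin_d.shape[1])]
        cols += [eff_d * bin_d[:, i] for i in range(bin_d.shape[1])]
        if three_way:
            cols += [pop_d * eff_d * bin_d[:, i] for i in range(bin_d.shape[1])]
        return np.column_stack(cols)

    import warnings

    with warnings.catch_warnings():
        # the full model is intentionally saturated (12 parameters, 12 cells)
        warnings.simplefilter("ignore")
        fit0 = sm.GLM(y, design(False), family=sm.families.Poisson()).fit()
        fit1 = sm.GLM(y, design(True), family=sm.families.Poisson()).fit()
    lrt = max(float(fit0.deviance - fit1.deviance), 0.0)
    df_lrt = bin_d.shape[1]  # (2-1)(2-1)(3-1) added parameters
    pvalue = float(st.chi2.sf(lrt, df_lrt))
    return LLMResult(
        deviance_null=float(fit0.deviance),
        deviance_full=float(fit1.deviance),
        lrt=lrt,
        df=df_lrt,
        pvalue=pvalue,
    )
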