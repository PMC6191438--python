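"""Readers/writers for the external formats and the in-memory genotype container.

Coordinate discipline: physical positions are 1-based everywhere inside the
package; all window output (BED-like tracks) is 0-based half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cacao_popgen")

#: genotype code for a missing diploid call
MISSING: int = -1


class PopgenError(Exception):
    """Base class for package errors."""


class FormatError(PopgenError):
    """A file did not conform to its declared format."""


class MissingSampleError(PopgenError):
    """A requested sample is absent from the data."""


class ParameterError(PopgenError, ValueError):
    """An operation received invalid parameters."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: 1-based physical position plus optional map position (cM)."""

    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "T"
    cm: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParameterError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ParameterError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class EffectAnnotation:
    """Per-variant functional label derived from a SIFT-style conservation score.

    A substitution is deleterious iff its score is <= 0.05 and tolerated otherwise;
    the label is validated against the score on construction.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    effect: str
    sift_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sift_score <= 1.0):
            raise ParameterError(f"SIFT score outside [0,1]: {self.sift_score}")
        expected = "deleterious" if self.sift_score <= 0.05 else "tolerated"
        if self.effect != expected:
            raise ParameterError(
                f"effect label {self.effect!r} inconsistent with score {self.sift_score}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def classify_effect(sift_score: float) -> str:
    """Return 'deleterious' for scores <= 0.05, else 'tolerated'."""
    if not (0.0 <= sift_score <= 1.0):
        raise ParameterError(f"SIFT score outside [0,1]: {sift_score}")
    return "deleterious" if sift_score <= 0.05 else "tolerated"


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites, codes in {0,1,2,MISSING} counting alt alleles.

    ``calls`` is an int8 array of shape (n_samples, n_sites). ``pop_of`` maps a
    sample ID to its population label; samples absent from the map carry no label.
    """

    samples: list[str]
    sites: list[VariantSite]
    calls: np.ndarray
    pop_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ParameterError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ParameterError(f"invalid genotype codes {bad.tolist()}")
        by_chrom: dict[str, int] = {}
        for s in self.sites:
            prev = by_chrom.get(s.chrom)
            if prev is not None and s.pos <= prev:
                raise ParameterError(
                    f"sites on {s.chrom} not strictly increasing at pos {s.pos}"
                )
            by_chrom[s.chrom] = s.pos

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    @property
    def cm_positions(self) -> np.ndarray:
        """Genetic-map positions; sites without a map default to 1 cM/Mb."""
        return np.array(
            [s.cm if s.cm is not None else s.pos * 1e-6 for s in self.sites]
        )

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            p = self.pop_of.get(s)
            if p is not None:
                seen.setdefault(p, None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.pop_of.get(s) == pop],
            dtype=np.int64,
        )
        if idx.size == 0:
            raise MissingSampleError(f"population {pop!r} has no samples")
        return idx

    # -- per-site summaries ----------------------------------------------
    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele count, non-missing haploid count) per site."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        obs = calls != MISSING
        alt = np.where(obs, calls, 0).sum(axis=0).astype(np.int64)
        n_hap = 2 * obs.sum(axis=0).astype(np.int64)
        return alt, n_hap

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        alt, n = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        p = self.alt_freq(sample_idx)
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------
    def take_sites(self, site_idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        site_idx = np.asarray(site_idx, dtype=np.int64)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in site_idx],
            calls=self.calls[:, site_idx],
            pop_of=dict(self.pop_of),
        )

    def take_samples(self, sample_idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        sample_idx = np.asarray(sample_idx, dtype=np.int64)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            sites=list(self.sites),
            calls=self.calls[sample_idx],
            pop_of=dict(self.pop_of),
        )

    def drop_high_missing(self, max_missing: float = 0.5) -> "GenotypeMatrix":
        """Drop sites whose fraction of missing calls exceeds ``max_missing``."""
        frac = (self.calls == MISSING).mean(axis=0)
        keep = np.flatnonzero(frac <= max_missing)
        if keep.size < self.n_sites:
            logger.info("dropping %d/%d sites with >%d%% missing calls",
                        self.n_sites - keep.size, self.n_sites, int(100 * max_missing))
        return self.take_sites(keep)


@dataclass
class WindowTrack:
    """BED-like per-window statistic records (chrom, start, end, label, value).

    Starts are 0-based inclusive, ends exclusive.
    """

    records: pd.DataFrame

    COLUMNS = ("chrom", "start", "end", "label", "value")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        if len(df) and not (df["start"] < df["end"]).all():
            raise ParameterError("window start must be < end")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)


def write_window_track(track: WindowTrack, path: str, header: bool = False) -> None:
    """Serialize a track as a 5-column BED-compatible TSV."""
    track.records.to_csv(path, sep="\t", header=header, index=False)


def read_window_track(path: str) -> WindowTrack:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=list(WindowTrack.COLUMNS),
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "label": str, "value": float},
    )
    return WindowTrack(df)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str,
    samples_filter: list[str] | None = None,
    pop_map: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read diploid biallelic SNP genotypes from a VCF (GT field only).

    Codes 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> MISSING; phased separators
    are treated as unphased. Multiallelic and indel records are skipped with a
    logged count.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # malformed header or unreadable file
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    all_samples = list(vcf.samples)
    if samples_filter is not None:
        absent = [s for s in samples_filter if s not in all_samples]
        if absent:
            raise MissingSampleError(f"samples absent from VCF: {absent}")
        keep = [all_samples.index(s) for s in samples_filter]
        samples = list(samples_filter)
    else:
        keep = list(range(len(all_samples)))
        samples = all_samples

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        sites.append(VariantSite(var.CHROM, var.POS, var.REF, var.ALT[0]))
        gts = var.genotypes  # [[a, b, phased], ...]
        row = np.empty(len(keep), dtype=np.int8)
        for out_i, samp_i in enumerate(keep):
            a, b = gts[samp_i][0], gts[samp_i][1]
            row[out_i] = a + b if (a >= 0 and b >= 0) else MISSING
        rows.append(row)
    if n_skipped:
        logger.info("skipped %d multiallelic/indel records", n_skipped)
    calls = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls, pop_of=dict(pop_map or {}))


def write_vcf_genotypes(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 (GT only) readable by :func:`read_vcf_genotypes`."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(s.chrom for s in G.sites)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        for j, site in enumerate(G.sites):
            gts = "\t".join(code_to_gt[int(c)] for c in G.calls[:, j])
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# TSV side files
# ---------------------------------------------------------------------------

def read_population_map(path: str, header: bool = False) -> dict[str, str]:
    """Read a two-column (sample, population) TSV; duplicate samples are rejected."""
    df = pd.read_csv(path, sep="\t", header=0 if header else None,
                     names=["sample", "population"], dtype=str)
    if df.empty:
        raise FormatError(f"population map {path} is empty")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"duplicate sample IDs in population map: {dups}")
    return dict(zip(df["sample"], df["population"]))


def read_effect_annotations(path: str) -> list[EffectAnnotation]:
    """Read the per-variant effect TSV (chrom, pos, ref, alt, effect, sift_score)."""
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "pos", "ref", "alt", "effect", "sift_score"],
                     header=None, comment="#")
    return [
        EffectAnnotation(str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                         str(r.effect), float(r.sift_score))
        for r in df.itertuples()
    ]


def read_genetic_map(path: str) -> pd.DataFrame:
    """Read a genetic map TSV (chrom, pos, cM), sorted within chromosome."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "cm"], header=None,
                     dtype={"chrom": str, "pos": np.int64, "cm": float}, comment="#")
    if df.empty:
        raise FormatError(f"genetic map {path} is empty")
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def interpolate_cm(G: GenotypeMatrix, genetic_map: pd.DataFrame | None = None,
                   default_cm_per_mb: float = 1.0) -> GenotypeMatrix:
    """Attach genetic-map positions to every site by linear interpolation.

    Outside the mapped range the terminal map values are extended flat by
    ``np.interp``; with no map at all a constant rate (default 1 cM/Mb) is used.
    """
    new_sites = []
    if genetic_map is None:
        for s in G.sites:
            new_sites.append(replace(s, cm=s.pos * default_cm_per_mb / 1e6))
    else:
        by_chrom = {c: g for c, g in genetic_map.groupby("chrom")}
        for s in G.sites:
            g = by_chrom.get(s.chrom)
            if g is None:
                cm = s.pos * default_cm_per_mb / 1e6
            else:
                cm = float(np.interp(s.pos, g["pos"].to_numpy(), g["cm"].to_numpy()))
            new_sites.append(replace(s, cm=cm))
    return GenotypeMatrix(samples=list(G.samples), sites=new_sites,
                          calls=G.calls.copy(), pop_of=dict(G.pop_of))


def read_ne_trajectory(path: str) -> pd.DataFrame:
    """Read an Ne-trajectory TSV (t_start, t_end in generations before present, Ne).

    Epochs must be contiguous, non-overlapping, with positive Ne. Trajectories of
    this shape come from external PSMC/SMC++ runs; they are consumed, not inferred.
    """
    df = pd.read_csv(path, sep="\t", names=["t_start", "t_end", "ne"], header=None,
                     dtype=float, comment="#")
    df = df.sort_values("t_start").reset_index(drop=True)
    if (df["ne"] <= 0).any():
        raise FormatError("Ne values must be positive")
    if not np.allclose(df["t_start"].to_numpy()[1:], df["t_end"].to_numpy()[:-1]):
        raise FormatError("Ne trajectory epochs must be contiguous")
    return df


def read_phenotypes(path: str, header: bool = False) -> pd.DataFrame:
    """Read a phenotype TSV (sample, yield in kg per hectare per year)."""
    df = pd.read_csv(path, sep="\t", header=0 if header else None,
                     names=["sample", "yield"], dtype={"sample": str, "yield": float})
    if df.empty:
        raise FormatError(f"phenotype file {path} is empty")
    return df


def load_config(path: str) -> dict:
    """Load the YAML config; a single top-level ``seed`` key is required."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise FormatError("config must define a top-level 'seed'")
    return cfg
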