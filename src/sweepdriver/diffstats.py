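"""Allele-frequency differentiation statistics: Weir–Cockerham F_ST and PBS.

Per-site F_ST uses the Weir & Cockerham (1984) variance-component estimator
on diploid genotypes (haplotype pairs 2i, 2i+1 recombined into genotypes):
F_ST = a / (a + b + c), where a, b, c are the among-population,
among-individual-within-population and within-individual components. The
estimator can be negative at weakly differentiated sites; a + b + c = 0
leaves it undefined.

The population branch statistic transforms pairwise F_ST into branch lengths
T = -ln(1 - F_ST) and isolates allele-frequency change on the test
population's branch since its divergence from a sister population, with a
shared outgroup:

    PBS = (T_test,sister + T_test,outgroup - T_sister,outgroup) / 2

Outlier calling is empirical: per-frequency-bin top-quantile thresholds for
F_ST (F_ST co-varies with allele frequency, so each site is contrasted with
its own frequency class) and a genome-wide top-quantile threshold for PBS.
Outlier thresholds are rank-based (the k-th largest value of the bin or
genome, k = ceil(quantile*n), ties included) so that perfect-LD blocks of
identical statistics at the top of a bin are flagged as a unit; a
degenerate all-equal distribution flags nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .haplostats import ScoreTrack
from .popio import HaplotypeMatrix

_CLAMP = 1.0 - 1e-12


@dataclass
class FstRecord:
    """Variance components and F_ST for one site and population pair."""

    populations: tuple[str, str]
    a: float
    b: float
    c: float

    @property
    def fst(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else np.nan


def _genotypes(matrix: HaplotypeMatrix) -> np.ndarray:
    """Diploid derived-allele dosage (n_individuals x n_sites) in {0,1,2}."""
    return matrix.entries[0::2].astype(np.int64) + matrix.entries[1::2]


def _wc_components(
    geno1: np.ndarray, geno2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Weir & Cockerham (1984) a, b, c for two populations.

    ``geno*`` are dosage matrices (individuals x sites).
    """
    r = 2.0
    n1, n2 = float(geno1.shape[0]), float(geno2.shape[0])
    p1 = geno1.mean(axis=0) / 2.0
    p2 = geno2.mean(axis=0) / 2.0
    h1 = (geno1 == 1).mean(axis=0)
    h2 = (geno2 == 1).mean(axis=0)

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1.0))
        * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst(
    geno1: Sequence[int] | np.ndarray,
    geno2: Sequence[int] | np.ndarray,
    populations: tuple[str, str] = ("pop1", "pop2"),
) -> FstRecord:
    """Weir & Cockerham F_ST components for one biallelic site.

    ``geno1``/``geno2`` are per-individual derived-allele dosages (0/1/2)
    for the two populations; at least two individuals each.
    """
    g1 = np.asarray(geno1, dtype=np.int64).reshape(-1, 1)
    g2 = np.asarray(geno2, dtype=np.int64).reshape(-1, 1)
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("need >= 2 diploid individuals per population")
    if not (set(np.unique(g1)) | set(np.unique(g2))) <= {0, 1, 2}:
        raise ValueError("dosages must be 0, 1 or 2 (biallelic site)")
    a, b, c = _wc_components(g1, g2)
    return FstRecord(populations, float(a[0]), float(b[0]), float(c[0]))


def fst_scan(
    matrix_a: HaplotypeMatrix, matrix_b: HaplotypeMatrix
) -> ScoreTrack:
    """Per-site Weir & Cockerham F_ST across a shared site list.

    Sites monomorphic across both populations (a + b + c = 0) are
    undefined with reason "monomorphic". The track also carries the pooled
    minor allele frequency used by the binned outlier test.
    """
    if not np.array_equal(matrix_a.positions, matrix_b.positions):
        raise ValueError("matrices do not share a site list")
    g1, g2 = _genotypes(matrix_a), _genotypes(matrix_b)
    a, b, c = _wc_components(g1, g2)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)

    n_tot = matrix_a.n_haplotypes + matrix_b.n_haplotypes
    pooled = (
        matrix_a.entries.sum(axis=0, dtype=np.int64)
        + matrix_b.entries.sum(axis=0, dtype=np.int64)
    ) / n_tot

    df = matrix_a.sites[["chrom", "pos"]].copy()
    df["derived_freq"] = pooled
    df["maf"] = np.minimum(pooled, 1.0 - pooled)
    df["raw"] = fst
    df["standardized"] = np.nan
    df["reason"] = np.where(denom != 0, "ok", "monomorphic")
    return ScoreTrack(
        "FST", df, populations=(matrix_a.population, matrix_b.population)
    )


def binned_fst_flags(
    track: ScoreTrack,
    bin_width: float = 0.05,
    quantile: float = 0.05,
    min_per_bin: int = 20,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-site high-F_ST flags from frequency-binned empirical thresholds.

    Defined F_ST values are grouped into pooled-MAF bins of ``bin_width``
    over [0, 0.5]; a site is flagged iff its F_ST reaches its own bin's
    k-th largest value (k = ceil(quantile * n), ties included) and strictly
    exceeds the bin minimum. Bins with fewer than ``min_per_bin`` defined
    sites are merged with the nearest occupied bin below (or above, for the
    first). Returns (flags, per-bin threshold table).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    df = track.data
    fst = df["raw"].to_numpy(dtype=float)
    maf = df["maf"].to_numpy(dtype=float)
    defined = np.isfinite(fst)

    n_bins = int(np.ceil(0.5 / bin_width))
    bin_of = np.clip((maf / bin_width).astype(np.int64), 0, n_bins - 1)
    occupied = np.unique(bin_of[defined])
    counts = {b: int(((bin_of == b) & defined).sum()) for b in occupied}

    # merge sparse bins into their left neighbor group
    groups: list[list[int]] = []
    for b in occupied:
        if groups and (
            counts_group(groups[-1], counts) < min_per_bin
            or counts[b] < min_per_bin
        ):
            groups[-1].append(b)
        else:
            groups.append([b])
    if len(groups) > 1 and counts_group(groups[-1], counts) < min_per_bin:
        tail = groups.pop()
        groups[-1].extend(tail)

    group_of = {b: g for g, bins in enumerate(groups) for b in bins}
    gid = np.array([group_of.get(b, -1) for b in bin_of])
    flags = np.zeros(len(df), dtype=bool)
    rows = []
    for g, bins in enumerate(groups):
        mask = defined & (gid == g)
        vals = fst[mask]
        thr, bin_flags = _rank_top_flags(vals, quantile)
        flags[mask] = bin_flags
        rows.append(
            {
                "maf_lo": min(bins) * bin_width,
                "maf_hi": (max(bins) + 1) * bin_width,
                "n_sites": int(mask.sum()),
                "threshold": thr,
            }
        )
    return flags, pd.DataFrame(rows)


def counts_group(bins: list[int], counts: dict[int, int]) -> int:
    return sum(counts[b] for b in bins)


def _rank_top_flags(vals: np.ndarray, quantile: float) -> tuple[float, np.ndarray]:
    """Rank-based top-quantile outliers: the threshold is the k-th largest
    value with k = ceil(quantile * n); a value qualifies iff it reaches the
    threshold (ties included) and strictly exceeds the minimum, so an
    all-equal distribution flags nothing. Including ties matters because
    perfect-LD SNPs share identical statistics: a tied maximal block must
    not be excluded just because the threshold order statistic lands on it.
    """
    k = max(1, int(np.ceil(quantile * vals.size)))
    thr = float(np.sort(vals)[-k])
    return thr, (vals >= thr) & (vals > vals.min())


@dataclass
class PbsComparison:
    """PBS values for one (test, sister, outgroup) role assignment."""

    test: str
    sister: str
    outgroup: str
    data: pd.DataFrame  # chrom, pos, t_ts, t_to, t_so, pbs


def branch_length(fst: np.ndarray | float) -> np.ndarray | float:
    """T = -ln(1 - F_ST), with F_ST clamped into [0, 1 - 1e-12].

    Negative estimator values clamp to 0 so branch lengths stay
    non-negative; the raw F_ST is untouched elsewhere.
    """
    clamped = np.clip(fst, 0.0, _CLAMP)
    return -np.log(1.0 - clamped)


def pbs(
    fst_ts: ScoreTrack,
    fst_to: ScoreTrack,
    fst_so: ScoreTrack,
    test: str,
    sister: str,
    outgroup: str,
) -> PbsComparison:
    """Per-site PBS for a (test, sister, outgroup) population triplet.

    The three F_ST tracks must be aligned on the same site list
    (test-sister, test-outgroup, sister-outgroup). Sites with any undefined
    F_ST are undefined. Any of the six role assignments of a four-population
    design are obtained by relabeling the inputs.
    """
    pos = fst_ts.data["pos"].to_numpy()
    for other in (fst_to, fst_so):
        if not np.array_equal(other.data["pos"].to_numpy(), pos):
            raise ValueError("F_ST tracks are not aligned on one site list")
    t_ts = branch_length(fst_ts.data["raw"].to_numpy(dtype=float))
    t_to = branch_length(fst_to.data["raw"].to_numpy(dtype=float))
    t_so = branch_length(fst_so.data["raw"].to_numpy(dtype=float))
    values = (t_ts + t_to - t_so) / 2.0

    df = fst_ts.data[["chrom", "pos"]].copy()
    df["t_ts"], df["t_to"], df["t_so"] = t_ts, t_to, t_so
    df["pbs"] = values
    return PbsComparison(test=test, sister=sister, outgroup=outgroup, data=df)


def pbs_top_flags(
    values: np.ndarray | pd.Series, quantile: float = 0.05, min_values: int = 100
) -> tuple[np.ndarray, float]:
    """Genome-wide empirical top-quantile flags for PBS values.

    Returns (flags, threshold): the threshold is the k-th largest defined
    value (k = ceil(quantile * n)); values reaching it (ties included) and
    strictly above the minimum are flagged.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    vals = np.asarray(values, dtype=float)
    defined = np.isfinite(vals)
    if defined.sum() < min_values:
        import warnings

        warnings.warn(
            f"only {int(defined.sum())} defined PBS values; "
            "the empirical threshold may be unstable",
            stacklevel=2,
        )
    thr, def_flags = _rank_top_flags(vals[defined], quantile)
    flags = np.zeros(vals.size, dtype=bool)
    flags[defined] = def_flags
    return flags, thr
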