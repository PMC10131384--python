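"""Haplotype-homozygosity selection statistics: EHH, iHH, iHS, xpEHH.

EHH (extended haplotype homozygosity) at an extent j away from a core SNP is
the probability that two randomly drawn haplotypes carrying the core allele
are identical at every site from the core through j:

    EHH(j) = sum_h C(k_h, 2) / C(n, 2)

where the n carrier haplotypes split into groups of size k_h by the identity
of the sub-haplotype spanning core..j. EHH is 1 at the core by convention
(zero-length interval) and non-increasing outward. iHH integrates EHH against
physical position (bp) separately for the upstream and downstream arms,
truncating where EHH falls below a cutoff; the unstandardized scores are

    iHS   = ln(iHH_ancestral / iHH_derived)      (within one population)
    xpEHH = ln(iHH_popA / iHH_popB)              (pooled alleles per population)

Large |iHS| marks unusually long haplotypes around one allele class (an
ongoing sweep); positive xpEHH marks longer haplotypes in population A
(a sweep near or at fixation there). Raw scores are standardized within
derived-allele-frequency bins against the genome-wide empirical distribution.

Distances are physical bp throughout (no genetic map).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _ehh_kernels as kernels
from .popio import HaplotypeMatrix

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000

#: reason codes attached to cores that receive no score
REASONS = ("ok", "monomorphic", "edge", "max_gap", "zero-area", "low-maf")


class MonomorphicCoreError(ValueError):
    """Core site has fewer than two carriers of the requested allele class."""


@dataclass
class EHHCurve:
    """EHH decay away from a core SNP for one allele class.

    Each arm is a list of (position bp, EHH) pairs starting at the core
    (EHH = 1) and ending either at the first extent whose EHH dropped below
    the cutoff (status "cutoff"), at the chromosome edge (status "edge"), or
    at an inter-site gap larger than max_gap (status "gap").
    """

    core: int
    allele: str
    upstream: list[tuple[float, float]]
    downstream: list[tuple[float, float]]
    upstream_status: str
    downstream_status: str


@dataclass
class ScoreTrack:
    """Per-SNP values of one statistic with optional standardization."""

    statistic: str
    data: pd.DataFrame  # chrom, pos, derived_freq, raw, standardized, reason
    populations: tuple[str, ...] = ()
    bin_table: Optional[pd.DataFrame] = None

    def defined(self) -> pd.DataFrame:
        return self.data[self.data["raw"].notna()]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# statistic={self.statistic}\n")
            fh.write(f"# populations={','.join(self.populations)}\n")
            self.data.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _pair_homozygosity(group_sizes: np.ndarray, n: int) -> float:
    return float((group_sizes * (group_sizes - 1)).sum() / (n * (n - 1)))


_STATUS = {kernels.STATUS_CUTOFF: "cutoff", kernels.STATUS_EDGE: "edge",
           kernels.STATUS_GAP: "gap"}


class _WalkBuffers:
    """Reusable per-scan output buffers for the compiled EHH walks."""

    def __init__(self, matrix: HaplotypeMatrix):
        n = matrix.n_sites
        self.positions = matrix.positions.astype(np.float64)
        self.pos = np.empty(n, dtype=np.float64)
        self.ehh = np.empty(n, dtype=np.float64)

    def walk(self, entries, carriers, core, cutoff, max_gap, step):
        count, status = kernels.walk(
            entries, self.positions, carriers, core, cutoff,
            -1.0 if max_gap is None else float(max_gap), step,
            self.pos, self.ehh,
        )
        return count, _STATUS[status]

    def arm_area(self, core_pos: float, count: int, cutoff: float) -> float:
        """Trapezoid area from the core through ``count`` extents; only
        trapezoids whose both endpoints have EHH >= cutoff contribute."""
        pp = np.concatenate(([core_pos], self.pos[:count]))
        ee = np.concatenate(([1.0], self.ehh[:count]))
        ok = (ee[:-1] >= cutoff) & (ee[1:] >= cutoff)
        return float(np.sum(0.5 * (ee[:-1] + ee[1:]) * np.abs(np.diff(pp)) * ok))


def _carriers(matrix: HaplotypeMatrix, core: int, allele: str) -> np.ndarray:
    col = matrix.entries[:, core]
    if allele == "derived":
        return np.flatnonzero(col == 1).astype(np.int64)
    if allele == "ancestral":
        return np.flatnonzero(col == 0).astype(np.int64)
    if allele == "pooled":
        return np.arange(matrix.n_haplotypes, dtype=np.int64)
    raise ValueError(f"unknown allele class {allele!r}")


def ehh(
    matrix: HaplotypeMatrix,
    core: int,
    allele: str = "derived",
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: Optional[float] = None,
) -> EHHCurve:
    """EHH decay curve around ``core`` for one allele class.

    Raises :class:`MonomorphicCoreError` if fewer than two haplotypes carry
    the requested allele class at the core.
    """
    carriers = _carriers(matrix, core, allele)
    if carriers.size < 2:
        raise MonomorphicCoreError(
            f"monomorphic core: {carriers.size} carriers of {allele!r} "
            f"at site {core}"
        )
    buf = _WalkBuffers(matrix)
    core_pt = (float(matrix.positions[core]), 1.0)
    arms, statuses = [], []
    for step in (-1, +1):
        count, status = buf.walk(
            matrix.entries, carriers, core, cutoff, max_gap, step
        )
        arms.append(
            [core_pt] + list(zip(buf.pos[:count].tolist(), buf.ehh[:count].tolist()))
        )
        statuses.append(status)
    return EHHCurve(
        core=core,
        allele=allele,
        upstream=arms[0],
        downstream=arms[1],
        upstream_status=statuses[0],
        downstream_status=statuses[1],
    )


def _arm_area(arm: list[tuple[float, float]], cutoff: float) -> float:
    """Trapezoidal area of one arm; only trapezoids whose both endpoints
    have EHH >= cutoff contribute (no interpolation at the boundary)."""
    area = 0.0
    for (p0, e0), (p1, e1) in zip(arm, arm[1:]):
        if e0 >= cutoff and e1 >= cutoff:
            area += 0.5 * (e0 + e1) * abs(p1 - p0)
    return area


def ihh(curve: EHHCurve, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Integrated EHH (bp): trapezoid area of both arms against position."""
    return _arm_area(curve.upstream, cutoff) + _arm_area(curve.downstream, cutoff)


def _empty_track(matrix: HaplotypeMatrix) -> pd.DataFrame:
    df = matrix.sites[["chrom", "pos"]].copy()
    df["derived_freq"] = matrix.derived_freq()
    df["raw"] = np.nan
    df["standardized"] = np.nan
    df["reason"] = "ok"
    return df


def ihs_scan(
    matrix: HaplotypeMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: Optional[float] = DEFAULT_MAX_GAP,
) -> ScoreTrack:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) per core SNP.

    The matrix must be polarized and MAF-filtered. Cores are skipped with a
    reason code when either allele class has <2 carriers ("monomorphic"),
    an arm reaches the chromosome edge before EHH < cutoff ("edge"), an
    inter-site gap exceeds max_gap ("max_gap"), or an iHH is zero
    ("zero-area").
    """
    df = _empty_track(matrix)
    raw = np.full(matrix.n_sites, np.nan)
    reasons = np.full(matrix.n_sites, "ok", dtype=object)
    buf = _WalkBuffers(matrix)
    entries = matrix.entries
    counts1 = entries.sum(axis=0, dtype=np.int64)
    n = matrix.n_haplotypes
    for j in range(matrix.n_sites):
        if counts1[j] < 2 or n - counts1[j] < 2:
            reasons[j] = "monomorphic"
            continue
        core_pos = buf.positions[j]
        areas = []
        skip = None
        for allele in ("ancestral", "derived"):
            carriers = _carriers(matrix, j, allele)
            area = 0.0
            for step in (-1, +1):
                count, status = buf.walk(entries, carriers, j, cutoff, max_gap, step)
                if status == "edge":
                    skip = "edge"
                    break
                if status == "gap":
                    skip = skip or "max_gap"
                    break
                area += buf.arm_area(core_pos, count, cutoff)
            if skip == "edge":
                break
            areas.append(area)
        if skip:
            reasons[j] = skip
            continue
        ihh_a, ihh_d = areas
        if ihh_a <= 0.0 or ihh_d <= 0.0:
            reasons[j] = "zero-area"
            continue
        raw[j] = np.log(ihh_a / ihh_d)
    df["raw"], df["reason"] = raw, reasons
    return ScoreTrack("iHS", df, populations=(matrix.population,))


def xpehh_scan(
    matrix_a: HaplotypeMatrix,
    matrix_b: HaplotypeMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: Optional[float] = DEFAULT_MAX_GAP,
    maf_min: Optional[float] = None,
    trunc_ok: bool = True,
) -> ScoreTrack:
    """Unstandardized xpEHH = ln(iHH_a / iHH_b) per core SNP.

    Both matrices must share the site list. iHH is computed on all haplotypes
    (pooled alleles) within each population; the integration extent in both
    populations is set by where the EHH of the two populations pooled
    together falls below the cutoff, so the two areas cover the same
    interval. Positive scores indicate longer haplotypes (candidate
    selection) in ``matrix_a``'s population. ``maf_min``, if given, skips
    cores whose pooled minor allele frequency is below it ("low-maf").

    ``trunc_ok`` (default) scores cores whose combined EHH is still above
    the cutoff at the chromosome edge by integrating up to the edge; both
    populations share the truncated boundary, so the ratio remains
    comparable. With ``trunc_ok=False`` such cores are suppressed ("edge").
    """
    if not np.array_equal(matrix_a.positions, matrix_b.positions):
        raise ValueError("matrices do not share a site list")
    combined = np.concatenate([matrix_a.entries, matrix_b.entries], axis=0)
    pooled_freq = combined.mean(axis=0)

    df = _empty_track(matrix_a)
    df["derived_freq"] = pooled_freq
    raw = np.full(matrix_a.n_sites, np.nan)
    reasons = np.full(matrix_a.n_sites, "ok", dtype=object)
    buf = _WalkBuffers(matrix_a)
    all_c = np.arange(combined.shape[0], dtype=np.int64)
    carriers_a = np.arange(matrix_a.n_haplotypes, dtype=np.int64)
    carriers_b = np.arange(matrix_b.n_haplotypes, dtype=np.int64)
    for j in range(matrix_a.n_sites):
        if maf_min is not None and min(pooled_freq[j], 1 - pooled_freq[j]) < maf_min:
            reasons[j] = "low-maf"
            continue
        core_pos = buf.positions[j]
        # combined walk sets the integration boundary in both directions
        steps = []
        skip = None
        for step in (-1, +1):
            count, status = buf.walk(combined, all_c, j, cutoff, max_gap, step)
            if status == "edge" and not trunc_ok:
                skip = "edge"
                break
            if status == "gap":
                skip = "max_gap"
                break
            # extents with combined EHH >= cutoff contribute trapezoids;
            # an edge-truncated arm contributes every extent it reached
            steps.append(count - 1 if status == "cutoff" else count)
        if skip:
            reasons[j] = skip
            continue
        area_a = _bounded_area(matrix_a.entries, buf, carriers_a, j, core_pos, steps)
        area_b = _bounded_area(matrix_b.entries, buf, carriers_b, j, core_pos, steps)
        if area_a <= 0.0 or area_b <= 0.0:
            reasons[j] = "zero-area"
            continue
        raw[j] = np.log(area_a / area_b)
    df["raw"], df["reason"] = raw, reasons
    return ScoreTrack(
        "xpEHH", df, populations=(matrix_a.population, matrix_b.population)
    )


def _bounded_area(
    entries: np.ndarray,
    buf: _WalkBuffers,
    carriers: np.ndarray,
    core: int,
    core_pos: float,
    steps: list[int],
) -> float:
    """One population's iHH over a fixed per-arm number of extents.

    Within the combined-EHH boundary every trapezoid contributes, whatever
    the population's own EHH value.
    """
    area = 0.0
    for step, n_steps in zip((-1, +1), steps):
        if n_steps <= 0:
            continue
        kernels.walk_fixed(
            entries, buf.positions, carriers, core, n_steps, step,
            buf.pos, buf.ehh,
        )
        area += buf.arm_area(core_pos, n_steps, cutoff=-np.inf)
    return area


def standardize(
    track: ScoreTrack,
    n_bins: int = 100,
    bin_variable: str = "derived_freq",
    min_per_bin: int = 20,
) -> ScoreTrack:
    """Standardize raw scores within derived-allele-frequency bins.

    Bins partition [0, 1] into ``n_bins`` equal widths on the core SNP's
    derived allele frequency; ``bin_variable="none"`` uses a single
    genome-wide bin. Occupied bins with fewer than ``min_per_bin`` defined
    scores are merged with their nearest neighbor. Standardization uses
    population moments (divide by n), so each bin's sample mean/variance of
    the standardized scores are exactly 0 and 1. Bins with zero variance
    yield undefined standardized scores.
    """
    df = track.data.copy()
    defined = df["raw"].notna().to_numpy()
    std = np.full(len(df), np.nan)
    if bin_variable == "none":
        bin_of = np.zeros(len(df), dtype=np.int64)
    elif bin_variable == "derived_freq":
        freq = df["derived_freq"].to_numpy()
        bin_of = np.clip((freq * n_bins).astype(np.int64), 0, n_bins - 1)
    else:
        raise ValueError(f"unknown bin_variable {bin_variable!r}")

    occupied = np.unique(bin_of[defined])
    counts = {b: int(((bin_of == b) & defined).sum()) for b in occupied}
    groups = _merge_sparse_bins(list(occupied), counts, min_per_bin)

    rows = []
    group_of = {}
    for gid, bins in enumerate(groups):
        for b in bins:
            group_of[b] = gid
    gid_arr = np.array([group_of.get(b, -1) for b in bin_of])
    for gid, bins in enumerate(groups):
        mask = defined & (gid_arr == gid)
        vals = df.loc[mask, "raw"].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=0))
        rows.append(
            {
                "bins": ",".join(str(b) for b in bins),
                "n": int(mask.sum()),
                "mean": mean,
                "sd": sd,
            }
        )
        if sd > 0:
            std[mask] = (df.loc[mask, "raw"].to_numpy() - mean) / sd
    df["standardized"] = std
    return ScoreTrack(
        track.statistic,
        df,
        populations=track.populations,
        bin_table=pd.DataFrame(rows),
    )


def _merge_sparse_bins(
    occupied: list[int], counts: dict[int, int], min_per_bin: int
) -> list[list[int]]:
    """Greedily merge adjacent occupied bins until every group reaches
    ``min_per_bin`` (the final group is folded into its neighbor if short)."""
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_n = 0
    for b in occupied:
        cur.append(b)
        cur_n += counts[b]
        if cur_n >= min_per_bin:
            groups.append(cur)
            cur, cur_n = [], 0
    if cur:
        if groups:
            groups[-1].extend(cur)
        else:
            groups.append(cur)
    return groups
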