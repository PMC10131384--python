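"""Phased-genotype, panel, and region I/O.

Reads phased diploid VCFs into per-population binary haplotype matrices,
polarizes alleles against the ancestral-allele (INFO/AA) annotation, applies
the minor-allele-frequency filter, and annotates sites against BED regions.

Coordinate conventions: VCF positions are 1-based; BED intervals are 0-based
half-open. The conversion happens only inside :func:`annotate_regions`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "ancestral"]


class PopIOError(ValueError):
    """Raised on malformed genotype, panel, or region input."""


@dataclass
class HaplotypeMatrix:
    """Binary phased haplotypes for one population.

    Parameters
    ----------
    entries : ndarray of shape (n_haplotypes, n_sites), dtype uint8
        0/1 allele codes. Before polarization 1 means the ALT allele;
        after :func:`polarize_by_ancestral` 1 means the derived allele.
    sites : DataFrame with columns chrom, pos, ref, alt, ancestral
        Ordered site table; ``pos`` is 1-based and strictly increasing
        within a chromosome.
    sample_ids : list of str
        Diploid sample names; haplotype rows 2i and 2i+1 belong to sample i.
    population : str
        Population label.
    polarized : bool
        True once entries are coded ancestral(0)/derived(1).
    """

    entries: np.ndarray
    sites: pd.DataFrame
    sample_ids: list[str]
    population: str
    polarized: bool = False

    def __post_init__(self) -> None:
        self.entries = np.ascontiguousarray(self.entries, dtype=np.uint8)
        if self.entries.ndim != 2:
            raise PopIOError("entries must be 2-dimensional")
        if self.entries.shape[0] != 2 * len(self.sample_ids):
            raise PopIOError(
                f"{self.entries.shape[0]} haplotypes for "
                f"{len(self.sample_ids)} diploid samples"
            )
        if self.entries.shape[1] != len(self.sites):
            raise PopIOError("entries/sites length mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_sites(self) -> int:
        return self.entries.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def derived_freq(self) -> np.ndarray:
        """Per-site frequency of the 1-coded allele in this population."""
        return self.entries.mean(axis=0)

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        """Column subset preserving order."""
        return replace(
            self,
            entries=self.entries[:, index],
            sites=self.sites.iloc[index].reset_index(drop=True),
        )


@dataclass
class RegionSet:
    """Sorted, merged half-open genomic intervals (BED semantics)."""

    intervals: pd.DataFrame  # columns chrom, start, end
    label: str = "regions"

    def __post_init__(self) -> None:
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            raise PopIOError("region with start >= end")
        self.intervals = _merge_intervals(df)

    @classmethod
    def from_bed(cls, path, label: str = "regions") -> "RegionSet":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        return cls(df, label=label)


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    out = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # touching intervals merge too
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def read_panel(path) -> dict[str, str]:
    """Read a two-column sample→population TSV into a dict."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1],
        names=["sample", "population"], dtype=str,
    )
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise PopIOError(f"duplicate sample in panel: {dup}")
    return dict(zip(df["sample"], df["population"]))


_SNP_ALLELES = frozenset("ACGT")


def read_phased_vcf(
    vcf_path,
    panel: dict[str, str],
    populations: list[str] | None = None,
) -> dict[str, HaplotypeMatrix]:
    """Read a phased diploid VCF into one HaplotypeMatrix per population.

    Indels and multi-allelic records are dropped. All matrices share an
    identical site list. Entries are ALT-coded (1 = ALT allele) and not yet
    polarized; the INFO/AA value, if present, is carried in the site table.

    Raises
    ------
    PopIOError
        If a panel sample is absent from the VCF or any retained genotype
        is unphased or missing.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    vcf_samples = list(vcf.samples)
    missing = [s for s in panel if s not in vcf_samples]
    if missing:
        raise PopIOError(f"panel sample absent from VCF: {missing[0]}")
    if populations is None:
        populations = sorted(set(panel.values()))

    sample_col = {s: i for i, s in enumerate(vcf_samples)}
    pop_samples = {
        p: [s for s, q in panel.items() if q == p] for p in populations
    }
    for p, samples in pop_samples.items():
        if not samples:
            raise PopIOError(f"population {p!r} has no samples in the panel")

    site_rows = []
    columns: list[np.ndarray] = []
    n_dropped_nonsnp = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_dropped_nonsnp += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            n_dropped_nonsnp += 1  # indel or symbolic allele
            continue
        gts = np.asarray(var.genotype.array())  # (n_samples, ploidy+1)
        if gts.shape[1] != 3:
            raise PopIOError(f"non-diploid genotype at {var.CHROM}:{var.POS}")
        alleles = gts[:, :2]
        phased = gts[:, 2]
        if (alleles < 0).any():
            bad = vcf_samples[int(np.argmax((alleles < 0).any(axis=1)))]
            raise PopIOError(
                f"missing genotype at {var.CHROM}:{var.POS} sample {bad}"
            )
        het = alleles[:, 0] != alleles[:, 1]
        if (het & (phased == 0)).any():
            bad = vcf_samples[int(np.argmax(het & (phased == 0)))]
            raise PopIOError(
                f"unphased genotype at {var.CHROM}:{var.POS} sample {bad}"
            )
        aa = var.INFO.get("AA")
        site_rows.append((var.CHROM, var.POS, ref, alt, aa if aa else None))
        columns.append(alleles.astype(np.uint8).reshape(-1))

    if n_dropped_nonsnp:
        logger.info("dropped %d non-SNP/multi-allelic records", n_dropped_nonsnp)
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(vcf_samples), 0), dtype=np.uint8)
    )  # rows: sample-major haplotypes

    out = {}
    for pop in populations:
        rows = []
        for s in pop_samples[pop]:
            rows.extend((2 * sample_col[s], 2 * sample_col[s] + 1))
        out[pop] = HaplotypeMatrix(
            entries=geno[rows, :],
            sites=sites.copy(),
            sample_ids=pop_samples[pop],
            population=pop,
        )
    return out


@dataclass
class PolarizationReport:
    """Site attrition during ancestral-allele polarization."""

    n_input: int = 0
    n_retained: int = 0
    n_missing_aa: int = 0
    n_low_confidence: int = 0
    n_mismatch: int = 0


def polarize_by_ancestral(
    matrix: HaplotypeMatrix,
    *,
    keep_low_confidence: bool = False,
) -> tuple[HaplotypeMatrix, PolarizationReport]:
    """Recode entries so 1 means the derived (non-ancestral) allele.

    Sites whose ancestral allele is missing, low-confidence (lowercase AA,
    unless ``keep_low_confidence``), or equal to neither REF nor ALT are
    excluded and counted in the report.
    """
    report = PolarizationReport(n_input=matrix.n_sites)
    keep = np.zeros(matrix.n_sites, dtype=bool)
    flip = np.zeros(matrix.n_sites, dtype=bool)
    for j, (ref, alt, aa) in enumerate(
        zip(matrix.sites["ref"], matrix.sites["alt"], matrix.sites["ancestral"])
    ):
        if aa is None or (isinstance(aa, float) and np.isnan(aa)) or aa == "":
            report.n_missing_aa += 1
            continue
        aa = str(aa).split("|")[0]  # 1000G-style AA|REF|ALT|IndelType payload
        if aa in (".", "-", "N"):
            report.n_missing_aa += 1
            continue
        if aa != aa.upper() and not keep_low_confidence:
            report.n_low_confidence += 1
            continue
        aa = aa.upper()
        if aa == ref:
            keep[j] = True
        elif aa == alt:
            keep[j], flip[j] = True, True
        else:
            report.n_mismatch += 1
    report.n_retained = int(keep.sum())

    entries = matrix.entries.copy()
    entries[:, flip] ^= 1
    sites = matrix.sites.copy()
    # record the derived allele orientation in the site table
    anc = np.where(flip, sites["alt"], sites["ref"])
    der = np.where(flip, sites["ref"], sites["alt"])
    sites["ancestral"] = anc
    sites["derived"] = der
    polarized = replace(matrix, entries=entries, sites=sites, polarized=True)
    idx = np.flatnonzero(keep)
    out = polarized.take_sites(idx)
    if report.n_retained < report.n_input:
        logger.info(
            "polarization: %d/%d sites retained (%d missing AA, %d low-conf, "
            "%d AA mismatch)",
            report.n_retained, report.n_input, report.n_missing_aa,
            report.n_low_confidence, report.n_mismatch,
        )
    return out, report


def filter_maf(matrix: HaplotypeMatrix, maf_min: float = 0.05) -> HaplotypeMatrix:
    """Keep sites with minor allele frequency >= ``maf_min`` (inclusive).

    Frequency is computed within the matrix's own population.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise PopIOError(f"maf_min must be in [0, 0.5], got {maf_min}")
    # compare in allele counts so the inclusive >= boundary is float-exact
    counts = matrix.entries.sum(axis=0, dtype=np.int64)
    n = matrix.n_haplotypes
    minor = np.minimum(counts, n - counts)
    keep = minor >= maf_min * n - 1e-9
    return matrix.take_sites(np.flatnonzero(keep))


def annotate_regions(sites: pd.DataFrame, regions: RegionSet) -> np.ndarray:
    """Boolean flag per site: does its 0-based position fall in a region?

    A 1-based VCF position ``pos`` is inside the half-open interval
    ``[start, end)`` iff ``start <= pos - 1 < end``.
    """
    sites = sites.reset_index(drop=True)
    flags = np.zeros(len(sites), dtype=bool)
    by_chrom = dict(tuple(regions.intervals.groupby("chrom", sort=False)))
    for chrom, grp in sites.groupby("chrom", sort=False):
        ivals = by_chrom.get(chrom)
        if ivals is None:
            logger.info("no %s intervals for chromosome %s", regions.label, chrom)
            continue
        starts = ivals["start"].to_numpy()
        ends = ivals["end"].to_numpy()
        pos0 = grp["pos"].to_numpy() - 1
        # intervals are merged+sorted: the candidate interval is the last
        # one starting at or before pos0
        k = np.searchsorted(starts, pos0, side="right") - 1
        ok = k >= 0
        inside = np.zeros(len(pos0), dtype=bool)
        inside[ok] = pos0[ok] < ends[k[ok]]
        flags[grp.index.to_numpy()] = inside
    return flags
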