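"""End-to-end orchestration: haplotype scans -> differentiation -> decision.

``run_pipeline`` takes per-population polarized haplotype matrices sharing
one site list and executes the full two-level scan: per-population iHS,
pairwise xpEHH, pairwise Weir–Cockerham F_ST with frequency-binned outlier
thresholds, PBS per (test, sister, outgroup) triplet, 51-SNP window
clustering of haplotype scores, and the intersection decision rule. Every
empirical threshold used along the way is collected into a thresholds
report, and all outputs are deterministic functions of the inputs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import diffstats, haplostats, popio, scan

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Tunable thresholds of the selection scan (defaults follow the
    study design: MAF >= 0.05, |score| > 2 in 51-SNP windows, top-1%
    windows, top-5% binned F_ST, top-5% PBS)."""

    populations: tuple[str, ...] = ()
    outgroup: Optional[str] = None
    focal_only: Optional[str] = None  # restrict scans/decision to one pop
    maf_min: float = 0.05
    ehh_cutoff: float = 0.05
    max_gap: float = 200_000.0
    ihs_bins: int = 100
    xpehh_bins: int = 0  # 0 = single genome-wide bin
    min_per_bin: int = 20
    window_size: int = 51
    score_cutoff: float = 2.0
    window_quantile: float = 0.01
    fst_quantile: float = 0.05
    fst_bin_width: float = 0.1
    pbs_quantile: float = 0.05
    fst_min_pairs: int = 2
    pbs_strict: bool = False
    window_policy: str = "rank"

    def __post_init__(self) -> None:
        for q in (self.window_quantile, self.fst_quantile, self.pbs_quantile):
            if not 0 < q < 1:
                raise ValueError("quantiles must be in (0, 1)")
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")

    def to_flat_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = ",".join(self.populations)
        return d


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    thresholds: pd.DataFrame
    sites: pd.DataFrame
    exonic: np.ndarray
    ihs_tracks: dict = field(default_factory=dict)
    xpehh_tracks: dict = field(default_factory=dict)
    fst_tracks: dict = field(default_factory=dict)
    pbs_comparisons: list = field(default_factory=list)
    config: Optional[ScanConfig] = None


def _align_to_shared(
    shared_pos: np.ndarray, track_pos: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Scatter per-track values back onto the shared site list."""
    out = np.zeros(shared_pos.size, dtype=values.dtype)
    idx = np.searchsorted(shared_pos, track_pos)
    if not np.array_equal(shared_pos[idx], track_pos):
        raise ValueError("track sites are not a subset of the shared list")
    out[idx] = values
    return out


def run_pipeline(
    matrices: Mapping[str, popio.HaplotypeMatrix],
    config: ScanConfig,
    regions: Optional[popio.RegionSet] = None,
    associations: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run the full two-level scan and return the candidate table.

    ``matrices`` are polarized per-population haplotype matrices sharing one
    site list (as produced by popio.read_phased_vcf + polarize, or by the
    simulator). ``regions`` restricts final calls to exonic SNPs; when
    omitted, every site counts as exonic.
    """
    pops = tuple(config.populations) or tuple(matrices)
    for p in pops:
        if p not in matrices:
            raise ValueError(f"population {p!r} missing from matrices")
    first = matrices[pops[0]]
    shared_pos = first.positions
    for p in pops[1:]:
        if not np.array_equal(matrices[p].positions, shared_pos):
            raise ValueError("matrices do not share a site list")

    sites = first.sites
    exonic = (
        popio.annotate_regions(sites, regions)
        if regions is not None
        else np.ones(len(sites), dtype=bool)
    )
    scan_pops = [config.focal_only] if config.focal_only else list(pops)
    thresholds: list[dict] = []

    # --- haplotype level: iHS within populations -------------------------
    ihs_tracks, ihs_hits = {}, {}
    for pop in scan_pops:
        filtered = popio.filter_maf(matrices[pop], config.maf_min)
        track = haplostats.ihs_scan(
            filtered, cutoff=config.ehh_cutoff, max_gap=config.max_gap
        )
        track = haplostats.standardize(
            track, n_bins=config.ihs_bins, min_per_bin=config.min_per_bin
        )
        windows = scan.window_counts(
            track, config.window_size, config.score_cutoff
        )
        qualifying, thr = scan.top_window_flags(
            windows, config.window_quantile, policy=config.window_policy
        )
        hits = scan.haplotype_hits(track, qualifying, config.score_cutoff)
        ihs_tracks[pop] = track
        ihs_hits[pop] = _align_to_shared(
            shared_pos, track.data["pos"].to_numpy(), hits
        )
        thresholds.append(
            {"stage": "ihs_windows", "name": pop, "value": thr}
        )
        logger.info("iHS %s: %d/%d hit SNPs", pop, hits.sum(), len(hits))

    # --- haplotype level: xpEHH between populations ----------------------
    if config.focal_only:
        xp_pairs = [
            (config.focal_only, q) for q in pops if q != config.focal_only
        ]
    else:
        xp_pairs = list(itertools.combinations(pops, 2))
    xpehh_tracks, xp_hits, xp_scores = {}, {}, {}
    for pa, pb in xp_pairs:
        track = haplostats.xpehh_scan(
            matrices[pa],
            matrices[pb],
            cutoff=config.ehh_cutoff,
            max_gap=config.max_gap,
            maf_min=config.maf_min,
        )
        track = haplostats.standardize(
            track,
            n_bins=config.xpehh_bins or 1,
            bin_variable="none" if not config.xpehh_bins else "derived_freq",
            min_per_bin=config.min_per_bin,
        )
        windows = scan.window_counts(
            track, config.window_size, config.score_cutoff
        )
        qualifying, thr = scan.top_window_flags(
            windows, config.window_quantile, policy=config.window_policy
        )
        hits = scan.haplotype_hits(track, qualifying, config.score_cutoff)
        xpehh_tracks[(pa, pb)] = track
        xp_hits[(pa, pb)] = hits
        xp_scores[(pa, pb)] = track.data["standardized"].to_numpy()
        thresholds.append(
            {"stage": "xpehh_windows", "name": f"{pa}-{pb}", "value": thr}
        )

    # --- differentiation level: F_ST and PBS -----------------------------
    fst_pairs = list(itertools.combinations(pops, 2))
    fst_tracks, fst_flags = {}, {}
    for pa, pb in fst_pairs:
        track = diffstats.fst_scan(matrices[pa], matrices[pb])
        flags, bin_table = diffstats.binned_fst_flags(
            track,
            bin_width=config.fst_bin_width,
            quantile=config.fst_quantile,
            min_per_bin=config.min_per_bin,
        )
        fst_tracks[(pa, pb)] = track
        fst_flags[(pa, pb)] = flags
        for row in bin_table.itertuples():
            thresholds.append(
                {
                    "stage": "fst_bins",
                    "name": f"{pa}-{pb}:[{row.maf_lo:.2f},{row.maf_hi:.2f})",
                    "value": row.threshold,
                }
            )

    pbs_comps = []
    pbs_tests = [p for p in scan_pops if p != config.outgroup]
    if config.outgroup is not None:
        for test in pbs_tests:
            for sister in pops:
                if sister in (test, config.outgroup):
                    continue
                comp = diffstats.pbs(
                    fst_tracks[_key(fst_tracks, test, sister)],
                    fst_tracks[_key(fst_tracks, test, config.outgroup)],
                    fst_tracks[_key(fst_tracks, sister, config.outgroup)],
                    test=test,
                    sister=sister,
                    outgroup=config.outgroup,
                )
                flags, thr = diffstats.pbs_top_flags(
                    comp.data["pbs"], config.pbs_quantile
                )
                pbs_comps.append((comp, flags))
                thresholds.append(
                    {
                        "stage": "pbs",
                        "name": f"{test}|{sister}|{config.outgroup}",
                        "value": thr,
                    }
                )

    # --- decision ---------------------------------------------------------
    candidates = scan.decide(
        sites,
        ihs_hits,
        xp_hits,
        xp_scores,
        fst_flags,
        pbs_comps,
        exonic,
        fst_min_pairs=config.fst_min_pairs,
        pbs_strict=config.pbs_strict,
    )
    candidates = scan.annotate(candidates, associations)
    return PipelineResult(
        candidates=candidates,
        thresholds=pd.DataFrame(thresholds, columns=["stage", "name", "value"]),
        sites=sites,
        exonic=exonic,
        ihs_tracks=ihs_tracks,
        xpehh_tracks=xpehh_tracks,
        fst_tracks=fst_tracks,
        pbs_comparisons=pbs_comps,
        config=config,
    )


def _key(d: dict, a: str, b: str) -> tuple[str, str]:
    if (a, b) in d:
        return (a, b)
    if (b, a) in d:
        return (b, a)
    raise KeyError((a, b))


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write candidate and threshold TSVs with the resolved config echoed
    in '#' header lines, so a run is reproducible from its outputs."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    header = "".join(
        f"# {k}={v}\n" for k, v in (result.config.to_flat_dict().items())
    )
    with open(os.path.join(out_dir, "candidates.tsv"), "w") as fh:
        fh.write(header)
        result.candidates.to_csv(fh, sep="\t", index=False, na_rep="NA")
    with open(os.path.join(out_dir, "thresholds.tsv"), "w") as fh:
        fh.write(header)
        result.thresholds.to_csv(fh, sep="\t", index=False, na_rep="NA")
    for pop, track in result.ihs_tracks.items():
        track.to_tsv(os.path.join(out_dir, f"ihs_{pop}.tsv"))
    for (pa, pb), track in result.xpehh_tracks.items():
        track.to_tsv(os.path.join(out_dir, f"xpehh_{pa}_{pb}.tsv"))
    for (pa, pb), track in result.fst_tracks.items():
        track.to_tsv(os.path.join(out_dir, f"fst_{pa}_{pb}.tsv"))
    for comp, flags in result.pbs_comparisons:
        path = os.path.join(
            out_dir, f"pbs_{comp.test}_{comp.sister}_{comp.outgroup}.tsv"
        )
        df = comp.data.copy()
        df["pbs_high"] = flags
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
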