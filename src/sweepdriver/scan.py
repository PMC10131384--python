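"""Window-based outlier clustering and the candidate decision rule.

Under a sweep, SNPs with large |standardized haplotype score| cluster
together, so single-SNP exceedances are corroborated by their neighborhood:
sliding windows of ``window_size`` consecutive scored SNPs (step 1, per
chromosome) are ranked by their count of |score| > score_cutoff SNPs, and
only SNPs that both exceed the cutoff and sit inside a top-quantile window
count as haplotype-test hits.

The final decision intersects evidence streams per SNP and population:

    final_call = (iHS hit or xpEHH hit) and high F_ST and exonic

PBS corroboration is attached for reporting (``pbs_high``); it vetoes a
candidate only in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .diffstats import PbsComparison
from .haplostats import ScoreTrack

DEFAULT_WINDOW_SIZE = 51
DEFAULT_SCORE_CUTOFF = 2.0
DEFAULT_WINDOW_QUANTILE = 0.01


@dataclass
class WindowSummary:
    """One sliding window of scored SNPs and its exceedance count."""

    chrom: str
    index: int
    first: int  # inclusive indices among the chromosome's scored SNPs
    last: int
    span_bp: int
    count: int
    truncated: bool = False


def window_counts(
    track: ScoreTrack,
    window_size: int = DEFAULT_WINDOW_SIZE,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> list[WindowSummary]:
    """Sliding-window exceedance counts over the scored SNPs of a track.

    Windows hold ``window_size`` consecutive scored (standardized-defined)
    SNPs and slide by one SNP within each chromosome. A chromosome with
    fewer scored SNPs than the window size yields a single truncated,
    flagged window.
    """
    if window_size % 2 == 0 or window_size < 1:
        raise ValueError("window_size must be odd and positive")
    out: list[WindowSummary] = []
    df = track.data
    scored = df[df["standardized"].notna()]
    for chrom, grp in scored.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        exceed = (np.abs(grp["standardized"].to_numpy()) > score_cutoff).astype(
            np.int64
        )
        n = len(grp)
        if n == 0:
            continue
        if n < window_size:
            out.append(
                WindowSummary(
                    chrom=str(chrom),
                    index=0,
                    first=0,
                    last=n - 1,
                    span_bp=int(pos[-1] - pos[0]),
                    count=int(exceed.sum()),
                    truncated=True,
                )
            )
            continue
        csum = np.concatenate([[0], np.cumsum(exceed)])
        for w in range(n - window_size + 1):
            hi = w + window_size - 1
            out.append(
                WindowSummary(
                    chrom=str(chrom),
                    index=w,
                    first=w,
                    last=hi,
                    span_bp=int(pos[hi] - pos[w]),
                    count=int(csum[hi + 1] - csum[w]),
                )
            )
    return out


def top_window_flags(
    summaries: Sequence[WindowSummary],
    quantile: float = DEFAULT_WINDOW_QUANTILE,
    policy: str = "rank",
) -> tuple[list[WindowSummary], float]:
    """Top-quantile windows by exceedance count, pooled genome-wide.

    ``policy="rank"`` (default): the threshold is the k-th largest count
    with k = ceil(quantile * n_windows); a window qualifies iff its count
    reaches the threshold (ties included) and is positive. On a long-tailed
    genome-wide count distribution this matches the percentile rule; unlike
    it, the most extreme windows still qualify when the outlier cluster
    itself spans more than ``quantile`` of all windows (small scans).

    ``policy="strict-percentile"``: threshold = empirical (1 - quantile)
    percentile of the counts, qualify iff strictly above it; a degenerate
    (all-equal) distribution qualifies nothing.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if not summaries:
        return [], float("nan")
    counts = np.array([w.count for w in summaries], dtype=float)
    if policy == "rank":
        k = max(1, int(np.ceil(quantile * counts.size)))
        thr = float(np.sort(counts)[-k])
        qualifying = [w for w in summaries if w.count >= thr and w.count > 0]
    elif policy == "strict-percentile":
        thr = float(np.quantile(counts, 1.0 - quantile))
        qualifying = [w for w in summaries if w.count > thr]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return qualifying, thr


def haplotype_hits(
    track: ScoreTrack,
    qualifying: Sequence[WindowSummary],
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> np.ndarray:
    """Per-SNP hit flags: |standardized| > cutoff AND inside a top window.

    Returned flags align with ``track.data`` rows.
    """
    df = track.data
    flags = np.zeros(len(df), dtype=bool)
    scored_mask = df["standardized"].notna().to_numpy()
    std = df["standardized"].to_numpy()
    chroms = df["chrom"].to_numpy()

    # map window (chrom, scored-index range) back to track rows
    for chrom in pd.unique(df["chrom"]):
        rows = np.flatnonzero((chroms == chrom) & scored_mask)
        in_window = np.zeros(rows.size, dtype=bool)
        for w in qualifying:
            if w.chrom == str(chrom):
                in_window[w.first : w.last + 1] = True
        exceed = np.abs(std[rows]) > score_cutoff
        flags[rows] = exceed & in_window
    return flags


def decide(
    sites: pd.DataFrame,
    ihs_hits: Mapping[str, np.ndarray],
    xpehh_hits: Mapping[tuple[str, str], np.ndarray],
    xpehh_scores: Mapping[tuple[str, str], np.ndarray],
    fst_flags: Mapping[tuple[str, str], np.ndarray],
    pbs_comparisons: Sequence[tuple[PbsComparison, np.ndarray]],
    exonic: np.ndarray,
    fst_min_pairs: int = 1,
    pbs_strict: bool = False,
) -> pd.DataFrame:
    """Intersect the evidence streams into the candidate table.

    All inputs are aligned on ``sites`` rows. ``ihs_hits`` maps population
    -> flags; ``xpehh_hits``/``xpehh_scores`` map ordered population pairs
    -> flags / standardized scores (a hit is attributed to the population
    on the positive side of the score); ``fst_flags`` maps unordered pairs
    -> high-F_ST flags; ``pbs_comparisons`` pairs each PbsComparison with
    its top-PBS flags. A population's F_ST requirement is met when the site
    is flagged in at least ``fst_min_pairs`` pairwise comparisons involving
    it. ``final_call = (ihs or xpehh) and fst_high and exonic``; PBS
    discordance is reported (``pbs_high`` False) and vetoes only when
    ``pbs_strict``.

    Returns one row per (site, population) with any evidence.
    """
    n = len(sites)
    populations = sorted(
        set(ihs_hits)
        | {p for pair in xpehh_hits for p in pair}
        | {p for pair in fst_flags for p in pair}
    )
    zero = np.zeros(n, dtype=bool)

    rows = []
    for pop in populations:
        ihs_flag = np.asarray(ihs_hits.get(pop, zero), dtype=bool)
        xp_flag = zero.copy()
        for (pa, pb), hits in xpehh_hits.items():
            score = np.asarray(xpehh_scores[(pa, pb)], dtype=float)
            hits = np.asarray(hits, dtype=bool)
            with np.errstate(invalid="ignore"):
                if pop == pa:
                    xp_flag = xp_flag | (hits & (score > 0))
                elif pop == pb:
                    xp_flag = xp_flag | (hits & (score < 0))
        n_fst = np.zeros(n, dtype=np.int64)
        involved = False
        for pair, flags in fst_flags.items():
            if pop in pair:
                involved = True
                n_fst += np.asarray(flags, dtype=bool)
        fst_high = n_fst >= fst_min_pairs if involved else zero
        pbs_val = np.full(n, np.nan)
        pbs_high = zero.copy()
        for comp, flags in pbs_comparisons:
            if comp.test == pop:
                vals = comp.data["pbs"].to_numpy(dtype=float)
                take = np.isnan(pbs_val) | (vals > pbs_val)
                take &= np.isfinite(vals)
                pbs_val[take] = vals[take]
                pbs_high = pbs_high | np.asarray(flags, dtype=bool)

        final = (ihs_flag | xp_flag) & fst_high & np.asarray(exonic, dtype=bool)
        if pbs_strict:
            final = final & pbs_high
        keep = ihs_flag | xp_flag | final
        for i in np.flatnonzero(keep):
            rows.append(
                {
                    "chrom": sites["chrom"].iloc[i],
                    "pos": int(sites["pos"].iloc[i]),
                    "population": pop,
                    "ihs_hit": bool(ihs_flag[i]),
                    "xpehh_hit": bool(xp_flag[i]),
                    "fst_high": bool(fst_high[i]),
                    "pbs": float(pbs_val[i]),
                    "pbs_high": bool(pbs_high[i]),
                    "exonic": bool(exonic[i]),
                    "final_call": bool(final[i]),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "population", "ihs_hit", "xpehh_hit",
            "fst_high", "pbs", "pbs_high", "exonic", "final_call",
        ],
    )
    return out


def annotate(
    candidates: pd.DataFrame, associations: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Left-join candidate SNPs against a SNP->(gene, cancer types) table.

    ``associations`` needs columns chrom, pos, gene, cancer_types. Unmatched
    candidates keep empty annotations; duplicate association keys are all
    kept (one candidate row per match) with a warning.
    """
    out = candidates.copy()
    if associations is None or len(associations) == 0:
        out["gene"] = ""
        out["cancer_types"] = ""
        return out
    assoc = associations[["chrom", "pos", "gene", "cancer_types"]].copy()
    if assoc.duplicated(["chrom", "pos"]).any():
        import warnings

        warnings.warn("duplicate association keys; keeping all", stacklevel=2)
    assoc["chrom"] = assoc["chrom"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    merged = out.merge(assoc, on=["chrom", "pos"], how="left")
    merged["gene"] = merged["gene"].fillna("")
    merged["cancer_types"] = merged["cancer_types"].fillna("")
    return merged
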