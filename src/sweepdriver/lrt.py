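"""Branch-site likelihood-ratio decision layer.

Consumes externally produced log-likelihood pairs from codon-model fits
(alternative model with a positively selected site class on the foreground
branch vs a null with that class's omega fixed at 1) and applies the
decision arithmetic: LRT statistic 2*(lnL_alt - lnL_null), a p-value from
the chi-square(1 df) null halved because the null distribution is a 50:50
mixture of chi-square(1) and a point mass at zero, and Bonferroni
correction across the gene family tested on each foreground branch.

The codon-model maximum-likelihood fitting itself is out of scope here; the
input is a TSV of (gene, branch, lnl_alt, lnl_null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LrtResult:
    gene: str
    branch: str
    lnl_alt: float
    lnl_null: float
    lrt_stat: float
    p_half: float
    p_adjusted: float
    omega: float | None = None  # pass-through from the external fit
    negative_stat: bool = False  # optimizer noise: lnL_alt < lnL_null


def lrt_stat(lnl_alt: float, lnl_null: float) -> float:
    """LRT statistic 2*(lnL_alt - lnL_null); finite inputs required.

    Slightly negative values (numerical optimizer noise) are returned
    as-is and flagged downstream rather than clamped.
    """
    if not (np.isfinite(lnl_alt) and np.isfinite(lnl_null)):
        raise ValueError("log-likelihoods must be finite")
    return 2.0 * (lnl_alt - lnl_null)


def mixture_pvalue(stat: float) -> float:
    """Half the chi-square(1 df) upper-tail probability at max(stat, 0).

    The null distribution of the branch-site LRT is a 50:50 mixture of a
    point mass at 0 and chi-square(1), so p = 0.5 * P(chi2_1 > stat);
    negative statistics clamp to 0 (p = 0.5).
    """
    if not np.isfinite(stat):
        raise ValueError("statistic must be finite")
    return 0.5 * float(stats.chi2.sf(max(stat, 0.0), df=1))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def lrt_table(
    table: pd.DataFrame,
    m: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the full decision layer to a (gene, branch, lnl_alt, lnl_null)
    table; Bonferroni family is per foreground branch across genes unless
    ``m`` overrides it. Adds lrt_stat, p_half, p_adjusted, significant."""
    out = table.copy()
    out["lrt_stat"] = [
        lrt_stat(a, b) for a, b in zip(out["lnl_alt"], out["lnl_null"])
    ]
    out["p_half"] = [mixture_pvalue(s) for s in out["lrt_stat"]]
    if m is not None:
        out["p_adjusted"] = bonferroni(out["p_half"].to_numpy(), m)
    else:
        out["p_adjusted"] = np.nan
        for _, idx in out.groupby("branch").groups.items():
            out.loc[idx, "p_adjusted"] = bonferroni(
                out.loc[idx, "p_half"].to_numpy()
            )
    out["significant"] = out["p_adjusted"] < alpha
    return out


def read_loglik_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "branch", "lnl_alt", "lnl_null"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"log-likelihood TSV lacks columns: {sorted(missing)}")
    return df
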