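"""Two-proportion Z test for comparing cancer incidence between populations.

With c_1/n_1 and c_2/n_2 cases over persons in two populations, the pooled
two-proportion statistic is

    Z = (c1/n1 - c2/n2) / sqrt( p*(1-p) * (1/n1 + 1/n2) ),   p = (c1+c2)/(n1+n2)

The signed statistic is retained (positive when population 1 has the higher
proportion); its absolute value matches the magnitude-only form, and the
two-sided p-value comes from the standard normal. Per-100,000 rates are
derived for display only — inputs are crude case/person counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class IncidenceRecord:
    population: str
    sex: str
    cases: int
    persons: int

    def __post_init__(self) -> None:
        if not 0 <= self.cases <= self.persons:
            raise ValueError("need 0 <= cases <= persons")

    @property
    def rate_per_100k(self) -> float:
        return 1e5 * self.cases / self.persons


@dataclass
class ZResult:
    z: float  # signed: positive when population 1 has the higher proportion
    p: float  # two-sided


def z_statistic(c1: int, n1: int, c2: int, n2: int) -> ZResult:
    """Pooled two-proportion Z statistic and two-sided normal p-value.

    Undefined (raises) when the pooled proportion is 0 or 1: the pooled
    variance vanishes and no comparison is possible.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("population sizes must be positive")
    if not (0 <= c1 <= n1 and 0 <= c2 <= n2):
        raise ValueError("case counts must lie in [0, n]")
    pooled = (c1 + c2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise ValueError("pooled proportion at the boundary; Z undefined")
    num = c1 / n1 - c2 / n2
    den = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = num / den
    return ZResult(z=float(z), p=float(2.0 * stats.norm.sf(abs(z))))


def compare_all(records: list[IncidenceRecord]) -> dict[str, pd.DataFrame]:
    """All pairwise Z tests per sex, as matrix-form tables.

    Returns one square DataFrame per sex with signed z above the diagonal,
    two-sided p below, and per-100,000 rates on the diagonal.
    """
    out: dict[str, pd.DataFrame] = {}
    for sex in sorted({r.sex for r in records}):
        recs = [r for r in records if r.sex == sex]
        labels = [r.population for r in recs]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate population labels for sex {sex!r}")
        if len(recs) < 2:
            raise ValueError(f"need >= 2 populations for sex {sex!r}")
        mat = pd.DataFrame(
            np.full((len(recs), len(recs)), np.nan), index=labels, columns=labels
        )
        for i, ri in enumerate(recs):
            mat.iloc[i, i] = ri.rate_per_100k
            for j in range(i + 1, len(recs)):
                rj = recs[j]
                res = z_statistic(ri.cases, ri.persons, rj.cases, rj.persons)
                mat.iloc[i, j] = res.z  # upper triangle: signed z
                mat.iloc[j, i] = res.p  # lower triangle: p
        out[sex] = mat
    return out


def read_incidence_tsv(path) -> list[IncidenceRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"population", "sex", "cases", "persons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"incidence TSV lacks columns: {sorted(missing)}")
    return [
        IncidenceRecord(
            population=str(r.population),
            sex=str(r.sex),
            cases=int(r.cases),
            persons=int(r.persons),
        )
        for r in df.itertuples()
    ]
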