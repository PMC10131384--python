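"""Bundled example input tables.

``branch_site_loglik`` — log-likelihood pairs from branch-site codon-model
fits (alternative vs omega2=1 null) for eight cancer driver genes tested on
the human lineage, the input contract of the :mod:`~sweepdriver.lrt` layer.

``thca_incidence`` — a synthetic crude-count reconstruction of thyroid
cancer incidence in four continental registry aggregates, back-derived from
published age-standardized rates per 100,000 (treated as crude) and registry
person totals split evenly by sex; it exercises the
:mod:`~sweepdriver.incidence` input contract and preserves the published
rate ordering, but is not registry microdata.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .incidence import IncidenceRecord, read_incidence_tsv
from .lrt import read_loglik_tsv


def _path(name: str):
    return resources.files("sweepdriver.data").joinpath(name)


def branch_site_loglik() -> pd.DataFrame:
    with resources.as_file(_path("branch_site_loglik.tsv")) as p:
        return read_loglik_tsv(p)


def thca_incidence() -> list[IncidenceRecord]:
    with resources.as_file(_path("thca_incidence_synthetic.tsv")) as p:
        return read_incidence_tsv(p)
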