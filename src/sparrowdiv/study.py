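"""Published summary tables of the Israeli house sparrow survey.

Fourteen genetic populations sampled south to north across a ~420 km
climatic gradient: pairwise geographic distances and microsatellite
differentiation (theta), the 18 capture localities with coordinates, the
population -> representative-locality mapping used for merged localities,
and the published P_ST - F_ST decision table.  These are observational
inputs transcribed from the survey's printed tables and shipped as package
data; nothing in them is computed by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import read_matrix_tsv
from .types import LocalityTable, PairwiseMatrix

#: F_ST upper 95% CI bounds from the survey (both sexes / males only)
FST_UPPER_CI_BOTH_SEXES = 0.016
FST_UPPER_CI_MALES = 0.024


def _path(name: str):
    return resources.files("sparrowdiv.data").joinpath(name)


def geographic_km() -> PairwiseMatrix:
    """Pairwise great-circle distances (km) between the 14 populations."""
    with resources.as_file(_path("pairwise_geo_km.tsv")) as p:
        return read_matrix_tsv(p)


def pairwise_fst() -> PairwiseMatrix:
    """Pairwise theta between the 14 populations (negative values as
    published; clip to zero before distance-based analyses)."""
    with resources.as_file(_path("pairwise_fst.tsv")) as p:
        return read_matrix_tsv(p)


def localities() -> LocalityTable:
    """The 18 capture localities (name, region, coordinates, altitude)."""
    with resources.as_file(_path("localities.csv")) as p:
        return LocalityTable(pd.read_csv(p))


def population_localities() -> dict[str, str]:
    """Population -> representative locality (first-listed of each merge)."""
    with resources.as_file(_path("population_localities.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["population"], df["locality"]))


def pst_fst_summary() -> pd.DataFrame:
    """Published per-trait P_ST (c = h2), 95% CI, critical c/h2, verdict."""
    with resources.as_file(_path("pst_fst_summary.csv")) as p:
        return pd.read_csv(p)
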