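"""Bundled reference tables from a two-year temporal SSR survey.

A longitudinal field survey of the diamondback moth *Plutella xylostella*
across Southern China and Southeast Asia: 48 population samples collected
over four sampling times (two per year), genotyped at 15 microsatellite
loci.  The raw genotypes are not redistributable, so the bundle carries the
published site metadata (coordinates, sample sizes, dates, time codes) and
the published per-population diversity metrics, which together support the
pipeline's bookkeeping and reporting layers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data import read_sites
from .diversity import DiversityRow


def _path(name: str):
    return resources.files("kinflow").joinpath("datasets", name)


def load_survey_sites() -> pd.DataFrame:
    """Site metadata for the 48 survey populations (sites CSV layout)."""
    with resources.as_file(_path("px_survey_sites.csv")) as p:
        return read_sites(p)


def load_survey_diversity() -> pd.DataFrame:
    """Published per-population diversity metrics (Na, Ne, I, Ho, He, Ar)."""
    with resources.as_file(_path("px_survey_diversity.csv")) as p:
        return pd.read_csv(p)


def survey_diversity_rows(time_code: int) -> list[DiversityRow]:
    """Diversity rows for one sampling time, as :class:`DiversityRow` objects."""
    df = load_survey_diversity()
    sub = df[df["time_code"] == time_code]
    if sub.empty:
        raise KeyError(f"no survey rows for time_code {time_code}")
    return [
        DiversityRow(r.population, r.na, r.ne, r.shannon, r.ho, r.he, ar=r.ar)
        for r in sub.itertuples()
    ]
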