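"""Data model and file I/O for temporally structured microsatellite genotypes.

Diploid individuals are typed at a shared panel of microsatellite (SSR) loci;
each call is an unordered pair of integer allele lengths (base pairs) or
missing.  Individuals are grouped into population samples that carry a site
name, decimal-degree coordinates, a sampling date and a sampling-time code
(1-4, two samplings per year over two consecutive years).

Supported exchange formats:

* GenAlEx codominant CSV (two allele columns per locus, ``0`` = missing);
* STRUCTURE two-row-per-individual text (one column per locus, ``-9`` =
  missing);
* a sites metadata CSV (population, site, latitude, longitude, sample_size,
  date, time_code).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal missing-data sentinel.  GenAlEx files use 0, STRUCTURE files -9;
#: both are mapped to ``None`` on read.
MISSING: None = None

Genotype = Optional[tuple[int, int]]  # sorted ascending, or None (missing)

VALID_TIME_CODES = (1, 2, 3, 4)


class FormatError(ValueError):
    """A file does not conform to its declared layout."""


class ConsistencyError(ValueError):
    """Header bookkeeping disagrees with the file body or dataset state."""


def make_genotype(a1: int, a2: int) -> Genotype:
    """Build a sorted genotype from two allele calls; (0, 0) maps to MISSING."""
    if a1 == 0 and a2 == 0:
        return MISSING
    if a1 == 0 or a2 == 0:
        raise FormatError(f"half-called genotype ({a1}, {a2}); both alleles or neither")
    if a1 < 0 or a2 < 0:
        raise FormatError(f"negative allele length ({a1}, {a2})")
    return (a1, a2) if a1 <= a2 else (a2, a1)


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker and the allele lengths observed at it."""

    name: str
    allele_universe: frozenset[int] = frozenset()


@dataclass
class Individual:
    id: str
    genotypes: dict[str, Genotype]

    def genotype(self, locus: str) -> Genotype:
        return self.genotypes.get(locus)


@dataclass
class PopulationSample:
    """Individuals collected at one site in one sampling-time interval."""

    code: str
    site_name: str
    latitude: float
    longitude: float
    time_code: int
    sampling_date: str
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.code}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.code}: longitude {self.longitude} out of range")
        if self.time_code not in VALID_TIME_CODES:
            raise ValueError(f"{self.code}: time_code {self.time_code} not in {VALID_TIME_CODES}")

    @property
    def size(self) -> int:
        return len(self.individuals)


@dataclass
class TemporalDataset:
    """A panel of loci plus population samples spanning one or more times."""

    loci: list[str]
    populations: list[PopulationSample]

    def __post_init__(self) -> None:
        codes = [p.code for p in self.populations]
        if len(set(codes)) != len(codes):
            dupes = [c for c, k in Counter(codes).items() if k > 1]
            raise ConsistencyError(f"duplicate population codes: {dupes}")
        lset = set(self.loci)
        for pop in self.populations:
            for ind in pop.individuals:
                extra = set(ind.genotypes) - lset
                if extra:
                    raise ConsistencyError(f"{ind.id}: genotypes at unknown loci {sorted(extra)}")

    # -- bookkeeping -------------------------------------------------------

    def individuals(self) -> Iterator[tuple[PopulationSample, Individual]]:
        for pop in self.populations:
            for ind in pop.individuals:
                yield pop, ind

    @property
    def n_individuals(self) -> int:
        return sum(p.size for p in self.populations)

    def population(self, code: str) -> PopulationSample:
        for pop in self.populations:
            if pop.code == code:
                return pop
        raise KeyError(code)

    def time_slice(self, time_code: int) -> "TemporalDataset":
        pops = [p for p in self.populations if p.time_code == time_code]
        return TemporalDataset(list(self.loci), pops)

    @property
    def time_codes(self) -> list[int]:
        return sorted({p.time_code for p in self.populations})

    def locus(self, name: str) -> Locus:
        if name not in self.loci:
            raise KeyError(name)
        alleles = frozenset(
            a for _, ind in self.individuals()
            for gt in [ind.genotype(name)] if gt is not None for a in gt
        )
        return Locus(name, alleles)

    def allele_matrix(self) -> tuple[list[str], list[str], np.ndarray]:
        """Return (ids, pop codes per individual, (n, n_loci, 2) array, -1 missing)."""
        ids, pops, rows = [], [], []
        for pop, ind in self.individuals():
            ids.append(ind.id)
            pops.append(pop.code)
            row = np.full((len(self.loci), 2), -1, dtype=np.int64)
            for j, loc in enumerate(self.loci):
                gt = ind.genotype(loc)
                if gt is not None:
                    row[j] = gt
            rows.append(row)
        arr = np.stack(rows) if rows else np.empty((0, len(self.loci), 2), dtype=np.int64)
        return ids, pops, arr


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class FreqCell:
    """Allele frequencies for one (population, locus) cell."""

    counts: dict[int, int]
    copies_sampled: int

    @property
    def empty(self) -> bool:
        return self.copies_sampled == 0

    @property
    def freqs(self) -> dict[int, float]:
        if self.empty:
            return {}
        n = self.copies_sampled
        return {a: c / n for a, c in sorted(self.counts.items())}


class AlleleFreqTable:
    """Per-(population, locus) allele counts/frequencies, with pooled access.

    Frequencies are computed over non-missing gene copies only;
    ``copies_sampled`` is twice the number of non-missing individuals.
    Cells with no data are flagged empty rather than treated as fatal.
    """

    def __init__(self, loci: Sequence[str], pop_codes: Sequence[str]):
        self.loci = list(loci)
        self.pop_codes = list(pop_codes)
        self._cells: dict[tuple[str, str], FreqCell] = {
            (p, l): FreqCell({}, 0) for p in pop_codes for l in loci
        }

    def cell(self, pop: str, locus: str) -> FreqCell:
        return self._cells[(pop, locus)]

    def freqs(self, pop: str, locus: str) -> dict[int, float]:
        return self.cell(pop, locus).freqs

    def pooled_cell(self, locus: str) -> FreqCell:
        counts: Counter[int] = Counter()
        copies = 0
        for p in self.pop_codes:
            c = self.cell(p, locus)
            counts.update(c.counts)
            copies += c.copies_sampled
        return FreqCell(dict(counts), copies)

    def pooled_freqs(self, locus: str) -> dict[int, float]:
        return self.pooled_cell(locus).freqs

    def empty_cells(self) -> list[tuple[str, str]]:
        return [k for k, c in self._cells.items() if c.empty]


def allele_frequencies(dataset: TemporalDataset) -> AlleleFreqTable:
    """Tabulate allele counts and frequencies for every (population, locus)."""
    table = AlleleFreqTable(dataset.loci, [p.code for p in dataset.populations])
    for pop in dataset.populations:
        for locus in dataset.loci:
            counts: Counter[int] = Counter()
            n_typed = 0
            for ind in pop.individuals:
                gt = ind.genotype(locus)
                if gt is None:
                    continue
                counts.update(gt)
                n_typed += 1
            table._cells[(pop.code, locus)] = FreqCell(dict(counts), 2 * n_typed)
    return table


# ---------------------------------------------------------------------------
# Dataset bookkeeping
# ---------------------------------------------------------------------------


class EmptyDatasetError(ValueError):
    pass


def filter_min_size(dataset: TemporalDataset, min_n: int = 10) -> TemporalDataset:
    """Drop populations with fewer than ``min_n`` individuals.

    Small samples carry too little pedigree information for kinship-based
    gene-flow inference, so downstream parentage analysis excludes them.
    Order is preserved and removals are logged.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    kept = [p for p in dataset.populations if p.size >= min_n]
    removed = [p.code for p in dataset.populations if p.size < min_n]
    if removed:
        logger.info("filter_min_size(min_n=%d): removed %s", min_n, removed)
    if not kept:
        raise EmptyDatasetError(f"no population has >= {min_n} individuals")
    return TemporalDataset(list(dataset.loci), kept)


def tabulate_by_time(data) -> pd.DataFrame:
    """Per-time-code population and individual counts, with a Total row.

    Accepts a :class:`TemporalDataset`, a sequence of
    :class:`PopulationSample`, or a DataFrame with ``time_code`` and
    ``sample_size`` columns (sites metadata).
    """
    if isinstance(data, TemporalDataset):
        recs = [(p.time_code, p.size) for p in data.populations]
    elif isinstance(data, pd.DataFrame):
        recs = list(zip(data["time_code"].astype(int), data["sample_size"].astype(int)))
    else:
        recs = [(p.time_code, p.size) for p in data]
    rows = []
    for t in sorted({t for t, _ in recs}):
        sizes = [n for tc, n in recs if tc == t]
        rows.append({"time_code": t, "n_populations": len(sizes), "n_individuals": sum(sizes)})
    out = pd.DataFrame(rows, columns=["time_code", "n_populations", "n_individuals"])
    total = pd.DataFrame(
        [{"time_code": "Total",
          "n_populations": int(out["n_populations"].sum()),
          "n_individuals": int(out["n_individuals"].sum())}]
    )
    return pd.concat([out, total], ignore_index=True)


# ---------------------------------------------------------------------------
# GenAlEx codominant CSV
# ---------------------------------------------------------------------------


def read_genalex(path, sites: Optional[pd.DataFrame] = None) -> TemporalDataset:
    """Read a GenAlEx codominant CSV into a :class:`TemporalDataset`.

    Layout: row 1 = n_loci, n_individuals, n_pops, pop sizes; row 2 = title
    then population names aligned with the sizes; row 3 = "Ind", "Pop",
    locus names (one per allele-column pair); data rows follow, two integer
    allele columns per locus, 0 = missing.

    ``sites`` (a DataFrame as returned by :func:`read_sites`) supplies
    coordinates and time codes; without it populations get placeholder
    coordinates and time_code 1.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise FormatError(f"{path}: fewer than 3 header rows")

    def _ints(cells, line_no):
        try:
            return [int(c) for c in cells]
        except ValueError as exc:
            raise FormatError(f"{path}, line {line_no}: non-integer header field ({exc})")

    head = [c for c in rows[0] if c.strip() != ""]
    if len(head) < 3:
        raise FormatError(f"{path}, line 1: expected n_loci, n_individuals, n_pops, sizes...")
    nums = _ints(head, 1)
    n_loci, n_ind, n_pops = nums[0], nums[1], nums[2]
    sizes = nums[3:]
    if len(sizes) != n_pops:
        raise FormatError(f"{path}, line 1: {n_pops} populations declared but {len(sizes)} sizes")
    if sum(sizes) != n_ind:
        raise ConsistencyError(f"{path}, line 1: sizes sum to {sum(sizes)}, header says {n_ind}")

    name_row = rows[1]
    pop_names = [c for c in name_row[3:3 + n_pops]]
    if len(pop_names) != n_pops or any(not c.strip() for c in pop_names):
        raise FormatError(f"{path}, line 2: expected {n_pops} population names from column 4")

    header = rows[2]
    locus_cells = [c for c in header[2:] if c.strip() != ""]
    if len(locus_cells) != n_loci:
        raise FormatError(f"{path}, line 3: {len(locus_cells)} locus names, header says {n_loci}")
    loci = locus_cells

    data_rows = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(data_rows) != n_ind:
        raise ConsistencyError(f"{path}: {len(data_rows)} data rows, header says {n_ind}")

    site_index: Mapping[str, dict] = {}
    if sites is not None:
        site_index = {r["population"]: r for r in sites.to_dict("records")}

    populations: list[PopulationSample] = []
    cursor = 0
    for pop_name, size in zip(pop_names, sizes):
        inds = []
        for k in range(size):
            r = data_rows[cursor + k]
            line_no = 4 + cursor + k
            if r[1].strip() != pop_name:
                raise ConsistencyError(
                    f"{path}, line {line_no}: population '{r[1]}' where '{pop_name}' expected")
            calls = [c for c in r[2:2 + 2 * n_loci]]
            if len(calls) != 2 * n_loci:
                raise FormatError(
                    f"{path}, line {line_no}: expected {2 * n_loci} allele columns, got {len(calls)}")
            alleles = _ints(calls, line_no)
            gts = {
                loci[j]: make_genotype(alleles[2 * j], alleles[2 * j + 1])
                for j in range(n_loci)
            }
            inds.append(Individual(r[0], gts))
        cursor += size
        meta = site_index.get(pop_name, {})
        populations.append(PopulationSample(
            code=pop_name,
            site_name=str(meta.get("site", pop_name)),
            latitude=float(meta.get("latitude", 0.0)),
            longitude=float(meta.get("longitude", 0.0)),
            time_code=int(meta.get("time_code", 1)),
            sampling_date=str(meta.get("date", "")),
            individuals=inds,
        ))
    return TemporalDataset(loci, populations)


def write_genalex(dataset: TemporalDataset, path) -> None:
    """Write a dataset as a GenAlEx codominant CSV (missing coded 0)."""
    loci = dataset.loci
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        sizes = [p.size for p in dataset.populations]
        w.writerow([len(loci), dataset.n_individuals, len(sizes), *sizes])
        w.writerow(["kinflow export", "", "", *[p.code for p in dataset.populations]])
        header = ["Ind", "Pop"]
        for loc in loci:
            header.extend([loc, ""])
        w.writerow(header)
        for pop in dataset.populations:
            for ind in pop.individuals:
                row = [ind.id, pop.code]
                for loc in loci:
                    gt = ind.genotype(loc)
                    row.extend([0, 0] if gt is None else list(gt))
                w.writerow(row)


# ---------------------------------------------------------------------------
# STRUCTURE two-row format
# ---------------------------------------------------------------------------


def write_structure(dataset: TemporalDataset, path) -> None:
    """Write the STRUCTURE two-row-per-individual format (missing = -9).

    Columns: individual label, integer population code (1-based, file
    order), then one allele per locus; each individual contributes two
    consecutive rows, one per gene copy.
    """
    if not dataset.populations:
        raise EmptyDatasetError("cannot write an empty dataset")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["ind", "pop", *dataset.loci]) + "\n")
        for pi, pop in enumerate(dataset.populations, start=1):
            for ind in pop.individuals:
                for copy in (0, 1):
                    cells = [ind.id, str(pi)]
                    for loc in dataset.loci:
                        gt = ind.genotype(loc)
                        cells.append("-9" if gt is None else str(gt[copy]))
                    fh.write("\t".join(cells) + "\n")


def read_structure(path) -> tuple[list[str], list[int], list[str], np.ndarray]:
    """Read a STRUCTURE two-row file back to (ids, pop codes, loci, alleles).

    Returns the allele matrix with shape (n_individuals, n_loci, 2) and -9
    preserved as the missing code.  Intended for round-trip checks; site
    metadata is not represented in this format.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    loci = header[2:]
    body = [ln.split("\t") for ln in lines[1:]]
    if len(body) % 2 != 0:
        raise FormatError(f"{path}: odd number of data rows")
    ids, pops, mats = [], [], []
    for i in range(0, len(body), 2):
        r1, r2 = body[i], body[i + 1]
        if r1[0] != r2[0]:
            raise ConsistencyError(f"{path}: row pair {i} labels differ ({r1[0]!r}, {r2[0]!r})")
        ids.append(r1[0])
        pops.append(int(r1[1]))
        mat = np.stack([[int(x) for x in r1[2:]], [int(x) for x in r2[2:]]], axis=1)
        mats.append(mat)
    return ids, pops, loci, np.stack(mats)


# ---------------------------------------------------------------------------
# Sites metadata CSV
# ---------------------------------------------------------------------------

SITES_COLUMNS = ["population", "site", "latitude", "longitude", "sample_size", "date", "time_code"]


def read_sites(path) -> pd.DataFrame:
    """Read a sites metadata CSV (population, site, lat, lon, size, date, time)."""
    df = pd.read_csv(path, dtype={"population": str, "site": str, "date": str})
    missing = set(SITES_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~df["time_code"].astype(int).isin(VALID_TIME_CODES)]
    if len(bad):
        raise FormatError(f"{path}: invalid time codes {bad['time_code'].tolist()}")
    return df[SITES_COLUMNS]


def write_sites(dataset: TemporalDataset, path) -> None:
    rows = [
        {"population": p.code, "site": p.site_name, "latitude": p.latitude,
         "longitude": p.longitude, "sample_size": p.size, "date": p.sampling_date,
         "time_code": p.time_code}
        for p in dataset.populations
    ]
    pd.DataFrame(rows, columns=SITES_COLUMNS).to_csv(path, index=False)
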