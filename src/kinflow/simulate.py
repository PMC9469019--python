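"""Forward-time simulator of a partially migrating microsatellite metapopulation.

The generator exists to validate the whole pipeline against known truth: it
emits pipeline-ready genotype and site files together with the full pedigree
and every realized migration event.

Model: a fixed set of demes on a km-scale map, non-overlapping generations.
Each sampling-time slice corresponds to one generation: every offspring born
in deme i draws each of its two parents independently from deme j with
probability M[i][j] (j = i is resident mating) and a uniformly chosen adult
within that deme; each parent transmits one allele per locus Mendelianly.
Migration thus acts through parentage — an immigrant adult mates in the
destination deme — which is exactly the signal kinship-based gene-flow
inference detects (windborne adults breeding where they land).  The sample
for a slice contains a fixed number of offspring per deme plus a fraction of
the parental cohort, mirroring a field collection that mixes generations.

Allele frequencies start from a Dirichlet draw shared by all demes (the
demes are recently connected); drift then differentiates them.  Genotyping
noise (class-II mistyping and missing calls) is injected after sampling and
never touches the recorded truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .data import Individual, PopulationSample, TemporalDataset, allele_frequencies
from .network import MigrationCountMatrix

logger = logging.getLogger(__name__)

_DEME_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class SimConfig:
    """Study-design parameters of the simulated metapopulation.

    Defaults mirror the field design the pipeline targets: ~12 demes sampled
    over 4 time slices at ~30 individuals each, 15 microsatellite loci with
    up to 10 alleles.  ``migration_matrix`` rows are the per-parent origin
    distributions (row-stochastic); ``slice_migration_scale`` optionally
    rescales off-diagonal migration per slice (seasonally varying flow).
    """

    n_demes: int = 12
    deme_size: int = 100
    n_loci: int = 15
    alleles_per_locus: int = 10
    dirichlet_alpha: float = 1.0
    migration_matrix: Optional[np.ndarray] = None
    n_generations: int = 2            # burn-in generations before the first slice
    sample_per_deme: int = 30
    parent_sampling_fraction: float = 0.5
    error_rate: float = 0.0
    missing_rate: float = 0.0
    n_time_slices: int = 4
    slice_migration_scale: Optional[Sequence[float]] = None
    deme_spacing_km: float = 500.0
    origin_lat: float = 18.0
    origin_lon: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.migration_matrix is None:
            self.migration_matrix = uniform_migration(self.n_demes, 0.2)
        M = np.asarray(self.migration_matrix, dtype=float)
        if M.shape != (self.n_demes, self.n_demes):
            raise ValueError("migration matrix shape does not match n_demes")
        if not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("migration matrix rows must sum to 1")
        if (M < 0).any() or (M > 1).any():
            raise ValueError("migration probabilities outside [0, 1]")
        self.migration_matrix = M
        if self.deme_size <= 0 or self.sample_per_deme <= 0:
            raise ValueError("sizes must be positive")
        if self.sample_per_deme > self.deme_size:
            raise ValueError(
                f"sample_per_deme {self.sample_per_deme} exceeds deme_size {self.deme_size}")
        if self.slice_migration_scale is not None and \
                len(self.slice_migration_scale) != self.n_time_slices:
            raise ValueError("slice_migration_scale length must equal n_time_slices")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["migration_matrix"] = np.asarray(self.migration_matrix).tolist()
        if self.slice_migration_scale is not None:
            d["slice_migration_scale"] = list(self.slice_migration_scale)
        return d


def uniform_migration(n_demes: int, total_m: float) -> np.ndarray:
    """Row-stochastic matrix with off-diagonal mass total_m split evenly."""
    if n_demes == 1:
        return np.ones((1, 1))
    M = np.full((n_demes, n_demes), total_m / (n_demes - 1))
    np.fill_diagonal(M, 1.0 - total_m)
    return M


def distance_decay_migration(
    coords_km: np.ndarray, scale_km: float, total_m: float
) -> np.ndarray:
    """Migration kernel exp(-d/scale) over deme coordinates, off-diagonal mass total_m."""
    d = np.linalg.norm(coords_km[:, None, :] - coords_km[None, :, :], axis=-1)
    K = np.exp(-d / scale_km)
    np.fill_diagonal(K, 0.0)
    rows = K.sum(axis=1, keepdims=True)
    M = total_m * K / np.where(rows == 0, 1.0, rows)
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    return M


@dataclass
class PedigreeRecord:
    parent1: str
    parent2: str
    natal_deme: int
    parent_demes: tuple[int, int]
    time_code: int
    sampled: bool = False


@dataclass
class SimTruth:
    """Ground truth: pedigree, per-slice migration events, true frequencies."""

    deme_codes: list[str]
    pedigree: dict[str, PedigreeRecord] = field(default_factory=dict)
    raw_genotypes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    true_frequencies: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def to_json(self, path) -> None:
        out = {
            "deme_codes": self.deme_codes,
            "pedigree": {
                k: {"parent1": r.parent1, "parent2": r.parent2,
                    "natal_deme": r.natal_deme, "parent_demes": list(r.parent_demes),
                    "time_code": r.time_code, "sampled": r.sampled}
                for k, r in self.pedigree.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=0, sort_keys=True)

    def true_parents(self, offspring_id: str) -> set[str]:
        r = self.pedigree[offspring_id]
        return {r.parent1, r.parent2}


def realized_migration(
    truth: SimTruth, time_code: int, sampled_only: bool = False
) -> MigrationCountMatrix:
    """Offspring-parent link counts by (natal deme, parent origin deme).

    Each offspring contributes two links (one per parent).  Labels carry the
    slice's population codes (deme code + time digit).
    """
    k = len(truth.deme_codes)
    n = np.zeros((k, k), dtype=np.int64)
    for rec in truth.pedigree.values():
        if rec.time_code != time_code:
            continue
        if sampled_only and not rec.sampled:
            continue
        for pd_ in rec.parent_demes:
            n[rec.natal_deme, pd_] += 1
    labels = [f"{c}{time_code}" for c in truth.deme_codes]
    return MigrationCountMatrix(labels, n, time_code)


def _deme_codes(n: int) -> list[str]:
    return [f"P{_DEME_LETTERS[i]}" if n <= 26 else f"P{i:02d}" for i in range(n)]


def deme_coordinates(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Deme positions (km) on a jittered grid spanning ~spacing_km * sqrt(n)."""
    n = config.n_demes
    cols = int(np.ceil(np.sqrt(n)))
    pts = []
    for i in range(n):
        r, c = divmod(i, cols)
        jitter = rng.uniform(-0.2, 0.2, size=2) * config.deme_spacing_km
        pts.append([c * config.deme_spacing_km + jitter[0],
                    r * config.deme_spacing_km + jitter[1]])
    return np.asarray(pts)


def _km_to_latlon(xy: np.ndarray, lat0: float, lon0: float) -> np.ndarray:
    km_per_deg = 111.19492664455873  # 2*pi*R/360
    lat = lat0 + xy[:, 1] / km_per_deg
    lon = lon0 + xy[:, 0] / (km_per_deg * np.cos(np.radians(lat0)))
    return np.stack([lat, lon], axis=1)


def simulate_metapopulation(config: SimConfig) -> tuple[TemporalDataset, SimTruth]:
    """Run the forward simulation; returns the sampled dataset and its truth.

    Deterministic under ``config.seed``.  Offspring of slice t become the
    parental cohort of slice t+1.  Genotyping error and missing calls are
    injected into the emitted dataset only.
    """
    rng = np.random.default_rng(config.seed)
    n, L, k = config.n_demes, config.n_loci, config.alleles_per_locus
    codes = _deme_codes(n)
    truth = SimTruth(deme_codes=codes)

    base_freqs = rng.dirichlet(np.full(k, config.dirichlet_alpha), size=L)  # (L, k)
    truth.true_frequencies[0] = base_freqs

    # founding adults: HWE draws from the shared base frequencies
    adults = np.empty((n, config.deme_size, L, 2), dtype=np.int16)
    for l in range(L):
        adults[:, :, l, :] = rng.choice(k, size=(n, config.deme_size, 2), p=base_freqs[l])
    adult_ids = np.array(
        [[f"G0_{codes[d]}_{i:04d}" for i in range(config.deme_size)] for d in range(n)])
    for d in range(n):
        for i in range(config.deme_size):
            truth.raw_genotypes[adult_ids[d, i]] = adults[d, i].copy()

    def breed(adults, adult_ids, M, gen_label, time_code):
        """One generation: returns (offspring array, ids) and logs pedigree."""
        off = np.empty_like(adults)
        off_ids = np.empty_like(adult_ids)
        for d in range(n):
            origin = np.stack([rng.choice(n, size=config.deme_size, p=M[d]),
                               rng.choice(n, size=config.deme_size, p=M[d])], axis=1)
            pick = rng.integers(0, config.deme_size, size=(config.deme_size, 2))
            which = rng.integers(0, 2, size=(config.deme_size, 2, L))
            for i in range(config.deme_size):
                oid = f"{gen_label}_{codes[d]}_{i:04d}"
                o1, o2 = origin[i]
                p1, p2 = pick[i]
                g1 = adults[o1, p1, np.arange(L), which[i, 0]]
                g2 = adults[o2, p2, np.arange(L), which[i, 1]]
                off[d, i, :, 0] = g1
                off[d, i, :, 1] = g2
                off_ids[d, i] = oid
                truth.raw_genotypes[oid] = off[d, i].copy()
                if time_code is not None:
                    truth.pedigree[oid] = PedigreeRecord(
                        adult_ids[o1, p1], adult_ids[o2, p2], d, (int(o1), int(o2)),
                        time_code)
        return off, off_ids

    M0 = config.migration_matrix
    for g in range(config.n_generations):
        adults, adult_ids = breed(adults, adult_ids, M0, f"G{g+1}", None)

    xy = deme_coordinates(config, rng)
    latlon = _km_to_latlon(xy, config.origin_lat, config.origin_lon)

    populations: list[PopulationSample] = []
    loci = [f"L{j+1:02d}" for j in range(L)]
    allele_lengths = 100 + 2 * np.arange(k)  # integer fragment lengths, 2-bp ladder

    for t in range(1, config.n_time_slices + 1):
        scale = 1.0 if config.slice_migration_scale is None \
            else float(config.slice_migration_scale[t - 1])
        M = np.eye(n) + scale * (M0 - np.eye(n))
        offspring, off_ids = breed(adults, adult_ids, M, f"T{t}", t)

        n_par = int(round(config.parent_sampling_fraction * config.deme_size))
        for d in range(n):
            take_off = rng.choice(config.deme_size, size=config.sample_per_deme, replace=False)
            take_par = rng.choice(config.deme_size, size=n_par, replace=False) \
                if n_par > 0 else np.array([], dtype=int)
            inds = []
            for i in sorted(take_off):
                oid = off_ids[d, i]
                truth.pedigree[oid].sampled = True
                gts = {loci[l]: tuple(sorted(allele_lengths[offspring[d, i, l]]))
                       for l in range(L)}
                inds.append(Individual(oid, gts))
            for i in sorted(take_par):
                pid = adult_ids[d, i]
                gts = {loci[l]: tuple(sorted(allele_lengths[adults[d, i, l]]))
                       for l in range(L)}
                inds.append(Individual(pid, gts))
            populations.append(PopulationSample(
                code=f"{codes[d]}{t}", site_name=codes[d],
                latitude=float(latlon[d, 0]), longitude=float(latlon[d, 1]),
                time_code=t, sampling_date=f"20{15 + t}-01-01",
                individuals=inds))
        adults, adult_ids = offspring, off_ids

    dataset = TemporalDataset(loci, populations)
    if config.error_rate > 0 or config.missing_rate > 0:
        dataset = inject_genotyping_error(
            dataset, config.error_rate, config.missing_rate,
            seed=int(rng.integers(0, 2**31 - 1)))
    return dataset, truth


def inject_genotyping_error(
    dataset: TemporalDataset, e: float, missing_rate: float, seed: int
) -> TemporalDataset:
    """Mistype each allele with probability e; drop genotypes at missing_rate.

    A mistyped allele is replaced by a random allele drawn from the locus's
    pooled frequency distribution (class-II error).  Returns a new dataset;
    the input (and any simulator truth) is untouched.
    """
    if not (0 <= e < 0.5 and 0 <= missing_rate < 0.5):
        raise ValueError("rates must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    table = allele_frequencies(dataset)
    pooled = {}
    for locus in dataset.loci:
        f = table.pooled_freqs(locus)
        alleles = np.array(sorted(f))
        probs = np.array([f[a] for a in alleles])
        pooled[locus] = (alleles, probs)

    new_pops = []
    for pop in dataset.populations:
        new_inds = []
        for ind in pop.individuals:
            gts = {}
            for locus in dataset.loci:
                gt = ind.genotype(locus)
                if gt is not None:
                    if missing_rate > 0 and rng.random() < missing_rate:
                        gt = None
                    else:
                        a = list(gt)
                        for c in (0, 1):
                            if e > 0 and rng.random() < e:
                                alleles, probs = pooled[locus]
                                a[c] = int(rng.choice(alleles, p=probs))
                        gt = tuple(sorted(a))
                gts[locus] = gt
            new_inds.append(Individual(ind.id, gts))
        new_pops.append(PopulationSample(
            pop.code, pop.site_name, pop.latitude, pop.longitude,
            pop.time_code, pop.sampling_date, new_inds))
    return TemporalDataset(list(dataset.loci), new_pops)
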