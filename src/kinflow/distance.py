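"""Genetic and geographic distances, ordination, and isolation by distance.

Nei's standard genetic distance D = -ln I is computed with the J terms
(within- and between-population expected homozygosities) averaged
arithmetically across loci before forming the identity I, the convention of
the common codominant-marker toolkits.  Principal coordinates analysis uses
Gower double-centering of -D^2/2.  Geographic distances are great-circle
(haversine) kilometres on a sphere of mean radius 6371.0088 km.  The
genetic-geographic association is tested with a Mantel permutation test:
matrix entries are not independent, so a joint row/column permutation null
replaces the naive regression p-value.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import TemporalDataset, allele_frequencies

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix (genetic Nei units or km)."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "genetic" | "geographic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        finite = np.isfinite(v)
        if not np.allclose(v[finite & finite.T], v.T[finite & finite.T], atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(v[finite] < 0):
            raise ValueError("negative distances")
        self.values = v

    @property
    def has_infinite(self) -> bool:
        return bool(np.isinf(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _offdiag_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------


def nei_distance_matrix(dataset: TemporalDataset) -> DistanceMatrix:
    """Nei (1972) standard distance between all population pairs.

    Per shared typed locus: Jx = sum p^2, Jy = sum q^2, Jxy = sum p*q; the
    three J terms are averaged arithmetically across loci, then
    I = Jxy / sqrt(Jx * Jy) and D = -ln I.  Loci untyped in either
    population are excluded pairwise; a pair with no shared typed locus is
    an error; a pair sharing no alleles at all gets D = +inf (flagged).
    """
    table = allele_frequencies(dataset)
    codes = [p.code for p in dataset.populations]
    if len(codes) < 2:
        raise ValueError("need at least 2 populations")
    n = len(codes)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        jx = jy = jxy = 0.0
        n_loci = 0
        for locus in dataset.loci:
            fx = table.freqs(codes[i], locus)
            fy = table.freqs(codes[j], locus)
            if not fx or not fy:
                continue
            n_loci += 1
            jx += sum(p * p for p in fx.values())
            jy += sum(q * q for q in fy.values())
            jxy += sum(p * fy.get(a, 0.0) for a, p in fx.items())
        if n_loci == 0:
            raise ValueError(f"populations {codes[i]} and {codes[j]} share no typed loci")
        identity = (jxy / n_loci) / math.sqrt((jx / n_loci) * (jy / n_loci))
        if identity <= 0.0:
            logger.warning("no shared alleles between %s and %s; D = inf", codes[i], codes[j])
            d = math.inf
        else:
            d = -math.log(min(identity, 1.0))
        D[i, j] = D[j, i] = d
    return DistanceMatrix(codes, D, "genetic")


# ---------------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray       # populations x retained positive axes
    eigenvalues: np.ndarray       # all eigenvalues, descending
    percent_variance: np.ndarray  # per retained positive axis, sums to <=100

    def coords_frame(self) -> pd.DataFrame:
        cols = [f"axis{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(dist: DistanceMatrix, n_axes: Optional[int] = None) -> PcoaResult:
    """Classical PCoA (Gower double-centering + eigendecomposition).

    Negative eigenvalues are reported but excluded from percent_variance;
    coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    axes only.  Infinite distances must be resolved (capped or the pair
    dropped) before ordination.
    """
    if dist.has_infinite:
        raise ValueError(
            "distance matrix contains infinite entries; drop or cap the offending pairs first")
    D = dist.values
    n = D.shape[0]
    if n_axes is None:
        n_axes = n - 1
    if n_axes > n - 1:
        raise ValueError(f"n_axes={n_axes} exceeds n-1={n-1}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0])) if n > 1 else eigvals > 0
    k = min(n_axes, int(pos.sum()))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[pos].sum()
    pct = 100.0 * eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return PcoaResult(list(dist.labels), coords, eigvals, pct)


# ---------------------------------------------------------------------------
# Geodesic distance
# ---------------------------------------------------------------------------


def geodesic_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points in decimal degrees."""
    for lat, lon in (a, b):
        if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_distance_matrix(dataset: TemporalDataset) -> DistanceMatrix:
    codes = [p.code for p in dataset.populations]
    pts = [(p.latitude, p.longitude) for p in dataset.populations]
    n = len(codes)
    G = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        G[i, j] = G[j, i] = geodesic_km(pts[i], pts[j])
    return DistanceMatrix(codes, G, "geographic")


# ---------------------------------------------------------------------------
# Isolation by distance (Mantel test)
# ---------------------------------------------------------------------------


@dataclass
class IbdResult:
    r: float
    p: float
    n_pairs: int
    n_perm: int
    seed: int


def ibd_test(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> IbdResult:
    """Two-sided Mantel test of genetic vs geographic distance.

    r is the Pearson correlation over the n(n-1)/2 off-diagonal pairs;
    p is the fraction of joint row/column permutations of the genetic
    matrix with |r_perm| >= |r_obs|, with +1/+1 continuity correction.
    Pairs with infinite genetic distance are excluded (logged).
    """
    if genetic.labels != geographic.labels:
        raise ValueError("label mismatch between distance matrices")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = len(genetic.labels)
    iu = _offdiag_pairs(n)
    gvals = genetic.values
    finite_mask = np.isfinite(gvals)
    n_dropped = int((~finite_mask[iu]).sum())
    if n_dropped:
        logger.warning("ibd_test: excluding %d pairs with infinite genetic distance", n_dropped)

    def _r(mat: np.ndarray) -> float:
        x = mat[iu]
        y = geographic.values[iu]
        keep = np.isfinite(x)
        if keep.sum() < 3 or np.std(x[keep]) == 0 or np.std(y[keep]) == 0:
            return 0.0
        return float(np.corrcoef(x[keep], y[keep])[0, 1])

    r_obs = _r(gvals)
    if math.factorial(n) <= n_perm + 1:
        # small label sets: exact test over all n! joint permutations
        perms = list(itertools.permutations(range(n)))
        count = sum(
            1 for perm in perms
            if abs(_r(gvals[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12)
        p = count / len(perms)
        n_perm_used = len(perms) - 1
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if abs(_r(gvals[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        n_perm_used = n_perm
    return IbdResult(r_obs, p, n_pairs=int(finite_mask[iu].sum()),
                     n_perm=n_perm_used, seed=seed)
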