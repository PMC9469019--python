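"""Per-population diversity metrics and rarefaction of allelic richness.

Per-locus statistics follow the conventions of standard codominant-marker
toolkits: Na (observed alleles), Ne (effective number of alleles, 1/sum p^2),
Shannon index I, observed heterozygosity Ho and expected heterozygosity
He = 1 - sum p^2 (plug-in estimator by default).  A population's row reports
the unweighted mean over loci.

Rarefaction standardizes allelic richness to a common number of gene copies
g: the expected number of distinct alleles in a random subsample of g copies,
and the expected number of private alleles (present in a focal group's
subsample and absent from equally sized subsamples of all other groups).
Hypergeometric "absence" probabilities are computed in log space so that
groups with hundreds of gene copies do not overflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import AlleleFreqTable, FreqCell, TemporalDataset, allele_frequencies

logger = logging.getLogger(__name__)

#: Per-locus allele copy counts for one group: locus -> {allele: copies}.
GroupCounts = Mapping[str, Mapping[int, int]]

METRICS = ("na", "ne", "shannon", "ho", "he")


@dataclass
class DiversityRow:
    """Mean-over-loci diversity metrics for one population."""

    population: str
    na: float
    ne: float
    shannon: float
    ho: float
    he: float
    ar: Optional[float] = None
    n_loci_used: int = 0


def _locus_stats(cell: FreqCell) -> tuple[float, float, float, float]:
    """(Na, Ne, I, He) from one frequency cell; requires non-empty cell."""
    p = np.array(list(cell.freqs.values()))
    na = float((p > 0).sum())
    sum_p2 = float((p ** 2).sum())
    ne = 1.0 / sum_p2
    shannon = float(-(p * np.log(p)).sum())
    he = 1.0 - sum_p2
    return na, ne, shannon, he


def diversity_table(
    dataset: TemporalDataset,
    freq_table: Optional[AlleleFreqTable] = None,
    unbiased_he: bool = False,
) -> list[DiversityRow]:
    """Per-population diversity metrics, averaged over loci with data.

    ``unbiased_he`` applies the small-sample 2N/(2N-1) correction to He;
    the default is the plug-in estimator 1 - sum p^2.  Loci with no typed
    individuals in a population are excluded from that population's mean
    (logged); a population typed at zero loci is an error.
    """
    freq_table = freq_table or allele_frequencies(dataset)
    rows = []
    for pop in dataset.populations:
        per_locus = []
        for locus in dataset.loci:
            cell = freq_table.cell(pop.code, locus)
            if cell.empty:
                logger.info("diversity_table: %s/%s has no data; excluded", pop.code, locus)
                continue
            na, ne, shannon, he = _locus_stats(cell)
            if unbiased_he:
                n2 = cell.copies_sampled
                he *= n2 / (n2 - 1) if n2 > 1 else 1.0
            n_typed = cell.copies_sampled // 2
            n_het = sum(
                1 for ind in pop.individuals
                if (gt := ind.genotype(locus)) is not None and gt[0] != gt[1]
            )
            ho = n_het / n_typed
            per_locus.append((na, ne, shannon, ho, he))
        if not per_locus:
            raise ValueError(f"population {pop.code} has no typed loci")
        means = np.mean(np.array(per_locus), axis=0)
        rows.append(DiversityRow(pop.code, *map(float, means), n_loci_used=len(per_locus)))
    return rows


def group_means(rows: Sequence[DiversityRow]) -> DiversityRow:
    """Unweighted arithmetic mean of each metric across population rows.

    ``ar`` is averaged only if present in every row.  Rounding is left to
    report time.
    """
    if not rows:
        raise ValueError("group_means of empty row list")
    vals = {m: float(np.mean([getattr(r, m) for r in rows])) for m in METRICS}
    ar = None
    if all(r.ar is not None for r in rows):
        ar = float(np.mean([r.ar for r in rows]))
    return DiversityRow("Mean", **vals, ar=ar, n_loci_used=rows[0].n_loci_used)


def diversity_frame(rows: Sequence[DiversityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"population": r.population, "na": r.na, "ne": r.ne, "shannon": r.shannon,
          "ho": r.ho, "he": r.he, "ar": r.ar} for r in rows]
    )


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def _log_absence_prob(n_total: int, n_allele: int, g: int) -> float:
    """log P(allele absent from a subsample of g of N copies) = log C(N-Na,g)/C(N,g)."""
    if n_total - n_allele < g:
        return -math.inf  # allele certainly drawn
    m = n_total - n_allele
    return float(
        gammaln(m + 1) - gammaln(m - g + 1) - (gammaln(n_total + 1) - gammaln(n_total - g + 1))
    )


def _locus_expected_distinct(counts: Mapping[int, int], g: int) -> float:
    n_total = sum(counts.values())
    if g > n_total:
        raise ValueError(f"g={g} exceeds N={n_total}")
    return float(sum(1.0 - math.exp(_log_absence_prob(n_total, na, g)) for na in counts.values()))


def rarefied_richness(group: GroupCounts, g: int) -> tuple[float, dict[str, float]]:
    """Expected distinct alleles per locus in a subsample of g gene copies.

    Returns (mean over available loci, per-locus values).  Loci whose total
    copy count is below g are unavailable at this g and are excluded from the
    mean (the curve is truncated, not an error).
    """
    if g < 2:
        raise ValueError("g must be >= 2")
    per_locus = {}
    for locus, counts in group.items():
        n_total = sum(counts.values())
        if n_total == 0 or g > n_total:
            continue
        per_locus[locus] = _locus_expected_distinct(counts, g)
    if not per_locus:
        raise ValueError(f"no locus has >= {g} gene copies")
    return float(np.mean(list(per_locus.values()))), per_locus


def rarefied_private_richness(
    groups: Sequence[GroupCounts], focal: int, g: int
) -> tuple[float, dict[str, float]]:
    """Expected private alleles per locus for one focal group at sample size g.

    An allele counts as private when it appears in the focal group's g-copy
    subsample and in none of the other groups' independent g-copy
    subsamples.  Loci where any group has fewer than g copies are excluded
    from the mean.
    """
    if len(groups) < 2:
        raise ValueError("private richness needs at least 2 groups")
    if not 0 <= focal < len(groups):
        raise IndexError(f"focal index {focal} out of range")
    per_locus = {}
    loci = set(groups[focal])
    for grp in groups:
        loci &= set(grp)
    for locus in sorted(loci):
        totals = [sum(grp[locus].values()) for grp in groups]
        if any(t < g for t in totals):
            continue
        f_counts = groups[focal][locus]
        n_f = totals[focal]
        total = 0.0
        for allele, n_fa in f_counts.items():
            term = 1.0 - math.exp(_log_absence_prob(n_f, n_fa, g))
            for k, grp in enumerate(groups):
                if k == focal:
                    continue
                n_ka = grp[locus].get(allele, 0)
                term *= math.exp(_log_absence_prob(totals[k], n_ka, g))
                if term == 0.0:
                    break
            total += term
        per_locus[locus] = total
    if not per_locus:
        raise ValueError(f"no locus has >= {g} copies in every group")
    return float(np.mean(list(per_locus.values()))), per_locus


def group_counts_by_time(dataset: TemporalDataset) -> dict[int, dict[str, dict[int, int]]]:
    """Pool allele copy counts per locus within each sampling time (group)."""
    out: dict[int, dict[str, dict[int, int]]] = {}
    for t in dataset.time_codes:
        sl = dataset.time_slice(t)
        table = allele_frequencies(sl)
        out[t] = {locus: dict(table.pooled_cell(locus).counts) for locus in sl.loci}
    return out


@dataclass
class RarefactionCurve:
    """Per-g expected distinct and private alleles per locus for one group."""

    group: str
    g_values: list[int]
    richness: list[float]
    private_richness: list[float]


def rarefaction_curves(
    dataset: TemporalDataset, g_values: Optional[Sequence[int]] = None
) -> list[RarefactionCurve]:
    """Rarefaction curves for each sampling-time group of a dataset.

    ``g_values`` defaults to every even g from 2 up to the smallest group's
    copy count (step chosen to keep ~50 points).
    """
    groups = group_counts_by_time(dataset)
    times = sorted(groups)
    if g_values is None:
        gmax = min(
            min(sum(c.values()) for c in grp.values() if c) for grp in groups.values()
        )
        step = max(1, (gmax - 2) // 50)
        g_values = list(range(2, gmax + 1, step))
    curves = []
    glist = sorted(set(int(g) for g in g_values))
    ordered = [groups[t] for t in times]
    for idx, t in enumerate(times):
        rich, priv, gs = [], [], []
        for g in glist:
            try:
                r, _ = rarefied_richness(groups[t], g)
                p, _ = (rarefied_private_richness(ordered, idx, g)
                        if len(ordered) > 1 else (0.0, {}))
            except ValueError:
                continue
            gs.append(g)
            rich.append(r)
            priv.append(p)
        curves.append(RarefactionCurve(f"time{t}", gs, rich, priv))
    return curves


def curves_frame(curves: Sequence[RarefactionCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for g, r, p in zip(c.g_values, c.richness, c.private_richness):
            rows.append({"group": c.group, "g": g, "richness": r, "private_richness": p})
    return pd.DataFrame(rows, columns=["group", "g", "richness", "private_richness"])
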