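"""Pedigree depth, completeness, generation intervals and progeny statistics.

Three notions of pedigree depth are computed per animal:

* ``max_generations`` — length of the longest chain of known parents;
* ``complete_generations`` — deepest generation at which *all* ``2^g``
  ancestral slots are filled;
* ``equivalent_generations`` — ``sum over known ancestors of (1/2)^g``,
  the expected depth of a randomly sampled allele's pedigree path.

Completeness per ascending generation counts known ancestors per pedigree
slot (a duplicated ancestor counts once per slot), and the aggregate pedigree
completeness index (PCI) is the simple mean of the per-generation
proportions over generations 1..5.

Generation intervals follow the classical four gametic pathways
(sire-son, sire-daughter, dam-son, dam-daughter): the interval proper is the
mean parental age at the birth of offspring that themselves reproduced,
while the mean parental age is taken over all dated offspring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

PCI_DEPTH = 5  # generations averaged into the aggregate PCI


@dataclass(frozen=True)
class GenerationProfile:
    id: str
    max_generations: int
    complete_generations: int
    equivalent_generations: float


@dataclass(frozen=True)
class CompletenessProfile:
    """Mean proportion of known ancestors at generations 1..d, plus PCI."""

    proportions: np.ndarray  # index k-1 -> generation k
    pci: float


@dataclass
class PathwayStats:
    n: int
    mean: float
    sd: float


@dataclass
class IntervalReport:
    """Generation intervals, parental ages, and progeny statistics."""

    intervals: dict[str, PathwayStats]          # parent age at birth of *reproducing* offspring
    parental_ages: dict[str, PathwayStats]      # parent age at birth of all offspring
    n_undated_links: int
    progeny_per_sire_mean: float
    progeny_per_sire_max: int
    progeny_per_dam_mean: float
    progeny_per_dam_max: int
    pct_males_breeding: float
    pct_females_breeding: float
    male_female_ratio: float


def generation_numbers(ped: Pedigree) -> pd.DataFrame:
    """Vectorized depth measures for every animal (topological one-pass)."""
    n = len(ped)
    maxg = np.zeros(n, dtype=int)
    comp = np.zeros(n, dtype=int)
    equiv = np.zeros(n, dtype=float)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        mg = 0
        if s >= 0:
            mg = max(mg, 1 + maxg[s])
            equiv[i] += 0.5 * (1.0 + equiv[s])
        if d >= 0:
            mg = max(mg, 1 + maxg[d])
            equiv[i] += 0.5 * (1.0 + equiv[d])
        maxg[i] = mg
        comp[i] = 1 + min(comp[s], comp[d]) if (s >= 0 and d >= 0) else 0
    return pd.DataFrame(
        {
            "id": ped.ids,
            "max_generations": maxg,
            "complete_generations": comp,
            "equivalent_generations": equiv,
        }
    ).set_index("id")


def generation_profile(ped: Pedigree, animal_id: str) -> GenerationProfile:
    """Depth measures for one animal."""
    i = ped.index(animal_id)  # raises KeyError for unknown ids
    df = generation_numbers(ped)
    row = df.iloc[i]
    return GenerationProfile(
        id=animal_id,
        max_generations=int(row["max_generations"]),
        complete_generations=int(row["complete_generations"]),
        equivalent_generations=float(row["equivalent_generations"]),
    )


def _known_slots(ped: Pedigree, depth: int) -> np.ndarray:
    """known[i, k-1] = number of known ancestors of i at generation k.

    Slot-based: each of the 2^k ancestral positions counts separately even
    when occupied by the same animal.
    """
    n = len(ped)
    known = np.zeros((n, depth), dtype=float)
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                known[i, 0] += 1.0
                if depth > 1:
                    known[i, 1:] += known[p, :-1]
    return known


def completeness(
    ped: Pedigree, reference: list[str] | np.ndarray | None = None, depth: int = PCI_DEPTH
) -> CompletenessProfile:
    """Per-generation proportion of known ancestors, averaged over a reference.

    ``reference`` defaults to the pedigree's focal animals.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if reference is None:
        idx = ped.focal_indices
    else:
        idx = np.array([ped.index(a) for a in reference])
    if len(idx) == 0:
        raise ValueError("empty reference population")
    known = _known_slots(ped, depth)
    slots = 2.0 ** np.arange(1, depth + 1)
    props = known[idx].mean(axis=0) / slots
    pci_depth = min(depth, PCI_DEPTH)
    return CompletenessProfile(proportions=props, pci=float(props[:pci_depth].mean()))


_PATHWAYS = {
    ("M", "M"): "sire_son",
    ("M", "F"): "sire_daughter",
    ("F", "M"): "dam_son",
    ("F", "F"): "dam_daughter",
}


def generation_intervals(ped: Pedigree) -> IntervalReport:
    """Interval and progeny statistics over the four gametic pathways.

    Links lacking a birth date on either side are skipped (counted and
    logged).  Raises if no pathway has any dated link.
    """
    has_progeny = np.zeros(len(ped), dtype=bool)
    n_off_sire: dict[int, int] = {}
    n_off_dam: dict[int, int] = {}
    for i in range(len(ped)):
        for p, tally in ((ped.sire[i], n_off_sire), (ped.dam[i], n_off_dam)):
            if p >= 0:
                has_progeny[p] = True
                tally[p] = tally.get(p, 0) + 1

    ages: dict[str, list[float]] = {k: [] for k in _PATHWAYS.values()}
    ages_repro: dict[str, list[float]] = {k: [] for k in _PATHWAYS.values()}
    undated = 0
    for i in range(len(ped)):
        if np.isnan(ped.birth_year[i]):
            if ped.sire[i] >= 0 or ped.dam[i] >= 0:
                undated += 1
            continue
        off_sex = ped.sex[i] if ped.sex[i] in ("M", "F") else None
        for p, role in ((ped.sire[i], "M"), (ped.dam[i], "F")):
            if p < 0 or off_sex is None:
                continue
            if np.isnan(ped.birth_year[p]):
                undated += 1
                continue
            age = ped.birth_year[i] - ped.birth_year[p]
            key = _PATHWAYS[(role, off_sex)]
            ages[key].append(age)
            if has_progeny[i]:
                ages_repro[key].append(age)
    if undated:
        logger.info("generation_intervals: skipped %d undated parent-offspring links", undated)
    if all(len(v) == 0 for v in ages.values()):
        raise ValueError("no dated parent-offspring link in any gametic pathway")

    def stats(values: list[float]) -> PathwayStats:
        if not values:
            return PathwayStats(n=0, mean=float("nan"), sd=float("nan"))
        arr = np.asarray(values)
        return PathwayStats(n=len(arr), mean=float(arr.mean()),
                            sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)

    males = ped.sex == "M"
    females = ped.sex == "F"
    sire_counts = list(n_off_sire.values())
    dam_counts = list(n_off_dam.values())
    return IntervalReport(
        intervals={k: stats(v) for k, v in ages_repro.items()},
        parental_ages={k: stats(v) for k, v in ages.items()},
        n_undated_links=undated,
        progeny_per_sire_mean=float(np.mean(sire_counts)) if sire_counts else 0.0,
        progeny_per_sire_max=int(max(sire_counts)) if sire_counts else 0,
        progeny_per_dam_mean=float(np.mean(dam_counts)) if dam_counts else 0.0,
        progeny_per_dam_max=int(max(dam_counts)) if dam_counts else 0,
        pct_males_breeding=float(100.0 * has_progeny[males].mean()) if males.any() else 0.0,
        pct_females_breeding=float(100.0 * has_progeny[females].mean()) if females.any() else 0.0,
        male_female_ratio=float(males.sum() / females.sum()) if females.any() else float("inf"),
    )


def offspring_counts(ped: Pedigree) -> np.ndarray:
    """Number of registered offspring per animal (CDA feature)."""
    counts = np.zeros(len(ped), dtype=int)
    for i in range(len(ped)):
        if ped.sire[i] >= 0:
            counts[ped.sire[i]] += 1
        if ped.dam[i] >= 0:
            counts[ped.dam[i]] += 1
    return counts
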