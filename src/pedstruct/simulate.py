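"""Synthetic studbook generator.

Emulates the data-generating situation the analyses in this package assume:
two closed purebred base populations bred over overlapping birth cohorts, and
a composite breed formed from them by a staged crossing program in which the
composite's ancestry fraction is tracked (25/50/75% blood classes and their
combinations).  Right-skewed sire progeny distributions, configurable
missing-parent rates and a living/dead split reproduce the statistical
texture of real registries.

The ancestry ("blood") fractions attached to composite animals are simulator
truth labels for testing only; no analysis module reads them.

All stochastic draws within one simulation call flow from a single
``numpy.random.Generator`` seeded from the config, so a fixed seed yields a
byte-identical pedigree.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pedigree import AnimalRecord, Pedigree, PedigreeError


@dataclass(frozen=True)
class CrossingStage:
    """One stage of a composite breeding scheme.

    Sires are drawn from ``sire_breed`` animals whose ancestry fraction is
    ``sire_fraction`` (purebreds: the founding breed has fraction 1.0, the
    other 0.0); dams likewise.  ``n_offspring`` composite foals are produced,
    each annotated with the mean of its parents' fractions.
    """

    sire_breed: str
    sire_fraction: float
    dam_breed: str
    dam_fraction: float
    n_offspring: int


@dataclass
class SimulationConfig:
    """Parameters of a purebred simulation.

    ``progeny_distribution`` is ``("poisson", mean)`` for near-equal sire use
    or ``("skewed", mean, max_sire_share)`` where one dominant sire receives
    ``max_sire_share`` of all matings — the right-skewed progeny profile real
    studbooks show.
    """

    n_founders_per_breed: int = 40
    n_generations: int = 5
    n_per_generation: int | None = None  # default: n_founders_per_breed
    progeny_distribution: tuple = ("skewed", 4.0, 0.3)
    sex_ratio: float = 0.5
    missing_parent_rate: float = 0.0
    mortality_rate: float = 0.3
    base_year: float = 1980.5
    generation_step: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders_per_breed < 2:
            raise ValueError("need at least 2 founders per breed")
        if self.n_generations < 1:
            raise ValueError("need at least 1 generation")
        for p in (self.sex_ratio, self.missing_parent_rate, self.mortality_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _draw_sexes(rng: np.random.Generator, n: int, sex_ratio: float) -> np.ndarray:
    """Random sexes, guaranteed to include both when n >= 2."""
    sexes = np.where(rng.random(n) < sex_ratio, "M", "F")
    if n >= 2:
        if (sexes == "M").all():
            sexes[rng.integers(n)] = "F"
        elif (sexes == "F").all():
            sexes[rng.integers(n)] = "M"
    return sexes


def _sire_weights(dist: tuple, k: int, rng: np.random.Generator) -> np.ndarray:
    """Per-sire mating probabilities under the configured progeny law."""
    if dist[0] == "poisson":
        return np.full(k, 1.0 / k)
    if dist[0] == "skewed":
        share = float(dist[2])
        if k == 1:
            return np.ones(1)
        w = np.full(k, (1.0 - share) / (k - 1))
        w[rng.integers(k)] = share
        return w
    raise ValueError(f"unknown progeny distribution {dist[0]!r}")


def simulate_purebred(cfg: SimulationConfig, breed: str = "A") -> Pedigree:
    """Closed purebred population with unknown-parent founders.

    Generation 0 animals have both parents unknown; each later animal draws
    its sire from the previous generation's males (weighted per the progeny
    distribution) and its dam uniformly from its females.  Birth years step
    by ``generation_step`` per generation.  Non-terminal animals are flagged
    dead with probability ``mortality_rate``; the terminal generation is
    always alive so "current" subsets are never empty.
    """
    rng = np.random.default_rng(cfg.seed)
    records = _grow_purebred(cfg, breed, rng, id_prefix=breed)
    return Pedigree.from_records(records)


def _grow_purebred(cfg, breed, rng, id_prefix):
    n_gen = cfg.n_generations
    n_per = cfg.n_per_generation or cfg.n_founders_per_breed
    records: list[AnimalRecord] = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"{id_prefix}{counter:05d}"

    sexes = _draw_sexes(rng, cfg.n_founders_per_breed, cfg.sex_ratio)
    cohort = []
    for s in sexes:
        records.append(
            AnimalRecord(id=new_id(), sex=s, birth_year=cfg.base_year, breed=breed, alive=False)
        )
        cohort.append(records[-1])

    for g in range(1, n_gen + 1):
        males = [r for r in cohort if r.sex == "M"]
        females = [r for r in cohort if r.sex == "F"]
        if not males or not females:
            raise PedigreeError(f"generation {g - 1} of breed {breed} has a single sex")
        w_sire = _sire_weights(cfg.progeny_distribution, len(males), rng)
        sexes = _draw_sexes(rng, n_per, cfg.sex_ratio)
        year = cfg.base_year + g * cfg.generation_step
        new_cohort = []
        for j in range(n_per):
            sire = males[rng.choice(len(males), p=w_sire)]
            dam = females[rng.integers(len(females))]
            sire_id = None if rng.random() < cfg.missing_parent_rate else sire.id
            dam_id = None if rng.random() < cfg.missing_parent_rate else dam.id
            rec = AnimalRecord(
                id=new_id(),
                sire=sire_id,
                dam=dam_id,
                sex=sexes[j],
                birth_year=year,
                breed=breed,
                alive=True,
            )
            records.append(rec)
            new_cohort.append(rec)
        cohort = new_cohort

    # mortality: terminal generation stays alive
    terminal = {r.id for r in cohort}
    out = []
    for r in records:
        if r.id in terminal:
            out.append(r if r.alive else dataclasses.replace(r, alive=True))
        else:
            out.append(dataclasses.replace(r, alive=bool(rng.random() >= cfg.mortality_rate)))
    return out


def default_composite_scheme(
    breed_a: str = "A", breed_b: str = "B", n_per_stage: int = 30, composite: str = "AB"
) -> list[CrossingStage]:
    """Staged formation of a two-ancestor composite breed.

    Approximates a multi-stage program: F1 (A sires x B dams, fraction 0.5),
    backcrosses to each purebred producing 0.75 and 0.25 blood classes, a
    0.25 x 0.75 cross fixing the 50:50 genotype, and inter-se matings of
    0.5 x 0.5 animals.  Ratios of the historical program it emulates are only
    qualitative, so this is documented as an approximation.
    """
    return [
        CrossingStage(breed_a, 1.0, breed_b, 0.0, n_per_stage),          # F1 -> 0.5
        CrossingStage(breed_a, 1.0, composite, 0.5, n_per_stage),        # -> 0.75
        CrossingStage(composite, 0.5, breed_b, 0.0, n_per_stage),        # -> 0.25
        CrossingStage(composite, 0.25, composite, 0.75, n_per_stage),    # -> 0.50 fixed
        CrossingStage(composite, 0.5, composite, 0.5, n_per_stage),      # inter se
    ]


def simulate_composite(
    cfg_a: SimulationConfig,
    cfg_b: SimulationConfig,
    scheme: Sequence[CrossingStage] | None = None,
    seed: int = 0,
    breed_a: str = "A",
    breed_b: str = "B",
    composite: str = "AB",
) -> tuple[Pedigree, dict[str, float]]:
    """Two purebreds plus a staged composite in one merged pedigree.

    Returns the pedigree and a dict of ancestry fractions (proportion of
    ``breed_a`` blood) for every animal — purebred A animals are 1.0, B are
    0.0, composites the mean of their parents.  The fractions are truth
    labels for tests; analyses never read them.
    """
    if scheme is None:
        scheme = default_composite_scheme(breed_a, breed_b, composite=composite)
    rng = np.random.default_rng(seed)
    recs_a = _grow_purebred(cfg_a, breed_a, rng, id_prefix=breed_a)
    recs_b = _grow_purebred(cfg_b, breed_b, rng, id_prefix=breed_b)
    records = recs_a + recs_b
    frac: dict[str, float] = {}
    for r in recs_a:
        frac[r.id] = 1.0
    for r in recs_b:
        frac[r.id] = 0.0
    breed_of = {r.id: r.breed for r in records}
    sex_of = {r.id: r.sex for r in records}
    alive_ids = [r.id for r in records]
    counter = 0
    last_year = max(r.birth_year for r in records if r.birth_year is not None)
    for si, stage in enumerate(scheme, start=1):
        sires = [
            a
            for a in alive_ids
            if breed_of[a] == stage.sire_breed
            and sex_of[a] == "M"
            and np.isclose(frac[a], stage.sire_fraction)
        ]
        dams = [
            a
            for a in alive_ids
            if breed_of[a] == stage.dam_breed
            and sex_of[a] == "F"
            and np.isclose(frac[a], stage.dam_fraction)
        ]
        if not sires or not dams:
            raise PedigreeError(
                f"stage {si}: no {'sires' if not sires else 'dams'} with breed/fraction "
                f"({stage.sire_breed}/{stage.sire_fraction}, {stage.dam_breed}/{stage.dam_fraction})"
            )
        year = last_year + si * min(cfg_a.generation_step, cfg_b.generation_step) / 2.0
        sexes = _draw_sexes(rng, stage.n_offspring, 0.5)
        for j in range(stage.n_offspring):
            counter += 1
            cid = f"{composite}{counter:05d}"
            s = sires[rng.integers(len(sires))]
            d = dams[rng.integers(len(dams))]
            records.append(
                AnimalRecord(
                    id=cid, sire=s, dam=d, sex=sexes[j], birth_year=year,
                    breed=composite, alive=True,
                )
            )
            frac[cid] = 0.5 * (frac[s] + frac[d])
            breed_of[cid] = composite
            sex_of[cid] = sexes[j]
            alive_ids.append(cid)
    return Pedigree.from_records(records), frac


def ideal_population(n: int, generations: int, seed: int = 0) -> Pedigree:
    """Wright-Fisher-like idealized pedigree: the oracle for Ne recovery.

    Discrete non-overlapping generations of constant size ``n`` with an equal
    sex ratio; each offspring draws its sire uniformly from the previous
    generation's males and its dam from its females (monogamy not enforced).
    Under this idealization the realized effective size estimated downstream
    from the mean rate of inbreeding is ~n.
    """
    if n % 2 != 0 or n < 4:
        raise ValueError("n must be even and >= 4")
    if generations < 1:
        raise ValueError("need at least 1 generation")
    rng = np.random.default_rng(seed)
    records: list[AnimalRecord] = []
    half = n // 2
    cohort: list[AnimalRecord] = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"I{counter:06d}"

    for j in range(n):
        rec = AnimalRecord(
            id=new_id(), sex="M" if j < half else "F", birth_year=2000.5, breed="IDEAL",
            alive=False,
        )
        records.append(rec)
        cohort.append(rec)
    for g in range(1, generations + 1):
        males = cohort[:half] if g == 1 else [r for r in cohort if r.sex == "M"]
        females = cohort[half:] if g == 1 else [r for r in cohort if r.sex == "F"]
        new_cohort = []
        terminal = g == generations
        for j in range(n):
            rec = AnimalRecord(
                id=new_id(),
                sire=males[rng.integers(len(males))].id,
                dam=females[rng.integers(len(females))].id,
                sex="M" if j < half else "F",
                birth_year=2000.5 + g,
                breed="IDEAL",
                alive=terminal,
            )
            records.append(rec)
            new_cohort.append(rec)
        cohort = new_cohort
    return Pedigree.from_records(records)
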