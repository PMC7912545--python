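"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import sys

import numpy as np
import pytest

import pedstruct as ps


# ---------------------------------------------------------------------------
# independent oracle: textbook recursive coancestry -> dense relationship matrix


def oracle_relationship_matrix(ped: ps.Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix from the recursive coancestry
    definition (f_xx = (1 + f_sd)/2, f_xy = (f_x,sy + f_x,dy)/2), written
    independently of the package's Meuwissen-Luo / indirect-product paths.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    memo: dict[tuple[int, int], float] = {}
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * n + 1000))

    def f(x: int, y: int) -> float:
        if x < 0 or y < 0:
            return 0.0
        if x > y:
            x, y = y, x
        key = (x, y)
        if key not in memo:
            if x == y:
                memo[key] = 0.5 * (1.0 + f(sire[x], dam[x]))
            else:
                memo[key] = 0.5 * (f(x, sire[y]) + f(x, dam[y]))
        return memo[key]

    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = 2.0 * f(i, j)
    return A


# ---------------------------------------------------------------------------
# small hand-built pedigrees


@pytest.fixture
def fullsib_ped() -> ps.Pedigree:
    """Full-sib mating: offspring X of full sibs S and D; F_X = 0.25."""
    return ps.Pedigree.from_records(
        [
            ps.AnimalRecord("G1", sex="M"),
            ps.AnimalRecord("G2", sex="F"),
            ps.AnimalRecord("S", "G1", "G2", "M"),
            ps.AnimalRecord("D", "G1", "G2", "F"),
            ps.AnimalRecord("X", "S", "D", "M"),
        ]
    )


@pytest.fixture
def trio_ped() -> ps.Pedigree:
    """Two unrelated founders and their offspring."""
    return ps.Pedigree.from_records(
        [
            ps.AnimalRecord("A", sex="M"),
            ps.AnimalRecord("B", sex="F"),
            ps.AnimalRecord("C", "A", "B", "F"),
        ]
    )


def founders_only(n: int) -> ps.Pedigree:
    return ps.Pedigree.from_records(
        [ps.AnimalRecord(f"F{i}", sex="M" if i % 2 else "F") for i in range(n)]
    )


# ---------------------------------------------------------------------------
# simulated pedigrees (session-scoped: reused across modules)


@pytest.fixture(scope="session")
def sim_ped200() -> ps.Pedigree:
    """~200-animal purebred pedigree with some missing parents."""
    cfg = ps.SimulationConfig(
        n_founders_per_breed=30, n_generations=6, missing_parent_rate=0.05, seed=11
    )
    return ps.simulate_purebred(cfg, breed="P")


@pytest.fixture(scope="session")
def composite_small():
    """Small two-purebred + composite pedigree with ancestry fractions."""
    a = ps.SimulationConfig(n_founders_per_breed=20, n_generations=4, seed=1)
    b = ps.SimulationConfig(n_founders_per_breed=20, n_generations=4, seed=2)
    return ps.simulate_composite(a, b, seed=3)


def majority_scheme(n1=20, n2=30, n3=30) -> list[ps.CrossingStage]:
    """Composite scheme with ~70:30 A:B ancestry in the composite cohort.

    F1 (0.5), backcross to A (0.75), then 0.75 x 0.75 inter se; the composite
    animals average ~0.69 A blood.
    """
    return [
        ps.CrossingStage("A", 1.0, "B", 0.0, n1),
        ps.CrossingStage("A", 1.0, "AB", 0.5, n2),
        ps.CrossingStage("AB", 0.75, "AB", 0.75, n3),
    ]
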