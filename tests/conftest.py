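"""Shared fixtures: hand-built pedigrees and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from famgxe.pedigree import Individual, Pedigree, compute_kinship


@pytest.fixture
def trio() -> Pedigree:
    """Two unrelated founders and their child."""
    return Pedigree(
        [
            Individual("1", "F1", sex="male"),
            Individual("2", "F1", sex="female"),
            Individual("3", "F1", "1", "2", "male"),
        ]
    )


@pytest.fixture
def sib_pedigree() -> Pedigree:
    """Founder couple with two full siblings."""
    return Pedigree(
        [
            Individual("p", "F1", sex="male"),
            Individual("m", "F1", sex="female"),
            Individual("s1", "F1", "p", "m", "male"),
            Individual("s2", "F1", "p", "m", "female"),
        ]
    )


def inbred_pedigree_20() -> Pedigree:
    """20 members, 3 generations, one inbred loop (half-sib mating).

    A1 has children with both A2 and B2; the half-sibs C4 and C2 mate,
    so I1 carries inbreeding coefficient F = 1/8 (K_ii = 1.125).
    """
    rows = [
        ("A1", "0", "0", "male"),
        ("A2", "0", "0", "female"),
        ("B1", "0", "0", "male"),
        ("B2", "0", "0", "female"),
        ("S1", "0", "0", "female"),
        ("S2", "0", "0", "female"),
        ("C1", "A1", "A2", "male"),
        ("C2", "A1", "A2", "female"),
        ("C3", "A1", "A2", "male"),
        ("C4", "A1", "B2", "male"),
        ("D1", "B1", "B2", "female"),
        ("D2", "B1", "B2", "male"),
        ("E1", "C1", "D1", "male"),
        ("E2", "C1", "D1", "female"),
        ("E3", "C1", "D1", "male"),
        ("I1", "C4", "C2", "female"),
        ("E4", "D2", "S2", "male"),
        ("E5", "D2", "S2", "female"),
        ("E6", "C3", "S1", "male"),
        ("E7", "C3", "S1", "female"),
    ]
    return Pedigree(
        [
            Individual(i, "F1", None if f == "0" else f, None if m == "0" else m, s)
            for i, f, m, s in rows
        ]
    )


@pytest.fixture(name="inbred_pedigree")
def inbred_pedigree_fixture() -> Pedigree:
    return inbred_pedigree_20()


def random_pedigree(rng: np.random.Generator, max_members: int = 20) -> Pedigree:
    """Small random multi-generation pedigree for oracle comparisons."""
    n_found = int(rng.integers(2, 5)) * 2
    inds = [
        Individual(f"f{i}", "F1", sex="male" if i % 2 == 0 else "female")
        for i in range(n_found)
    ]
    next_id = 0
    gen = list(inds)
    for _ in range(int(rng.integers(1, 3))):
        nxt = []
        males = [p for p in gen if p.sex == "male"]
        females = [p for p in gen if p.sex == "female"]
        for dad, mom in zip(males, females):
            for _ in range(int(rng.integers(0, 4))):
                if len(inds) >= max_members:
                    break
                sex = "male" if rng.random() < 0.5 else "female"
                child = Individual(f"c{next_id}", "F1", dad.id, mom.id, sex)
                next_id += 1
                inds.append(child)
                nxt.append(child)
        gen = nxt or gen
    return Pedigree(inds)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def trio_kinship(trio):
    return compute_kinship(trio)
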