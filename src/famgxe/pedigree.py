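"""Pedigree structures and the additive genetic relationship matrix.

A pedigree is an acyclic graph of individuals with optional father/mother
links.  From it we compute the additive (numerator) relationship matrix
``K = 2Φ``, where Φ is the matrix of kinship coefficients: the probability
that a random allele drawn from each of two individuals is identical by
descent.  Under this convention a non-inbred individual has ``K_ii = 1``
(more generally ``1 + F`` with F the inbreeding coefficient), a non-inbred
parent-offspring or full-sib pair has ``K_ij = 0.5``, and the phenotypic
covariance model ``Σ = K σg² + I σe²`` assigns additive genetic variance
σg² to a non-inbred individual.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "compute_kinship",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or object."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids are ``None`` for (unknown) founders."""

    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # "male" | "female" | "unknown"


_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_CODES_OUT = {"male": "1", "female": "2", "unknown": "0"}


class Pedigree:
    """An ordered collection of :class:`Individual` with resolved parent links.

    Ids are opaque strings, globally unique across families.  Construction
    validates that parent references resolve (individuals referenced only as
    parents are added as unknown-sex founders) and that the graph is acyclic;
    a topological order (parents before offspring) is computed once and
    reused by downstream algorithms.
    """

    def __init__(self, individuals: list[Individual]):
        seen: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in seen:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            seen[ind.id] = ind
        # add parents that never occur as rows: unknown founders
        extras: list[Individual] = []
        for ind in individuals:
            for pid, sex in ((ind.father_id, "male"), (ind.mother_id, "female")):
                if pid is not None and pid not in seen:
                    founder = Individual(id=pid, family_id=ind.family_id, sex=sex)
                    seen[pid] = founder
                    extras.append(founder)
        self.individuals: list[Individual] = list(individuals) + extras
        self._index = {ind.id: i for i, ind in enumerate(self.individuals)}
        self._topo = self._topological_order()

    def _topological_order(self) -> list[int]:
        n = len(self.individuals)
        n_parents = np.zeros(n, dtype=int)
        children: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, ind in enumerate(self.individuals):
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    if pid == ind.id:
                        raise PedigreeError(
                            f"cycle: individual {ind.id!r} is its own parent"
                        )
                    p = self._index[pid]
                    n_parents[i] += 1
                    children[p].append(i)
        order: list[int] = []
        ready = deque(i for i in range(n) if n_parents[i] == 0)
        while ready:
            i = ready.popleft()
            order.append(i)
            for c in children[i]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    ready.append(c)
        if len(order) != n:
            bad = [self.individuals[i].id for i in range(n) if n_parents[i] > 0]
            raise PedigreeError(f"cycle: individuals {bad} are their own ancestors")
        return order

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def family_ids(self) -> list[str]:
        return [ind.family_id for ind in self.individuals]

    def index_of(self, ind_id: str) -> int:
        return self._index[ind_id]

    def founders(self) -> list[Individual]:
        return [
            ind
            for ind in self.individuals
            if ind.father_id is None and ind.mother_id is None
        ]

    def family_blocks(self) -> dict[str, np.ndarray]:
        """Index arrays grouping individuals by family, in pedigree order."""
        blocks: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individuals):
            blocks.setdefault(ind.family_id, []).append(i)
        return {fam: np.asarray(ix, dtype=int) for fam, ix in blocks.items()}


@dataclass
class KinshipMatrix:
    """Dense additive relationship matrix ``K = 2Φ`` with its id map."""

    values: np.ndarray
    ids: list[str]
    id_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship matrix must be square")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("id list does not match matrix dimension")
        self.id_index = {s: i for i, s in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        """Sub-matrix for an analysis sample, preserving the requested order.

        Relatedness computed through unphenotyped connectors is retained
        because the full pedigree matrix is computed first and subset after.
        """
        ix = np.array([self.id_index[s] for s in ids], dtype=int)
        return KinshipMatrix(self.values[np.ix_(ix, ix)], list(ids))

    def to_tsv(self, path, sparse: bool = True) -> None:
        """Write as (id1, id2, value) triplets (upper triangle, nonzero) or dense."""
        if sparse:
            rows = []
            for i in range(self.n):
                for j in range(i, self.n):
                    v = self.values[i, j]
                    if v != 0.0:
                        rows.append((self.ids[i], self.ids[j], v))
            pd.DataFrame(rows, columns=["id1", "id2", "kinship2"]).to_csv(
                path, sep="\t", index=False
            )
        else:
            pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
                path, sep="\t"
            )

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        """Read a sparse triplet file written by :meth:`to_tsv`."""
        df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
        ids = list(dict.fromkeys(pd.concat([df["id1"], df["id2"]])))
        index = {s: i for i, s in enumerate(ids)}
        k = np.zeros((len(ids), len(ids)))
        for id1, id2, v in df.itertuples(index=False):
            i, j = index[id1], index[id2]
            k[i, j] = v
            k[j, i] = v
        return cls(k, ids)


def read_pedigree(path, dialect: str = "linkage") -> Pedigree:
    """Read a pedigree file in LINKAGE pre-makeped or PLINK ``.fam`` layout.

    Both dialects are whitespace- or tab-delimited with columns
    ``family id father mother sex [...]``; ``0`` denotes an unknown parent
    and sex is coded 1 = male, 2 = female, 0 = unknown.  PLINK ``.fam``
    carries a sixth phenotype column, which is ignored.
    """
    if dialect not in ("linkage", "plink_fam"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 5:
                raise PedigreeError(
                    f"line {lineno}: expected >= 5 columns, got {len(parts)}"
                )
            fam, iid, fid, mid, sex_code = parts[:5]
            if sex_code not in _SEX_CODES:
                raise PedigreeError(
                    f"line {lineno}: unparseable sex code {sex_code!r}"
                )
            individuals.append(
                Individual(
                    id=iid,
                    family_id=fam,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_CODES[sex_code],
                )
            )
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write in the 5-column LINKAGE layout consumed by :func:`read_pedigree`."""
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(
                f"{ind.family_id}\t{ind.id}\t{ind.father_id or 0}\t"
                f"{ind.mother_id or 0}\t{_SEX_CODES_OUT[ind.sex]}\n"
            )


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Additive relationship matrix ``K = 2Φ`` by the tabular recursion.

    Processing individuals parents-before-offspring:

    * founders: ``K_ii = 1``, unrelated to everyone already placed;
    * offspring ``i`` with parents f, m: ``K_ij = (K_jf + K_jm) / 2`` for
      every earlier ``j``, and ``K_ii = 1 + K_fm / 2`` (the ``K_fm / 2``
      term is the inbreeding coefficient, the kinship of the parents).

    An unknown parent contributes 0, i.e. behaves as a unique unrelated
    founder.
    """
    n = len(ped)
    k = np.zeros((n, n))
    placed = np.zeros(n, dtype=bool)
    for i in ped._topo:
        ind = ped.individuals[i]
        f = ped._index[ind.father_id] if ind.father_id is not None else None
        m = ped._index[ind.mother_id] if ind.mother_id is not None else None
        row = np.zeros(n)
        if f is not None:
            row += 0.5 * k[f]
        if m is not None:
            row += 0.5 * k[m]
        row[~placed] = 0.0
        k[i, :] = row
        k[:, i] = row
        k[i, i] = 1.0 + (0.5 * k[f, m] if f is not None and m is not None else 0.0)
        placed[i] = True
    return KinshipMatrix(k, ped.ids)
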