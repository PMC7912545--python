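"""Pedigree container: validated, topologically ordered animal records.

A :class:`Pedigree` is the substrate every analysis in this package runs on.
It holds one record per animal (identifier, sire, dam, sex, birth year, breed
label, alive flag) with parents guaranteed to precede offspring, so that all
recursive quantities (inbreeding, contributions, generation counts) can be
computed in a single forward pass over the arrays.

Missing parents are coded internally as index ``-1`` (``None`` at the record
level).  Dangling parent references — ids used as a parent but never recorded,
which real studbooks contain — are by default materialized as phantom founders
and logged.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: sex codes
MALE = "M"
FEMALE = "F"
UNKNOWN_SEX = "U"


class PedigreeError(ValueError):
    """Raised for structural problems in a pedigree (duplicates, cycles...)."""


@dataclass(frozen=True)
class AnimalRecord:
    """One studbook entry.

    ``sire``/``dam`` are ids of other records or ``None`` when unknown.
    ``birth_year`` is a decimal year (e.g. 2004.5); ``None`` when unrecorded.
    """

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = UNKNOWN_SEX
    birth_year: float | None = None
    breed: str = ""
    alive: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("animal id must be a non-empty string")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"animal {self.id!r} listed as its own parent")
        if self.sex not in (MALE, FEMALE, UNKNOWN_SEX):
            raise PedigreeError(f"invalid sex code {self.sex!r} for {self.id!r}")


class Pedigree:
    """Topologically ordered collection of :class:`AnimalRecord`.

    Construct with :meth:`from_records`; the constructor assumes its inputs
    are already ordered and consistent.  ``focal`` marks the animals a subset
    operation selected (ancestors kept only as computational context); it is
    all-true for a freshly read pedigree.
    """

    def __init__(
        self,
        ids: Sequence[str],
        sire: np.ndarray,
        dam: np.ndarray,
        sex: np.ndarray,
        birth_year: np.ndarray,
        breed: np.ndarray,
        alive: np.ndarray,
        focal: np.ndarray | None = None,
    ) -> None:
        self.ids = list(ids)
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        self.sex = np.asarray(sex, dtype="<U1")
        self.birth_year = np.asarray(birth_year, dtype=float)
        self.breed = np.asarray(breed, dtype=object)
        self.alive = np.asarray(alive, dtype=bool)
        self.focal = (
            np.ones(len(self.ids), dtype=bool) if focal is None else np.asarray(focal, dtype=bool)
        )
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate ids passed to Pedigree constructor")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[AnimalRecord],
        on_missing_parent: str = "phantom",
    ) -> "Pedigree":
        """Validate, resolve parent links and topologically sort.

        Parameters
        ----------
        records:
            Animal records in any order.
        on_missing_parent:
            ``"phantom"`` creates founder records for parent ids that have no
            record of their own (logged); ``"error"`` raises.
        """
        recs = list(records)
        seen: dict[str, AnimalRecord] = {}
        for r in recs:
            if r.id in seen:
                raise PedigreeError(f"duplicate animal id {r.id!r}")
            seen[r.id] = r

        # dangling parent references -> phantom founders
        phantoms: list[AnimalRecord] = []
        for r in recs:
            for parent, psex in ((r.sire, MALE), (r.dam, FEMALE)):
                if parent is not None and parent not in seen:
                    if on_missing_parent == "error":
                        raise PedigreeError(
                            f"parent {parent!r} of {r.id!r} has no record"
                        )
                    ph = AnimalRecord(id=parent, sex=psex, alive=False)
                    seen[parent] = ph
                    phantoms.append(ph)
        if phantoms:
            logger.warning(
                "created %d phantom founder(s) for dangling parent references: %s",
                len(phantoms),
                ", ".join(p.id for p in phantoms[:10]) + ("..." if len(phantoms) > 10 else ""),
            )
        recs = recs + phantoms

        # sex consistency: an id used as sire must not be recorded female, etc.
        resolved_sex: dict[str, str] = {r.id: r.sex for r in recs}
        for r in recs:
            for parent, want in ((r.sire, MALE), (r.dam, FEMALE)):
                if parent is None:
                    continue
                have = resolved_sex[parent]
                if have == UNKNOWN_SEX:
                    resolved_sex[parent] = want
                elif have != want:
                    role = "sire" if want == MALE else "dam"
                    raise PedigreeError(
                        f"animal {parent!r} recorded as {have} but used as {role} of {r.id!r}"
                    )

        order = _stable_toposort(recs, {r.id: i for i, r in enumerate(recs)})
        ordered = [recs[i] for i in order]
        idx = {r.id: i for i, r in enumerate(ordered)}
        n = len(ordered)
        sire = np.array([idx[r.sire] if r.sire is not None else -1 for r in ordered])
        dam = np.array([idx[r.dam] if r.dam is not None else -1 for r in ordered])
        return cls(
            ids=[r.id for r in ordered],
            sire=sire,
            dam=dam,
            sex=np.array([resolved_sex[r.id] for r in ordered]),
            birth_year=np.array(
                [np.nan if r.birth_year is None else float(r.birth_year) for r in ordered]
            ),
            breed=np.array([r.breed for r in ordered], dtype=object),
            alive=np.array([r.alive for r in ordered]),
        )

    # -- protocol ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def index(self, animal_id: str) -> int:
        try:
            return self._index[animal_id]
        except KeyError:
            raise KeyError(f"unknown animal id {animal_id!r}") from None

    def record(self, i: int) -> AnimalRecord:
        s, d = self.sire[i], self.dam[i]
        by = self.birth_year[i]
        return AnimalRecord(
            id=self.ids[i],
            sire=self.ids[s] if s >= 0 else None,
            dam=self.ids[d] if d >= 0 else None,
            sex=str(self.sex[i]),
            birth_year=None if np.isnan(by) else float(by),
            breed=str(self.breed[i]),
            alive=bool(self.alive[i]),
        )

    def records(self) -> Iterator[AnimalRecord]:
        return (self.record(i) for i in range(len(self)))

    # -- derived masks -----------------------------------------------------

    @property
    def is_founder(self) -> np.ndarray:
        """Both parents unknown."""
        return (self.sire < 0) & (self.dam < 0)

    @property
    def n_known_parents(self) -> np.ndarray:
        return (self.sire >= 0).astype(int) + (self.dam >= 0).astype(int)

    @property
    def focal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.focal)

    def to_frame(self):
        """Pedigree content as a pandas DataFrame (one row per animal)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.ids[s] if s >= 0 else None for s in self.sire],
                "dam": [self.ids[d] if d >= 0 else None for d in self.dam],
                "sex": self.sex,
                "birth_year": self.birth_year,
                "breed": self.breed,
                "alive": self.alive,
            }
        )

    # -- subsetting --------------------------------------------------------

    def ancestors_of(self, indices: np.ndarray) -> np.ndarray:
        """Boolean mask of ``indices`` plus all their known ancestors."""
        keep = np.zeros(len(self), dtype=bool)
        keep[indices] = True
        # reverse topological order: children before parents
        for i in range(len(self) - 1, -1, -1):
            if keep[i]:
                if self.sire[i] >= 0:
                    keep[self.sire[i]] = True
                if self.dam[i] >= 0:
                    keep[self.dam[i]] = True
        return keep

    def subset(self, focal_mask: np.ndarray) -> "Pedigree":
        """Pedigree restricted to ``focal_mask`` animals plus their ancestors.

        Ancestors outside the focal set are retained as context; the result's
        ``focal`` attribute marks the requested animals.
        """
        focal_mask = np.asarray(focal_mask, dtype=bool)
        if not focal_mask.any():
            raise PedigreeError("selection produced an empty pedigree")
        keep = self.ancestors_of(np.flatnonzero(focal_mask))
        old_to_new = -np.ones(len(self), dtype=np.int64)
        old_to_new[keep] = np.arange(int(keep.sum()))
        remap = lambda arr: np.where(arr[keep] >= 0, old_to_new[np.clip(arr[keep], 0, None)], -1)
        return Pedigree(
            ids=[a for a, k in zip(self.ids, keep) if k],
            sire=remap(self.sire),
            dam=remap(self.dam),
            sex=self.sex[keep],
            birth_year=self.birth_year[keep],
            breed=self.breed[keep],
            alive=self.alive[keep],
            focal=focal_mask[keep],
        )


def _stable_toposort(recs: list[AnimalRecord], pos: dict[str, int]) -> list[int]:
    """Kahn's algorithm with a min-heap on original position.

    Deterministic: re-reading the same file always yields the same order.
    Raises :class:`PedigreeError` listing a cycle if one exists.
    """
    n = len(recs)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for i, r in enumerate(recs):
        for p in (r.sire, r.dam):
            if p is not None:
                children[pos[p]].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) < n:
        cyc = [recs[i].id for i in range(n) if indeg[i] > 0]
        raise PedigreeError(f"parent links form a cycle through: {cyc}")
    return order
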