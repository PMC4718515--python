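"""Pedigree data model, kinship and household covariance, relative-pair classification.

The central objects are :class:`Pedigree` (a validated, topologically ordered
collection of individuals partitioned into families) and the two covariance
structures used by the variance-component models: the additive relationship
matrix ``2*Phi`` (twice the kinship coefficient, block-diagonal by family) and
the household-sharing indicator matrix ``H``.

Kinship is computed by the classic recursive founder-to-descendant algorithm:

    Phi(i, i) = 1/2 + Phi(father_i, mother_i) / 2
    Phi(i, j) = (Phi(father_i, j) + Phi(mother_i, j)) / 2    for j before i

with founders assumed non-inbred and mutually unrelated.  We store ``2*Phi``
throughout, so a parent-offspring pair has entry 0.5 and a non-inbred
individual has diagonal 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "HouseholdMatrix",
    "PedigreeError",
    "build_pedigree",
    "kinship_matrix",
    "household_matrix",
    "classify_pairs",
]

MALE = "male"
FEMALE = "female"

#: canonical 2*Phi values for the named relationship classes
PAIR_CLASS_VALUES = {
    "self": 1.0,
    "parent-offspring": 0.5,
    "siblings": 0.5,
    "grandparent-grandchild": 0.25,
    "avuncular": 0.25,
    "half siblings": 0.25,
    "double 1st cousins": 0.25,
    "3rd degree": 0.125,
    "4th degree": 0.0625,
    "5th degree": 0.03125,
    "6th degree": 0.015625,
    "7th degree": 0.0078125,
    "unrelated": 0.0,
}


class PedigreeError(ValueError):
    """Structural, referential or validation problem in a pedigree."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id``/``household_id`` are ``None`` when missing.
    A missing household means the individual shares a household with nobody.
    """

    id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str
    household_id: Optional[str] = None
    proband: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """Validated pedigree, individuals topologically ordered (parents first)."""

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals = list(individuals)
        self.ids = [ind.id for ind in self.individuals]
        self._index = {iid: k for k, iid in enumerate(self.ids)}
        self.families: dict[str, list[str]] = {}
        for ind in self.individuals:
            self.families.setdefault(ind.family_id, []).append(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[self._index[iid]]

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    @property
    def founders(self) -> list[str]:
        return [ind.id for ind in self.individuals if ind.is_founder]

    def founder_mask(self) -> np.ndarray:
        return np.array([ind.is_founder for ind in self.individuals])

    def children_of(self, iid: str) -> list[str]:
        return [
            ind.id
            for ind in self.individuals
            if iid in (ind.father_id, ind.mother_id)
        ]

    def generation_depth(self) -> dict[str, int]:
        """Depth from the family's founding generation (founders at depth 0).

        A married-in founder takes the depth of their co-parent's generation so
        that spouses share a generation.
        """
        depth = {}
        for ind in self.individuals:  # topological order: parents first
            if ind.is_founder:
                depth[ind.id] = 0
            else:
                depth[ind.id] = 1 + max(depth[ind.father_id], depth[ind.mother_id])
        # lift married-in founders to their spouse's level
        for ind in self.individuals:
            if not ind.is_founder:
                level = depth[ind.id] - 1
                for pid in (ind.father_id, ind.mother_id):
                    if self[pid].is_founder and depth[pid] < level:
                        depth[pid] = level
        return depth

    def first_degree_relatives(self, iid: str) -> set[str]:
        """Parents, offspring and full siblings of ``iid``."""
        ind = self[iid]
        rels = {p for p in (ind.father_id, ind.mother_id) if p is not None}
        rels.update(self.children_of(iid))
        if ind.father_id is not None and ind.mother_id is not None:
            for other in self.individuals:
                if (
                    other.id != iid
                    and other.father_id == ind.father_id
                    and other.mother_id == ind.mother_id
                ):
                    rels.add(other.id)
        return rels

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per individual, topological order)."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "family_id": [i.family_id for i in self.individuals],
                "father_id": [i.father_id for i in self.individuals],
                "mother_id": [i.mother_id for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "household_id": [i.household_id for i in self.individuals],
                "proband": [i.proband for i in self.individuals],
            }
        )

    def subset_families(self, family_ids: Iterable[str]) -> "Pedigree":
        keep = set(family_ids)
        return Pedigree([i for i in self.individuals if i.family_id in keep])

    def with_probands(self, proband_ids: Iterable[str]) -> "Pedigree":
        flag = set(proband_ids)
        return Pedigree(
            [
                Individual(
                    i.id, i.family_id, i.father_id, i.mother_id, i.sex,
                    i.household_id, proband=i.id in flag,
                )
                for i in self.individuals
            ]
        )


@dataclass
class KinshipMatrix:
    """Additive relationship matrix ``2*Phi``, block-diagonal by family."""

    ids: list[str]
    families: list[str]
    values: np.ndarray

    def __post_init__(self):
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def loc(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def family_blocks(self) -> dict[str, np.ndarray]:
        """Member index arrays per family, in matrix order."""
        fams = np.asarray(self.families)
        return {f: np.flatnonzero(fams == f) for f in dict.fromkeys(self.families)}

    def submatrix(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = np.array([self._index[i] for i in ids])
        return KinshipMatrix(
            list(ids),
            [self.families[k] for k in idx],
            self.values[np.ix_(idx, idx)],
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (id1, id2, 2phi) for nonzero entries, upper triangle."""
        iu, ju = np.triu_indices(len(self.ids))
        vals = self.values[iu, ju]
        nz = vals != 0
        return pd.DataFrame(
            {
                "id1": [self.ids[k] for k in iu[nz]],
                "id2": [self.ids[k] for k in ju[nz]],
                "2phi": vals[nz],
            }
        )


@dataclass
class HouseholdMatrix:
    """0/1 indicator of household sharing (diagonal 1)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def loc(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def submatrix(self, ids: Sequence[str]) -> "HouseholdMatrix":
        idx = np.array([self._index[i] for i in ids])
        return HouseholdMatrix(list(ids), self.values[np.ix_(idx, idx)])


def _norm_missing(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s in ("", "0", "NA", "nan", "None", "."):
        return None
    return s


_SEX_CODES = {
    "1": MALE, "2": FEMALE,
    "m": MALE, "f": FEMALE,
    "male": MALE, "female": FEMALE,
}


def _norm_sex(value) -> str:
    s = str(value).strip().lower()
    try:
        return _SEX_CODES[s]
    except KeyError:
        raise PedigreeError(f"unknown sex code {value!r}") from None


def build_pedigree(records) -> Pedigree:
    """Validate and topologically order raw individual records.

    Parameters
    ----------
    records
        ``pandas.DataFrame`` or iterable of mappings with columns/keys
        ``id``, ``family_id``, ``father_id``, ``mother_id``, ``sex`` and
        optionally ``household_id`` and ``proband``.  ``0``/``NA``/empty
        denote a missing parent or household.

    Raises
    ------
    PedigreeError
        On duplicate ids, dangling parent references, sex-inconsistent
        parents, cross-family parents, or cycles (an individual being its
        own ancestor).
    """
    if isinstance(records, pd.DataFrame):
        rows = records.to_dict("records")
    else:
        rows = [dict(r) for r in records]
    if not rows:
        raise PedigreeError("empty pedigree")

    inds: dict[str, Individual] = {}
    order: list[str] = []
    for row in rows:
        iid = _norm_missing(row.get("id"))
        if iid is None:
            raise PedigreeError(f"missing individual id in row {row!r}")
        if iid in inds:
            raise PedigreeError(f"duplicate individual id {iid!r}")
        inds[iid] = Individual(
            id=iid,
            family_id=str(row.get("family_id", "F1")),
            father_id=_norm_missing(row.get("father_id")),
            mother_id=_norm_missing(row.get("mother_id")),
            sex=_norm_sex(row.get("sex")),
            household_id=_norm_missing(row.get("household_id")),
            proband=bool(int(row.get("proband", 0) or 0)),
        )
        order.append(iid)

    for ind in inds.values():
        for role, pid, want in (
            ("father", ind.father_id, MALE),
            ("mother", ind.mother_id, FEMALE),
        ):
            if pid is None:
                continue
            if pid not in inds:
                raise PedigreeError(
                    f"{role} {pid!r} of {ind.id!r} is not in the pedigree"
                )
            if inds[pid].sex != want:
                raise PedigreeError(
                    f"{role} {pid!r} of {ind.id!r} is not {want}"
                )
            if inds[pid].family_id != ind.family_id:
                raise PedigreeError(
                    f"parent {pid!r} of {ind.id!r} is in a different family"
                )

    # Kahn topological sort; founders keep file order and precede everyone.
    from collections import deque

    n_parents = {
        iid: sum(p is not None for p in (ind.father_id, ind.mother_id))
        for iid, ind in inds.items()
    }
    children: dict[str, list[str]] = {iid: [] for iid in order}
    for iid in order:
        ind = inds[iid]
        for p in (ind.father_id, ind.mother_id):
            if p is not None:
                children[p].append(iid)
    queue = deque(iid for iid in order if n_parents[iid] == 0)
    sorted_ids: list[str] = []
    while queue:
        iid = queue.popleft()
        sorted_ids.append(iid)
        for cid in children[iid]:
            n_parents[cid] -= 1
            if n_parents[cid] == 0:
                queue.append(cid)
    if len(sorted_ids) != len(inds):
        stuck = sorted(set(order) - set(sorted_ids))
        raise PedigreeError(
            f"cycle detected in pedigree involving individual(s) {stuck[:5]}"
        )

    ped = Pedigree([inds[iid] for iid in sorted_ids])
    for fam, members in ped.families.items():
        if not any(ped[m].is_founder for m in members):
            raise PedigreeError(f"family {fam!r} has no founder")
    return ped


def family_kinship_block(ped: Pedigree, members: Sequence[str]) -> np.ndarray:
    """``2*Phi`` for the members of one family (topological order assumed)."""
    local = {iid: k for k, iid in enumerate(members)}
    m = len(members)
    K = np.zeros((m, m))
    for i, iid in enumerate(members):
        ind = ped[iid]
        if ind.is_founder:
            K[i, i] = 1.0
            continue
        fi = local[ind.father_id]
        mi = local[ind.mother_id]
        if fi >= i or mi >= i:
            raise RuntimeError("pedigree not topologically ordered")
        # 2*Phi(i,i) = 1 + Phi(f,m) = 1 + (2*Phi(f,m))/2
        K[i, i] = 1.0 + 0.5 * K[fi, mi]
        prev = np.arange(i)
        row = 0.5 * (K[fi, prev] + K[mi, prev])
        K[i, prev] = row
        K[prev, i] = row
    return K


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Twice the kinship coefficient for every pair, by the recursive algorithm.

    Founders are assumed non-inbred and mutually unrelated, so the diagonal is
    ``1 + F`` with ``F`` the inbreeding coefficient, and entries between
    members of different families are exactly zero (block-diagonal by family).
    """
    n = len(ped)
    K = np.zeros((n, n))
    for fam, members in ped.families.items():
        block = family_kinship_block(ped, members)
        gidx = np.array([ped.index_of(m) for m in members])
        K[np.ix_(gidx, gidx)] = block
    fams = [ind.family_id for ind in ped.individuals]
    return KinshipMatrix(list(ped.ids), fams, K)


def household_matrix(ped: Pedigree) -> HouseholdMatrix:
    """Indicator of shared (non-missing) household; diagonal always 1."""
    hh = [ind.household_id for ind in ped.individuals]
    n = len(hh)
    H = np.eye(n)
    arr = np.array([h if h is not None else f"\x00missing{k}" for k, h in enumerate(hh)])
    same = arr[:, None] == arr[None, :]
    H[same] = 1.0
    return HouseholdMatrix(list(ped.ids), H)


def _structural_label(ped: Pedigree, a: Individual, b: Individual, two_phi: float) -> str:
    """Name the relationship of a within-family pair from pedigree structure."""
    if a.id == b.id:
        return "self"
    pa = {p for p in (a.father_id, a.mother_id) if p is not None}
    pb = {p for p in (b.father_id, b.mother_id) if p is not None}
    if b.id in pa or a.id in pb:
        return "parent-offspring"
    if pa and pa == pb:
        return "siblings"
    shared = pa & pb
    if shared and len(pa) == 2 and len(pb) == 2:
        return "half siblings"
    # grandparent: a parent of one is a child of the other
    for pid in pa:
        if {q for q in (ped[pid].father_id, ped[pid].mother_id)} & {b.id}:
            return "grandparent-grandchild"
    for pid in pb:
        if {q for q in (ped[pid].father_id, ped[pid].mother_id)} & {a.id}:
            return "grandparent-grandchild"
    # avuncular: a parent of one is a full sibling of the other
    def full_sibs(x: Individual, y: Individual) -> bool:
        px = {x.father_id, x.mother_id} - {None}
        py = {y.father_id, y.mother_id} - {None}
        return bool(px) and px == py

    for pid in pa:
        if full_sibs(ped[pid], b):
            return "avuncular"
    for pid in pb:
        if full_sibs(ped[pid], a):
            return "avuncular"
    if np.isclose(two_phi, 0.25):
        return "double 1st cousins"
    for name, val in (
        ("3rd degree", 0.125),
        ("4th degree", 0.0625),
        ("5th degree", 0.03125),
        ("6th degree", 0.015625),
        ("7th degree", 0.0078125),
    ):
        if np.isclose(two_phi, val):
            return name
    if two_phi == 0.0:
        return "unrelated"
    return f"other (2phi={two_phi:g})"


def classify_pairs(kin: KinshipMatrix, ped: Pedigree) -> pd.DataFrame:
    """Count ordered-once relative pairs per (2*Phi value, relationship label).

    Pairs in the 0.5 and 0.25 classes are split into their structural
    relationships (parent-offspring vs siblings; grandparent vs avuncular vs
    half siblings vs double first cousins); deeper classes are binned purely
    by their 2*Phi value.  Counts over all classes, self pairs included, sum
    to ``n * (n + 1) / 2``.
    """
    n = len(kin.ids)
    counts: dict[tuple[float, str], int] = {}
    for i in range(n):
        for j in range(i, n):
            two_phi = float(kin.values[i, j])
            a, b = ped[kin.ids[i]], ped[kin.ids[j]]
            if a.family_id != b.family_id:
                label = "unrelated"
            else:
                label = _structural_label(ped, a, b, two_phi)
            key = (round(two_phi, 10), label)
            counts[key] = counts.get(key, 0) + 1
    out = pd.DataFrame(
        [(v, k[0], k[1]) for k, v in counts.items()],
        columns=["n_pairs", "2phi", "relation"],
    )
    return out.sort_values(["2phi", "relation"], ascending=[False, True]).reset_index(
        drop=True
    )
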