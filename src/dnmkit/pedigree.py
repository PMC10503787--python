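"""Pedigree structure: members, trios and full-sib groups.

The on-disk form is 6-column PED (family, id, father, mother, sex,
phenotype), with the phenotype column carrying a ``population:generation``
tag (e.g. ``pop1:F1``) — a documented dialect that lets one file describe
both the crossing design and the sampling populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

GENERATIONS = ("F0", "F1", "F2")


@dataclass(frozen=True)
class Member:
    id: str
    family: str
    sex: int  # 1 male, 2 female, 0 unknown
    father: str | None
    mother: str | None
    generation: str
    population: str = ""

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass(frozen=True)
class Trio:
    """Father, mother and one offspring — the unit of DNM screening."""

    father: str
    mother: str
    child: str
    family: str = ""

    @property
    def id(self) -> str:
        return self.child

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.father, self.mother, self.child)


class Pedigree:
    """A set of families with acyclic parent links.

    Every non-founder must have both parents present in the pedigree
    (consistency is validated at construction).
    """

    def __init__(self, members: Iterable[Member]) -> None:
        self.members: dict[str, Member] = {}
        for m in members:
            if m.id in self.members:
                raise ValueError(f"duplicate member id {m.id!r}")
            self.members[m.id] = m
        for m in self.members.values():
            parents = (m.father, m.mother)
            if sum(p is None for p in parents) == 1:
                raise ValueError(f"member {m.id!r} has exactly one parent")
            for p in parents:
                if p is not None and p not in self.members:
                    raise ValueError(f"member {m.id!r} references missing parent {p!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 1:
                raise ValueError(f"parent links contain a cycle through {mid!r}")
            if state.get(mid) == 2:
                return
            state[mid] = 1
            m = self.members[mid]
            for p in (m.father, m.mother):
                if p is not None:
                    visit(p)
            state[mid] = 2

        for mid in self.members:
            visit(mid)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, mid: str) -> bool:
        return mid in self.members

    def __getitem__(self, mid: str) -> Member:
        return self.members[mid]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.members)

    @property
    def founders(self) -> list[Member]:
        return [m for m in self.members.values() if m.is_founder]

    def trios(self) -> list[Trio]:
        """All (father, mother, offspring) units, in member order.

        In 3-generation families an F1 individual appears both as a trio
        offspring (with its F0 parents) and as a trio parent (of F2s).
        """
        out = []
        for m in self.members.values():
            if m.father is not None and m.mother is not None:
                out.append(Trio(m.father, m.mother, m.id, m.family))
        return out

    def full_sib_groups(self) -> list[list[str]]:
        """Groups of members sharing both parents (size ≥ 2 first)."""
        groups: dict[tuple[str, str], list[str]] = {}
        for m in self.members.values():
            if m.father is not None and m.mother is not None:
                groups.setdefault((m.father, m.mother), []).append(m.id)
        return sorted(groups.values(), key=lambda g: (-len(g), g[0]))

    def sib_group_of(self, mid: str) -> list[str]:
        m = self.members[mid]
        if m.father is None:
            return [mid]
        return [
            x.id
            for x in self.members.values()
            if x.father == m.father and x.mother == m.mother
        ]

    def offspring_of(self, mid: str) -> list[str]:
        return [
            m.id for m in self.members.values() if mid in (m.father, m.mother)
        ]

    def are_full_sibs(self, a: str, b: str) -> bool:
        ma, mb = self.members[a], self.members[b]
        return (
            a != b
            and ma.father is not None
            and (ma.father, ma.mother) == (mb.father, mb.mother)
        )

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for m in self.members.values():
            fams.setdefault(m.family, []).append(m.id)
        return fams
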