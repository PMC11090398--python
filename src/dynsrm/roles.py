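"""Family-role and dyad-type algebra.

A round-robin family design distinguishes members by role: mother (M),
father (F), younger child (S1) and older child (S2).  Every ordered pair of
distinct roles is a *directed* dyad type (actor -> partner); every unordered
pair is an *undirected* dyad type.  With the full four-role set there are 12
directed and 6 undirected dyad types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

ROLES: tuple[str, ...] = ("M", "F", "S1", "S2")
_ROLE_ORDER = {r: i for i, r in enumerate(ROLES)}


def check_role(label: str) -> str:
    if label not in _ROLE_ORDER:
        raise ValueError(f"unknown role {label!r}; admissible roles are {ROLES}")
    return label


@dataclass(frozen=True, order=True)
class DirectedDyad:
    """Ordered (actor, partner) pair of distinct roles, e.g. M -> F."""

    actor: str
    partner: str

    def __post_init__(self) -> None:
        check_role(self.actor)
        check_role(self.partner)
        if self.actor == self.partner:
            raise ValueError("actor and partner roles must differ")

    @property
    def reverse(self) -> "DirectedDyad":
        return DirectedDyad(self.partner, self.actor)

    @property
    def undirected(self) -> "UndirectedDyad":
        return UndirectedDyad.of(self.actor, self.partner)

    def __str__(self) -> str:  # "M.F" = mother acting towards father
        return f"{self.actor}.{self.partner}"

    @classmethod
    def parse(cls, s: str) -> "DirectedDyad":
        a, _, p = s.partition(".")
        return cls(a, p)


@dataclass(frozen=True, order=True)
class UndirectedDyad:
    """Unordered pair of distinct roles, stored in canonical role order."""

    first: str
    second: str

    def __post_init__(self) -> None:
        check_role(self.first)
        check_role(self.second)
        if self.first == self.second:
            raise ValueError("dyad members must differ")
        if _ROLE_ORDER[self.first] > _ROLE_ORDER[self.second]:
            raise ValueError(
                f"members out of canonical order; use UndirectedDyad.of({self.first!r}, {self.second!r})"
            )

    @classmethod
    def of(cls, a: str, b: str) -> "UndirectedDyad":
        if _ROLE_ORDER[check_role(a)] > _ROLE_ORDER[check_role(b)]:
            a, b = b, a
        return cls(a, b)

    @property
    def directed(self) -> tuple[DirectedDyad, DirectedDyad]:
        """The two directed dyad types of this pair (canonical direction first)."""
        return (DirectedDyad(self.first, self.second), DirectedDyad(self.second, self.first))

    def __str__(self) -> str:  # "M:F"
        return f"{self.first}:{self.second}"

    @classmethod
    def parse(cls, s: str) -> "UndirectedDyad":
        a, _, b = s.partition(":")
        return cls.of(a, b)


def directed_dyads(roles: Iterable[str] = ROLES) -> list[DirectedDyad]:
    """All ordered pairs of distinct roles, in canonical role order."""
    rs = sorted(set(roles), key=_ROLE_ORDER.__getitem__)
    return [DirectedDyad(a, p) for a in rs for p in rs if a != p]


def undirected_dyads(roles: Iterable[str] = ROLES) -> list[UndirectedDyad]:
    rs = sorted(set(roles), key=_ROLE_ORDER.__getitem__)
    return [UndirectedDyad(a, b) for i, a in enumerate(rs) for b in rs[i + 1 :]]


def check_composition(roles: Iterable[str]) -> tuple[str, ...]:
    """Validate a family composition: >= 2 distinct admissible roles."""
    rs = tuple(sorted(set(roles), key=_ROLE_ORDER.__getitem__))
    for r in rs:
        check_role(r)
    if len(rs) < 2:
        raise ValueError(f"a family composition needs at least two roles, got {rs}")
    return rs
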