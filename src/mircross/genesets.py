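"""Named gene/miRNA sets and the plain-text formats they travel in.

A :class:`GeneSet` holds a disease gene list (e.g. an HPO-term panel), a
background universe, or a set of miRNA identifiers — the urn colourings of
the enrichment tests.  Sets round-trip through GMT files (one set per
line: name, description, then members, tab-separated) and through plain
one-identifier-per-line lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = ["GeneSet", "read_gmt", "write_gmt", "read_id_list", "write_id_list"]


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free collection of identifiers.

    Membership is set-semantics; ``members`` preserves first-seen order so
    file output is deterministic.
    """

    name: str
    members: tuple[str, ...]
    description: str = ""
    _index: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for m in self.members:
            if m in seen:
                raise ValueError(f"duplicate identifier {m!r} in gene set {self.name!r}")
            seen[m] = None
        object.__setattr__(self, "members", tuple(seen))
        object.__setattr__(self, "_index", frozenset(seen))

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str], description: str = "") -> "GeneSet":
        # tolerate duplicates on ingestion; keep first occurrence
        seen: dict[str, None] = {}
        for m in members:
            seen.setdefault(m, None)
        return cls(name=name, members=tuple(seen), description=description)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self._index

    def __iter__(self):
        return iter(self.members)

    def intersect(self, other: Iterable[str], name: str | None = None) -> "GeneSet":
        other_set = other._index if isinstance(other, GeneSet) else set(other)
        return GeneSet.from_iterable(
            name or self.name, (m for m in self.members if m in other_set), self.description
        )

    def as_set(self) -> frozenset[str]:
        return self._index


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 member): {line!r}")
        sets.append(GeneSet.from_iterable(fields[0], fields[2:], description=fields[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description or "na", *s.members]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_id_list(path: str | Path, name: str | None = None) -> GeneSet:
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return GeneSet.from_iterable(name or Path(path).stem, ids)


def write_id_list(s: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(s.members) + "\n")
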