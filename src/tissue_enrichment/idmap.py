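"""Gene-name canonicalization: map user-supplied names to canonical gene IDs.

Users paste gene lists in whatever nomenclature they have — locus names
("unc-54"), sequence names, or canonical WBGene-style ids.  A local
alias->canonical mapping table resolves them; every input name is accounted
for exactly once, either in the mapped set or, verbatim, in the discarded
list (both are reported alongside results).  Matching is whitespace-trimmed
and case-insensitive; no fuzzy matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = ["GeneMapping", "MappingError", "canonicalize", "read_gene_list"]


class MappingError(ValueError):
    """Raised for unusable mapping tables or empty inputs."""


def _norm(name: str) -> str:
    return name.strip().casefold()


@dataclass
class GeneMapping:
    """Alias -> canonical gene id lookup.

    Aliases are stored case-normalized; each alias maps to exactly one
    canonical id, and canonical ids always map to themselves (an exact
    canonical id beats any synonym claiming the same spelling).
    """

    aliases: dict[str, str]
    source: str = "unspecified"

    @classmethod
    def from_tsv(cls, source: str | IO[str]) -> "GeneMapping":
        """Load a two-column ``alias<TAB>canonical_id`` table.

        Conflicting duplicate aliases (same alias, different canonical id)
        raise :class:`MappingError` naming the alias.
        """
        if isinstance(source, str):
            label, fh = source, open(source, encoding="utf-8")
        else:
            label, fh = getattr(source, "name", "stream"), source
        aliases: dict[str, str] = {}
        canonicals: set[str] = set()
        with_fh = fh
        for line_no, line in enumerate(with_fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise MappingError(
                    f"{label}, line {line_no}: expected 'alias<TAB>canonical_id'"
                )
            alias, canonical = parts[0].strip(), parts[1].strip()
            key = _norm(alias)
            if key in aliases and aliases[key] != canonical:
                raise MappingError(
                    f"alias {alias!r} maps to both {aliases[key]!r} and "
                    f"{canonical!r}"
                )
            aliases[key] = canonical
            canonicals.add(canonical)
        # canonical ids map to themselves, overriding any synonym claiming
        # the same spelling (exact-match priority)
        for canonical in canonicals:
            aliases[_norm(canonical)] = canonical
        if isinstance(source, str):
            fh.close()
        return cls(aliases=aliases, source=label)

    def get(self, name: str) -> str | None:
        return self.aliases.get(_norm(name))


def canonicalize(
    names: Iterable[str], mapping: GeneMapping
) -> tuple[set[str], list[str]]:
    """Resolve raw gene names against a mapping.

    Returns ``(mapped, discarded)``: the set of canonical ids found
    (duplicates collapse), and every unmapped input name verbatim, in input
    order.  An empty input list is an error.
    """
    names = [n for n in names if n.strip()]
    if not names:
        raise MappingError("empty gene list")
    mapped: set[str] = set()
    discarded: list[str] = []
    for raw in names:
        canonical = mapping.get(raw)
        if canonical is None:
            discarded.append(raw)
        else:
            mapped.add(canonical)
    return mapped, discarded


def read_gene_list(source: str | IO[str]) -> list[str]:
    """Read a plain-text gene list: one name per line, '#' comments ignored."""
    fh = open(source, encoding="utf-8") if isinstance(source, str) else source
    names = []
    for line in fh:
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            names.append(stripped)
    if isinstance(source, str):
        fh.close()
    return names
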