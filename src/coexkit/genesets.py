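"""Gene-set libraries (GMT) and protein-protein interaction edge lists."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeneSetLibrary",
    "GMTParseError",
    "PPINetwork",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
]


class GMTParseError(ValueError):
    """A GMT line does not have the required name/description/members columns."""


@dataclass
class GeneSetLibrary:
    """Named collections of gene symbols.

    ``sets`` maps set name to its member symbols; members are unique after
    case-folding (first spelling wins) and no set is empty.  ``provenance``
    is optional bookkeeping (e.g. planted-module origin for synthetic
    libraries) and does not affect any computation.
    """

    name: str
    sets: dict[str, list[str]]
    provenance: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for sname, members in self.sets.items():
            deduped = _dedupe_casefold(members)
            if not deduped:
                raise ValueError(f"gene set {sname!r} is empty")
            clean[sname] = deduped
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self) -> set[str]:
        """All member symbols, case-folded to uppercase."""
        return {g.upper() for members in self.sets.values() for g in members}


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network as an edge list.

    Edges are unordered symbol pairs; self-loops are rejected and
    duplicates (in either orientation, case-insensitively) are collapsed,
    keeping the first spelling encountered.
    """

    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        clean: list[tuple[str, str]] = []
        for a, b in self.edges:
            a, b = str(a), str(b)
            key = frozenset((a.upper(), b.upper()))
            if len(key) < 2:
                raise ValueError(f"self-loop edge {a!r}-{b!r} is not allowed")
            if key in seen:
                continue
            seen.add(key)
            clean.append((a, b))
        self.edges = clean

    def __len__(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> set[frozenset[str]]:
        """Case-folded unordered pairs, for set algebra across networks."""
        return {frozenset((a.upper(), b.upper())) for a, b in self.edges}

    def nodes(self) -> set[str]:
        return {x.upper() for e in self.edges for x in e}

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.edges:
            deg[a.upper()] = deg.get(a.upper(), 0) + 1
            deg[b.upper()] = deg.get(b.upper(), 0) + 1
        return deg


def _dedupe_casefold(symbols) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for s in symbols:
        s = str(s).strip()
        if not s:
            continue
        key = s.upper()
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def read_gmt(path: str, name: str | None = None) -> GeneSetLibrary:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>members...``.

    Comment lines starting with ``#`` and blank lines are skipped.  A line
    with fewer than three columns (i.e. a set with no members) raises
    :class:`GMTParseError` carrying the 1-based line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            members = [c for c in cols[2:] if c.strip()]
            if len(cols) < 3 or not members:
                raise GMTParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(cols)} column(s))"
                )
            sets[cols[0]] = members
    if not sets:
        raise GMTParseError(f"{path}: no gene sets found")
    import os

    return GeneSetLibrary(name=name or os.path.basename(path), sets=sets)


def write_gmt(lib: GeneSetLibrary, path: str) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        for sname, members in lib.sets.items():
            fh.write("\t".join([sname, lib.name] + list(members)) + "\n")
    return path


def read_edge_list(path: str) -> PPINetwork:
    """Parse a two-column tab-separated edge list; ``#`` lines are skipped.

    Duplicate edges in either orientation collapse to one; self-loops are
    dropped (a degenerate record, not a malformed file).
    """
    edges: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: edge line needs two tab-separated symbols"
                )
            a, b = cols[0].strip(), cols[1].strip()
            if a.upper() == b.upper():
                continue
            edges.append((a, b))
    return PPINetwork(edges=edges)


def write_edge_list(net: PPINetwork, path: str) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\n")
    return path
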