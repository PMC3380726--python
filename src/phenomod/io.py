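"""Readers for organismal association networks, protein-to-COG maps and panels.

Input dialects
--------------
* Network files follow the STRING ``protein.links`` convention: one edge per
  line, whitespace-delimited ``protein1 protein2 combined_score`` with the
  combined score an integer in [0, 1000].  A single header line is detected
  automatically (non-integer third field on the first line).
* The orthology mapping is a two-column TSV ``protein_id<TAB>cog_id``,
  optional header.
* The panel manifest is a three-column TSV
  ``organism_id<TAB>network_path<TAB>label`` with label ``expressing`` or
  ``non_expressing``; network paths are resolved relative to the manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

#: A COG-COG association, canonically ordered (first element < second).
CogPair = tuple[str, str]

EXPRESSING = "expressing"
NON_EXPRESSING = "non_expressing"
PANEL_LABELS = frozenset({EXPRESSING, NON_EXPRESSING})


class ParseError(ValueError):
    """A malformed line in one of the text inputs (message names the line)."""


class MappingConflictError(ValueError):
    """A protein assigned to two different COGs in the mapping table."""


def canonical_pair(u: str, v: str) -> CogPair:
    """Order an unordered identifier pair canonically (lexicographic)."""
    return (u, v) if u < v else (v, u)


@dataclass
class ProteinNetwork:
    """One organism's protein functional-association network.

    ``edges`` maps each canonical unordered protein pair to its best
    (maximum) combined score; self-edges are never stored.
    """

    organism_id: str
    edges: dict[CogPair, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class CogMapping:
    """Protein -> orthologous-group assignment (at most one COG per protein)."""

    entries: dict[str, str] = field(default_factory=dict)

    def get(self, protein_id: str) -> str | None:
        return self.entries.get(protein_id)

    @property
    def cogs(self) -> frozenset[str]:
        """The COG universe named by the mapping."""
        return frozenset(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CogNetwork:
    """An organism's network projected to COG level: a set of canonical,
    deduplicated COG pairs with distinct endpoints."""

    organism_id: str
    edges: frozenset[CogPair] = frozenset()

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class PanelEntry:
    organism_id: str
    path: Path
    label: str

    @property
    def is_expressing(self) -> bool:
        return self.label == EXPRESSING


def _data_lines(path: Path):
    """Yield (lineno, stripped line) skipping blanks and ``#`` comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(
    path: str | Path,
    score_cutoff: int = 700,
    organism_id: str | None = None,
) -> ProteinNetwork:
    """Parse a STRING-dialect links file, keeping edges scoring >= cutoff.

    Self-edges are dropped; duplicate unordered pairs are collapsed keeping
    the maximum score.  The organism id defaults to the filename stem.
    An empty result after filtering is a warning, not an error.
    """
    path = Path(path)
    org = organism_id if organism_id is not None else path.stem
    best: dict[CogPair, int] = {}
    n_lines = 0
    first_data_line = True
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: expected >=3 whitespace-delimited fields, "
                f"got {len(fields)}"
            )
        try:
            score = int(fields[2])
        except ValueError:
            if first_data_line:  # header row, e.g. "protein1 protein2 combined_score"
                first_data_line = False
                continue
            raise ParseError(
                f"{path}:{lineno}: third field {fields[2]!r} is not an integer score"
            ) from None
        first_data_line = False
        if not 0 <= score <= 1000:
            raise ParseError(f"{path}:{lineno}: score {score} outside [0, 1000]")
        n_lines += 1
        a, b = fields[0], fields[1]
        if a == b:
            continue
        key = canonical_pair(a, b)
        if score > best.get(key, -1):
            best[key] = score
    edges = {pair: s for pair, s in best.items() if s >= score_cutoff}
    logger.info(
        "read_network %s: %d data lines, %d edges retained at cutoff %d",
        org, n_lines, len(edges), score_cutoff,
    )
    if n_lines and not edges:
        logger.warning("read_network %s: no edges pass score cutoff %d", org, score_cutoff)
    return ProteinNetwork(organism_id=org, edges=edges)


_MAPPING_HEADER_TOKENS = {"protein", "protein_id", "cog", "cog_id", "#protein_id"}


def read_mapping(path: str | Path) -> CogMapping:
    """Read the protein -> COG TSV.

    Duplicate identical rows collapse silently; a protein mapped to two
    different COGs raises :class:`MappingConflictError` naming the proteins.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    conflicts: dict[str, set[str]] = {}
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        protein, cog = fields[0].strip(), fields[1].strip()
        if first:
            first = False
            if protein.lower() in _MAPPING_HEADER_TOKENS or cog.lower() in _MAPPING_HEADER_TOKENS:
                continue
        seen = entries.get(protein)
        if seen is not None and seen != cog:
            conflicts.setdefault(protein, {seen}).add(cog)
        entries[protein] = cog
    if conflicts:
        detail = "; ".join(
            f"{p} -> {{{', '.join(sorted(cs))}}}" for p, cs in sorted(conflicts.items())
        )
        raise MappingConflictError(
            f"{path}: conflicting COG assignments for protein(s): {detail}"
        )
    logger.info("read_mapping %s: %d proteins, %d COGs", path, len(entries), len(set(entries.values())))
    return CogMapping(entries=entries)


def project_to_cogs(net: ProteinNetwork, mapping: CogMapping) -> CogNetwork:
    """Collapse a protein network to COG level.

    A COG edge (u, v), u != v, exists iff some protein edge joins a protein
    of u to a protein of v (existential semantics).  Edges touching unmapped
    proteins are dropped (counted, logged); within-COG (paralog) edges are
    dropped; the result is canonical and deduplicated.
    """
    cog_edges: set[CogPair] = set()
    n_unmapped = 0
    n_self = 0
    for (x, y) in net.edges:
        u = mapping.get(x)
        v = mapping.get(y)
        if u is None or v is None:
            n_unmapped += 1
            continue
        if u == v:
            n_self += 1
            continue
        cog_edges.add(canonical_pair(u, v))
    if n_unmapped:
        logger.info(
            "project_to_cogs %s: dropped %d edges with unmapped proteins",
            net.organism_id, n_unmapped,
        )
    logger.info(
        "project_to_cogs %s: %d protein edges -> %d COG edges (%d within-COG dropped)",
        net.organism_id, len(net.edges), len(cog_edges), n_self,
    )
    return CogNetwork(organism_id=net.organism_id, edges=frozenset(cog_edges))


def read_manifest(path: str | Path) -> list[PanelEntry]:
    """Read the panel manifest; network paths resolve relative to it."""
    path = Path(path)
    entries: list[PanelEntry] = []
    seen: set[str] = set()
    first = True
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
        org, net_path, label = fields[0], fields[1], fields[2]
        if first:
            first = False
            if org.lower() in {"organism", "organism_id"}:
                continue
        if label not in PANEL_LABELS:
            raise ParseError(
                f"{path}:{lineno}: label {label!r} not in {sorted(PANEL_LABELS)}"
            )
        if org in seen:
            raise ParseError(f"{path}:{lineno}: duplicate organism_id {org!r}")
        seen.add(org)
        resolved = Path(net_path)
        if not resolved.is_absolute():
            resolved = path.parent / resolved
        entries.append(PanelEntry(organism_id=org, path=resolved, label=label))
    return entries
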